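"""Exception taxonomy shared across the package."""


class WoundscreenError(Exception):
    """Base class for all package-specific errors."""


class ImageValidationError(WoundscreenError):
    """Raised when a raster violates the image contracts (shape, range)."""


class StructuringElementError(WoundscreenError):
    """Raised for invalid structuring elements (memberships, origin, size)."""


class AxisUndeterminableError(WoundscreenError):
    """Raised when a wound axis is requested but fewer than two staple
    centroids are available."""


class InpaintError(WoundscreenError):
    """Raised when inpainting is impossible (e.g. the mask covers the
    whole image, leaving no boundary data)."""


class QuestionnaireError(WoundscreenError):
    """Base class for questionnaire validation failures."""


class IncompleteQuestionnaireError(QuestionnaireError):
    """A required answer is missing; the screening gate requires all items."""


class CodingError(QuestionnaireError):
    """An answer is present but outside its coding scheme (range/binary)."""


class MetricError(WoundscreenError):
    """Raised when a diagnostic metric is undefined for the given counts."""


class DegenerateMarginalsError(MetricError):
    """Both raters constant: chance agreement is 1 and kappa is undefined."""


class SceneError(WoundscreenError):
    """Raised when synthetic-scene parameters are geometrically invalid."""
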