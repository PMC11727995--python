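"""Core image types, HSV conversion and PNG/JPEG I/O.

The screening pipeline works on RGB wound photographs normalised to
``[0, 1]`` floats.  Redness is defined on hue/saturation/value, with hue in
degrees on the colour circle so that "close to red" is a symmetric circular
distance from 0°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import color as _skcolor

from .errors import ImageValidationError, StructuringElementError

#: Minimum side length (pixels) below which an image is flagged undersized.
#: Undersized photographs are analysed anyway; the flag feeds a warning.
MIN_SIDE_PX = 500


@dataclass(frozen=True)
class WoundImage:
    """An RGB wound photograph with provenance metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array with all channels in ``[0, 1]``.
    source_id
        Opaque identifier (patient/image code); the only identifier the
        pipeline ever logs.
    capture_tag
        Optional free-text capture annotation (e.g. visit day).
    """

    pixels: np.ndarray
    source_id: str = ""
    capture_tag: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageValidationError(
                f"expected (H, W, 3) raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageValidationError("image must have at least one pixel")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ImageValidationError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def undersized(self) -> bool:
        """True when min(width, height) is below the 500 px intake rule."""
        return min(self.width_px, self.height_px) < MIN_SIDE_PX


def to_hsv(image: WoundImage) -> np.ndarray:
    """Convert to HSV with hue in degrees.

    Returns an ``(H, W, 3)`` array of ``(hue_deg, saturation, value)`` with
    hue in ``[0, 360)``.  Achromatic pixels (saturation 0) get hue 0 by
    convention, making circular hue distance well defined everywhere.
    """
    hsv = _skcolor.rgb2hsv(image.pixels)
    out = hsv.copy()
    out[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    out[out[..., 1] == 0.0, 0] = 0.0
    return out


def load_image(path, source_id: str | None = None) -> WoundImage:
    """Read an 8-bit PNG/JPEG and scale to [0, 1] by division by 255."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return WoundImage(pixels=arr, source_id=source_id or str(path))


def save_image(image: WoundImage | np.ndarray, path) -> None:
    """Write an image (or bare [0,1] array) as 8-bit PNG/JPEG."""
    px = image.pixels if isinstance(image, WoundImage) else np.asarray(image)
    arr = np.clip(np.rint(px * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def as_gray_channel(values: np.ndarray) -> np.ndarray:
    """Validate a 2-D gray channel (float, range [0, 1]) and return it."""
    f = np.asarray(values, dtype=float)
    if f.ndim != 2:
        raise ImageValidationError(f"gray channel must be 2-D, got {f.shape}")
    if f.size == 0:
        raise ImageValidationError("gray channel must be non-empty")
    if f.min() < 0.0 or f.max() > 1.0:
        raise ImageValidationError("gray channel values must lie in [0, 1]")
    return f


@dataclass(frozen=True)
class StructuringElement:
    """A fuzzy structuring element: graded memberships with an origin.

    ``memberships`` is an ``(h, w)`` array in ``[0, 1]``; ``origin`` indexes
    into it.  At least one membership in the 3×3 neighbourhood of the origin
    must equal 1, so erosion/dilation behave as contractions/extensions of
    the probed image rather than arbitrary filters.
    """

    memberships: np.ndarray
    origin: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.memberships, dtype=float)
        if m.ndim != 2 or m.size == 0:
            raise StructuringElementError("memberships must be a non-empty 2-D raster")
        if m.min() < 0.0 or m.max() > 1.0:
            raise StructuringElementError("memberships must lie in [0, 1]")
        origin = self.origin
        if origin is None:
            origin = (m.shape[0] // 2, m.shape[1] // 2)
        r, c = origin
        if not (0 <= r < m.shape[0] and 0 <= c < m.shape[1]):
            raise StructuringElementError(f"origin {origin} outside {m.shape}")
        near = m[max(r - 1, 0): r + 2, max(c - 1, 0): c + 2]
        if not np.any(near == 1.0):
            raise StructuringElementError(
                "no membership equal to 1 at or adjacent to the origin"
            )
        object.__setattr__(self, "memberships", m)
        object.__setattr__(self, "origin", (int(r), int(c)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.memberships.shape  # type: ignore[return-value]

    @classmethod
    def flat(cls, size: int | tuple[int, int] = 3) -> "StructuringElement":
        """Crisp flat square (or rectangular) element, centred origin."""
        if isinstance(size, int):
            size = (size, size)
        return cls(np.ones(size))

    @classmethod
    def line(cls, length: int, angle_deg: float, thickness: int = 1) -> "StructuringElement":
        """Crisp oriented linear element of the given length and angle.

        The angle is measured from the +column axis toward +row, matching
        the orientation convention used for staples and the wound axis.
        """
        if length < 1:
            raise StructuringElementError("line length must be >= 1")
        half = (length - 1) / 2.0
        n = int(np.ceil(length)) | 1
        rr, cc = np.mgrid[0:n, 0:n] - n // 2
        theta = np.deg2rad(angle_deg)
        d_row, d_col = np.sin(theta), np.cos(theta)
        along = rr * d_row + cc * d_col
        perp = -rr * d_col + cc * d_row
        m = ((np.abs(along) <= half) & (np.abs(perp) <= thickness / 2.0)).astype(float)
        m[n // 2, n // 2] = 1.0
        return cls(m)


class FuzzyLogicPair:
    """A t-norm together with its residual implication.

    The conjunction ``C`` must be a t-norm (commutative, associative,
    monotone, identity 1); the implication is its residuum
    ``I(a, b) = sup {c : C(a, c) <= b}``.  With the minimum t-norm the
    residuum is the Gödel implication and the fuzzy operators reduce to
    classical flat morphology on crisp elements.
    """

    def __init__(self, name: str, conjunction, implication) -> None:
        self.name = name
        self._conj = conjunction
        self._impl = implication

    def conjunction(self, a, b):
        return self._conj(np.asarray(a, dtype=float), np.asarray(b, dtype=float))

    def implication(self, a, b):
        return self._impl(np.asarray(a, dtype=float), np.asarray(b, dtype=float))

    def __repr__(self) -> str:  # pragma: no cover
        return f"FuzzyLogicPair({self.name!r})"


def _godel_impl(a, b):
    return np.where(a <= b, 1.0, b)


def _luk_conj(a, b):
    return np.maximum(0.0, a + b - 1.0)


def _luk_impl(a, b):
    return np.minimum(1.0, 1.0 - a + b)


#: Minimum t-norm with Gödel residuum (default; classical flat morphology
#: on crisp elements).
GODEL = FuzzyLogicPair("godel", np.minimum, _godel_impl)

#: Łukasiewicz pair, kept as the alternative graded logic.
LUKASIEWICZ = FuzzyLogicPair("lukasiewicz", _luk_conj, _luk_impl)

_LOGICS = {"godel": GODEL, "minimum": GODEL, "lukasiewicz": LUKASIEWICZ}


def get_logic(name: str | FuzzyLogicPair) -> FuzzyLogicPair:
    if isinstance(name, FuzzyLogicPair):
        return name
    try:
        return _LOGICS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown fuzzy logic {name!r}; choose from {sorted(set(_LOGICS))}"
        ) from None
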