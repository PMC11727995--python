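"""Erythema quantification: the redness proportion and its cutoff.

An image-level infection score is the proportion of peri-wound pixels
whose colour is "close to red".  Closeness is a trapezoidal fuzzy
membership on circular hue distance from 0°, gated by minimum saturation
and value so that shadows and desaturated skin do not count.  The default
positivity cutoff on the proportion is 0.63, the operating point selected
by ROC analysis in the original clinical calibration; it is exposed as a
configurable constant because it was fitted to one study's photographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import WoundImage, to_hsv

#: Clinical-calibration default cutoff on the redness proportion.
DEFAULT_THRESHOLD = 0.63


@dataclass(frozen=True)
class RedMembershipParams:
    """Trapezoidal "close to red" membership on the hue circle.

    Membership is 1 for circular hue distance ≤ ``hue_full_deg``, 0 for
    distance ≥ ``hue_zero_deg``, linear in between, and forced to 0 when
    saturation < ``min_saturation`` or value < ``min_value``.
    """

    hue_center_deg: float = 0.0
    hue_full_deg: float = 10.0
    hue_zero_deg: float = 30.0
    min_saturation: float = 0.25
    min_value: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_full_deg <= self.hue_zero_deg <= 180.0):
            raise ValueError("require 0 <= hue_full_deg <= hue_zero_deg <= 180")
        for name in ("min_saturation", "min_value"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class RednessResult:
    """Redness proportion over an ROI, optionally classified."""

    proportion: float
    roi_pixel_count: int
    method: str
    threshold: float | None = None
    positive: bool | None = None

    def classified(self, threshold: float = DEFAULT_THRESHOLD) -> "RednessResult":
        return RednessResult(
            proportion=self.proportion,
            roi_pixel_count=self.roi_pixel_count,
            method=self.method,
            threshold=threshold,
            positive=classify_redness(self.proportion, threshold),
        )

    def to_dict(self) -> dict:
        return {
            "proportion": self.proportion,
            "roi_pixel_count": self.roi_pixel_count,
            "method": self.method,
            "threshold": self.threshold,
            "positive": self.positive,
        }


def red_membership(hsv, params: RedMembershipParams | None = None) -> np.ndarray:
    """Degree in [0, 1] to which HSV pixels are close to red.

    Accepts a single ``(hue_deg, sat, val)`` triple or an ``(..., 3)``
    array; vectorised over leading dimensions.
    """
    params = params or RedMembershipParams()
    arr = np.asarray(hsv, dtype=float)
    hue, sat, val = arr[..., 0], arr[..., 1], arr[..., 2]
    d = np.abs((hue - params.hue_center_deg + 180.0) % 360.0 - 180.0)
    if params.hue_zero_deg == params.hue_full_deg:
        ramp = (d <= params.hue_full_deg).astype(float)
    else:
        ramp = np.clip(
            (params.hue_zero_deg - d) / (params.hue_zero_deg - params.hue_full_deg),
            0.0,
            1.0,
        )
    gate = (sat >= params.min_saturation) & (val >= params.min_value)
    return ramp * gate


def redness_proportion(
    image: WoundImage,
    roi: np.ndarray,
    params: RedMembershipParams | None = None,
    method: str = "crisp",
) -> RednessResult:
    """Proportion of near-red pixels in the ROI (unclassified result).

    ``crisp`` counts pixels with membership ≥ 0.5; ``weighted`` averages
    the membership itself (used for sensitivity analyses where a graded
    response is preferable to a count).
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.pixels.shape[:2]:
        raise ValueError(f"ROI shape {roi.shape} does not match image")
    n = int(roi.sum())
    if n == 0:
        raise ValueError("empty ROI: redness proportion undefined")
    if method not in ("crisp", "weighted"):
        raise ValueError(f"unknown method {method!r}")
    mu = red_membership(to_hsv(image)[roi], params)
    prop = float((mu >= 0.5).mean()) if method == "crisp" else float(mu.mean())
    return RednessResult(proportion=prop, roi_pixel_count=n, method=method)


def classify_redness(proportion: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Image-level call: positive iff proportion ≥ threshold.

    A tie at the threshold counts positive — the screening is
    sensitivity-first, so borderline images go to in-person review.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return proportion >= threshold


def score_redness(
    image: WoundImage,
    roi: np.ndarray,
    params: RedMembershipParams | None = None,
    method: str = "crisp",
    threshold: float = DEFAULT_THRESHOLD,
) -> RednessResult:
    """Convenience: proportion plus the binary call in one result."""
    return redness_proportion(image, roi, params, method).classified(threshold)
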