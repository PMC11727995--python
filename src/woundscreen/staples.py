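"""Staple localisation, wound-axis estimation, peri-wound ROI, inpainting.

Metallic staples are the brightest thin elongated structures in a stapled
wound photograph.  The detector extracts them from a "metallic sheen"
channel (value × (1 − saturation), bright *and* achromatic) with a fuzzy
white top-hat, thresholds the response and keeps connected components that
are small and elongated.  Staples straddle the incision, so the wound axis
is the total-least-squares line through the staple centroids, and the
peri-wound region of interest is a band around that axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

from .errors import AxisUndeterminableError, ImageValidationError, InpaintError
from .imaging import StructuringElement, WoundImage, to_hsv
from .morphology import top_hat


@dataclass(frozen=True)
class StapleComponent:
    """One detected staple: its pixels and shape summary."""

    coords: np.ndarray          # (n, 2) array of (row, col) pixels
    centroid: tuple[float, float]
    length_px: float            # major-axis extent
    orientation_deg: float      # [0, 180), from +col axis toward +row

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class WoundAxis:
    """A line: a point on it and a unit direction (row, col)."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def perpendicular_distance(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr, dc = self.direction
        nr, nc = -dc, dr  # unit normal
        return np.abs((rows - self.point[0]) * nr + (cols - self.point[1]) * nc)

    @property
    def angle_deg(self) -> float:
        ang = np.degrees(np.arctan2(self.direction[0], self.direction[1]))
        return float(ang % 180.0)


@dataclass(frozen=True)
class StapleDetection:
    staple_mask: np.ndarray
    components: list[StapleComponent]
    wound_axis: WoundAxis | None
    roi_mask: np.ndarray | None
    params: "StapleParams"

    def to_report(self) -> dict:
        """JSON-serialisable detection report."""
        return {
            "n_staples": len(self.components),
            "components": [
                {
                    "centroid": list(map(float, c.centroid)),
                    "length_px": float(c.length_px),
                    "orientation_deg": float(c.orientation_deg),
                    "area": c.area,
                }
                for c in self.components
            ],
            "wound_axis": None
            if self.wound_axis is None
            else {
                "point": list(map(float, self.wound_axis.point)),
                "direction": list(map(float, self.wound_axis.direction)),
                "angle_deg": self.wound_axis.angle_deg,
            },
            "params": self.params.to_dict(),
        }


@dataclass(frozen=True)
class StapleParams:
    """Detection knobs.

    ``se_size``: flat structuring-element side for the top-hat; must exceed
    the staple thickness so staples cannot contain it.
    ``brightness_threshold``: minimum top-hat response on the sheen channel.
    ``min_area`` / ``max_area_frac``: component area gate (absolute px /
    fraction of the image area).
    ``min_elongation``: major/minor axis ratio gate for thin bars.
    ``roi_halfwidth_px``: peri-wound band half-width; ``None`` means
    2 × median detected staple length.
    """

    se_size: int = 7
    brightness_threshold: float = 0.15
    min_area: int = 20
    max_area_frac: float = 0.01
    min_elongation: float = 2.5
    roi_halfwidth_px: float | None = None
    logic: str = "godel"

    def to_dict(self) -> dict:
        return {
            "se_size": self.se_size,
            "brightness_threshold": self.brightness_threshold,
            "min_area": self.min_area,
            "max_area_frac": self.max_area_frac,
            "min_elongation": self.min_elongation,
            "roi_halfwidth_px": self.roi_halfwidth_px,
            "logic": self.logic,
        }


def _orientation_and_length(coords: np.ndarray) -> tuple[float, float]:
    """Principal-axis orientation [0,180) and extent of a pixel set."""
    pts = coords.astype(float)
    centered = pts - pts.mean(axis=0)
    if len(pts) == 1:
        return 0.0, 1.0
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    d_row, d_col = evecs[:, int(np.argmax(evals))]
    ang = float(np.degrees(np.arctan2(d_row, d_col)) % 180.0)
    proj = centered @ np.array([d_row, d_col])
    length = float(proj.max() - proj.min()) + 1.0
    return ang, length


def detect_staples(image: WoundImage, params: StapleParams | None = None) -> StapleDetection:
    """Locate staples and derive the wound axis and peri-wound ROI.

    Deterministic: identical image and params give identical output.  With
    fewer than two staples the axis (and hence the ROI) is absent and the
    caller falls back to a whole-image ROI.
    """
    params = params or StapleParams()
    hsv = to_hsv(image)
    sheen = hsv[..., 2] * (1.0 - hsv[..., 1])
    se = StructuringElement.flat(params.se_size)
    response = top_hat(sheen, se, params.logic)
    binary = response >= params.brightness_threshold

    labels = measure.label(binary, connectivity=2)
    max_area = params.max_area_frac * image.height_px * image.width_px
    components: list[StapleComponent] = []
    for region in measure.regionprops(labels):
        if not (params.min_area <= region.area <= max_area):
            continue
        minor = max(region.axis_minor_length, 1.0)
        if region.axis_major_length / minor < params.min_elongation:
            continue
        coords = region.coords
        ang, length = _orientation_and_length(coords)
        components.append(
            StapleComponent(
                coords=coords,
                centroid=tuple(map(float, region.centroid)),
                length_px=length,
                orientation_deg=ang,
            )
        )
    # row-major order by centroid for deterministic downstream behaviour
    components.sort(key=lambda c: c.centroid)

    mask = np.zeros(binary.shape, dtype=bool)
    for c in components:
        mask[c.coords[:, 0], c.coords[:, 1]] = True

    axis = roi = None
    if len(components) >= 2:
        axis = estimate_wound_axis([c.centroid for c in components])
        halfwidth = params.roi_halfwidth_px
        if halfwidth is None:
            halfwidth = 2.0 * float(np.median([c.length_px for c in components]))
        roi = wound_roi(axis, halfwidth, mask.shape)
    return StapleDetection(mask, components, axis, roi, params)


def estimate_wound_axis(centroids) -> WoundAxis:
    """Total-least-squares line through staple centroids.

    The direction is the principal eigenvector of the centroid scatter,
    sign-normalised so its first nonzero component is positive.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise AxisUndeterminableError(
            f"axis undeterminable: need >= 2 staple centroids, got {len(pts)}"
        )
    mean = pts.mean(axis=0)
    centered = pts - mean
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, int(np.argmax(evals))]
    for comp in direction:
        if comp != 0.0:
            if comp < 0.0:
                direction = -direction
            break
    return WoundAxis(point=tuple(map(float, mean)), direction=tuple(map(float, direction)))


def wound_roi(axis: WoundAxis, band_halfwidth_px: float, shape: tuple[int, int]) -> np.ndarray:
    """Band of pixels within ``band_halfwidth_px`` of the wound axis."""
    if band_halfwidth_px < 0:
        raise ValueError("band_halfwidth_px must be >= 0")
    rows, cols = np.mgrid[0: shape[0], 0: shape[1]]
    return axis.perpendicular_distance(rows.astype(float), cols.astype(float)) <= band_halfwidth_px


def inpaint_staples(
    image: WoundImage,
    staple_mask: np.ndarray,
    max_iterations: int = 500,
    tol: float = 1e-5,
    margin: int = 8,
) -> WoundImage:
    """Reconstruct the image under the staple mask by diffusion.

    Masked pixels are repeatedly replaced by their 4-neighbour mean until
    the largest change falls below ``tol`` or the iteration cap is hit —
    the harmonic (Laplace) fill with the unmasked pixels as boundary data.
    Pixels outside the mask are never modified.  An empty mask returns the
    input unchanged, bit for bit.
    """
    mask = np.asarray(staple_mask, dtype=bool)
    if mask.shape != image.pixels.shape[:2]:
        raise ImageValidationError(
            f"mask shape {mask.shape} does not match image {image.pixels.shape[:2]}"
        )
    if not mask.any():
        return WoundImage(image.pixels.copy(), image.source_id, image.capture_tag)
    if mask.all():
        raise InpaintError("mask covers the entire image; no boundary data")

    out = image.pixels.copy()
    kernel = np.array([[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]])
    labeled, _ = ndimage.label(mask)
    for sl in ndimage.find_objects(labeled):
        rs = slice(max(sl[0].start - margin, 0), min(sl[0].stop + margin, mask.shape[0]))
        cs = slice(max(sl[1].start - margin, 0), min(sl[1].stop + margin, mask.shape[1]))
        sub_mask = mask[rs, cs]
        sub = out[rs, cs]
        known = sub[~sub_mask]
        sub[sub_mask] = known.mean(axis=0) if known.size else 0.5
        for _ in range(max_iterations):
            avg = ndimage.convolve(sub, kernel[..., None], mode="nearest")
            delta = np.abs(avg[sub_mask] - sub[sub_mask]).max()
            sub[sub_mask] = avg[sub_mask]
            if delta < tol:
                break
        out[rs, cs] = sub
    np.clip(out, 0.0, 1.0, out=out)
    out[~mask] = image.pixels[~mask]  # guarantee unmasked pixels untouched
    return WoundImage(out, image.source_id, image.capture_tag)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as single-channel PNG (0/255)."""
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def load_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) >= 128


def save_report(detection: StapleDetection, path) -> None:
    with open(path, "w") as fh:
        json.dump(detection.to_report(), fh, indent=2)
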