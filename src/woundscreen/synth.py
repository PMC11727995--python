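"""Seeded synthetic wound-photograph generator with ground truth.

Emulates the imaging setting of staple-closed abdominal wounds
photographed by patients' phones: a skin-tone background with Gaussian
texture, a linear incision, metallic staples crossing it perpendicular to
the incision axis, peri-incisional erythema whose red shift scales with an
intensity parameter and decays with distance from the axis, and optional
confounders (coloured antiseptic stains, a dressing edge).  Every image
comes with its ground truth (staple mask and centroids, incision axis,
erythema intensity, infection label), so detection and classification can
be validated without patient data.

The erythema colour shift uses a square-law amplitude in the intensity
parameter: mild erythema is visually faint, and only intensities past the
generative infection cutoff push peri-wound hue inside the "close to red"
band.  Cohorts pair every image with a questionnaire drawn from per-item
Bernoulli models (infected vs not).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SceneError
from .imaging import WoundImage, save_image
from .staples import WoundAxis, save_mask

#: Intensity above which a synthetic wound is labelled infected.
GENERATIVE_INFECTION_CUTOFF = 0.5


@dataclass(frozen=True)
class WoundSceneParams:
    """Full description of one synthetic wound scene (seed included)."""

    image_size: tuple[int, int] = (512, 512)
    skin_rgb: tuple[float, float, float] = (0.75, 0.62, 0.50)
    skin_noise_sd: float = 0.02
    incision_center: tuple[float, float] | None = None  # default: image centre
    incision_orientation_deg: float = 0.0
    incision_length_px: float = 300.0
    incision_width_px: float = 3.0
    incision_rgb: tuple[float, float, float] = (0.45, 0.20, 0.18)
    n_staples: int = 6
    staple_spacing_px: float = 40.0
    staple_length_px: float = 22.0
    staple_width_px: float = 3.0
    staple_brightness: float = 0.92
    staple_jitter_px: float = 1.5
    erythema_intensity: float = 0.0
    erythema_halfwidth_px: float = 30.0
    erythema_rgb: tuple[float, float, float] = (0.82, 0.26, 0.26)
    erythema_gamma: float = 2.0
    stain_probability: float = 0.0
    stain_rgb: tuple[float, float, float] = (0.72, 0.35, 0.20)
    dressing_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] < 1 or self.image_size[1] < 1:
            raise SceneError("image_size must be positive")
        if not (0.0 <= self.erythema_intensity <= 1.0):
            raise SceneError("erythema_intensity must lie in [0, 1]")
        if self.n_staples < 0:
            raise SceneError("n_staples must be >= 0")
        for p in ("stain_probability", "dressing_probability"):
            if not (0.0 <= getattr(self, p) <= 1.0):
                raise SceneError(f"{p} must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    staple_mask: np.ndarray
    staple_centroids: np.ndarray  # (n, 2) of (row, col)
    incision_axis: WoundAxis
    erythema_intensity: float
    infected_label: int


def _axis_frame(params: WoundSceneParams):
    H, W = params.image_size
    center = params.incision_center or ((H - 1) / 2.0, (W - 1) / 2.0)
    theta = np.deg2rad(params.incision_orientation_deg)
    d = np.array([np.sin(theta), np.cos(theta)])   # along-axis unit (row, col)
    n = np.array([-d[1], d[0]])                    # perpendicular unit
    return np.asarray(center, dtype=float), d, n


def generate_wound_image(params: WoundSceneParams) -> tuple[WoundImage, GroundTruth]:
    """Render one wound scene; byte-identical for identical params."""
    H, W = params.image_size
    rng = np.random.default_rng(params.seed)
    center, d, n = _axis_frame(params)

    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    u = (rows - center[0]) * d[0] + (cols - center[1]) * d[1]   # along axis
    v = (rows - center[0]) * n[0] + (cols - center[1]) * n[1]   # across axis

    img = np.empty((H, W, 3))
    img[:] = params.skin_rgb
    img += rng.normal(0.0, params.skin_noise_sd, size=(H, W, 3))

    # peri-incisional erythema: square-law amplitude, Gaussian cross-axis
    # decay, soft falloff past the incision ends
    if params.erythema_intensity > 0.0:
        sigma = params.erythema_halfwidth_px
        overhang = np.maximum(0.0, np.abs(u) - params.incision_length_px / 2.0)
        amp = (
            params.erythema_intensity ** params.erythema_gamma
            * np.exp(-(v ** 2) / (2.0 * sigma ** 2))
            * np.exp(-(overhang ** 2) / (2.0 * 15.0 ** 2))
        )
        img += amp[..., None] * (np.asarray(params.erythema_rgb) - img)

    # incision line
    on_incision = (np.abs(v) <= params.incision_width_px / 2.0) & (
        np.abs(u) <= params.incision_length_px / 2.0
    )
    img[on_incision] = params.incision_rgb

    # antiseptic stains / dressing edge confounders
    if params.stain_probability > 0.0 and rng.random() < params.stain_probability:
        # antiseptic is painted along the incision: stain centres cluster
        # on the wound axis, which is what confounds the redness reading
        for _ in range(rng.integers(1, 4)):
            su = rng.uniform(-params.incision_length_px / 2.0, params.incision_length_px / 2.0)
            sv = rng.normal(0.0, params.erythema_halfwidth_px)
            cr, cc = center + su * d + sv * n
            radius = rng.uniform(0.06, 0.12) * min(H, W)
            dist2 = (rows - cr) ** 2 + (cols - cc) ** 2
            blend = 0.85 * np.exp(-dist2 / (2.0 * radius ** 2))
            img += blend[..., None] * (np.asarray(params.stain_rgb) - img)
    if params.dressing_probability > 0.0 and rng.random() < params.dressing_probability:
        strip = int(0.08 * H)
        edge = rng.integers(0, 4)
        sl = {
            0: (slice(0, strip), slice(None)),
            1: (slice(H - strip, H), slice(None)),
            2: (slice(None), slice(0, strip)),
            3: (slice(None), slice(W - strip, W)),
        }[edge]
        img[sl] = 0.95

    # staples: bright bars perpendicular to the incision, evenly spaced
    staple_mask = np.zeros((H, W), dtype=bool)
    centroids = []
    for k in range(params.n_staples):
        offset = (k - (params.n_staples - 1) / 2.0) * params.staple_spacing_px
        offset += rng.uniform(-params.staple_jitter_px, params.staple_jitter_px)
        pos = center + offset * d
        half = params.staple_length_px / 2.0
        for endpoint in (pos + half * n, pos - half * n):
            if not (0 <= endpoint[0] <= H - 1 and 0 <= endpoint[1] <= W - 1):
                raise SceneError(
                    f"staple {k} endpoint {endpoint} falls outside the image"
                )
        bar = (np.abs(u - offset) <= params.staple_width_px / 2.0) & (np.abs(v) <= half)
        staple_mask |= bar
        img[bar] = params.staple_brightness + rng.normal(0.0, 0.01, (int(bar.sum()), 3))
        centroids.append(tuple(pos))

    np.clip(img, 0.0, 1.0, out=img)
    truth = GroundTruth(
        staple_mask=staple_mask,
        staple_centroids=np.asarray(centroids, dtype=float).reshape(-1, 2),
        incision_axis=WoundAxis(point=tuple(center), direction=tuple(d)),
        erythema_intensity=params.erythema_intensity,
        infected_label=int(params.erythema_intensity > GENERATIVE_INFECTION_CUTOFF),
    )
    image = WoundImage(img, source_id=f"synth-{params.seed}")
    return image, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class EffectParams:
    """Separation between infected and non-infected generative regimes.

    Erythema intensities are uniform on disjoint intervals straddling the
    generative infection cutoff; questionnaire items are per-item
    Bernoulli, with VAS = base + Binomial.
    """

    erythema_negative: tuple[float, float] = (0.05, 0.35)
    erythema_positive: tuple[float, float] = (0.65, 0.95)
    symptom_p_infected: dict = field(
        default_factory=lambda: {
            "redness": 0.85,
            "burning": 0.60,
            "opening": 0.25,
            "swelling": 0.60,
            "secretion": 0.55,
            "fever": 0.50,
        }
    )
    symptom_p_clean: dict = field(
        default_factory=lambda: {
            "redness": 0.08,
            "burning": 0.08,
            "opening": 0.03,
            "swelling": 0.08,
            "secretion": 0.05,
            "fever": 0.04,
        }
    )
    vas_infected: tuple[int, int, float] = (3, 7, 0.5)   # base + Binomial(n, p)
    vas_clean: tuple[int, int, float] = (0, 4, 0.3)


@dataclass(frozen=True)
class CohortImage:
    """One manifest row: scene parameters plus paired questionnaire."""

    image_id: str
    patient_code: str
    visit_day: int
    infected: int
    scene: WoundSceneParams
    questionnaire: dict

    def render(self) -> tuple[WoundImage, GroundTruth]:
        return generate_wound_image(self.scene)


@dataclass(frozen=True)
class CohortBundle:
    rows: list[CohortImage]
    seed: int
    n_patients: int
    prevalence: float
    effect: EffectParams
    scene_defaults: WoundSceneParams = field(default_factory=WoundSceneParams)
    images_per_patient: int = 2

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": r.image_id,
                    "patient_code": r.patient_code,
                    "visit_day": r.visit_day,
                    "infected": r.infected,
                    "erythema_intensity": r.scene.erythema_intensity,
                    "image_file": f"images/{r.image_id}.png",
                    "mask_file": f"masks/{r.image_id}.png",
                    "questionnaire_file": f"questionnaires/{r.image_id}.json",
                }
                for r in self.rows
            ]
        )

    def write(self, outdir) -> Path:
        """Materialise the cohort: images/, masks/, questionnaires/,
        manifest.csv and params.json (exact reproduction record)."""
        out = Path(outdir)
        for sub in ("images", "masks", "questionnaires"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        for row in self.rows:
            image, truth = row.render()
            save_image(image, out / "images" / f"{row.image_id}.png")
            save_mask(truth.staple_mask, out / "masks" / f"{row.image_id}.png")
            with open(out / "questionnaires" / f"{row.image_id}.json", "w") as fh:
                json.dump(row.questionnaire, fh, indent=2)
        self.manifest().to_csv(out / "manifest.csv", index=False)
        with open(out / "params.json", "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "n_patients": self.n_patients,
                    "prevalence": self.prevalence,
                    "images_per_patient": self.images_per_patient,
                    "effect": asdict(self.effect),
                    "scene_defaults": asdict(self.scene_defaults),
                },
                fh,
                indent=2,
            )
        return out


def _draw_questionnaire(rng, infected: bool, effect: EffectParams, patient_code: str) -> dict:
    probs = effect.symptom_p_infected if infected else effect.symptom_p_clean
    items = {k: int(rng.random() < p) for k, p in probs.items()}
    base, n, p = effect.vas_infected if infected else effect.vas_clean
    vas = int(min(10, base + rng.binomial(n, p)))
    if items["fever"]:
        temp = float(np.round(rng.uniform(37.8, 39.5), 1))
    else:
        temp = float(np.round(rng.uniform(36.0, 37.4), 1))
    record = {"vas": vas, "temperature_c": temp, "patient_code": patient_code}
    record.update(items)
    del record["fever"]  # fever coded from the raw temperature
    return record


def generate_cohort(
    n_patients: int,
    prevalence: float = 0.122,
    images_per_patient: int = 2,
    effect: EffectParams | None = None,
    seed: int = 0,
    scene_defaults: WoundSceneParams | None = None,
) -> CohortBundle:
    """Plan a seeded synthetic cohort (images rendered lazily).

    Each patient is infected with probability ``prevalence``; infected
    patients draw erythema intensity from the positive interval and
    symptom-rich questionnaires, non-infected from the negative interval.
    Visits mirror the day-3 / day-10 follow-up schedule.  The default
    prevalence matches a typical abdominal-surgery infection rate (~12%).
    """
    if not (0.0 <= prevalence <= 1.0):
        raise SceneError(f"prevalence {prevalence} outside [0, 1]")
    if n_patients < 1:
        raise SceneError("n_patients must be >= 1")
    effect = effect or EffectParams()
    base = scene_defaults or WoundSceneParams()
    rng = np.random.default_rng(seed)
    days = [3, 10] if images_per_patient == 2 else list(range(1, images_per_patient + 1))

    rows: list[CohortImage] = []
    for i in range(n_patients):
        code = f"P{i:04d}"
        infected = bool(rng.random() < prevalence)
        lo, hi = effect.erythema_positive if infected else effect.erythema_negative
        e_base = rng.uniform(lo, hi)
        orientation = float(rng.uniform(0.0, 180.0))
        for day in days:
            e = float(np.clip(e_base + rng.normal(0.0, 0.03), lo, hi))
            scene = replace(
                base,
                erythema_intensity=e,
                incision_orientation_deg=orientation,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            rows.append(
                CohortImage(
                    image_id=f"{code}_d{day:02d}",
                    patient_code=code,
                    visit_day=day,
                    infected=int(infected),
                    scene=scene,
                    questionnaire=_draw_questionnaire(rng, infected, effect, code),
                )
            )
    return CohortBundle(
        rows=rows,
        seed=seed,
        n_patients=n_patients,
        prevalence=prevalence,
        effect=effect,
        scene_defaults=base,
        images_per_patient=images_per_patient,
    )


def scene_params_from_dict(data: dict) -> WoundSceneParams:
    """Rebuild scene parameters from a params.json record (lists → tuples)."""
    clean = dict(data)
    for key in (
        "image_size",
        "skin_rgb",
        "incision_center",
        "incision_rgb",
        "erythema_rgb",
        "stain_rgb",
    ):
        if clean.get(key) is not None:
            clean[key] = tuple(clean[key])
    return WoundSceneParams(**clean)
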