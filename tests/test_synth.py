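"""Synthetic scene/cohort generator: determinism, ground truth, and the
generative effects the screening pipeline is validated against."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage, stats

from woundscreen import (
    EffectParams,
    RunConfig,
    WoundImage,
    WoundSceneParams,
    analyze_image,
    generate_cohort,
    generate_wound_image,
    redness_proportion,
)
from woundscreen.errors import SceneError
from woundscreen.synth import GENERATIVE_INFECTION_CUTOFF, scene_params_from_dict


def test_identical_params_give_byte_identical_images(small_scene):
    p = small_scene(erythema_intensity=0.6, stain_probability=0.5, seed=42)
    img1, t1 = generate_wound_image(p)
    img2, t2 = generate_wound_image(p)
    assert np.array_equal(img1.pixels, img2.pixels)
    assert np.array_equal(t1.staple_mask, t2.staple_mask)
    assert np.array_equal(t1.staple_centroids, t2.staple_centroids)


def test_truth_mask_has_requested_staple_count(small_scene):
    _, truth = generate_wound_image(small_scene(n_staples=7, seed=1))
    _, n = ndimage.label(truth.staple_mask)
    assert n == 7
    assert truth.staple_centroids.shape == (7, 2)
    H, W = 256, 256
    assert np.all((truth.staple_centroids >= 0) & (truth.staple_centroids <= [H - 1, W - 1]))


def test_infection_label_follows_generative_cutoff(small_scene):
    for e in (0.2, 0.5, 0.51, 0.9):
        _, truth = generate_wound_image(small_scene(erythema_intensity=e, seed=0))
        assert truth.infected_label == int(e > GENERATIVE_INFECTION_CUTOFF)


def test_erythema_raises_redness_proportion(small_scene):
    img0, t0 = generate_wound_image(small_scene(erythema_intensity=0.0, seed=8))
    img1, _ = generate_wound_image(small_scene(erythema_intensity=1.0, seed=8))
    a0 = analyze_image(img0).redness.proportion
    a1 = analyze_image(img1).redness.proportion
    assert a1 > a0


def test_redness_increases_monotonically_with_erythema(small_scene):
    """Membership-weighted redness over the truth-derived ROI tracks the
    erythema intensity (rank correlation > 0.9 over 50 images)."""
    intensities = np.linspace(0.0, 1.0, 50)
    props = []
    for i, e in enumerate(intensities):
        params = small_scene(erythema_intensity=float(e), seed=100 + i)
        img, truth = generate_wound_image(params)
        roi = truth.incision_axis.perpendicular_distance(
            *np.mgrid[0:256, 0:256].astype(float)
        ) <= 28.0
        props.append(redness_proportion(img, roi, method="weighted").proportion)
    rho = stats.spearmanr(intensities, props).statistic
    assert rho > 0.9


def test_staples_outside_image_rejected(small_scene):
    with pytest.raises(SceneError, match="outside"):
        generate_wound_image(small_scene(n_staples=30, staple_spacing_px=40.0))


def test_scene_param_validation():
    with pytest.raises(SceneError):
        WoundSceneParams(erythema_intensity=1.5)
    with pytest.raises(SceneError):
        WoundSceneParams(n_staples=-1)
    with pytest.raises(SceneError):
        WoundSceneParams(stain_probability=2.0)


def test_scene_params_json_roundtrip():
    from dataclasses import asdict

    p = WoundSceneParams(erythema_intensity=0.4, seed=9)
    assert scene_params_from_dict(asdict(p)) == p


# --- cohorts --------------------------------------------------------------

def test_cohort_manifest_structure_and_determinism():
    b1 = generate_cohort(n_patients=47, images_per_patient=2, seed=5)
    b2 = generate_cohort(n_patients=47, images_per_patient=2, seed=5)
    m1, m2 = b1.manifest(), b2.manifest()
    assert len(m1) == 94
    assert m1.equals(m2)
    assert set(m1["visit_day"]) == {3, 10}
    assert m1["image_id"].is_unique
    # infection label constant within patient, erythema consistent with it
    for _, grp in m1.groupby("patient_code"):
        assert grp["infected"].nunique() == 1
        if grp["infected"].iloc[0] == 1:
            assert (grp["erythema_intensity"] > GENERATIVE_INFECTION_CUTOFF).all()
        else:
            assert (grp["erythema_intensity"] <= GENERATIVE_INFECTION_CUTOFF).all()


def test_zero_prevalence_cohort_is_all_negative():
    b = generate_cohort(n_patients=10, prevalence=0.0, seed=3)
    assert all(r.infected == 0 for r in b.rows)
    clean_p = EffectParams().symptom_p_clean
    # symptom rates must come from the non-infected model (low rates)
    rates = np.mean([[r.questionnaire[k] for k in clean_p if k != "fever"] for r in b.rows])
    assert rates < 0.5


def test_prevalence_concentration_at_large_n():
    b = generate_cohort(n_patients=1000, prevalence=0.12, images_per_patient=1, seed=17)
    frac = np.mean([r.infected for r in b.rows])
    assert abs(frac - 0.12) <= 0.03


def test_invalid_cohort_parameters():
    with pytest.raises(SceneError):
        generate_cohort(n_patients=5, prevalence=1.5)
    with pytest.raises(SceneError):
        generate_cohort(n_patients=0)


def test_stains_reduce_specificity_on_average(small_scene):
    """Antiseptic stains push negative wounds over a cutoff calibrated on
    artifact-free images: average specificity strictly drops (20 seeds)."""
    cfg_threshold = 0.42  # midpoint of the artifact-free score clusters
    cfg = RunConfig()
    spec_clean, spec_stain = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        fps = {"clean": 0, "stain": 0}
        n_neg = 4
        for k in range(n_neg):
            e = float(rng.uniform(0.05, 0.35))
            for kind, prob in (("clean", 0.0), ("stain", 1.0)):
                p = small_scene(
                    erythema_intensity=e, stain_probability=prob, seed=1000 * seed + k
                )
                img, _ = generate_wound_image(p)
                prop = analyze_image(img, cfg).redness.proportion
                fps[kind] += prop >= cfg_threshold
        spec_clean.append(1 - fps["clean"] / n_neg)
        spec_stain.append(1 - fps["stain"] / n_neg)
    assert np.mean(spec_stain) < np.mean(spec_clean)
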