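"""Diagnostic statistics: confusion, sensitivity/specificity with exact
CIs, Cohen's kappa and ROC cutoff selection, each against an independent
reference (brute force, sklearn or statsmodels)."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn import metrics as skm
from statsmodels.stats.proportion import proportion_confint

from woundscreen import (
    ConfusionTable,
    cohens_kappa,
    confusion,
    roc_and_cutoff,
    sensitivity_specificity,
)
from woundscreen.errors import DegenerateMarginalsError, MetricError
from woundscreen.evalstats import clopper_pearson

from _oracles import brute_best_youden, brute_kappa


# --- confusion ------------------------------------------------------------

def test_confusion_counts():
    t = confusion([1, 1, 0, 0], [1, 1, 0, 0])
    assert (t.tp, t.tn, t.fp, t.fn) == (2, 2, 0, 0)
    t = confusion([0, 0, 0], [1, 1, 1])
    assert (t.fn, t.tp, t.fp, t.tn) == (3, 0, 0, 0)


def test_study_scale_cohort_counts():
    """88 screened images: 5 infected all flagged, 14 clean flagged."""
    truth = [1] * 5 + [0] * 83
    pred = [1] * 5 + [1] * 14 + [0] * 69
    t = confusion(pred, truth)
    assert (t.tp, t.fn, t.fp, t.tn) == (5, 0, 14, 69)
    assert t.total == 88


def test_confusion_input_validation():
    with pytest.raises(ValueError):
        confusion([1, 0], [1])
    with pytest.raises(ValueError):
        confusion([1, 2], [1, 0])


def test_metrics_invariant_to_permutation(rng):
    pred = rng.integers(0, 2, 50)
    truth = np.r_[rng.integers(0, 2, 49), 1]  # ensure a positive
    perm = rng.permutation(50)
    m1 = sensitivity_specificity(confusion(pred, truth))
    m2 = sensitivity_specificity(confusion(pred[perm], truth[perm]))
    assert m1 == m2


# --- sensitivity / specificity -------------------------------------------

def test_screening_operating_point():
    m = sensitivity_specificity(ConfusionTable(tp=5, fn=0, fp=14, tn=69))
    assert m.sensitivity == 1.0
    assert m.specificity == pytest.approx(0.8313, abs=5e-5)
    assert m.sensitivity_ci[0] <= m.sensitivity <= m.sensitivity_ci[1]
    assert m.specificity_ci[0] <= m.specificity <= m.specificity_ci[1]


def test_undefined_margins_raise():
    with pytest.raises(MetricError, match="sensitivity"):
        sensitivity_specificity(ConfusionTable(tp=0, fn=0, fp=1, tn=1))
    with pytest.raises(MetricError, match="specificity"):
        sensitivity_specificity(ConfusionTable(tp=1, fn=1, fp=0, tn=0))


@pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (5, 83), (69, 83), (1, 2)])
def test_clopper_pearson_matches_statsmodels(k, n):
    lo, hi = clopper_pearson(k, n)
    sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="beta")
    assert lo == pytest.approx(sm_lo, abs=1e-10)
    assert hi == pytest.approx(sm_hi, abs=1e-10)
    assert lo <= k / n <= hi


# --- kappa ----------------------------------------------------------------

def test_kappa_reference_values():
    assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)
    # p_o = 0.5 and p_e = 0.5 → κ = 0
    assert cohens_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0, abs=1e-12)


def test_kappa_matches_brute_force_and_sklearn(rng):
    for _ in range(200):
        n = int(rng.integers(2, 30))
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue
        k = cohens_kappa(a, b)
        assert k == pytest.approx(brute_kappa(a, b), abs=1e-12)
        assert k == pytest.approx(skm.cohen_kappa_score(a, b), abs=1e-10)
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        assert k == pytest.approx(cohens_kappa(b, a), abs=1e-12)  # symmetry


def test_kappa_degenerate_marginals():
    with pytest.raises(DegenerateMarginalsError):
        cohens_kappa([1, 1, 1], [1, 1, 1])


def test_kappa_multiclass():
    a = ["x", "y", "z", "x", "y"]
    b = ["x", "y", "z", "y", "y"]
    assert cohens_kappa(a, b) == pytest.approx(brute_kappa(a, b), abs=1e-12)


# --- ROC ------------------------------------------------------------------

def test_perfectly_separated_scores():
    roc = roc_and_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert roc.auc == pytest.approx(1.0)
    assert roc.optimal_threshold == pytest.approx(0.5)  # midpoint convention


def test_anti_separated_scores():
    roc = roc_and_cutoff([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
    assert roc.auc == pytest.approx(0.0)


def test_roc_monotone_sweep_and_brute_force_J(rng):
    for _ in range(30):
        n = int(rng.integers(4, 40))
        scores = np.round(rng.random(n), 2)
        truth = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        roc = roc_and_cutoff(scores, truth)
        assert np.all(np.diff(roc.tpr) >= -1e-12)
        assert np.all(np.diff(roc.fpr) >= -1e-12)
        assert 0.0 <= roc.auc <= 1.0
        # the selected threshold achieves the exhaustive-search optimum
        pred = scores >= roc.optimal_threshold
        tpr = np.sum(pred & (truth == 1)) / truth.sum()
        fpr = np.sum(pred & (truth == 0)) / (len(truth) - truth.sum())
        assert tpr - fpr == pytest.approx(brute_best_youden(scores, truth), abs=1e-12)


def test_auc_equals_mann_whitney(rng):
    for _ in range(20):
        n = int(rng.integers(6, 50))
        scores = rng.normal(size=n)
        truth = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        roc = roc_and_cutoff(scores, truth)
        pos, neg = scores[truth == 1], scores[truth == 0]
        u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)
        assert roc.auc == pytest.approx(skm.roc_auc_score(truth, scores), abs=1e-12)


def test_roc_tie_breaks_toward_sensitivity():
    # thresholds 0.35 and 0.75 both reach J = 0.5; the lower one wins
    roc = roc_and_cutoff([0.1, 0.6, 0.5, 0.9], [0, 0, 1, 1])
    pred = np.array([0.1, 0.6, 0.5, 0.9]) >= roc.optimal_threshold
    assert pred.sum() == 3  # the more sensitive of the tied rules


def test_roc_single_class_rejected():
    with pytest.raises(MetricError):
        roc_and_cutoff([0.1, 0.9], [1, 1])
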