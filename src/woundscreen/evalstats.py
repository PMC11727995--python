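"""Diagnostic-accuracy statistics: confusion tables, sensitivity and
specificity with exact confidence intervals, Cohen's kappa, and ROC
analysis with Youden-optimal cutoff selection.

Conventions mirror a sensitivity-first screening design: a score ties at
a threshold as positive, and Youden ties are broken toward the lower
threshold (higher sensitivity).  Confidence intervals are Clopper–Pearson
exact, appropriate at the small sample sizes typical of single-centre
wound cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateMarginalsError, MetricError


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    kappa: float | None = None
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "kappa": self.kappa,
            "notes": self.notes,
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC sweep: thresholds (descending) with their operating points."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_threshold: float
    criterion: str = "youden"

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return [
            (float(t), float(a), float(b))
            for t, a, b in zip(self.thresholds, self.tpr, self.fpr)
        ]


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1, found values {vals}")
    return arr.astype(int)


def confusion(pred, truth) -> ConfusionTable:
    """Exact 2×2 counts from paired binary predictions and truth."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(t)} truths")
    return ConfusionTable(
        tp=int(np.sum((p == 1) & (t == 1))),
        fn=int(np.sum((p == 0) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided CI for a binomial proportion."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid counts k={k}, n={n}")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def sensitivity_specificity(
    table: ConfusionTable, ci: str = "clopper-pearson", alpha: float = 0.05
) -> DiagnosticMetrics:
    """Point estimates and exact 95% CIs from a 2×2 table.

    sensitivity = tp / (tp + fn);  specificity = tn / (tn + fp).
    """
    if ci != "clopper-pearson":
        raise ValueError(f"unsupported CI method {ci!r}")
    pos = table.tp + table.fn
    neg = table.tn + table.fp
    if pos < 1:
        raise MetricError("sensitivity undefined: no positive cases (tp + fn = 0)")
    if neg < 1:
        raise MetricError("specificity undefined: no negative cases (tn + fp = 0)")
    return DiagnosticMetrics(
        sensitivity=table.tp / pos,
        sensitivity_ci=clopper_pearson(table.tp, pos, alpha),
        specificity=table.tn / neg,
        specificity_ci=clopper_pearson(table.tn, neg, alpha),
    )


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    ``p_o`` is the observed agreement rate; ``p_e`` the chance agreement
    from the raters' marginal label frequencies.  Raises when both raters
    are constant (p_e = 1, κ undefined).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise ValueError("raters must be equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 paired ratings")
    labels = np.unique(np.concatenate([a, b]))
    n = len(a)
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == lab) for lab in labels])
    pb = np.array([np.mean(b == lab) for lab in labels])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        raise DegenerateMarginalsError(
            "both raters constant: chance agreement 1, kappa undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def roc_and_cutoff(scores, truth, criterion: str = "youden") -> RocCurve:
    """ROC sweep over unique scores and Youden-optimal cutoff.

    The decision rule is positive iff score ≥ threshold.  The sweep runs
    from "predict none" down through every unique score; AUC is the
    trapezoid over (fpr, tpr).  The optimal threshold maximises
    J = tpr − fpr, ties broken toward the lower threshold (higher
    sensitivity), and is reported as the midpoint between the lowest
    included score and the next lower score.
    """
    if criterion != "youden":
        raise ValueError(f"unsupported criterion {criterion!r}")
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth, "truth")
    if s.ndim != 1 or len(s) != len(t):
        raise ValueError("scores and truth must be equal-length 1-D sequences")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC undefined: truth contains a single class")

    uniq = np.unique(s)[::-1]  # descending
    # operating point at threshold u: positive iff score >= u
    tpr = np.array([np.sum((s >= u) & (t == 1)) / n_pos for u in uniq])
    fpr = np.array([np.sum((s >= u) & (t == 0)) / n_neg for u in uniq])
    thresholds = np.concatenate([[np.inf], uniq])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = int(np.max(np.flatnonzero(j == j.max())))  # lowest threshold among ties
    if best == 0:  # predict-none optimum
        optimal = float(uniq[0] + 1.0)
    else:
        included = uniq[best - 1]
        if best < len(thresholds) - 1:
            optimal = float((included + uniq[best]) / 2.0)
        else:
            optimal = float(included)  # include everything
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        optimal_threshold=optimal,
        criterion=criterion,
    )
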