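"""Independent brute-force oracles used by the test suite.

These are deliberately naive (double loops over offsets, exhaustive
sweeps) and share no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def impl_godel(a, b):
    return 1.0 if a <= b else b


def impl_luk(a, b):
    return min(1.0, 1.0 - a + b)


def conj_min(a, b):
    return min(a, b)


def conj_luk(a, b):
    return max(0.0, a + b - 1.0)


def brute_erode(f, memberships, origin, implication):
    """(f ⊖ B)(x) = inf over offsets of I(B(offset), f(x + offset)),
    reading outside the image as 1."""
    H, W = f.shape
    h, w = memberships.shape
    orow, ocol = origin
    out = np.empty_like(f)
    for r in range(H):
        for c in range(W):
            vals = []
            for i in range(h):
                for j in range(w):
                    rr, cc = r + i - orow, c + j - ocol
                    fv = f[rr, cc] if 0 <= rr < H and 0 <= cc < W else 1.0
                    vals.append(implication(memberships[i, j], fv))
            out[r, c] = min(vals)
    return out


def brute_dilate(f, memberships, origin, conjunction):
    """(f ⊕ B)(x) = sup over offsets of C(B(offset), f(x − offset)),
    reading outside the image as 0."""
    H, W = f.shape
    h, w = memberships.shape
    orow, ocol = origin
    out = np.empty_like(f)
    for r in range(H):
        for c in range(W):
            vals = []
            for i in range(h):
                for j in range(w):
                    rr, cc = r - (i - orow), c - (j - ocol)
                    fv = f[rr, cc] if 0 <= rr < H and 0 <= cc < W else 0.0
                    vals.append(conjunction(memberships[i, j], fv))
            out[r, c] = max(vals)
    return out


def brute_open(f, memberships, origin, conjunction, implication):
    return brute_dilate(
        brute_erode(f, memberships, origin, implication), memberships, origin, conjunction
    )


def brute_axis_angle(points, grid_deg=0.1):
    """Angle (degrees, [0, 180)) of the line through the centroid that
    minimises perpendicular SSE, by exhaustive sweep."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    best_ang, best_sse = 0.0, np.inf
    for ang in np.arange(0.0, 180.0, grid_deg):
        theta = np.deg2rad(ang)
        normal = np.array([-np.cos(theta), np.sin(theta)])  # unit normal to (sin, cos)
        sse = float(np.sum((centered @ normal) ** 2))
        if sse < best_sse:
            best_ang, best_sse = ang, sse
    return best_ang


def brute_kappa(a, b):
    """Cohen's kappa straight from the contingency table."""
    a = list(a)
    b = list(b)
    n = len(a)
    labels = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(lab) / n) * (b.count(lab) / n) for lab in labels)
    if p_e >= 1.0:
        raise ZeroDivisionError("degenerate marginals")
    return (p_o - p_e) / (1.0 - p_e)


def brute_best_youden(scores, truth):
    """Best achievable J = tpr − fpr over every 'score >= t' rule,
    enumerating all candidate thresholds."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n_pos = truth.sum()
    n_neg = len(truth) - n_pos
    best = -np.inf
    for t in np.concatenate([np.unique(scores), [scores.max() + 1.0]]):
        pred = scores >= t
        tpr = np.sum(pred & (truth == 1)) / n_pos
        fpr = np.sum(pred & (truth == 0)) / n_neg
        best = max(best, tpr - fpr)
    return best


def circular_angle_diff(a, b, period=180.0):
    d = abs(a - b) % period
    return min(d, period - d)
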