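"""Fuzzy gray-scale morphology: erosion, dilation, opening, top-hat.

Definitions (f a gray channel, B a structuring element with origin o,
C a t-norm, I its residual implication):

    erosion   (f ⊖ B)(x) = inf_y I(B(y − x), f(y))
    dilation  (f ⊕ B)(x) = sup_y C(B(x − y), f(y))
    opening   f ∘ B = (f ⊖ B) ⊕ B
    top-hat   f − (f ∘ B)

Erosion pads with 1 and dilation with 0 (the neutral values), so borders
never create spurious bright residues.  The pair (⊖, ⊕) is an adjunction,
hence ``dilate(erode(f)) <= f <= erode(dilate(f))`` pointwise and the
opening is idempotent; the test-suite checks both against brute force.
"""

from __future__ import annotations

import numpy as np

from .errors import StructuringElementError
from .imaging import FuzzyLogicPair, StructuringElement, as_gray_channel, get_logic


def _check_fits(f: np.ndarray, se: StructuringElement) -> None:
    if se.shape[0] > f.shape[0] or se.shape[1] > f.shape[1]:
        raise StructuringElementError(
            f"structuring element {se.shape} larger than image {f.shape}"
        )


def _pad_widths(se: StructuringElement) -> tuple[tuple[int, int], tuple[int, int]]:
    (h, w), (orow, ocol) = se.shape, se.origin
    return (orow, h - 1 - orow), (ocol, w - 1 - ocol)


def fuzzy_erode(
    f: np.ndarray,
    se: StructuringElement,
    logic: FuzzyLogicPair | str = "godel",
) -> np.ndarray:
    """Fuzzy erosion of a gray channel.

    Returns ``min`` over structuring-element offsets of
    ``I(B(offset), f(x + offset))``, with the image padded by 1.
    """
    f = as_gray_channel(f)
    _check_fits(f, se)
    logic = get_logic(logic)
    (pr, pc) = _pad_widths(se)
    fp = np.pad(f, (pr, pc), mode="constant", constant_values=1.0)
    H, W = f.shape
    out = np.full_like(f, np.inf)
    m = se.memberships
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            b = m[i, j]
            if b == 0.0 and logic.implication(0.0, 0.0) == 1.0:
                continue  # I(0, ·) = 1 never lowers the inf for residua
            view = fp[i: i + H, j: j + W]
            np.minimum(out, logic.implication(b, view), out=out)
    return np.clip(out, 0.0, 1.0)


def fuzzy_dilate(
    f: np.ndarray,
    se: StructuringElement,
    logic: FuzzyLogicPair | str = "godel",
) -> np.ndarray:
    """Fuzzy dilation: ``max`` over offsets of ``C(B(offset), f(x − offset))``."""
    f = as_gray_channel(f)
    _check_fits(f, se)
    logic = get_logic(logic)
    (pr, pc) = _pad_widths(se)
    # x − offset flips the element: pad reversed, index reversed.
    fp = np.pad(f, (pr[::-1], pc[::-1]), mode="constant", constant_values=0.0)
    H, W = f.shape
    out = np.zeros_like(f)
    m = se.memberships
    h, w = m.shape
    for i in range(h):
        for j in range(w):
            b = m[i, j]
            if b == 0.0:
                continue  # C(0, ·) = 0 never raises the sup
            view = fp[h - 1 - i: h - 1 - i + H, w - 1 - j: w - 1 - j + W]
            np.maximum(out, logic.conjunction(b, view), out=out)
    return np.clip(out, 0.0, 1.0)


def fuzzy_open(
    f: np.ndarray,
    se: StructuringElement,
    logic: FuzzyLogicPair | str = "godel",
) -> np.ndarray:
    """Morphological opening: dilation of the erosion."""
    return fuzzy_dilate(fuzzy_erode(f, se, logic), se, logic)


def top_hat(
    f: np.ndarray,
    se: StructuringElement,
    logic: FuzzyLogicPair | str = "godel",
) -> np.ndarray:
    """White top-hat: ``f`` minus its opening.

    Isolates bright structures too thin to contain the structuring
    element — exactly the signature of metallic staples on skin.
    """
    f = as_gray_channel(f)
    return np.clip(f - fuzzy_open(f, se, logic), 0.0, 1.0)
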