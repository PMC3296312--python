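"""Evaluation measures against a known ground truth.

* ``v_kT`` — misclassified-element count #{x: label(x) != truth(x)}, i.e.
  false positives plus false negatives.
* ``v_D = v_kT / V_truth`` — relative difference, normalized by the ground
  truth's foreground size only (hence asymmetric by design).
* ``DSC = 2|A∩B| / (|A|+|B|)`` — Dice similarity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_model import GeometryError, LabelImage, RaterSet

# sigma convention shared with the dissimilarity module: sample (K-1)
from .dissimilarity import DEFAULT_DDOF


@dataclass(frozen=True)
class EvalResult:
    v_kT: int
    v_D: float
    dsc: float
    V_truth: int


def _check_grids(label: LabelImage, truth: LabelImage) -> None:
    if not label.same_grid(truth):
        raise GeometryError("label and truth must share the same grid")


def vd(label: LabelImage, truth: LabelImage) -> EvalResult:
    """Misclassified-element count and relative difference vs. ground truth.

    An empty truth has no defined v_D (division by zero) and is an error.
    """
    _check_grids(label, truth)
    V_truth = truth.foreground_size
    if V_truth == 0:
        raise ValueError("v_D is undefined for an empty ground truth")
    v_kT = int((label.values != truth.values).sum())
    return EvalResult(
        v_kT=v_kT, v_D=v_kT / V_truth, dsc=dsc(label, truth), V_truth=V_truth
    )


def dsc(label: LabelImage, truth: LabelImage) -> float:
    """Dice similarity coefficient; two empty sets → 1 by convention."""
    _check_grids(label, truth)
    a = label.values.astype(bool)
    b = truth.values.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def test_summary(
    raters: RaterSet, truth: LabelImage, ddof: int = DEFAULT_DDOF
) -> tuple[float, float, float]:
    """Mean, standard deviation, and coefficient of variation of v_D over
    the K input labels of one fusion test.

    If every rater matches the truth (mu = 0), the coefficient of variation
    is defined as 0.
    """
    if raters.K < 2:
        raise ValueError("test summary needs at least 2 raters")
    v = np.array([vd(r, truth).v_D for r in raters])
    mu = float(v.mean())
    sigma = float(v.std(ddof=ddof))
    cov = sigma / mu if mu > 0 else 0.0
    return mu, sigma, cov
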