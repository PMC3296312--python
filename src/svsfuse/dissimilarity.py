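"""Ground-truth-free rater dissimilarity estimation.

Given only the K input labels, two empirical factors are estimated:

* the *dissimilarity coefficient* ``d_c = sigma(v_k) / mu(v_k)``, an estimate
  of the coefficient of variation of the raters' relative error v_D, and
* the *dissimilarity ratio* ``d_r = mu(v_k) / V``, an estimate of the mean
  relative error mu(v_D),

where v_k estimates each rater's misclassified-element count and V the true
foreground size.  Both rest on per-element label frequencies fed through a
binomial "virtual-rater majority" transform: for a misclassification
probability p, the probability that a clear majority of B virtual raters
(B odd) misclassifies the element.  B = 99 by default, so the majority sum
runs from 50 to 99.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .label_model import RaterSet, compute_disputed_mask

DEFAULT_B = 99

#: Variance convention for sigma(v_k): sample standard deviation (K-1
#: denominator).  Configurable for sensitivity checks.
DEFAULT_DDOF = 1


@dataclass(frozen=True)
class DissimilarityPair:
    """The (d_c, d_r) estimates with their intermediates."""

    d_c: float
    d_r: float
    v_k: np.ndarray  # per-rater estimated misclassified-element count
    V: float         # estimated true foreground size (elements)
    B: int
    unanimous: bool  # all raters identical -> (0, 0) by convention


def majority_lower_index(B: int) -> int:
    """Lower summation index of the majority mass: ceil((B+1)/2)."""
    if B % 2 == 0 or B < 1:
        raise ValueError("B must be an odd positive integer")
    return (B + 1) // 2


def majority_prob(p, B: int = DEFAULT_B):
    """Probability that a clear majority of B virtual raters (B odd) each
    misclassifying independently with probability p do so.

    Computed as the binomial survival function, which is numerically stable
    for extreme p; accepts scalars or arrays.
    """
    m = majority_lower_index(B)
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = binom.sf(m - 1, B, p)
    return float(out) if out.ndim == 0 else out


def label_frequency(raters: RaterSet) -> np.ndarray:
    """Per-element foreground frequency f(x, 1) = #{k: e_k(x)=1} / K."""
    return raters.stack().mean(axis=0, dtype=np.float64)


def rater_misclass_prob(raters: RaterSet) -> np.ndarray:
    """Per-rater, per-element estimated misclassification probability
    p_k(x) = 1 - f(x, e_k(x)), as a (K, *shape) array."""
    f1 = label_frequency(raters)
    stack = raters.stack()
    # f(x, e_k(x)) is f1 where the rater said 1, 1-f1 where it said 0
    return np.where(stack == 1, 1.0 - f1, f1)


def estimate_rater_error(raters: RaterSet, B: int = DEFAULT_B) -> np.ndarray:
    """Per-rater estimated misclassified-element count
    v_k = sum_x majority_prob(p_k(x), B)."""
    p = rater_misclass_prob(raters)
    return majority_prob(p, B).sum(axis=tuple(range(1, p.ndim)))


def estimate_truth_size(raters: RaterSet, B: int = DEFAULT_B) -> float:
    """Estimated true foreground size V = sum_x majority_prob(f(x,1), B)."""
    return float(majority_prob(label_frequency(raters), B).sum())


def dissimilarity_factors(
    raters: RaterSet, B: int = DEFAULT_B, ddof: int = DEFAULT_DDOF
) -> DissimilarityPair:
    """Estimate (d_c, d_r) from the input labels alone.

    Unanimous elements contribute exactly 0 to every v_k and exactly 0 or 1
    to V, so the sums are evaluated over the disputed elements plus a count
    of unanimous foreground — identical to the full-grid computation but
    much faster on large grids.

    Conventions: all raters identical → (0, 0) with the ``unanimous`` flag
    set (selection is then skipped; any fuser returns the input).  V = 0
    with mu(v_k) > 0 → d_r = +inf.
    """
    if raters.K < 2:
        raise ValueError("dissimilarity factors need at least 2 raters")
    m = majority_lower_index(B)  # validates B
    disputed = compute_disputed_mask(raters)
    if disputed.n_disputed == 0:
        return DissimilarityPair(
            d_c=0.0, d_r=0.0, v_k=np.zeros(raters.K),
            V=float(disputed.unanimous_label.foreground_size), B=B, unanimous=True,
        )
    stack = raters.stack()[:, disputed.mask]  # (K, M) disputed columns only
    f1 = stack.mean(axis=0, dtype=np.float64)
    p = np.where(stack == 1, 1.0 - f1, f1)
    v_k = binom.sf(m - 1, B, p).sum(axis=1)
    n_unanimous_fg = int(disputed.unanimous_label.foreground_size)
    V = n_unanimous_fg + float(binom.sf(m - 1, B, f1).sum())

    mu = float(v_k.mean())
    sigma = float(v_k.std(ddof=ddof))
    d_c = sigma / mu if mu > 0 else 0.0
    if V > 0:
        d_r = mu / V
    else:
        d_r = np.inf if mu > 0 else 0.0
    return DissimilarityPair(d_c=d_c, d_r=d_r, v_k=v_k, V=V, B=B, unanimous=False)
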