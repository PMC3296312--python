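"""The three base label-fusion algorithms: Vote, STAPLE, and SBA.

All three consume a :class:`~svsfuse.label_model.RaterSet` and return a fused
binary :class:`~svsfuse.label_model.LabelImage`.  Following common practice,
fusion is only ever needed on the *disputed* elements; unanimous elements
keep their label.  Vote and SBA give identical output either way; STAPLE's
performance parameters are estimated over the disputed set only (which both
speeds it up and improves it), so its `on_disputed` flag matters.

Tie rule (global, documented): whenever a fused quantity lands exactly on
the decision boundary — an even vote split, a mean signed distance of zero,
a STAPLE posterior of exactly 0.5 — the element is assigned to the
foreground (label 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .label_model import (
    DisputedMask,
    LabelImage,
    RaterSet,
    assemble_fusion,
    compute_disputed_mask,
)

logger = logging.getLogger(__name__)

_PARAM_EPS = 1e-7  # clamp for degenerate M-step denominators


@dataclass(frozen=True)
class RaterPerformance:
    """Per-rater sensitivity P(e_k=1 | T=1) and specificity P(e_k=0 | T=0),
    plus the scalar foreground prior used by the EM."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    foreground_prior: float


@dataclass(frozen=True)
class StapleResult:
    label: LabelImage
    performance: RaterPerformance
    converged: bool
    n_iter: int
    log_likelihood: np.ndarray  # per-iteration sum_x log(a+b)

    def __iter__(self):  # allow `label, perf = fuse_staple(...)`
        return iter((self.label, self.performance))


def fuse_vote(raters: RaterSet) -> LabelImage:
    """Majority vote (sum rule): each element takes its most frequent label.

    Even-K ties go to the foreground.
    """
    counts = raters.stack().sum(axis=0, dtype=np.int64)
    out = (2 * counts >= raters.K).astype(np.int8)
    return raters.grid.with_values(out)


def signed_distance(label: LabelImage) -> np.ndarray:
    """Exact signed Euclidean distance map of a binary label.

    Negative inside the foreground, positive outside; |d(x)| is the exact
    Euclidean distance from the element center to the nearest element center
    of the opposite label (the usual EDT convention — no half-element offset
    to a notional boundary).  Distances are index-space: spacing metadata is
    ignored.

    A label with empty or full foreground has no boundary; its map is a
    constant of the appropriate sign with magnitude equal to the grid
    diagonal, and a warning is logged.
    """
    vals = label.values
    n_fg = int(vals.sum())
    diag = float(np.sqrt(np.sum(np.square(vals.shape))))
    if n_fg == 0:
        logger.warning("signed_distance: empty foreground; using +diagonal map")
        warnings.warn("empty foreground label in signed_distance", stacklevel=2)
        return np.full(vals.shape, diag)
    if n_fg == vals.size:
        logger.warning("signed_distance: full foreground; using -diagonal map")
        warnings.warn("full foreground label in signed_distance", stacklevel=2)
        return np.full(vals.shape, -diag)
    inside = vals.astype(bool)
    # EDT(a) = distance from each True element to the nearest False element.
    d_out = ndimage.distance_transform_edt(~inside)  # >0 outside, 0 inside
    d_in = ndimage.distance_transform_edt(inside)    # >0 inside, 0 outside
    return d_out - d_in


def fuse_sba(raters: RaterSet) -> LabelImage:
    """Shape-Based Averaging: vote weighted by signed Euclidean distance.

    Each rater's label is converted to a signed distance map on the full
    grid; the mean map is thresholded at zero (exact zero → foreground,
    consistent with the global tie rule).
    """
    mean_d = np.zeros(raters.grid.shape)
    for r in raters:
        mean_d += signed_distance(r)
    mean_d /= raters.K
    return raters.grid.with_values((mean_d <= 0).astype(np.int8))


def fuse_staple(
    raters: RaterSet,
    max_iter: int = 100,
    tol: float = 1e-6,
    on_disputed: bool = True,
    init_p: float = 0.99999,
    foreground_prior: float | None = None,
) -> StapleResult:
    """Binary STAPLE: EM estimation of the true label and rater performance.

    The E-step computes the posterior foreground probability

        W(x) = a(x) / (a(x) + b(x)),
        a(x) = g * prod_k [sens_k if e_k(x)=1 else 1-sens_k],
        b(x) = (1-g) * prod_k [1-spec_k if e_k(x)=1 else spec_k],

    and the M-step re-estimates each rater's sensitivity and specificity
    from W.  Iteration stops when the change in sum_x W(x) drops below
    ``tol`` or after ``max_iter`` iterations (non-convergence is flagged,
    not an error).  The final label is W(x) >= 0.5.

    Parameters
    ----------
    on_disputed : bool
        If True (default), all EM sums run over the disputed elements only,
        which is both faster and markedly better-behaved when raters agree
        over most of the grid.  If False, the classic full-grid EM is run;
        this is the regime in which the estimated sensitivities and
        specificities recover the parameters of the generative rater model.
    init_p : float
        Initial sensitivity = specificity for every rater.
    foreground_prior : float, optional
        Prior probability g of foreground.  Default: the mean foreground
        fraction over raters, computed on the EM's element set.
    """
    if raters.K < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    disputed = compute_disputed_mask(raters)
    stack = raters.stack()

    if on_disputed:
        if disputed.n_disputed == 0:
            perf = RaterPerformance(
                sensitivity=np.ones(raters.K),
                specificity=np.ones(raters.K),
                foreground_prior=float(raters.grid.values.mean()),
            )
            return StapleResult(disputed.unanimous_label, perf, True, 0, np.array([]))
        D = stack[:, disputed.mask].astype(np.float64)  # (K, M)
    else:
        D = stack.reshape(raters.K, -1).astype(np.float64)

    K, M = D.shape
    g = float(D.mean()) if foreground_prior is None else float(foreground_prior)
    g = min(max(g, _PARAM_EPS), 1 - _PARAM_EPS)
    sens = np.full(K, init_p)
    spec = np.full(K, init_p)

    w_sum_prev = np.inf
    loglik = []
    W = np.full(M, 0.5)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step, in log space for numerical safety at extreme parameters
        log_a = np.log(g) + (
            D * np.log(sens)[:, None] + (1 - D) * np.log1p(-sens)[:, None]
        ).sum(axis=0)
        log_b = np.log1p(-g) + (
            D * np.log1p(-spec)[:, None] + (1 - D) * np.log(spec)[:, None]
        ).sum(axis=0)
        hi = np.maximum(log_a, log_b)
        denom = np.exp(log_a - hi) + np.exp(log_b - hi)
        W = np.exp(log_a - hi) / denom
        loglik.append(float((hi + np.log(denom)).sum()))

        w_sum = float(W.sum())
        if abs(w_sum - w_sum_prev) < tol:
            converged = True
            break
        w_sum_prev = w_sum

        # M-step
        sw = W.sum()
        snw = M - sw
        if sw <= 0 or snw <= 0:
            sens = np.clip(sens, _PARAM_EPS, 1 - _PARAM_EPS)
            spec = np.clip(spec, _PARAM_EPS, 1 - _PARAM_EPS)
            continue
        sens = (D * W).sum(axis=1) / sw
        spec = ((1 - D) * (1 - W)).sum(axis=1) / snw
        sens = np.clip(sens, _PARAM_EPS, 1 - _PARAM_EPS)
        spec = np.clip(spec, _PARAM_EPS, 1 - _PARAM_EPS)

    if not converged:
        logger.warning("STAPLE did not converge in %d iterations", max_iter)

    labels = (W >= 0.5).astype(np.int8)
    if on_disputed:
        fused = assemble_fusion(disputed, labels)
    else:
        fused = raters.grid.with_values(labels.reshape(raters.grid.shape))
    perf = RaterPerformance(sensitivity=sens, specificity=spec, foreground_prior=g)
    return StapleResult(fused, perf, converged, it, np.asarray(loglik))


def fuse(raters: RaterSet, method: str, **kwargs) -> LabelImage:
    """Run one of the base fusers by name ('vote', 'staple', 'sba')."""
    method = method.lower()
    if method == "vote":
        return fuse_vote(raters)
    if method == "sba":
        return fuse_sba(raters)
    if method == "staple":
        return fuse_staple(raters, **kwargs).label
    raise ValueError(f"unknown fusion method: {method}")
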