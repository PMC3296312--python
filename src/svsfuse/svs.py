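"""SVS: dissimilarity-driven selection among STAPLE, Vote, and SBA.

Training: for each labeled fusion test, compute the dissimilarity factors
(d_c, d_r) from the input labels, run all three fusers against the known
ground truth, count each method's misclassified elements v_m, and score the
methods 1 (lowest v_m) / 0 (highest) / linearly interpolated (middle).  A
smooth scoring surface s_m(d_c, d_r) is then fitted per method by locally
weighted linear regression (LOESS, tricube kernel, degree 1).

Selection: for new inputs, compute (d_c, d_r), evaluate the three surfaces,
and run only the method with the highest score.  Ties (within 1e-9) fall
back to a weighted-vote "meta fusion" of all three results using the scores
as weights.

For portability and determinism the fitted surfaces are persisted — and
evaluated — as a dense 101x101 lookup grid over the training bounding box,
with bilinear interpolation inside the box and nearest-edge clamping
outside; scores are clamped to [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dissimilarity import DEFAULT_B, dissimilarity_factors
from .fusers import fuse_sba, fuse_staple, fuse_vote
from .label_model import LabelImage, RaterSet

logger = logging.getLogger(__name__)

METHODS = ("STAPLE", "VOTE", "SBA")
TIE_TOL = 1e-9
GRID_N = 101
DEFAULT_SPAN = 0.25


@dataclass(frozen=True)
class ScoredTest:
    """One training test: its dissimilarity factors, per-method error
    counts v_m, and the derived scores."""

    d_c: float
    d_r: float
    v_m: dict
    scores: dict
    degenerate: bool  # all three v_m equal -> all scores 1


def score_methods(v_m: dict) -> tuple[dict, bool]:
    """Score rule: 1 to the lowest v_m, 0 to the highest, the middle method
    linearly interpolated as (v_max - v_mid) / (v_max - v_min).  All equal
    -> every score 1, flagged degenerate."""
    vals = np.array([v_m[m] for m in METHODS], dtype=float)
    v_min, v_max = vals.min(), vals.max()
    if v_max == v_min:
        return {m: 1.0 for m in METHODS}, True
    scores = (v_max - vals) / (v_max - v_min)
    return dict(zip(METHODS, scores.tolist())), False


def score_test(truth: LabelImage, fusions: dict) -> ScoredTest:
    """Score one test from its ground truth and per-method fusion results.
    (d_c, d_r are filled by the caller; NaN here.)"""
    v_m = {
        m: int((fusions[m].values != truth.values).sum()) for m in METHODS
    }
    scores, degenerate = score_methods(v_m)
    return ScoredTest(np.nan, np.nan, v_m, scores, degenerate)


def run_all_fusers(raters: RaterSet, staple_kwargs: dict | None = None) -> dict:
    kw = staple_kwargs or {}
    return {
        "STAPLE": fuse_staple(raters, **kw).label,
        "VOTE": fuse_vote(raters),
        "SBA": fuse_sba(raters),
    }


# ---------------------------------------------------------------------------
# Bivariate LOESS (tricube kernel, adaptive span bandwidth, degree 1)

def loess2d_fit_grid(
    x: np.ndarray, y: np.ndarray, s: np.ndarray, xg: np.ndarray, yg: np.ndarray,
    span: float = DEFAULT_SPAN,
) -> np.ndarray:
    """Evaluate a locally weighted linear regression of s on (x, y) at every
    node of the (xg, yg) grid; returns an array of shape (len(xg), len(yg)).

    The local window holds ceil(span * n) nearest training points (at least
    4, widened with a warning if span gives fewer); distances are measured
    after scaling each axis by its standard deviation so neither factor
    dominates.  Weights are tricube in distance / window radius.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    n = len(x)
    q = int(np.ceil(span * n))
    if q < 4:
        logger.warning("LOESS window (%d pts) below minimum; widened to 4", q)
        q = min(4, n)
    sx = x.std() or 1.0
    sy = y.std() or 1.0
    xs, ys = x / sx, y / sy

    out = np.empty((len(xg), len(yg)))
    for i, gx in enumerate(xg / sx):
        dx2 = (xs - gx) ** 2
        for j, gy in enumerate(yg / sy):
            d = np.sqrt(dx2 + (ys - gy) ** 2)
            h = np.partition(d, q - 1)[q - 1]
            if h == 0:
                # all window points coincide with the query
                out[i, j] = s[d == 0].mean()
                continue
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            sel = w > 0
            A = np.column_stack([np.ones(sel.sum()), xs[sel] - gx, ys[sel] - gy])
            Aw = A * w[sel, None]
            beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ s[sel], rcond=None)
            out[i, j] = beta[0]
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# The scoring model

@dataclass
class ScoringModel:
    """Fitted scoring surfaces s_m(d_c, d_r) for the three fusion methods.

    Construct with :meth:`train` from labeled fusion tests, or :meth:`load`
    from a serialized JSON file.  Evaluation goes through the dense lookup
    grid (bilinear inside the training bounding box, nearest-edge clamped
    outside), so a trained model and its serialized round-trip agree
    exactly.
    """

    dc_axis: np.ndarray
    dr_axis: np.ndarray
    grids: dict                      # method -> (GRID_N, GRID_N) score grid
    span: float = DEFAULT_SPAN
    training_points: list = field(default_factory=list)  # ScoredTest
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self._interp = {
            m: RegularGridInterpolator(
                (self.dc_axis, self.dr_axis), self.grids[m],
                method="linear", bounds_error=False,
            )
            for m in METHODS
        }

    # -- training ----------------------------------------------------------
    @classmethod
    def train(
        cls,
        tests,
        span: float = DEFAULT_SPAN,
        B: int = DEFAULT_B,
        staple_kwargs: dict | None = None,
        provenance: dict | None = None,
    ) -> "ScoringModel":
        """Fit the scoring surfaces from (RaterSet, ground truth) pairs or
        :class:`~svsfuse.shape_sim.TestCase` objects.

        Each test contributes one (d_c, d_r, s_STAPLE, s_VOTE, s_SBA) point;
        degenerate tests (all v_m equal) are kept with all-ones scores so
        the surfaces are not biased downward where the methods agree.
        Unanimous-rater tests carry no selection signal and are dropped.
        """
        points = []
        for t in tests:
            raters, truth = (t.raters, t.truth) if hasattr(t, "raters") else t
            pair = dissimilarity_factors(raters, B=B)
            if pair.unanimous:
                continue
            fusions = run_all_fusers(raters, staple_kwargs)
            st = score_test(truth, fusions)
            points.append(
                ScoredTest(pair.d_c, pair.d_r, st.v_m, st.scores, st.degenerate)
            )
        if not points:
            raise ValueError("no usable (non-unanimous) training tests")
        if all(p.degenerate for p in points):
            raise ValueError("all training tests are degenerate")

        dc = np.array([p.d_c for p in points])
        dr = np.array([p.d_r for p in points])

        def _axis(v):
            lo, hi = float(v.min()), float(v.max())
            if hi == lo:  # degenerate box: give the grid a nominal width
                lo, hi = lo - 0.5, hi + 0.5
            return np.linspace(lo, hi, GRID_N)

        dc_axis = _axis(dc)
        dr_axis = _axis(dr)
        grids = {}
        for m in METHODS:
            s = np.array([p.scores[m] for p in points])
            grids[m] = loess2d_fit_grid(dc, dr, s, dc_axis, dr_axis, span)
        return cls(
            dc_axis=dc_axis,
            dr_axis=dr_axis,
            grids=grids,
            span=span,
            training_points=points,
            provenance=provenance or {},
        )

    # -- evaluation --------------------------------------------------------
    def scores_at(self, d_c: float, d_r: float) -> dict:
        """Evaluate the three surfaces at (d_c, d_r), clamped to [0, 1].
        Queries outside the training box are clamped to the nearest edge."""
        q = np.array(
            [
                np.clip(d_c, self.dc_axis[0], self.dc_axis[-1]),
                np.clip(d_r, self.dr_axis[0], self.dr_axis[-1]),
            ]
        )
        return {
            m: float(np.clip(self._interp[m](q)[0], 0.0, 1.0)) for m in METHODS
        }

    def summary(self) -> str:
        """Human-readable description of the fitted model."""
        n = len(self.training_points)
        ndeg = sum(p.degenerate for p in self.training_points)
        wins = {m: 0 for m in METHODS}
        for p in self.training_points:
            if not p.degenerate:
                wins[max(METHODS, key=lambda m: p.scores[m])] += 1
        lines = [
            "SVS scoring model",
            f"  training tests : {n} ({ndeg} degenerate)",
            f"  LOESS span     : {self.span}",
            f"  d_c range      : [{self.dc_axis[0]:.4f}, {self.dc_axis[-1]:.4f}]",
            f"  d_r range      : [{self.dr_axis[0]:.4f}, {self.dr_axis[-1]:.4f}]",
            "  wins by method : "
            + ", ".join(f"{m}={wins[m]}" for m in METHODS),
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        doc = {
            "version": 1,
            "methods": list(METHODS),
            "span": self.span,
            "grid": {
                "dc_axis": self.dc_axis.tolist(),
                "dr_axis": self.dr_axis.tolist(),
                "scores": {m: self.grids[m].tolist() for m in METHODS},
            },
            "training_points": [
                {
                    "d_c": p.d_c,
                    "d_r": p.d_r,
                    "v_m": p.v_m,
                    "scores": p.scores,
                    "degenerate": p.degenerate,
                }
                for p in self.training_points
            ],
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "ScoringModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("version") != 1:
            raise ValueError("unsupported model file version")
        pts = [
            ScoredTest(
                p["d_c"], p["d_r"], p["v_m"], p["scores"], p["degenerate"]
            )
            for p in doc.get("training_points", [])
        ]
        return cls(
            dc_axis=np.array(doc["grid"]["dc_axis"]),
            dr_axis=np.array(doc["grid"]["dr_axis"]),
            grids={m: np.array(doc["grid"]["scores"][m]) for m in METHODS},
            span=doc["span"],
            training_points=pts,
            provenance=doc.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Selection and meta-fusion

@dataclass(frozen=True)
class SelectionReport:
    method: str
    d_c: float
    d_r: float
    scores: dict
    tie: bool


def meta_fuse(results: list[LabelImage], weights) -> LabelImage:
    """Weighted per-element vote over several fusion results: foreground
    where the weighted foreground mass reaches half the total weight."""
    if len(results) < 2:
        raise ValueError("meta fusion needs at least 2 results")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(results) or np.any(w < 0):
        raise ValueError("need one non-negative weight per result")
    if w.sum() == 0:
        logger.warning("meta_fuse: all weights zero; falling back to unweighted vote")
        w = np.ones_like(w)
    acc = sum(wi * r.values.astype(float) for wi, r in zip(w, results))
    out = (acc >= 0.5 * w.sum()).astype(np.int8)
    return results[0].with_values(out)


def select(
    raters: RaterSet,
    model: ScoringModel,
    B: int = DEFAULT_B,
    staple_kwargs: dict | None = None,
) -> tuple[LabelImage, SelectionReport]:
    """Pick and run the best fusion method for this rater set.

    Computes (d_c, d_r), evaluates the scoring surfaces, and lazily runs
    only the winning fuser.  Score ties (within 1e-9) trigger a weighted
    meta-fusion of all three results using the scores as weights; unanimous
    inputs are returned directly.
    """
    if raters.K < 2:
        raise ValueError("selection needs at least 2 raters")
    pair = dissimilarity_factors(raters, B=B)
    if pair.unanimous:
        report = SelectionReport("unanimous", 0.0, 0.0, {}, False)
        return raters.grid, report
    scores = model.scores_at(pair.d_c, pair.d_r)
    ordered = sorted(scores.values(), reverse=True)
    tie = ordered[0] - ordered[1] <= TIE_TOL
    if not tie:
        best = max(METHODS, key=lambda m: scores[m])
        if best == "VOTE":
            label = fuse_vote(raters)
        elif best == "SBA":
            label = fuse_sba(raters)
        else:
            label = fuse_staple(raters, **(staple_kwargs or {})).label
        return label, SelectionReport(best, pair.d_c, pair.d_r, scores, False)
    fusions = run_all_fusers(raters, staple_kwargs)
    label = meta_fuse([fusions[m] for m in METHODS], [scores[m] for m in METHODS])
    return label, SelectionReport("meta", pair.d_c, pair.d_r, scores, True)
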