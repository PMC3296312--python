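import numpy as np
import pytest

from svsfuse import (
    LabelImage,
    RaterSet,
    ScoringModel,
    dissimilarity_factors,
    fuse_sba,
    fuse_staple,
    fuse_vote,
    meta_fuse,
    score_methods,
    select,
)
from svsfuse.svs import GRID_N, METHODS, loess2d_fit_grid

from conftest import img, raters


class TestScoreRule:
    def test_linear_interpolation_of_middle_method(self):
        scores, deg = score_methods({"STAPLE": 10, "VOTE": 20, "SBA": 30})
        assert scores == {"STAPLE": 1.0, "VOTE": 0.5, "SBA": 0.0}
        assert not deg

    def test_all_equal_is_degenerate_all_ones(self):
        scores, deg = score_methods({"STAPLE": 5, "VOTE": 5, "SBA": 5})
        assert scores == {"STAPLE": 1.0, "VOTE": 1.0, "SBA": 1.0}
        assert deg

    def test_two_way_worst_tie(self):
        scores, deg = score_methods({"STAPLE": 0, "VOTE": 7, "SBA": 7})
        assert scores == {"STAPLE": 1.0, "VOTE": 0.0, "SBA": 0.0}
        assert not deg


class TestLoessSurface:
    def test_constant_scores_give_constant_surface(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, 40)
        y = rng.uniform(0, 0.5, 40)
        s = np.full(40, 0.7)
        grid = loess2d_fit_grid(x, y, s, np.linspace(0, 2, 21),
                                np.linspace(0, 0.5, 21))
        assert np.allclose(grid, 0.7, atol=1e-9)

    def test_two_cluster_argmax_boundary_between_clusters(self):
        """Two disjoint (d_c, d_r) clusters with opposite winners: the
        fitted surfaces must cross between them."""
        rng = np.random.default_rng(1)
        xa = rng.normal(0.3, 0.05, 30)
        xb = rng.normal(1.7, 0.05, 30)
        y = rng.uniform(0.1, 0.4, 60)
        x = np.concatenate([xa, xb])
        s_sba = np.concatenate([np.ones(30), np.zeros(30)])
        s_staple = 1 - s_sba
        xg = np.linspace(0, 2, 41)
        yg = np.linspace(0.1, 0.4, 11)
        g_sba = loess2d_fit_grid(x, y, s_sba, xg, yg, span=0.3)
        g_staple = loess2d_fit_grid(x, y, s_staple, xg, yg, span=0.3)
        assert (g_sba[xg < 0.5] > g_staple[xg < 0.5]).all()
        assert (g_sba[xg > 1.5] < g_staple[xg > 1.5]).all()


def constant_model(scores: dict) -> ScoringModel:
    axis = np.linspace(0.0, 2.0, GRID_N)
    grids = {m: np.full((GRID_N, GRID_N), s) for m, s in scores.items()}
    return ScoringModel(dc_axis=axis, dr_axis=axis.copy(), grids=grids)


class TestMetaFuse:
    def test_identical_results_unchanged(self):
        a = np.zeros((4, 4), dtype=int)
        a[1:3] = 1
        out = meta_fuse([img(a), img(a), img(a)], [0.2, 0.5, 1.0])
        assert np.array_equal(out.values, a)

    def test_degenerate_weights_copy_first(self):
        a = np.zeros((3, 3), dtype=int)
        b = np.ones((3, 3), dtype=int)
        out = meta_fuse([img(a), img(b), img(b)], [1.0, 0.0, 0.0])
        assert np.array_equal(out.values, a)

    def test_hand_computed_weighted_vote(self):
        # weights (2,1,1): element fused to 1 iff 2*r1 + r2 + r3 >= 2
        r1 = [[1, 1, 0, 0]]
        r2 = [[0, 1, 1, 0]]
        r3 = [[0, 0, 1, 0]]
        out = meta_fuse([img(r1), img(r2), img(r3)], [2, 1, 1])
        assert out.values.tolist() == [[1, 1, 1, 0]]

    def test_all_zero_weights_fall_back_to_majority(self):
        r1 = [[1, 0]]
        r2 = [[1, 1]]
        out = meta_fuse([img(r1), img(r2)], [0, 0])
        assert out.values.tolist() == [[1, 1]]


class TestSelect:
    def _noisy_raters(self, seed=0, K=5):
        rng = np.random.default_rng(seed)
        base = np.zeros((20, 20), dtype=int)
        base[5:15, 5:15] = 1
        return RaterSet(
            tuple(
                LabelImage(np.where(rng.random(base.shape) < 0.15, 1 - base, base))
                for _ in range(K)
            )
        )

    def test_unique_argmax_runs_that_fuser_only(self):
        rs = self._noisy_raters()
        model = constant_model({"STAPLE": 0.9, "VOTE": 0.2, "SBA": 0.4})
        label, report = select(rs, model)
        assert report.method == "STAPLE"
        assert label == fuse_staple(rs).label

    def test_vote_and_sba_selected_when_top(self):
        rs = self._noisy_raters(1)
        label, report = select(rs, constant_model({"STAPLE": 0.1, "VOTE": 0.8, "SBA": 0.2}))
        assert report.method == "VOTE" and label == fuse_vote(rs)
        label, report = select(rs, constant_model({"STAPLE": 0.1, "VOTE": 0.2, "SBA": 0.8}))
        assert report.method == "SBA" and label == fuse_sba(rs)

    def test_exact_tie_triggers_meta_fusion(self):
        rs = self._noisy_raters(2)
        model = constant_model({"STAPLE": 0.5, "VOTE": 0.5, "SBA": 0.2})
        label, report = select(rs, model)
        assert report.method == "meta"
        assert report.tie

    def test_unanimous_input_short_circuits(self):
        a = np.zeros((6, 6), dtype=int)
        a[2:4, 2:4] = 1
        rs = raters(a, a, a)
        label, report = select(rs, constant_model({m: 0.5 for m in METHODS}))
        assert report.method == "unanimous"
        assert np.array_equal(label.values, a)

    def test_output_is_one_of_the_base_fusions_or_meta(self):
        rs = self._noisy_raters(3)
        model = constant_model({"STAPLE": 0.3, "VOTE": 0.9, "SBA": 0.1})
        label, report = select(rs, model)
        candidates = [
            fuse_vote(rs),
            fuse_sba(rs),
            fuse_staple(rs).label,
        ]
        assert any(label == c for c in candidates)

    def test_report_carries_dissimilarity(self):
        rs = self._noisy_raters(4)
        pair = dissimilarity_factors(rs)
        _, report = select(rs, constant_model({"STAPLE": 1, "VOTE": 0, "SBA": 0}))
        assert report.d_c == pytest.approx(pair.d_c)
        assert report.d_r == pytest.approx(pair.d_r)


class TestModelRoundTrip:
    def test_serialized_model_evaluates_identically(self, tmp_path, model2d):
        """Save -> load -> surface evaluations agree to <= 1e-6 at 1000
        random query points (including points outside the training box)."""
        p = tmp_path / "model.json"
        model2d.save(p)
        back = ScoringModel.load(p)
        rng = np.random.default_rng(0)
        qc = rng.uniform(-0.5, 3.0, 1000)
        qr = rng.uniform(-0.2, 1.0, 1000)
        for dc, dr in zip(qc, qr):
            a = model2d.scores_at(dc, dr)
            b = back.scores_at(dc, dr)
            for m in METHODS:
                assert abs(a[m] - b[m]) <= 1e-6

    def test_summary_mentions_training_size(self, model2d):
        text = model2d.summary()
        assert "training tests" in text and "span" in text


class TestTrainedSelectionRegions:
    def test_sba_region_at_low_dc_staple_at_high_dc(self, model2d, model3d):
        """The fitted argmax maps partition (d_c, d_r) with SBA favored at
        low d_c and STAPLE at high d_c, in both 2D and 3D."""
        for model in (model2d, model3d):
            G = np.stack([model.grids[m] for m in METHODS])
            am = G.argmax(axis=0)
            dc_mesh = np.repeat(model.dc_axis[:, None], GRID_N, axis=1)
            i_staple = METHODS.index("STAPLE")
            i_sba = METHODS.index("SBA")
            assert (am == i_staple).any() and (am == i_sba).any()
            assert dc_mesh[am == i_sba].mean() < dc_mesh[am == i_staple].mean()

    def test_homogeneous_raters_select_sba(self, model3d, sigma3d):
        """Equally deformed raters (low d_c, moderate d_r) — the regime the
        selector sees on real anatomical labels — select SBA."""
        from svsfuse.shape_sim import DeformationSpec, ShapeSpec3D, deform_3d

        spec = ShapeSpec3D()
        picks = []
        for rep in range(3):
            rng = np.random.default_rng((50, rep))
            fs = np.clip(rng.normal(0.6, 0.05, 10), 0, 1)
            rs = RaterSet(
                tuple(
                    deform_3d(spec, DeformationSpec(float(f), sigma3d, seed=(50, rep, j)))
                    for j, f in enumerate(fs)
                )
            )
            pair = dissimilarity_factors(rs)
            scores = model3d.scores_at(pair.d_c, pair.d_r)
            picks.append(max(METHODS, key=lambda m: scores[m]))
        assert picks.count("SBA") >= 2
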