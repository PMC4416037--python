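import numpy as np
import pytest

from vipselect.experiments import loo_baseline_sq_errors
from vipselect.nested import (
    Grid,
    NestedCvError,
    aggregate_relevance,
    inner_tune_ncomp,
    msep,
    nested_select,
    outer_test_msep,
    outer_vip_filter,
    rank_and_smooth,
    select_optimal,
)
from vipselect.preprocess import FeatureTable, dummy_code, log_center_scale
from vipselect._stack import loo_index_matrix, loo_msep
from vipselect.synthetic import SyntheticSpec, generate, planted_shifts


def smooth_oracle(matrix):
    """Independent double-loop normalized 3x3 cross-kernel convolution."""
    kernel = [(-1, 0, 1.0), (0, -1, 1.0), (0, 0, 2.0), (0, 1, 1.0), (1, 0, 1.0)]
    R, C = matrix.shape
    out = np.empty_like(matrix, dtype=float)
    for i in range(R):
        for j in range(C):
            num = den = 0.0
            for di, dj, w in kernel:
                ii, jj = i + di, j + dj
                if 0 <= ii < R and 0 <= jj < C and np.isfinite(matrix[ii, jj]):
                    num += w * matrix[ii, jj]
                    den += w
            out[i, j] = num / den if den else np.inf
    return out


class TestGrid:
    def test_defaults_match_full_scan(self):
        g = Grid()
        assert g.nkeep_values == tuple(range(1, 101))
        assert g.ncomp_values == tuple(range(1, 11))

    def test_from_ranges(self):
        g = Grid.from_ranges("1:30", "1:4")
        assert g.shape == (30, 4)

    @pytest.mark.parametrize("nk", [(), (3, 2), (0, 1)])
    def test_invalid_grids_rejected(self, nk):
        with pytest.raises(NestedCvError):
            Grid(nk, (1,))


class TestMsep:
    def test_perfect_prediction_is_zero(self):
        Y = np.eye(4)
        assert msep(Y, Y) == 0.0

    def test_zero_predictor_five_classes(self):
        Y = np.zeros((6, 5))
        Y[np.arange(6), np.arange(6) % 5] = 1.0
        assert msep(np.zeros((6, 5)), Y) == pytest.approx(0.2)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(3)
        Yp = rng.standard_normal((4, 3))
        Yt = rng.standard_normal((4, 3))
        acc = 0.0
        for i in range(4):
            for k in range(3):
                acc += (Yp[i, k] - Yt[i, k]) ** 2
        assert msep(Yp, Yt) == pytest.approx(acc / 12, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(NestedCvError, match="shape"):
            msep(np.zeros((3, 2)), np.zeros((2, 3)))


class TestRankAndSmooth:
    def test_constant_matrix_is_fixed_point(self):
        ranks, sm = rank_and_smooth(np.full((4, 3), 0.25))
        # all cells tie -> identical average ranks, preserved by smoothing
        assert np.allclose(sm, ranks[0, 0])

    def test_single_cell(self):
        ranks, sm = rank_and_smooth(np.array([[0.7]]))
        assert ranks[0, 0] == 1.0 and sm[0, 0] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((5, 4))
        ranks, sm = rank_and_smooth(m)
        np.testing.assert_allclose(sm, smooth_oracle(ranks), rtol=1e-12)

    def test_tie_free_ranks_are_permutation(self):
        rng = np.random.default_rng(9)
        m = rng.permutation(20).reshape(5, 4).astype(float)
        ranks, _ = rank_and_smooth(m)
        assert sorted(ranks.ravel()) == list(range(1, 21))

    def test_smoothing_bounded_by_rank_range(self):
        rng = np.random.default_rng(4)
        m = rng.random((6, 5))
        ranks, sm = rank_and_smooth(m)
        assert sm.min() >= ranks.min() - 1e-12
        assert sm.max() <= ranks.max() + 1e-12

    def test_infinite_cells_excluded_from_neighbors(self):
        m = np.array([[0.1, np.inf], [0.2, 0.3]])
        ranks, sm = rank_and_smooth(m)
        assert np.isinf(sm[0, 1])
        # finite ranks are 1..3; the flagged cell carries rank 4 but
        # contributes to no neighbor's normalization
        oracle = smooth_oracle(np.where(np.isfinite(m), ranks, np.inf))
        fin = np.isfinite(m)
        np.testing.assert_allclose(sm[fin], oracle[fin])

    def test_all_infinite_error(self):
        with pytest.raises(NestedCvError):
            rank_and_smooth(np.full((2, 2), np.inf))


class TestSelectOptimal:
    def test_unique_minimum(self):
        g = Grid((1, 2, 3, 4, 5), (1, 2, 3, 4))
        s = np.ones(g.shape)
        s[2, 1] = 0.1  # nkeep=3, ncomp=2
        assert select_optimal(s, g)[:2] == (3, 2)

    def test_tie_prefers_smaller_ncomp(self):
        g = Grid((1, 2, 3, 4, 5), (1, 2, 3, 4))
        s = np.ones(g.shape)
        s[4, 1] = 0.1  # (nkeep=5, ncomp=2)
        s[2, 3] = 0.1  # (nkeep=3, ncomp=4)
        nkeep, ncomp, ties = select_optimal(s, g)
        assert (nkeep, ncomp) == (5, 2) and ties == 2

    def test_tie_then_smaller_nkeep(self):
        g = Grid((1, 2, 3), (1, 2))
        s = np.ones(g.shape)
        s[0, 1] = s[2, 1] = 0.2
        assert select_optimal(s, g)[:2] == (1, 2)


class TestOuterVipFilter:
    def test_minimal_cell_keeps_exactly_one_feature(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        cv = outer_vip_filter(t, Grid((1,), (1,)))
        masks = cv.masks()
        assert masks.shape == (t.n_samples, 1, 1, t.n_features)
        np.testing.assert_array_equal(masks[:, 0, 0].sum(axis=1), 1)

    def test_dense_cell_mask_equals_nonzero_vip(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        p = t.n_features
        cv = outer_vip_filter(t, Grid((p,), (2,)))
        assert np.all((cv.vips[:, 0, 0] > 0) == cv.masks()[:, 0, 0])
        assert np.all(cv.masks()[:, 0, 0].sum(axis=1) <= p)

    def test_every_sample_held_out_once(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        cv = outer_vip_filter(t, Grid((2,), (1,)))
        assert cv.sample_ids == t.sample_ids
        assert cv.n_folds == t.n_samples
        idx = loo_index_matrix(t.n_samples)
        for f in range(t.n_samples):
            assert f not in idx[f] and len(set(idx[f])) == t.n_samples - 1

    def test_informative_mask_frequency_dominates_noise(self):
        # planted features should enter the candidate sets far more often
        wins = 0
        reps = 50
        for seed in range(reps):
            spec = SyntheticSpec(
                n_features=200, informative=planted_shifts(10, 2.5),
                seed=3000 + seed,
            )
            table, truth = generate(spec)
            scaled = log_center_scale(table)
            cv = outer_vip_filter(scaled, Grid((10,), (2,)))
            freq = cv.masks()[:, 0, 0].mean(axis=0)
            inf_idx = truth["informative"]
            noise_idx = [j for j in range(200) if j not in set(inf_idx)]
            wins += freq[inf_idx].mean() > freq[noise_idx].mean()
        assert wins / reps >= 0.95

    def test_raw_table_rejected(self):
        spec = SyntheticSpec(n_features=10, class_names=("a", "b"),
                             samples_per_class=(3, 3), seed=0)
        table, _ = generate(spec)
        with pytest.raises(NestedCvError, match="autoscaled"):
            outer_vip_filter(table, Grid((2,), (1,)))


class TestInnerTune:
    def test_single_candidate_single_component(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        cv = outer_vip_filter(t, Grid((1,), (1,)))
        inner_tune_ncomp(t, cv)
        np.testing.assert_array_equal(cv.inner_optimal_ncomp, 1)
        assert np.all(np.isfinite(cv.inner_msep))

    def test_separated_classes_beat_intercept_baseline(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        cv = outer_vip_filter(t, Grid((4,), (1, 2)))
        inner_tune_ncomp(t, cv)
        idx = loo_index_matrix(t.n_samples)
        Y = dummy_code(t.class_labels).values
        for f in range(t.n_samples):
            base = loo_baseline_sq_errors(Y[idx[f]]).mean()
            assert cv.inner_msep[f].min() < base

    def test_bit_identical_reruns(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        g = Grid((1, 3), (1, 2))
        cv1 = inner_tune_ncomp(t, outer_vip_filter(t, g))
        cv2 = inner_tune_ncomp(t, outer_vip_filter(t, g))
        np.testing.assert_array_equal(cv1.inner_msep, cv2.inner_msep)
        np.testing.assert_array_equal(cv1.vips, cv2.vips)


class TestOuterTest:
    def test_single_cell_dense_reduces_to_plain_loocv(self, tiny_scaled_table):
        # nkeep = p leaves the candidate mask all-true, so the grid's only
        # cell must equal a plain pooled LOOCV at those parameters
        t, _ = tiny_scaled_table
        p = t.n_features
        g = Grid((p,), (2,))
        cv = outer_vip_filter(t, g)
        assert cv.masks().all()
        inner_tune_ncomp(t, cv)
        outer = outer_test_msep(t, cv)
        Y = dummy_code(t.class_labels).values
        plain = loo_msep(t.values, Y, 2, p)
        assert outer[0, 0] == pytest.approx(plain, rel=1e-10)

    def test_pure_noise_msep_tracks_class_proportion_baseline(self):
        # with no signal the model cannot beat (or badly trail) the
        # intercept-only predictor, on average over replicates
        ratios = []
        for seed in range(50):
            spec = SyntheticSpec(n_features=100, informative={},
                                 seed=5000 + seed)
            table, _ = generate(spec)
            scaled = log_center_scale(table)
            g = Grid((5,), (1,))
            cv = outer_vip_filter(scaled, g)
            inner_tune_ncomp(scaled, cv)
            outer = outer_test_msep(scaled, cv)
            Y = dummy_code(scaled.class_labels).values
            ratios.append(outer[0, 0] / loo_baseline_sq_errors(Y).mean())
        assert 0.8 < np.mean(ratios) < 1.2

    def test_contradiction_diagnostic_counts_folds(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        g = Grid((2,), (1, 2))
        cv = outer_vip_filter(t, g)
        inner_tune_ncomp(t, cv)
        outer_test_msep(t, cv)
        total = cv.contradiction_count.sum(axis=1)
        # each (fold, nkeep) has exactly one agreeing ncomp among the two
        np.testing.assert_array_equal(total, t.n_samples)


class TestAggregateRelevance:
    def _cv(self, tiny_scaled_table, grid=None):
        t, _ = tiny_scaled_table
        g = grid or Grid((3,), (1, 2))
        cv = outer_vip_filter(t, g)
        inner_tune_ncomp(t, cv)
        outer_test_msep(t, cv)
        return t, g, cv

    def test_all_zero_vips_empty_table(self, tiny_scaled_table):
        t, g, cv = self._cv(tiny_scaled_table)
        cv.vips[:] = 0.0
        df = aggregate_relevance(cv, (3, 1))
        assert len(df) == 0

    def test_rows_meet_threshold_and_sorted(self, tiny_scaled_table):
        t, g, cv = self._cv(tiny_scaled_table)
        df = aggregate_relevance(cv, (3, 2), feature_meta=t.feature_meta)
        assert (df["mean_VIP"] >= 1.0).all()
        assert list(df["mean_VIP"]) == sorted(df["mean_VIP"], reverse=True)
        ik, ic = 0, 1
        v = cv.vips[:, ik, ic, :]
        for _, row in df.iterrows():
            j = t.feature_names.index(row["feature"])
            assert row["occurrence"] == (v[:, j] >= 1.0).sum()
            assert row["mean_VIP"] == pytest.approx(v[:, j].mean())

    def test_strict_operator(self, tiny_scaled_table):
        t, g, cv = self._cv(tiny_scaled_table)
        loose = aggregate_relevance(cv, (3, 2), op=">=")
        strict = aggregate_relevance(cv, (3, 2), op=">")
        assert set(strict["feature"]) <= set(loose["feature"])


class TestFullProcedure:
    def test_deterministic_end_to_end(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        g = Grid((1, 2, 4), (1, 2))
        cv1, sel1 = nested_select(t, g)
        cv2, sel2 = nested_select(t, g)
        np.testing.assert_array_equal(cv1.outer_msep, cv2.outer_msep)
        np.testing.assert_array_equal(sel1.smoothed_scores, sel2.smoothed_scores)
        assert sel1.optimal_nkeep == sel2.optimal_nkeep
        assert sel1.optimal_ncomp == sel2.optimal_ncomp
        assert sel1.relevance_table.equals(sel2.relevance_table)

    def test_selected_cell_attains_smoothed_minimum(self, tiny_scaled_table):
        t, _ = tiny_scaled_table
        g = Grid((1, 2, 4), (1, 2))
        _, sel = nested_select(t, g)
        ik = g.nkeep_values.index(sel.optimal_nkeep)
        ic = g.ncomp_values.index(sel.optimal_ncomp)
        assert sel.smoothed_scores[ik, ic] == sel.smoothed_scores.min()

    def test_label_permutation_null_calibration(self):
        # destroying the labels must not let the selected model genuinely
        # beat the class-proportion baseline (selection bias aside)
        spec = SyntheticSpec(
            n_features=20, class_names=("a", "b", "c"),
            samples_per_class=(4, 4, 4),
            informative={j: tuple(2.5 if k == j % 3 else 0.0 for k in range(3))
                         for j in range(4)},
            seed=11,
        )
        table, _ = generate(spec)
        g = Grid((1, 2, 3, 4, 5), (1, 2))
        rng = np.random.default_rng(99)
        ratios = []
        for _rep in range(20):
            perm = rng.permutation(table.n_samples)
            pt = FeatureTable(
                table.sample_ids,
                [table.class_labels[i] for i in perm],
                table.values, table.feature_meta, "raw",
            )
            scaled = log_center_scale(pt)
            cv, sel = nested_select(scaled, g)
            ik = g.nkeep_values.index(sel.optimal_nkeep)
            ic = g.ncomp_values.index(sel.optimal_ncomp)
            base = loo_baseline_sq_errors(
                dummy_code(scaled.class_labels).values
            ).mean()
            ratios.append(cv.outer_msep[ik, ic] / base)
        assert np.mean(ratios) > 0.8
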