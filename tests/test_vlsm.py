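import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmhtracts.io import LesionMap, TractROISet
from wmhtracts.vlsm import (
    VLSM,
    _bm_vectorized,
    brunner_munzel,
    fdr_bh,
    residualize_scores,
    tract_voxel_summary,
    vlsm_map,
)

AFF = np.eye(4)


class TestBrunnerMunzel:
    def test_identical_groups_are_symmetric(self):
        res = brunner_munzel([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_hat == pytest.approx(0.5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_is_degenerate(self):
        res = brunner_munzel([1, 2, 3], [4, 5, 6])
        assert res.degenerate
        assert res.p_hat == pytest.approx(1.0)
        assert np.isnan(res.statistic)

    def test_frozen_four_plus_four_example(self):
        # pooled ranks a -> {1,2,4,7}, b -> {3,5,6,8}; closed form by hand
        res = brunner_munzel([1, 2, 4, 7], [3, 5, 6, 8])
        assert res.statistic == pytest.approx(np.sqrt(1.5), abs=1e-12)
        assert res.df == pytest.approx(4.8, abs=1e-12)
        assert res.p_value == pytest.approx(0.277354625308831, abs=1e-12)
        assert res.p_hat == pytest.approx(0.75)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(4, 12))
            b = rng.normal(1.0, 2.0, size=rng.integers(4, 12))
            mine = brunner_munzel(a, b)
            ref = stats.brunnermunzel(a, b)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_ties_use_midranks_like_scipy(self, rng):
        a = rng.integers(0, 4, size=15).astype(float)
        b = rng.integers(1, 5, size=12).astype(float)
        mine = brunner_munzel(a, b)
        ref = stats.brunnermunzel(a, b)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_close_to_exact_wilcoxon_at_moderate_n(self, rng):
        # no ties, equal spread: BM and the rank-sum test nearly coincide
        for _ in range(5):
            a = rng.normal(size=20)
            b = rng.normal(0.5, 1.0, size=20)
            p_bm = brunner_munzel(a, b).p_value
            p_w = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert abs(p_bm - p_w) < 0.02

    def test_one_sided_option_orders_correctly(self):
        a = [5.0, 6.0, 7.0, 8.0, 2.0]
        b = [1.0, 2.5, 3.0, 4.0, 9.0]  # b mostly lower
        res = brunner_munzel(a, b, sided="less")
        assert res.p_value < 0.5  # evidence toward lesion-present < lesion-absent

    def test_vectorized_path_equals_scalar_path(self, rng):
        scores = rng.normal(size=40)
        lesions = rng.random((40, 30)) < rng.uniform(0.15, 0.85, 30)
        keep = (lesions.sum(0) >= 2) & ((~lesions).sum(0) >= 2)
        lesions = lesions[:, keep]
        stat, df, p, phat = _bm_vectorized(scores, lesions, "two")
        for j in range(lesions.shape[1]):
            col = lesions[:, j]
            ref = brunner_munzel(scores[~col], scores[col])
            if ref.degenerate:
                assert np.isnan(stat[j])
            else:
                assert stat[j] == pytest.approx(ref.statistic, abs=1e-10)
                assert df[j] == pytest.approx(ref.df, abs=1e-10)
                assert p[j] == pytest.approx(ref.p_value, abs=1e-10)
                assert phat[j] == pytest.approx(ref.p_hat, abs=1e-10)


class TestFDR:
    def test_all_tiny_p_all_significant(self):
        flags, crit = fdr_bh([0.001] * 6, 0.05)
        assert flags.all() and crit == pytest.approx(0.001)

    def test_step_up_example(self):
        flags, crit = fdr_bh([0.01, 0.02, 0.03, 0.2], 0.05)
        assert flags.tolist() == [True, True, True, False]
        assert crit == pytest.approx(0.03)

    def test_large_p_nothing_significant(self):
        flags, crit = fdr_bh([0.9, 0.8], 0.05)
        assert not flags.any() and np.isnan(crit)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            flags, _ = fdr_bh(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(flags, ref)

    def test_bonferroni_rejections_are_bh_rejections(self, rng):
        p = rng.random(100) ** 2
        flags, _ = fdr_bh(p, 0.05)
        bonf = p <= 0.05 / len(p)
        assert flags[bonf].all()


class TestResidualize:
    def test_orthogonal_covariate_leaves_centered_scores(self):
        y = pd.Series([1.0, -1.0, 2.0, -2.0])
        cov = pd.DataFrame({"c": [1.0, 1.0, -1.0, -1.0]})  # orthogonal to y
        resid = residualize_scores(y, cov)
        assert np.allclose(resid, y)

    def test_exact_linear_scores_residual_zero(self, rng):
        cov = pd.DataFrame({"age": rng.normal(size=20), "edu": rng.normal(size=20)})
        y = pd.Series(1.0 + 0.5 * cov["age"] - 0.2 * cov["edu"])
        assert np.allclose(residualize_scores(y, cov), 0, atol=1e-10)

    def test_matches_ols_residual_oracle(self, rng):
        from wmhtracts.regression import fit_ols

        cov = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        y = pd.Series(rng.normal(size=30))
        resid = residualize_scores(y, cov)
        assert np.allclose(resid, fit_ols(y, cov).result.resid, atol=1e-12)
        assert abs(resid.mean()) < 1e-12


def _grid_cohort(rng, n=40, shape=(8, 8, 4), lesion_p=0.45):
    maps = []
    for i in range(n):
        data = (rng.random(shape) < lesion_p).astype(np.uint8)
        maps.append(LesionMap(f"s{i}", data, AFF))
    return maps


class TestVLSMMap:
    def test_monotone_score_transform_invariance(self, rng):
        maps = _grid_cohort(rng)
        scores = rng.normal(size=40)
        r1 = vlsm_map(maps, scores, min_subjects=5)
        r2 = vlsm_map(maps, np.exp(scores) + 3.0, min_subjects=5)  # strictly monotone
        assert np.array_equal(r1.significant, r2.significant)
        assert np.allclose(r1.statistic, r2.statistic, equal_nan=True)

    def test_constant_scores_rejected(self, rng):
        maps = _grid_cohort(rng)
        with pytest.raises(ValueError, match="constant"):
            vlsm_map(maps, np.ones(40), min_subjects=5)

    def test_no_sufficiently_lesioned_voxel_is_error(self, rng):
        maps = _grid_cohort(rng, lesion_p=0.02)
        with pytest.raises(ValueError, match="no voxel"):
            vlsm_map(maps, rng.normal(size=40), min_subjects=30)

    def test_lesion_shifted_scores_detected(self, rng):
        maps = _grid_cohort(rng, n=60)
        target = maps[0].data * 0  # one voxel drives the scores
        vox = (4, 4, 2)
        scores = rng.normal(size=60)
        for i, m in enumerate(maps):
            if m.data[vox]:
                scores[i] -= 2.5
        res = vlsm_map(maps, scores, min_subjects=5)
        assert res.significant[vox]

    def test_significant_is_subset_of_tested(self, rng):
        maps = _grid_cohort(rng)
        res = vlsm_map(maps, rng.normal(size=40), min_subjects=5)
        assert not (res.significant & ~res.tested).any()
        assert res.n_tested == int(res.tested.sum())
        p_tested = res.p[res.tested]
        finite = p_tested[~np.isnan(p_tested)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_model_object_residualizes_before_mapping(self, rng):
        maps = _grid_cohort(rng)
        scores = pd.Series(rng.normal(size=40))
        cov = pd.DataFrame({"age": rng.normal(size=40)})
        direct = vlsm_map(maps, residualize_scores(scores, cov).to_numpy(), min_subjects=5)
        via_model = VLSM(maps, scores, cov, min_subjects=5).fit()
        assert np.allclose(direct.statistic, via_model.statistic, equal_nan=True)


class TestTractSummary:
    def _summary_inputs(self, rng):
        maps = _grid_cohort(rng)
        res = vlsm_map(maps, rng.normal(size=40), min_subjects=5)
        masks = {
            "a": rng.random((8, 8, 4)) < 0.4,
            "b": rng.random((8, 8, 4)) < 0.4,
        }
        rois = TractROISet(["a", "b"], masks, AFF)
        return res, rois

    def test_counts_match_intersection_oracle(self, rng):
        res, rois = self._summary_inputs(rng)
        table = tract_voxel_summary(res, rois)
        for name in ("a", "b"):
            assert table.loc[name, "region_size"] == int(rois[name].sum())
            assert table.loc[name, "tested"] == int((rois[name] & res.tested).sum())
            assert table.loc[name, "significant_score"] == int(
                (rois[name] & res.significant).sum()
            )

    def test_disjoint_mask_counts_zero(self, rng):
        res, _ = self._summary_inputs(rng)
        empty = TractROISet(["none"], {"none": np.zeros((8, 8, 4), bool)}, AFF)
        table = tract_voxel_summary(res, empty)
        assert table.loc["none"].sum() == 0

    def test_counts_never_exceed_region_size(self, rng):
        res, rois = self._summary_inputs(rng)
        table = tract_voxel_summary({"exec": res, "mem": res}, rois)
        assert (table["tested"] <= table["region_size"]).all()
        assert (table["significant_exec"] <= table["tested"]).all()
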