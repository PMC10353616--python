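import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dalff.clinical import (
    chi_square_2x2,
    demographics_report,
    extract_roi_means,
    moment_matched_sample,
    roc_auc,
    spearman,
    two_sample_t_pooled,
)
from dalff.datatypes import ScalarMap


class TestExtractRoiMeans:
    def _map(self, values, mask=None):
        mask = np.ones(values.shape, bool) if mask is None else mask
        return ScalarMap(values=values, mask=mask, kind="dalff_cv")

    def test_constant_map(self):
        roi = np.zeros((3, 3, 3), bool)
        roi[1, 1, :] = True
        out = extract_roi_means([self._map(np.full((3, 3, 3), 0.7))], roi)
        npt.assert_allclose(out, [0.7])

    def test_two_voxel_mean(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0], vals[0, 0, 1] = 0.2, 0.4
        roi = np.zeros((2, 2, 2), bool)
        roi[0, 0, :] = True
        assert extract_roi_means([self._map(vals)], roi)[0] == pytest.approx(0.3)

    def test_matches_loop_oracle(self, rng):
        maps = [self._map(rng.random((4, 4, 4))) for _ in range(5)]
        roi = rng.random((4, 4, 4)) > 0.5
        out = extract_roi_means(maps, roi)
        for i, m in enumerate(maps):
            vals = [m.values[idx] for idx in zip(*np.nonzero(roi))]
            assert out[i] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_roi_means([self._map(np.ones((2, 2, 2)))], np.zeros((2, 2, 2), bool))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(size=20)
        rho, p = spearman(x, np.exp(x))
        assert rho == 1.0 and p == 0.0
        rho, _ = spearman(x, -np.exp(x))
        assert rho == -1.0

    def test_hand_rank_formula(self):
        # d^2 sum = 4 -> rho = 1 - 6*4/120 = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetry_and_monotone_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0], abs=1e-12)
        assert spearman(np.exp(x), y)[0] == pytest.approx(spearman(x, y)[0], abs=1e-12)

    def test_exact_permutation_small_n(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=7)
        rho, p_exact = spearman(x, y, exact=True)
        assert 0 < p_exact <= 1
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        auc, _ = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_pairwise_enumeration_example(self):
        # patients [0.9,0.8,0.4] vs controls [0.7,0.3,0.2]: 8/9 concordant
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0, 0])
        assert auc == pytest.approx(8.0 / 9.0, abs=1e-12)

    def test_complement_identity(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(scores, 1 - labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10**6))
    def test_equals_mann_whitney_u(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.arange(12, dtype=float))  # tie-free
        labels = np.r_[np.ones(5, int), np.zeros(7, int)]
        auc, _ = roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / (5 * 7), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


class TestPooledT:
    def test_printed_demographics_age_row(self):
        # moment-matched to n=34: 56.500 +/- 10.999 vs n=44: 55.340 +/- 11.485
        a = moment_matched_sample(34, 56.500, 10.999, seed=10)
        b = moment_matched_sample(44, 55.340, 11.485, seed=11)
        t, df, p = two_sample_t_pooled(a, b)
        assert t == pytest.approx(0.450, abs=0.001)
        assert df == 76

    def test_identical_samples(self):
        t, df, p = two_sample_t_pooled([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0

    def test_hand_example(self):
        t, df, _ = two_sample_t_pooled([1.0, 2, 3], [4.0, 5, 6])
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert df == 4

    def test_antisymmetric(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=12)
        assert two_sample_t_pooled(a, b)[0] == pytest.approx(
            -two_sample_t_pooled(b, a)[0], abs=1e-12)

    def test_matches_scipy_pooled(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, 2.0, size=15)
        t, df, p = two_sample_t_pooled(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestChiSquare:
    def test_printed_demographics_sex_row(self):
        chi2, df, p = chi_square_2x2([[25, 9], [19, 25]])
        assert chi2 == pytest.approx(7.184, abs=0.01)
        assert df == 1

    def test_balanced_table_zero(self):
        assert chi_square_2x2([[10, 10], [10, 10]])[0] == 0.0

    def test_diagonal_table(self):
        assert chi_square_2x2([[5, 0], [0, 5]])[0] == pytest.approx(10.0, abs=1e-12)

    def test_invariances(self):
        t = np.array([[12, 5], [7, 20]])
        base = chi_square_2x2(t)[0]
        assert chi_square_2x2(t.T)[0] == pytest.approx(base, abs=1e-12)
        assert chi_square_2x2(t[::-1, ::-1])[0] == pytest.approx(base, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [3, 4]])


class TestDemographicsReport:
    def _participants(self, rng, n1=8, n2=9):
        n = n1 + n2
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["patient"] * n1 + ["control"] * n2,
            "age": rng.normal(56, 11, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.normal(9, 3, n),
        })

    def test_statistics_rederivable_from_raw_columns(self, rng):
        part = self._participants(rng)
        rep = demographics_report(part)
        age_row = rep[rep["variable"] == "age"].iloc[0]
        pat = part[part["group"] == "patient"]["age"].to_numpy()
        ctl = part[part["group"] == "control"]["age"].to_numpy()
        t, _, _ = two_sample_t_pooled(pat, ctl)
        assert f"t = {t:.3f}" == age_row["statistic"]

    def test_single_group_omits_comparison(self, rng):
        part = self._participants(rng, n1=8, n2=0)
        part = part[part["group"] == "patient"]
        rep = demographics_report(part)
        assert (rep["note"].str.contains("single group")).any()

    def test_scale_quartiles_match_sort_based_oracle(self, rng):
        clin = pd.DataFrame({"subject_id": [f"s{i}" for i in range(11)],
                             "NIHSS": rng.integers(0, 20, 11).astype(float)})
        part = self._participants(rng, 6, 5)
        rep = demographics_report(part, clin)
        row = rep[rep["variable"] == "NIHSS"].iloc[0]
        v = np.sort(clin["NIHSS"].to_numpy())
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # type-7 interpolation
        assert row["patients"] == f"{med:.1f} ({q1:.1f}, {q3:.1f})"

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="group"):
            demographics_report(pd.DataFrame({"subject_id": ["a"]}))
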