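"""Phenotype scoring: log2FC normalization, t-tests, ABC, anoikis,
aggressiveness, and Pearson association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pathphen import (anoikis_scores, apoptosis_resistance_score,
                      gen_assay_replicates, gen_dose_response,
                      log2fc_normalize, one_sample_ttest,
                      overall_aggressiveness, pearson_association,
                      phenotype_matrix, score_phenotype_table,
                      shapiro_normality)


class TestLog2FC:
    def test_identity_gives_zero(self):
        s = log2fc_normalize([10, 10, 10], [10, 10, 10])
        assert s.log2fc == 0.0 and s.n == 3

    def test_mammosphere_area_worked_example(self):
        # mean spheroid areas of 65 vs 785 um^2
        s = log2fc_normalize([65.0], [785.0])
        assert s.log2fc == pytest.approx(np.log2(65 / 785))
        assert s.log2fc == pytest.approx(-3.594, abs=5e-4)

    def test_doubling_gives_one(self):
        s = log2fc_normalize([20, 20], [10, 10])
        assert s.log2fc == pytest.approx(1.0)

    def test_nonpositive_value_names_replicate(self):
        with pytest.raises(ValueError, match="replicate index 1"):
            log2fc_normalize([5.0, -2.0, 3.0], [10.0])

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_common_scale_invariance(self, c):
        a = np.array([3.0, 4.0, 5.0])
        ref = np.array([6.0, 7.0])
        assert log2fc_normalize(a * c, ref * c).log2fc == pytest.approx(
            log2fc_normalize(a, ref).log2fc, abs=1e-9)

    def test_ratio_of_means_option(self):
        s = log2fc_normalize([10, 30], [10, 10], method="ratio-of-means")
        assert s.log2fc == pytest.approx(1.0)


class TestOneSampleTTest:
    def test_symmetric_replicates_give_p_one(self):
        assert one_sample_ttest([-1.0, 0.0, 1.0]) == pytest.approx(1.0)

    def test_shrinking_jitter_drives_p_to_zero(self):
        last = 1.0
        for eps in (1e-1, 1e-3, 1e-5):
            p = one_sample_ttest([1.0 - eps, 1.0, 1.0 + eps])
            assert p < last
            last = p
        assert last < 1e-8

    def test_closed_form_t_cdf_cross_check(self):
        x = np.array([0.5, 1.0, 1.5])
        t = x.mean() / (x.std(ddof=1) / np.sqrt(3))
        expected = 2 * stats.t.sf(abs(t), df=2)
        assert one_sample_ttest(x) == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(one_sample_ttest([1.0, 1.0, 1.0]))


class TestShapiro:
    def test_gaussian_sample_flagged_normal(self):
        x = np.random.default_rng(0).normal(size=1000)
        stat, p, ok = shapiro_normality(x)
        assert ok and 0 < stat <= 1

    def test_point_mass_plus_outlier_flagged_non_normal(self):
        _, p, ok = shapiro_normality([1.0, 1.0, 1.0, 1.0001, 50.0])
        assert not ok and p < 0.05

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            shapiro_normality([1.0, 2.0])


class TestABCScore:
    doses = (0.3, 0.7, 1.0)

    def test_identical_curves_score_zero(self):
        ref = pd.Series([1.0, 2.0, 4.0], index=self.doses)
        assert apoptosis_resistance_score(ref, ref) == 0.0

    def test_constant_unit_delta_gives_dose_span(self):
        ref = pd.Series([2.0, 2.0, 2.0], index=self.doses)
        cell = ref / 2.0  # delta = log2(ref/cell) = 1 everywhere
        assert apoptosis_resistance_score(cell, ref) == pytest.approx(0.7)

    def test_triangular_delta_trapezoid_by_hand(self):
        # delta = (0, 1, 0) -> 0.5*0.4 + 0.5*0.3 = 0.35
        ref = pd.Series([1.0, 2.0, 1.0], index=self.doses)
        cell = pd.Series([1.0, 1.0, 1.0], index=self.doses)
        assert apoptosis_resistance_score(cell, ref) == pytest.approx(0.35)

    def test_antisymmetry_under_curve_swap(self, rng):
        ref = pd.Series(2.0 ** rng.normal(1, 0.5, 3), index=self.doses)
        cell = pd.Series(2.0 ** rng.normal(0, 0.5, 3), index=self.doses)
        a = apoptosis_resistance_score(cell, ref)
        b = apoptosis_resistance_score(ref, cell)
        assert a == pytest.approx(-b)

    def test_monotone_in_delta(self):
        ref = pd.Series([2.0, 2.0, 2.0], index=self.doses)
        scores = [apoptosis_resistance_score(ref * 2.0 ** (-d), ref)
                  for d in (0.5, 1.0, 1.5)]
        assert scores[0] < scores[1] < scores[2]

    def test_recovers_planted_shift_times_span(self):
        for s in (0.5, 2.0):
            ref, test = gen_dose_response(shift=s, noise_sd=0.0, seed=0)
            score = apoptosis_resistance_score(test, ref)
            assert score == pytest.approx(s * (1.0 - 0.3))

    def test_high_dose_excluded_by_default(self):
        doses4 = (0.3, 0.7, 1.0, 3.0)
        ref = pd.Series([2.0] * 4, index=doses4)
        cell = ref / 2.0
        assert apoptosis_resistance_score(cell, ref) == pytest.approx(0.7)

    def test_partial_dose_overlap_drops_with_warning(self):
        ref = pd.Series([2.0, 2.0, 2.0], index=(0.3, 0.7, 1.0))
        cell = pd.Series([1.0, 1.0], index=(0.3, 0.7))
        with pytest.warns(UserWarning):
            score = apoptosis_resistance_score(cell, ref)
        assert score == pytest.approx(1.0 * (0.7 - 0.3))

    def test_disjoint_dose_grids_rejected(self):
        ref = pd.Series([1.0, 1.0], index=(0.3, 0.7))
        cell = pd.Series([1.0, 1.0], index=(1.5, 2.0))
        with pytest.raises(ValueError):
            apoptosis_resistance_score(cell, ref)


class TestAnoikis:
    def test_worked_ratio(self):
        di, res = anoikis_scores(50, 100)
        assert (di, res) == (0.5, 2.0)

    def test_equal_counts_give_unit_scores(self):
        di, res = anoikis_scores(70, 70)
        assert di == 1.0 and res == 1.0 and np.log2(res) == 0.0

    def test_zero_dead_guarded(self):
        with pytest.warns(UserWarning):
            di, res = anoikis_scores(0, 100)
        assert di == 0.0 and np.isinf(res)

    def test_zero_live_rejected(self):
        with pytest.raises(ValueError):
            anoikis_scores(10, 0)


class TestAggressiveness:
    def test_constant_rows(self):
        m = pd.DataFrame({"a": [0.0] * 6, "b": [1.0] * 6}).T
        agg = overall_aggressiveness(m)
        assert agg["a"] == 0.0 and agg["b"] == 1.0

    def test_missing_entries_ignored_in_mean(self):
        row = pd.DataFrame([[2.0, -1.0, 0.0, np.nan, 1.0, 0.0]], index=["x"])
        assert overall_aggressiveness(row)["x"] == pytest.approx(0.4)

    def test_all_missing_row_excluded_with_warning(self):
        m = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan]], index=["ok", "gone"])
        with pytest.warns(UserWarning):
            agg = overall_aggressiveness(m)
        assert list(agg.index) == ["ok"]

    def test_ordering_total_with_lexicographic_ties(self):
        m = pd.DataFrame([[1.0], [1.0], [0.0]], index=["zeta", "alpha", "low"])
        assert list(overall_aggressiveness(m).index) == ["low", "alpha", "zeta"]


class TestPearson:
    def test_perfect_and_reversed(self):
        x = np.arange(5.0)
        assert pearson_association(x, x)[0] == pytest.approx(1.0)
        assert pearson_association(x, -2 * x + 5)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson_association([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_association([1, 1, 1], [1, 2, 3])


class TestScoreTable:
    def test_recovers_planted_log2fc(self):
        planted = {"mutA": 1.0, "mutB": -2.0, "mutC": 0.0}
        table = gen_assay_replicates(planted, n_replicates=5, noise_sd=0.02, seed=4)
        scored = score_phenotype_table(table, reference="WT_OE")
        m = phenotype_matrix(scored)
        for cell, fc in planted.items():
            assert m.loc[cell, "invasion"] == pytest.approx(fc, abs=0.1)

    def test_missing_reference_rejected(self):
        table = gen_assay_replicates({"mutA": 1.0}, seed=0)
        with pytest.raises(ValueError):
            score_phenotype_table(table, reference="NOPE")
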