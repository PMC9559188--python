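import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilatdr.cohort import Cohort
from bilatdr.simulate import arctan_weight
from bilatdr.weights import (
    WeightFit,
    WeightSeries,
    build_weight_series,
    compute_area_matrix,
    dc_from_areas,
    dp_from_areas,
    evaluate_weights,
    fit_weight_function,
    raw_weight,
)

from conftest import make_cohort_df


class TestSpreads:
    def test_equal_rows(self):
        S = [[1.0, 2.0], [1.0, 2.0]]
        assert dp_from_areas(S) == 0.0
        assert dc_from_areas(S) == 2.0

    def test_equal_columns(self):
        S = [[1.0, 1.0], [2.0, 2.0]]
        assert dp_from_areas(S) == 2.0
        assert dc_from_areas(S) == 0.0

    def test_hand_example(self):
        S = [[1.0, 2.0], [3.0, 5.0]]
        assert dp_from_areas(S) == 5.0  # |1-3| + |2-5|
        assert dc_from_areas(S) == 3.0  # |1-2| + |3-5|

    def test_shift_invariance(self):
        S = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert dp_from_areas(S + 7.3) == pytest.approx(dp_from_areas(S))
        assert dc_from_areas(S + 7.3) == pytest.approx(dc_from_areas(S))

    def test_transpose_swaps(self):
        S = np.array([[1.0, 2.0, 0.5], [3.0, 5.0, 1.0]])
        assert dp_from_areas(S.T) == pytest.approx(dc_from_areas(S))
        assert dc_from_areas(S.T) == pytest.approx(dp_from_areas(S))

    def test_missing_cells_skipped(self):
        S = np.array([[1.0, np.nan], [3.0, 5.0]])
        assert dp_from_areas(S) == 2.0
        assert dc_from_areas(S) == 2.0

    def test_degenerate_single_row(self):
        assert dp_from_areas([[1.0, 2.0]]) == 0.0


class TestRawWeight:
    def test_hand_example(self):
        assert raw_weight(5.0, 3.0) == pytest.approx(0.625)

    def test_zero_dp(self):
        assert raw_weight(0.0, 2.0) == 0.0

    def test_double_zero_fallback(self):
        assert raw_weight(0.0, 0.0) == 0.5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            raw_weight(-1.0, 1.0)


class TestAreaMatrix:
    def _block_cohort(self, spec):
        """spec: {(t_pbc, t_cbc): list of (followup, event)} -> Cohort."""
        rows = []
        k = 0
        for (lp, lc), obs in spec.items():
            for fu, ev in obs:
                rows.append(
                    dict(patient_id=f"X{k:04d}", age_pbc=50.0, age_cbc=55.0,
                         interval_time=5.0, t_pbc=lp, t_cbc=lc,
                         followup_time=fu, event=ev)
                )
                k += 1
        return Cohort(pd.DataFrame(rows))

    def test_single_cell(self):
        cohort = self._block_cohort({("T1", "T1"): [(1.0, 1), (2.0, 0)] * 12})
        S = compute_area_matrix(cohort, "t", (4.0, 6.0), upper=4.0, min_subgroup=5)
        assert S.shape == (1, 1)

    def test_identical_patterns_equal_entries(self):
        obs = [(1.0, 1), (2.0, 2), (3.0, 0)] * 8
        cohort = self._block_cohort({("T1", "T1"): obs, ("T2", "T1"): list(obs)})
        S = compute_area_matrix(cohort, "t", (4.0, 6.0), upper=5.0, min_subgroup=5)
        assert S.loc["T1", "T1"] == pytest.approx(S.loc["T2", "T1"])

    def test_known_step_integral(self):
        # every patient dies of cause 1 at t=2: CIF jumps to 1 at 2, area to R=4 is 2
        cohort = self._block_cohort({("T1", "T1"): [(2.0, 1)] * 25})
        S = compute_area_matrix(cohort, "t", (4.0, 6.0), upper=4.0, min_subgroup=5)
        assert S.loc["T1", "T1"] == pytest.approx(2.0)

    def test_sparse_cells_nan_and_all_sparse_error(self):
        cohort = self._block_cohort({("T1", "T1"): [(1.0, 1)] * 3})
        with pytest.raises(ValueError, match="unusable"):
            compute_area_matrix(cohort, "t", (4.0, 6.0), upper=4.0, min_subgroup=5)

    def test_unknown_variable(self):
        cohort = self._block_cohort({("T1", "T1"): [(1.0, 1)] * 25})
        with pytest.raises(KeyError):
            compute_area_matrix(cohort, "surgery", (4.0, 6.0))


class TestFitWeightFunction:
    def _series(self, t, w, counts=None):
        t = np.asarray(t, dtype=float)
        w = np.asarray(w, dtype=float)
        counts = np.full(t.shape, 500) if counts is None else np.asarray(counts)
        return WeightSeries(
            variable="t", bin_centers=t, raw_wp=w, bin_counts=counts,
            area_matrices=[None] * t.size, sparse=np.zeros(t.size, dtype=bool),
        )

    def test_noiseless_recovery(self):
        t = np.arange(1.0, 11.0)
        truth = (0.4, 0.5, -2.0)
        fit = fit_weight_function(self._series(t, arctan_weight(t, *truth)))
        assert np.allclose([fit.a, fit.b, fit.c], truth, atol=1e-6)
        assert fit.residual_rms < 1e-8

    def test_constant_series_fallback(self):
        t = np.arange(1.0, 9.0)
        fit = fit_weight_function(self._series(t, np.full(8, 0.5)))
        wp, wc = evaluate_weights(fit, 3.7)
        assert wp == pytest.approx(0.5)
        assert fit.b == 0.0

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(17)
        t = np.arange(1.0, 16.0)
        truth = (0.34, 0.5, -2.0)
        w = arctan_weight(t, *truth) + rng.normal(0, 0.03, t.size)
        fit = fit_weight_function(self._series(t, np.clip(w, 0, 1)))
        est = arctan_weight(t, fit.a, fit.b, fit.c)
        assert np.sqrt(np.mean((est - arctan_weight(t, *truth)) ** 2)) < 0.05

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="usable"):
            fit_weight_function(self._series([1.0, 2.0], [0.5, 0.4]))


class TestEvaluateWeights:
    def test_sum_to_one_exactly(self):
        fit = WeightFit("t", 0.34, 0.5, -2.0)
        for t in (0.0, 1.0, 5.0, 24.0):
            wp, wc = evaluate_weights(fit, t)
            assert wp + wc == 1.0

    def test_monotone_nonincreasing(self):
        fit = WeightFit("t", 0.34, 0.5, -2.0)
        grid = np.linspace(0, 25, 60)
        wp, _ = evaluate_weights(fit, grid)
        assert (np.diff(wp) <= 0).all()

    def test_paper_worked_example_weights(self):
        # calibrated so that w_p(5) = 0.37731 exactly
        a = 0.37731 / (np.pi / 2 - np.arctan(0.5))
        fit = WeightFit("t", a, 0.5, -2.0)
        wp, wc = evaluate_weights(fit, 5.0)
        assert round(wp, 5) == 0.37731
        assert round(wc, 5) == 0.62269

    def test_clipping(self):
        fit = WeightFit("t", 0.9, 0.0, -20.0)  # raw value far above 1
        wp, wc = evaluate_weights(fit, 1.0)
        assert wp == 0.99 and wc == pytest.approx(0.01)

    @given(st.floats(0.05, 0.9), st.floats(0.0, 2.0), st.floats(-5.0, 5.0),
           st.floats(0.0, 25.0))
    @settings(max_examples=50, deadline=None)
    def test_always_valid_weights(self, a, b, c, t):
        wp, wc = evaluate_weights(WeightFit("t", a, b, c), t)
        assert 0.01 <= wp <= 0.99
        assert wp + wc == 1.0


class TestSwapSymmetry:
    def test_swapping_sides_complements_raw_weights(self, sim_cohort):
        _, cohort, _ = sim_cohort
        s1 = build_weight_series(cohort, "grade", bin_centers=range(2, 13))
        df2 = cohort.df.rename(
            columns={"grade_pbc": "grade_cbc", "grade_cbc": "grade_pbc"}
        )
        s2 = build_weight_series(
            Cohort(df2), "grade", bin_centers=range(2, 13)
        )
        m = s1.usable() & s2.usable()
        assert m.sum() >= 3
        np.testing.assert_allclose(s1.raw_wp[m] + s2.raw_wp[m], 1.0, atol=1e-12)
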