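import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from bilatdr.competing import (
    CIFCurve,
    ConvergenceError,
    any_event_cif,
    cif_area,
    estimate_cif,
    fit_fine_gray,
    predict_cif,
)


def fg_sim(n, beta, seed, p=0.3, lam=0.3, cens=0.05, horizon=15.0, other=0.05):
    """One-covariate direct subdistribution simulation (test oracle)."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    eta = beta * x
    u = rng.uniform(size=n)
    c1 = u < 1 - (1 - p) ** np.exp(eta)
    tev = np.empty(n)
    inner = 1 - np.exp(np.exp(-eta[c1]) * np.log1p(-u[c1]))
    tev[c1] = -np.log1p(-inner / p) / lam
    tev[~c1] = rng.exponential(1 / other, (~c1).sum())
    tc = np.minimum(rng.exponential(1 / cens, n), horizon)
    obs = np.minimum(tev, tc)
    ev = np.where(tev <= tc, np.where(c1, 1, 2), 0)
    return pd.DataFrame({"x": x}), obs, ev


class TestEstimateCIF:
    def test_no_cause1_events(self):
        c = estimate_cif([1.0, 2.0], [2, 0], cause=1)
        assert c(10.0) == 0.0

    def test_three_record_hand_example(self):
        # times {1,2,3}, events {1,2,0}: CIF_1 = 1/3 from t=1 onward
        c = estimate_cif([1.0, 2.0, 3.0], [1, 2, 0], cause=1)
        assert c(0.99) == 0.0
        assert c(1.0) == pytest.approx(1 / 3, abs=1e-15)
        assert c(100.0) == pytest.approx(1 / 3, abs=1e-15)

    def test_equals_one_minus_km_single_cause(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(3, 400)
        e = rng.integers(0, 2, 400)  # only censoring and cause 1
        curve = estimate_cif(t, e, cause=1)
        km = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0, t.max(), 101)
        km_sf = km.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(curve(grid), 1 - km_sf, atol=1e-12)

    def test_causes_and_survival_sum_to_one(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(4, 300)
        e = rng.integers(0, 3, 300)
        c1 = estimate_cif(t, e, 1)
        c2 = estimate_cif(t, e, 2)
        s = any_event_cif(t, e)
        grid = np.linspace(0, t.max() * 1.1, 97)
        total = c1(grid) + c2(grid) + (1 - s(grid))
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_negative_times_error(self):
        with pytest.raises(ValueError):
            estimate_cif([-1.0, 2.0], [1, 1])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            estimate_cif([], [])


class TestCIFArea:
    def test_zero_curve(self):
        c = estimate_cif([1.0], [0], cause=1)
        assert cif_area(c, 5.0) == 0.0

    def test_single_step(self):
        c = CIFCurve(times=np.array([2.0]), values=np.array([0.5]), cause=1)
        assert cif_area(c, 4.0) == pytest.approx(1.0)

    def test_hand_example(self):
        c = estimate_cif([1.0, 2.0, 3.0], [1, 2, 0], cause=1)
        assert cif_area(c, 3.0) == pytest.approx(2 / 3)

    def test_monotone_in_upper(self):
        c = CIFCurve(times=np.array([1.0, 3.0]), values=np.array([0.2, 0.6]), cause=1)
        areas = [cif_area(c, R) for R in (1.0, 2.0, 4.0, 8.0)]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))

    def test_linear_in_curve(self):
        t = np.array([1.0, 2.5])
        a = CIFCurve(times=t, values=np.array([0.1, 0.3]), cause=1)
        b = CIFCurve(times=t, values=np.array([0.2, 0.4]), cause=1)
        ab = CIFCurve(times=t, values=a.values + b.values, cause=1)
        assert cif_area(ab, 6.0) == pytest.approx(cif_area(a, 6.0) + cif_area(b, 6.0))

    def test_bad_upper(self):
        c = CIFCurve(times=np.array([1.0]), values=np.array([0.5]), cause=1)
        with pytest.raises(ValueError):
            cif_area(c, 0.0)


class TestFineGray:
    def test_cox_oracle_no_competing_no_censoring(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-(0.5 * x[:, 0] - 0.3 * x[:, 1])))
        e = np.ones(n, dtype=int)
        fit = fit_fine_gray(
            pd.DataFrame(x, columns=["a", "b"]), t, e, variance="model"
        )
        df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "t": t, "e": e})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(
            fit.coefficients, cph.params_.to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(
            fit.se, cph.standard_errors_.to_numpy(), atol=1e-6
        )

    def test_parameter_recovery(self):
        X, t, e = fg_sim(20000, 0.7, seed=2024)
        fit = fit_fine_gray(X, t, e)
        assert abs(fit.coefficients[0] - 0.7) < 0.05

    def test_null_ci_coverage(self):
        covered = 0
        reps = 60
        for r in range(reps):
            X, t, e = fg_sim(1200, 0.0, seed=30000 + r)
            fit = fit_fine_gray(X, t, e)
            covered += fit.ci_low[0] <= 1.0 <= fit.ci_upp[0]
        assert covered / reps == pytest.approx(0.95, abs=0.07)

    def test_record_order_invariance(self):
        X, t, e = fg_sim(1500, 0.5, seed=3)
        fit1 = fit_fine_gray(X, t, e)
        perm = np.random.default_rng(9).permutation(len(t))
        fit2 = fit_fine_gray(X.iloc[perm], t[perm], e[perm])
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, atol=1e-9)
        np.testing.assert_allclose(fit1.covariance, fit2.covariance, atol=1e-9)

    def test_affine_recoding_rescales_coefficient(self):
        X, t, e = fg_sim(1500, 0.5, seed=4)
        fit1 = fit_fine_gray(X, t, e)
        X2 = (X - 0.25) / 2.0
        fit2 = fit_fine_gray(X2, t, e)
        assert fit2.coefficients[0] == pytest.approx(2.0 * fit1.coefficients[0],
                                                     rel=1e-8)

    def test_shr_ci_invariants(self):
        X, t, e = fg_sim(1500, 0.5, seed=5)
        fit = fit_fine_gray(X, t, e)
        np.testing.assert_allclose(fit.shr, np.exp(fit.coefficients))
        assert (fit.ci_low <= fit.shr).all() and (fit.shr <= fit.ci_upp).all()

    def test_needs_cause1_event(self):
        with pytest.raises(ValueError):
            fit_fine_gray(
                pd.DataFrame({"x": [0.0, 1.0, 0.0]}),
                [1.0, 2.0, 3.0],
                [0, 2, 0],
            )

    def test_separation_raises(self):
        # covariate perfectly splits early deaths from late: diverges
        t = np.concatenate([np.linspace(0.1, 1, 50), np.linspace(10, 20, 50)])
        x = np.concatenate([np.ones(50), np.zeros(50)])
        e = np.ones(100, dtype=int)
        with pytest.raises(ConvergenceError):
            fit_fine_gray(pd.DataFrame({"x": x}), t, e)

    def test_serialization_round_trip(self):
        from bilatdr.competing import FineGrayFit

        X, t, e = fg_sim(800, 0.5, seed=6)
        fit = fit_fine_gray(X, t, e)
        again = FineGrayFit.from_json(fit.to_json())
        np.testing.assert_allclose(fit.coefficients, again.coefficients)
        np.testing.assert_allclose(
            fit.baseline_cif.values, again.baseline_cif.values
        )


@pytest.fixture(scope="module")
def fit():
    X, t, e = fg_sim(4000, 0.7, seed=8)
    return fit_fine_gray(X, t, e)


class TestPredictCIF:
    def test_reference_pattern_is_baseline(self, fit):
        f0 = fit.baseline_cif(5.0)
        assert predict_cif(fit, {"x": 0.0}, 5.0) == pytest.approx(f0)

    def test_minus_inf_eta_limit(self, fit):
        assert predict_cif(fit, {"x": -50.0}, 5.0) == pytest.approx(0.0, abs=1e-8)

    def test_monotone_in_horizon(self, fit):
        ps = [predict_cif(fit, {"x": 1.0}, h) for h in (1.0, 3.0, 5.0, 10.0)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_unknown_covariate(self, fit):
        with pytest.raises(KeyError):
            predict_cif(fit, {"zzz": 1.0}, 5.0)
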