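"""Competing-risk machinery: cumulative incidence and subdistribution regression.

This is the statistical engine used by variable screening, the
interval-dependent weight estimation, and the nomogram.  Cumulative
incidence is estimated nonparametrically (Aalen–Johansen); regression is
on the subdistribution hazard, i.e. patients who die of the competing
cause remain in the risk set, down-weighted by the Kaplan–Meier estimate
of the censoring distribution.

Assumptions (documented, not mandated by the source material): tied event
times are handled Breslow-style, and 95% intervals are Wald on the log
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CIFCurve",
    "FineGrayFit",
    "ConvergenceError",
    "estimate_cif",
    "cif_area",
    "fit_fine_gray",
    "predict_cif",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last iterate and gradient norm."""

    def __init__(self, message: str, beta: np.ndarray, grad_norm: float):
        super().__init__(message)
        self.beta = beta
        self.grad_norm = grad_norm


@dataclass
class CIFCurve:
    """Right-continuous step estimate of cumulative incidence for one cause."""

    times: np.ndarray  # strictly increasing event times (any cause)
    values: np.ndarray  # cumulative incidence of `cause` at each time
    cause: int
    at_risk: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.at_risk = np.asarray(self.at_risk)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("values must be non-decreasing")
        if len(self.values) and (self.values[0] < -1e-12 or self.values[-1] > 1 + 1e-12):
            raise ValueError("values must lie in [0, 1]")

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate the step function at ``t`` (0 before the first jump)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return vals if vals.ndim else float(vals)


def estimate_cif(times, events, cause: int = 1) -> CIFCurve:
    """Aalen–Johansen estimate of the cumulative incidence of ``cause``.

    At each event time the increment is (overall event-free survival just
    before) x (events of this cause / number at risk); censored records
    leave the risk set without contributing an increment.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t < 0):
        raise ValueError("negative times")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, first = np.unique(t, return_index=True)

    n = t.size
    grid, vals, risks = [], [], []
    surv = 1.0
    cif = 0.0
    for k, u in enumerate(uniq):
        start = first[k]
        stop = first[k + 1] if k + 1 < len(uniq) else n
        ev = e[start:stop]
        d_any = int((ev > 0).sum())
        if d_any == 0:
            continue  # pure censoring: risk set shrinks, no jump
        at_risk = n - start
        d_cause = int((ev == cause).sum())
        cif += surv * d_cause / at_risk
        surv *= 1.0 - d_any / at_risk
        grid.append(u)
        vals.append(cif)
        risks.append(at_risk)
    return CIFCurve(
        times=np.array(grid), values=np.array(vals), cause=cause,
        at_risk=np.array(risks, dtype=int),
    )


def any_event_cif(times, events) -> CIFCurve:
    """CIF of time to *any* event, i.e. 1 - Kaplan–Meier of the event-free law.

    Event-free survival is ``1 - any_event_cif(...)(t)``; with the
    cause-specific CIFs it satisfies sum_k CIF_k(t) + S(t) = 1 exactly.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    curve = estimate_cif(t, (e > 0).astype(int), cause=1)
    return CIFCurve(times=curve.times, values=curve.values, cause=0,
                    at_risk=curve.at_risk)


def cif_area(curve: CIFCurve, upper: float) -> float:
    """Exact integral of the CIF step function on [0, upper].

    The curve is 0 before its first jump and extends flat beyond its last
    recorded time.
    """
    if upper <= 0:
        raise ValueError("upper must be > 0")
    if curve.times.size == 0:
        return 0.0
    knots = np.concatenate([curve.times[curve.times < upper], [upper]])
    starts = knots[:-1]
    vals = curve(starts)
    return float(np.sum(np.atleast_1d(vals) * np.diff(knots)))


@dataclass
class FineGrayFit:
    """Subdistribution-hazard regression result."""

    names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    baseline_cif: CIFCurve
    n_used: int
    n_events: int
    iterations: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def shr(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coefficients - 1.959963984540054 * self.se)

    @property
    def ci_upp(self) -> np.ndarray:
        return np.exp(self.coefficients + 1.959963984540054 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.coefficients / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def wald_test(self, which: list[str] | None = None) -> tuple[float, int, float]:
        """Joint Wald test beta' V^-1 beta for a subset of coefficients.

        Returns (statistic, df, p). With ``which=None`` all coefficients
        are tested jointly.
        """
        idx = (
            np.arange(len(self.names))
            if which is None
            else np.array([self.names.index(w) for w in which])
        )
        b = self.coefficients[idx]
        V = self.covariance[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "shr": self.shr,
                "ci_low": self.ci_low,
                "ci_upp": self.ci_upp,
                "p": self.p_values,
            },
            index=self.names,
        )

    def linear_predictor(self, covariates) -> float | np.ndarray:
        """eta for a single pattern (mapping) or a design frame/array."""
        if isinstance(covariates, dict):
            x = np.array([covariates[n] for n in self.names], dtype=float)
            return float(x @ self.coefficients)
        if isinstance(covariates, pd.DataFrame):
            x = covariates[self.names].to_numpy(dtype=float)
        else:
            x = np.asarray(covariates, dtype=float)
        return x @ self.coefficients

    def to_json(self) -> str:
        return json.dumps(
            {
                "names": self.names,
                "coefficients": self.coefficients.tolist(),
                "covariance": self.covariance.tolist(),
                "baseline_times": self.baseline_cif.times.tolist(),
                "baseline_values": self.baseline_cif.values.tolist(),
                "n_used": self.n_used,
                "n_events": self.n_events,
                "iterations": self.iterations,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FineGrayFit":
        d = json.loads(text)
        return cls(
            names=list(d["names"]),
            coefficients=np.array(d["coefficients"]),
            covariance=np.array(d["covariance"]),
            baseline_cif=CIFCurve(
                times=np.array(d["baseline_times"]),
                values=np.array(d["baseline_values"]),
                cause=1,
            ),
            n_used=int(d["n_used"]),
            n_events=int(d["n_events"]),
            iterations=int(d["iterations"]),
        )


def _censoring_km(t: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier of the censoring distribution G(t), right-continuous.

    Ties between events and censorings at the same instant are resolved
    events-first, so an event at t is still 'at risk of censoring' then.
    Returns (jump_times, G_values).
    """
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq, first = np.unique(ts, return_index=True)
    n = ts.size
    times, g = [], []
    surv = 1.0
    for k, u in enumerate(uniq):
        start = first[k]
        stop = first[k + 1] if k + 1 < len(uniq) else n
        d_cens = int((es[start:stop] == 0).sum())
        if d_cens == 0:
            continue
        at_risk = n - start
        surv *= 1.0 - d_cens / at_risk
        times.append(u)
        g.append(surv)
    return np.array(times), np.array(g)


def _g_at(times: np.ndarray, g: np.ndarray, t) -> np.ndarray:
    if times.size == 0:  # no censoring observed: G == 1
        return np.ones(np.asarray(t).shape)
    idx = np.searchsorted(times, t, side="right") - 1
    return np.where(idx >= 0, g[np.clip(idx, 0, None)], 1.0)


def _score_residuals(
    X: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    beta: np.ndarray,
    g_times: np.ndarray,
    g_vals: np.ndarray,
    ev_times: np.ndarray,
    d_k: np.ndarray,
) -> np.ndarray:
    """Per-subject sandwich contributions eta_i + psi_i (inputs time-sorted).

    eta_i is the weighted score residual at the fitted coefficients; psi_i
    corrects for the Kaplan–Meier estimation of the censoring law G via
    the censoring martingale of each subject.
    """
    n, p = X.shape
    r = np.exp(X @ beta)
    i0 = np.searchsorted(t, ev_times, side="left")
    c2 = np.flatnonzero(e == 2)
    t_c2 = t[c2]
    g_own = _g_at(g_times, g_vals, t_c2)
    b = r[c2] / g_own
    c_k = np.searchsorted(t_c2, ev_times, side="left")
    g_k = _g_at(g_times, g_vals, ev_times)

    suf_r = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
    suf_xr = np.concatenate(
        [np.cumsum((X * r[:, None])[::-1], axis=0)[::-1], np.zeros((1, p))]
    )
    pre_b = np.concatenate([[0.0], np.cumsum(b)])
    pre_xb = np.concatenate([np.zeros((1, p)), np.cumsum(X[c2] * b[:, None], axis=0)])
    S0 = suf_r[i0] + g_k * pre_b[c_k]
    S1 = suf_xr[i0] + g_k[:, None] * pre_xb[c_k]
    zbar = S1 / S0[:, None]
    dlam = d_k / S0

    resid = np.zeros((n, p))

    # dN part: each cause-1 death contributes Z_i - Zbar at its own time.
    ev1 = np.flatnonzero(e == 1)
    k_of = np.searchsorted(ev_times, t[ev1])
    resid[ev1] += X[ev1] - zbar[k_of]

    # Compensator over the natural risk period [0, T_i].
    C0 = np.concatenate([[0.0], np.cumsum(dlam)])
    C1 = np.concatenate([np.zeros((1, p)), np.cumsum(zbar * dlam[:, None], axis=0)])
    kk = np.searchsorted(ev_times, t, side="right")
    resid -= r[:, None] * (X * C0[kk][:, None] - C1[kk])

    # Weighted tail for competing-cause subjects (u_k > T_i).
    w0 = g_k * dlam
    w1 = zbar * w0[:, None]
    W0s = np.concatenate([np.cumsum(w0[::-1])[::-1], [0.0]])
    W1s = np.concatenate([np.cumsum(w1[::-1], axis=0)[::-1], np.zeros((1, p))])
    kk2 = np.searchsorted(ev_times, t_c2, side="right")
    resid[c2] -= b[:, None] * (X[c2] * W0s[kk2][:, None] - W1s[kk2])

    # psi: influence of the estimated censoring KM.
    cens_times = np.unique(t[e == 0])
    if cens_times.size:
        dc = np.array([((t == u) & (e == 0)).sum() for u in cens_times], dtype=float)
        R = n - np.searchsorted(t, cens_times, side="left")
        dlam_c = dc / R
        # q(c_m) = sum over cause-2 subjects with T_j < c_m of
        #          b_j (Z_j W0(c_m) - W1(c_m)),  W*(c_m) over u_k >= c_m
        mk = np.searchsorted(ev_times, cens_times, side="left")
        W0m = W0s[mk]
        W1m = W1s[mk]
        jm = np.searchsorted(t_c2, cens_times, side="left")
        q = W0m[:, None] * pre_xb[jm] - pre_b[jm][:, None] * W1m
        phi = q / R[:, None]
        D = np.cumsum(phi * dlam_c[:, None], axis=0)
        D = np.concatenate([np.zeros((1, p)), D])
        mm = np.searchsorted(cens_times, t, side="right")
        resid -= D[mm]
        cens0 = np.flatnonzero(e == 0)
        m_of = np.searchsorted(cens_times, t[cens0])
        resid[cens0] += phi[m_of]
    return resid


def fit_fine_gray(
    design,
    times,
    events,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    variance: str = "robust",
) -> FineGrayFit:
    """Fit a subdistribution-hazard (Fine–Gray) regression for cause 1.

    ``design`` is a DataFrame (column names kept) or a 2-D array.  The
    partial likelihood keeps competing-cause patients in the risk set after
    their event with inverse-probability-of-censoring weights
    G(t)/G(min(T_i, t)); Newton–Raphson with step halving, Breslow ties.

    ``variance="robust"`` (default) uses the sandwich estimator built from
    per-subject score residuals plus the correction for the estimated
    censoring distribution; ``variance="model"`` returns the inverse
    observed information (which ignores weight estimation and is slightly
    conservative under censoring).

    The baseline subdistribution CIF (at all covariates zero) is recovered
    by Breslow accumulation: F0(t) = 1 - exp(-sum d_k / S0(t_k)).
    """
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1 and np.asarray(times).size != 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n, p = X.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise ValueError("design, times and events lengths disagree")
    if (e == 1).sum() < 1:
        raise ValueError("need at least one cause-1 event")
    if len({tuple(row) for row in X[:200]}) < 2 and len({tuple(row) for row in X}) < 2:
        raise ValueError("need at least two distinct covariate patterns")

    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]

    g_times, g_vals = _censoring_km(t, e)

    # Cause-1 event times (Breslow groups).
    ev_mask = e == 1
    ev_times = np.unique(t[ev_mask])
    K = ev_times.size
    d_k = np.array([(t[ev_mask] == u).sum() for u in ev_times], dtype=float)
    sum_x_k = np.vstack([X[ev_mask & (t == u)].sum(axis=0) for u in ev_times])

    # Natural risk set boundaries: first sorted index with T >= t_k.
    i0 = np.searchsorted(t, ev_times, side="left")
    # Competing-cause subjects contribute for t > their own time, weighted.
    c2 = np.flatnonzero(e == 2)
    t_c2 = t[c2]
    g_own = _g_at(g_times, g_vals, t_c2)
    # Number of cause-2 subjects with T_j < t_k.
    c_k = np.searchsorted(t_c2, ev_times, side="left")
    g_k = _g_at(g_times, g_vals, ev_times)

    X_c2 = X[c2]
    XX = np.einsum("ni,nj->nij", X, X)
    XX_c2 = XX[c2]

    def sums(beta: np.ndarray):
        r = np.exp(X @ beta)
        # Suffix sums over the natural risk set.
        suf_r = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
        suf_xr = np.concatenate(
            [np.cumsum((X * r[:, None])[::-1], axis=0)[::-1], np.zeros((1, p))]
        )
        suf_xxr = np.concatenate(
            [np.cumsum((XX * r[:, None, None])[::-1], axis=0)[::-1],
             np.zeros((1, p, p))]
        )
        # Prefix sums over weighted competing-cause contributions.
        b = r[c2] / g_own
        pre_b = np.concatenate([[0.0], np.cumsum(b)])
        pre_xb = np.concatenate([np.zeros((1, p)), np.cumsum(X_c2 * b[:, None], axis=0)])
        pre_xxb = np.concatenate(
            [np.zeros((1, p, p)), np.cumsum(XX_c2 * b[:, None, None], axis=0)]
        )
        S0 = suf_r[i0] + g_k * pre_b[c_k]
        S1 = suf_xr[i0] + g_k[:, None] * pre_xb[c_k]
        S2 = suf_xxr[i0] + g_k[:, None, None] * pre_xxb[c_k]
        return S0, S1, S2

    def loglik_grad_hess(beta: np.ndarray):
        S0, S1, S2 = sums(beta)
        ll = float(np.sum(sum_x_k @ beta)) - float(np.sum(d_k * np.log(S0)))
        m = S1 / S0[:, None]
        U = sum_x_k.sum(axis=0) - (d_k[:, None] * m).sum(axis=0)
        H = np.einsum("k,kij->ij", d_k, S2 / S0[:, None, None]) - np.einsum(
            "k,ki,kj->ij", d_k, m, m
        )
        return ll, U, H

    beta = np.zeros(p)
    ll, U, H = loglik_grad_hess(beta)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(U)) < tol:
            break
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix: {exc}", beta, float(np.max(np.abs(U)))
            ) from exc
        # Step halving on likelihood decrease; near the optimum the ll
        # change is below float noise, so trust the pure Newton step there.
        near_optimum = np.max(np.abs(U)) < 1e-4
        new_beta = beta + step
        for _ in range(30):
            if np.max(np.abs(new_beta)) > 50:
                raise ConvergenceError(
                    "separation detected (diverging coefficients)",
                    new_beta,
                    float(np.max(np.abs(U))),
                )
            new_ll, new_U, new_H = loglik_grad_hess(new_beta)
            if near_optimum or new_ll >= ll - 1e-12:
                break
            step = step / 2.0
            new_beta = beta + step
        beta, ll, U, H = new_beta, new_ll, new_U, new_H
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations",
            beta,
            float(np.max(np.abs(U))),
        )

    if np.max(np.abs(beta)) > 20:
        # log-SHRs of this size only arise from monotone likelihoods
        raise ConvergenceError(
            "separation detected (coefficient path diverging)",
            beta,
            float(np.max(np.abs(U))),
        )

    h_inv = np.linalg.inv(H)
    if variance == "robust":
        resid = _score_residuals(X, t, e, beta, g_times, g_vals, ev_times, d_k)
        meat = resid.T @ resid
        cov = h_inv @ meat @ h_inv
    elif variance == "model":
        cov = h_inv
    else:
        raise ValueError(f"unknown variance {variance!r}")

    S0, _, _ = sums(beta)
    lam0 = d_k / S0
    base = CIFCurve(
        times=ev_times,
        values=1.0 - np.exp(-np.cumsum(lam0)),
        cause=1,
        at_risk=(n - i0).astype(int),
    )
    return FineGrayFit(
        names=names,
        coefficients=beta,
        covariance=cov,
        baseline_cif=base,
        n_used=n,
        n_events=int(ev_mask.sum()),
        iterations=it,
    )


def predict_cif(fit: FineGrayFit, covariates, horizon: float) -> float:
    """Predicted cumulative incidence 1 - (1 - F0(h))^exp(eta)."""
    if isinstance(covariates, dict):
        unknown = set(covariates) - set(fit.names)
        if unknown:
            raise KeyError(f"unknown covariate(s): {sorted(unknown)}")
        eta = float(sum(fit.coefficients[fit.names.index(k)] * v
                        for k, v in covariates.items()))
    else:
        eta = float(np.asarray(fit.linear_predictor(covariates)))
    f0 = fit.baseline_cif(horizon)
    return float(1.0 - (1.0 - f0) ** np.exp(eta))
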