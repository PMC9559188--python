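"""Synthetic paired-tumour cohorts with a known generating model.

The generator mirrors the structure the downstream analysis assumes: each
clinical variable carries a ground-truth interval-dependent weight
w_p(t) = a(pi/2 - arctan(b t + c)) blending the first-tumour and
second-tumour scores into one linear-predictor contribution, and death
times are drawn directly from a subdistribution (Fine–Gray) model

    F1(tau | eta) = 1 - (1 - p (1 - exp(-lam tau)))^exp(eta)

so that fitted subdistribution coefficients are directly comparable to the
generating ones.  Competing-cause times are exponential among patients not
assigned cause 1; censoring is independent exponential plus an
administrative horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_vaf_tables",
    "true_cif",
    "arctan_weight",
]

#: paired-feature variables and their cohort column stems
WEIGHT_VARIABLES = ("t", "n", "grade", "er")

VARIABLE_LEVELS = {
    "t": ("T1", "T2", "T3-4"),
    "n": ("N0", "N1", "N2-3"),
    "grade": ("I-II", "III-IV"),
    "er": ("+", "-"),
}

DEFAULT_MARGINALS = {
    "t": (0.6, 0.3, 0.1),
    "n": (0.65, 0.25, 0.10),
    "grade": (0.55, 0.45),
    "er": (0.7, 0.3),
}

DEFAULT_TRUE_WEIGHTS = {
    "t": (0.34, 0.50, -2.0),
    "n": (0.40, 0.35, -1.5),
    "grade": (0.30, 0.25, -1.0),
    "er": (0.36, 0.60, -2.5),
}

DEFAULT_EFFECTS = {"t": 0.6, "n": 0.5, "grade": 0.35, "er": 0.4}


def arctan_weight(t, a: float, b: float, c: float):
    """w_p(t) = a (pi/2 - arctan(b t + c))."""
    return a * (np.pi / 2.0 - np.arctan(b * np.asarray(t, dtype=float) + c))


@dataclass
class SimulationConfig:
    n: int = 1000
    seed: int = 0
    true_weights: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_WEIGHTS))
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    concordance: dict = field(
        default_factory=lambda: {v: 0.5 for v in WEIGHT_VARIABLES}
    )
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    interval_shape: float = 2.0
    interval_scale: float = 3.5
    interval_bounds: tuple = (0.5, 25.0)
    cause1_p: float = 0.35  # eventual cause-1 probability at eta = 0
    cause1_rate: float = 0.25  # lam: exponential time-scale of the cause-1 CIF
    other_cause_rate: float = 0.04
    censor_rate: float = 0.04
    admin_horizon: float = 20.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 < self.cause1_p < 1):
            raise ValueError("cause1_p must be in (0, 1)")
        for r in (self.cause1_rate, self.other_cause_rate):
            if r <= 0:
                raise ValueError("rates must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        lo, hi = self.interval_bounds
        grid = np.linspace(lo, hi, 200)
        for v in WEIGHT_VARIABLES:
            a, b, c = self.true_weights[v]
            w = arctan_weight(grid, a, b, c)
            if np.any(w < -1e-9) or np.any(w > 1 + 1e-9):
                raise ValueError(
                    f"true weight for {v!r} leaves [0, 1] on [{lo}, {hi}]"
                )
            conc = self.concordance[v]
            if not (0 <= conc <= 1):
                raise ValueError("concordance must be in [0, 1]")
            probs = np.asarray(self.marginals[v])
            if abs(probs.sum() - 1) > 1e-9 or np.any(probs < 0):
                raise ValueError(f"marginals for {v!r} must be a distribution")

    def to_dict(self) -> dict:
        return asdict(self)


def _truncated_gamma(rng, n, shape, scale, lo, hi):
    dist = stats.gamma(shape, scale=scale)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=n)
    return dist.ppf(u)


def true_cif(tau, eta, p: float, lam: float):
    """Closed-form cause-1 CIF of the generator at linear predictor eta."""
    tau = np.asarray(tau, dtype=float)
    return 1.0 - (1.0 - p * (1.0 - np.exp(-lam * tau))) ** np.exp(eta)


def _draw_cause1_time(rng, u, eta, p, lam):
    """Invert F1(t)=u conditional on u < eventual cause-1 probability."""
    # (1-u)^{exp(-eta)} computed in log space for stability
    inner = 1.0 - np.exp(np.exp(-eta) * np.log1p(-u))
    return -np.log1p(-inner / p) / lam


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Draw a cohort plus its ground-truth record.

    Returns ``(cohort, truth)`` where ``truth`` holds, per patient, the
    linear predictor eta, the latent cause and latent event time, and the
    per-variable true weights evaluated at the drawn interval time.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    interval = _truncated_gamma(
        rng, n, config.interval_shape, config.interval_scale, *config.interval_bounds
    )

    cols: dict[str, np.ndarray] = {}
    eta = np.zeros(n)
    truth: dict[str, np.ndarray] = {"interval_time": interval}
    for v in WEIGHT_VARIABLES:
        levels = VARIABLE_LEVELS[v]
        k = len(levels)
        probs = np.asarray(config.marginals[v], dtype=float)
        s_p = rng.choice(k, size=n, p=probs)
        same = rng.uniform(size=n) < config.concordance[v]
        shift = rng.integers(1, k, size=n)  # uniform over the other levels
        s_c = np.where(same, s_p, (s_p + shift) % k)
        a, b, c = config.true_weights[v]
        wp = arctan_weight(interval, a, b, c)
        combined = wp * (s_p + 1) + (1 - wp) * (s_c + 1)
        eta += config.effect_sizes[v] * (combined - 1.0)
        cols[f"{v}_pbc"] = np.array(levels)[s_p]
        cols[f"{v}_cbc"] = np.array(levels)[s_c]
        truth[f"wp_{v}"] = wp
        truth[f"combined_{v}"] = combined

    p, lam = config.cause1_p, config.cause1_rate
    u = rng.uniform(size=n)
    p1 = 1.0 - (1.0 - p) ** np.exp(eta)
    is_c1 = u < p1
    t_event = np.empty(n)
    t_event[is_c1] = _draw_cause1_time(rng, u[is_c1], eta[is_c1], p, lam)
    t_event[~is_c1] = rng.exponential(1.0 / config.other_cause_rate,
                                      size=int((~is_c1).sum()))
    cause = np.where(is_c1, 1, 2)

    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.admin_horizon)
    observed = np.minimum(t_event, t_cens)
    event = np.where(t_event <= t_cens, cause, 0)
    observed = np.maximum(observed, 1e-6)  # followup_time must be positive

    age_pbc = np.clip(rng.normal(58, 10, size=n), 18, 97 - 1e-9)
    cols.update(
        patient_id=np.array([f"SYN{i:06d}" for i in range(n)]),
        age_pbc=np.round(age_pbc, 1),
        age_cbc=np.round(age_pbc + interval, 1),
        interval_time=interval,
        race=rng.choice(["white", "black", "other"], size=n, p=(0.8, 0.1, 0.1)),
        marital_pair=rng.choice(
            ["NonP/NonP", "NonP/WithP", "WithP/NonP", "WithP/WithP"],
            size=n,
            p=(0.35, 0.05, 0.10, 0.50),
        ),
        pathology_pbc=rng.choice(["IDC", "ILC", "other"], size=n, p=(0.7, 0.1, 0.2)),
        pathology_cbc=rng.choice(["IDC", "ILC", "other"], size=n, p=(0.7, 0.1, 0.2)),
        surgery_pbc=rng.choice(["BCM", "SM", "RM"], size=n, p=(0.55, 0.2, 0.25)),
        surgery_cbc=rng.choice(["BCM", "SM", "RM"], size=n, p=(0.55, 0.2, 0.25)),
        followup_time=observed,
        event=event,
        distant_met=np.zeros(n, dtype=bool),
    )
    df = pd.DataFrame(cols)

    truth.update(eta=eta, latent_cause=cause, latent_time=t_event,
                 censor_time=t_cens, patient_id=cols["patient_id"])
    truth_df = pd.DataFrame(truth)
    return Cohort(df, provenance=f"simulated(seed={config.seed}, n={n})"), truth_df


def simulate_vaf_tables(
    n_shared: int,
    n_private_p: int,
    n_private_c: int,
    vaf_mean: float = 0.3,
    vaf_dispersion: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired per-lesion variant tables sharing exactly ``n_shared`` IDs.

    VAFs are beta-distributed with the given mean and concentration.
    Returns two frames with columns (lesion_id, variant_id, vaf).
    """
    for v in (n_shared, n_private_p, n_private_c):
        if v < 0:
            raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    alpha = vaf_mean * vaf_dispersion
    beta = (1.0 - vaf_mean) * vaf_dispersion

    def draw(k):
        return rng.beta(alpha, beta, size=k)

    shared = [f"SHARED{i:04d}" for i in range(n_shared)]
    priv_p = [f"PBCONLY{i:04d}" for i in range(n_private_p)]
    priv_c = [f"CBCONLY{i:04d}" for i in range(n_private_c)]
    vaf_shared = draw(n_shared)  # trunk variants keep one VAF in both lesions

    pbc = pd.DataFrame(
        {
            "lesion_id": "pbc",
            "variant_id": shared + priv_p,
            "vaf": np.concatenate([vaf_shared, draw(n_private_p)]),
        }
    )
    cbc = pd.DataFrame(
        {
            "lesion_id": "cbc",
            "variant_id": shared + priv_c,
            "vaf": np.concatenate([vaf_shared, draw(n_private_c)]),
        }
    )
    return pbc, cbc
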