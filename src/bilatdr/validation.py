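"""Model assessment: 2:1 splitting, competing-risk concordance, calibration.

The concordance index defaults to the competing-risk (Wolbers-type)
adaptation: a pair is comparable when one patient has the event of
interest by the horizon and the other is either still event-free at that
moment or has died of the competing cause (and hence can never have the
event).  A Harrell-style variant that treats competing deaths as censored
is also exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .competing import estimate_cif

__all__ = [
    "CIndexResult",
    "CalibrationResult",
    "split_cohort",
    "concordance_index",
    "calibration_curve",
]


def split_cohort(
    cohort: Cohort, seed: int, ratio: tuple[int, int] = (2, 1)
) -> tuple[Cohort, Cohort]:
    """Simple random split; with ratio 2:1 the validation part is ceil(n/3).

    (So n = 13,304 gives 8,869 / 4,435.)  Disjoint and exhaustive.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    r0, r1 = ratio
    n_val = int(np.ceil(n * r1 / (r0 + r1)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    mk = lambda idx, tag: Cohort(
        cohort.df.iloc[idx].reset_index(drop=True),
        provenance=f"{cohort.provenance}[{tag} split seed={seed}]",
    )
    return mk(train_idx, "train"), mk(val_idx, "val")


@dataclass
class CIndexResult:
    value: float
    ci_low: float = float("nan")
    ci_upp: float = float("nan")
    n_comparable: int = 0
    variant: str = "wolbers"


def _cindex_point(
    pred: np.ndarray, t: np.ndarray, e: np.ndarray, horizon: float, variant: str
) -> tuple[float, int]:
    conc = 0.0
    comp = 0
    cases = np.flatnonzero((e == 1) & (t <= horizon))
    for i in cases:
        if variant == "wolbers":
            mask = (t > t[i]) | (e == 2)
        elif variant == "harrell":
            mask = t > t[i]
        else:
            raise ValueError(f"unknown variant {variant!r}")
        mask[i] = False
        m = int(mask.sum())
        if m == 0:
            continue
        comp += m
        pj = pred[mask]
        conc += float((pred[i] > pj).sum()) + 0.5 * float((pred[i] == pj).sum())
    if comp == 0:
        raise ValueError("no comparable pairs at this horizon")
    return conc / comp, comp


def concordance_index(
    predictions,
    times,
    events,
    horizon: float,
    variant: str = "wolbers",
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> CIndexResult:
    """Truncated concordance of predicted risk with observed cancer deaths.

    Ties in predictions count 1/2.  The CI is a cohort-bootstrap
    percentile interval (``n_boot=0`` skips it).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    pred = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    value, comp = _cindex_point(pred, t, e, horizon, variant)
    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = t.size
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                v, _ = _cindex_point(pred[idx], t[idx], e[idx], horizon, variant)
            except ValueError:
                continue
            reps.append(v)
        if reps:
            lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return CIndexResult(
        value=value, ci_low=float(lo), ci_upp=float(hi),
        n_comparable=comp, variant=variant,
    )


@dataclass
class CalibrationResult:
    horizon: float
    table: pd.DataFrame  # group, n, mean_predicted, observed, ci_low, ci_upp, sparse
    n_boot: int = 0


def calibration_curve(
    predictions,
    times,
    events,
    horizon: float,
    groups: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Grouped predicted-vs-observed cumulative incidence at ``horizon``.

    Patients are ranked by prediction and cut into ``groups`` equal-size
    groups; per group the mean prediction is compared with the
    nonparametric (Aalen–Johansen) cancer-death CIF, with bootstrap
    percentile intervals on the observed value.
    """
    if groups < 2:
        raise ValueError("groups must be >= 2")
    pred = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(pred, kind="stable")
    chunks = np.array_split(order, groups)
    rng = np.random.default_rng(seed)
    rows = []
    for g, idx in enumerate(chunks):
        tg, eg, pg = t[idx], e[idx], pred[idx]
        sparse = bool((eg == 1).sum() == 0)
        observed = 0.0 if sparse else float(estimate_cif(tg, eg, cause=1)(horizon))
        lo = hi = float("nan")
        if n_boot > 0 and not sparse:
            reps = np.empty(n_boot)
            m = idx.size
            for b in range(n_boot):
                bi = rng.integers(0, m, size=m)
                if (eg[bi] == 1).sum() == 0:
                    reps[b] = 0.0
                else:
                    reps[b] = estimate_cif(tg[bi], eg[bi], cause=1)(horizon)
            lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        rows.append(
            {
                "group": g + 1,
                "n": idx.size,
                "mean_predicted": float(pg.mean()),
                "observed": observed,
                "ci_low": float(lo),
                "ci_upp": float(hi),
                "sparse": sparse,
            }
        )
    return CalibrationResult(
        horizon=horizon, table=pd.DataFrame(rows), n_boot=n_boot
    )


@dataclass
class ValidationReport:
    c_index: dict  # cohort label -> CIndexResult
    calibration: dict  # (cohort label, horizon) -> CalibrationResult
    split_seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "split_seed": self.split_seed,
            "c_index": {
                k: {
                    "value": r.value,
                    "ci_low": r.ci_low,
                    "ci_upp": r.ci_upp,
                    "n_comparable": r.n_comparable,
                    "variant": r.variant,
                }
                for k, r in self.c_index.items()
            },
            "calibration": {
                f"{label}@{hz:g}y": res.table.to_dict(orient="records")
                for (label, hz), res in self.calibration.items()
            },
            **self.extras,
        }
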