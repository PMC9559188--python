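"""Interval-time-dependent weighting of paired tumour features.

For each clinical variable (T, N, grade, ER) and each interval-time
window, patients are cross-classified by their (first-tumour level i,
second-tumour level j).  The cumulative incidence of cancer death in each
cell is integrated to an area S_ij = int_0^R F_ij(tau) dtau; the spread of
those areas across first-tumour levels (summed over second-tumour
columns) gives D_p, the symmetric construction gives D_c, and the raw
first-tumour weight for that window is D_p / (D_p + D_c).  A smooth
weight function w_p(t) = a(pi/2 - arctan(b t + c)) is then fitted to the
per-window raw weights by weighted nonlinear least squares; the
second-tumour weight is its complement w_c = 1 - w_p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cohort import Cohort
from .competing import cif_area, estimate_cif
from .simulate import arctan_weight

__all__ = [
    "WeightSeries",
    "WeightFit",
    "compute_area_matrix",
    "dp_from_areas",
    "dc_from_areas",
    "raw_weight",
    "build_weight_series",
    "fit_weight_function",
    "fit_all_weights",
    "evaluate_weights",
]

#: variables eligible for weighting -> their paired cohort columns
WEIGHTED_VARIABLES = {
    "t": ("t_pbc", "t_cbc"),
    "n": ("n_pbc", "n_cbc"),
    "grade": ("grade_pbc", "grade_cbc"),
    "er": ("er_pbc", "er_cbc"),
}

WEIGHT_CLIP = (0.01, 0.99)
A_UPPER = 1.5 * 2.0 / np.pi  # bound keeps w_p(0) within ~1.5


@dataclass
class WeightSeries:
    """Per-interval-window raw weights for one variable."""

    variable: str
    bin_centers: np.ndarray
    raw_wp: np.ndarray  # nan where the window was unusable
    bin_counts: np.ndarray
    area_matrices: list  # pd.DataFrame per window (None where unusable)
    sparse: np.ndarray  # bool: window below the count threshold / degenerate

    def usable(self) -> np.ndarray:
        return ~self.sparse & np.isfinite(self.raw_wp)


@dataclass
class WeightFit:
    """Fitted coefficients of w_p(t) = a(pi/2 - arctan(b t + c))."""

    variable: str
    a: float
    b: float
    c: float
    residual_rms: float = float("nan")
    series: WeightSeries | None = None

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "residual_rms": self.residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightFit":
        return cls(
            variable=d["variable"], a=float(d["a"]), b=float(d["b"]),
            c=float(d["c"]), residual_rms=float(d.get("residual_rms", "nan")),
        )


def compute_area_matrix(
    cohort: Cohort,
    variable: str,
    bin: tuple[float, float],
    upper: float = 10.0,
    min_subgroup: int = 20,
) -> pd.DataFrame:
    """CIF-area matrix S for one interval-time window.

    Entry (i, j) is the integral to ``upper`` of the cancer-death CIF among
    patients with first-tumour level i and second-tumour level j whose
    interval time falls in ``bin`` = [lo, hi).  Cells with fewer than
    ``min_subgroup`` patients are NaN.
    """
    if variable not in WEIGHTED_VARIABLES:
        raise KeyError(f"variable must be one of {sorted(WEIGHTED_VARIABLES)}")
    col_p, col_c = WEIGHTED_VARIABLES[variable]
    lo, hi = bin
    df = cohort.df
    sub = df[(df["interval_time"] >= lo) & (df["interval_time"] < hi)]
    sub = sub.dropna(subset=[col_p, col_c])
    if len(sub) == 0:
        raise ValueError(f"bin [{lo}, {hi}) unusable: no patients")

    levels_p = sorted(sub[col_p].unique())
    levels_c = sorted(sub[col_c].unique())
    S = pd.DataFrame(np.nan, index=levels_p, columns=levels_c)
    for i in levels_p:
        for j in levels_c:
            cell = sub[(sub[col_p] == i) & (sub[col_c] == j)]
            if len(cell) < min_subgroup:
                continue
            curve = estimate_cif(cell["followup_time"], cell["event"], cause=1)
            S.loc[i, j] = cif_area(curve, upper)
    if S.isna().all().all():
        raise ValueError(f"bin [{lo}, {hi}) unusable: all cells sparse")
    return S


def _spread_sum(S: np.ndarray) -> tuple[float, bool]:
    """Sum over columns of the max pairwise |difference| across rows."""
    total = 0.0
    comparable = False
    for j in range(S.shape[1]):
        col = S[:, j]
        col = col[np.isfinite(col)]
        if col.size >= 2:
            comparable = True
            total += float(col.max() - col.min())
    return total, not comparable


def dp_from_areas(S) -> float:
    """D_p: summed across-row (first-tumour) spread, per second-tumour column.

    Degenerate matrices (no column with two comparable rows) yield 0.
    """
    arr = np.asarray(S, dtype=float)
    value, _ = _spread_sum(arr)
    return value


def dc_from_areas(S) -> float:
    """D_c: the symmetric construction across columns (second-tumour levels)."""
    arr = np.asarray(S, dtype=float)
    value, _ = _spread_sum(arr.T)
    return value


def areas_degenerate(S) -> bool:
    """True when either D_p or D_c has fewer than 2 comparable levels."""
    arr = np.asarray(S, dtype=float)
    _, deg_p = _spread_sum(arr)
    _, deg_c = _spread_sum(arr.T)
    return deg_p or deg_c


def raw_weight(d_p: float, d_c: float) -> float:
    """Normalized first-tumour weight D_p / (D_p + D_c); 0.5 when both vanish."""
    if d_p < 0 or d_c < 0:
        raise ValueError("spreads must be non-negative")
    if d_p + d_c == 0:
        return 0.5
    return d_p / (d_p + d_c)


def build_weight_series(
    cohort: Cohort,
    variable: str,
    bin_centers=tuple(range(1, 16)),
    half_width: float = 1.0,
    upper: float = 10.0,
    min_subgroup: int = 20,
    min_bin: int = 100,
) -> WeightSeries:
    """Raw weight per overlapping interval-time window for one variable."""
    centers = np.asarray(bin_centers, dtype=float)
    raw = np.full(centers.shape, np.nan)
    counts = np.zeros(centers.shape, dtype=int)
    sparse = np.zeros(centers.shape, dtype=bool)
    mats: list = [None] * centers.size
    iv = cohort.df["interval_time"]
    for k, c in enumerate(centers):
        lo, hi = c - half_width, c + half_width
        counts[k] = int(((iv >= lo) & (iv < hi)).sum())
        if counts[k] < min_bin:
            sparse[k] = True
            continue
        try:
            S = compute_area_matrix(
                cohort, variable, (lo, hi), upper=upper, min_subgroup=min_subgroup
            )
        except ValueError:
            sparse[k] = True
            continue
        mats[k] = S
        if areas_degenerate(S):
            sparse[k] = True
            continue
        raw[k] = raw_weight(dp_from_areas(S), dc_from_areas(S))
    return WeightSeries(
        variable=variable, bin_centers=centers, raw_wp=raw,
        bin_counts=counts, area_matrices=mats, sparse=sparse,
    )


def fit_weight_function(series: WeightSeries) -> WeightFit:
    """Weighted nonlinear least squares of the arctan weight law.

    Windows are weighted by patient count.  Falls back to a constant fit
    (b = c = 0, a = mean / (pi/2)) when the series is flat or the
    optimizer fails.
    """
    use = series.usable()
    if use.sum() < 3:
        raise ValueError(
            f"need >= 3 usable windows, have {int(use.sum())} for "
            f"{series.variable!r}"
        )
    t = series.bin_centers[use]
    w = series.raw_wp[use]
    counts = np.maximum(series.bin_counts[use], 1)

    def constant_fallback() -> WeightFit:
        mean = float(np.average(w, weights=counts))
        a = mean / (np.pi / 2.0)
        resid = w - mean
        return WeightFit(
            variable=series.variable, a=a, b=0.0, c=0.0,
            residual_rms=float(np.sqrt(np.mean(resid**2))), series=series,
        )

    if np.std(w) < 1e-9:
        return constant_fallback()
    try:
        popt, _ = curve_fit(
            arctan_weight,
            t,
            w,
            p0=(0.35, 0.3, -1.5),
            sigma=1.0 / np.sqrt(counts),
            bounds=([1e-9, 0.0, -20.0], [A_UPPER, 50.0, 20.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return constant_fallback()
    a, b, c = (float(x) for x in popt)
    resid = w - arctan_weight(t, a, b, c)
    return WeightFit(
        variable=series.variable, a=a, b=b, c=c,
        residual_rms=float(np.sqrt(np.mean(resid**2))), series=series,
    )


def fit_all_weights(cohort: Cohort, variables=tuple(WEIGHTED_VARIABLES), **kwargs):
    """Independent WeightFit per variable; returns {variable: WeightFit}."""
    return {
        v: fit_weight_function(build_weight_series(cohort, v, **kwargs))
        for v in variables
    }


def evaluate_weights(fit: WeightFit, t):
    """(w_p, w_c) at interval time ``t``; w_p clipped to [0.01, 0.99]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    wp = np.clip(arctan_weight(t, fit.a, fit.b, fit.c), *WEIGHT_CLIP)
    wc = 1.0 - wp
    if wp.ndim == 0:
        return float(wp), float(wc)
    return wp, wc


def weights_to_json(fits: dict) -> str:
    return json.dumps({v: f.to_dict() for v, f in fits.items()}, indent=2)


def weights_from_json(text: str) -> dict:
    return {v: WeightFit.from_dict(d) for v, d in json.loads(text).items()}
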