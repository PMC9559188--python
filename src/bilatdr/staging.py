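"""Score assignment and interval-weighted staging of paired features.

Each side's feature level maps to an integer score; the two scores are
blended with the interval-evaluated weights (total = w_p * score_p +
w_c * score_c) and the total, rounded to 2 decimals, is binned into an
ordinal stage by half-open cutoff intervals (lower, upper], with the
minimum total mapping to stage 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord
from .weights import WeightFit, evaluate_weights

__all__ = [
    "ScoreTable",
    "DRStageResult",
    "default_score_table",
    "combine_scores",
    "bin_total_score",
    "stage_patient",
    "stage_cohort",
]

_ROUND = 2
_SLACK = 1e-6


@dataclass
class ScoreTable:
    """Per-variable level -> score maps and total-score cutoff bins."""

    scores: dict = field(default_factory=dict)
    cutoffs: dict = field(default_factory=dict)  # var -> [(lo, hi, stage), ...]

    def max_total(self, variable: str) -> float:
        return float(max(self.scores[variable].values()))


def default_score_table() -> ScoreTable:
    three = [(1.00, 1.50, 1), (1.50, 2.00, 2), (2.00, 2.50, 3), (2.50, 3.00, 4)]
    two = [(1.00, 1.50, 1), (1.50, 2.00, 2)]
    return ScoreTable(
        scores={
            "t": {"T1": 1, "T2": 2, "T3-4": 3},
            "n": {"N0": 1, "N1": 2, "N2-3": 3},
            "grade": {"I-II": 1, "III-IV": 2},
            "er": {"+": 1, "-": 2},
        },
        cutoffs={"t": three, "n": three, "grade": two, "er": two},
    )


@dataclass
class DRStageResult:
    """Weighted totals and stage bins for one patient."""

    interval_time: float
    total_score: dict  # variable -> weighted total
    dr_stage: dict  # variable -> stage index
    weights_used: dict  # variable -> (w_p, w_c)


def combine_scores(score_p: float, score_c: float, w_p: float, w_c: float) -> float:
    """Weighted total score w_p * score_p + w_c * score_c."""
    if abs(w_p + w_c - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return score_p * w_p + score_c * w_c


def bin_total_score(total: float, variable: str, table: ScoreTable) -> int:
    """Stage index of the half-open cutoff interval containing round(total, 2)."""
    cut = table.cutoffs[variable]
    r = round(float(total), _ROUND)
    lo0 = cut[0][0]
    hi_last = cut[-1][1]
    if r < lo0 - _SLACK or r > hi_last + _SLACK:
        raise ValueError(
            f"total {total} outside [{lo0}, {hi_last}] for {variable!r}"
        )
    if r <= lo0 + _SLACK:
        return cut[0][2]
    for lo, hi, stage in cut:
        if lo < r <= hi + _SLACK:
            return stage
    raise AssertionError("unreachable: cutoffs do not partition the range")


def stage_patient(
    record: PatientRecord, fits: dict, table: ScoreTable | None = None
) -> DRStageResult:
    """Evaluate weights at the record's interval time, combine and bin.

    ``fits`` maps variable name -> WeightFit.  Requires non-missing T, N,
    grade and ER on both sides.
    """
    table = table or default_score_table()
    totals: dict = {}
    stages: dict = {}
    wts: dict = {}
    for var, fit in fits.items():
        level_p = getattr(record, f"{var}_pbc")
        level_c = getattr(record, f"{var}_cbc")
        for side, lvl in (("pbc", level_p), ("cbc", level_c)):
            if lvl is None or (isinstance(lvl, float) and np.isnan(lvl)):
                raise ValueError(f"missing feature {var}_{side} "
                                 f"for patient {record.patient_id}")
        w_p, w_c = evaluate_weights(fit, record.interval_time)
        total = combine_scores(
            table.scores[var][level_p], table.scores[var][level_c], w_p, w_c
        )
        totals[var] = total
        stages[var] = bin_total_score(total, var, table)
        wts[var] = (w_p, w_c)
    return DRStageResult(
        interval_time=record.interval_time,
        total_score=totals,
        dr_stage=stages,
        weights_used=wts,
    )


def stage_cohort(
    cohort: Cohort, fits: dict, table: ScoreTable | None = None
) -> pd.DataFrame:
    """Vectorized staging: cohort table plus ``{var}_dr_total`` / ``{var}_dr``.

    Rows missing either side's level for a variable get NaN for that
    variable's columns (they are excluded listwise by downstream models).
    """
    table = table or default_score_table()
    df = cohort.df.copy()
    interval = df["interval_time"].to_numpy(dtype=float)
    for var, fit in fits.items():
        s_p = df[f"{var}_pbc"].map(table.scores[var]).to_numpy(dtype=float)
        s_c = df[f"{var}_cbc"].map(table.scores[var]).to_numpy(dtype=float)
        w_p, w_c = evaluate_weights(fit, interval)
        w_p = np.atleast_1d(w_p)
        total = s_p * w_p + s_c * (1.0 - w_p)
        r = np.round(total, _ROUND)
        uppers = np.array([hi for _, hi, _ in table.cutoffs[var]])
        stage_ids = np.array([st for _, _, st in table.cutoffs[var]])
        idx = np.clip(np.searchsorted(uppers, r - _SLACK, side="left"),
                      0, len(stage_ids) - 1)
        stage = stage_ids[idx].astype(float)
        stage[~np.isfinite(total)] = np.nan
        df[f"{var}_dr_total"] = total
        df[f"{var}_dr"] = stage
    return df
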