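"""Point-based presentation of the staged competing-risk model.

The four DR stages enter a subdistribution regression as ordinal integer
scores.  Points follow the conventional 0-100 normalization: within each
variable the stage with the smallest risk contribution gets 0 points, and
the variable with the widest contribution range spans exactly 100.
Predicted cancer-specific cumulative mortality at a horizon comes from
the underlying regression; the total-points table is presentation only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competing import FineGrayFit, fit_fine_gray, predict_cif
from .staging import DRStageResult

__all__ = ["NomogramModel", "fit_dr_nomogram", "predict_patient"]

STAGE_COLUMNS = ("t_dr", "n_dr", "grade_dr", "er_dr")


@dataclass
class NomogramModel:
    fit: FineGrayFit
    variables: list
    stage_min: dict  # variable -> reference (lowest observed) stage
    stage_levels: dict  # variable -> observed stages
    points: dict  # variable -> {stage: points}
    point_scale: float  # eta units per 100 points
    horizons: tuple = (3.0, 5.0, 10.0)
    horizon_table: pd.DataFrame | None = None

    def eta(self, stages: dict) -> float:
        return float(
            sum(
                self.fit.coefficients[self.fit.names.index(v)]
                * (stages[v] - self.stage_min[v])
                for v in self.variables
            )
        )

    def total_points(self, stages: dict) -> float:
        return float(sum(self.points[v][stages[v]] for v in self.variables))

    def to_json(self) -> str:
        return json.dumps(
            {
                "fit": json.loads(self.fit.to_json()),
                "variables": self.variables,
                "stage_min": self.stage_min,
                "stage_levels": {k: list(v) for k, v in self.stage_levels.items()},
                "points": {
                    v: {str(s): p for s, p in m.items()}
                    for v, m in self.points.items()
                },
                "point_scale": self.point_scale,
                "horizons": list(self.horizons),
                "horizon_table": (
                    None
                    if self.horizon_table is None
                    else self.horizon_table.to_dict(orient="list")
                ),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NomogramModel":
        d = json.loads(text)
        return cls(
            fit=FineGrayFit.from_json(json.dumps(d["fit"])),
            variables=list(d["variables"]),
            stage_min={k: float(v) for k, v in d["stage_min"].items()},
            stage_levels={
                k: [float(x) for x in v] for k, v in d["stage_levels"].items()
            },
            points={
                v: {float(s): p for s, p in m.items()}
                for v, m in d["points"].items()
            },
            point_scale=float(d["point_scale"]),
            horizons=tuple(d["horizons"]),
            horizon_table=(
                None
                if d["horizon_table"] is None
                else pd.DataFrame(d["horizon_table"])
            ),
        )


def fit_dr_nomogram(
    staged: pd.DataFrame,
    stage_columns=STAGE_COLUMNS,
    horizons=(3.0, 5.0, 10.0),
    grid_step: float = 10.0,
) -> NomogramModel:
    """Fit the staged model and derive the point and horizon tables.

    ``staged`` must carry the stage columns plus ``followup_time`` and
    ``event``; rows with any missing stage are dropped listwise.
    """
    cols = list(stage_columns)
    missing = [c for c in cols if c not in staged.columns]
    if missing:
        raise KeyError(f"missing stage column(s): {missing}")
    df = staged.dropna(subset=cols)
    stage_min = {c: float(df[c].min()) for c in cols}
    design = pd.DataFrame(
        {c: df[c].to_numpy(dtype=float) - stage_min[c] for c in cols},
        index=df.index,
    )
    fit = fit_fine_gray(design, df["followup_time"], df["event"])

    stage_levels = {c: sorted(df[c].unique().tolist()) for c in cols}
    beta = dict(zip(fit.names, fit.coefficients))
    # Risk contribution per stage, shifted so each variable's minimum is 0.
    contrib = {
        c: {s: beta[c] * (s - stage_min[c]) for s in stage_levels[c]} for c in cols
    }
    shifted = {
        c: {s: v - min(m.values()) for s, v in m.items()}
        for c, m in contrib.items()
    }
    denom = max(max(m.values()) for m in shifted.values())
    if denom <= 0:
        denom = 1.0
    points = {
        c: {s: 100.0 * v / denom for s, v in m.items()} for c, m in shifted.items()
    }

    # eta = point_scale * total_points / 100 + eta at the all-minimum pattern
    eta_floor = float(sum(min(m.values()) for m in contrib.values()))
    max_points = sum(max(m.values()) for m in points.values())
    grid = np.arange(0.0, max_points + grid_step / 2, grid_step)
    table = {"total_points": grid}
    for h in horizons:
        f0 = fit.baseline_cif(h)
        eta = denom * grid / 100.0 + eta_floor
        table[f"bccm_{h:g}y"] = 1.0 - (1.0 - f0) ** np.exp(eta)
    model = NomogramModel(
        fit=fit,
        variables=cols,
        stage_min=stage_min,
        stage_levels=stage_levels,
        points=points,
        point_scale=denom,
        horizons=tuple(horizons),
        horizon_table=pd.DataFrame(table),
    )
    return model


def _stages_of(staged) -> dict:
    if isinstance(staged, DRStageResult):
        return {f"{v}_dr": float(s) for v, s in staged.dr_stage.items()}
    if isinstance(staged, dict):
        return {k: float(v) for k, v in staged.items()}
    raise TypeError("staged must be a DRStageResult or a {column: stage} mapping")


def predict_patient(
    model: NomogramModel, staged, horizon: float
) -> tuple[float, float]:
    """(predicted cancer-specific cumulative mortality, total points)."""
    stages = _stages_of(staged)
    missing = [v for v in model.variables if v not in stages]
    if missing:
        raise ValueError(f"unstaged input: missing {missing}")
    covs = {v: stages[v] - model.stage_min[v] for v in model.variables}
    prob = predict_cif(model.fit, covs, horizon)
    return prob, model.total_points(stages)
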