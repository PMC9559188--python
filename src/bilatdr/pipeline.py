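"""End-to-end orchestration: simulate/read -> filter -> screen -> weights
-> stage -> nomogram -> validate, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, apply_eligibility_filters, read_cohort
from .nomogram import fit_dr_nomogram, predict_patient
from .screening import screen_variables
from .simulate import SimulationConfig, simulate_cohort
from .staging import default_score_table, stage_cohort
from .validation import (
    ValidationReport,
    calibration_curve,
    concordance_index,
    split_cohort,
)
from .weights import fit_all_weights, weights_to_json

log = logging.getLogger("bilatdr")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "bilatdr_run"
    cohort_path: str | None = None
    dialect: dict | None = None
    simulate: dict | None = None
    screening_variables: tuple = ("t", "n", "grade", "er")
    alpha: float = 0.05
    bin_centers: tuple = tuple(range(1, 16))
    half_width: float = 1.0
    area_horizon: float = 10.0
    min_subgroup: int = 20
    min_bin: int = 100
    split_ratio: tuple = (2, 1)
    horizons: tuple = (3.0, 5.0, 10.0)
    cindex_boot: int = 200
    calibration_boot: int = 1000
    calibration_groups: int = 3
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("screening_variables", "bin_centers", "split_ratio", "horizons"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(raw=raw, **kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.cohort_path is None and self.simulate is None:
            raise ConfigError("config needs either cohort_path or a simulate block")

    def canonical(self) -> str:
        # output_dir is excluded: it cannot change any computed number
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("raw", "output_dir")
        }
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing intermediate artifacts to the run dir.

    Returns the run directory.  Any stage error aborts with a StageError
    naming the stage; artifacts written so far are preserved.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash}
    manifest = {
        "version": __version__,
        **stamp,
        "stages": [],
        "config": json.loads(config.canonical()),
    }

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("stage %s complete", name)

    # ingest / simulate + eligibility
    stage = "cohort"
    try:
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            cohort, truth = simulate_cohort(sim)
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        else:
            cohort, ingest = read_cohort(config.cohort_path, config.dialect)
            ingest.rejects.to_csv(out / "ingest_rejects.tsv", sep="\t", index=False)
        cohort, excl = apply_eligibility_filters(cohort)
        excl.to_frame().to_csv(out / "exclusions.tsv", sep="\t", index=False)
        cohort.write(out / "cohort.tsv")
    except (ConfigError, ValueError, OSError, TypeError) as exc:
        raise StageError(stage, exc) from exc
    finish_stage(stage)

    stage = "screen"
    try:
        report = screen_variables(cohort, config.screening_variables, config.alpha)
        report.table.to_csv(out / "screening.tsv", sep="\t", index=False)
        (out / "screening_selected.json").write_text(
            json.dumps({"selected": report.selected, **stamp})
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc
    finish_stage(stage)

    stage = "fit-weights"
    try:
        fits = fit_all_weights(
            cohort,
            bin_centers=config.bin_centers,
            half_width=config.half_width,
            upper=config.area_horizon,
            min_subgroup=config.min_subgroup,
            min_bin=config.min_bin,
        )
        (out / "weights.json").write_text(weights_to_json(fits))
        curves = []
        grid = np.linspace(0.5, 25, 99)
        for v, f in fits.items():
            from .weights import evaluate_weights

            wp, wc = evaluate_weights(f, grid)
            curves.append(pd.DataFrame({"variable": v, "t": grid, "wp": wp, "wc": wc}))
        pd.concat(curves).to_csv(out / "weight_curves.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    finish_stage(stage)

    stage = "stage"
    try:
        staged = stage_cohort(cohort, fits, default_score_table())
        staged.to_csv(out / "staged.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    finish_stage(stage)

    stage = "fit-nomogram"
    try:
        train, val = split_cohort(
            Cohort(staged, provenance=cohort.provenance),
            seed=config.seed,
            ratio=config.split_ratio,
        )
        model = fit_dr_nomogram(train.df, horizons=config.horizons)
        (out / "nomogram.json").write_text(model.to_json())
        model.horizon_table.to_csv(out / "nomogram_points.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    finish_stage(stage)

    stage = "validate"
    try:
        report = ValidationReport(c_index={}, calibration={}, split_seed=config.seed)
        h_max = max(config.horizons)
        for label, part in (("training", train), ("validation", val)):
            mask = part.df[list(model.variables)].notna().all(axis=1)
            sub = part.df.loc[mask]
            design = pd.DataFrame(
                {v: sub[v] - model.stage_min[v] for v in model.variables}
            )
            eta = np.asarray(model.fit.linear_predictor(design))
            t = sub["followup_time"].to_numpy()
            e = sub["event"].to_numpy()
            preds_max = 1.0 - (1.0 - model.fit.baseline_cif(h_max)) ** np.exp(eta)
            report.c_index[label] = concordance_index(
                preds_max, t, e, horizon=h_max,
                n_boot=config.cindex_boot, seed=config.seed,
            )
            for hz in config.horizons:
                ph = 1.0 - (1.0 - model.fit.baseline_cif(hz)) ** np.exp(eta)
                report.calibration[(label, hz)] = calibration_curve(
                    ph, t, e, horizon=hz,
                    groups=config.calibration_groups,
                    n_boot=config.calibration_boot,
                    seed=config.seed,
                )
        (out / "validation.json").write_text(
            json.dumps({**report.to_dict(), **stamp}, indent=2)
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc
    finish_stage(stage)

    return out
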