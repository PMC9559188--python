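"""Variable screening by univariate and multivariate subdistribution regression.

Paired categorical variables are recoded to combined levels
("<pbc level>/<cbc level>"), dummy-coded against the concordant-lowest
reference.  Each variable is first fitted alone; variables significant on
a joint Wald test then enter one multivariate model, and those still
significant there are selected.  Numeric variables (e.g. interval time)
enter as single continuous columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .competing import ConvergenceError, FineGrayFit, fit_fine_gray

__all__ = ["ScreeningReport", "screen_variables", "PAIRED_VARIABLES"]

#: screenable paired variables -> (pbc column, cbc column)
PAIRED_VARIABLES = {
    "t": ("t_pbc", "t_cbc"),
    "n": ("n_pbc", "n_cbc"),
    "grade": ("grade_pbc", "grade_cbc"),
    "er": ("er_pbc", "er_cbc"),
    "pr": ("pr_pbc", "pr_cbc"),
    "her2": ("her2_pbc", "her2_cbc"),
    "pathology": ("pathology_pbc", "pathology_cbc"),
    "surgery": ("surgery_pbc", "surgery_cbc"),
    "marital_pair": ("marital_pair",),
    "race": ("race",),
}


@dataclass
class ScreeningReport:
    table: pd.DataFrame
    selected: list
    univariate: dict = field(default_factory=dict)  # var -> FineGrayFit
    multivariate: FineGrayFit | None = None
    univariate_p: dict = field(default_factory=dict)  # var -> joint Wald p
    multivariate_p: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)


def _combined_levels(df: pd.DataFrame, variable: str) -> pd.Series | None:
    """Combined "p/c" level string per row (NaN if either side missing)."""
    cols = PAIRED_VARIABLES.get(variable)
    if cols is None:
        if variable in df.columns:
            return None  # numeric / continuous
        raise KeyError(f"unknown variable {variable!r}")
    if len(cols) == 1:
        return df[cols[0]]
    a, b = df[cols[0]], df[cols[1]]
    out = a.astype("string") + "/" + b.astype("string")
    out[a.isna() | b.isna()] = pd.NA
    return out


def _dummy_design(levels: pd.Series, variable: str) -> pd.DataFrame | None:
    """Dummies against the first (sorted) observed level; None if degenerate."""
    observed = sorted(levels.dropna().unique())
    if len(observed) < 2:
        return None
    ref = observed[0]
    cols = {
        f"{variable}[{lvl}]": (levels == lvl).astype(float)
        for lvl in observed
        if lvl != ref
    }
    design = pd.DataFrame(cols, index=levels.index)
    design[levels.isna()] = np.nan
    return design


def screen_variables(
    cohort: Cohort, variables, alpha: float = 0.05
) -> ScreeningReport:
    """Two-step screen: univariate fits, then one joint multivariate fit.

    Per-level Wald statistics are reported for every level; the screening
    decision itself uses the variable's joint Wald test so that
    multi-level variables keep a type-I rate of ``alpha``.
    """
    df = cohort.df
    times = df["followup_time"]
    events = df["event"]

    designs: dict[str, pd.DataFrame] = {}
    notes: dict[str, str] = {}
    for var in variables:
        levels = _combined_levels(df, var)
        if levels is None:
            designs[var] = pd.DataFrame({var: pd.to_numeric(df[var])})
            continue
        design = _dummy_design(levels, var)
        if design is None:
            notes[var] = "single observed level; skipped"
            continue
        designs[var] = design

    uni_fits: dict[str, FineGrayFit] = {}
    uni_p: dict[str, float] = {}
    for var, design in designs.items():
        mask = design.notna().all(axis=1) & times.notna()
        try:
            fit = fit_fine_gray(design[mask], times[mask], events[mask])
        except (ConvergenceError, ValueError) as exc:
            raise RuntimeError(f"univariate fit failed for {var!r}: {exc}") from exc
        uni_fits[var] = fit
        uni_p[var] = fit.wald_test()[2]

    entering = [v for v in designs if uni_p[v] < alpha]
    multi_fit = None
    multi_p: dict[str, float] = {}
    selected: list = []
    if entering:
        joint = pd.concat([designs[v] for v in entering], axis=1)
        mask = joint.notna().all(axis=1) & times.notna()
        try:
            multi_fit = fit_fine_gray(joint[mask], times[mask], events[mask])
        except (ConvergenceError, ValueError) as exc:
            raise RuntimeError(f"multivariate fit failed: {exc}") from exc
        for var in entering:
            cols = list(designs[var].columns)
            multi_p[var] = multi_fit.wald_test(cols)[2]
            if multi_p[var] < alpha:
                selected.append(var)

    rows = []
    for var, design in designs.items():
        fit = uni_fits[var]
        summ = fit.summary()
        msum = multi_fit.summary() if multi_fit is not None else None
        for name in design.columns:
            level = name[name.find("[") + 1:-1] if "[" in name else name
            count = int(np.nansum(design[name] == 1)) if "[" in name else len(design)
            row = {
                "variable": var,
                "level": level,
                "count": count,
                "uni_shr": summ.loc[name, "shr"],
                "uni_ci_low": summ.loc[name, "ci_low"],
                "uni_ci_upp": summ.loc[name, "ci_upp"],
                "uni_p": summ.loc[name, "p"],
                "uni_joint_p": uni_p[var],
            }
            if msum is not None and name in msum.index:
                row.update(
                    multi_shr=msum.loc[name, "shr"],
                    multi_ci_low=msum.loc[name, "ci_low"],
                    multi_ci_upp=msum.loc[name, "ci_upp"],
                    multi_p=msum.loc[name, "p"],
                    multi_joint_p=multi_p.get(var, np.nan),
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    return ScreeningReport(
        table=table,
        selected=selected,
        univariate=uni_fits,
        multivariate=multi_fit,
        univariate_p=uni_p,
        multivariate_p=multi_p,
        notes=notes,
    )
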