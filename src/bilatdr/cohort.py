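"""Domain types and table handling for paired-tumour cohorts.

A cohort row describes one patient with two breast tumours diagnosed at
different times: the first ("pbc") and the contralateral second ("cbc").
Each clinical feature is recorded for both sides; follow-up starts at the
second diagnosis and ends in censoring (0), breast-cancer death (1) or
other-cause death (2).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Allowed levels per categorical column. Order is meaningful: the first
#: level is the reference / lowest-score level.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "race": ("white", "black", "other"),
    "marital_pair": ("NonP/NonP", "NonP/WithP", "WithP/NonP", "WithP/WithP"),
    "t_pbc": ("T1", "T2", "T3-4"),
    "t_cbc": ("T1", "T2", "T3-4"),
    "n_pbc": ("N0", "N1", "N2-3"),
    "n_cbc": ("N0", "N1", "N2-3"),
    "grade_pbc": ("I-II", "III-IV"),
    "grade_cbc": ("I-II", "III-IV"),
    "er_pbc": ("+", "-"),
    "er_cbc": ("+", "-"),
    "pr_pbc": ("+", "-"),
    "pr_cbc": ("+", "-"),
    "her2_pbc": ("+", "-"),
    "her2_cbc": ("+", "-"),
    "pathology_pbc": ("IDC", "ILC", "other"),
    "pathology_cbc": ("IDC", "ILC", "other"),
    "surgery_pbc": ("BCM", "SM", "RM"),
    "surgery_cbc": ("BCM", "SM", "RM"),
}

NUMERIC_COLUMNS = ("age_pbc", "age_cbc", "interval_time", "followup_time")

#: Columns that every input table must provide (possibly via a dialect map).
MANDATORY_COLUMNS = (
    "patient_id",
    "age_pbc",
    "interval_time",
    "followup_time",
    "event",
)

#: Columns allowed to be missing per record (modelled listwise downstream).
OPTIONAL_COLUMNS = ("pr_pbc", "pr_cbc", "her2_pbc", "her2_cbc", "distant_met")

EVENT_CENSORED = 0
EVENT_CANCER = 1
EVENT_OTHER = 2


@dataclass
class PatientRecord:
    """One patient with paired tumour features and competing-risk follow-up."""

    patient_id: str
    age_pbc: float
    interval_time: float
    followup_time: float
    event: int
    age_cbc: float | None = None
    race: str | None = None
    marital_pair: str | None = None
    t_pbc: str | None = None
    t_cbc: str | None = None
    n_pbc: str | None = None
    n_cbc: str | None = None
    grade_pbc: str | None = None
    grade_cbc: str | None = None
    er_pbc: str | None = None
    er_cbc: str | None = None
    pr_pbc: str | None = None
    pr_cbc: str | None = None
    her2_pbc: str | None = None
    her2_cbc: str | None = None
    pathology_pbc: str | None = None
    pathology_cbc: str | None = None
    surgery_pbc: str | None = None
    surgery_cbc: str | None = None
    distant_met: bool = False

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out: list[str] = []
        if not (self.interval_time > 0):
            out.append("interval_time must be > 0")
        if not (self.followup_time > 0):
            out.append("followup_time must be > 0")
        if self.event not in (EVENT_CENSORED, EVENT_CANCER, EVENT_OTHER):
            out.append(f"event code {self.event!r} not in {{0, 1, 2}}")
        if self.age_cbc is not None and not math.isnan(self.age_cbc):
            if self.age_cbc < self.age_pbc:
                out.append("age_cbc < age_pbc")
        for col, levels in CATEGORICAL_LEVELS.items():
            val = getattr(self, col)
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                if val not in levels:
                    out.append(f"{col}={val!r} not in {levels}")
        return out


@dataclass
class Cohort:
    """Ordered collection of patient rows backed by a DataFrame."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if "patient_id" in self.df.columns:
            ids = self.df["patient_id"]
            if ids.duplicated().any():
                dup = ids[ids.duplicated()].iloc[0]
                raise ValueError(f"duplicate patient_id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[PatientRecord]:
        fields = {f.name for f in dataclasses.fields(PatientRecord)}
        for _, row in self.df.iterrows():
            kwargs = {k: row[k] for k in row.index if k in fields}
            if "distant_met" in kwargs:
                v = kwargs["distant_met"]
                kwargs["distant_met"] = bool(v) if not pd.isna(v) else False
            yield PatientRecord(**kwargs)

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], provenance: str = ""
    ) -> "Cohort":
        rows = [dataclasses.asdict(r) for r in records]
        return cls(pd.DataFrame(rows), provenance=provenance)

    def write(self, path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index=False)


@dataclass
class IngestReport:
    n_read: int
    n_kept: int
    rejects: pd.DataFrame  # columns: row, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


@dataclass
class ExclusionReport:
    n_in: int
    n_out: int
    counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "excluded": v} for k, v in self.counts.items()]
        rows.append({"criterion": "retained", "excluded": self.n_out})
        return pd.DataFrame(rows)


def _apply_dialect(df: pd.DataFrame, dialect: Mapping | None) -> pd.DataFrame:
    if not dialect:
        return df
    columns = dialect.get("columns", {})
    if columns:
        df = df.rename(columns=dict(columns))
    codes = dialect.get("codes", {})
    for col, mapping in codes.items():
        if col in df.columns:
            df[col] = df[col].map(lambda v: mapping.get(v, mapping.get(str(v), v)))
    return df


def read_cohort(path, dialect: Mapping | None = None) -> tuple[Cohort, IngestReport]:
    """Read a delimited cohort table, mapping source columns via ``dialect``.

    ``dialect`` may carry ``sep`` (default sniffed from extension),
    ``columns`` (source name -> canonical field) and ``codes``
    (field -> {source code -> canonical level}).  Rows that fail type
    coercion or violate record invariants are dropped and counted.
    """
    sep = None
    if dialect:
        sep = dialect.get("sep")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    raw = _apply_dialect(raw, dialect)

    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    reasons: list[tuple[int, str]] = []
    keep = np.ones(len(raw), dtype=bool)

    for col in NUMERIC_COLUMNS:
        if col not in raw.columns:
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        for i in np.flatnonzero(bad.to_numpy()):
            reasons.append((i, f"{col}: not numeric"))
        keep &= ~bad.to_numpy()
        raw[col] = coerced

    ev = pd.to_numeric(raw["event"], errors="coerce")
    bad_ev = ~ev.isin([EVENT_CENSORED, EVENT_CANCER, EVENT_OTHER])
    for i in np.flatnonzero(bad_ev.to_numpy()):
        reasons.append((i, f"event: code {raw['event'].iloc[i]!r} not in {{0,1,2}}"))
    keep &= ~bad_ev.to_numpy()
    raw["event"] = ev

    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in raw.columns:
            continue
        vals = raw[col]
        bad = vals.notna() & ~vals.isin(levels)
        for i in np.flatnonzero(bad.to_numpy()):
            reasons.append((i, f"{col}: unmapped code {vals.iloc[i]!r}"))
        keep &= ~bad.to_numpy()

    for col, pred, why in (
        ("interval_time", lambda s: s > 0, "interval_time not > 0"),
        ("followup_time", lambda s: s > 0, "followup_time not > 0"),
    ):
        ok = pred(raw[col]).fillna(False) | raw[col].isna()
        for i in np.flatnonzero((~ok & keep).to_numpy()):
            reasons.append((i, why))
        keep &= ok.to_numpy()

    if "age_cbc" in raw.columns:
        bad = (raw["age_cbc"] < raw["age_pbc"]).fillna(False)
        for i in np.flatnonzero((bad & keep).to_numpy()):
            reasons.append((i, "age_cbc < age_pbc"))
        keep &= ~bad.to_numpy()

    kept = raw.loc[keep].reset_index(drop=True)
    kept["event"] = kept["event"].astype(int)
    report = IngestReport(
        n_read=len(raw),
        n_kept=len(kept),
        rejects=pd.DataFrame(reasons, columns=["row", "reason"]),
    )
    return Cohort(kept, provenance=str(path)), report


def apply_eligibility_filters(
    cohort: Cohort,
    min_interval: float = 0.5,
    min_followup: float = 0.25,
    age_range: tuple[float, float] = (18.0, 97.0),
) -> tuple[Cohort, ExclusionReport]:
    """Apply the study eligibility rules and count exclusions per criterion.

    Retains patients whose second diagnosis came at least ``min_interval``
    years after the first, with at least ``min_followup`` years of follow-up,
    first-diagnosis age within ``age_range``, and no distant-metastasis flag.
    Idempotent: filtering a filtered cohort is a no-op.
    """
    df = cohort.df
    n = len(df)
    crit = {
        "interval_time < 6 months": df["interval_time"] < min_interval,
        "followup_time < 3 months": df["followup_time"] < min_followup,
        "age_pbc outside [18, 97]": (df["age_pbc"] < age_range[0])
        | (df["age_pbc"] > age_range[1]),
    }
    if "distant_met" in df.columns:
        dm = df["distant_met"]
        crit["distant metastasis at diagnosis"] = dm.fillna(False).astype(bool)
    excluded = np.zeros(n, dtype=bool)
    counts = {}
    for name, mask in crit.items():
        mask = mask.fillna(False).to_numpy(dtype=bool)
        counts[name] = int(mask.sum())
        excluded |= mask
    kept = df.loc[~excluded].reset_index(drop=True)
    report = ExclusionReport(n_in=n, n_out=len(kept), counts=counts)
    return Cohort(kept, provenance=cohort.provenance), report


def summarize_cohort(
    cohort: Cohort,
    variable: str,
    bins: Sequence[tuple[str, float, float]] | Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Counts and percentages of ``variable`` over a partition of its values.

    ``bins`` is either ``None`` (one group per observed level), a list of
    ``(label, lower, upper)`` half-open intervals ``(lower, upper]`` for a
    numeric variable, or a mapping ``label -> levels`` for a categorical one.
    Percentages use the count of records non-missing for the variable as
    denominator; the ``percent`` column is rounded to 2 decimals while
    ``fraction`` keeps full precision.
    """
    df = cohort.df
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    col = df[variable]
    denom = int(col.notna().sum())
    rows = []
    if bins is None:
        for level, count in col.value_counts(dropna=True).sort_index().items():
            rows.append((str(level), int(count)))
    elif isinstance(bins, Mapping):
        for label, levels in bins.items():
            rows.append((label, int(col.isin(list(levels)).sum())))
    else:
        vals = pd.to_numeric(col, errors="coerce")
        for label, lo, hi in bins:
            rows.append((label, int(((vals > lo) & (vals <= hi)).sum())))
    out = pd.DataFrame(rows, columns=["group", "count"])
    out["fraction"] = out["count"] / denom if denom else np.nan
    out["percent"] = (100.0 * out["fraction"]).round(2)
    return out
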