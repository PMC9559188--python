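"""Per-lesion intratumour heterogeneity from variant allele fractions.

The MATH score is 100 x (1.4826 x median absolute deviation of the VAFs)
divided by their median — the normal-consistency constant follows the
original MATH definition.  The bilateral MATH ratio is defined here as
MATH(second tumour) / MATH(first tumour); note the direction, which is an
inference rather than a published formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantTable",
    "HeterogeneityMetrics",
    "read_variant_table",
    "math_score",
    "trunk_branch_fractions",
    "math_ratio",
    "regress_ratio_on_interval",
]

MAD_SCALE = 1.4826


@dataclass
class VariantTable:
    lesion_id: str
    variants: pd.DataFrame  # columns: variant_id, vaf

    def __post_init__(self) -> None:
        v = self.variants
        if v["variant_id"].duplicated().any():
            raise ValueError("variant identifiers must be unique within a lesion")
        if ((v["vaf"] < 0) | (v["vaf"] > 1)).any():
            raise ValueError("VAF must lie in [0, 1]")

    @property
    def ids(self) -> set:
        return set(self.variants["variant_id"])


@dataclass
class HeterogeneityMetrics:
    math_pbc: float
    math_cbc: float
    math_ratio: float
    trunk_fraction: float
    branch_fraction: float
    interval_time: float


def read_variant_table(path, lesion_id: str | None = None, sep="\t") -> VariantTable:
    """Read (lesion_id, variant_id, vaf) or minimal MAF-like columns.

    MAF-like input needs gene/chrom/pos/ref/alt plus t_alt_count and
    t_depth; VAF is computed as t_alt_count / t_depth.
    """
    df = pd.read_csv(path, sep=sep)
    if "vaf" in df.columns and "variant_id" in df.columns:
        lid = lesion_id or (str(df["lesion_id"].iloc[0]) if "lesion_id" in df else "?")
        if "lesion_id" in df.columns and lesion_id is not None:
            df = df[df["lesion_id"] == lesion_id]
        return VariantTable(lid, df[["variant_id", "vaf"]].reset_index(drop=True))
    maf_cols = {"chrom", "pos", "ref", "alt", "t_alt_count", "t_depth"}
    if maf_cols.issubset(df.columns):
        out = pd.DataFrame(
            {
                "variant_id": df["chrom"].astype(str)
                + ":"
                + df["pos"].astype(str)
                + df["ref"].astype(str)
                + ">"
                + df["alt"].astype(str),
                "vaf": df["t_alt_count"] / df["t_depth"],
            }
        )
        return VariantTable(lesion_id or "?", out)
    raise ValueError("unrecognized variant table: need (variant_id, vaf) "
                     "or MAF-like columns")


def math_score(table: VariantTable) -> float:
    """100 x scaled-MAD / median of the positive VAFs.

    Scale-invariant: multiplying every VAF by a constant leaves it fixed.
    """
    vaf = table.variants["vaf"].to_numpy(dtype=float)
    vaf = vaf[vaf > 0]
    if vaf.size < 2:
        raise ValueError("need at least 2 variants with VAF > 0")
    med = float(np.median(vaf))
    mad = float(np.median(np.abs(vaf - med)))
    return 100.0 * MAD_SCALE * mad / med


def trunk_branch_fractions(
    pbc: VariantTable, cbc: VariantTable
) -> tuple[float, float]:
    """(shared / union, 1 - shared / union) of the two lesions' variant sets."""
    a, b = pbc.ids, cbc.ids
    union = a | b
    if not union:
        raise ValueError("both lesions are empty")
    trunk = len(a & b) / len(union)
    return trunk, 1.0 - trunk


def math_ratio(pbc: VariantTable, cbc: VariantTable) -> float:
    """MATH(second tumour) / MATH(first tumour)."""
    return math_score(cbc) / math_score(pbc)


def compute_metrics(
    pbc: VariantTable, cbc: VariantTable, interval_time: float
) -> HeterogeneityMetrics:
    trunk, branch = trunk_branch_fractions(pbc, cbc)
    m_p, m_c = math_score(pbc), math_score(cbc)
    return HeterogeneityMetrics(
        math_pbc=m_p,
        math_cbc=m_c,
        math_ratio=m_c / m_p,
        trunk_fraction=trunk,
        branch_fraction=branch,
        interval_time=interval_time,
    )


def regress_ratio_on_interval(metrics) -> tuple[float, float, float]:
    """OLS of MATH ratio on interval time -> (slope, intercept, R^2)."""
    pts = [(m.interval_time, m.math_ratio) for m in metrics]
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all interval times equal")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
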