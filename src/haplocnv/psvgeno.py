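"""Paralogous sequence variant (PSV) genotyping inside multicopy segments.

Reads from all paralogous copies of a repeat are presumed realigned to a
collapsed reference containing a single copy, so pileup counts at a PSV site
aggregate evidence across copies.  The PSV allele fraction (fraction of
repeat units carrying the variant) is estimated from the pileup and scaled by
the individual's total repeat copy number — a continuous dosage from the
common-CNV pipeline — to give the PSV copy number (number of repeat units
carrying the variant).  Downstream phasing/denoising reuses the
haplotype-sharing machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PSVGenotype",
    "aggregate_paralog_pileup",
    "psv_allele_fraction",
    "psv_copy_number",
]


@dataclass
class PSVGenotype:
    sample: str
    psv_site: int
    allele_fraction: float
    af_ci: tuple[float, float]
    cn_total: float
    psv_cn_cont: float
    psv_cn_int: int
    rounding_residual: float
    missing: bool = False


def aggregate_paralog_pileup(
    per_paralog_counts: pd.DataFrame,
    paralog_map: pd.DataFrame,
) -> pd.DataFrame:
    """Sum per-paralog pileup counts onto collapsed-reference coordinates.

    ``per_paralog_counts``: columns sample, copy_id, pos (reference bp),
    alt_count, total_count.  ``paralog_map``: columns copy_id, start, end,
    strand, collapsed_offset — each reference copy maps onto the collapsed
    coordinate by offset, with minus-strand copies position-reversed.  All
    copies must have equal length.
    """
    lengths = (paralog_map["end"] - paralog_map["start"]).to_numpy()
    if len(np.unique(lengths)) != 1:
        raise ValueError("inconsistent paralog copy lengths")
    cmap = paralog_map.set_index("copy_id")
    rows = per_paralog_counts.copy()
    info = cmap.loc[rows["copy_id"]]
    start = info["start"].to_numpy()
    end = info["end"].to_numpy()
    offset = info["collapsed_offset"].to_numpy()
    strand = info["strand"].to_numpy()
    pos = rows["pos"].to_numpy()
    if np.any(pos < start) or np.any(pos >= end):
        raise ValueError("pileup position outside its paralog copy")
    collapsed = np.where(strand == "+", offset + (pos - start), offset + (end - 1 - pos))
    rows["psv_site"] = collapsed
    agg = (
        rows.groupby(["sample", "psv_site"], as_index=False)[["alt_count", "total_count"]]
        .sum()
        .sort_values(["sample", "psv_site"])
        .reset_index(drop=True)
    )
    return agg


def psv_allele_fraction(
    counts: pd.DataFrame, t_min: int = 10, ci_alpha: float = 0.05
) -> pd.DataFrame:
    """Allele fraction AF = a/t with a Wilson score interval per (sample, site).

    Genotypes with total depth below ``t_min`` are flagged missing.
    """
    a = counts["alt_count"].to_numpy()
    t = counts["total_count"].to_numpy()
    if np.any(a < 0) or np.any(a > t):
        raise ValueError("require 0 <= alt_count <= total_count")
    missing = t < t_min
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(t > 0, a / np.where(t > 0, t, 1), np.nan)
    lo, hi = proportion_confint(a, np.maximum(t, 1), alpha=ci_alpha, method="wilson")
    out = counts[["sample", "psv_site"]].copy()
    out["allele_fraction"] = np.where(missing, np.nan, af)
    out["af_lo"] = np.where(missing, np.nan, lo)
    out["af_hi"] = np.where(missing, np.nan, hi)
    out["missing"] = missing
    return out


def psv_copy_number(
    af: np.ndarray | pd.Series, cn_total: np.ndarray | pd.Series | float
) -> pd.DataFrame:
    """Scale total repeat copy number by allele fraction.

    Returns the continuous PSV copy number ``AF * cn_total``, its nearest
    integer clipped to [0, round(cn_total)], and the rounding residual as a
    per-genotype quality metric.
    """
    af = np.asarray(af, dtype=float)
    cn_total = np.broadcast_to(np.asarray(cn_total, dtype=float), af.shape).copy()
    if np.any(cn_total < 0):
        raise ValueError("cn_total must be non-negative")
    cont = af * cn_total
    upper = np.round(cn_total)
    integer = np.clip(np.round(cont), 0, upper)
    residual = np.abs(cont - integer)
    integer = np.where(np.isnan(cont), np.nan, integer)
    return pd.DataFrame(
        {
            "psv_cn_cont": cont,
            "psv_cn_int": integer,
            "rounding_residual": residual,
            "cn_total": cn_total,
        }
    )
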