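"""Weighted methylation levels and genome-scale summaries.

The central statistic is the *weighted methylation level* of a set of
cytosines: sum of methylation-supporting reads over the sum of all reads,

    level = sum(#C) / sum(#C + #T),

which weights each site by its coverage and is in general different from the
unweighted mean of per-site fractions. A region with zero total reads has an
*undefined* level, represented as NaN and flagged via ``covered_sites`` /
``total_reads`` — never silently coerced to 0.

Count tables are pandas DataFrames with columns
``chrom, pos (1-based), strand (+/-), context (CG|CHG|CHH), c_count, t_count``
— the shape of BSMAP methratio output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CONTEXTS

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "strand", "context", "c_count", "t_count"]


@dataclass(frozen=True)
class RegionLevel:
    """Weighted methylation level of one site set / region."""

    context: str
    weighted_level: float  # NaN when undefined
    covered_sites: int
    total_reads: int

    @property
    def defined(self) -> bool:
        return self.total_reads > 0

    def __float__(self) -> float:
        return float(self.weighted_level)


def weighted_level(sites: pd.DataFrame) -> RegionLevel:
    """Weighted level of a site collection sharing one context.

    ``sites`` needs columns ``c_count``, ``t_count`` and (if present)
    a single ``context`` value — mixed contexts are a contract violation,
    since pooling reads across contexts has no biological meaning.
    """
    if "context" in sites.columns and sites["context"].nunique() > 1:
        raise ValueError(
            "weighted_level requires a single context; got "
            f"{sorted(sites['context'].unique())}"
        )
    context = sites["context"].iloc[0] if ("context" in sites.columns and len(sites)) else ""
    c = int(sites["c_count"].sum())
    t = int(sites["t_count"].sum())
    total = c + t
    covered = int(((sites["c_count"] + sites["t_count"]) > 0).sum())
    level = c / total if total > 0 else float("nan")
    return RegionLevel(context=str(context), weighted_level=level,
                       covered_sites=covered, total_reads=total)


def pool_replicates(*tables: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate count tables by summing reads per site.

    Weighted levels are invariant to pooling vs concatenation, but per-site
    statistics (coverage filters, dyad pairing) need one row per site.
    """
    merged = pd.concat(tables, ignore_index=True)
    return (merged.groupby(["chrom", "pos", "strand", "context"],
                           observed=True, as_index=False)[["c_count", "t_count"]]
            .sum())


def site_levels(table: pd.DataFrame) -> pd.Series:
    """Per-site fraction #C/(#C+#T); NaN where coverage is zero."""
    cov = table["c_count"] + table["t_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return table["c_count"] / cov.where(cov > 0)


def genome_wide_levels(count_table: pd.DataFrame,
                       context_index: pd.DataFrame | None = None,
                       ) -> dict[str, RegionLevel]:
    """One weighted level per context over all covered sites.

    When a ``context_index`` is supplied, count rows absent from the index
    are logged and excluded and the index's labels take precedence over the
    table's own ``context`` column (AMBIGUOUS sites drop out).
    """
    table = count_table
    if context_index is not None:
        merged = table.merge(
            context_index, on=["chrom", "pos", "strand"],
            how="left", suffixes=("_table", ""))
        missing = merged["context"].isna()
        if missing.any():
            logger.warning("%d count rows not present in context index; excluded",
                           int(missing.sum()))
        table = merged.loc[~missing]
    out: dict[str, RegionLevel] = {}
    for ctx in CONTEXTS:
        sub = table.loc[table["context"] == ctx, ["c_count", "t_count"]]
        c, t = int(sub["c_count"].sum()), int(sub["t_count"].sum())
        total = c + t
        out[ctx] = RegionLevel(
            context=ctx,
            weighted_level=c / total if total else float("nan"),
            covered_sites=int(((sub["c_count"] + sub["t_count"]) > 0).sum()),
            total_reads=total,
        )
    return out


def window_levels(count_table: pd.DataFrame, window_size: int,
                  chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Weighted level per non-overlapping genomic window per context.

    Windows tile each chromosome from position 1 in steps of ``window_size``.
    With ``chrom_sizes`` every window of every chromosome appears (undefined
    ones as NaN); otherwise only windows up to the last observed site.
    Returns columns chrom, window_start (1-based), context, weighted_level,
    covered_sites, total_reads.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    tbl = count_table.copy()
    tbl["window_start"] = ((tbl["pos"] - 1) // window_size) * window_size + 1
    tbl["covered"] = (tbl["c_count"] + tbl["t_count"]) > 0
    grouped = (
        tbl.groupby(["chrom", "window_start", "context"], observed=True)
        .agg(c=("c_count", "sum"), t=("t_count", "sum"),
             covered_sites=("covered", "sum"))
        .reset_index()
    )
    grouped["covered_sites"] = grouped["covered_sites"].astype(int)
    grouped["total_reads"] = grouped["c"] + grouped["t"]
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["weighted_level"] = grouped["c"] / grouped["total_reads"].where(
            grouped["total_reads"] > 0)
    grouped = grouped.drop(columns=["c", "t"])

    if chrom_sizes is not None:
        frames = []
        for chrom, size in chrom_sizes.items():
            starts = np.arange(1, size + 1, window_size)
            for ctx in CONTEXTS:
                frames.append(pd.DataFrame(
                    {"chrom": chrom, "window_start": starts, "context": ctx}))
        full = pd.concat(frames, ignore_index=True)
        grouped = full.merge(grouped, on=["chrom", "window_start", "context"],
                             how="left")
        grouped[["covered_sites", "total_reads"]] = (
            grouped[["covered_sites", "total_reads"]].fillna(0).astype(int))
    return grouped.sort_values(["chrom", "window_start", "context"],
                               ignore_index=True)


def replicate_correlation(table_rep1: pd.DataFrame, table_rep2: pd.DataFrame,
                          window_size: int = 2000,
                          method: str = "pearson") -> dict[str, float]:
    """Per-context correlation of windowed levels between two replicates.

    Windows where either replicate is undefined are dropped pairwise
    (complete-case); fewer than 3 jointly defined windows is an error.
    """
    w1 = window_levels(table_rep1, window_size)
    w2 = window_levels(table_rep2, window_size)
    merged = w1.merge(w2, on=["chrom", "window_start", "context"],
                      suffixes=("_1", "_2"))
    out: dict[str, float] = {}
    for ctx in CONTEXTS:
        sub = merged.loc[merged["context"] == ctx,
                         ["weighted_level_1", "weighted_level_2"]].dropna()
        if len(sub) < 3:
            raise ValueError(
                f"replicate_correlation: only {len(sub)} jointly defined "
                f"{ctx} windows (need >= 3)")
        if method == "pearson":
            r = stats.pearsonr(sub["weighted_level_1"], sub["weighted_level_2"]).statistic
        elif method == "spearman":
            r = stats.spearmanr(sub["weighted_level_1"], sub["weighted_level_2"]).statistic
        else:
            raise ValueError(f"unknown method {method!r}")
        out[ctx] = float(r)
    return out


def strand_symmetry(count_table: pd.DataFrame,
                    context_index: pd.DataFrame | None = None,
                    context: str = "CG",
                    min_coverage: int = 4) -> tuple[float, pd.DataFrame]:
    """Correlation of methylation across the two strands of symmetric dyads.

    A plus-strand CG at position i pairs with the minus-strand CG at i+1;
    a CHG pairs at i+2. Only dyads where both strands reach ``min_coverage``
    reads enter the correlation of per-site fractions. CHH is asymmetric and
    therefore rejected. Returns (Pearson r, dyad table).
    """
    if context == "CG":
        offset = 1
    elif context == "CHG":
        offset = 2
    else:
        raise ValueError(f"strand symmetry is defined for CG/CHG only, got {context!r}")
    tbl = count_table
    if context_index is not None:
        tbl = tbl.drop(columns=["context"]).merge(
            context_index, on=["chrom", "pos", "strand"], how="inner")
    tbl = tbl.loc[tbl["context"] == context].copy()
    cov = tbl["c_count"] + tbl["t_count"]
    tbl["level"] = site_levels(tbl)
    tbl = tbl.loc[cov >= min_coverage]

    plus = tbl.loc[tbl["strand"] == "+", ["chrom", "pos", "level"]].copy()
    minus = tbl.loc[tbl["strand"] == "-", ["chrom", "pos", "level"]].copy()
    minus["pos"] = minus["pos"] - offset
    dyads = plus.merge(minus, on=["chrom", "pos"], suffixes=("_plus", "_minus"))
    if len(dyads) < 2:
        raise ValueError(f"only {len(dyads)} covered {context} dyads; need >= 2")
    r = stats.pearsonr(dyads["level_plus"], dyads["level_minus"]).statistic
    return float(r), dyads


def methylcytosine_composition(count_table: pd.DataFrame,
                               context_index: pd.DataFrame | None = None,
                               call_threshold: float = 0.5,
                               min_coverage: int = 4) -> dict[str, float]:
    """Fraction of called methyl-cytosines in each context (sums to 1).

    A covered site is called methylated when its per-site fraction reaches
    ``call_threshold`` and its coverage reaches ``min_coverage``. Raises when
    no site is called (composition undefined).
    """
    if not 0 < call_threshold < 1:
        raise ValueError("call_threshold must be in (0, 1)")
    tbl = count_table
    if context_index is not None:
        tbl = tbl.drop(columns=["context"]).merge(
            context_index, on=["chrom", "pos", "strand"], how="inner")
    cov = tbl["c_count"] + tbl["t_count"]
    lvl = site_levels(tbl)
    called = tbl.loc[(cov >= min_coverage) & (lvl >= call_threshold)]
    called = called.loc[called["context"].isin(CONTEXTS)]
    n = len(called)
    if n == 0:
        raise ValueError("no methyl-cytosines called; composition undefined")
    counts = called["context"].value_counts()
    return {ctx: float(counts.get(ctx, 0)) / n for ctx in CONTEXTS}
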