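"""Feature-centred methylation analyses.

Covers the gene/TE-centred views of a methylome:

* **metaplots** — each feature body is proportionally divided into 20 bins
  and flanked by 20 fixed 100-bp bins on each side (2 kb up- and downstream),
  oriented by feature strand; bin levels are weighted levels pooled over all
  features' sites falling in that bin;
* **genic region levels** — per-gene weighted levels for the promoter
  (2 kb upstream of the TSS), gene body, and downstream (2 kb past the TES);
* **expression stratification** — the five-group scheme (group 1 = FPKM
  below 0.5, the rest rank-split into four near-equal groups) and
  low/mid/high thirds;
* **strata comparison** — two-sided Mann–Whitney rank tests between per-gene
  level distributions;
* **TE-associated genes** — genes whose body or 2-kb flanks intersect any
  annotated TE (half-open interval intersection, strand-ignored).

Features are stored 0-based half-open; count-table positions are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .contexts import CONTEXTS

logger = logging.getLogger(__name__)

N_BODY_BINS = 20
FLANK_BP = 2000
FLANK_BIN_BP = 100  # 20 bins per flank


@dataclass
class MethylationProfile:
    """60 weighted levels: 20 upstream, 20 body, 20 downstream bins."""

    context: str
    group: str
    levels: np.ndarray          # length 60, NaN where undefined
    c_counts: np.ndarray        # pooled methylated reads per bin
    total_reads: np.ndarray     # pooled reads per bin
    n_features: int

    @property
    def upstream(self) -> np.ndarray:
        return self.levels[:N_BODY_BINS]

    @property
    def body(self) -> np.ndarray:
        return self.levels[N_BODY_BINS:2 * N_BODY_BINS]

    @property
    def downstream(self) -> np.ndarray:
        return self.levels[2 * N_BODY_BINS:]


def body_bin_edges(length: int, n_bins: int = N_BODY_BINS) -> np.ndarray:
    """Offsets of the proportional body-bin boundaries: bin k covers
    [floor(k*L/n), floor((k+1)*L/n)). The bins tile [0, L) exactly."""
    return (np.arange(n_bins + 1) * length) // n_bins


def _assign_bins(offsets: np.ndarray, length: int) -> np.ndarray:
    """Bin index (0..59) for site offsets measured 5'->3' from the start of
    the upstream flank window; -1 for sites outside the profiled span."""
    out = np.full(offsets.size, -1, dtype=np.int64)
    up = (offsets >= 0) & (offsets < FLANK_BP)
    out[up] = offsets[up] // FLANK_BIN_BP
    body = (offsets >= FLANK_BP) & (offsets < FLANK_BP + length)
    edges = body_bin_edges(length)
    out[body] = N_BODY_BINS + (
        np.searchsorted(edges, offsets[body] - FLANK_BP, side="right") - 1)
    down = (offsets >= FLANK_BP + length) & (offsets < FLANK_BP + length + FLANK_BP)
    out[down] = 2 * N_BODY_BINS + (offsets[down] - FLANK_BP - length) // FLANK_BIN_BP
    return out


def feature_metaplot(count_table: pd.DataFrame, features: pd.DataFrame,
                     context: str, group: str = "all",
                     per_feature_mean: bool = False) -> MethylationProfile:
    """Average methylation profile over features with 2-kb flanks.

    Sites on both strands contribute. Bin coordinates follow the feature
    strand: bin 0 starts 2 kb upstream of the TSS, bin 59 ends 2 kb
    downstream of the TES. Features shorter than 20 bp are excluded (logged).
    By default bins pool reads across features (weighted level); with
    ``per_feature_mean`` each feature contributes its own bin level and bins
    average those.
    """
    feats = features.loc[features["end"] - features["start"] >= N_BODY_BINS]
    dropped = len(features) - len(feats)
    if dropped:
        logger.warning("%d features shorter than %d bp excluded from metaplot",
                       dropped, N_BODY_BINS)
    if feats.empty:
        raise ValueError("no usable features for metaplot")

    tbl = count_table.loc[count_table["context"] == context]
    c_bins = np.zeros(3 * N_BODY_BINS)
    t_bins = np.zeros(3 * N_BODY_BINS)
    per_feat_levels = []
    by_chrom = {chrom: sub for chrom, sub in tbl.groupby("chrom")}
    for row in feats.itertuples():
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        pos0 = sub["pos"].to_numpy() - 1
        length = row.end - row.start
        if row.strand == "-":
            # measure from the downstream (right) end, running leftwards
            offsets = (row.end - 1 + FLANK_BP) - pos0
        else:
            offsets = pos0 - (row.start - FLANK_BP)
        bins = _assign_bins(offsets, length)
        keep = bins >= 0
        if not keep.any():
            continue
        c = np.bincount(bins[keep], weights=sub["c_count"].to_numpy()[keep],
                        minlength=3 * N_BODY_BINS)
        t = np.bincount(bins[keep], weights=sub["t_count"].to_numpy()[keep],
                        minlength=3 * N_BODY_BINS)
        c_bins += c
        t_bins += t
        if per_feature_mean:
            tot = c + t
            with np.errstate(invalid="ignore", divide="ignore"):
                per_feat_levels.append(np.where(tot > 0, c / np.where(tot > 0, tot, 1), np.nan))

    total = c_bins + t_bins
    if per_feature_mean:
        stack = np.vstack(per_feat_levels) if per_feat_levels else np.full((1, 60), np.nan)
        levels = np.nanmean(stack, axis=0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            levels = np.where(total > 0, c_bins / np.where(total > 0, total, 1), np.nan)
    return MethylationProfile(context=context, group=group, levels=levels,
                              c_counts=c_bins, total_reads=total,
                              n_features=len(feats))


def genic_region_levels(count_table: pd.DataFrame, genes: pd.DataFrame,
                        chrom_sizes: dict[str, int] | None = None,
                        flank: int = FLANK_BP) -> pd.DataFrame:
    """Per-gene weighted levels for promoter / body / downstream per context.

    Promoter is the strand-aware ``flank`` bp upstream of the TSS, downstream
    the same past the TES. Flanks are truncated at chromosome bounds and
    flagged in the ``truncated`` column. Undefined levels are NaN.
    Returns tidy rows: gene_id, region, context, weighted_level,
    covered_sites, total_reads, truncated.
    """
    by_chrom = {chrom: sub.sort_values("pos")
                for chrom, sub in count_table.groupby("chrom")}
    rows = []
    for g in genes.itertuples():
        if g.strand == "+":
            regions = {"promoter": (g.start - flank, g.start),
                       "body": (g.start, g.end),
                       "downstream": (g.end, g.end + flank)}
        else:
            regions = {"promoter": (g.end, g.end + flank),
                       "body": (g.start, g.end),
                       "downstream": (g.start - flank, g.start)}
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        sub = by_chrom.get(g.chrom)
        for region, (s, e) in regions.items():
            truncated = s < 0 or (size is not None and e > size)
            s2 = max(s, 0)
            e2 = min(e, size) if size is not None else e
            if sub is not None:
                pos0 = sub["pos"].to_numpy() - 1
                lo, hi = np.searchsorted(pos0, [s2, e2])
                window = sub.iloc[lo:hi]
            else:
                window = None
            for ctx in CONTEXTS:
                if window is not None:
                    w = window.loc[window["context"] == ctx]
                    c, t = int(w["c_count"].sum()), int(w["t_count"].sum())
                    covered = int(((w["c_count"] + w["t_count"]) > 0).sum())
                else:
                    c = t = covered = 0
                tot = c + t
                rows.append(dict(
                    gene_id=g.id, region=region, context=ctx,
                    weighted_level=c / tot if tot else np.nan,
                    covered_sites=covered, total_reads=tot,
                    truncated=truncated))
    return pd.DataFrame(rows)


def group_genes_by_expression(expression: pd.DataFrame,
                              scheme: str = "five_group") -> pd.DataFrame:
    """Label genes by expression stratum.

    ``five_group``: group 1 holds genes with FPKM below 0.5; the remaining
    genes, rank-ordered by FPKM (ties broken by gene id for determinism),
    are split into four near-equal groups, group 5 the highest expressed.
    ``thirds``: tertiles labelled low/mid/high.
    Returns the table with an added ``group`` column.
    """
    if expression.empty:
        raise ValueError("expression table is empty")
    if (expression["fpkm"] < 0).any():
        raise ValueError("FPKM values must be non-negative")
    out = expression.copy()
    if scheme == "five_group":
        out["group"] = 0
        low = out["fpkm"] < 0.5
        out.loc[low, "group"] = 1
        rest = out.loc[~low].sort_values(["fpkm", "gene_id"], kind="stable")
        if rest.empty:
            logger.warning("all genes have FPKM < 0.5; groups 2-5 are empty")
        else:
            chunks = np.array_split(rest.index.to_numpy(), 4)
            for k, idx in enumerate(chunks, start=2):
                out.loc[idx, "group"] = k
        out["group"] = out["group"].astype(int)
    elif scheme == "thirds":
        ranked = out.sort_values(["fpkm", "gene_id"], kind="stable")
        chunks = np.array_split(ranked.index.to_numpy(), 3)
        labels = ["low", "mid", "high"]
        out["group"] = ""
        for lab, idx in zip(labels, chunks):
            out.loc[idx, "group"] = lab
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return out


def stratified_metaplot(count_table: pd.DataFrame, genes: pd.DataFrame,
                        groups: pd.DataFrame, context: str,
                        ) -> dict[object, MethylationProfile]:
    """One metaplot per expression group (ordered group 1 -> 5 or
    low/mid/high); empty groups are omitted with a warning."""
    order = sorted(groups["group"].unique(),
                   key=lambda v: (isinstance(v, str), v))
    out = {}
    for grp in order:
        ids = set(groups.loc[groups["group"] == grp, "gene_id"])
        feats = genes.loc[genes["id"].isin(ids)]
        if feats.empty:
            logger.warning("expression group %r is empty; profile omitted", grp)
            continue
        out[grp] = feature_metaplot(count_table, feats, context,
                                    group=str(grp))
    return out


@dataclass(frozen=True)
class StrataComparison:
    p_value: float
    statistic: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float


def compare_strata(levels_a, levels_b) -> StrataComparison:
    """Two-sided Mann–Whitney rank test between two sets of per-gene levels.

    NaNs (undefined levels) are dropped; each stratum needs at least 3
    defined values. When every value in both strata is identical the test is
    degenerate and p is reported as 1.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each stratum needs >= 3 defined values")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return StrataComparison(1.0, len(a) * len(b) / 2.0, len(a), len(b),
                                float(np.median(a)), float(np.median(b)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return StrataComparison(float(res.pvalue), float(res.statistic),
                            len(a), len(b),
                            float(np.median(a)), float(np.median(b)))


def classify_te_associated(genes: pd.DataFrame, tes: pd.DataFrame,
                           flank: int = FLANK_BP
                           ) -> tuple[pd.DataFrame, float]:
    """Flag genes whose flank-extended interval intersects any TE.

    A gene is TE-associated iff [start - flank, end + flank) intersects at
    least one TE interval (half-open, strand-ignored); the gene body is
    inside that window, so body overlaps count. Returns (per-gene table
    with ``te_associated`` boolean, genome-wide associated proportion).
    """
    trees: dict[str, IntervalTree] = {}
    for te in tes.itertuples():
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end)
    labels = []
    for g in genes.itertuples():
        tree = trees.get(g.chrom)
        hit = bool(tree.overlap(g.start - flank, g.end + flank)) if tree else False
        labels.append(hit)
    out = genes[["id", "chrom", "start", "end"]].copy()
    out["te_associated"] = labels
    proportion = float(np.mean(labels)) if labels else float("nan")
    return out, proportion
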