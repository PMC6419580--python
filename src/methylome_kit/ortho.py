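"""Cross-species ortholog-pair methylation comparison.

Given a list of ortholog pairs (genes from collinear blocks of two species)
and per-gene gene-body methylation levels in each species, compares the two
species' level distributions per context (two-sided Mann–Whitney), measures
the across-pair correlation (whether orthologs retain similar methylation),
and contrasts the TE-associated gene proportions between species with a
two-proportion chi-square test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CONTEXTS
from .features import classify_te_associated

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologComparison:
    context: str
    n_pairs: int
    mannwhitney_p: float
    correlation: float
    median_a: float
    median_b: float
    scatter: pd.DataFrame = field(repr=False)  # level_A, level_B per pair


def _gene_levels(levels: pd.DataFrame, region: str, context: str) -> pd.Series:
    sub = levels.loc[(levels["region"] == region)
                     & (levels["context"] == context)]
    return sub.set_index("gene_id")["weighted_level"]


def ortholog_methylation_compare(pairs: pd.DataFrame,
                                 levels_a: pd.DataFrame,
                                 levels_b: pd.DataFrame,
                                 region: str = "body",
                                 method: str = "pearson",
                                 ) -> dict[str, OrthologComparison]:
    """Per-context comparison of ortholog methylation between two species.

    ``levels_a``/``levels_b`` are per-gene region tables (the output of
    :func:`methylome_kit.features.genic_region_levels`). Pairs whose ids do
    not resolve, or whose level is undefined in either species, are excluded
    with a log message; fewer than 10 usable pairs is an error.
    """
    out = {}
    for ctx in CONTEXTS:
        la = _gene_levels(levels_a, region, ctx)
        lb = _gene_levels(levels_b, region, ctx)
        a = pairs["gene_A"].map(la)
        b = pairs["gene_B"].map(lb)
        ok = a.notna() & b.notna()
        n_drop = int((~ok).sum())
        if n_drop:
            logger.warning("%s: %d pairs excluded (unresolved id or "
                           "undefined level)", ctx, n_drop)
        a, b = a[ok].to_numpy(), b[ok].to_numpy()
        if len(a) < 10:
            raise ValueError(f"only {len(a)} usable pairs for {ctx} (need >= 10)")
        if np.array_equal(a, b) or (np.all(a == a[0]) and np.all(b == a[0])):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        if np.array_equal(a, b):
            r = 1.0
        elif method == "pearson":
            r = float(stats.pearsonr(a, b).statistic)
        else:
            r = float(stats.spearmanr(a, b).statistic)
        out[ctx] = OrthologComparison(
            context=ctx, n_pairs=len(a), mannwhitney_p=p, correlation=r,
            median_a=float(np.median(a)), median_b=float(np.median(b)),
            scatter=pd.DataFrame({"gene_A": pairs.loc[ok, "gene_A"].to_numpy(),
                                  "gene_B": pairs.loc[ok, "gene_B"].to_numpy(),
                                  "level_A": a, "level_B": b}))
    return out


@dataclass(frozen=True)
class TEAssociationContrast:
    proportion_a: float
    proportion_b: float
    n_pairs: int
    difference: float
    chi2_p: float  # two-proportion test (extension; not part of the classic figure)


def te_association_contrast(genes_a: pd.DataFrame, tes_a: pd.DataFrame,
                            genes_b: pd.DataFrame, tes_b: pd.DataFrame,
                            pairs: pd.DataFrame,
                            flank: int = 2000) -> TEAssociationContrast:
    """TE-associated proportions among paired genes in each species.

    Classification follows :func:`classify_te_associated` (body + 2-kb
    flanks). The species difference gets a chi-square test with continuity
    correction; with no associated genes anywhere the test is degenerate
    and p is 1.
    """
    assoc_a, _ = classify_te_associated(genes_a, tes_a, flank=flank)
    assoc_b, _ = classify_te_associated(genes_b, tes_b, flank=flank)
    map_a = assoc_a.set_index("id")["te_associated"]
    map_b = assoc_b.set_index("id")["te_associated"]
    flag_a = pairs["gene_A"].map(map_a).dropna().astype(bool)
    flag_b = pairs["gene_B"].map(map_b).dropna().astype(bool)
    pa = float(flag_a.mean()) if len(flag_a) else float("nan")
    pb = float(flag_b.mean()) if len(flag_b) else float("nan")
    table = np.array([[flag_a.sum(), (~flag_a).sum()],
                      [flag_b.sum(), (~flag_b).sum()]])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        p = 1.0  # degenerate: identical proportions by construction
    else:
        p = float(stats.chi2_contingency(table, correction=True).pvalue)
    return TEAssociationContrast(proportion_a=pa, proportion_b=pb,
                                 n_pairs=min(len(flag_a), len(flag_b)),
                                 difference=pa - pb, chi2_p=p)
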