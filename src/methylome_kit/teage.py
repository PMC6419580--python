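"""Transposable-element dating via the Kimura two-parameter distance.

The divergence of a TE copy from its family consensus is a proxy for its
insertion age: recently inserted copies are near-identical to the consensus
(low distance), ancient ones have accumulated substitutions. The Kimura
two-parameter model corrects separately for transitions (proportion p of
aligned sites: A<->G, C<->T) and transversions (proportion q, all other
mismatches):

    K = -1/2 ln(1 - 2p - q) - 1/4 ln(1 - 2q)

Distances are reported x100 ("substitutions per 100 sites") by default, the
scale on which repeat-landscape burst modes are usually quoted; the raw
scale is available via ``scale100=False``. Alignments outside the formula's
domain (1 - 2p - q <= 0 or 1 - 2q <= 0) are saturated: the distance is
undefined and reported as an explicit error, never clipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CONTEXTS

logger = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = set("ACGT")


class KimuraSaturationError(ValueError):
    """Alignment too diverged for the two-parameter correction."""


@dataclass(frozen=True)
class KimuraEstimate:
    copy_id: str
    family: str
    aligned_sites: int
    p: float  # transition proportion
    q: float  # transversion proportion
    K: float  # Kimura distance (x100 scale unless stated otherwise)


def kimura_distance(p: float, q: float, scale100: bool = True) -> float:
    """Kimura two-parameter distance from transition/transversion proportions.

    Raises :class:`KimuraSaturationError` outside the formula's domain.
    """
    if p < 0 or q < 0 or p + q > 1:
        raise ValueError(f"invalid proportions p={p}, q={q}")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        raise KimuraSaturationError(
            f"alignment saturated (p={p}, q={q}); distance undefined")
    k = -0.5 * math.log(a) - 0.25 * math.log(b)
    return 100.0 * k if scale100 else k


def count_substitutions(copy_alignment: str, consensus_alignment: str
                        ) -> tuple[int, float, float]:
    """Transition/transversion proportions from two aligned sequences.

    Columns with a gap or an ambiguous base on either side are excluded
    from the aligned-site count. Returns ``(aligned_sites, p, q)``.
    """
    if len(copy_alignment) != len(consensus_alignment):
        raise ValueError(
            f"alignment lengths differ: {len(copy_alignment)} vs "
            f"{len(consensus_alignment)}")
    transitions = transversions = aligned = 0
    for x, y in zip(copy_alignment.upper(), consensus_alignment.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        aligned += 1
        if x != y:
            if (x, y) in TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if aligned == 0:
        raise ValueError("zero aligned sites")
    return aligned, transitions / aligned, transversions / aligned


def estimate_from_alignment(copy_id: str, family: str,
                            copy_alignment: str, consensus_alignment: str,
                            scale100: bool = True) -> KimuraEstimate:
    aligned, p, q = count_substitutions(copy_alignment, consensus_alignment)
    return KimuraEstimate(copy_id, family, aligned, p, q,
                          kimura_distance(p, q, scale100=scale100))


def estimates_from_summary(summary: pd.DataFrame, scale100: bool = True
                           ) -> pd.DataFrame:
    """Kimura estimates from a substitution-summary table
    (columns copy_id, family, aligned_sites, transitions, transversions),
    the shape of RepeatMasker alignment summaries. Saturated copies get
    K = NaN with a logged count."""
    out = summary.copy()
    p = out["transitions"] / out["aligned_sites"]
    q = out["transversions"] / out["aligned_sites"]
    k = np.full(len(out), np.nan)
    for i, (pi, qi) in enumerate(zip(p, q)):
        try:
            k[i] = kimura_distance(float(pi), float(qi), scale100=scale100)
        except KimuraSaturationError:
            pass
    n_sat = int(np.isnan(k).sum())
    if n_sat:
        logger.warning("%d saturated TE copies (K undefined); dropped from "
                       "association analyses", n_sat)
    out["p"], out["q"], out["K"] = p, q, k
    return out


def te_methylation_levels(count_table: pd.DataFrame, tes: pd.DataFrame
                          ) -> pd.DataFrame:
    """Weighted level per TE copy per context over the copy's interval.

    Returns tidy rows: copy_id, family, age (if present), context,
    weighted_level, covered_sites, total_reads.
    """
    by_chrom = {chrom: sub.sort_values("pos")
                for chrom, sub in count_table.groupby("chrom")}
    rows = []
    for te in tes.itertuples():
        sub = by_chrom.get(te.chrom)
        for ctx in CONTEXTS:
            c = t = covered = 0
            if sub is not None:
                pos0 = sub["pos"].to_numpy() - 1
                lo, hi = np.searchsorted(pos0, [te.start, te.end])
                w = sub.iloc[lo:hi]
                w = w.loc[w["context"] == ctx]
                c, t = int(w["c_count"].sum()), int(w["t_count"].sum())
                covered = int(((w["c_count"] + w["t_count"]) > 0).sum())
            tot = c + t
            rows.append(dict(
                copy_id=te.id, family=getattr(te, "family", None),
                age=getattr(te, "age", np.nan), context=ctx,
                weighted_level=c / tot if tot else np.nan,
                covered_sites=covered, total_reads=tot))
    return pd.DataFrame(rows)


def age_methylation_association(kimura_table: pd.DataFrame,
                                te_levels: pd.DataFrame,
                                method: str = "pearson",
                                bin_width: float = 5.0) -> pd.DataFrame:
    """Correlate TE age (K) with per-copy methylation level, per context.

    ``kimura_table`` needs copy_id and K; ``te_levels`` is the output of
    :func:`te_methylation_levels`. Copies with undefined K or level are
    dropped; fewer than 10 usable copies in a context is an error. Returns
    one row per context with the correlation, its p-value, n, and per-K-bin
    median levels (for boxplot-style summaries) in ``bin_medians``.
    """
    merged = te_levels.merge(kimura_table[["copy_id", "K"]], on="copy_id")
    rows = []
    for ctx in CONTEXTS:
        sub = merged.loc[(merged["context"] == ctx)].dropna(
            subset=["K", "weighted_level"])
        if len(sub) < 10:
            raise ValueError(
                f"only {len(sub)} TEs with defined K and {ctx} level "
                "(need >= 10)")
        if method == "pearson":
            res = stats.pearsonr(sub["K"], sub["weighted_level"])
        elif method == "spearman":
            res = stats.spearmanr(sub["K"], sub["weighted_level"])
        else:
            raise ValueError(f"unknown method {method!r}")
        bins = (sub["K"] // bin_width) * bin_width
        medians = sub.groupby(bins)["weighted_level"].median().to_dict()
        rows.append(dict(context=ctx, correlation=float(res.statistic),
                         p_value=float(res.pvalue), n=len(sub),
                         bin_medians=medians))
    return pd.DataFrame(rows)


def age_histogram(kimura_table: pd.DataFrame, bin_width: float = 5.0
                  ) -> pd.DataFrame:
    """TE copy counts per Kimura-distance bin, overall and per family.

    Returns columns family ('all' for the pooled histogram), bin_start,
    count. Empty input yields an empty table.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    tbl = kimura_table.dropna(subset=["K"])
    if tbl.empty:
        return pd.DataFrame(columns=["family", "bin_start", "count"])
    bins = (tbl["K"] // bin_width) * bin_width
    rows = []
    overall = bins.value_counts().sort_index()
    for b, n in overall.items():
        rows.append(dict(family="all", bin_start=float(b), count=int(n)))
    if "family" in tbl.columns:
        for fam, sub in tbl.groupby("family"):
            fam_bins = (sub["K"] // bin_width) * bin_width
            for b, n in fam_bins.value_counts().sort_index().items():
                rows.append(dict(family=fam, bin_start=float(b), count=int(n)))
    return pd.DataFrame(rows)


def mutate_copy(consensus: str, n_transitions: int, n_transversions: int,
                rng: np.random.Generator) -> str:
    """Plant an exact number of transitions and transversions into a copy of
    ``consensus`` (distinct random positions) — an integer oracle for
    :func:`count_substitutions`."""
    seq = list(consensus.upper())
    n = len(seq)
    if n_transitions + n_transversions > n:
        raise ValueError("more substitutions than sites")
    sites = rng.choice(n, size=n_transitions + n_transversions, replace=False)
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    for i in sites[:n_transitions]:
        seq[i] = ts_map[seq[i]]
    for i in sites[n_transitions:]:
        seq[i] = tv_map[seq[i]][rng.integers(2)]
    return "".join(seq)
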