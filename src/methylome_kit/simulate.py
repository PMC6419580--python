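"""Synthetic bisulfite-sequencing data with a plant-like methylation landscape.

The generator produces a toy genome, non-overlapping gene and TE annotations,
a long-tailed expression table, and per-cytosine C/T count tables with the
statistical structure the downstream analyses assume:

* TE cytosines are heavily methylated per context (defaults CG 0.82,
  CHG 0.70, CHH 0.10 — the genome-wide averages of a TE-rich asterid leaf
  methylome), decaying multiplicatively with insertion age as
  ``exp(-age_decay_rate * age)``;
* gene-body CG sites carry moderate body methylation; everything else sits
  at a low background;
* TE ages (Kimura distances, x100 "per 100 sites" scale) are drawn from a
  mixture of a uniform background and a burst mode centred near 20,
  emulating a historical transposon proliferation episode;
* observed counts are binomial draws at Poisson coverage around 25x, with a
  small bisulfite conversion failure so unmethylated sites read slightly
  above zero;
* replicates are independent draws from the same true methylome.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contexts import build_context_index

__all__ = [
    "AgeMixture", "SimulationConfig", "PackingError",
    "simulate_genome", "assign_true_methylome", "simulate_counts",
    "simulate_expression", "simulate_ortholog_pairs",
]


class PackingError(ValueError):
    """Requested features cannot be packed into the genome without overlap."""


@dataclass(frozen=True)
class AgeMixture:
    """TE insertion-age distribution: uniform background + Gaussian burst.

    Ages are Kimura distances on the x100 scale; the burst mode near 20
    mirrors a recent transposon proliferation event. Draws outside
    [low, high] are resampled (truncation).
    """

    burst_weight: float = 0.65
    burst_mean: float = 20.0
    burst_sd: float = 5.0
    low: float = 0.0
    high: float = 50.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        from_burst = rng.random(n) < self.burst_weight
        ages = rng.uniform(self.low, self.high, size=n)
        k = int(from_burst.sum())
        burst = rng.normal(self.burst_mean, self.burst_sd, size=k)
        # truncate the burst mode by resampling
        bad = (burst < self.low) | (burst > self.high)
        while bad.any():
            burst[bad] = rng.normal(self.burst_mean, self.burst_sd, size=int(bad.sum()))
            bad = (burst < self.low) | (burst > self.high)
        ages[from_burst] = burst
        return ages


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 400_000          # total bp over all chromosomes
    chromosome_count: int = 2
    gc_fraction: float = 0.4
    gene_count: int = 40
    te_count: int = 60
    gene_length_range: tuple[int, int] = (1000, 3000)
    te_length_range: tuple[int, int] = (500, 2000)
    mean_coverage: float = 25.0           # reads per cytosine (Poisson mean)
    conversion_failure: float = 0.005     # unmethylated C read as C
    context_levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.82, "CHG": 0.70, "CHH": 0.10})
    gene_body_cg_level: float = 0.6
    background_level: float = 0.02
    age_decay_rate: float = 0.02          # per Kimura unit (x100 scale)
    te_age_distribution: AgeMixture = field(default_factory=AgeMixture)

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "conversion_failure",
                     "gene_body_cg_level", "background_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for ctx, v in self.context_levels.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"context_levels[{ctx}]={v} outside [0, 1]")
        if self.genome_length <= 0 or self.chromosome_count <= 0:
            raise ValueError("genome_length and chromosome_count must be positive")
        if self.gene_count < 0 or self.te_count < 0:
            raise ValueError("feature counts must be non-negative")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.age_decay_rate < 0:
            raise ValueError("age_decay_rate must be non-negative")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _chromosome_sizes(config: SimulationConfig) -> dict[str, int]:
    n = config.chromosome_count
    base = config.genome_length // n
    sizes = [base] * n
    sizes[-1] += config.genome_length - base * n
    return {f"chr{i + 1}": s for i, s in enumerate(sizes)}


_TE_FAMILIES = ("Gypsy", "Copia", "LINE", "hAT", "Mutator")


def _place_features(sizes: dict[str, int], lengths: np.ndarray,
                    rng: np.random.Generator,
                    occupied: dict[str, list[tuple[int, int]]],
                    max_tries: int = 2000) -> list[tuple[str, int, int]]:
    """Place intervals of the given lengths without overlapping each other
    or anything already in ``occupied`` (per-chromosome interval lists,
    mutated in place). Rejection sampling; raises PackingError on failure."""
    chroms = list(sizes)
    placed = []
    for length in lengths:
        length = int(length)
        ok = False
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            size = sizes[chrom]
            if size < length:
                continue
            start = int(rng.integers(0, size - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                placed.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place a feature of length {length}; "
                "feature demand exceeds genome capacity")
    return placed


def simulate_genome(config: SimulationConfig
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome plus non-overlapping gene/TE annotations.

    Returns ``(genome, features)`` where genome maps chromosome name to
    sequence and features has columns ``id, chrom, start, end`` (0-based
    half-open), ``strand, kind`` (gene|TE), ``family, age`` (TEs only;
    age is a Kimura distance on the x100 scale).
    """
    rng = np.random.default_rng(config.seed)
    sizes = _chromosome_sizes(config)

    demand = (config.gene_count * config.gene_length_range[1]
              + config.te_count * config.te_length_range[1])
    if demand > 0.9 * config.genome_length:
        raise PackingError(
            f"feature demand up to {demand} bp exceeds 90% of the "
            f"{config.genome_length} bp genome")

    p = config.gc_fraction
    probs = [(1 - p) / 2, p / 2, p / 2, (1 - p) / 2]
    genome = {
        chrom: "".join(np.array(list("ACGT"))[
            rng.choice(4, size=size, p=probs)])
        for chrom, size in sizes.items()
    }

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    gene_lengths = rng.integers(config.gene_length_range[0],
                                config.gene_length_range[1] + 1,
                                size=config.gene_count)
    te_lengths = rng.integers(config.te_length_range[0],
                              config.te_length_range[1] + 1,
                              size=config.te_count)
    gene_loc = _place_features(sizes, gene_lengths, rng, occupied)
    te_loc = _place_features(sizes, te_lengths, rng, occupied)

    rows = []
    strands = np.array(["+", "-"])
    for i, (chrom, start, end) in enumerate(gene_loc):
        rows.append(dict(id=f"gene{i + 1:04d}", chrom=chrom, start=start,
                         end=end, strand=strands[rng.integers(2)],
                         kind="gene", family=None, age=np.nan))
    ages = config.te_age_distribution.sample(config.te_count, rng)
    for i, (chrom, start, end) in enumerate(te_loc):
        rows.append(dict(id=f"TE{i + 1:04d}", chrom=chrom, start=start,
                         end=end, strand=strands[rng.integers(2)], kind="TE",
                         family=_TE_FAMILIES[rng.integers(len(_TE_FAMILIES))],
                         age=float(ages[i])))
    features = pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "strand",
                       "kind", "family", "age"])
    return genome, features.sort_values(
        ["chrom", "start"], ignore_index=True)


def assign_true_methylome(genome: dict[str, str], features: pd.DataFrame,
                          config: SimulationConfig,
                          context_index: pd.DataFrame | None = None,
                          ) -> pd.DataFrame:
    """True per-cytosine methylation probability for every cytosine.

    TE cytosines get the configured per-context level scaled by
    ``exp(-age_decay_rate * age)``; gene-body CG sites get
    ``gene_body_cg_level``; all other sites (including AMBIGUOUS-context
    ones) sit at ``background_level``. Returns the context index plus a
    ``true_level`` column.
    """
    if context_index is None:
        context_index = build_context_index(genome)
    truth = context_index.copy()
    truth["true_level"] = config.background_level

    pos0 = truth["pos"].to_numpy() - 1  # 0-based
    for kind in ("gene", "TE"):
        feats = features.loc[features["kind"] == kind]
        for chrom, sub in feats.groupby("chrom"):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            in_chrom = (truth["chrom"] == chrom).to_numpy()
            idx = np.searchsorted(starts, pos0, side="right") - 1
            inside = in_chrom & (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
            if kind == "gene":
                mask = inside & (truth["context"] == "CG").to_numpy()
                truth.loc[mask, "true_level"] = config.gene_body_cg_level
            else:
                ages = sub["age"].to_numpy()
                decay = np.exp(-config.age_decay_rate * ages)
                for ctx, base in config.context_levels.items():
                    mask = inside & (truth["context"] == ctx).to_numpy()
                    truth.loc[mask, "true_level"] = base * decay[idx[mask]]
    assert ((truth["true_level"] >= 0) & (truth["true_level"] <= 1)).all()
    return truth


def simulate_counts(true_methylome: pd.DataFrame, config: SimulationConfig,
                    n_replicates: int = 2) -> list[pd.DataFrame]:
    """Observed C/T count tables: independent replicate draws from one truth.

    Coverage is Poisson around ``mean_coverage``; the methylated-read count
    is binomial with success probability ``m + (1 - m) * conversion_failure``
    so conversion failure inflates the observed level of unmethylated sites.
    """
    tables = []
    m = true_methylome["true_level"].to_numpy()
    p_obs = m + (1.0 - m) * config.conversion_failure
    for rep in range(n_replicates):
        rng = np.random.default_rng([config.seed, 7919, rep])
        cov = rng.poisson(config.mean_coverage, size=len(true_methylome))
        c = rng.binomial(cov, p_obs)
        tbl = true_methylome[["chrom", "pos", "strand", "context"]].copy()
        tbl["c_count"] = c
        tbl["t_count"] = cov - c
        tables.append(tbl)
    return tables


def invert_kimura(k_raw: float, ts_tv_ratio: float = 2.0) -> tuple[float, float]:
    """Transition/transversion proportions (p, q) whose Kimura two-parameter
    distance equals ``k_raw`` (raw scale), holding p/q at ``ts_tv_ratio``.

    Solved by bracketed root finding inside the formula's domain.
    """
    from scipy.optimize import brentq

    if k_raw < 0:
        raise ValueError("distance must be non-negative")
    if k_raw == 0:
        return 0.0, 0.0
    r = ts_tv_ratio

    def f(p: float) -> float:
        q = p / r
        return (-0.5 * math.log(1 - 2 * p - q)
                - 0.25 * math.log(1 - 2 * q)) - k_raw

    upper = (1.0 / (2.0 + 1.0 / r)) * (1 - 1e-12)
    p = brentq(f, 0.0, upper)
    return float(p), float(p / r)


def simulate_te_alignment_summary(tes: pd.DataFrame, config: SimulationConfig,
                                  alignment_length: int = 1000,
                                  ts_tv_ratio: float = 2.0) -> pd.DataFrame:
    """Substitution summaries for TE copies consistent with their true ages.

    For each TE copy the true Kimura age (x100 scale) is inverted into
    (p, q) at the given transition/transversion ratio, and integer
    substitution counts are planted into an alignment of
    ``alignment_length`` sites. Returns columns copy_id, family,
    aligned_sites, transitions, transversions — the precomputed-summary
    shape consumed by the TE-dating module. Rounding to integer counts
    makes the recovered K exact to ~1/alignment_length.
    """
    rows = []
    for te in tes.itertuples():
        p, q = invert_kimura(te.age / 100.0, ts_tv_ratio)
        rows.append(dict(copy_id=te.id, family=te.family,
                         aligned_sites=alignment_length,
                         transitions=int(round(p * alignment_length)),
                         transversions=int(round(q * alignment_length))))
    return pd.DataFrame(rows, columns=["copy_id", "family", "aligned_sites",
                                       "transitions", "transversions"])


def simulate_expression(features: pd.DataFrame, config: SimulationConfig,
                        zero_fraction: float = 0.2,
                        lognorm_mean: float = 1.0,
                        lognorm_sigma: float = 1.5) -> pd.DataFrame:
    """Long-tailed FPKM table for the simulated genes.

    A ``zero_fraction`` of genes is silent (FPKM 0, landing in the first
    expression group); the rest draw from a log-normal, giving the heavy
    right tail typical of RNA-seq FPKM distributions.
    """
    genes = features.loc[features["kind"] == "gene", "id"]
    rng = np.random.default_rng([config.seed, 104729])
    fpkm = rng.lognormal(lognorm_mean, lognorm_sigma, size=len(genes))
    fpkm[rng.random(len(genes)) < zero_fraction] = 0.0
    return pd.DataFrame({"gene_id": genes.to_numpy(), "fpkm": fpkm})


def simulate_ortholog_pairs(features_a: pd.DataFrame,
                            features_b: pd.DataFrame) -> pd.DataFrame:
    """Pair the i-th gene of species A with the i-th gene of species B,
    emulating an ortholog list extracted from collinear blocks."""
    ga = features_a.loc[features_a["kind"] == "gene", "id"].to_numpy()
    gb = features_b.loc[features_b["kind"] == "gene", "id"].to_numpy()
    n = min(len(ga), len(gb))
    return pd.DataFrame({"gene_A": ga[:n], "gene_B": gb[:n]})
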