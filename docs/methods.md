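# Methods

## Scope and data model

methylome-kit operates strictly downstream of read alignment: its inputs
are per-cytosine C/T count tables (columns `chrom, pos, strand, context,
c_count, t_count`, 1-based positions — the shape of BSMAP-methratio
output), genome FASTA, gene annotations (GFF3), TE annotations (BED6 with
`id|family:age` names), an FPKM expression table, an ortholog-pair list,
and TE substitution summaries (`copy_id, family, aligned_sites,
transitions, transversions`, the shape of RepeatMasker alignment
summaries). Feature intervals are 0-based half-open in memory and converted
at the GFF/BED boundaries.

## Context classification

A cytosine's context is decided by the bases 3′ of it on its own strand:
CG if the next base is G; else CHG if the base after next is G; else CHH
when both are in {A,C,T}; AMBIGUOUS when the needed bases run off the
chromosome end or are not plain A/C/G/T. AMBIGUOUS sites are excluded from
every statistic. Soft-masked (lower-case) bases classify normally. The
CG-before-CHG priority is the field convention; one consequence worth
knowing is that CCG trinucleotides are CHG on their own strand while their
strand partner (a CGG) is labelled CG, so exact cross-strand CHG pairing
holds only for the palindromic CAG/CTG subset. All CHG subtypes are
otherwise treated identically (no CCG special-casing).

## Weighted levels and derived summaries

The unit statistic is the weighted methylation level Σ#C/Σ(#C+#T) over a
site set; zero-read sets are undefined and propagate as NaN with explicit
`covered_sites`/`total_reads` bookkeeping — undefined never silently
becomes 0, and pooling two regions always pools their reads rather than
averaging their levels.

Derived summaries and their defaults:

* **Windows** — non-overlapping tiles, default 2000 bp, per context.
* **Replicate correlation** — Pearson (Spearman by flag) over windows where
  both replicates are defined (complete-case); <3 joint windows is an
  error.
* **Strand symmetry** — plus/minus site-level correlation over CG (+1) or
  CHG (+2) dyads with ≥4 reads on both strands (CHH is asymmetric and
  rejected). The 4-read floor keeps per-site fractions from being dominated
  by 1–2 read noise; the coverage-reporting threshold of "≥1 read" is a
  different quantity.
* **mC composition** — a covered site is called methylated when its
  fraction ≥ 0.5 at ≥4 reads (a fixed-threshold rule; a binomial test
  against conversion failure would need a per-library failure estimate the
  inputs do not carry), and composition is the per-context share of all
  called mC.
* **Replicate pooling** — counts are summed per site; per-replicate modes
  just skip the pooling step.

## Feature analyses

Metaplots use 20 proportional body bins (bin *k* = offsets
[⌊kL/20⌋,⌊(k+1)L/20⌋), tiling the body exactly) plus 20 fixed 100-bp bins
per 2-kb flank, oriented by feature strand; sites on both strands
contribute; features shorter than 20 bp are excluded with a log message.
Bin levels pool reads across features (weighted-level semantics); a
per-feature-mean mode exists for comparison. Note the proportional floor
edges make an exact profile mirror under strand reversal hold when the body
length is a multiple of 20; otherwise bin boundaries may shift by 1 bp.

Genic regions are promoter (2 kb upstream of the TSS, strand-aware), body,
and downstream (2 kb past the TES); flanks truncate at chromosome edges and
are flagged. No exclusion is applied when a promoter window overlaps a
neighbouring gene.

Expression stratification: five-group (group 1 = FPKM<0.5, remainder
rank-split into four groups differing by ≤1 in size, ties broken by gene id
for determinism) and thirds. Strata are compared by two-sided Mann–Whitney;
when every value in both strata is identical the variance of the rank
statistic is zero and p is reported as 1 rather than NaN.

TE association: a gene is TE-associated iff [start−flank, end+flank)
intersects any TE (half-open, strand-ignored, flank default 2000 bp); the
body lies inside the window, so body overlaps count. The classification is
monotone in the flank by construction.

## TE dating

K2P distance K = −½ln(1−2p−q) − ¼ln(1−2q) from transition/transversion
proportions of gap- and N-free alignment columns, reported ×100
("per 100 sites") so burst modes land on the customary scale (raw scale by
flag). Outside the domain (1−2p−q ≤ 0 or 1−2q ≤ 0) the distance is
saturated: an explicit error per copy, NaN in tables, and a logged count —
never clipped to a maximum. No CpG-adjusted divergence is applied. Per-copy
methylation is the weighted level over the copy's genomic interval;
the age–methylation association reports per-context Pearson (Spearman by
flag) correlation over copies with defined K and level (≥10 required) plus
per-5-K-bin median levels for boxplot-style summaries.

## Ortholog comparison

Pairs are consumed as a two-column list (collinearity detection is out of
scope). The default compared quantity is the gene-body level (region
selectable); per context the two species' distributions get a two-sided
Mann–Whitney test and the across-pair Pearson correlation. The
TE-association contrast adds a chi-square test with continuity correction
on the 2×2 associated/not table — an extension beyond the classic pie-chart
presentation, labelled as such in the API docs.

## Synthetic data generator

The generator emulates the statistical structure these analyses assume:

* **Genome** — i.i.d. bases at a configurable GC fraction (default 0.40),
  default 400 kb over 2 chromosomes (large enough for ≥50 kb of TE sequence
  and stable window statistics while keeping test runtimes in seconds).
* **Features** — 40 genes (1–3 kb) and 60 TEs (0.5–2 kb) placed uniformly
  without overlap by rejection sampling; infeasible packing raises an
  explicit error. TE families are labels only.
* **True methylome** — TE cytosines get per-context levels (defaults CG
  0.82, CHG 0.70, CHH 0.10 — the genome-wide averages of a TE-rich asterid
  leaf methylome) scaled by exp(−λ·age) with λ = 0.02 per Kimura unit;
  gene-body CG sites get 0.6; everything else 0.02.
* **TE ages** — mixture of a uniform background on [0,50] (weight 0.35) and
  a truncated Normal(20, 5) burst mode (weight 0.65), reproducing a
  burst-dominated repeat landscape.
* **Counts** — coverage ~ Poisson(25) per site (the simplest
  overdispersion-free choice), methylated reads ~ Binomial(cov,
  m + (1−m)·ε) with conversion failure ε = 0.005, so unmethylated sites
  converge to ε, not 0, unless corrected. Replicates are independent draws
  from one truth.
* **Expression** — 20% silent genes, the rest log-normal(1, 1.5): a heavy
  right tail with a group-1-sized low mode.
* **TE alignments** — each copy's true age is inverted through the K2P
  formula at a 2:1 transition:transversion ratio and planted as integer
  substitution counts in a 1000-site alignment, so estimated K matches the
  true age to ~0.1 K units.

All outputs are bit-reproducible for a fixed seed (numpy `default_rng`
seeded per stage and replicate).

**What passing tests show — and what they do not.** The generator has
independent sites, uniform coverage, no mappability or GC bias, no
batch/batch-replicate structure, no read-level errors or PCR duplicates,
and its expression is independent of methylation. Recovery tests therefore
validate the estimators' correctness and calibration under the stated
model, not robustness to real-library artefacts; conclusions about real
data still require the usual QC.

## Numerical and design notes

* Parameter-recovery checks (TE levels within ±0.01 of the configured
  0.82/0.70/0.10) run with λ = 0 so the configured levels are the TE-wide
  truth; the default keeps λ = 0.02 so age analyses have signal. The
  residual bias from uncorrected conversion failure, (1−m)·ε ≤ 0.005, sits
  inside that band by design.
* Pipeline problem sizes (400 kb main genome, 500 small TEs for the dating
  study, 200 ortholog pairs across two 700-kb species) are scaled-down
  study designs chosen so every stage completes in seconds while leaving
  sampling error well below the effects being measured.
* Correlations use pairwise-complete observations; undefined levels are
  never imputed.
* The pipeline manifest stores sha256 checksums of all emitted files and no
  timestamps, so determinism can be asserted at the byte level.

## Known limitations

No DMR calling, smoothing, or beta-binomial modelling; no conversion-rate
estimation from unmethylated controls; no sub-context (CAG/CTG/CCG, CHH
subtype) decomposition; TE discovery, consensus building and collinearity
detection are consumed as inputs, not performed.
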