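"""End-to-end pipeline orchestration and reporting.

Runs the full post-alignment analysis stack — context extraction, weighted
levels, replicate correlation, strand symmetry, mC composition, metaplots,
expression stratification, TE association, TE dating and the two-species
ortholog comparison — either on user-supplied files or on a self-contained
synthetic dataset, and writes a run manifest (paths + sha256 checksums +
config snapshot) plus a Markdown report. Re-running with the same seed and
inputs reproduces every numeric output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, features as feat, io, ortho, simulate as sim, teage
from .contexts import CONTEXTS, build_context_index

logger = logging.getLogger(__name__)

ALL_STAGES = ("contexts", "methlevels", "repcor", "symmetry", "composition",
              "metaplot", "stratify", "teassoc", "teage", "orthocompare")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    seed: int
    config: dict
    inputs: dict[str, dict] = field(default_factory=dict)   # path + sha256
    outputs: dict[str, list[str]] = field(default_factory=dict)  # stage -> paths
    warnings: list[str] = field(default_factory=list)
    success: bool = False

    def add_output(self, stage: str, path: Path) -> None:
        self.outputs.setdefault(stage, []).append(str(path))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fmt(x: float) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.4f}"


def run_pipeline(outdir: str | Path, seed: int = 0,
                 config: sim.SimulationConfig | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> RunManifest:
    """Run the synthetic end-to-end pipeline into ``outdir``.

    Generates the dataset (genome, annotations, two count replicates,
    expression, TE alignment summaries, a second 'species' for the ortholog
    comparison), runs the requested stages in order, and writes
    ``manifest.json`` and ``report.md``. Any stage failure raises
    :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or sim.SimulationConfig(seed=seed)
    if config.seed != seed:
        config = config.with_(seed=seed)
    manifest = RunManifest(seed=seed, config={
        k: (dict(v) if isinstance(v, dict) else str(v))
        for k, v in config.__dict__.items()})
    report: list[str] = ["# methylome-kit run report", ""]

    # ---- simulate the dataset -------------------------------------------
    genome, featset = sim.simulate_genome(config)
    truth = sim.assign_true_methylome(genome, featset, config)
    rep1, rep2 = sim.simulate_counts(truth, config, n_replicates=2)
    expr = sim.simulate_expression(featset, config)
    genes = featset.loc[featset["kind"] == "gene"].reset_index(drop=True)
    tes = featset.loc[featset["kind"] == "TE"].reset_index(drop=True)

    io.write_fasta(genome, outdir / "genome.fa")
    io.write_gene_gff3(genes, outdir / "genes.gff3")
    io.write_te_bed(tes, outdir / "tes.bed")
    io.write_counts(rep1, outdir / "counts_rep1.tsv")
    io.write_counts(rep2, outdir / "counts_rep2.tsv")
    io.write_expression(expr, outdir / "expression.tsv")
    io.write_config(config, outdir / "config.txt")
    for name in ("genome.fa", "genes.gff3", "tes.bed", "counts_rep1.tsv",
                 "counts_rep2.tsv", "expression.tsv", "config.txt"):
        p = outdir / name
        manifest.inputs[name] = {"path": str(p), "sha256": _sha256(p)}
        manifest.add_output("simulate", p)
    pooled = core.pool_replicates(rep1, rep2)

    ctx_index = None
    genic = None

    def _need(stage: str, condition: bool, what: str) -> None:
        if not condition:
            raise StageError(stage, f"missing prerequisite: {what}")

    current_stage = "simulate"
    try:
        if "contexts" in stages:
            current_stage = "contexts"
            ctx_index = build_context_index(genome)
            counts = ctx_index["context"].value_counts()
            path = outdir / "context_counts.tsv"
            counts.rename_axis("context").rename("sites").to_csv(path, sep="\t")
            manifest.add_output("contexts", path)
            report += ["## contexts",
                       "Cytosine sites per context (both strands):", ""]
            report += [f"- {ctx}: {int(counts.get(ctx, 0))}"
                       for ctx in (*CONTEXTS, "AMBIGUOUS")] + [""]

        if "methlevels" in stages:
            current_stage = "methlevels"
            levels = core.genome_wide_levels(pooled, ctx_index)
            path = outdir / "genome_levels.tsv"
            pd.DataFrame([
                dict(context=c, weighted_level=l.weighted_level,
                     covered_sites=l.covered_sites, total_reads=l.total_reads)
                for c, l in levels.items()]).to_csv(path, sep="\t", index=False)
            manifest.add_output("methlevels", path)
            report += ["## methlevels",
                       "Genome-wide weighted methylation (replicates pooled):", ""]
            report += [f"- {c}: {_fmt(l.weighted_level)}"
                       for c, l in levels.items()] + [""]

        if "repcor" in stages:
            current_stage = "repcor"
            rc = core.replicate_correlation(rep1, rep2, window_size=2000)
            path = outdir / "replicate_correlation.tsv"
            pd.Series(rc, name="pearson_r").rename_axis("context").to_csv(
                path, sep="\t")
            manifest.add_output("repcor", path)
            report += ["## repcor",
                       "Replicate Pearson r over 2 kb windows:", ""]
            report += [f"- {c}: {_fmt(r)}" for c, r in rc.items()] + [""]

        if "symmetry" in stages:
            current_stage = "symmetry"
            rows = []
            for ctx in ("CG", "CHG"):
                r, dyads = core.strand_symmetry(pooled, ctx_index, ctx)
                rows.append(dict(context=ctx, pearson_r=r, dyads=len(dyads)))
            path = outdir / "strand_symmetry.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            manifest.add_output("symmetry", path)
            report += ["## symmetry", "Strand-symmetry Pearson r:", ""]
            report += [f"- {row['context']}: {_fmt(row['pearson_r'])} "
                       f"({row['dyads']} dyads)" for row in rows] + [""]

        if "composition" in stages:
            current_stage = "composition"
            comp = core.methylcytosine_composition(pooled, ctx_index)
            path = outdir / "mc_composition.tsv"
            pd.Series(comp, name="fraction").rename_axis("context").to_csv(
                path, sep="\t")
            manifest.add_output("composition", path)
            report += ["## composition", "Called mC composition:", ""]
            report += [f"- {c}: {_fmt(v)}" for c, v in comp.items()] + [""]

        if "metaplot" in stages:
            current_stage = "metaplot"
            frames = []
            for kind, fs in (("gene", genes), ("TE", tes)):
                for ctx in CONTEXTS:
                    prof = feat.feature_metaplot(pooled, fs, ctx, group=kind)
                    frames.append(pd.DataFrame(
                        {"feature_kind": kind, "context": ctx,
                         "bin": np.arange(60), "weighted_level": prof.levels}))
            path = outdir / "metaplots.tsv"
            pd.concat(frames, ignore_index=True).to_csv(path, sep="\t",
                                                        index=False)
            manifest.add_output("metaplot", path)
            report += ["## metaplot",
                       "Gene and TE metaplots (60 bins) written to "
                       "metaplots.tsv", ""]

        if "stratify" in stages:
            current_stage = "stratify"
            _need("stratify", expr is not None, "expression table")
            groups = feat.group_genes_by_expression(expr, scheme="five_group")
            profs = feat.stratified_metaplot(pooled, genes, groups, "CG")
            frames = [pd.DataFrame({"group": g, "bin": np.arange(60),
                                    "weighted_level": p.levels})
                      for g, p in profs.items()]
            path = outdir / "stratified_metaplot_CG.tsv"
            pd.concat(frames, ignore_index=True).to_csv(path, sep="\t",
                                                        index=False)
            manifest.add_output("stratify", path)
            genic = feat.genic_region_levels(pooled, genes)
            gpath = outdir / "genic_region_levels.tsv"
            genic.to_csv(gpath, sep="\t", index=False)
            manifest.add_output("stratify", gpath)
            thirds = feat.group_genes_by_expression(expr, scheme="thirds")
            body = genic.loc[(genic["region"] == "body")
                             & (genic["context"] == "CG")]
            lows = body.loc[body["gene_id"].isin(
                thirds.loc[thirds["group"] == "low", "gene_id"]),
                "weighted_level"]
            highs = body.loc[body["gene_id"].isin(
                thirds.loc[thirds["group"] == "high", "gene_id"]),
                "weighted_level"]
            cmp_res = feat.compare_strata(lows, highs)
            report += ["## stratify",
                       f"Five-group sizes: "
                       f"{groups['group'].value_counts().sort_index().to_dict()}",
                       f"Body CG low- vs high-expression thirds: "
                       f"Mann-Whitney p = {cmp_res.p_value:.3g} "
                       f"(medians {_fmt(cmp_res.median_a)} vs "
                       f"{_fmt(cmp_res.median_b)})", ""]

        if "teassoc" in stages:
            current_stage = "teassoc"
            assoc, prop = feat.classify_te_associated(genes, tes)
            path = outdir / "te_associated_genes.tsv"
            assoc.to_csv(path, sep="\t", index=False)
            manifest.add_output("teassoc", path)
            report += ["## teassoc",
                       f"TE-associated gene proportion: {_fmt(prop)}", ""]

        if "teage" in stages:
            current_stage = "teage"
            summary = sim.simulate_te_alignment_summary(tes, config)
            kim = teage.estimates_from_summary(summary)
            path = outdir / "kimura_estimates.tsv"
            kim.to_csv(path, sep="\t", index=False)
            manifest.add_output("teage", path)
            te_levels = teage.te_methylation_levels(pooled, tes)
            assoc = teage.age_methylation_association(kim, te_levels)
            apath = outdir / "age_methylation.tsv"
            assoc.drop(columns=["bin_medians"]).to_csv(apath, sep="\t",
                                                       index=False)
            manifest.add_output("teage", apath)
            hist = teage.age_histogram(kim)
            hpath = outdir / "age_histogram.tsv"
            hist.to_csv(hpath, sep="\t", index=False)
            manifest.add_output("teage", hpath)
            report += ["## teage", "K-vs-level correlation per context:", ""]
            report += [f"- {row.context}: r = {_fmt(row.correlation)} "
                       f"(p = {row.p_value:.3g}, n = {row.n})"
                       for row in assoc.itertuples()] + [""]

        if "orthocompare" in stages:
            current_stage = "orthocompare"
            config_b = config.with_(seed=config.seed + 1000)
            genome_b, featset_b = sim.simulate_genome(config_b)
            truth_b = sim.assign_true_methylome(genome_b, featset_b, config_b)
            counts_b = sim.simulate_counts(truth_b, config_b,
                                           n_replicates=1)[0]
            genes_b = featset_b.loc[featset_b["kind"] == "gene"]
            tes_b = featset_b.loc[featset_b["kind"] == "TE"]
            pairs = sim.simulate_ortholog_pairs(featset, featset_b)
            if genic is None:
                genic = feat.genic_region_levels(pooled, genes)
            genic_b = feat.genic_region_levels(counts_b, genes_b)
            comps = ortho.ortholog_methylation_compare(pairs, genic, genic_b)
            path = outdir / "ortholog_comparison.tsv"
            pd.DataFrame([
                dict(context=c.context, n_pairs=c.n_pairs,
                     mannwhitney_p=c.mannwhitney_p, correlation=c.correlation,
                     median_A=c.median_a, median_B=c.median_b)
                for c in comps.values()]).to_csv(path, sep="\t", index=False)
            manifest.add_output("orthocompare", path)
            contrast = ortho.te_association_contrast(genes, tes, genes_b,
                                                     tes_b, pairs)
            report += ["## orthocompare",
                       "Ortholog gene-body comparison (species A vs B):", ""]
            report += [f"- {c.context}: r = {_fmt(c.correlation)}, "
                       f"Mann-Whitney p = {c.mannwhitney_p:.3g}"
                       for c in comps.values()]
            report += [f"TE-associated proportions: "
                       f"A {_fmt(contrast.proportion_a)} vs "
                       f"B {_fmt(contrast.proportion_b)} "
                       f"(chi2 p = {contrast.chi2_p:.3g})", ""]
    except StageError:
        raise
    except Exception as exc:  # surface the failing stage
        raise StageError(current_stage, str(exc)) from exc

    (outdir / "report.md").write_text("\n".join(report))
    manifest.success = True
    for stage, paths in manifest.outputs.items():
        for p in paths:
            assert Path(p).exists(), f"{stage} output missing: {p}"
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
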