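"""Readers and writers for the pipeline's interchange formats.

Genomes travel as FASTA (via Biopython); gene annotations as GFF3 and TE
annotations as BED6 whose name field carries ``family:age``; per-cytosine
counts as TSV with columns chrom, pos (1-based), strand, context, c_count,
t_count; expression as TSV (gene_id, fpkm); ortholog pairs as TSV
(gene_A, gene_B). Feature coordinates are 0-based half-open in memory,
converted at the BED/GFF boundaries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COUNT_COLUMNS = ["chrom", "pos", "strand", "context", "c_count", "t_count"]


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t",
                        dtype={"chrom": str, "pos": np.int64, "strand": str,
                               "context": str, "c_count": np.int64,
                               "t_count": np.int64})
    missing = set(COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"count table {path} lacks columns {sorted(missing)}")
    return table


def write_gene_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Genes as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(f"{g.chrom}\tmethylome-kit\tgene\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\tID={g.id}\n")


def read_gene_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append(dict(id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                             chrom=f[0], start=int(f[3]) - 1, end=int(f[4]),
                             strand=f[6], kind="gene", family=None,
                             age=np.nan))
    return pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "strand", "kind",
                       "family", "age"])


def write_te_bed(tes: pd.DataFrame, path: str | Path) -> None:
    """TEs as BED6 (0-based half-open); name field is 'id|family:age'."""
    with open(path, "w") as fh:
        for te in tes.itertuples():
            age = "" if pd.isna(te.age) else f"{te.age:.6g}"
            name = f"{te.id}|{te.family}:{age}"
            fh.write(f"{te.chrom}\t{te.start}\t{te.end}\t{name}\t0\t{te.strand}\n")


def read_te_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}"
            te_id, _, famage = name.partition("|")
            family, _, age = famage.partition(":")
            rows.append(dict(id=te_id, chrom=f[0], start=int(f[1]),
                             end=int(f[2]),
                             strand=f[5] if len(f) > 5 else "+", kind="TE",
                             family=family or None,
                             age=float(age) if age else np.nan))
    return pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "strand", "kind",
                       "family", "age"])


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr[["gene_id", "fpkm"]].to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "fpkm": float})


def read_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_config(config, path: str | Path) -> None:
    """Flat key=value snapshot of a SimulationConfig."""
    from dataclasses import asdict
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            fh.write(f"{key}={val}\n")
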