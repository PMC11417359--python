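"""On-disk exchange formats: MatrixMarket counts, TSV metadata, FASTA,
BED/GFF-lite annotation.  All intervals are 0-based half-open."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import CellMatrixPair, ToyGenome

__all__ = [
    "write_pair",
    "read_pair",
    "write_genome",
    "read_fasta",
    "read_bed_peaks",
    "read_tss_bed",
    "read_gene_models",
    "load_yaml",
    "dump_yaml",
]


def write_pair(pair: CellMatrixPair, outdir: str | Path) -> None:
    """Counts as sparse MatrixMarket plus TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, M in (("spliced", pair.spliced), ("unspliced", pair.unspliced)):
        scipy.io.mmwrite(str(outdir / f"{name}.mtx"), scipy.sparse.coo_matrix(M))
    pair.cell_meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    pair.gene_meta.to_csv(outdir / "genes.tsv", sep="\t", index=False)


def read_pair(indir: str | Path) -> CellMatrixPair:
    indir = Path(indir)
    spliced = np.asarray(scipy.io.mmread(str(indir / "spliced.mtx")).todense())
    unspliced = np.asarray(scipy.io.mmread(str(indir / "unspliced.mtx")).todense())
    return CellMatrixPair(
        spliced=spliced,
        unspliced=unspliced,
        cell_meta=pd.read_csv(indir / "cells.tsv", sep="\t"),
        gene_meta=pd.read_csv(indir / "genes.tsv", sep="\t"),
    )


def write_genome(genome: ToyGenome, outdir: str | Path) -> None:
    """FASTA contigs, BED6 TSS, GFF-lite gene models, BED peaks, ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, outdir / "contigs.fasta", "fasta")

    tss = genome.tss_records
    bed6 = pd.DataFrame(
        {
            "contig": tss["contig"],
            "start": tss["position"],
            "end": tss["position"] + 1,
            "name": tss["gene_id"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    bed6.to_csv(outdir / "tss.bed", sep="\t", index=False, header=False)
    genome.gene_models[["contig", "feature", "start", "end", "strand", "gene_id"]].to_csv(
        outdir / "gene_models.gff", sep="\t", index=False, header=False
    )
    peaks = genome.peaks.copy()
    peaks.insert(3, "name", [f"peak_{i}" for i in range(len(peaks))])
    peaks.to_csv(outdir / "peaks.bed", sep="\t", index=False, header=False)
    genome.planted_motifs.to_csv(outdir / "planted_motifs.tsv", sep="\t", index=False)
    genome.peak_genes.to_csv(outdir / "peak_genes.tsv", sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, [0, 1, 2, 4]] if df.shape[1] >= 5 else df.iloc[:, :4]
    df.columns = ["contig", "start", "end", "score"]
    return df


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    return pd.DataFrame(
        {
            "gene_id": df[3],
            "contig": df[0],
            "position": df[1],
            "strand": df[5] if df.shape[1] > 5 else "+",
        }
    )


def read_gene_models(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["contig", "feature", "start", "end", "strand", "gene_id"]
    return df[["gene_id", "contig", "start", "end", "strand", "feature"]]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
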