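"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats go through pandas; FASTA and MEME-minimal motif
files go through Biopython. BED and bedGraph are consumed 0-based
half-open as on disk; GTF-lite input (1-based, inclusive) is converted
at this boundary so the rest of the package sees a single convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from .intervals import IntervalSet, SignalTrack
from .tables import ExpressionMatrix, GeneAnnotation, MethylationTable, SampleTable

__all__ = [
    "read_bed", "write_bed", "read_bedgraph", "write_bedgraph",
    "read_sample_sheet", "write_sample_sheet",
    "read_gene_annotation", "read_gtf_lite", "write_gene_annotation",
    "read_methylation", "load_methylation", "write_methylation",
    "read_expression", "write_expression",
    "read_chrom_sizes", "write_chrom_sizes",
    "read_fasta", "write_fasta",
    "read_meme_pwms", "write_meme_pwms",
    "apply_chrom_style",
]


def apply_chrom_style(names: pd.Series, style: str | None) -> pd.Series:
    """Normalize chromosome-name dialects.

    style=None leaves names alone; "chr" ensures a chr prefix; "plain"
    strips one.
    """
    if style is None:
        return names
    if style == "chr":
        return names.where(names.str.startswith("chr"), "chr" + names)
    if style == "plain":
        return names.str.removeprefix("chr")
    raise ValueError(f"unknown chromosome style: {style}")


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path, chrom_style: str | None = None) -> IntervalSet:
    """Read BED3/BED5 (tab-separated, no header; track lines skipped)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            score = float(parts[4]) if len(parts) >= 5 else np.nan
            rows.append((parts[0], int(parts[1]), int(parts[2]), score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if len(df):
        df["chrom"] = apply_chrom_style(df["chrom"], chrom_style)
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path: str | Path, name_prefix: str | None = None) -> None:
    """Write BED3, or BED5 when scores are present or a name prefix is given."""
    df = intervals.df
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            if name_prefix is not None or not pd.isna(row.score):
                name = f"{name_prefix or 'region'}_{i + 1}"
                score = 0 if pd.isna(row.score) else row.score
                score_s = f"{score:g}"
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score_s}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def read_bedgraph(path: str | Path, chrom_style: str | None = None) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        skiprows=_count_track_lines(path),
    )
    df["chrom"] = apply_chrom_style(df["chrom"], chrom_style)
    return SignalTrack(df)


def _count_track_lines(path: str | Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ------------------------------------------------------ sample sheet

def read_sample_sheet(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleTable(df)


def write_sample_sheet(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# -------------------------------------------------- gene annotation

def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """TSV with header gene_id/gene_name/chrom/start/end/strand (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneAnnotation(df)


def write_gene_annotation(genes: GeneAnnotation, path: str | Path) -> None:
    cols = ["gene_id", "gene_name", "chrom", "start", "end", "strand"]
    genes.df[cols].to_csv(path, sep="\t", index=False)


def read_gtf_lite(path: str | Path) -> GeneAnnotation:
    """Minimal GTF reader: 'gene' features with a gene_id attribute.

    GTF coordinates are 1-based inclusive; converted to 0-based
    half-open here.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = {}
            for item in parts[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"gene line without gene_id: {line!r}")
            rows.append((
                gid, attrs.get("gene_name", gid), parts[0],
                int(parts[3]) - 1, int(parts[4]), parts[6],
            ))
    df = pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end", "strand"])
    return GeneAnnotation(df)


# ------------------------------------------------------- methylation

def read_methylation(path: str | Path) -> pd.DataFrame:
    """One sample's CpG table: chrom, pos, beta, coverage (TSV, header)."""
    return pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "pos": np.int64, "beta": float, "coverage": np.int64},
    )


def write_methylation(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "pos", "beta", "coverage"]].to_csv(path, sep="\t", index=False)


def load_methylation(samples: SampleTable, base_dir: str | Path | None = None) -> MethylationTable:
    """Load every WGBS sample referenced by the sample sheet."""
    data = {}
    for row in samples.select(assay="WGBS").itertuples(index=False):
        path = Path(row.path)
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        data[row.sample_id] = read_methylation(path)
    return MethylationTable(data)


# -------------------------------------------------------- expression

def read_expression(path: str | Path, samples: SampleTable) -> ExpressionMatrix:
    """Genes-as-rows, samples-as-columns TSV; labels from the sample sheet."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    rna = samples.select(assay="RNA")
    pops = dict(zip(rna["sample_id"], rna["population"]))
    return ExpressionMatrix(values, pops)


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


# ------------------------------------------------------- chrom sizes

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    return dict(zip(df["chrom"], df["length"]))


def write_chrom_sizes(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


# ------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# --------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Named gene sets: one set per line, name<TAB>description<TAB>genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ----------------------------------------------------- MEME minimal

def read_meme_pwms(path: str | Path):
    """Parse MEME minimal motif format into PWM objects."""
    from .motifs import PWM  # local import to avoid a cycle

    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    pwms = []
    for m in records:
        mat = np.array([[m.pwm[base][i] for base in "ACGT"]
                        for i in range(m.length)])
        bg = np.array([m.background.get(b, 0.25) for b in "ACGT"])
        pwms.append(PWM(m.name or m.id, mat, bg))
    return pwms


def write_meme_pwms(pwms, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.array([0.25] * 4)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(p.matrix)} "
                f"nsites= 1000000 E= 0\n"  # large nsites keeps probabilities exact

            )
            for row in p.matrix:
                fh.write(" {:8.6f} {:8.6f} {:8.6f} {:8.6f}\n".format(*row))
            fh.write("\n")
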