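"""Tabular containers: samples, genes, methylation, expression.

These are thin, validated wrappers around pandas DataFrames; every
per-group computation in the pipeline is driven by the SampleTable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

POPULATIONS = ("pb-NBC", "t-NBC", "GCBC", "MBC", "t-PC", "bm-PC", "MM")
#: normal populations that define the stable-differentiation baseline
BASELINE_POPULATIONS = ("pb-NBC", "t-NBC", "GCBC", "MBC", "t-PC")
ASSAYS = (
    "H3K27ac", "H3K4me1", "H3K4me3", "H3K36me3", "H3K27me3", "H3K9me3",
    "ATAC", "WGBS", "RNA",
)
HISTONE_MARKS = ASSAYS[:6]


class SampleTable:
    """sample_id -> (population, assay, path) mapping.

    (sample_id, assay) pairs must be unique and populations must come
    from the fixed vocabulary. An optional ``signal_path`` column points
    at a per-sample bedGraph track.
    """

    REQUIRED = ("sample_id", "population", "assay", "path")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        df = df.copy()
        if "signal_path" not in df.columns:
            df["signal_path"] = ""
        bad_pop = set(df["population"]) - set(POPULATIONS)
        if bad_pop:
            raise ValueError(f"unknown populations: {sorted(bad_pop)}")
        bad_assay = set(df["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ValueError(f"unknown assays: {sorted(bad_assay)}")
        if df.duplicated(["sample_id", "assay"]).any():
            raise ValueError("(sample_id, assay) pairs must be unique")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def select(self, population: str | Iterable[str] | None = None,
               assay: str | None = None) -> pd.DataFrame:
        sub = self.df
        if population is not None:
            pops = [population] if isinstance(population, str) else list(population)
            sub = sub[sub["population"].isin(pops)]
        if assay is not None:
            sub = sub[sub["assay"] == assay]
        return sub

    def populations(self, assay: str | None = None) -> list[str]:
        sub = self.select(assay=assay)
        return [p for p in POPULATIONS if p in set(sub["population"])]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


class GeneAnnotation:
    """Gene bodies with strand-aware TSS positions."""

    def __init__(self, df: pd.DataFrame):
        req = ["gene_id", "gene_name", "chrom", "start", "end", "strand"]
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise ValueError(f"gene annotation missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        if not set(df["strand"]) <= {"+", "-"}:
            raise ValueError("strand must be + or -")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        self.df = df.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def bodies(self) -> IntervalSet:
        return IntervalSet(self.df.rename(columns={})[["chrom", "start", "end"]])

    def gene(self, gene_id: str) -> Gene:
        row = self.df[self.df["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return Gene(r.gene_id, r.gene_name, r.chrom, int(r.start), int(r.end), r.strand)

    def tss_order(self) -> pd.DataFrame:
        """Genes sorted by (chrom, tss) — adjacency order."""
        return self.df[["gene_id", "chrom", "tss"]]


class MethylationTable:
    """Per-sample CpG beta values keyed by (chrom, pos).

    ``data`` maps sample_id -> DataFrame(chrom, pos, beta, coverage).
    """

    def __init__(self, data: Mapping[str, pd.DataFrame]):
        self.data: dict[str, pd.DataFrame] = {}
        for sample, df in data.items():
            req = ["chrom", "pos", "beta", "coverage"]
            missing = [c for c in req if c not in df.columns]
            if missing:
                raise ValueError(f"{sample}: methylation table missing {missing}")
            if ((df["beta"] < 0) | (df["beta"] > 1)).any():
                raise ValueError(f"{sample}: beta outside [0,1]")
            if df.duplicated(["chrom", "pos"]).any():
                raise ValueError(f"{sample}: duplicate CpG positions")
            self.data[sample] = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        self._index: dict[tuple[str, str], pd.DataFrame] = {}

    @property
    def samples(self) -> list[str]:
        return list(self.data)

    def _chrom_frame(self, sample: str, chrom: str) -> pd.DataFrame:
        key = (sample, chrom)
        if key not in self._index:
            df = self.data[sample]
            self._index[key] = df[df["chrom"] == chrom].reset_index(drop=True)
        return self._index[key]

    def in_window(self, sample: str, chrom: str, start: int, end: int,
                  min_cov: int = 0) -> pd.DataFrame:
        sub = self._chrom_frame(sample, chrom)
        lo = sub["pos"].searchsorted(start, side="left")
        hi = sub["pos"].searchsorted(end, side="left")
        sub = sub.iloc[lo:hi]
        if min_cov:
            sub = sub[sub["coverage"] >= min_cov]
        return sub

    def region_sample_means(self, regions: IntervalSet, samples: Iterable[str],
                            min_cov: int = 0) -> pd.DataFrame:
        """Mean beta per (region, sample); NaN when a region has no CpG."""
        rows = []
        for i, iv in enumerate(regions):
            for s in samples:
                sub = self.in_window(s, iv.chrom, iv.start, iv.end, min_cov)
                rows.append((i, s, sub["beta"].mean() if len(sub) else np.nan))
        return pd.DataFrame(rows, columns=["region_idx", "sample_id", "mean_beta"])


class ExpressionMatrix:
    """Gene x sample matrix of non-negative normalized abundances."""

    def __init__(self, values: pd.DataFrame, populations: Mapping[str, str]):
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in values.columns if s not in populations]
        if missing:
            raise ValueError(f"samples without population label: {missing}")
        self.values = values
        self.populations = {s: populations[s] for s in values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def columns_for(self, population: str | Iterable[str]) -> pd.DataFrame:
        pops = [population] if isinstance(population, str) else set(population)
        cols = [s for s in self.samples if self.populations[s] in pops]
        return self.values[cols]
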