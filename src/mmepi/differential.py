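"""Stage 1: consensus peaks, the stable-differentiation baseline, and
gain/loss calls in tumor plasma cells.

"Stable" is operationalized base-wise: a base is stably present for a
mark when every normal B-cell population's consensus covers it, and
stably absent when no population's consensus covers it. Gains are
recurrent MM peaks restricted to stably absent ground; losses are
stably present bases with near-zero MM peak support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, count_overlaps, coverage_select
from .stats import DEResult
from .tables import (
    BASELINE_POPULATIONS, GeneAnnotation, MethylationTable, SampleTable,
)

__all__ = [
    "ConsensusSet", "DifferentialRegionSet",
    "build_consensus", "stable_baseline", "call_differential",
    "annotate_differential",
]


@dataclass
class ConsensusSet:
    """Merged within-population peaks with per-interval sample support."""

    population: str
    mark: str
    intervals: IntervalSet
    support: np.ndarray  # fraction of samples overlapping each interval

    def __post_init__(self) -> None:
        if len(self.support) and (
            (self.support <= 0).any() or (self.support > 1).any()
        ):
            raise ValueError("support fractions must lie in (0, 1]")


@dataclass
class DifferentialRegionSet:
    """Gain or loss regions for one mark, with annotation columns."""

    mark: str
    direction: str  # "gain" | "loss"
    regions: IntervalSet
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.regions)


def _min_count(frac: float, n: int) -> int:
    """Smallest sample count whose fraction of n reaches frac."""
    return max(1, math.ceil(frac * n - 1e-9))


def build_consensus(
    sample_peaks: Sequence[IntervalSet],
    min_frac: float,
    population: str = "",
    mark: str = "",
) -> ConsensusSet:
    """Base-wise voting consensus across the samples of one population.

    A base enters the consensus when the fraction of samples whose
    (merged) peaks cover it is at least ``min_frac``; covered bases are
    then merged into intervals.
    """
    if len(sample_peaks) == 0:
        raise ValueError("need at least one sample peak set")
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must lie in (0, 1]")
    k = len(sample_peaks)
    consensus = coverage_select(sample_peaks, min_count=_min_count(min_frac, k))
    if len(consensus):
        votes = np.zeros(len(consensus))
        for s in sample_peaks:
            ind, _ = count_overlaps(consensus, s, min_bp=1)
            votes += ind
        support = votes / k
    else:
        support = np.zeros(0)
    return ConsensusSet(population, mark, consensus, support)


def stable_baseline(
    consensus_by_pop: Mapping[str, ConsensusSet],
    genome: Mapping[str, int],
    required: Sequence[str] = BASELINE_POPULATIONS,
) -> tuple[IntervalSet, IntervalSet]:
    """(stably_present, stably_absent) across the normal populations.

    stably_present: bases in every population's consensus.
    stably_absent: bases in no population's consensus.
    Bases covered by some but not all populations are unstable and
    belong to neither set.
    """
    missing = [p for p in required if p not in consensus_by_pop]
    if missing:
        raise ValueError(f"missing population consensus: {missing}")
    if len(required) < 2:
        raise ValueError("need at least two normal populations")
    sets = [consensus_by_pop[p].intervals for p in required]
    present = coverage_select(sets, min_count=len(sets))
    absent = coverage_select(sets, genome=genome, min_count=0, max_count=0)
    return present, absent


def call_differential(
    mark: str,
    mm_sample_peaks: Sequence[IntervalSet],
    stably_present: IntervalSet,
    stably_absent: IntervalSet,
    genome: Mapping[str, int],
    min_mm_frac: float = 0.66,
    min_region_bp: int = 200,
) -> tuple[DifferentialRegionSet, DifferentialRegionSet]:
    """Gain and loss region calls for one mark.

    Gains: bases carried by >= min_mm_frac of MM samples, restricted to
    stably absent ground. Losses: stably present bases carried by
    <= 1 - min_mm_frac of MM samples (tolerating spurious peaks).
    Regions shorter than min_region_bp are dropped.
    """
    n = len(mm_sample_peaks)
    if n == 0:
        raise ValueError(f"no MM samples for mark {mark}")
    merged_samples = [s if s.merged else s.merge() for s in mm_sample_peaks]

    recurrent = coverage_select(merged_samples, min_count=_min_count(min_mm_frac, n))
    gain = recurrent.intersect(stably_absent)
    gain = _length_filter(gain, min_region_bp)

    max_loss_count = int(math.floor((1.0 - min_mm_frac) * n + 1e-9))
    sparse = coverage_select(merged_samples, genome=genome,
                             min_count=0, max_count=max_loss_count)
    loss = sparse.intersect(stably_present)
    loss = _length_filter(loss, min_region_bp)

    return (
        DifferentialRegionSet(mark, "gain", gain,
                              _support_table(gain, merged_samples)),
        DifferentialRegionSet(mark, "loss", loss,
                              _support_table(loss, merged_samples)),
    )


def _length_filter(regions: IntervalSet, min_bp: int) -> IntervalSet:
    df = regions.df
    keep = (df["end"] - df["start"]) >= min_bp
    return IntervalSet(df[keep], merged=regions.merged)


def _support_table(regions: IntervalSet, samples: Sequence[IntervalSet]) -> pd.DataFrame:
    votes = np.zeros(len(regions))
    for s in samples:
        ind, _ = count_overlaps(regions, s, min_bp=1)
        votes += ind
    out = regions.df[["chrom", "start", "end"]].copy()
    out["mm_support"] = votes / max(1, len(samples))
    return out


def annotate_differential(
    diff: DifferentialRegionSet,
    samples: SampleTable,
    atac_peaks: Mapping[str, IntervalSet],
    methylation: MethylationTable | None,
    genes: GeneAnnotation | None,
    de: DEResult | None,
    min_bp: int = 1,
) -> DifferentialRegionSet:
    """Attach accessibility, methylation, and host-gene panels.

    Per region: the fraction of MM and of normal samples with an
    ATAC peak overlap, the group median of per-sample mean CpG beta,
    the gene whose body contains the region midpoint (else intergenic),
    and that host gene's differential-expression status.
    """
    regions = diff.regions
    out = regions.df[["chrom", "start", "end"]].copy()
    if "mm_support" in diff.annotations.columns and len(diff.annotations) == len(out):
        out["mm_support"] = diff.annotations["mm_support"].to_numpy()

    pop = dict(zip(samples.df["sample_id"], samples.df["population"]))
    mm_ids = [s for s in atac_peaks if pop.get(s) == "MM"]
    normal_ids = [s for s in atac_peaks if pop.get(s, "MM") != "MM"]
    for label, ids in (("mm", mm_ids), ("normal", normal_ids)):
        frac = np.full(len(regions), np.nan)
        if ids:
            votes = np.zeros(len(regions))
            for sid in ids:
                ind, _ = count_overlaps(regions, atac_peaks[sid], min_bp=min_bp)
                votes += ind
            frac = votes / len(ids)
        out[f"atac_fraction_{label}"] = frac

    if methylation is not None:
        wgbs = samples.select(assay="WGBS")
        meth_pop = dict(zip(wgbs["sample_id"], wgbs["population"]))
        for label, want_mm in (("mm", True), ("normal", False)):
            ids = [s for s in methylation.samples
                   if (meth_pop.get(s) == "MM") == want_mm]
            med = np.full(len(regions), np.nan)
            if ids:
                means = methylation.region_sample_means(regions, ids)
                grouped = means.groupby("region_idx")["mean_beta"].median()
                if len(grouped):
                    med[grouped.index.to_numpy(dtype=int)] = grouped.to_numpy()
            out[f"medmeth_{label}"] = med
    else:
        out["medmeth_mm"] = np.nan
        out["medmeth_normal"] = np.nan

    host = np.array([""] * len(regions), dtype=object)
    host_de = np.array(["na"] * len(regions), dtype=object)
    if genes is not None and len(regions):
        status = de.status() if de is not None else pd.Series(dtype=object)
        gdf = genes.df
        mids = ((out["start"] + out["end"]) // 2).to_numpy()
        for i, (chrom, mid) in enumerate(zip(out["chrom"], mids)):
            inside = gdf[(gdf["chrom"] == chrom) & (gdf["start"] <= mid) & (gdf["end"] > mid)]
            if inside.empty:
                continue
            gid = inside.iloc[0]["gene_id"]
            host[i] = gid
            host_de[i] = status.get(gid, "na") if de is not None else "na"
    out["host_gene"] = host
    out["host_gene_de"] = host_de
    return DifferentialRegionSet(diff.mark, diff.direction, regions, out)
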