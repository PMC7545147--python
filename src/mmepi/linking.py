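"""Stage 3: TAD-constrained enhancer-gene linking and coregulated
adjacent gene groups.

A de novo region is linked to the genes sharing its topologically
associating domain (TAD) that are up-regulated in MM against every
normal population with RNA data — mirroring the bone-marrow plasma
cell filter on the expression side. Adjacent linked genes whose
expression correlates across MM samples (Pearson r > 0.5, p < 0.05)
are chained into coregulated groups; transitive chaining yields pairs,
triplets, and longer runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .denovo import DeNovoRegion
from .stats import DEResult, pearson_test
from .tables import GeneAnnotation
from .intervals import IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "TADSet", "RegionGeneLink", "CoexpressionGroup",
    "assign_tad", "link_targets", "find_coregulated",
]


class TADSet:
    """Non-overlapping topologically associating domains with ids."""

    def __init__(self, intervals: IntervalSet):
        m = intervals.df
        for chrom, sub in m.groupby("chrom"):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping TADs on {chrom}")
        self.df = m[["chrom", "start", "end"]].reset_index(drop=True)
        self.df["tad_id"] = [f"TAD_{i + 1}" for i in range(len(self.df))]

    def __len__(self) -> int:
        return len(self.df)

    def locate(self, chrom: str, pos: int) -> str | None:
        """TAD containing a position, or None in an inter-TAD gap."""
        sub = self.df[self.df["chrom"] == chrom]
        if sub.empty:
            return None
        starts = sub["start"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        if i < 0:
            return None
        row = sub.iloc[i]
        return row["tad_id"] if row["start"] <= pos < row["end"] else None


@dataclass
class RegionGeneLink:
    region_id: str
    chrom: str
    start: int
    end: int
    gene_id: str
    same_tad: bool
    fallback: bool
    distance_to_tss: int


@dataclass
class CoexpressionGroup:
    genes: list[str]
    pair_r: list[float]
    pair_p: list[float]
    chrom: str
    span_start: int
    span_end: int


def assign_tad(regions: IntervalSet, tads: TADSet) -> list[str | None]:
    """TAD id per region (midpoint rule), None in inter-TAD gaps."""
    out = []
    for iv in regions:
        out.append(tads.locate(iv.chrom, iv.midpoint))
    return out


def link_targets(
    regions: Sequence[DeNovoRegion],
    tads: TADSet,
    genes: GeneAnnotation,
    de_by_population: Mapping[str, DEResult],
    fallback_window: int = 1_000_000,
) -> list[RegionGeneLink]:
    """Link each de novo region to up-in-MM genes in its TAD.

    ``de_by_population`` maps each normal population (including bm-PC)
    to the MM-vs-that-population DE result; a candidate gene qualifies
    only when flagged up against every one of them. Regions whose
    midpoint falls outside all TADs fall back to a TSS window, flagged
    as such. All qualifying genes are linked — a region may have
    several targets and a gene may serve several regions.
    """
    if not de_by_population:
        raise ValueError("need DE results against at least one normal population")
    up_sets = []
    for pop, de in de_by_population.items():
        up_sets.append(set(de.flagged("up")["gene_id"]))
    up_everywhere = set.intersection(*up_sets)

    gdf = genes.df
    links: list[RegionGeneLink] = []
    for ridx, region in enumerate(regions):
        rid = f"region_{ridx + 1}"
        mid = (region.start + region.end) // 2
        tad = tads.locate(region.chrom, mid)
        if tad is not None:
            trow = tads.df[tads.df["tad_id"] == tad].iloc[0]
            cand = gdf[(gdf["chrom"] == region.chrom)
                       & (gdf["tss"] >= trow["start"]) & (gdf["tss"] < trow["end"])]
            fallback = False
        else:
            cand = gdf[(gdf["chrom"] == region.chrom)
                       & (abs(gdf["tss"] - mid) <= fallback_window)]
            fallback = True
        hit_any = False
        for row in cand.itertuples(index=False):
            if row.gene_id not in up_everywhere:
                continue
            hit_any = True
            links.append(RegionGeneLink(
                region_id=rid, chrom=region.chrom,
                start=region.start, end=region.end,
                gene_id=row.gene_id, same_tad=not fallback, fallback=fallback,
                distance_to_tss=int(abs(row.tss - mid)),
            ))
            if row.gene_id not in region.target_genes:
                region.target_genes.append(row.gene_id)
        if not hit_any:
            logger.debug("region %s: no qualifying target gene", rid)
    return links


def find_coregulated(
    target_genes: Sequence[str],
    annotation: GeneAnnotation,
    expr_mm: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 0.05,
    adjacency: str = "annotation",
) -> list[CoexpressionGroup]:
    """Chains of adjacent coexpressed target genes across MM samples.

    Candidate pairs are consecutive target-list genes in full-annotation
    TSS order with no other annotated gene's TSS strictly between them
    (``adjacency="target"`` relaxes this to consecutive within the
    target list). A pair is kept when Pearson r > r_min and p < p_max
    (strict inequalities); kept pairs sharing a gene merge into maximal
    chains.
    """
    if expr_mm.shape[1] < 3:
        raise ValueError("need at least 3 MM expression samples")
    if adjacency not in ("annotation", "target"):
        raise ValueError("adjacency must be 'annotation' or 'target'")
    targets = [g for g in dict.fromkeys(target_genes) if g in expr_mm.index]
    tset = set(targets)
    order = annotation.tss_order()

    pairs: list[tuple[str, str]] = []
    for chrom, sub in order.groupby("chrom", sort=False):
        ids = list(sub["gene_id"])
        if adjacency == "annotation":
            for g1, g2 in zip(ids, ids[1:]):
                if g1 in tset and g2 in tset:
                    pairs.append((g1, g2))
        else:
            tids = [g for g in ids if g in tset]
            pairs.extend(zip(tids, tids[1:]))

    kept: dict[tuple[str, str], tuple[float, float]] = {}
    for g1, g2 in pairs:
        x = expr_mm.loc[g1].to_numpy(dtype=float)
        y = expr_mm.loc[g2].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            logger.warning("constant expression for pair (%s, %s); skipped", g1, g2)
            continue
        r, p = pearson_test(x, y)
        if r > r_min and p < p_max:
            kept[(g1, g2)] = (r, p)

    # chain kept pairs that share a gene into maximal runs
    groups: list[CoexpressionGroup] = []
    tss = dict(zip(order["gene_id"], order["tss"]))
    chrom_of = dict(zip(order["gene_id"], order["chrom"]))
    adjacency_next = {g1: g2 for (g1, g2) in kept}
    chain_starts = [g1 for (g1, g2) in kept
                    if g1 not in {b for (_, b) in kept}]
    for start in sorted(chain_starts, key=lambda g: (chrom_of[g], tss[g])):
        chain = [start]
        while chain[-1] in adjacency_next:
            chain.append(adjacency_next[chain[-1]])
        rs, ps = [], []
        for g1, g2 in zip(chain, chain[1:]):
            r, p = kept[(g1, g2)]
            rs.append(r)
            ps.append(p)
        bodies = annotation.df[annotation.df["gene_id"].isin(chain)]
        groups.append(CoexpressionGroup(
            genes=chain, pair_r=rs, pair_p=ps,
            chrom=chrom_of[start],
            span_start=int(bodies["start"].min()),
            span_end=int(bodies["end"].max()),
        ))
    return groups
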