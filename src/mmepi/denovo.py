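"""Stage 2: de novo H3K27ac-activated regions and superenhancers.

A de novo region is an H3K27ac gain in MM with zero base overlap
against every individual normal sample's H3K27ac peaks — including
bone-marrow plasma cells, the key cell-of-origin filter. Superenhancer
calling follows ROSE conventions: TSS-proximal peaks excluded, nearby
peaks stitched, stitched regions ranked by aggregate signal, and the
superenhancer cutoff placed where the scaled rank curve's tangent
slope reaches 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, SignalTrack, count_overlaps
from .tables import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "DeNovoRegion", "SuperEnhancer",
    "select_de_novo", "audit_de_novo", "stitch_superenhancers",
    "intersect_atac", "denovo_table",
]


@dataclass
class DeNovoRegion:
    chrom: str
    start: int
    end: int
    mm_support: float
    atac_gain: bool = False
    se_id: str | None = None
    target_genes: list[str] = field(default_factory=list)


def select_de_novo(
    mm_gains: pd.DataFrame | IntervalSet,
    normal_peaks: Mapping[str, IntervalSet],
    min_mm_frac: float = 0.66,
    require_bmpc: bool = True,
    bmpc_samples: Sequence[str] = (),
) -> list[DeNovoRegion]:
    """Retain H3K27ac gain regions untouched by any normal sample peak.

    ``mm_gains`` is the gain table from stage 1 (chrom/start/end with an
    optional mm_support column); ``normal_peaks`` maps every individual
    normal sample id (all five B-cell populations plus bm-PC) to its
    peak set. A single base of overlap with any of them disqualifies a
    region. The bm-PC filter is mandatory unless explicitly overridden.
    """
    if isinstance(mm_gains, IntervalSet):
        gains_df = mm_gains.df[["chrom", "start", "end"]].copy()
        gains_df["mm_support"] = np.nan
    else:
        gains_df = mm_gains.copy()
        if "mm_support" not in gains_df.columns:
            gains_df["mm_support"] = np.nan
    if require_bmpc and not bmpc_samples:
        raise ValueError(
            "bm-PC H3K27ac peaks are required as the cell-of-origin filter; "
            "pass bmpc_samples or set require_bmpc=False explicitly"
        )
    if not require_bmpc and not bmpc_samples:
        logger.warning("bm-PC filter overridden: de novo calls lack the "
                       "cell-of-origin control")
    regions = IntervalSet(gains_df[["chrom", "start", "end"]])
    keep = np.ones(len(regions), dtype=bool)
    for sid, peaks in normal_peaks.items():
        ind, _ = count_overlaps(regions, peaks, min_bp=1)
        keep &= ~ind
    # align the support column with the sorted region order
    merged = gains_df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    out = []
    for i, row in merged.iterrows():
        if not keep[i]:
            continue
        if not np.isnan(row["mm_support"]) and row["mm_support"] < min_mm_frac:
            continue
        out.append(DeNovoRegion(row["chrom"], int(row["start"]), int(row["end"]),
                                float(row["mm_support"])))
    return out


def audit_de_novo(
    regions: Sequence[DeNovoRegion], normal_peaks: Mapping[str, IntervalSet]
) -> int:
    """Independent second pass: total bases of normal-peak overlap.

    Returns the summed overlap (must be zero for a valid call set),
    recomputed per sample file rather than via the selection path.
    """
    ivs = IntervalSet.from_records(
        [(r.chrom, r.start, r.end) for r in regions]
    )
    total = 0
    for peaks in normal_peaks.values():
        _, bp = count_overlaps(ivs, peaks, min_bp=1)
        total += int(bp.sum())
    return total


@dataclass
class SuperEnhancer:
    se_id: str
    chrom: str
    start: int
    end: int
    n_constituents: int
    total_signal: float
    rank: int
    is_super: bool


def stitch_superenhancers(
    peaks: IntervalSet,
    signal_tracks: Mapping[str, SignalTrack],
    genes: GeneAnnotation | None = None,
    stitch_distance: int = 12_500,
    tss_exclusion: int = 2_000,
) -> tuple[list[SuperEnhancer], pd.DataFrame]:
    """ROSE-style stitching and ranking of H3K27ac peaks.

    Peaks lying fully within +-tss_exclusion of an annotated TSS are
    removed, the rest are merged whenever gaps are <= stitch_distance,
    and each stitched region is scored by the across-sample mean of its
    total signal. With both axes scaled to [0, 1] on the ascending rank
    curve, regions past the first point where the discrete slope
    reaches 1 are superenhancers; a flat curve yields none.

    Returns the superenhancer list plus a constituent table mapping
    each retained peak to its stitched region.
    """
    df = peaks.df[["chrom", "start", "end"]].copy()
    if genes is not None and len(df) and tss_exclusion > 0:
        drop = np.zeros(len(df), dtype=bool)
        tss = genes.df[["chrom", "tss"]]
        for chrom, sub in tss.groupby("chrom"):
            pos = np.sort(sub["tss"].to_numpy())
            m = df["chrom"] == chrom
            if not m.any():
                continue
            s = df.loc[m, "start"].to_numpy()
            e = df.loc[m, "end"].to_numpy()
            # fully contained in some TSS window: find a TSS with
            # window start <= peak start and window end >= peak end
            idx = np.searchsorted(pos, s - tss_exclusion, side="left")
            idx = np.clip(idx, 0, len(pos) - 1)
            contained = np.zeros(len(s), dtype=bool)
            for cand in (idx, np.clip(idx - 1, 0, len(pos) - 1),
                         np.clip(idx + 1, 0, len(pos) - 1)):
                w0 = pos[cand] - tss_exclusion
                w1 = pos[cand] + tss_exclusion + 1
                contained |= (w0 <= s) & (e <= w1)
            drop[np.where(m)[0]] = contained
        df = df[~drop]
    retained = IntervalSet(df)
    stitched = retained.merge(gap=stitch_distance)
    if len(stitched) == 0:
        return [], pd.DataFrame(columns=["chrom", "start", "end", "se_id"])

    totals = np.zeros(len(stitched))
    for track in signal_tracks.values():
        totals += track.quantify(stitched)["total"].to_numpy()
    if signal_tracks:
        totals /= len(signal_tracks)

    order = np.argsort(totals, kind="stable")  # ascending signal
    is_super = np.zeros(len(stitched), dtype=bool)
    if len(stitched) < 3:
        warnings.warn("fewer than 3 stitched regions: inflection undefined, "
                      "all flagged non-super")
    else:
        cutoff = _tangent_cutoff(totals[order])
        if cutoff is not None:
            is_super[order[cutoff + 1:]] = True

    ses = []
    sdf = stitched.df
    ranks = np.empty(len(stitched), dtype=int)
    # rank 1 = highest signal
    ranks[order[::-1]] = np.arange(1, len(stitched) + 1)
    for i in range(len(stitched)):
        ses.append(SuperEnhancer(
            se_id=f"SE_{i + 1}",
            chrom=sdf.iloc[i]["chrom"],
            start=int(sdf.iloc[i]["start"]),
            end=int(sdf.iloc[i]["end"]),
            n_constituents=0,
            total_signal=float(totals[i]),
            rank=int(ranks[i]),
            is_super=bool(is_super[i]),
        ))
    cons = retained.df[["chrom", "start", "end"]].copy()
    ind, _ = count_overlaps(retained, stitched, min_bp=1)
    se_ids = []
    for row in retained.df.itertuples(index=False):
        hit = sdf[(sdf["chrom"] == row.chrom) & (sdf["start"] <= row.start)
                  & (sdf["end"] >= row.end)]
        se_ids.append(f"SE_{hit.index[0] + 1}" if len(hit) else "")
    cons["se_id"] = se_ids
    counts = cons["se_id"].value_counts()
    for se in ses:
        se.n_constituents = int(counts.get(se.se_id, 0))
    return ses, cons


def _tangent_cutoff(sorted_signal: np.ndarray) -> int | None:
    """Index of the tangency point on the scaled ascending rank curve.

    Both axes are scaled to [0, 1]; the cutoff is the point where a
    line of slope 1 is tangent to the curve from below, i.e. the index
    minimizing y - x (for a convex curve this is exactly where the
    tangent slope reaches 1). Regions past that index are super. A
    flat curve puts the minimum at the last index, so nothing is super
    — the documented degenerate convention.
    """
    n = len(sorted_signal)
    lo, hi = sorted_signal[0], sorted_signal[-1]
    if hi == lo:
        return None
    x = np.arange(n) / (n - 1)
    y = (sorted_signal - lo) / (hi - lo)
    return int(np.argmin(y - x))


def intersect_atac(
    regions: Sequence[DeNovoRegion], atac_gains: IntervalSet
) -> list[DeNovoRegion]:
    """Flag de novo regions that also gained chromatin accessibility."""
    if not regions:
        return []
    ivs = IntervalSet.from_records([(r.chrom, r.start, r.end) for r in regions])
    ind, _ = count_overlaps(ivs, atac_gains, min_bp=1) if len(atac_gains) else (
        np.zeros(len(regions), dtype=bool), None)
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    for r, flag in zip(ordered, ind):
        r.atac_gain = bool(flag)
    return list(regions)


def denovo_table(regions: Sequence[DeNovoRegion]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": r.chrom, "start": r.start, "end": r.end,
         "mm_support": r.mm_support, "atac_gain": r.atac_gain,
         "se_id": r.se_id or "",
         "target_genes": ",".join(r.target_genes)}
        for r in regions
    ])
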