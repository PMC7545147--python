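"""Genomic interval algebra.

Coordinates are 0-based half-open everywhere: an interval [start, end)
covers bases start .. end-1. Strand is ignored for all interval
arithmetic; peaks are unstranded. All set operations are implemented
base-wise on sorted numpy arrays, so results agree with a boolean
genome-mask formulation by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "SignalTrack",
    "merge_intervals",
    "count_overlaps",
    "quantify_signal",
    "coverage_select",
]


@dataclass(frozen=True)
class GenomicInterval:
    """One half-open genomic interval with an optional signal score."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("score must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered collection of genomic intervals.

    Intervals are stored (chrom, start, end)-sorted in a DataFrame with
    columns chrom/start/end/score. ``merged`` is True when the set is
    known to be pairwise non-overlapping and non-abutting per chromosome.
    """

    def __init__(self, df: pd.DataFrame | None = None, merged: bool = False):
        if df is None or len(df) == 0:
            df = pd.DataFrame(
                {"chrom": pd.Series(dtype=str),
                 "start": pd.Series(dtype=np.int64),
                 "end": pd.Series(dtype=np.int64),
                 "score": pd.Series(dtype=float)}
            )
            merged = True
        else:
            df = df.copy()
            if "score" not in df.columns:
                df["score"] = np.nan
            df = df[["chrom", "start", "end", "score"]]
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                raise ValueError("intervals must satisfy 0 <= start < end")
            df = df.sort_values(
                ["chrom", "start", "end"], kind="mergesort"
            ).reset_index(drop=True)
        self.df = df
        self.merged = merged

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple | GenomicInterval], merged: bool = False
    ) -> "IntervalSet":
        rows = []
        for r in records:
            if isinstance(r, GenomicInterval):
                rows.append((r.chrom, r.start, r.end, r.score))
            else:
                chrom, start, end = r[0], r[1], r[2]
                score = r[3] if len(r) > 3 else None
                rows.append((chrom, start, end, score))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        return cls(df, merged=merged)

    # -- basics -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            score = None if pd.isna(row.score) else float(row.score)
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), score)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def total_bp(self) -> int:
        m = self if self.merged else self.merge()
        return int((m.df["end"] - m.df["start"]).sum())

    # -- algebra ------------------------------------------------------
    def merge(self, gap: int = 0) -> "IntervalSet":
        """Merge intervals whose separation is <= gap on one chromosome."""
        if gap < 0:
            raise ValueError("gap must be non-negative")
        if len(self) == 0:
            return IntervalSet()
        out = {"chrom": [], "start": [], "end": []}
        for chrom in self.chroms:
            starts, ends = self.chrom_arrays(chrom)
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s - cur_e <= gap:
                    cur_e = max(cur_e, e)
                else:
                    out["chrom"].append(chrom)
                    out["start"].append(cur_s)
                    out["end"].append(cur_e)
                    cur_s, cur_e = s, e
            out["chrom"].append(chrom)
            out["start"].append(cur_s)
            out["end"].append(cur_e)
        return IntervalSet(pd.DataFrame(out), merged=(gap == 0))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-wise intersection of the two covered sets."""
        return coverage_select([self, other], min_count=2)

    def complement(self, genome: Mapping[str, int]) -> "IntervalSet":
        """Bases of the genome covered by no interval of this set."""
        return coverage_select([self], genome=genome, min_count=0, max_count=0)

def merge_intervals(intervals: IntervalSet, gap: int = 0) -> IntervalSet:
    """Functional alias for :meth:`IntervalSet.merge`."""
    return intervals.merge(gap)


def coverage_select(
    sets: Sequence[IntervalSet],
    genome: Mapping[str, int] | None = None,
    min_count: int = 1,
    max_count: int | None = None,
) -> IntervalSet:
    """Bases covered by between min_count and max_count of the given sets.

    Each input set contributes at most one count per base (sets are
    merged first). With ``min_count=0`` a genome (chrom -> length) is
    required to bound the uncovered segments.
    """
    if max_count is None:
        max_count = len(sets)
    if min_count == 0 and genome is None:
        raise ValueError("min_count=0 requires explicit genome bounds")
    merged = [s if s.merged else s.merge() for s in sets]
    if genome is not None:
        chroms: list[str] = list(genome)
    else:
        seen: dict[str, None] = {}
        for m in merged:
            for c in m.chroms:
                seen.setdefault(c)
        chroms = list(seen)

    out = {"chrom": [], "start": [], "end": []}
    for chrom in chroms:
        pts = []
        deltas = []
        for m in merged:
            s, e = m.chrom_arrays(chrom)
            pts.append(s)
            deltas.append(np.ones(len(s), dtype=np.int64))
            pts.append(e)
            deltas.append(-np.ones(len(e), dtype=np.int64))
        pos = np.concatenate(pts) if pts else np.array([], dtype=np.int64)
        delta = np.concatenate(deltas) if deltas else np.array([], dtype=np.int64)
        limit = genome[chrom] if genome is not None else None
        if limit is not None:
            pos = np.concatenate([pos, [0, limit]])
            delta = np.concatenate([delta, [0, 0]])
        if len(pos) == 0:
            continue
        upos, inv = np.unique(pos, return_inverse=True)
        net = np.bincount(inv, weights=delta).astype(np.int64)
        counts = np.cumsum(net)  # coverage on [upos[i], upos[i+1])
        keep = (counts[:-1] >= min_count) & (counts[:-1] <= max_count)
        seg_s = upos[:-1][keep]
        seg_e = upos[1:][keep]
        if limit is not None:
            inside = (seg_s < limit) & (seg_e > 0)
            seg_s, seg_e = seg_s[inside], seg_e[inside]
            seg_s = np.clip(seg_s, 0, limit)
            seg_e = np.clip(seg_e, 0, limit)
        # merge abutting kept segments
        for s, e in zip(seg_s, seg_e):
            if out["chrom"] and out["chrom"][-1] == chrom and out["end"][-1] == s:
                out["end"][-1] = e
            else:
                out["chrom"].append(chrom)
                out["start"].append(int(s))
                out["end"].append(int(e))
    return IntervalSet(pd.DataFrame(out), merged=True)


def count_overlaps(
    query: IntervalSet, subject: IntervalSet, min_bp: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-query overlap with the union of the subject set.

    Returns (indicator, bp): indicator[i] is True when at least
    ``min_bp`` bases of query interval i intersect the merged subject;
    bp[i] is the exact overlapping base count. Order follows the
    query's sorted iteration order.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    subj = subject if subject.merged else subject.merge()
    n = len(query)
    bp = np.zeros(n, dtype=np.int64)
    qdf = query.df
    offset = 0
    for chrom in query.chroms:
        qs = qdf[qdf["chrom"] == chrom]
        s = qs["start"].to_numpy()
        e = qs["end"].to_numpy()
        ms, me = subj.chrom_arrays(chrom)
        if len(ms) == 0:
            offset += len(qs)
            continue
        lens = me - ms
        cum = np.concatenate([[0], np.cumsum(lens)])
        # j0: first subject interval ending after query start
        j0 = np.searchsorted(me, s, side="right")
        # j1: last subject interval starting before query end
        j1 = np.searchsorted(ms, e, side="left") - 1
        valid = j1 >= j0
        tot = np.zeros(len(qs), dtype=np.int64)
        if valid.any():
            a, b = j0[valid], j1[valid]
            full = cum[b + 1] - cum[a]
            clip_l = np.maximum(0, s[valid] - ms[a])
            clip_r = np.maximum(0, me[b] - e[valid])
            tot[valid] = full - clip_l - clip_r
        bp[offset:offset + len(qs)] = tot
        offset += len(qs)
    return bp >= min_bp, bp


class SignalTrack:
    """A step signal: non-overlapping scored intervals per chromosome.

    This models bedGraph content. Per-region totals are computed with
    weighted prefix sums, exact for any step function.
    """

    def __init__(self, df: pd.DataFrame):
        if len(df) == 0:
            self._by_chrom: dict[str, tuple[np.ndarray, ...]] = {}
            return
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self._by_chrom = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy(np.int64)
            e = sub["end"].to_numpy(np.int64)
            v = sub["value"].to_numpy(float)
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping track intervals on {chrom}")
            w = np.concatenate([[0.0], np.cumsum(v * (e - s))])
            self._by_chrom[str(chrom)] = (s, e, v, w)

    def quantify(self, regions: IntervalSet) -> pd.DataFrame:
        """Total and mean signal per region (region order = sorted)."""
        totals = np.zeros(len(regions))
        rdf = regions.df
        offset = 0
        for chrom in regions.chroms:
            sub = rdf[rdf["chrom"] == chrom]
            qs = sub["start"].to_numpy()
            qe = sub["end"].to_numpy()
            if chrom not in self._by_chrom:
                offset += len(sub)
                continue
            s, e, v, w = self._by_chrom[chrom]
            j0 = np.searchsorted(e, qs, side="right")
            j1 = np.searchsorted(s, qe, side="left") - 1
            t = np.zeros(len(sub))
            valid = j1 >= j0
            if valid.any():
                a, b = j0[valid], j1[valid]
                full = w[b + 1] - w[a]
                clip_l = np.maximum(0, qs[valid] - s[a]) * v[a]
                clip_r = np.maximum(0, e[b] - qe[valid]) * v[b]
                t[valid] = full - clip_l - clip_r
            totals[offset:offset + len(sub)] = t
            offset += len(sub)
        out = rdf[["chrom", "start", "end"]].copy()
        out["total"] = totals
        out["mean"] = totals / (out["end"] - out["start"])
        return out


def quantify_signal(track: SignalTrack, regions: IntervalSet) -> pd.DataFrame:
    """Functional alias for :meth:`SignalTrack.quantify`."""
    return track.quantify(regions)
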