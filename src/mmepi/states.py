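"""Rule-based chromatin-state assignment and the state transition matrix.

A fixed nine-state vocabulary is assigned from binary presence of the
six histone marks by a deterministic precedence table, replacing an
HMM-style segmentation: downstream summaries consume state labels, and
a rule table makes every number reproducible. States are computed only
on analysis regions, not genome-wide.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, count_overlaps
from .tables import HISTONE_MARKS, SampleTable

#: activity-ordered vocabulary; lower rank = more active (wins ties)
STATE_VOCABULARY = (
    "ActiveProm", "WeakProm", "BivalentProm", "ActiveEnh", "WeakEnh",
    "Transcription", "PolycombRepr", "Heterochrom", "LowSignal",
)
STATE_RANK = {s: i for i, s in enumerate(STATE_VOCABULARY)}

#: presence-vector order expected by assign_state
MARK_ORDER = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K36me3", "H3K27me3", "H3K9me3")


def assign_state(presence: Sequence[bool]) -> str:
    """Map one region/sample mark-presence vector to a state label.

    ``presence`` is ordered (K4me3, K27ac, K4me1, K36me3, K27me3,
    K9me3). The rule table is a strict precedence cascade; it is total,
    so every one of the 64 possible vectors maps to exactly one state.
    """
    if len(presence) != 6:
        raise ValueError("presence vector must have 6 entries")
    k4me3, k27ac, k4me1, k36me3, k27me3, k9me3 = map(bool, presence)
    if k4me3 and k27me3:
        return "BivalentProm"
    if k4me3 and k27ac:
        return "ActiveProm"
    if k4me3:
        return "WeakProm"
    if k4me1 and k27ac:
        return "ActiveEnh"
    if k4me1:
        return "WeakEnh"
    if k36me3:
        return "Transcription"
    if k27me3:
        return "PolycombRepr"
    if k9me3:
        return "Heterochrom"
    return "LowSignal"


def group_state(states: Iterable[str]) -> str:
    """Majority state across samples; ties broken toward activity.

    The winner is the most frequent label; among equally frequent
    labels the one ranked more active in STATE_VOCABULARY wins.
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one sample state")
    counts = Counter(states)
    best = max(counts.items(), key=lambda kv: (kv[1], -STATE_RANK[kv[0]]))
    return best[0]


def sample_states(
    regions: IntervalSet,
    samples: SampleTable,
    peaks: dict[tuple[str, str], IntervalSet],
    min_bp: int = 1,
) -> pd.DataFrame:
    """Per-region, per-sample state calls from peak overlap.

    ``peaks`` maps (sample_id, mark) to that sample's peak set. Only
    sample_ids with all six histone marks available are scored.
    """
    by_sample: dict[str, dict[str, IntervalSet]] = {}
    for (sid, mark), ivs in peaks.items():
        by_sample.setdefault(sid, {})[mark] = ivs
    complete = [s for s, d in by_sample.items() if all(m in d for m in HISTONE_MARKS)]
    pop = dict(zip(samples.df["sample_id"], samples.df["population"]))
    rows = []
    region_df = regions.df
    for sid in complete:
        presence = np.zeros((len(regions), 6), dtype=bool)
        for j, mark in enumerate(MARK_ORDER):
            ind, _ = count_overlaps(regions, by_sample[sid][mark], min_bp=min_bp)
            presence[:, j] = ind
        for i in range(len(regions)):
            rows.append((
                region_df.iloc[i]["chrom"], int(region_df.iloc[i]["start"]),
                int(region_df.iloc[i]["end"]), sid, pop.get(sid, ""),
                assign_state(presence[i]),
            ))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "sample_id", "population", "state"]
    )


def group_states_per_region(calls: pd.DataFrame, populations: Iterable[str]) -> pd.Series:
    """Majority state per region over the samples of the given populations."""
    pops = set(populations)
    sub = calls[calls["population"].isin(pops)]
    if sub.empty:
        raise ValueError(f"no state calls for populations {sorted(pops)}")
    return sub.groupby(["chrom", "start", "end"], sort=True)["state"].agg(group_state)


def transition_matrix(normal_states: pd.Series, mm_states: pd.Series) -> pd.DataFrame:
    """Percentage matrix of per-region state transitions.

    Rows are the MM state, columns the normal state; entries are
    percentages of all regions and sum to 100.
    """
    joined = pd.concat(
        {"normal": normal_states, "mm": mm_states}, axis=1, join="inner"
    )
    if joined.empty:
        raise ValueError("no regions with states in both groups")
    mat = pd.DataFrame(
        0.0, index=list(STATE_VOCABULARY), columns=list(STATE_VOCABULARY)
    )
    for _, row in joined.iterrows():
        mat.loc[row["mm"], row["normal"]] += 1
    mat = 100.0 * mat / len(joined)
    return mat
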