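"""Planted-truth recovery metrics.

Shared by the test suite and the reproduction script: compares
pipeline outputs against the TruthManifest emitted by the synthetic
generator.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, count_overlaps
from .simulate import TruthManifest

__all__ = [
    "region_recovery", "coexpression_recovery", "block_hypomethylation",
    "null_de_calibration",
]


def null_de_calibration(
    n_genes: int = 2_000,
    n_reps: int = 200,
    n_per_group: int = 10,
    seed: int = 0,
) -> float:
    """Raw p < 0.05 rate of de_call under a pure null.

    Both groups are drawn from one log-normal distribution; the
    returned fraction should sit at the nominal 0.05 level.
    """
    from .stats import de_call
    from .tables import ExpressionMatrix

    rng = np.random.default_rng(seed)
    hits = 0
    cols = ([f"a{j}" for j in range(n_per_group)]
            + [f"b{j}" for j in range(n_per_group)])
    pops = {c: ("GCBC" if c.startswith("a") else "MM") for c in cols}
    genes = [f"g{i}" for i in range(n_genes)]
    for _ in range(n_reps):
        vals = rng.lognormal(np.log(50), 0.5, size=(n_genes, 2 * n_per_group))
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=cols), pops)
        res = de_call(expr, "GCBC", "MM")
        hits += int((res.table["p_value"] < 0.05).sum())
    return hits / (n_genes * n_reps)


def region_recovery(
    recovered: IntervalSet, truth: IntervalSet
) -> tuple[float, float]:
    """(precision, recall) with >= 1 bp overlap as the match rule.

    Precision: fraction of recovered regions touching a truth region.
    Recall: fraction of truth regions touched by a recovered region.
    """
    if len(recovered) == 0:
        return (float("nan"), 0.0 if len(truth) else float("nan"))
    prec_ind, _ = count_overlaps(recovered, truth)
    rec_ind, _ = count_overlaps(truth, recovered)
    precision = float(prec_ind.mean())
    recall = float(rec_ind.mean()) if len(truth) else float("nan")
    return precision, recall


def _consecutive_pairs(genes: Sequence[str]) -> set[frozenset]:
    return {frozenset(p) for p in zip(genes, genes[1:])}


def coexpression_recovery(
    reported_groups: Iterable[Sequence[str]], manifest: TruthManifest
) -> tuple[float, int]:
    """(recall of planted groups, number of background groups).

    A planted group counts as recovered when one reported group
    contains all of its genes. A reported group is background when
    none of its internal adjacent pairs comes from a planted group.
    """
    reported = [list(g) for g in reported_groups]
    planted = [p["genes"] for p in manifest.planted_pairs]
    recovered = 0
    for genes in planted:
        if any(set(genes) <= set(g) for g in reported):
            recovered += 1
    recall = recovered / len(planted) if planted else float("nan")
    planted_pairs = set().union(*(_consecutive_pairs(g) for g in planted)) \
        if planted else set()
    background = sum(
        1 for g in reported if not (_consecutive_pairs(g) & planted_pairs)
    )
    return recall, background


def block_hypomethylation(
    annotations: pd.DataFrame, manifest: TruthManifest
) -> float:
    """Fraction of planted repressed blocks with lower median beta in MM.

    ``annotations`` must carry medmeth_mm / medmeth_normal rows for the
    planted block coordinates (as produced by annotate_differential on
    the block interval set).
    """
    if not manifest.planted_hypo_blocks:
        return float("nan")
    keyed = annotations.set_index(["chrom", "start", "end"])
    hits = 0
    total = 0
    for b in manifest.planted_hypo_blocks:
        key = (b["chrom"], b["start"], b["end"])
        if key not in keyed.index:
            continue
        row = keyed.loc[key]
        if np.isnan(row["medmeth_mm"]) or np.isnan(row["medmeth_normal"]):
            continue
        total += 1
        hits += int(row["medmeth_mm"] < row["medmeth_normal"])
    return hits / total if total else float("nan")
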