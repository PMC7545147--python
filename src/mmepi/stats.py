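"""Statistical primitives used by every pipeline stage.

Two-sided Welch t-tests, Pearson correlation with its t-based p-value,
Benjamini-Hochberg FDR, threshold-based differential-expression calls
(FDR < 0.05, |FC| > 1.5 by default), and hypergeometric gene-set
enrichment. Tests are delegated to scipy/statsmodels; this module owns
the calling conventions and the DE threshold logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tables import ExpressionMatrix

__all__ = [
    "welch_t_test", "pearson_test", "bh_adjust", "de_call",
    "hypergeom_enrichment", "DEResult",
]


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Groups of fewer than two values are rejected; two identical
    zero-variance groups give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if b.mean() < a.mean() else -np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene differential expression table.

    ``table`` columns: gene_id, mean_a, mean_b, fold_change (linear,
    b over a, pseudocount applied), log2fc, p_value, q_value, is_de.
    """

    table: pd.DataFrame
    fdr_threshold: float
    fc_threshold: float

    def flagged(self, direction: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["is_de"]]
        if direction == "up":
            sub = sub[sub["fold_change"] > 1]
        elif direction == "down":
            sub = sub[sub["fold_change"] < 1]
        return sub

    def status(self) -> pd.Series:
        """Per-gene label: up / down / ns."""
        t = self.table
        lab = np.where(~t["is_de"], "ns", np.where(t["fold_change"] > 1, "up", "down"))
        return pd.Series(lab, index=t["gene_id"].to_numpy())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def de_call(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fdr: float = 0.05,
    fc: float = 1.5,
    pseudocount: float = 1.0,
) -> DEResult:
    """Welch test on log2(x + pseudocount), fold change on linear means.

    A gene is differential when q < fdr and the linear fold change
    (mean_b + pc)/(mean_a + pc) exceeds fc or falls below 1/fc —
    the |FC| > 1.5 convention applied on the linear scale.
    """
    a = expr.columns_for(group_a).to_numpy(dtype=float)
    b = expr.columns_for(group_b).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(la, lb, axis=1, equal_var=False)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    # degenerate rows: zero variance in both groups
    var0 = (la.std(axis=1) == 0) & (lb.std(axis=1) == 0)
    same = var0 & (la.mean(axis=1) == lb.mean(axis=1))
    p = np.where(same, 1.0, p)
    p = np.where(var0 & ~same, 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    fold = (mean_b + pseudocount) / (mean_a + pseudocount)
    q = bh_adjust(p)
    is_de = (q < fdr) & ((fold > fc) | (fold < 1.0 / fc))
    table = pd.DataFrame({
        "gene_id": expr.genes,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold_change": fold,
        "log2fc": np.log2(fold),
        "p_value": p,
        "q_value": q,
        "is_de": is_de,
    })
    return DEResult(table, fdr, fc)


def hypergeom_enrichment(
    hits: set[str], universe: set[str], annotation: dict[str, set[str]]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of hit genes per named set.

    Gene sets are intersected with the universe first; the p-value is
    P(overlap >= observed) and q is BH across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(hits) <= set(universe):
        raise ValueError("hits must be a subset of the universe")
    M, n = len(universe), len(hits)
    rows = []
    for name, genes in annotation.items():
        inset = set(genes) & set(universe)
        k = len(inset & set(hits))
        # survival function at k-1 gives the inclusive upper tail
        p = float(sps.hypergeom.sf(k - 1, M, len(inset), n))
        rows.append((name, len(inset), k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"]) if len(df) else []
    return df
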