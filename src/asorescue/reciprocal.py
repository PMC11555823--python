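"""Cross-disorder comparison of two disease signatures.

Joins two DE tables by gene symbol, tests the significance of the
overlap of their significant gene sets with a one-sided (enrichment)
Fisher exact test, and measures directional concordance of the shared
genes' log2 fold-changes with a Pearson correlation.  The motivating
use is a gain-of-dosage signature against a loss-of-function companion
dataset, where reciprocal regulation shows up as anticorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataValidationError


@dataclass
class OverlapResult:
    n_universe: int
    n_sig_a: int
    n_sig_b: int
    n_shared: int
    fisher_p: float
    pearson_r: float
    pearson_p: float
    per_gene: pd.DataFrame  # gene, log2fc_a, log2fc_b, concordance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_universe": [self.n_universe],
                "n_sig_a": [self.n_sig_a],
                "n_sig_b": [self.n_sig_b],
                "n_shared": [self.n_shared],
                "fisher_p": [self.fisher_p],
                "pearson_r": [self.pearson_r],
                "pearson_p": [self.pearson_p],
            }
        )


def merge_by_symbol(de_a: pd.DataFrame, de_b: pd.DataFrame, case_fold: bool = False) -> pd.DataFrame:
    """Inner join of two DE tables on gene symbol.

    Gene symbols are case-sensitive by default (``case_fold=True``
    upper-cases both sides first).  Duplicate symbols in either input
    are rejected: silently aggregating them would distort the universe
    count of the overlap test.
    """
    frames = []
    for name, de in (("A", de_a), ("B", de_b)):
        t = de.copy()
        t["gene"] = t["gene"].astype(str)
        if case_fold:
            t["gene"] = t["gene"].str.upper()
        dup = t["gene"][t["gene"].duplicated()]
        if len(dup):
            raise DataValidationError(f"duplicate gene symbol(s) in table {name}: {sorted(set(dup))[:5]}")
        frames.append(t)
    a, b = frames
    joined = a.merge(b, on="gene", how="inner", suffixes=("_a", "_b"))
    return joined


def shared_signature(joined: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Genes significant in both datasets (adjusted p < alpha in each)."""
    mask = (joined["p_adj_a"] < alpha) & (joined["p_adj_b"] < alpha)
    return joined.loc[mask.fillna(False), "gene"].tolist()


def fisher_overlap(
    n_universe: int, n_sig_a: int, n_sig_b: int, n_shared: int, two_sided: bool = False
) -> float:
    """Significance of the overlap of two gene sets drawn from a common
    universe: one-sided hypergeometric enrichment tail
    P(X >= n_shared) by default, or the two-sided Fisher exact p."""
    if not (0 <= n_shared <= min(n_sig_a, n_sig_b)):
        raise DataValidationError("n_shared exceeds a margin")
    if max(n_sig_a, n_sig_b) > n_universe:
        raise DataValidationError("a margin exceeds the universe")
    if n_shared < n_sig_a + n_sig_b - n_universe:
        raise DataValidationError("counts inconsistent: overlap below its minimum")
    if n_sig_a == 0 or n_sig_b == 0:
        return 1.0
    table = [
        [n_shared, n_sig_a - n_shared],
        [n_sig_b - n_shared, n_universe - n_sig_a - n_sig_b + n_shared],
    ]
    alternative = "two-sided" if two_sided else "greater"
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def directional_correlation(
    joined: pd.DataFrame, genes: list[str] | None = None
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of the two log2 fold-change columns over a
    gene set, with per-gene concordance labels (``inverse`` when the
    signs differ).  Rows with a missing fold-change are excluded; with
    fewer than 3 usable genes the p-value is undefined (NaN)."""
    sub = joined if genes is None else joined[joined["gene"].isin(set(genes))]
    sub = sub[np.isfinite(sub["log2fc_a"]) & np.isfinite(sub["log2fc_b"])]
    if sub.empty:
        raise DataValidationError("no genes with finite fold-changes in both datasets")
    x = sub["log2fc_a"].to_numpy()
    y = sub["log2fc_b"].to_numpy()
    labels = np.where(np.sign(x) * np.sign(y) < 0, "inverse", "concordant")
    per_gene = pd.DataFrame(
        {"gene": sub["gene"].to_numpy(), "log2fc_a": x, "log2fc_b": y, "concordance": labels}
    )
    if len(sub) < 2:
        return float("nan"), float("nan"), per_gene
    r = float(np.corrcoef(x, y)[0, 1])
    if len(sub) < 3 or abs(r) == 1.0:
        p = float("nan") if len(sub) < 3 else 0.0
    else:
        t = r * np.sqrt((len(sub) - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df=len(sub) - 2))
    return r, p, per_gene


def compare_signatures(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    alpha: float = 0.05,
    case_fold: bool = False,
    universe: int | None = None,
) -> OverlapResult:
    """Full reciprocal-dysregulation analysis of two DE tables.

    The universe defaults to the joined set of genes expressed in both
    datasets; the overlap test and the correlation are computed over
    the genes significant in both at ``alpha``.
    """
    joined = merge_by_symbol(de_a, de_b, case_fold=case_fold)
    n_universe = universe if universe is not None else len(joined)
    sig_a = joined["p_adj_a"] < alpha
    sig_b = joined["p_adj_b"] < alpha
    shared = shared_signature(joined, alpha)
    p_fisher = fisher_overlap(n_universe, int(sig_a.sum()), int(sig_b.sum()), len(shared))
    if shared:
        r, p_r, per_gene = directional_correlation(joined, shared)
    else:
        r, p_r = float("nan"), float("nan")
        per_gene = pd.DataFrame(columns=["gene", "log2fc_a", "log2fc_b", "concordance"])
    return OverlapResult(
        n_universe=n_universe,
        n_sig_a=int(sig_a.sum()),
        n_sig_b=int(sig_b.sum()),
        n_shared=len(shared),
        fisher_p=p_fisher,
        pearson_r=r,
        pearson_p=p_r,
        per_gene=per_gene,
    )
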