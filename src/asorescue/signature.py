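"""Disease-signature extraction and the z-scored expression heatmap matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import CountMatrix, DataValidationError, DiseaseSignature
from .de import DEFAULT_PSEUDOCOUNT, cpm


def extract_signature(de: pd.DataFrame, alpha: float = 0.05) -> DiseaseSignature:
    """Genes with BH-adjusted p below ``alpha``; direction from the sign
    of the log2 fold-change (affected over unaffected)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if "p_adj" not in de.columns:
        raise DataValidationError("DE table lacks a p_adj column")
    hits = de[(de["p_adj"].notna()) & (de["p_adj"] < alpha) & (de["log2fc"] != 0)].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
    table = hits.loc[:, ["gene", "direction", "log2fc", "p_adj"]].reset_index(drop=True)
    return DiseaseSignature(table, alpha=alpha)


def signature_heatmap_matrix(
    counts: CountMatrix,
    design: pd.DataFrame,
    signature: DiseaseSignature,
    alpha_strict: float = 0.005,
    linkage_method: str = "average",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row-z-scored log CPM of the most significant signature genes with
    hierarchical (Euclidean) row and column orders.

    Genes are restricted to signature entries with adjusted p below
    ``alpha_strict``; a zero-variance gene gets an all-zero z-score row
    rather than being dropped, keeping the matrix aligned with the
    signature.  The column order is derived from sorted sample labels
    before clustering so the tree is invariant to input sample order.
    """
    if len(signature) == 0:
        raise DataValidationError("signature is empty")
    strict = signature.table[signature.table["p_adj"] < alpha_strict]
    genes = list(strict["gene"])
    if not genes:
        raise DataValidationError(f"no signature gene passes alpha_strict={alpha_strict}")
    log_cpm = cpm(counts, log=True, pseudocount=pseudocount).loc[genes]
    log_cpm = log_cpm.loc[:, sorted(log_cpm.columns)]
    vals = log_cpm.to_numpy()
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    z = np.divide(vals - mu, sd, out=np.zeros_like(vals), where=sd > 0)
    zmat = pd.DataFrame(z, index=log_cpm.index, columns=log_cpm.columns)

    def leaf_order(matrix: np.ndarray, labels: list[str]) -> list[str]:
        if len(labels) < 2:
            return list(labels)
        link = hierarchy.linkage(pdist(matrix, metric="euclidean"), method=linkage_method)
        return [labels[i] for i in hierarchy.leaves_list(link)]

    row_order = leaf_order(z, list(zmat.index))
    col_order = leaf_order(z.T, list(zmat.columns))
    return zmat, row_order, col_order
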