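"""Relative qPCR quantification by the delta-delta-Ct method.

Fold-change of a target transcript against a housekeeping gene and a
reference sample group, assuming perfect (two-fold per cycle)
amplification: technical replicates are averaged, delta-Ct is target
minus housekeeping per sample, delta-delta-Ct subtracts the mean
delta-Ct of the reference group, and fold-change is 2^(-ddCt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import DataValidationError

CT_COLUMNS = ("sample_id", "gene", "replicate", "ct")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise DataValidationError(f"Ct table missing columns: {missing}")
    out = table.copy()
    out["ct"] = pd.to_numeric(out["ct"], errors="raise")
    if (out["ct"] <= 0).any():
        raise DataValidationError("Ct values must be positive cycle numbers")
    return out


def ddct(
    table: pd.DataFrame,
    target: str,
    housekeeping: str,
    reference_samples: list[str],
) -> pd.DataFrame:
    """Per-sample fold-change of ``target`` relative to ``housekeeping``
    and the mean delta-Ct of ``reference_samples``.

    Returns a table with sample_id, delta_ct, delta_delta_ct and
    fold_change columns; the reference group's mean fold-change is 1 by
    construction, and a constant plate offset on every Ct cancels.
    """
    tab = validate_ct_table(table)
    if not reference_samples:
        raise DataValidationError("reference group is empty")
    means = (
        tab[tab["gene"].isin([target, housekeeping])]
        .groupby(["sample_id", "gene"], observed=True)["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in (target, housekeeping):
        if gene not in means.columns:
            raise DataValidationError(f"no Ct measurements for gene {gene!r}")
        missing = means.index[means[gene].isna()].tolist()
        if missing:
            raise DataValidationError(f"missing {gene!r} Ct for samples {missing}")
    absent = [s for s in reference_samples if s not in means.index]
    if absent:
        raise DataValidationError(f"reference samples not in Ct table: {absent}")
    delta_ct = means[target] - means[housekeeping]
    ref_mean = delta_ct.loc[reference_samples].mean()
    ddct_vals = delta_ct - ref_mean
    return pd.DataFrame(
        {
            "sample_id": means.index,
            "delta_ct": delta_ct.to_numpy(),
            "delta_delta_ct": ddct_vals.to_numpy(),
            "fold_change": np.exp2(-ddct_vals.to_numpy()),
        }
    ).reset_index(drop=True)


def simulate_ct_table(
    abundances: dict[str, dict[str, float]],
    n_replicates: int = 2,
    noise_sd: float = 0.0,
    base_cycles: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct measurements from the exponential amplification model.

    ``abundances`` maps sample_id -> {gene: relative abundance}; a
    transcript at relative abundance ``a`` crosses threshold at
    ``base_cycles - log2(a)`` cycles (perfect efficiency), plus optional
    Gaussian replicate noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample, genes in abundances.items():
        for gene, level in genes.items():
            for rep in range(1, n_replicates + 1):
                ct = base_cycles - np.log2(level)
                rows.append(
                    {
                        "sample_id": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                    }
                )
    return pd.DataFrame(rows)
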