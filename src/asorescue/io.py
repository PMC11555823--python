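"""Plain-text (TSV) readers and writers for the pipeline tables.

All result tables round-trip bit-identically for integer columns and to
12 significant digits for reals.  Counts are rows = genes with a leading
``gene`` column; the header row carries sample identifiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    DataValidationError,
    DiseaseSignature,
    SIGNATURE_COLUMNS,
    validate_design,
)

FLOAT_FORMAT = "%.12g"


def read_count_matrix(path, sep: str = "\t") -> CountMatrix:
    """Read an integer gene x sample count matrix from a delimited file.

    The first column holds gene symbols, the header row sample
    identifiers.  Duplicate identifiers and negative or non-numeric
    cells are rejected with a structured error naming the offender.
    """
    raw = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if raw.shape[1] < 1:
        raise DataValidationError(f"{path}: no columns found")
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str).tolist()
    samples = [str(c) for c in raw.columns[1:]]
    body = raw.iloc[:, 1:]
    values = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for j, col in enumerate(body.columns):
        parsed = pd.to_numeric(body[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"{path}: non-numeric count at row {i + 1} (gene {genes[i]!r}), column {samples[j]!r}"
            )
        vals = parsed.to_numpy(dtype=float)
        if np.any(vals != np.floor(vals)):
            i = int(np.flatnonzero(vals != np.floor(vals))[0])
            raise DataValidationError(
                f"{path}: non-integer count at row {i + 1} (gene {genes[i]!r}), column {samples[j]!r}"
            )
        if np.any(vals < 0):
            i = int(np.flatnonzero(vals < 0)[0])
            raise DataValidationError(
                f"{path}: negative count at row {i + 1} (gene {genes[i]!r}), column {samples[j]!r}"
            )
        values[:, j] = vals.astype(np.int64)
    return CountMatrix(genes, samples, values)


def write_count_matrix(cm: CountMatrix, path, sep: str = "\t") -> None:
    frame = cm.to_frame()
    frame.to_csv(path, sep=sep, index=True, index_label="gene")


def read_design(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a sample design table (TSV)."""
    raw = pd.read_csv(path, sep=sep, header=0)
    return validate_design(raw)


def write_design(design: pd.DataFrame, path, sep: str = "\t") -> None:
    out = validate_design(design)
    out.to_csv(path, sep=sep, index=False, na_rep="NA", float_format=FLOAT_FORMAT)


def write_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write any tabular result deterministically (column order preserved,
    floats to 12 significant digits, missing values as ``NA``)."""
    if table is None:
        raise ValueError("cannot write a null table")
    table.to_csv(path, sep=sep, index=False, na_rep="NA", float_format=FLOAT_FORMAT)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, header=0, na_values=["NA"], keep_default_na=True)


def write_signature(sig: DiseaseSignature, path, sep: str = "\t") -> None:
    write_table(sig.table, path, sep=sep)


def read_signature(path, alpha: float = 0.05, sep: str = "\t") -> DiseaseSignature:
    tab = read_table(path, sep=sep)
    return DiseaseSignature(tab.loc[:, list(SIGNATURE_COLUMNS)], alpha=alpha)


def read_external_de(
    path,
    sep: str = "\t",
    gene_col: str | None = None,
    log2fc_col: str | None = None,
    p_adj_col: str | None = None,
) -> pd.DataFrame:
    """Read an externally produced DE table (e.g. a published LOF dataset).

    Column aliases are resolved case-insensitively among common
    conventions; ``NA`` fold-changes are preserved as missing.
    """
    raw = pd.read_csv(path, sep=sep, header=0, na_values=["NA"])
    cols = {c.lower(): c for c in raw.columns}

    def pick(explicit: str | None, *aliases: str) -> str:
        if explicit is not None:
            if explicit not in raw.columns:
                raise DataValidationError(f"{path}: column {explicit!r} not found")
            return explicit
        for a in aliases:
            if a in cols:
                return cols[a]
        raise DataValidationError(f"{path}: none of columns {aliases} found")

    out = pd.DataFrame(
        {
            "gene": raw[pick(gene_col, "gene", "symbol", "gene_symbol")].astype(str),
            "log2fc": pd.to_numeric(raw[pick(log2fc_col, "log2fc", "log2foldchange", "logfc")], errors="coerce"),
            "p_adj": pd.to_numeric(raw[pick(p_adj_col, "p_adj", "padj", "adj.p.val", "fdr")], errors="coerce"),
        }
    )
    if "base_mean" in cols or "basemean" in cols:
        out["base_mean"] = pd.to_numeric(raw[cols.get("base_mean", cols.get("basemean"))], errors="coerce")
    return out
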