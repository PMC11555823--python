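"""Core data types for the dosage-rescue pipeline.

The pipeline operates on four tabular objects: an integer gene x sample
count matrix, a per-sample design table (genotype, cell line, treatment
arm, ASO sequence, dose), per-gene differential-expression results, and
the disease signature extracted from them.  All of them are thin,
validated wrappers around :class:`pandas.DataFrame` so that the rest of
the package can rely on the invariants (unique identifiers, non-negative
integer counts, canonical factor levels) having been checked once at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("unaffected", "affected")
TREATMENTS = ("naive", "scramble", "targeting")

DESIGN_COLUMNS = ("sample_id", "genotype", "cell_line", "treatment", "aso_sequence", "dose")
DE_COLUMNS = ("gene", "base_mean", "log2fc", "p_value", "p_adj")
SIGNATURE_COLUMNS = ("gene", "direction", "log2fc", "p_adj")


class DataValidationError(ValueError):
    """A structural invariant of one of the pipeline tables is violated."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen.add(v)
    if dups:
        raise DataValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw read counts.

    Parameters
    ----------
    genes
        Ordered gene symbols (unique, case-sensitive).
    samples
        Ordered sample identifiers (unique).
    counts
        Integer array of shape ``(len(genes), len(samples))`` with
        non-negative read counts.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        counts = np.asarray(self.counts)
        if counts.size == 0:
            counts = counts.reshape(len(self.genes), len(self.samples))
        if counts.shape != (len(self.genes), len(self.samples)):
            raise DataValidationError(
                f"count matrix shape {counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere((counts != np.floor(counts)) | ~np.isfinite(counts))
                g, s = bad[0]
                raise DataValidationError(
                    f"non-integer count at gene {self.genes[g]!r}, sample {self.samples[s]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            g, s = np.argwhere(counts < 0)[0]
            raise DataValidationError(
                f"negative count at gene {self.genes[g]!r}, sample {self.samples[s]!r}"
            )
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.samples, "sample identifier")
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.genes, name="gene"), columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index.astype(str)), list(frame.columns.astype(str)), frame.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.samples]
        if missing:
            raise DataValidationError(f"samples not in count matrix: {missing}")
        idx = [self.samples.index(s) for s in sample_ids]
        return CountMatrix(list(self.genes), [self.samples[i] for i in idx], self.counts[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise DataValidationError(f"genes not in count matrix: {missing[:10]}")
        idx = [pos[g] for g in gene_ids]
        return CountMatrix([self.genes[i] for i in idx], list(self.samples), self.counts[idx, :])


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a sample design table.

    Factor levels are lower-cased to canonical form; ``aso_sequence`` is
    NA for naive samples; a naive sample with a positive dose, or an
    ASO-treated sample with dose 0, violates the design contract.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DataValidationError(f"design table missing columns: {missing}")
    out = design.loc[:, list(DESIGN_COLUMNS)].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    _check_unique(out["sample_id"], "sample_id")
    for col, levels in (("genotype", GENOTYPES), ("treatment", TREATMENTS)):
        out[col] = out[col].astype(str).str.strip().str.lower()
        bad = sorted(set(out[col]) - set(levels))
        if bad:
            raise DataValidationError(f"unknown {col} level(s) {bad}; expected one of {levels}")
    out["cell_line"] = out["cell_line"].astype(str)
    out["dose"] = pd.to_numeric(out["dose"], errors="raise").astype(float)
    if (out["dose"] < 0).any():
        raise DataValidationError("negative dose in design")
    aso = out["aso_sequence"].astype(object)
    aso = aso.where(~aso.isin(["", "none", "None", "NA", None, np.nan]), other=pd.NA)
    out["aso_sequence"] = aso
    naive = out["treatment"] == "naive"
    if (naive & (out["dose"] > 0)).any():
        bad_ids = out.loc[naive & (out["dose"] > 0), "sample_id"].tolist()
        raise DataValidationError(f"naive samples must have dose 0: {bad_ids}")
    if (naive & out["aso_sequence"].notna()).any():
        bad_ids = out.loc[naive & out["aso_sequence"].notna(), "sample_id"].tolist()
        raise DataValidationError(f"naive samples must have no ASO sequence: {bad_ids}")
    dosed = out["treatment"].isin(["scramble", "targeting"])
    if (dosed & (out["dose"] <= 0)).any():
        bad_ids = out.loc[dosed & (out["dose"] <= 0), "sample_id"].tolist()
        raise DataValidationError(f"ASO-treated samples must have dose > 0: {bad_ids}")
    return out.reset_index(drop=True)


def join_counts_design(
    counts: CountMatrix, design: pd.DataFrame, require_equal: bool = False
) -> tuple[CountMatrix, pd.DataFrame]:
    """Align a count matrix with a design table on sample id.

    Returns the intersection in design order.  With ``require_equal``
    the sample sets must match exactly.
    """
    design = validate_design(design)
    in_counts = set(counts.samples)
    in_design = set(design["sample_id"])
    if require_equal and in_counts != in_design:
        raise DataValidationError(
            f"sample sets differ; only in counts: {sorted(in_counts - in_design)}; "
            f"only in design: {sorted(in_design - in_counts)}"
        )
    keep = design[design["sample_id"].isin(in_counts)].reset_index(drop=True)
    if keep.empty:
        raise DataValidationError("no overlapping samples between counts and design")
    return counts.subset_samples(list(keep["sample_id"])), keep


@dataclass
class DiseaseSignature:
    """Set of significantly dysregulated genes with direction labels."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(SIGNATURE_COLUMNS)))
    alpha: float = 0.05

    def __post_init__(self) -> None:
        missing = [c for c in SIGNATURE_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"signature table missing columns: {missing}")
        tab = self.table.loc[:, list(SIGNATURE_COLUMNS)].reset_index(drop=True).copy()
        _check_unique(tab["gene"].astype(str), "signature gene")
        bad = tab[(tab["direction"] == "up") != (tab["log2fc"] > 0)]
        if len(bad):
            raise DataValidationError(
                f"direction label inconsistent with log2fc sign for genes {bad['gene'].tolist()[:5]}"
            )
        self.table = tab

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    def __len__(self) -> int:
        return len(self.table)

    @property
    def fraction_down(self) -> float:
        return self.n_down / len(self.table) if len(self.table) else float("nan")

    def directions(self) -> pd.Series:
        return self.table.set_index("gene")["direction"]
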