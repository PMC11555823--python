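"""Count normalization and negative-binomial Wald differential expression.

Normalization uses median-of-ratios size factors (per-sample median of
count / per-gene geometric-mean reference, rescaled to geometric mean 1)
and counts-per-million.  The test is a simplified NB Wald contrast of
size-factor-normalized group means: per-gene dispersion is estimated by
method of moments from within-group residual variance, the log2
fold-change uses a 0.5 pseudocount on the normalized group means, the
standard error follows the NB variance model via the delta method, and
p-values are Benjamini-Hochberg adjusted over the tested genes.  This is
a transparent analog of the standard bulk RNA-seq GLM tools, not a
numeric replica of any of them.

Contrasts are organized into normalization batches: size factors and
dispersions are computed independently within each batch, mirroring a
scheme in which controls, the disease comparison and each genotype's
treatment comparisons are normalized separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix, DataValidationError

DEFAULT_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-6
EXPRESSION_FLOOR = 1.0  # mean normalized count required for testing


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: CountMatrix, min_positive_fraction: float = 1.0) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across samples,
    computed over genes positive in all samples.  If no gene is
    positive everywhere, pass ``min_positive_fraction < 1`` (e.g. 0.9)
    to build the reference from genes positive in at least that
    fraction of samples.
    """
    k = counts.counts.astype(float)
    if k.shape[1] == 0:
        raise DataValidationError("size factors need at least one sample")
    positive_frac = (k > 0).mean(axis=1)
    use = positive_frac >= min_positive_fraction
    if not use.any():
        raise DataValidationError(
            "no gene positive in the required fraction of samples; "
            "lower min_positive_fraction (e.g. 0.9) to use an inclusive reference"
        )
    ref_rows = k[use]
    with np.errstate(divide="ignore"):
        log_ref = np.where(ref_rows > 0, np.log(ref_rows), np.nan)
    # geometric mean over samples where the gene is observed
    gmean = np.exp(np.nanmean(log_ref, axis=1))
    factors = np.empty(k.shape[1])
    for j in range(k.shape[1]):
        ratios = ref_rows[:, j] / gmean
        ratios = ratios[ref_rows[:, j] > 0]
        if ratios.size == 0:
            raise DataValidationError(f"sample {counts.samples[j]!r} has no usable reference genes")
        factors[j] = np.median(ratios)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def cpm(counts: CountMatrix, log: bool = False, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Counts per million; the log variant returns log2(CPM + pseudocount)."""
    k = counts.counts.astype(float)
    libs = k.sum(axis=0)
    if np.any(libs <= 0):
        bad = [counts.samples[j] for j in np.flatnonzero(libs <= 0)]
        raise DataValidationError(f"zero library size for samples {bad}")
    vals = k / libs * 1e6
    if log:
        vals = np.log2(vals + pseudocount)
    return pd.DataFrame(vals, index=pd.Index(counts.genes, name="gene"), columns=counts.samples)


def normalized_counts(counts: CountMatrix, factors: pd.Series) -> np.ndarray:
    f = factors.reindex(counts.samples).to_numpy()
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise DataValidationError("size factors must be positive for all samples")
    return counts.counts.astype(float) / f


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersion(
    counts: CountMatrix,
    factors: pd.Series,
    groups: Sequence[Sequence[str]],
    floor: float = DISPERSION_FLOOR,
    shrink: bool = False,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    For each group with >= 2 replicates the within-group mean ``m`` and
    variance ``v`` contribute to the pooled moment estimator
    ``alpha = sum (n-1)(v - m) / sum (n-1) m^2``, floored at a small
    positive value.  With ``shrink=True`` the raw estimate is averaged
    on the log scale with a fitted mean-dispersion trend
    ``a0 + a1 / mean``.
    """
    y = normalized_counts(counts, factors)
    sample_pos = {s: j for j, s in enumerate(counts.samples)}
    num = np.zeros(counts.n_genes)
    den = np.zeros(counts.n_genes)
    any_replicated = False
    for grp in groups:
        idx = [sample_pos[s] for s in grp]
        n = len(idx)
        if n < 2:
            continue
        any_replicated = True
        sub = y[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (n - 1) * (v - m)
        den += (n - 1) * m**2
    if not any_replicated:
        raise DataValidationError("dispersion estimation requires a group with >= 2 replicates")
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, floor)
    alpha = np.clip(alpha, floor, None)
    if shrink:
        mean_all = y.mean(axis=1)
        ok = (mean_all > EXPRESSION_FLOOR) & (alpha > floor)
        if ok.sum() >= 10:
            x = np.column_stack([np.ones(ok.sum()), 1.0 / mean_all[ok]])
            coef, *_ = np.linalg.lstsq(x, alpha[ok], rcond=None)
            a0, a1 = max(coef[0], floor), max(coef[1], 0.0)
            with np.errstate(divide="ignore"):
                trend = np.clip(a0 + a1 / np.where(mean_all > 0, mean_all, np.inf), floor, None)
            alpha = np.exp((1 - shrink_weight) * np.log(alpha) + shrink_weight * np.log(trend))
    return pd.Series(alpha, index=counts.genes, name="dispersion")


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are ignored
    (returned as NaN, excluded from the denominator)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# the NB Wald contrast


@dataclass(frozen=True)
class ContrastSpec:
    """One differential-expression contrast within a normalization batch.

    ``numerator`` / ``denominator`` are predicates: mappings from design
    column to an allowed value or list of values; a sample belongs to
    the group if it matches every entry.
    """

    name: str
    numerator: Mapping[str, object]
    denominator: Mapping[str, object]
    batch: str = "default"
    mode: str = "group"  # "group" or "centered" (within cell-line pairing)

    def select(self, design: pd.DataFrame, which: str) -> list[str]:
        pred = self.numerator if which == "numerator" else self.denominator
        mask = np.ones(len(design), dtype=bool)
        for col, val in pred.items():
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            if col == "dose":
                allowed = [float(a) for a in allowed]
            mask &= design[col].isin(list(allowed)).to_numpy()
        ids = design.loc[mask, "sample_id"].tolist()
        if not ids:
            raise DataValidationError(f"contrast {self.name!r}: empty {which} group ({dict(pred)})")
        return ids


def _group_log_means(
    y: np.ndarray,
    idx: Sequence[int],
    alpha: np.ndarray,
    factors: np.ndarray,
    pseudocount: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean normalized count per gene and the delta-method variance of
    its log2, under Var(K/s) = mu/s + alpha*mu^2."""
    sub = y[:, idx]
    mean = sub.mean(axis=1)
    n = len(idx)
    inv_s = np.mean(1.0 / factors[list(idx)])
    var_mean = (mean * inv_s + alpha * mean**2) / n
    var_log2 = var_mean / ((mean + pseudocount) ** 2 * np.log(2) ** 2)
    return mean, var_log2


def nb_wald_test(
    counts: CountMatrix,
    factors: pd.Series,
    contrast: ContrastSpec,
    dispersions: pd.Series,
    design: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    expression_floor: float = EXPRESSION_FLOOR,
) -> pd.DataFrame:
    """NB Wald test of ``numerator`` vs ``denominator`` group means.

    Genes whose mean normalized count over the contrast's samples falls
    below ``expression_floor`` are reported with NA p-values and are
    excluded from the BH denominator.  In ``centered`` mode the log2
    fold-change is the mean of per-cell-line fold-changes over lines
    represented in both groups, absorbing baseline line differences.
    """
    num_ids = contrast.select(design, "numerator")
    den_ids = contrast.select(design, "denominator")
    if set(num_ids) & set(den_ids):
        raise DataValidationError(f"contrast {contrast.name!r}: groups overlap")
    y = normalized_counts(counts, factors)
    f = factors.reindex(counts.samples).to_numpy()
    alpha = dispersions.reindex(counts.genes).to_numpy()
    pos = {s: j for j, s in enumerate(counts.samples)}
    num_idx = [pos[s] for s in num_ids]
    den_idx = [pos[s] for s in den_ids]

    all_idx = num_idx + den_idx
    base_mean = y[:, all_idx].mean(axis=1)
    tested = base_mean >= expression_floor

    mean_n, var_n = _group_log_means(y, num_idx, alpha, f, pseudocount)
    mean_d, var_d = _group_log_means(y, den_idx, alpha, f, pseudocount)

    if contrast.mode == "centered":
        line_of = design.set_index("sample_id")["cell_line"]
        lines = sorted(set(line_of[s] for s in num_ids) & set(line_of[s] for s in den_ids))
        if not lines:
            raise DataValidationError(
                f"contrast {contrast.name!r}: centered mode needs cell lines present in both groups"
            )
        lfc = np.zeros(counts.n_genes)
        for ln in lines:
            ni = [pos[s] for s in num_ids if line_of[s] == ln]
            di = [pos[s] for s in den_ids if line_of[s] == ln]
            lfc += np.log2(y[:, ni].mean(axis=1) + pseudocount) - np.log2(y[:, di].mean(axis=1) + pseudocount)
        lfc /= len(lines)
    else:
        lfc = np.log2(mean_n + pseudocount) - np.log2(mean_d + pseudocount)

    se = np.sqrt(var_n + var_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    # t reference with residual df: the dispersion behind the SE is
    # estimated from the replicates, so normal tails are too light at
    # the study's sample sizes
    df = max(len(num_idx) + len(den_idx) - 2, 1)
    p = 2.0 * stats.t.sf(np.abs(z), df=df)
    p = np.where(tested, p, np.nan)
    p_adj = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene": counts.genes,
            "base_mean": base_mean,
            "log2fc": lfc,
            "p_value": p,
            "p_adj": p_adj,
        }
    )


def run_contrast_scheme(
    counts: CountMatrix,
    design: pd.DataFrame,
    scheme: Sequence[ContrastSpec],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_positive_fraction: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Run a list of contrasts, normalizing independently per batch.

    Size factors and dispersions for each normalization batch are
    computed on the union of the samples used by that batch's
    contrasts; each contrast's two groups act as the replicate groups
    for dispersion estimation.
    """
    results: dict[str, pd.DataFrame] = {}
    by_batch: dict[str, list[ContrastSpec]] = {}
    for c in scheme:
        by_batch.setdefault(c.batch, []).append(c)
    for batch, contrasts in by_batch.items():
        batch_samples: list[str] = []
        groups: list[list[str]] = []
        for c in contrasts:
            for which in ("numerator", "denominator"):
                grp = c.select(design, which)
                groups.append(grp)
                for s in grp:
                    if s not in batch_samples:
                        batch_samples.append(s)
        sub = counts.subset_samples(batch_samples)
        factors = size_factors(sub, min_positive_fraction=min_positive_fraction)
        disp = estimate_dispersion(sub, factors, groups)
        for c in contrasts:
            results[c.name] = nb_wald_test(sub, factors, c, disp, design, pseudocount=pseudocount)
    return results


def study_scheme(
    targeting_sequences: Sequence[str] = ("ASO1", "ASO2"),
    doses: Sequence[float] = (6.6, 20.0),
    signature_mode: str = "group",
) -> list[ContrastSpec]:
    """The study's five-normalization / eleven-contrast scheme.

    Two scramble-vs-naive negative controls (one per genotype), one
    disease-signature contrast of affected vs unaffected controls
    (naive and scramble pooled as control), and eight targeting-ASO
    vs scramble contrasts (per genotype x sequence x dose), each
    genotype's treatment contrasts sharing one normalization batch.
    """
    scheme: list[ContrastSpec] = []
    for g in ("unaffected", "affected"):
        scheme.append(
            ContrastSpec(
                name=f"scramble_vs_naive_{g}",
                numerator={"genotype": g, "treatment": "scramble"},
                denominator={"genotype": g, "treatment": "naive"},
                batch=f"ctrl_{g}",
                mode="centered",
            )
        )
    scheme.append(
        ContrastSpec(
            name="disease_signature",
            numerator={"genotype": "affected", "treatment": ["naive", "scramble"]},
            denominator={"genotype": "unaffected", "treatment": ["naive", "scramble"]},
            batch="disease",
            mode=signature_mode,
        )
    )
    for g in ("unaffected", "affected"):
        for seq in targeting_sequences:
            for dose in doses:
                scheme.append(
                    ContrastSpec(
                        name=f"{seq}_{dose:g}uM_vs_scramble_{g}",
                        numerator={
                            "genotype": g,
                            "treatment": "targeting",
                            "aso_sequence": seq,
                            "dose": dose,
                        },
                        denominator={"genotype": g, "treatment": "scramble"},
                        batch=f"aso_{g}",
                        mode="centered",
                    )
                )
    return scheme
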