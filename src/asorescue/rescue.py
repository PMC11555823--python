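"""Rescue assessment of a disease signature under dosage-lowering treatment.

Three complementary read-outs, all computed on pooled log2 CPM of the
signature genes:

* **sign-flip scoring** -- a signature gene counts as qualitatively
  rescued in a treatment arm when the log ratio of treated over
  affected-control pooled expression has the opposite sign of its
  baseline affected-over-unaffected ratio (the gene moved back toward
  control levels, with no magnitude threshold);
* **rank-order patterns** -- pooled expression in the four canonical
  groups (unaffected, treated unaffected, affected, treated affected)
  is ranked 1-4 per gene and the rank vectors are clustered; a cluster
  whose mean rank vector tracks the nominal target-gene dosage order is
  flagged dosage-consistent;
* **principal-component shift** -- PCA of all samples on the signature
  genes, each treated sample's PC score minus the mean score of its own
  cell line's untreated samples, averaged per ASO across doses, tested
  with a t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import CountMatrix, DataValidationError, DiseaseSignature
from .de import DEFAULT_PSEUDOCOUNT, cpm

CANONICAL_GROUPS = ("unaffected", "unaffected_aso", "affected", "affected_aso")
# rank of target-gene dosage in the canonical group order:
# treated unaffected < unaffected < treated affected < affected
DOSAGE_ORDER = np.array([2.0, 1.0, 4.0, 3.0])


@dataclass(frozen=True)
class GroupDef:
    """A pooled expression group: label + design predicate.  A list
    value pools all matching samples (e.g. two doses of one ASO)."""

    label: str
    predicate: Mapping[str, object]

    def select(self, design: pd.DataFrame) -> list[str]:
        mask = np.ones(len(design), dtype=bool)
        for col, val in self.predicate.items():
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            if col == "dose":
                allowed = [float(a) for a in allowed]
            mask &= design[col].isin(list(allowed)).to_numpy()
        ids = design.loc[mask, "sample_id"].tolist()
        if not ids:
            raise DataValidationError(f"group {self.label!r} matches no samples ({dict(self.predicate)})")
        return ids


def control_group(genotype: str) -> GroupDef:
    """Untreated pool of a genotype: naive plus scramble-ASO samples."""
    return GroupDef(f"{genotype}_ctrl", {"genotype": genotype, "treatment": ["naive", "scramble"]})


def targeting_group(genotype: str, aso_sequence: str, doses: Sequence[float]) -> GroupDef:
    label = f"{genotype}_{aso_sequence}" + ("" if len(doses) > 1 else f"_{float(doses[0]):g}")
    return GroupDef(
        label,
        {"genotype": genotype, "treatment": "targeting", "aso_sequence": aso_sequence, "dose": list(doses)},
    )


def pooled_group_cpm(
    counts: CountMatrix,
    design: pd.DataFrame,
    grouping: Sequence[GroupDef],
    signature: DiseaseSignature | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    stat: str = "mean_log",
) -> pd.DataFrame:
    """Pooled log2 CPM per group (columns) and gene (rows).

    ``mean_log`` (default) averages per-sample log2(CPM + pseudocount)
    over the group's samples; ``log_mean`` takes log2 of the group's
    mean CPM plus the pseudocount.
    """
    log_cpm = cpm(counts, log=(stat == "mean_log"), pseudocount=pseudocount)
    if signature is not None:
        missing = [g for g in signature.genes if g not in log_cpm.index]
        if missing:
            raise DataValidationError(f"signature genes absent from counts: {missing[:5]}")
        log_cpm = log_cpm.loc[signature.genes]
    cols = {}
    for grp in grouping:
        ids = grp.select(design)
        vals = log_cpm.loc[:, ids].mean(axis=1)
        if stat == "log_mean":
            vals = np.log2(vals + pseudocount)
        cols[grp.label] = vals
    return pd.DataFrame(cols, index=log_cpm.index)


@dataclass
class RescueReport:
    """Sign-flip rescue calls per signature gene and treatment arm."""

    per_gene: pd.DataFrame  # gene-indexed: baseline_log_ratio, ratio_<arm>, rescued_<arm>
    summary: pd.DataFrame  # arm, direction, n_genes, n_rescued, percent_rescued
    arms: list[str]
    n_baseline_sign_mismatch: int = 0

    def percent_rescued(self, arm: str, direction: str) -> float:
        row = self.summary[(self.summary["arm"] == arm) & (self.summary["direction"] == direction)]
        return float(row["percent_rescued"].iloc[0]) if len(row) else float("nan")


def sign_flip_rescue(
    pooled: pd.DataFrame,
    signature: DiseaseSignature,
    baseline: tuple[str, str] = ("affected_ctrl", "unaffected_ctrl"),
    arms: Mapping[str, str] | None = None,
) -> RescueReport:
    """Classify each signature gene as rescued or not per treatment arm.

    ``baseline`` names the (affected control, unaffected control)
    pooled columns; ``arms`` maps each treatment column to its control
    column (default: every non-baseline column against the affected
    control).  A gene is rescued in an arm when
    sign(treated - control) == -sign(affected - unaffected); percentages
    are aggregated per arm and signature direction.
    """
    num, den = baseline
    for col in (num, den):
        if col not in pooled.columns:
            raise DataValidationError(f"baseline column {col!r} missing from pooled matrix")
    if arms is None:
        arms = {c: num for c in pooled.columns if c not in (num, den)}
    directions = signature.directions()
    genes = [g for g in pooled.index if g in directions.index]
    sub = pooled.loc[genes]
    baseline_ratio = sub[num] - sub[den]
    per_gene = pd.DataFrame({"direction": directions.loc[genes], "baseline_log_ratio": baseline_ratio})
    mismatch = int(
        (
            np.sign(baseline_ratio.to_numpy())
            != np.where(per_gene["direction"].to_numpy() == "up", 1.0, -1.0)
        ).sum()
    )
    rows = []
    for arm, ctrl in arms.items():
        ratio = sub[arm] - sub[ctrl]
        rescued = np.sign(ratio) == -np.sign(baseline_ratio)
        per_gene[f"ratio_{arm}"] = ratio
        per_gene[f"rescued_{arm}"] = rescued
        for direction in ("up", "down"):
            mask = per_gene["direction"] == direction
            n = int(mask.sum())
            n_resc = int(rescued[mask].sum())
            rows.append(
                {
                    "arm": arm,
                    "direction": direction,
                    "n_genes": n,
                    "n_rescued": n_resc,
                    "percent_rescued": 100.0 * n_resc / n if n else float("nan"),
                }
            )
    return RescueReport(
        per_gene=per_gene,
        summary=pd.DataFrame(rows),
        arms=list(arms),
        n_baseline_sign_mismatch=mismatch,
    )


@dataclass
class RankPattern:
    """1-4 rank vectors of pooled expression and their clustering."""

    ranks: pd.DataFrame  # gene-indexed, canonical group columns, values 1..4
    clusters: pd.Series  # gene -> cluster id
    cluster_summary: pd.DataFrame  # cluster, n_genes, mean ranks, dosage_rho, consistency


def rank_order_patterns(
    pooled: pd.DataFrame,
    signature: DiseaseSignature,
    n_clusters: int = 6,
    dosage_rho_threshold: float = 0.8,
    linkage_method: str = "average",
) -> RankPattern:
    """Rank pooled expression 1-4 across the canonical groups per gene
    and cluster the rank vectors (Euclidean distance).

    The pooled matrix must have exactly the four canonical columns.
    Ties are broken by canonical group order (deterministic).  Each
    cluster's mean rank vector is correlated (Spearman) with the
    nominal target-gene dosage order; a cluster is dosage-consistent
    for up-signature genes when rho >= threshold and for down genes
    when rho <= -threshold.
    """
    if list(pooled.columns) != list(CANONICAL_GROUPS):
        raise DataValidationError(
            f"pooled matrix must have exactly the canonical group columns {CANONICAL_GROUPS}, "
            f"got {list(pooled.columns)}"
        )
    genes = [g for g in pooled.index if g in set(signature.genes)]
    sub = pooled.loc[genes]
    ranks = np.vstack(
        [stats.rankdata(row, method="ordinal") for row in sub.to_numpy()]
    ) if len(sub) else np.empty((0, 4))
    rank_df = pd.DataFrame(ranks, index=sub.index, columns=list(CANONICAL_GROUPS))
    if len(rank_df) < 2:
        clusters = pd.Series(np.ones(len(rank_df), dtype=int), index=rank_df.index)
    else:
        order = np.argsort(rank_df.index.to_numpy(), kind="mergesort")
        sorted_ranks = ranks[order]
        link = hierarchy.linkage(pdist(sorted_ranks, metric="euclidean"), method=linkage_method)
        assign = hierarchy.fcluster(link, t=min(n_clusters, len(rank_df)), criterion="maxclust")
        clusters = pd.Series(0, index=rank_df.index, dtype=int)
        clusters.iloc[order] = assign
    rows = []
    for cid in sorted(clusters.unique()):
        members = clusters[clusters == cid].index
        mean_ranks = rank_df.loc[members].mean(axis=0).to_numpy()
        rho = float(stats.spearmanr(mean_ranks, DOSAGE_ORDER).statistic)
        rows.append(
            {
                "cluster": int(cid),
                "n_genes": len(members),
                **{f"mean_rank_{c}": mean_ranks[i] for i, c in enumerate(CANONICAL_GROUPS)},
                "dosage_rho": rho,
                "consistent_up": rho >= dosage_rho_threshold,
                "consistent_down": rho <= -dosage_rho_threshold,
            }
        )
    return RankPattern(ranks=rank_df, clusters=clusters, cluster_summary=pd.DataFrame(rows))


def pc_shift_test(
    counts: CountMatrix,
    design: pd.DataFrame,
    signature: DiseaseSignature,
    component: int | str = "dosage",
    test: str = "two_sample",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift of treated samples along a principal component of the
    signature genes, relative to matched untreated line-mates.

    PCA is computed on gene-centered log2 CPM of all samples.  Each
    component is oriented so the affected-control group mean is
    non-negative, removing the sign ambiguity.  ``component="dosage"``
    (default) uses the component that best separates the two genotypes'
    untreated samples -- the disease axis, whose index depends on the
    gene set (it is the second component when line-to-line variability
    dominates, the first when it does not); an integer forces a
    specific component.  For every treated sample, delta = PC(sample)
    - mean PC of the untreated (naive or scramble) samples of the same
    cell line; deltas are averaged per cell line per ASO across doses
    and t-tested per (genotype, ASO): two-sample Welch against the same
    genotype's control-sample deltas (default) or one-sample against
    zero.

    Returns ``(per_sample_scores, arm_tests)``; the tests table records
    the component used.
    """
    if len(signature) == 0:
        raise DataValidationError("signature is empty")
    ids = list(design["sample_id"])
    sub = counts.subset_samples(ids)
    log_cpm = cpm(sub, log=True, pseudocount=pseudocount)
    genes = [g for g in signature.genes if g in log_cpm.index]
    x = log_cpm.loc[genes].to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    dsg = design.set_index("sample_id")
    affected_ctrl = [
        i
        for i, sid in enumerate(ids)
        if dsg.loc[sid, "genotype"] == "affected" and dsg.loc[sid, "treatment"] in ("naive", "scramble")
    ]
    unaffected_ctrl = [
        i
        for i, sid in enumerate(ids)
        if dsg.loc[sid, "genotype"] == "unaffected" and dsg.loc[sid, "treatment"] in ("naive", "scramble")
    ]
    if affected_ctrl:
        flip = np.where(scores[affected_ctrl].mean(axis=0) < 0, -1.0, 1.0)
        scores = scores * flip
    if component == "dosage":
        if affected_ctrl and unaffected_ctrl:
            sep = np.abs(
                scores[affected_ctrl].mean(axis=0) - scores[unaffected_ctrl].mean(axis=0)
            ) / (scores.std(axis=0, ddof=1) + 1e-12)
            k = int(np.argmax(sep[: min(10, scores.shape[1])]))
        else:
            k = min(1, scores.shape[1] - 1)  # no genotype contrast available
    else:
        k = int(component) - 1
    if k >= scores.shape[1]:
        raise DataValidationError(f"component {component} not available with {scores.shape[1]} samples")
    pc = pd.Series(scores[:, k], index=ids, name=f"pc{k + 1}")

    untreated = dsg["treatment"].isin(["naive", "scramble"])
    line_ctrl_mean = pc[untreated[ids].to_numpy()].groupby(dsg.loc[untreated[untreated].index, "cell_line"]).mean()
    deltas = []
    for sid in ids:
        line = dsg.loc[sid, "cell_line"]
        if line not in line_ctrl_mean.index:
            raise DataValidationError(f"sample {sid!r}: no untreated line-mates for cell line {line!r}")
        deltas.append(pc[sid] - line_ctrl_mean[line])
    per_sample = design.copy()
    per_sample["component"] = k + 1
    per_sample["pc_score"] = pc.to_numpy()
    per_sample["delta"] = deltas

    treated = per_sample[per_sample["treatment"] == "targeting"]
    ctrl = per_sample[per_sample["treatment"].isin(["naive", "scramble"])]
    rows = []
    for (genotype, seq), grp in treated.groupby(["genotype", "aso_sequence"], observed=True):
        per_line = grp.groupby("cell_line", observed=True)["delta"].mean()
        ref = ctrl.loc[ctrl["genotype"] == genotype, "delta"]
        vals = per_line.to_numpy()
        if np.allclose(vals, 0) and np.allclose(ref.to_numpy(), 0):
            p = 1.0
        elif test == "one_sample":
            p = float(stats.ttest_1samp(vals, 0.0).pvalue) if len(vals) > 1 else float("nan")
        else:
            p = float(stats.ttest_ind(vals, ref.to_numpy(), equal_var=False).pvalue)
        rows.append(
            {
                "genotype": genotype,
                "aso_sequence": seq,
                "component": k + 1,
                "n_lines": len(per_line),
                "mean_shift": float(np.mean(vals)),
                "p_value": p,
            }
        )
    return per_sample, pd.DataFrame(rows)
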