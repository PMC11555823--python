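#!/usr/bin/env python
"""Score rescue of the disease signature under targeting-ASO treatment.

Three read-outs on pooled log2 CPM of the signature genes: sign-flip
percentages per ASO sequence (doses pooled), 1-4 rank-order clustering
across the four canonical groups, and the per-sample PC2 shift relative
to matched untreated line-mates.  Writes rescue tables under
results/rescue/.
"""

from pathlib import Path

from asorescue.io import read_count_matrix, read_design, read_signature, write_table
from asorescue.rescue import (
    CANONICAL_GROUPS,
    control_group,
    pc_shift_test,
    pooled_group_cpm,
    rank_order_patterns,
    sign_flip_rescue,
    targeting_group,
)

SEQUENCES = ("ASO1", "ASO2")
DOSES = (6.6, 20.0)
OUT = Path("results/rescue")


def main() -> None:
    counts = read_count_matrix(Path("results/cohort/counts.tsv"))
    design = read_design(Path("results/cohort/design.tsv"))
    sig = read_signature(Path("results/signature/signature.tsv"))
    OUT.mkdir(parents=True, exist_ok=True)

    grouping = [control_group("affected"), control_group("unaffected")]
    for seq in SEQUENCES:
        for g in ("affected", "unaffected"):
            grouping.append(targeting_group(g, seq, DOSES))
    pooled = pooled_group_cpm(counts, design, grouping, sig)
    report = sign_flip_rescue(pooled, sig, arms={f"affected_{s}": "affected_ctrl" for s in SEQUENCES})
    write_table(report.summary, OUT / "rescue_summary.tsv")
    write_table(report.per_gene.reset_index(names="gene"), OUT / "rescue_genes.tsv")
    for _, row in report.summary.iterrows():
        print(f"sign-flip {row['arm']} ({row['direction']}): "
              f"{row['n_rescued']}/{row['n_genes']} = {row['percent_rescued']:.1f}% rescued")

    for seq in SEQUENCES:
        four = pooled.loc[:, ["unaffected_ctrl", f"unaffected_{seq}", "affected_ctrl", f"affected_{seq}"]]
        four.columns = list(CANONICAL_GROUPS)
        rp = rank_order_patterns(four, sig)
        write_table(rp.cluster_summary, OUT / f"rank_clusters_{seq}.tsv")
        cons = rp.cluster_summary
        n_cons = int(cons.loc[cons["consistent_up"] | cons["consistent_down"], "n_genes"].sum())
        print(f"rank order {seq}: {n_cons}/{int(cons['n_genes'].sum())} genes in "
              f"dosage-consistent clusters")

    per_sample, tests = pc_shift_test(counts, design, sig)
    write_table(per_sample, OUT / "pc_scores.tsv")
    write_table(tests, OUT / "pc_shift_tests.tsv")
    for _, row in tests.iterrows():
        print(f"PC{row['component']} shift {row['genotype']}/{row['aso_sequence']}: "
              f"mean {row['mean_shift']:+.2f}, p = {row['p_value']:.3g}")


if __name__ == "__main__":
    main()
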