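#!/usr/bin/env python
"""Reciprocal-dysregulation comparison against the companion dataset.

Merges the disease-signature DE table with the loss-of-function
companion table by gene symbol, tests the overlap of their significant
gene sets with a one-sided Fisher exact test, and measures the Pearson
correlation of the shared genes' fold-changes -- anticorrelation is the
reciprocity signal.  Writes overlap.tsv and shared_genes.tsv under
results/reciprocal/.
"""

from pathlib import Path

from asorescue.io import read_external_de, read_table, write_table
from asorescue.reciprocal import compare_signatures

ALPHA = 0.05
OUT = Path("results/reciprocal")


def main() -> None:
    de_a = read_table(Path("results/de/disease_signature.tsv"))
    de_b = read_external_de(Path("results/cohort/companion_de.tsv"))
    OUT.mkdir(parents=True, exist_ok=True)
    res = compare_signatures(de_a, de_b, alpha=ALPHA)
    write_table(res.to_frame(), OUT / "overlap.tsv")
    write_table(res.per_gene, OUT / "shared_genes.tsv")
    n_inv = int((res.per_gene["concordance"] == "inverse").sum())
    print(f"universe: {res.n_universe} genes expressed in both datasets")
    print(f"significant: {res.n_sig_a} (gain-of-dosage) vs {res.n_sig_b} (loss-of-function); "
          f"shared: {res.n_shared} (Fisher p = {res.fisher_p:.3g})")
    print(f"directionality: r = {res.pearson_r:.3f} (p = {res.pearson_p:.3g}); "
          f"{n_inv}/{len(res.per_gene)} shared genes inversely regulated")


if __name__ == "__main__":
    main()
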