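"""Sign-flip rescue scoring, 1-4 rank patterns and the PC-shift test."""

import numpy as np
import pandas as pd
import pytest

from asorescue.datamodel import CountMatrix, DataValidationError, DiseaseSignature
from asorescue.de import run_contrast_scheme, study_scheme
from asorescue.rescue import (
    CANONICAL_GROUPS,
    GroupDef,
    control_group,
    pc_shift_test,
    pooled_group_cpm,
    rank_order_patterns,
    sign_flip_rescue,
    targeting_group,
)
from asorescue.signature import extract_signature


def _signature(genes, lfc):
    return DiseaseSignature(
        pd.DataFrame(
            {
                "gene": genes,
                "direction": ["up" if v > 0 else "down" for v in lfc],
                "log2fc": lfc,
                "p_adj": [0.01] * len(genes),
            }
        )
    )


class TestPooledCpm:
    def test_identical_samples_pool_to_single_value(self, small_cohort):
        cm, design, _ = small_cohort
        dup = cm.subset_samples([cm.samples[0]])
        dup2 = CountMatrix(dup.genes, ["x1", "x2"], np.hstack([dup.counts, dup.counts]))
        dsn = pd.DataFrame(
            {
                "sample_id": ["x1", "x2"],
                "genotype": ["affected"] * 2,
                "cell_line": ["L1", "L1"],
                "treatment": ["naive"] * 2,
                "aso_sequence": [None] * 2,
                "dose": [0.0] * 2,
            }
        )
        pooled = pooled_group_cpm(dup2, dsn, [GroupDef("grp", {"genotype": "affected"})])
        single = pooled_group_cpm(
            dup2.subset_samples(["x1"]), dsn.iloc[:1], [GroupDef("grp", {"genotype": "affected"})]
        )
        np.testing.assert_allclose(pooled["grp"], single["grp"])

    def test_dose_pooling_is_arithmetic_mean_of_log_cpm(self, small_cohort):
        cm, design, _ = small_cohort
        one = design[(design["treatment"] == "targeting") & (design["aso_sequence"] == "ASO1")]
        lines = one["cell_line"].unique()[:1]
        sub_ids = one[one["cell_line"].isin(lines)]["sample_id"].tolist()  # one sample per dose
        from asorescue.de import cpm

        log_cpm = cpm(cm, log=True)
        pooled = pooled_group_cpm(
            cm,
            design,
            [GroupDef("pool", {"sample_id": sub_ids})],
        )
        np.testing.assert_allclose(pooled["pool"], log_cpm[sub_ids].mean(axis=1))

    def test_sample_order_invariance(self, small_cohort):
        cm, design, _ = small_cohort
        grouping = [control_group("affected"), control_group("unaffected")]
        p1 = pooled_group_cpm(cm, design, grouping)
        perm = list(reversed(cm.samples))
        p2 = pooled_group_cpm(cm.subset_samples(perm), design.iloc[::-1].reset_index(drop=True), grouping)
        pd.testing.assert_frame_equal(p1, p2)

    def test_empty_group_names_the_key(self, small_cohort):
        cm, design, _ = small_cohort
        with pytest.raises(DataValidationError, match="ghost"):
            pooled_group_cpm(cm, design, [GroupDef("ghost", {"treatment": "targeting", "dose": 99.0})])


class TestSignFlip:
    def _pooled(self):
        return pd.DataFrame(
            {
                "affected_ctrl": [5.8, 4.0],
                "unaffected_ctrl": [5.0, 4.8],
                "affected_ASO1": [5.5, 4.1],
            },
            index=["up_gene", "down_gene"],
        )

    def test_rule_application(self):
        sig = _signature(["up_gene", "down_gene"], [1.0, -1.0])
        rep = sign_flip_rescue(self._pooled(), sig, arms={"affected_ASO1": "affected_ctrl"})
        # up_gene: baseline +0.8, treatment -0.3 -> rescued
        assert bool(rep.per_gene.loc["up_gene", "rescued_affected_ASO1"])
        # down_gene: baseline -0.8, treatment +0.1 -> rescued
        assert bool(rep.per_gene.loc["down_gene", "rescued_affected_ASO1"])
        assert rep.percent_rescued("affected_ASO1", "up") == 100.0

    def test_not_rescued_when_sign_preserved(self):
        pooled = self._pooled()
        pooled.loc["up_gene", "affected_ASO1"] = 5.9  # treatment ratio +0.1
        sig = _signature(["up_gene", "down_gene"], [1.0, -1.0])
        rep = sign_flip_rescue(pooled, sig, arms={"affected_ASO1": "affected_ctrl"})
        assert not bool(rep.per_gene.loc["up_gene", "rescued_affected_ASO1"])

    def test_global_sign_flip_preserves_calls(self):
        """Negating every pooled value negates both the baseline and the
        treatment log-ratio, which leaves every rescued/not-rescued call
        unchanged (the call depends only on the XOR of the two signs)."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        pooled = pd.DataFrame(
            rng.normal(5.0, 1.0, size=(30, 3)),
            index=genes,
            columns=["affected_ctrl", "unaffected_ctrl", "affected_ASO1"],
        )
        lfc = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        sig = _signature(genes, lfc)
        rep = sign_flip_rescue(pooled, sig, arms={"affected_ASO1": "affected_ctrl"})
        rep2 = sign_flip_rescue(-pooled, sig, arms={"affected_ASO1": "affected_ctrl"})
        np.testing.assert_array_equal(
            rep.per_gene["rescued_affected_ASO1"].to_numpy(),
            rep2.per_gene["rescued_affected_ASO1"].to_numpy(),
        )

    def test_percent_equals_mean_indicator(self, small_cohort):
        cm, design, _ = small_cohort
        tables = run_contrast_scheme(cm, design, study_scheme())
        sig = extract_signature(tables["disease_signature"])
        grouping = [control_group("affected"), control_group("unaffected"),
                    targeting_group("affected", "ASO1", [6.6, 20.0])]
        pooled = pooled_group_cpm(cm, design, grouping, sig)
        rep = sign_flip_rescue(pooled, sig, arms={"affected_ASO1": "affected_ctrl"})
        for direction in ("up", "down"):
            mask = rep.per_gene["direction"] == direction
            expect = 100.0 * rep.per_gene.loc[mask, "rescued_affected_ASO1"].mean()
            assert rep.percent_rescued("affected_ASO1", direction) == pytest.approx(expect)


class TestRankPatterns:
    def _pooled4(self, rows, genes):
        return pd.DataFrame(rows, index=genes, columns=list(CANONICAL_GROUPS))

    def test_simple_ordering(self):
        pooled = self._pooled4([[1.0, 2.0, 3.0, 4.0]], ["g"])
        sig = _signature(["g"], [1.0])
        rp = rank_order_patterns(pooled, sig)
        np.testing.assert_array_equal(rp.ranks.loc["g"], [1, 2, 3, 4])

    def test_tie_broken_by_canonical_order(self):
        pooled = self._pooled4([[2.0, 2.0, 1.0, 3.0]], ["g"])
        sig = _signature(["g"], [1.0])
        rp = rank_order_patterns(pooled, sig)
        # tie between the first two groups: earlier canonical group wins the lower rank
        np.testing.assert_array_equal(rp.ranks.loc["g"], [2, 3, 1, 4])

    def test_ranks_are_permutations_and_gene_order_invariant(self, small_cohort):
        cm, design, _ = small_cohort
        tables = run_contrast_scheme(cm, design, study_scheme())
        sig = extract_signature(tables["disease_signature"])
        grouping = [control_group("unaffected"), targeting_group("unaffected", "ASO1", [6.6, 20.0]),
                    control_group("affected"), targeting_group("affected", "ASO1", [6.6, 20.0])]
        pooled = pooled_group_cpm(cm, design, grouping, sig)
        pooled.columns = list(CANONICAL_GROUPS)
        rp = rank_order_patterns(pooled, sig)
        assert (np.sort(rp.ranks.to_numpy(), axis=1) == [1, 2, 3, 4]).all()
        shuffled = pooled.iloc[::-1]
        rp2 = rank_order_patterns(shuffled, sig)
        common = rp.clusters.index
        pd.testing.assert_series_equal(rp2.clusters.loc[common], rp.clusters.loc[common])

    def test_wrong_group_count_rejected(self):
        sig = _signature(["g"], [1.0])
        bad = pd.DataFrame([[1, 2, 3]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(DataValidationError, match="canonical"):
            rank_order_patterns(bad, sig)

    def test_halfway_rescue_puts_treated_between_genotypes(self, small_cohort):
        """With treatment moving responsive genes toward baseline, the
        dominant clusters rank treated-affected between the genotypes,
        tracking the nominal target-gene dosage order."""
        cm, design, truth = small_cohort
        tables = run_contrast_scheme(cm, design, study_scheme())
        sig = extract_signature(tables["disease_signature"])
        grouping = [control_group("unaffected"), targeting_group("unaffected", "ASO1", [6.6, 20.0]),
                    control_group("affected"), targeting_group("affected", "ASO1", [6.6, 20.0])]
        pooled = pooled_group_cpm(cm, design, grouping, sig)
        pooled.columns = list(CANONICAL_GROUPS)
        rp = rank_order_patterns(pooled, sig)
        summary = rp.cluster_summary
        up_ok = summary[summary["consistent_up"]]["n_genes"].sum()
        down_ok = summary[summary["consistent_down"]]["n_genes"].sum()
        resp = truth.table[truth.table["responsive"] & (truth.table["gene_class"] != "null")]
        n_resp_in_sig = len(set(resp["gene"]) & set(sig.genes))
        assert up_ok + down_ok >= 0.7 * n_resp_in_sig


class TestPcShift:
    def test_untreated_identical_to_treated_gives_zero_shift(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(40, 4))
        counts = np.hstack([counts, counts])  # treated columns identical to untreated
        genes = [f"g{i}" for i in range(40)]
        samples = [f"c{i}" for i in range(4)] + [f"t{i}" for i in range(4)]
        cm = CountMatrix(genes, samples, counts)
        design = pd.DataFrame(
            {
                "sample_id": samples,
                "genotype": ["affected"] * 8,
                "cell_line": [f"L{i}" for i in range(4)] * 2,
                "treatment": ["scramble"] * 4 + ["targeting"] * 4,
                "aso_sequence": ["SCR"] * 4 + ["ASO1"] * 4,
                "dose": [20.0] * 8,
            }
        )
        sig = _signature(genes[:10], [1.0] * 10)
        per_sample, tests = pc_shift_test(cm, design, sig)
        treated = per_sample[per_sample["treatment"] == "targeting"]
        np.testing.assert_allclose(treated["delta"], 0.0, atol=1e-9)

    def test_orientation_deterministic_across_runs(self, small_cohort):
        cm, design, _ = small_cohort
        tables = run_contrast_scheme(cm, design, study_scheme())
        sig = extract_signature(tables["disease_signature"])
        a = pc_shift_test(cm, design, sig)
        b = pc_shift_test(cm, design, sig)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_treatment_shift_detected(self, small_cohort):
        """Treatment moves samples toward the unaffected centroid along
        the dosage component; the shift is negative and significant in
        the strong (unaffected) arm and same-signed in the affected arm."""
        cm, design, _ = small_cohort
        tables = run_contrast_scheme(cm, design, study_scheme())
        sig = extract_signature(tables["disease_signature"])
        _, tests = pc_shift_test(cm, design, sig)
        tests = tests.set_index(["genotype", "aso_sequence"])
        for seq in ("ASO1", "ASO2"):
            assert tests.loc[("unaffected", seq), "p_value"] < 0.05
            assert tests.loc[("unaffected", seq), "mean_shift"] < 0
            assert tests.loc[("affected", seq), "mean_shift"] < 0

    def test_unmatched_treated_sample_rejected(self):
        genes = ["g1", "g2", "g3"]
        counts = np.array([[10, 20], [30, 40], [50, 60]])
        cm = CountMatrix(genes, ["a", "b"], counts)
        design = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "genotype": ["affected", "affected"],
                "cell_line": ["L1", "L2"],
                "treatment": ["scramble", "targeting"],
                "aso_sequence": ["SCR", "ASO1"],
                "dose": [20.0, 20.0],
            }
        )
        sig = _signature(genes, [1.0, 1.0, -1.0])
        with pytest.raises(DataValidationError, match="L2"):
            pc_shift_test(cm, design, sig)
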