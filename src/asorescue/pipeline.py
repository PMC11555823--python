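"""End-to-end orchestration: simulate -> DE -> signature -> reciprocal
-> rescue, driven by a YAML config, with a machine-readable manifest.

A run is reconstructible from its manifest: it records the package and
library versions, the seed, every threshold used, a hash of the full
config, and per-stage gene counts (read, tested, significant, rescued).
Identical config + seed produces byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .datamodel import DataValidationError
from .de import run_contrast_scheme, study_scheme
from .io import (
    read_count_matrix,
    read_design,
    read_external_de,
    write_count_matrix,
    write_design,
    write_signature,
    write_table,
)
from .reciprocal import compare_signatures
from .rescue import (
    CANONICAL_GROUPS,
    GroupDef,
    control_group,
    pc_shift_test,
    pooled_group_cpm,
    rank_order_patterns,
    sign_flip_rescue,
    targeting_group,
)
from .signature import extract_signature
from .simulate import (
    Arm,
    CompanionConfig,
    SimulationConfig,
    simulate_companion_lof,
    simulate_dataset,
)


def simulation_config_from_dict(block: dict, seed: int | None = None) -> SimulationConfig:
    block = dict(block)
    if "arms" in block:
        block["arms"] = [
            Arm(
                treatment=a["treatment"],
                aso_sequence=a.get("aso_sequence"),
                dose=float(a.get("dose", 0.0)),
                n_replicates=int(a.get("n_replicates", 1)),
            )
            for a in block["arms"]
        ]
    if "knockdown_per_dose" in block:
        block["knockdown_per_dose"] = {float(k): float(v) for k, v in block["knockdown_per_dose"].items()}
    if "library_size_range" in block:
        block["library_size_range"] = tuple(float(v) for v in block["library_size_range"])
    if seed is not None:
        block.setdefault("seed", seed)
    return SimulationConfig(**block)


def _config_hash(config: dict) -> str:
    # identity of the analysis, not of where its outputs land
    relevant = {k: v for k, v in config.items() if k != "out_dir"}
    blob = json.dumps(relevant, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, log=print) -> Path:
    """Execute the pipeline described by ``config`` (dict or YAML path).

    Returns the output directory.  Stages run in order: simulate (if a
    ``simulation`` block is present, otherwise ``counts``/``design``
    paths are read), differential expression over the study contrast
    scheme, signature extraction, reciprocal comparison (if a
    ``companion`` block or ``external_de`` path is given) and rescue
    scoring (if a ``rescue`` block is given; otherwise the run stops
    after the signature with a message).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    out_dir = Path(config.get("out_dir", "asorescue_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "asorescue": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "seed": seed,
        "alpha": alpha,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    # ---- stage: inputs / simulation
    truth = None
    if "simulation" in config:
        sim_cfg = simulation_config_from_dict(config["simulation"], seed=seed)
        counts, design, truth = simulate_dataset(sim_cfg)
        write_count_matrix(counts, out_dir / "counts.tsv")
        write_design(design, out_dir / "design.tsv")
        write_table(truth.table, out_dir / "truth.tsv")
        manifest["stages"]["simulate"] = {
            "n_genes": counts.n_genes,
            "n_samples": counts.n_samples,
            "config": json.loads(json.dumps(asdict(sim_cfg), default=str)),
        }
        log(f"[simulate] {counts.n_genes} genes x {counts.n_samples} samples")
    elif "counts" in config and "design" in config:
        counts = read_count_matrix(config["counts"])
        design = read_design(config["design"])
        manifest["stages"]["inputs"] = {"n_genes": counts.n_genes, "n_samples": counts.n_samples}
        log(f"[inputs] read {counts.n_genes} genes x {counts.n_samples} samples")
    else:
        raise DataValidationError("config needs either a 'simulation' block or 'counts' + 'design' paths")

    # ---- stage: differential expression (11-contrast scheme)
    sequences = sorted(
        {str(s) for s in design.loc[design["treatment"] == "targeting", "aso_sequence"].dropna()}
    )
    doses = sorted({float(d) for d in design.loc[design["treatment"] == "targeting", "dose"]})
    scheme = study_scheme(targeting_sequences=sequences, doses=doses) if sequences else study_scheme([], [])
    scheme = [c for c in scheme if c.name == "disease_signature" or sequences]
    de_tables = run_contrast_scheme(counts, design, scheme)
    de_dir = out_dir / "de"
    de_dir.mkdir(exist_ok=True)
    for name, tab in de_tables.items():
        write_table(tab, de_dir / f"{name}.tsv")
    n_sig_per = {n: int((t["p_adj"] < alpha).sum()) for n, t in de_tables.items()}
    manifest["stages"]["de"] = {"n_contrasts": len(de_tables), "n_significant": n_sig_per}
    log(f"[de] {len(de_tables)} contrasts; significant genes per contrast: {n_sig_per}")

    # ---- stage: signature
    disease = de_tables["disease_signature"]
    sig = extract_signature(disease, alpha=alpha)
    write_signature(sig, out_dir / "signature.tsv")
    manifest["stages"]["signature"] = {
        "n_genes": len(sig),
        "n_up": sig.n_up,
        "n_down": sig.n_down,
        "fraction_down": sig.fraction_down if len(sig) else None,
    }
    log(f"[signature] {len(sig)} genes ({sig.n_up} up, {sig.n_down} down)")

    # ---- stage: reciprocal comparison
    external = None
    if "companion" in config:
        if truth is None:
            raise DataValidationError("companion simulation requires a simulated dataset (ground truth)")
        comp_cfg = CompanionConfig(**{**config["companion"], "seed": config["companion"].get("seed", seed + 1)})
        external = simulate_companion_lof(comp_cfg, truth)
        write_table(external, out_dir / "companion_de.tsv")
    elif "external_de" in config:
        external = read_external_de(config["external_de"])
    if external is not None:
        overlap = compare_signatures(disease, external, alpha=alpha)
        write_table(overlap.to_frame(), out_dir / "reciprocal_overlap.tsv")
        write_table(overlap.per_gene, out_dir / "reciprocal_genes.tsv")
        manifest["stages"]["reciprocal"] = {
            "n_universe": overlap.n_universe,
            "n_shared": overlap.n_shared,
            "fisher_p": overlap.fisher_p,
            "pearson_r": overlap.pearson_r,
        }
        log(
            f"[reciprocal] {overlap.n_shared} shared genes of {overlap.n_universe}; "
            f"fisher p={overlap.fisher_p:.3g}, r={overlap.pearson_r:.3f}"
        )

    # ---- stage: rescue
    if "rescue" not in config:
        log("[rescue] no 'rescue' block in config; stopping after signature extraction")
        _write_manifest(manifest, out_dir)
        return out_dir
    if len(sig) == 0:
        log("[rescue] signature is empty; writing empty rescue report")
        write_table(pd.DataFrame(columns=["arm", "direction", "n_genes", "n_rescued", "percent_rescued"]),
                    out_dir / "rescue_summary.tsv")
        _write_manifest(manifest, out_dir)
        return out_dir
    resc_cfg = config["rescue"]
    seqs = [str(s) for s in resc_cfg.get("sequences", sequences)]
    pool_doses = [float(d) for d in resc_cfg.get("doses", doses)]
    grouping: list[GroupDef] = [control_group("affected"), control_group("unaffected")]
    for seq in seqs:
        for g in ("affected", "unaffected"):
            grouping.append(targeting_group(g, seq, pool_doses))
    pooled = pooled_group_cpm(counts, design, grouping, sig)
    arms = {f"affected_{seq}": "affected_ctrl" for seq in seqs}
    report = sign_flip_rescue(pooled, sig, arms=arms)
    write_table(report.summary, out_dir / "rescue_summary.tsv")
    write_table(report.per_gene.reset_index(names="gene"), out_dir / "rescue_genes.tsv")

    rank_results = {}
    for seq in seqs:
        four = pooled.loc[:, ["unaffected_ctrl", f"unaffected_{seq}", "affected_ctrl", f"affected_{seq}"]]
        four.columns = list(CANONICAL_GROUPS)
        rp = rank_order_patterns(four, sig)
        write_table(rp.cluster_summary, out_dir / f"rank_clusters_{seq}.tsv")
        rank_results[seq] = rp
    per_sample, pc_tests = pc_shift_test(counts, design, sig)
    write_table(pc_tests, out_dir / "pc_shift_tests.tsv")
    write_table(per_sample, out_dir / "pc_scores.tsv")
    manifest["stages"]["rescue"] = {
        "arms": list(arms),
        "percent_rescued": {
            f"{row['arm']}:{row['direction']}": row["percent_rescued"] for _, row in report.summary.iterrows()
        },
        "pc_shift_p": {
            f"{row['genotype']}:{row['aso_sequence']}": row["p_value"] for _, row in pc_tests.iterrows()
        },
    }
    for _, row in report.summary.iterrows():
        log(
            f"[rescue] {row['arm']} {row['direction']}: "
            f"{row['n_rescued']}/{row['n_genes']} genes ({row['percent_rescued']:.1f}%) sign-flipped"
        )
    _write_manifest(manifest, out_dir)
    return out_dir


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def demo_config(out_dir: str = "asorescue_demo", seed: int = 1, n_genes: int = 4000) -> dict:
    """A small, complete demo configuration exercising every stage."""
    return {
        "seed": seed,
        "alpha": 0.05,
        "out_dir": out_dir,
        "simulation": {
            "n_genes": n_genes,
            "n_dosage_up": 100,
            "n_dosage_down": 200,
            "library_size_range": [2e6, 3e6],
        },
        "companion": {"inversion_fraction": 0.8, "noise_sd": 0.3},
        "rescue": {"doses": [6.6, 20.0]},
    }
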