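"""Synthetic bulk RNA-seq counts with the dosage-perturbation study design.

The generator emulates a two-genotype cohort (affected = gene-dosage
gain, unaffected control), several patient-derived cell lines per
genotype, and treatment arms of naive / scramble-ASO / targeting-ASO
samples at micromolar doses.  Counts are negative-binomial draws around
a log-linear mean:

    log2 mu = log2(library * baseline_g)
              + genotype effect + cell-line effect + treatment effect

Signature genes carry a +/- effect in the affected genotype; the
targeting ASO knocks the target gene down to a dose-dependent residual
fraction in both genotypes and moves responsive signature genes a
configured fraction of the way back toward baseline in affected lines
(and past baseline, in the opposite direction, in unaffected lines --
the aberrant response of healthy cells to depletion of the target).
Scramble arms have no treatment effect.

Cell-line variability has two parts: an idiosyncratic per-gene effect
and a line-specific loading on one shared latent expression program,
which reproduces the empirical observation that replicate samples
cluster by cell line and that line-to-line variability dominates the
first principal component.  Both parts are centered across the lines of
each genotype so the configured genotype contrast equals the realized
expected pooled contrast exactly.

Randomness is counter-based: every sample owns an independent stream
derived from the master seed and a stable hash of its identity, so
adding arms or replicates never perturbs earlier draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .datamodel import CountMatrix, DataValidationError, validate_design


@dataclass(frozen=True)
class Arm:
    """One treatment arm, applied to every cell line."""

    treatment: str  # naive | scramble | targeting
    aso_sequence: str | None = None
    dose: float = 0.0
    n_replicates: int = 1

    def label(self) -> str:
        if self.treatment == "naive":
            return "naive"
        return f"{self.treatment}_{self.aso_sequence}_{self.dose:g}"


def default_arms() -> list[Arm]:
    """Study layout: naive, scramble at the top dose, two targeting
    sequences at the two highest doses."""
    return [
        Arm("naive"),
        Arm("scramble", "SCR", 20.0),
        Arm("targeting", "ASO1", 6.6),
        Arm("targeting", "ASO1", 20.0),
        Arm("targeting", "ASO2", 6.6),
        Arm("targeting", "ASO2", 20.0),
    ]


def baseline_arms() -> list[Arm]:
    """Control-only layout (naive + scramble) used for the baseline
    disease-signature comparison."""
    return [Arm("naive"), Arm("scramble", "SCR", 20.0)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: ~12k expressed genes, four
    cell lines per genotype, 300 up / 600 down signature genes (the
    observed two-thirds-down split) with mean |log2FC| of 1, a target
    gene two-fold up in the affected genotype and knocked down to a
    35% residual at the 20 uM dose.
    """

    n_genes: int = 12000
    n_lines_per_genotype: int = 4
    arms: list[Arm] = field(default_factory=default_arms)
    n_dosage_up: int = 300
    n_dosage_down: int = 600
    effect_size_log2: float = 1.0
    effect_cv: float = 0.25  # sd of |effect| as fraction of the mean
    rescue_fraction: float = 0.7
    rescue_strength: float = 0.5  # fraction of the way back toward baseline at full dose
    aberrant_strength: float = 0.5  # unaffected response past baseline, same scale
    knockdown_per_dose: dict[float, float] = field(
        default_factory=lambda: {2.2: 0.7, 6.6: 0.5, 20.0: 0.35}
    )
    target_gene: str = "MECP2"
    target_effect_log2: float = 1.0  # two-fold up in affected
    line_sd_log2: float = 0.15
    # loading sd on the shared line-variability program; sized so that
    # line-to-line variability dominates the first principal component
    # across realizations, with the genotype/dosage axis second
    line_axis_sd: float = 0.8
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.0
    baseline_log_sd: float = 1.5
    library_size_range: tuple[float, float] = (8e6, 12e6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 3:
            raise DataValidationError("n_genes must be >= 3")
        if self.n_dosage_up + self.n_dosage_down > self.n_genes - 1:
            raise DataValidationError("more signature genes than genes available")
        if not (0.0 <= self.rescue_fraction <= 1.0):
            raise DataValidationError("rescue_fraction must lie in [0, 1]")
        if self.n_lines_per_genotype < 1:
            raise DataValidationError("need at least one cell line per genotype")
        for d, r in self.knockdown_per_dose.items():
            if not (0.0 < r <= 1.0):
                raise DataValidationError(f"knockdown residual for dose {d} must be in (0, 1]")
        for arm in self.arms:
            if arm.treatment not in ("naive", "scramble", "targeting"):
                raise DataValidationError(f"unknown treatment {arm.treatment!r}")
            if arm.treatment == "targeting" and float(arm.dose) not in {float(k) for k in self.knockdown_per_dose}:
                raise DataValidationError(f"no knockdown residual configured for dose {arm.dose}")
            if arm.n_replicates < 1:
                raise DataValidationError("replicate counts must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise DataValidationError("invalid library size range")


@dataclass
class GroundTruth:
    """Per-gene truth of a simulated cohort.

    ``table`` columns: gene, gene_class in {null, dosage_up,
    dosage_down, target}, responsive flag, effect_log2 (signed
    affected-vs-unaffected log2FC).  ``treatment_log2fc`` returns the
    expected targeting-arm effect per gene for a genotype and dose.
    """

    table: pd.DataFrame
    target_gene: str
    config: SimulationConfig

    @property
    def signature_genes(self) -> pd.DataFrame:
        return self.table[self.table["gene_class"].isin(["dosage_up", "dosage_down", "target"])]

    def dose_response_scale(self, dose: float) -> float:
        kd = self.config.knockdown_per_dose
        max_depth = 1.0 - min(kd.values())
        return (1.0 - kd[float(dose)]) / max_depth if max_depth > 0 else 0.0

    def treatment_log2fc(self, genotype: str, dose: float) -> pd.Series:
        """Expected log2 effect of a targeting arm vs same-genotype control."""
        cfg = self.config
        scale = self.dose_response_scale(dose)
        eff = self.table["effect_log2"].to_numpy().copy()
        resp = self.table["responsive"].to_numpy()
        strength = cfg.rescue_strength if genotype == "affected" else cfg.aberrant_strength
        out = np.where(resp, -strength * scale * eff, 0.0)
        is_target = (self.table["gene"] == self.target_gene).to_numpy()
        out[is_target] = np.log2(cfg.knockdown_per_dose[float(dose)])
        return pd.Series(out, index=self.table["gene"].to_numpy(), name=f"{genotype}@{dose:g}")

    def to_de_table(self) -> pd.DataFrame:
        """Idealized DE table of the disease signature (true effects,
        vanishing p for signature genes); useful as a noise-free input
        to the reciprocal comparison."""
        sig = self.table["gene_class"] != "null"
        return pd.DataFrame(
            {
                "gene": self.table["gene"],
                "base_mean": 100.0,
                "log2fc": self.table["effect_log2"],
                "p_value": np.where(sig, 1e-9, 0.5),
                "p_adj": np.where(sig, 1e-6, 0.9),
            }
        )


def _rng_for(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(key.encode()),)))


def _centered_normal(rng: np.random.Generator, sd: float, shape: tuple[int, ...], axis: int) -> np.ndarray:
    draw = rng.normal(0.0, sd, size=shape) if sd > 0 else np.zeros(shape)
    return draw - draw.mean(axis=axis, keepdims=True)


def simulate_dataset(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a synthetic cohort; identical config + seed gives identical output."""
    config.validate()
    cfg = config
    prng = _rng_for(cfg.seed, "params")

    genes = [cfg.target_gene] + [f"G{i:06d}" for i in range(1, cfg.n_genes)]
    n = cfg.n_genes

    # relative baseline abundances (log-normal); target gene pinned to a
    # comfortably expressed level so knockdown is measurable
    log_w = prng.normal(0.0, cfg.baseline_log_sd, size=n)
    log_w[0] = np.quantile(log_w, 0.85)
    w = np.exp(log_w)
    p_base = w / w.sum()

    # gene classes and effects.  Signature genes are drawn from the
    # expressed fraction of the transcriptome (expected baseline count
    # comfortably above the testing floor): a disease signature is by
    # construction a set of genes detected as expressed.
    classes = np.array(["null"] * n, dtype=object)
    classes[0] = "target"
    lo_lib = cfg.library_size_range[0]
    expressed = np.flatnonzero(p_base * lo_lib >= 20.0)
    expressed = expressed[expressed != 0]
    n_sig = cfg.n_dosage_up + cfg.n_dosage_down
    if expressed.size < n_sig:
        raise DataValidationError(
            f"only {expressed.size} expressed genes available for {n_sig} signature genes; "
            "increase n_genes or library sizes"
        )
    candidates = prng.permutation(expressed)
    up_idx = candidates[: cfg.n_dosage_up]
    down_idx = candidates[cfg.n_dosage_up : cfg.n_dosage_up + cfg.n_dosage_down]
    classes[up_idx] = "dosage_up"
    classes[down_idx] = "dosage_down"

    mags = np.abs(
        prng.normal(cfg.effect_size_log2, cfg.effect_cv * cfg.effect_size_log2, size=n)
    )
    effect = np.zeros(n)
    effect[up_idx] = mags[up_idx]
    effect[down_idx] = -mags[down_idx]
    effect[0] = cfg.target_effect_log2

    responsive = np.zeros(n, dtype=bool)
    sig_idx = np.concatenate([up_idx, down_idx])
    responsive[sig_idx] = prng.random(sig_idx.size) < cfg.rescue_fraction
    responsive[0] = True

    # cell-line structure: shared latent program + idiosyncratic effects,
    # centered within genotype.  Loadings are fixed, evenly spaced
    # normal quantiles (shuffled across lines) so every realization
    # exhibits the line-separation structure, not just on average.
    n_lines = cfg.n_lines_per_genotype
    line_axis = prng.normal(0.0, 1.0, size=n)  # the shared program
    from scipy import stats as _stats

    quantiles = cfg.line_axis_sd * _stats.norm.ppf((np.arange(n_lines) + 0.5) / n_lines)
    loadings = {g: prng.permutation(quantiles) for g in ("unaffected", "affected")}
    idio = {
        g: _centered_normal(prng, cfg.line_sd_log2, (n, n_lines), axis=1) for g in ("unaffected", "affected")
    }

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "gene": genes,
                "gene_class": classes,
                "responsive": responsive,
                "effect_log2": effect,
            }
        ),
        target_gene=cfg.target_gene,
        config=cfg,
    )

    # per-sample draws
    sample_ids: list[str] = []
    design_rows: list[dict] = []
    columns: list[np.ndarray] = []
    lo, hi = cfg.library_size_range
    for gi, genotype in enumerate(("unaffected", "affected")):
        geno_effect = effect if genotype == "affected" else np.zeros(n)
        for li in range(n_lines):
            line_id = f"{'U' if genotype == 'unaffected' else 'M'}{li + 1}"
            line_shift = loadings[genotype][li] * line_axis + idio[genotype][:, li]
            for arm in cfg.arms:
                if arm.treatment == "targeting":
                    trt = truth.treatment_log2fc(genotype, arm.dose).to_numpy()
                else:
                    trt = np.zeros(n)
                for rep in range(1, arm.n_replicates + 1):
                    sid = f"{line_id}_{arm.label()}_r{rep}"
                    rng = _rng_for(cfg.seed, sid)
                    lib = rng.uniform(lo, hi)
                    log2_rel = np.log2(p_base) + geno_effect + line_shift + trt
                    mu = lib * np.exp2(log2_rel)
                    alpha = cfg.dispersion_a0 + cfg.dispersion_a1 / np.maximum(mu, 1e-8)
                    size = 1.0 / alpha
                    prob = size / (size + mu)
                    counts = rng.negative_binomial(size, prob)
                    sample_ids.append(sid)
                    columns.append(counts)
                    design_rows.append(
                        {
                            "sample_id": sid,
                            "genotype": genotype,
                            "cell_line": line_id,
                            "treatment": arm.treatment,
                            "aso_sequence": arm.aso_sequence if arm.treatment != "naive" else None,
                            "dose": float(arm.dose),
                        }
                    )

    cm = CountMatrix(genes, sample_ids, np.column_stack(columns))
    design = validate_design(pd.DataFrame(design_rows))
    return cm, design, truth


@dataclass
class CompanionConfig:
    """How the companion loss-of-function DE table is constructed.

    A ``detect_fraction`` of the cohort's signature genes appear as
    significant in the companion dataset; of those, ``inversion_fraction``
    carry a sign-inverted true effect (the reciprocal-dysregulation
    signal) and the rest keep the original sign.  Reported fold-changes
    add Gaussian noise of ``noise_sd``; a small ``background_sig_rate``
    of null genes is significant by chance.
    """

    inversion_fraction: float = 0.8
    noise_sd: float = 0.3
    detect_fraction: float = 0.9
    background_sig_rate: float = 0.02
    seed: int = 1

    def validate(self) -> None:
        if not (0.0 <= self.inversion_fraction <= 1.0):
            raise DataValidationError("inversion_fraction must lie in [0, 1]")
        if not (0.0 <= self.detect_fraction <= 1.0):
            raise DataValidationError("detect_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise DataValidationError("noise_sd must be non-negative")


def simulate_companion_lof(config: CompanionConfig, truth: GroundTruth) -> pd.DataFrame:
    """External-style DE table (gene, log2fc, p_adj) of a companion
    loss-of-function dataset with reciprocal effects on shared genes."""
    config.validate()
    rng = _rng_for(config.seed, "companion")
    tab = truth.table
    n = len(tab)
    is_sig = (tab["gene_class"] != "null").to_numpy()
    eff = tab["effect_log2"].to_numpy()

    detected = is_sig & (rng.random(n) < config.detect_fraction)
    inverted = rng.random(n) < config.inversion_fraction
    sign = np.where(inverted, -1.0, 1.0)
    lfc = np.where(detected, sign * eff, rng.normal(0.0, 0.1, size=n))
    if config.noise_sd > 0:
        lfc = lfc + np.where(detected, rng.normal(0.0, config.noise_sd, size=n), 0.0)

    p_adj = rng.uniform(0.05, 1.0, size=n)
    p_adj[detected] = 10.0 ** rng.uniform(-6.0, np.log10(0.05), size=int(detected.sum()))
    background = ~detected & (rng.random(n) < config.background_sig_rate)
    p_adj[background] = 10.0 ** rng.uniform(-3.0, np.log10(0.05), size=int(background.sum()))

    return pd.DataFrame(
        {
            "gene": tab["gene"],
            "base_mean": 50.0,
            "log2fc": lfc,
            "p_adj": p_adj,
        }
    )


def with_overrides(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience: a copy of a config with fields replaced."""
    return replace(config, **kwargs)
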