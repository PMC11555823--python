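# Methods

This note documents the models, estimators and design choices behind
`asorescue`, and what the simulation-based validation does and does not
establish.

## The synthetic cohort

Counts for gene *g* in sample *s* are negative-binomial:

    K_gs ~ NB(mean = mu_gs, dispersion = alpha(mu_gs))
    log2 mu_gs = log2(L_s · p_g) + G_gs + C_gs + T_gs

with library size `L_s` uniform on `library_size_range` (default
8–12 M), relative baseline abundance `p_g` log-normal (sd 1.5 on the
natural-log scale), and dispersion following the standard bulk RNA-seq
trend `alpha(mu) = a0 + a1/mu` (defaults 0.01 and 1.0, i.e. a ~10 %
biological CV at high expression).

**Genotype term `G`.** A configurable number of signature genes
(default 300 up, 600 down — the two-thirds-down split observed in
gene-dosage-gain neurons) receive a signed effect in the affected
genotype with magnitudes ~N(1, 0.25²) log2 units (mean set by
`effect_size_log2`).  Signature candidates are drawn from the expressed
fraction of the transcriptome (expected baseline count ≥ 20): a disease
signature is by construction a set of genes detected as expressed, and
without this restriction the testing floor censors lowly expressed
down-regulated genes asymmetrically.  One designated target gene is
two-fold up in affected lines.

**Cell-line term `C`.** Two parts, both centered across the lines of a
genotype so that the configured genotype contrast equals the realized
expected pooled contrast exactly: (i) an idiosyncratic per-gene,
per-line effect (sd 0.15 log2); (ii) a line-specific loading on one
shared latent expression program (per-gene weights ~N(0,1)).  Loadings
are fixed, evenly spaced normal quantiles of scale `line_axis_sd`
(default 0.8) shuffled across lines, so every simulated cohort — not
just the average one — shows samples clustering by cell line with
line-to-line variability dominating the first principal component over
the signature genes, as observed in patient-derived cohorts.  Random
loadings for only four lines occasionally collapse that spread, which
would make the principal-component geometry a lottery.

**Treatment term `T`.** Scramble arms are exactly null.  Targeting
arms multiply the target gene by the dose-specific residual
(`knockdown_per_dose`, default 70 % / 50 % / 35 % remaining at
2.2 / 6.6 / 20 µM) in both genotypes.  A `rescue_fraction` (default
0.7) of signature genes is responsive: in affected lines they move
`rescue_strength` (default 0.5, i.e. halfway) of the way back toward
baseline at the top dose; in unaffected lines they move past baseline
in the opposite direction with weight `aberrant_strength` (default
0.5) — the aberrant response of healthy cells to target depletion.
The magnitude of that aberrant response is not quantified in the
motivating literature, so it is an explicit free parameter rather than
an asserted value.  Dose response scales with knockdown depth,
normalized to 1 at the deepest configured dose.

**Randomness.** Every sample owns an independent generator derived
from the master seed and a CRC of its identity, so adding arms or
replicates never perturbs existing draws, and identical seeds give
byte-identical cohorts.

The companion loss-of-function table flags a `detect_fraction` of the
signature genes as significant, inverts the sign of an
`inversion_fraction` of their true effects, and adds Gaussian noise —
the reciprocal-dysregulation structure reported when comparing
gain-of-dosage and loss-of-function models of the same gene.

What the generator does **not** emulate: read-level artifacts (GC,
mappability, gene length), correlated gene programs beyond the single
line-variability axis, compositional effects beyond the target gene's
own mass shift, batch/plate structure, and single-cell heterogeneity
within a differentiation.  Passing recovery tests therefore shows the
estimators are correct under a realistic NB generative model, not that
they are robust to every artifact of real libraries.

## Normalization and differential expression

Size factors are median-of-ratios against the per-gene geometric-mean
reference over genes positive in all samples, rescaled to geometric
mean 1 (so identical samples get factors of exactly 1 and a global
depth change is absorbed).  If no gene is positive everywhere, an
explicit fallback builds the reference from genes positive in ≥ 90 % of
samples.

The test is a deliberately transparent analog of the standard NB GLM
tools, not a numeric replica.  Per-gene dispersion is pooled method of
moments over replicate groups, `alpha = Σ(n_j−1)(v_j−m_j) / Σ(n_j−1)m_j²`,
floored at 1e−6, with optional shrinkage toward a fitted `a0 + a1/mean`
trend (off by default).  The log2 fold-change is the difference of
log2(group mean normalized count + 0.5); the pseudocount keeps zeros
finite.  The standard error comes from the delta method on
`Var(K/s) = mu/s + alpha·mu²`.  The Wald statistic is referred to a t
distribution with `n_A + n_B − 2` df rather than a normal: the
dispersion behind the SE is itself estimated from ~13 replicates at the
study's sample sizes, and the normal reference is measurably
anti-conservative there (null fraction p < 0.05 ≈ 0.076 vs ≈ 0.052 with
the t reference).  Genes whose mean normalized count over the
contrast's samples falls below 1 are reported with NA p-values and
excluded from the BH denominator.

Contrasts carry a normalization-batch label; factors and dispersions
are computed per batch on the union of that batch's samples.  The
bundled scheme mirrors the study design: scramble-vs-naive per genotype
(negative controls), one disease-signature contrast pooling naive and
scramble as controls, and ASO-vs-scramble per genotype × sequence ×
dose — five normalizations, eleven contrasts.  Treatment contrasts use
`centered` mode (mean of per-cell-line fold-changes, absorbing baseline
line differences, since both groups contain the same lines); the
disease contrast compares disjoint line sets and uses plain group
means.  Whether a line covariate can enter the disease contrast at all
is limited by that disjointness, which is why both modes are exposed.

With centered line effects, line variability inflates within-group
variance but cancels in genotype means, so the disease-contrast test is
conservative in the presence of line heterogeneity.  Type-I calibration
is therefore assessed on a null cohort with all effects and line
heterogeneity off — the exchangeability setting the test's variance
model actually assumes.

## Signature, reciprocity

The signature is `padj < alpha` (default 0.05) with direction from the
fold-change sign.  The heatmap matrix z-scores log2 CPM per gene over
samples (zero-variance genes get all-zero rows rather than being
dropped, keeping alignment) and clusters rows and columns with
Euclidean average linkage; columns are pre-sorted by label so the tree
is invariant to input order.

Reciprocal comparison joins on exact gene symbol (case folding
optional; duplicates are an error because silent aggregation would
distort the universe).  The overlap test is the one-sided
hypergeometric enrichment tail with the universe defaulting to the
joined expressed set — the universe is an explicit argument because the
choice is consequential and conventions differ.  Correlation of shared
genes' fold-changes uses Pearson r with a t-based p (NA below n = 3).

## Rescue scoring

Pooling is the arithmetic mean of per-sample log2(CPM + 0.5) over a
group's samples (mean of logs, symmetric with the log-ratio
definition; log-of-mean is available by flag).  The affected baseline
pool includes naive and scramble samples.  Sign-flip rescue is purely
qualitative, exactly the sign rule, with no magnitude threshold (an
optional minimum-magnitude filter defaults off).  Percent rescued is
reported per arm and signature direction over all signature genes with
defined pooled values.

A caveat the null calibration makes visible: when the same affected
control samples both define the signature and anchor the treatment
ratio, selection noise gives a small winner's-curse offset, so the
"pure noise" symmetry point sits a few points above 50 % rather than
exactly at it.

Rank patterns order the four canonical pools (unaffected, treated
unaffected, affected, treated affected) 1–4 per gene, ties broken by
canonical group order (deterministic; exact ties are measure-zero on
real data), and cluster the rank vectors (Euclidean, average linkage,
6 clusters by default).  A cluster is dosage-consistent when the
Spearman correlation between its mean rank vector and the nominal
target-dosage order (treated-unaffected < unaffected <
treated-affected < affected) reaches 0.8 in the direction appropriate
to the gene set; the threshold is configurable since no canonical value
exists.

The PC-shift test computes PCA on gene-centered log2 CPM of the
signature genes over all samples, orients every component so the
affected-control mean is non-negative (removing the sign ambiguity),
and measures each treated sample's score minus the mean score of its
own line's untreated samples, averaged per line per ASO across doses,
then t-tested per genotype × ASO (two-sample Welch against the same
genotype's control deltas by default; one-sample against zero
available).  The component defaults to "dosage": the component that
best separates the genotypes' untreated samples.  Over the full
signature, line variability owns PC1 and the dosage axis is PC2; over a
DE-extracted signature the extraction step selects against
high-line-variance genes (their dispersion is inflated), which shrinks
the line axis and moves the dosage axis to PC1.  Fixing the index
would make the statistic measure different things on different gene
sets; forcing a specific component remains possible via the integer
argument.

## ΔΔCt

Technical replicates are averaged; ΔCt = Ct_target − Ct_housekeeping;
ΔΔCt subtracts the reference group's mean ΔCt; fold-change = 2^(−ΔΔCt)
(perfect-efficiency assumption; efficiency-corrected variants are out
of scope).  The reference group's mean fold-change is 1 by
construction and plate-wide Ct offsets cancel exactly.

## Problem sizes used in validation

Unit tests run on 2 000-gene cohorts; calibration and recovery checks
use 5 000-gene null cohorts (8 vs 7 samples, the baseline layout after
dropping one affected naive sample) and full 12 000-gene, 48-sample
cohorts.  These sizes give the recovery statistics comfortable
Monte-Carlo margins while keeping the full suite around half a minute.

## Known limitations

* The NB Wald analog matches no external tool number-for-number; exact
  agreement with any specific GLM implementation is a non-goal.
* No independent filtering, outlier handling, or fold-change
  shrinkage; no limma-style pipeline.
* The PC-shift t-test treats per-line averaged deltas as independent
  observations; with four lines per genotype its df are small, and the
  two-sample reference absorbs only control-side variance.
* Under strong cell-line heterogeneity the disease-signature test is
  conservative by construction (see above); power, not type-I error,
  is what suffers.
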