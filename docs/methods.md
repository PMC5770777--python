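# Methods notes

This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data experiments do and do not
demonstrate.

## The synthetic cohort

The generator emulates a two-generation family study profiled for
whole-blood miRNA expression on the qPCR Ct scale.

**Pedigrees.** Nuclear families (two founders plus 1–4 children), 300
families by default (~1350 individuals). Small pedigrees keep the kinship
matrix block-diagonal, which the heritability machinery exploits. Founders
draw ages from N(66, 9²) and children from N(46, 9²), clipped at 24 years;
with family sizes 3–6 this yields a founder fraction near 0.44, matching
the older/younger cohort split such studies report. Batch is assigned
within cohort by default (the two cohorts were profiled in independent
batches, so batch and age are confounded); a flag decouples them, and the
null-calibration tests use the decoupled configuration because the
confounded one is *deliberately* not an age-null.

**Latent aging deviation.** Each individual carries a latent Δage with SD
5 years, split into a polygenic part (kinship-correlated, h² = 0.38) and an
environmental remainder. This deviation drives mortality and the trait
couplings, and feeds the miRNA panel (below), creating the causal chain
the downstream analyses assume.

**miRNA Ct values.** For miRNA *j*,

Ct_ij = baseline_j + β_j·B_i + sex_j·male_i + tech_ij + g_ij + ε_ij,

where B_i = (age_i − 55) + Δage_i + state_i is a shared "biological age"
axis, `state` ~ N(0, 12²) being panel-shared physiological/technical
variation that is independent of age. 127 of 150 miRNAs are age-affected
(β ≠ 0), 103 of those with β > 0 — expression declining with age, the
direction such panels predominantly show — and |β| uniform on 0.03–0.11
Ct/year, the range spanned by the strongest reported per-miRNA effects.
Because `state` is independent of age, the *marginal* slope of Ct on age is
exactly β_j (recovery tests are unaffected), but the shared axis caps the
best achievable clock correlation at cor(age, B) ≈ 0.72. Without it, 127
independently informative miRNAs would predict age almost perfectly
(held-out r > 0.99), which no whole-blood panel does; the 12-year SD places
held-out clock performance in the r ≈ 0.6–0.8 regime reported for real
panels. The polygenic term g has per-miRNA h² = 0.30 of the unit
genetic+environmental variance. Technical structure (batch shifts plus
linear RNA-concentration / RIN / 260/280 terms) is scaled per miRNA so that
it explains a U(0.25, 0.55) share of variance — the "20–60% for most
miRNAs" regime the QC stage is meant to remove. Values at or above Ct 27
are recorded as not expressed; with baselines U(16, 23.5) the realized
censoring rate is ~1%, loosely matching the low residual missingness such
panels report after filtering.

**mRNA, cells, sequences.** mRNA log2 values mix a Dirichlet cell-mixture
signature, three latent batch factors, and coupling terms for 30 designated
(miRNA, target) pairs — negative on the expression scale, as repression
predicts — plus unit noise. Mature-miRNA and transcript-region sequences
are uniform random with one 8mer seed-match site planted in the 3'UTR of
every coupled target; planted coordinates are returned as ground truth.

**Survival and traits.** Exponential proportional hazards with baseline
0.012/year at age 55, log-HR 0.085/year of age, 0.3 for male sex, and
0.0953 per year of latent Δage (hazard ratio 1.10), administratively
censored at 6 years — giving ~10–12% deaths, concentrated in the older
cohort. Traits are linear (binary: logistic) in age and latent Δage with
effect sizes and residual SDs set to the published association table;
treatment flags mostly follow prevalent disease. At desk scale several of
these planted trait effects are intentionally *below* detection power —
they reproduce the generating conditions, not a guaranteed positive.

**What passing tests do not show.** The generator draws miRNAs (given the
shared axis) and mRNAs with independent residuals; real panels have richer
correlation structure, amplification artifacts, and non-linear age trends.
Recovery of planted parameters here validates the estimators' correctness
and calibration, not their behavior under real-data misspecification.

## Preprocessing

QC rules run in a fixed order: limit-masking → per-miRNA 5-SD two-sided
outlier masking (statistics computed *after* limit masking, so censored
values cannot inflate the SD) → drop miRNAs expressed in < 95% of samples
(the published absolute count threshold generalized to a fraction so it
scales with cohort size) → drop samples missing > 10% of the kept panel →
fill remaining missing with the limit value. The sequence makes QC
idempotent. Technical normalization is per-miRNA least squares (batch
categorical; aliased design columns dropped with a warning). The clock
uses residuals on concentration/RIN/260-280/sex only — batch is excluded
because batch is cohort-confounded and removing it would remove age
signal — then z-scored per column (1/n variance). Cell-count imputation is
partial least squares with 10 components by default (selectable by CV; no
published value exists), reporting k-fold cross-validated r² per cell type.

## Mixed model

Kinship is the textbook recursion on the pedigree, returned on the 2φ
scale so σ²_A is the additive variance. The REML fit eigendecomposes
K = U D Uᵀ once (negative eigenvalues clipped at 0 with a warning),
rotates y and X, and profiles the restricted likelihood over h² ∈
[0, 1−10⁻⁶] with bounded scalar minimization (xatol 10⁻⁹); β and the total
variance are closed-form at each candidate. Ties at the boundary resolve
to h² = 0 (parsimony). REML rather than ML is used to match standard
variance-component practice. Wald p-values use the normal approximation;
the residual df is reported for t-based use. A flat-likelihood probe marks
fits where σ²_A and σ²_E are not separately identifiable (e.g. K = I).
Scans reuse one eigendecomposition across responses. The per-covariate
partial r² is t²/(t²+df) — the symmetric squared-partial-correlation
definition, documented here because the reported r² in such tables is
ambiguous between model directions. Family-level bootstrap (resampling
pedigrees, whose rotated blocks are cached) provides the spread of ĥ²
cheaply.

## Clock

Elastic net at α = 0.5 on standardized residuals, solved by cyclical
coordinate descent with covariance updates and an active-set loop
(convergence max|Δβ| < 10⁻⁷, 10⁵-sweep cap), warm-started along a
decreasing λ path (50 points, λ_min/λ_max = 10⁻³). λ is CV-selected by
default because a published λ value is only meaningful on its original
implementation's scale; a fixed λ (e.g. 0.2) is available for protocol
fidelity. CV folds and the discovery/replication split are pedigree-blocked
(greedy largest-first, seed-shuffled ties) so relatives never straddle a
fold or the split. Δage is exact subtraction; the Δage-vs-predicted-age
correlation is attached as a diagnostic.

## Survival and traits

Cox partial likelihood maximized by Newton–Raphson with step-halving;
Efron tie correction by default, Breslow optional; SEs from the inverse
observed information. A per-SD log-HR above 15 after convergence is
reported as monotone likelihood (perfect separation) instead of returning
an unbounded estimate. No familial frailty term is included — the mixed
model handles family structure in the linear analyses, and the Cox models
here mirror a plain `coxph`-style analysis; this omission is a known
simplification. Kaplan–Meier curves come from the product-limit estimator
(via lifelines); Δage tertiles are sample-quantile cuts with boundary ties
going down. Trait associations fit Δage as the response with the trait
tested, adjusting for age, sex and BMI (BMI dropped when it is the trait),
excluding treated individuals per trait (antihypertensive / lipid /
diabetes treatment for continuous traits; the matching treatment for
prevalent hypertension/diabetes; no exclusion for CHD), Bonferroni at
0.05/(traits tested).

## Coexpression, targets, enrichment

Surrogate variables are the top left-singular vectors of the
covariate-residualized mRNA matrix — a deliberate simplification of
permutation-based SV dimension selection — retained only if associated
with ≥ 1 miRNA at 0.05/n_mirna. mRNA is the response in each pairwise fit
(the direction is otherwise arbitrary); the miRNA enters as a fixed
effect; BH FDR is applied across all pairs; the expression-scale sign
flips the Ct-scale sign. Seed sites: seed = miRNA positions 2–8,
sense-strand scanning only, each position classified once under the most
specific type (8mer ⊃ 7mer-m8 / 7mer-A1 ⊃ 6mer), 0-based half-open
coordinates; context++-style scoring is out of scope. Per-region counts
are reported and aggregation to a target call (≥ 1 site in any region) is
a separate helper, since how overlapping regions should be pooled is a
user decision. The hypergeometric upper tail is computed in log space so
p-values far below float underflow remain exact in magnitude; Fisher
enrichment is the one-sided exact test per category with BH across
categories.

## Problem sizes and numerical tolerances

Recovery experiments use ~450 families (~2000 individuals): heritability
recovery (generating h² = 0.38) is averaged over 8 independent cohort
replicates because a single cohort of this size carries an ĥ² sampling SD
of ~0.05; Cox CI coverage uses 500 replicates and reports the log-scale
mean HR across them; the differential-expression recovery plants
0.07 Ct/year on a 30-miRNA panel. Clock and replication checks run at the
default 300-family scale. Coexpression scans in tests cover the planted
pairs plus random null pairs rather than the full grid — the estimator is
identical per pair, so the subset only bounds runtime, not validity.
Oracle equivalences are asserted at: REML vs. dense grid (h² step 10⁻⁴,
log-likelihood within 10⁻⁶), Cox vs. partial-likelihood grid (2×10⁻⁴ in
log-HR), elastic net vs. OLS/soft-threshold closed forms (10⁻⁶/10⁻¹⁰),
seed sites and hypergeometric tails exactly.

## Known limitations

- Single random effect; no SNP-based relationship matrices, no GWAS.
- The Cox model ignores residual familial correlation (no frailty).
- SV estimation is SVD-based, not the full permutation procedure.
- The generator's independence assumptions (see above) make power
  estimates optimistic relative to real panels at equal n.
- Measured Δage is a noisy proxy of the latent deviation; its downstream
  associations (heritability, hazard) are attenuated at desk scale — the
  recovery experiments therefore target the latent quantities the
  generator planted.
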