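# Methods

`cardiomr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics: per-SNP associations with an exposure
(γ̂ⱼ, σ_γⱼ) and with an outcome (Γ̂ⱼ, σ_Γⱼ), measured in two
non-overlapping samples, are combined into an estimate of the causal
effect θ of the exposure on the outcome. The package was built around the
design of MR studies of glycemic traits (composite insulin resistance,
fasting insulin, HbA1c, fasting glucose) on left-ventricular structure and
function, but every component is generic.

## Model and assumptions

Each SNP j is assumed to satisfy, at the summary level,

    Γⱼ = θ γⱼ + αⱼ

where αⱼ is a horizontal-pleiotropy (direct) effect. A SNP is a *valid*
instrument when (1) it associates with the exposure, (2) it is independent
of exposure–outcome confounders, and (3) αⱼ = 0. The estimators differ in
how much of assumption (3) they relax:

* **Wald ratio** (single SNP): θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ, SE σ_Γⱼ/|γ̂ⱼ| by the
  first-order delta method (exposure uncertainty ignored — the "no
  measurement error" approximation appropriate for genome-wide-significant
  instruments).
* **IVW**: inverse-variance-weighted mean of the ratios with weights
  wⱼ = γ̂ⱼ²/σ_Γⱼ²; algebraically identical to weighted least squares of
  Γ̂ on γ̂ through the origin. The *multiplicative random-effects* variant
  (the primary analysis) inflates the fixed-effect SE by
  max(1, √(Q/(J−1))), so it never undercuts the fixed-effect SE. Requires
  all instruments valid, or pleiotropy balanced with mean zero.
* **MR-Egger**: weighted regression of Γ̂ on γ̂ *with* an intercept after
  orienting every SNP to γ̂ⱼ ≥ 0. Under InSIDE (instrument strength
  independent of direct effects) the slope is consistent for θ even when
  all instruments are invalid, and the intercept estimates the mean
  directional pleiotropy. Inference is t-based on J−2 df; the same
  multiplicative over-dispersion floor is applied.
* **Weighted median**: the 0.5-quantile of the ratio estimates under
  inverse-variance weights, interpolated across order statistics; a single
  SNP holding a strict weight majority is returned directly. Consistent
  whenever valid instruments carry more than half of the total weight,
  regardless of the pleiotropy pattern of the rest. SE by seeded
  parametric bootstrap (default 1000 draws of γ̂ⱼ*, Γ̂ⱼ* from normals at
  their reported SEs).
* **Cochran's Q**: heterogeneity of the ratio estimates. The first-order
  weights above understate exposure uncertainty, so the default "modified"
  variant solves wⱼ = 1/(σ_Γⱼ²/γ̂ⱼ² + θ̂²σ_γⱼ²/γ̂ⱼ²) jointly with θ̂ by
  fixed-point iteration (convergence tolerance 1e-12, max 50 iterations).
  Both schemes are exposed because the literature uses both.
* **Leave-one-out**: J random-effects IVW refits, each omitting one SNP;
  an influence diagnostic, emitted as a table.
* **MR-PRESSO**: the observed weighted residual sum of squares
  RSS = Σⱼ wⱼ(Γ̂ⱼ − θ̂₍₋ⱼ₎γ̂ⱼ)², with leave-one-out slopes θ̂₍₋ⱼ₎ and
  wⱼ = 1/σ_Γⱼ², is compared against a parametric-bootstrap null built by
  redrawing Γⱼ* ~ N(θ̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ²) and γⱼ* ~ N(γ̂ⱼ, σ_γⱼ²) (default
  1000 draws, add-one-smoothed empirical p). Per-SNP squared residuals are
  compared to their own simulated distributions with Bonferroni correction
  (α/J); flagged SNPs are removed and IVW recomputed. Two deliberate
  simplifications, chosen for determinism and speed: simulated datasets
  are scored with the *observed* leave-one-out slopes rather than slopes
  re-estimated per simulated dataset, and the distortion test compares the
  observed raw-vs-corrected shift against removals of random subsets of
  the same size. Requires J ≥ 4 and at least half of the SNPs valid.

### Multivariable MR

With K exposures, weighted multivariate regression of Γ̂ on the J×K matrix
of exposure associations without an intercept (weights 1/σ_Γⱼ²) estimates
each exposure's *direct* effect conditional on the others. The instrument
is the de-duplicated, LD-clumped union of the per-exposure instruments;
every SNP must have a measured association with every exposure at any
p-value, which is why assembly consumes full summary tables. Residual df
is J−K (J−K−1 with the Egger intercept); over-dispersion is floored at 1
as in the univariable case. The Egger variant orients SNPs so the
first-listed (primary) exposure's betas are non-negative. The
weighted-median extension is realized as weighted-L1 (median quantile)
regression on the 1/σ_Γ-scaled design with bootstrap SEs — the univariable
weighted median generalizes in more than one way, and the L1 construction
is the one that reduces exactly to a weighted median in one dimension; it
is cross-checked against MV-IVW on clean data in the test suite. An
all-zero exposure column is dropped from the fit (reducing to the nested
model) rather than raised as collinearity; genuinely rank-deficient
designs are an error.

Bidirectional analysis runs the univariable suite A→B with A's instruments
and B→A with B's; one-way causation shows a non-null forward estimate and
a reverse CI covering zero.

## Harmonization

Both studies' records for each shared SNP are aligned to the exposure's
effect allele. Non-palindromic variants align directly or after strand
complementation, negating the outcome beta (and complementing its allele
frequency) when effect/other labels are exchanged; irreconcilable allele
pairs are dropped. Palindromic variants (A/T, C/G) carry no strand
information in their letters, so orientation comes entirely from allele
frequency: the SNP is retained only if both studies report a frequency,
both minor-allele frequencies are below the threshold (default 0.3), and
then the outcome record is flipped exactly when the two effect-allele
frequencies fall on opposite sides of 0.5. Missing frequency on a
palindromic SNP drops it — the rule cannot be evaluated. The MAF condition
is applied to *both* studies (the conservative reading; applying it to one
side only would admit ambiguous SNPs whose other-study frequency is near
0.5).

## Instruments

* Genome-wide selection keeps SNPs with p strictly below the threshold
  (default 5×10⁻⁸); the boundary value is excluded.
* LD clumping is greedy: the smallest-p unclaimed SNP indexes a clump and
  removes unclaimed SNPs on the same chromosome within the window
  (default 10,000 kb, centre-to-centre) with r² ≥ the threshold (default
  0.001). Ties on p break lexicographically by rsid, making the result
  independent of input order. LD is consumed as a precomputed symmetric
  r² table; absent pairs count as r² = 0. No reference-panel computation
  is attempted.
* The composite insulin-resistance exposure meta-analyses, per SNP, the
  absolute standardized effects on fasting insulin (BMI-adjusted),
  triglycerides and HDL-C, after orienting all three to the
  insulin-raising allele: β_IR = Σwₜ|βₜ*|/Σwₜ, se_IR = (Σwₜ)^(−1/2) with
  wₜ = 1/seₜ*². Standardization defaults to the summary-data
  approximation βₜ* = zₜ/√nₜ, seₜ* = 1/√nₜ (zₜ = βₜ/seₜ), which needs no
  individual-level input; per-trait SDs may be supplied instead. The
  resulting per-SNP effect is non-negative by construction and carries
  "per 1-SD composite IR" units.
* Every filter (selection, clumping, named exclusion lists, removal of
  SNPs genome-wide associated with the outcome) appends a
  (filter, removed-SNPs) provenance entry, so retained ∪ removed always
  reconstructs the input and sensitivity families (e.g. 52 → 51/46/43/28/20)
  are auditable.

## Synthetic data generator

The generator works at the summary level: true effects γⱼ ~ N(μ_γ, σ_γ²)
(default 0.3, 0.1 — strong instruments, as genome-wide-significant SNP
sets are), pleiotropy αⱼ added directly to Γⱼ in four modes (none;
balanced N(0, σ_α); directional N(μ_α, σ_α); InSIDE-violating with
correlation ρ between αⱼ and γⱼ), an `invalid_fraction` controlling how
many SNPs receive a direct effect, and observed betas adding noise with
SEs 1/√n under unit trait variance (defaults n_exp = 100,000,
n_out = 17,000 — consortium-scale exposure GWAS against a cardiac-MRI-scale
outcome GWAS). Allele dressing (random pairs, strand complements,
effect/other swaps, palindromic variants) exercises harmonization
end-to-end; the `truth` payload carries the aligned arrays so estimator
studies can bypass table plumbing. Everything is reproducible from the
config seed.

What the generator does **not** emulate: individual-level genotypes, LD
structure among instruments (LD enters only as toy r² tables for clumping
logic), sample overlap between the two studies, winner's-curse selection
of instruments, allele-frequency-dependent SEs, and non-normal effect
distributions. Passing calibration on these simulations therefore
demonstrates the estimators' correctness under their own model, not
robustness to those real-data complications.

## Calibration experiments and the quantities reported

`calibration_experiment` and `scripts/acceptance.py` recompute, from
scratch at fixed design points: the IVW/WLS oracle agreement (1000 random
instances); the closed-form Wald and composite-meta examples; the type-I
error of random-effects IVW under θ = 0, J = 50, balanced pleiotropy
(σ_α = 0.02, 2000 replicates); Egger-intercept recovery of a planted
μ_α = 0.05 (2000 replicates); the weighted-median bias with half the
J = 100 instruments carrying large balanced pleiotropy (σ_α = 0.1, 500
replicates); 95% CI coverage for univariable IVW (θ = 0.3, 1000
replicates) and for both exposures of a K = 2 MVMR with
exposure correlation 0.5 and θ = (0.3, −0.1) (1000 replicates); MR-PRESSO
detection of a planted 10-SE outlier and its null global-test level (200
replicates each); the instrument bookkeeping counts; and the Bonferroni
threshold 0.05/20 = 0.0025.

The half-invalid weighted-median condition deliberately uses *balanced*
large pleiotropy: at exactly 50% invalid instruments the estimator's
validity boundary is reached, and under one-sided (directional) direct
effects of that prevalence no median-type estimator is consistent — the
majority-of-weight guarantee is the estimator's actual contract.
Directional-pleiotropy robustness is asserted separately at 30% invalid,
the regime the method was designed for, where the weighted median must be
(and is) markedly less biased than IVW.

## Numerical choices

* 95% CIs are Wald-type, ±1.959964·SE; Egger and MVMR-Egger use t
  quantiles on their residual df.
* p-values: normal for IVW and weighted median, t for Egger slopes and
  intercepts, χ² for Q, add-one-smoothed empirical for MR-PRESSO.
* Over-dispersion scales are floored at 1 everywhere (never below the
  homoskedastic model).
* Significance tiers: p < α/n_tests "significant" (strict inequality;
  p equal to the threshold is marginal), p < α "marginal", else "null";
  defaults α = 0.05, n_tests = 20 (a 4-exposure × 5-outcome grid),
  n_tests configurable because the size of the inspection family is a
  study-level decision.
* p-values of exactly 0 in input files are clamped to the smallest
  positive double with a warning; table writes use 17 significant digits
  so write→read round-trips are bit-exact.
* All randomness (bootstraps, PRESSO simulations, generators, pipeline
  cells) flows through `numpy.random.default_rng` seeds spawned from one
  run-level `SeedSequence`, recorded in the report manifest.

## Limitations

* Weak-instrument behaviour: first-order ratio SEs and the
  no-measurement-error approximation degrade when γ̂/σ_γ is small; the
  modified Q option mitigates this for heterogeneity testing but the
  estimators assume strong instruments.
* The MVMR weighted median is an L1 approximation; other generalizations
  exist and can differ under heavy contamination.
* Binary outcomes are handled on the log-odds scale with exponentiated
  reports; no correction for non-collapsibility is attempted.
* Matching between studies is by rsid only — no positional liftover, no
  proxy-SNP search for instruments missing from an outcome GWAS (they are
  reported and dropped), no multi-allelic handling.
* LD clumping requires a user-supplied r²/position table; the package
  never computes LD from genotypes.
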