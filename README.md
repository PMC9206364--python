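# cardiomr

Two-sample Mendelian randomization (MR) from GWAS summary statistics,
built for studies of glycemic traits — a composite insulin-resistance (IR)
exposure, fasting insulin, HbA1c, fasting glucose — on left-ventricular
structure and function, and usable for any summary-level MR analysis.

MR treats genetic variants as instrumental variables: given per-SNP
associations with an exposure (γ̂ⱼ, σ_γⱼ) and with an outcome
(Γ̂ⱼ, σ_Γⱼ) from two non-overlapping samples, the model
Γⱼ = θγⱼ + αⱼ identifies the causal effect θ when the direct
(pleiotropic) effects αⱼ vanish — or under weaker conditions that the
sensitivity estimators relax. The package provides:

* **gwas_io** — validated TSV summary-statistics I/O with column mapping
  for consortium dialects (`cardiomr.io`);
* **instruments** — genome-wide selection (p < 5×10⁻⁸), greedy LD
  clumping (r² < 0.001, 10,000 kb window), named exclusion lists with
  full filter provenance, removal of SNPs genome-wide associated with the
  outcome, and the composite IR exposure: per SNP, a fixed-effect
  inverse-variance meta-analysis of the absolute standardized effects on
  fasting insulin (BMI-adjusted), triglycerides and HDL-C, oriented to
  the insulin-raising allele (`cardiomr.instruments`);
* **harmonization** — effect-allele alignment with strand-complement
  resolution and the palindromic-SNP rule (aligned by allele-frequency
  agreement when both minor-allele frequencies < 0.3, otherwise dropped)
  (`cardiomr.harmonize`);
* **estimators** — Wald ratio, fixed/multiplicative-random-effects IVW,
  MR-Egger with intercept test, weighted median with bootstrap SE,
  first-order and modified Cochran's Q, leave-one-out, MR-PRESSO
  (global/outlier/distortion), Bonferroni significance tiers
  (`cardiomr.estimators`);
* **mvmr** — multivariable IVW/Egger/weighted-median for joint exposures
  (e.g. IR + HbA1c), union-instrument assembly with the same bookkeeping,
  and bidirectional univariable analysis (`cardiomr.mvmr`);
* **synthetic data** — a seeded summary-level generator with configurable
  horizontal pleiotropy (none/balanced/directional/InSIDE-violating),
  realistic allele coding including strand flips and palindromes, and
  calibration experiments (`cardiomr.simulate`);
* **pipeline** — the exposure × outcome grid, sensitivity-subset
  families, deterministic report rendering, plus a thin `cardiomr` CLI
  (`cardiomr.pipeline`, `cardiomr.cli`).

## Worked example

`examples/01_simulate_and_estimate.py` simulates 50 SNPs instrumenting an
exposure with true effect θ = 0.3 (10% palindromic variants, random
outcome-side allele recoding), harmonizes the two tables and runs the full
univariable toolbox:

```
harmonized 48 of 50 SNPs; actions: {'kept': 31, 'flipped': 16,
  'palindromic_aligned': 1, 'dropped_palindromic': 2}
IVW (random effects): +0.2964 [+0.2893, +0.3035], p = 0.00e+00
weighted median:      +0.2956 [+0.2855, +0.3056]
MR-Egger slope:       +0.2831 [+0.2565, +0.3097]
MR-Egger intercept:   +0.00423 (p = 0.300) -> no directional pleiotropy expected
modified Cochran's Q: 41.9 on 47 df (p = 0.684)
MR-PRESSO global p:   0.634, outliers: none
```

Two palindromic SNPs with ambiguous frequencies were excluded and sixteen
outcome records were sign-flipped back onto the exposure's effect allele;
every estimator's CI covers the true θ = 0.3, the Egger intercept is
compatible with zero and neither heterogeneity nor outlier diagnostics
fire — exactly what a clean (pleiotropy-free) instrument should produce.
The other examples cover the instrument-subset sensitivity family
(52/51/46/43/28/20 SNPs), multivariable MR, the full grid pipeline with
Bonferroni tiering, and composite-exposure construction.

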