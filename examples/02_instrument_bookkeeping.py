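"""Instrument construction and the sensitivity-subset family.

Builds the demonstration composite-insulin-resistance workflow: a 53-SNP
instrument of which one SNP is absent from the outcome GWAS, named
exclusion lists (weak component / BMI / lipids / confounders) and an LD
table, then derives the 52/51/46/43/28/20-SNP subset family and estimates
the causal effect under each subset.  Stable estimates across subsets argue
against confounding by any single excluded pathway.
"""

import warnings

from cardiomr import (
    AnalysisConfig,
    ExposureSpec,
    InstrumentSet,
    OutcomeSpec,
    build_instrument_family,
    extract_for_instruments,
    make_bookkeeping_fixture,
    run_sensitivity_family,
)

fx = make_bookkeeping_fixture(seed=0, theta=0.4)
found, missing = extract_for_instruments(fx.instrument.rsids, fx.outcome_table)
print(f"instrument SNPs: {len(fx.instrument)}; extractable from outcome: "
      f"{len(found)} (missing: {missing})")

base = InstrumentSet("IR-52", found.rsids)
pvals = dict(zip(fx.exposure_table.data["rsid"], fx.exposure_table.data["pvalue"]))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # one exclusion names the missing SNP
    family = build_instrument_family(base, fx.exclusions, ld=fx.ld, pvals=pvals)
print("subset family sizes:", sorted((int(k) for k in family), reverse=True))

config = AnalysisConfig(exposures=[], outcomes=[], methods=("ivw_random",), seed=5)
table = run_sensitivity_family(
    ExposureSpec("IR", fx.exposure_table, base),
    [OutcomeSpec("LV-parameter", fx.outcome_table)],
    family,
    config,
)
print("\nIVW estimate per instrument subset (true effect = 0.4):")
for row in table.sort_values("subset", key=lambda s: s.astype(int),
                             ascending=False).itertuples():
    print(f"  {row.subset:>3} SNPs: {row.estimate:+.3f} "
          f"[{row.ci_low:+.3f}, {row.ci_high:+.3f}]")
print("\nestimates stay mutually consistent across subsets, as they should "
      "when no excluded SNP group drives the result.")
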