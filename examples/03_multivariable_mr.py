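"""Multivariable MR: direct effects of two correlated exposures.

Simulates 100 SNPs acting on two exposures correlated at r = 0.5 with true
direct effects theta = (+0.3, -0.1) on the outcome, then fits the
multivariable IVW, Egger and weighted-median-style estimators.  Each
exposure's estimate is its effect *conditional on* the other — the reason
this design can separate insulin resistance from glycemic level when both
are instrumented by overlapping SNP sets.
"""

from cardiomr import (
    SimulationConfig,
    mvmr_egger,
    mvmr_ivw,
    mvmr_median,
    simulate_multivariable,
)

study = simulate_multivariable(
    SimulationConfig(J=100, theta=(0.3, -0.1), exposure_correlation=0.5, seed=8)
)
inp = study.mvmr_input()
print(f"{inp.J} SNPs, {inp.K} exposures; true direct effects (+0.3, -0.1)\n")

for fit in (mvmr_ivw(inp), mvmr_egger(inp), mvmr_median(inp, n_boot=200, seed=9)):
    print(fit.method)
    for exposure, res in fit.results.items():
        print(f"  {exposure}: {res.estimate:+.4f} "
              f"[{res.ci_low:+.4f}, {res.ci_high:+.4f}], p = {res.pvalue:.2e}")
    if fit.intercept is not None:
        print(f"  intercept: {fit.intercept.estimate:+.5f} "
              f"(p = {fit.intercept.pvalue:.3f})")
print("\nall three methods should recover both signs and magnitudes; the "
      "Egger intercept should be compatible with zero (no pleiotropy "
      "simulated).")
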