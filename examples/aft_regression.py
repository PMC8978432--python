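"""Covariate effects on both gap types via the AFT model.

Fits log X0 = g1 + A'beta1 + e1, log Y0 = g2 + A'beta2 + e2 by the
smooth U-statistic method (default) and the rank-based method, and
prints Wald summaries.  exp(beta) is a gap-time ratio: exp(0.5) = 1.65
means 65% longer gaps per unit of covariate.
"""

from altrec import (
    RegressionSpec,
    SimulationScenario,
    fit_aft,
    sim_bivariate_recurrent,
    summarize,
)

table = sim_bivariate_recurrent(SimulationScenario(seed=42))
# data were generated with beta1 = (0.5, 0.5), beta2 = (0, -0.5)

lee = fit_aft(RegressionSpec(table, ["a1", "a2"], method="lee", seed=1))
print("smooth U-statistic method:")
print(summarize(lee).round(3).to_string())

chang = fit_aft(
    RegressionSpec(table, ["a1", "a2"], method="chang", n_resample=50, seed=1)
)
print("\nrank-based method (resampling variance, 50 replicates):")
print(summarize(chang).round(3).to_string())

print(
    "\nBoth methods should recover the generating coefficients within "
    "sampling error;\nthe smooth method is the recommended default (fast, "
    "unique root)."
)
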