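"""Finalize thermal traits from replicated observations and evaluate the TPC.

The curve maps water temperature to survivorship in [0, 1]: a slow Gaussian
rise below the optimum, a rapid parabolic drop above it, zero outside the
critical window.
"""

import numpy as np

import thermoscape as ts

truth = ts.NicheConfig().truth("Salmo synthetica")
observations = ts.generate_traits(truth, n_obs_per_trait=5, obs_noise_C=0.5, seed=1)

print("replicated laboratory observations (head):")
print(observations.head(6).to_string(index=False))

# narrowest-window aggregation: max of CTmin observations, min of CTmax
adult = ts.finalize_traits(observations, "Salmo synthetica", "adult")
print(
    f"\nfinal adult traits: CTmin={adult.ct_min:.2f}, "
    f"Topt={adult.t_opt:.2f}, CTmax={adult.ct_max:.2f} degC"
)

tpc = ts.TPC(adult)
for temp in (adult.ct_min, 8.0, adult.t_opt, 20.0, adult.ct_max, 30.0):
    print(f"  survivorship at {temp:5.1f} degC: {ts.tpc_evaluate(tpc, temp):.3f}")

# a year at a seasonal site: the monthly series drives all later summaries
months = np.arange(1, 13)
temps = 12 + 8 * np.cos(2 * np.pi * (months - 7) / 12)
rates = ts.performance_series(tpc, temps)
print("\nmonthly survivorship at a seasonal NH site (Jan..Dec):")
print("  " + " ".join(f"{r:.2f}" for r in rates))
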