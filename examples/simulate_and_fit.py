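"""Simulate a twin study with trial noise and compare the three estimators.

Generates trait data for 500 MZ and 500 DZ twin pairs, 20 trials each, with
generating h^2 = 0.6, c^2 = 0.2 and variability ratio Rv = 2, then fits:
the trial-level hierarchical model (unbiased), the conventional aggregated
two-level model (attenuated by U), and the aggregated model with the
measurement-error adjustment (disattenuated).
"""

from twinhlm import (
    AttenuationContext,
    EstimatorOptions,
    aggregate,
    attenuation_factor,
    config_from_targets,
    fit_adjusted,
    fit_aggregated,
    fit_hlm_ml,
    simulate,
)

cfg = config_from_targets(
    h2=0.6, c2=0.2, rv=2.0, n_fam_mz=500, n_fam_dz=500, n_trials=20, seed=7
)
table = simulate(cfg)
agg = aggregate(table)

trial = fit_hlm_ml(table, EstimatorOptions(method="ml"))
conventional = fit_aggregated(agg)
adjusted = fit_adjusted(agg)

u = attenuation_factor(AttenuationContext(rv=2.0, n_trials=20))
print(f"generating: h2=0.60  c2=0.20  Rv=2.0  T=20   (predicted U={u:.3f})")
print(f"{'method':<22} {'h2':>6} {'c2':>6} {'e2':>6} {'r_MZ':>6} {'r_DZ':>6}")
for name, fit in (
    ("trial-level ML", trial),
    ("aggregated (conv.)", conventional),
    ("aggregated+adjusted", adjusted),
):
    p, r = fit.proportions, fit.correlations
    print(f"{name:<22} {p.h2:6.3f} {p.c2:6.3f} {p.e2:6.3f} {r.r_mz:6.3f} {r.r_dz:6.3f}")

print()
print("The conventional fit underestimates h2 by roughly the factor U; the")
print("trial-level fit and the adjusted fit both sit near the generating value.")
print(f"fitted variability ratio (trial-level): Rv = {trial.rv:.2f}")
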