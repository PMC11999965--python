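"""Per-condition and contrast heritability in a two-condition design.

Tasks with two conditions (e.g. congruent/incongruent trials) support
heritability estimates per condition and for their contrast. The contrast
is the hard case: its family/individual variances shrink with the
cross-condition correlation while its trial-mean noise doubles (2*omega_0^2/T),
inflating the contrast's variability ratio.
"""

from twinhlm import SemComponents, SimConfig, fit_two_condition, simulate
from twinhlm.simulate import two_condition_truth

cfg = SimConfig(
    n_fam_mz=1000, n_fam_dz=1000, n_trials=50,
    components=SemComponents(0.4, 0.2, 0.4),
    omega02=1.0,
    n_conditions=2,
    cross_condition_corr=(0.5, 0.5),
    alpha=(1.0, 1.3),
    seed=11,
)
table = simulate(cfg)
fit = fit_two_condition(table)
truth = two_condition_truth(cfg)

print(f"{'effect':<12} {'h2':>6} {'c2':>6} {'e2':>6} {'Rv':>6}")
for label, summary in fit.conditions.items():
    p = summary.proportions
    print(f"{label:<12} {p.h2:6.3f} {p.c2:6.3f} {p.e2:6.3f} {summary.rv:6.2f}")
p = fit.contrast.proportions
print(f"{'contrast':<12} {p.h2:6.3f} {p.c2:6.3f} {p.e2:6.3f} {fit.contrast.rv:6.2f}")

print()
tp = truth["contrast"]["proportions"]
print(f"generating contrast h2 = {tp.h2:.2f}; the contrast's variability ratio is")
print("sqrt(2) times the per-condition one here, so its estimate is noisier —")
print("precise contrast heritability needs far larger samples than condition-level.")
print(f"effect-coding vs direct-difference route gap: "
      f"{fit.diagnostics['route_discrepancy']:.2e}")
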