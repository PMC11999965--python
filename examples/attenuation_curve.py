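"""How trial aggregation biases heritability: the attenuation factor U.

Averaging T noisy trials per individual before fitting a twin model shrinks
the fitted twin correlations — and with them h^2 and c^2 — by
U = 1/(1 + Rv^2/T), where Rv is the intra-individual SD relative to the
combined family+individual SD. This script tabulates U over a grid.
"""

from twinhlm import AttenuationContext, attenuation_factor

print(f"{'Rv':>5} | " + " | ".join(f"T={t:>4}" for t in (20, 50, 100, 500)))
print("-" * 45)
for rv in (0.5, 1.0, 2.0, 3.0, 10.0):
    us = [attenuation_factor(AttenuationContext(rv, t)) for t in (20, 50, 100, 500)]
    print(f"{rv:>5} | " + " | ".join(f"{u:6.3f}" for u in us))

print()
print("U is the multiplicative bias on h^2 and c^2: U = 0.5 means the")
print("conventional aggregated analysis reports only half the true values.")
print("With 100 trials, Rv = 1 is harmless (U ~ 0.99) but Rv = 10 halves h^2.")
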