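# Methods

## Model

The package treats a twin study as a three-level Gaussian hierarchy. For
individual *i* in family *f* of zygosity *z* ∈ {MZ, DZ}, trial *t* = 1..T:

    trial:       y_ifzt ~ Normal(θ_ifz, ω₀²)
    individual:  θ_ifz  ~ Normal(ν_fz, σ_z²)
    family:      ν_fz   ~ Normal(α, τ_z²)

The within-family correlation is r_z = τ_z²/(τ_z² + σ_z²), and Falconer's
formula maps (r_MZ, r_DZ) to the variance proportions (h², c², e²). The
classical ACE representation connects to the hierarchy through
τ_MZ² = σ_A² + σ_C², τ_DZ² = σ_A²/2 + σ_C², σ_MZ² = σ_E²,
σ_DZ² = σ_A²/2 + σ_E² (with DZ relatedness ρ_DZ = ½). The inverse map
σ_A² = 2(τ_MZ² − τ_DZ²), σ_C² = 2τ_DZ² − τ_MZ², σ_E² = σ_MZ² is
overdetermined; `sem_from_hlm` reports the discrepancy between the redundant
identities when the input violates total-variance homogeneity (the default
reporting threshold is 5% of total variance, sized for estimated inputs —
exact algebra can pass a smaller tolerance).

Fits are per-zygosity: Falconer's formula needs only *proportionality* of
the variance fractions across zygosities, not equality of the variances
themselves, so no homogeneity constraint is imposed during fitting.
`sem_components_from_fit` applies the homogeneity mapping afterwards for
ACE-scale output; a jointly constrained likelihood is deliberately not
offered.

### Aggregation bias and its correction

Averaging T trials replaces σ_z² by σ̃_z² = σ_z² + ω₀²/T, so the fitted
correlations become r̃_z = r_z·U with U = 1/(1 + Rv²/T) and
Rv = ω₀/√(τ_z² + σ_z²). Rv is defined on the *standard-deviation* scale —
this is what makes U reproduce its limiting values (U ≈ 0.99 at Rv = 1,
T = 100; U = 0.5 at Rv = 10, T = 100); the variance-scale ratio is exposed
as `AttenuationContext.rv2`. A single reported Rv averages the MZ and DZ
ratios; per-zygosity values are available.

The adjustment estimates ω₀² as the unweighted mean of per-individual
cross-trial sample variances (individuals with one trial are skipped) and
subtracts k·ω̂₀²/T from σ̃_z² (k = 1, or 2 for a two-condition contrast,
whose trial-mean difference carries twice the sampling variance). For
proportions, h² and c² share the deflated denominator and e² additionally
deflates its numerator, so the three still sum to one exactly. When the
subtraction empties a denominator, an `OverAdjustmentError` carrying the
unadjusted value is raised; callers may opt into clipping at a floor of
1e−8 × total variance (`boundary_policy="clip"`), and the fit records that
it clipped. Negative raw estimates are never silently truncated anywhere:
raw values carry flags, and a clipped-and-renormalized view is a separate
accessor.

## Estimators

**Moments.** On balanced data (two twins per family, common T) the nested
ANOVA mean squares are inverted: ω̂₀² = MS_trial,
σ̂² = (MS_ind − MS_trial)/T, τ̂² = (MS_fam − MS_ind)/(2T). These are
mean-unbiased and may be negative; unbalanced input raises an error
directing to the ML route.

**Maximum likelihood.** The marginal Gaussian likelihood is evaluated
through sufficient statistics: each individual contributes its
within-trial sum of squares at ω₀², and the per-individual means enter a
per-family bivariate normal with covariance τ² off-diagonal and
τ² + σ² + ω₀²/T_i on the diagonal. This is exact, handles unequal trial
counts and single-twin families, and costs O(F) per evaluation. L-BFGS-B
optimizes (α, τ², σ², ω₀²) with variances floored at 1e−8 × empirical total
variance; boundary contact is flagged. ML divides family sums of squares by
F where the moment estimator divides by F−1, so the two agree to O(1/F) on
balanced data. Data with T = 1 everywhere cannot separate ω₀² from σ²; the
fit refuses and points to the aggregated route.

**MCMC.** `fit_hlm_bayes` samples (α, τ, σ, ω₀) — SDs, not variances —
with half-normal priors on the SDs (scale 2.5 × empirical total SD, a
weakly-informative default that keeps mass near plausible values without
truncating large ones) and a wide normal prior on α. The sampler is an
emcee ensemble (16 walkers) using differential-evolution moves, which mix
far better than the stretch move on these correlated variance posteriors;
walkers start in a small ball around the ML solution. Defaults are 500
warmup and 3000 retained steps per walker. Because walkers are mutually
correlated, chains are thinned by half the estimated autocorrelation time
before computing split-R̂ (walkers as chains); fits with R̂ ≥ 1.01 on any
variance parameter are flagged and a warning is emitted. Heritability
quantities are computed per draw and reported as the KDE posterior mode
with the narrowest 95% interval (HDI). MZ and DZ posteriors are sampled
independently and paired by draw index, which is exact for independent
factors. Point proportions in the result are Falconer applied to the modal
correlations, so they sum to one; per-quantity modes (which need not) are
reported separately.

**Uncertainty for point fits.** `parametric_bootstrap` re-simulates at the
fitted per-zygosity variances (clipped at zero, without imposing
homogeneity), refits with the same method, and returns percentile 95%
intervals; refit failures are counted and >20% marks the interval
unreliable.

**Covariates.** `residualize_covariates` replaces y by OLS residuals on
dummy-coded covariates (per condition when present). This is a fixed-effects
approximation to modeling covariates jointly with the hierarchy: it ignores
the uncertainty of the covariate coefficients, which is negligible at the
sample sizes where twin modeling is feasible.

## Simulator

The generator draws the ACE mechanism exactly: per family, (A₁, A₂)
bivariate normal with correlation ρ_z and variance σ_A², C shared, E
independent; trials are Gaussian around θ = α + A + C + E, or, in
`lognormal` mode, log y ~ Normal(θ, ω₀²) — the ACE structure then lives on
the log scale (the natural-scale variant is ill-posed without further
assumptions and is not offered). `config_from_targets` parameterizes studies
on the (h², c², Rv) axes with unit total variance by default.

Two-condition mode draws bivariate family and individual effects across
conditions, parameterized by cross-condition correlations (default 0.5 at
both levels — a deliberate, moderate choice; the data-generating covariances
are nuisance for heritability but set the contrast's variance
2v(1 − ρ)). Trial counts are balanced by design; unbalanced data are
exercised in tests by mutating simulated tables.

Determinism: each (stage, zygosity) pair owns a seeded stream, and random
numbers are laid out family-major, so identical configs give bitwise-equal
tables and growing the family count appends families without reshuffling
earlier ones.

What the simulator does **not** emulate: skewed or heavy-tailed latent
distributions, trial-level non-Gaussian families (counts, binary), missing
trials, covariate structure (age/sex effects must be injected manually),
assortative mating, dominance, or gene–environment interplay. Passing tests
therefore certify the estimators under the assumed Gaussian hierarchy; on
real data, distributional violations can leave residual bias even after
adjustment.

## Study harness and claim checks

`run_study` crosses (Rv, T, F, scenario) cells with n seeded replicates and
summarizes bias, Monte-Carlo SD, RMSE (satisfying RMSE² = bias² + variance
exactly), boundary/failure rates, the predicted U and the observed
attenuation ratio mean(r̃̂)/r per zygosity. The default grid is
Rv ∈ {0.5, 1, 2, 10}, T ∈ {20, 100}, F ∈ {100, 500}, h² = 0.5, c² = 0.25,
100 replicates — sized to exercise every attenuation regime in about a
minute and a half on one core, and containing the matched-total pair
(F=100, T=100) vs (F=500, T=20).

`check_claims` renders three verdicts:

- **Precision degrades with Rv.** Monte-Carlo SDs estimated from n
  replicates carry ≈ 1/√(2(n−1)) relative noise, so consecutive-Rv
  monotonicity is asserted with a 3/√(2(n−1)) margin plus a strict overall
  increase from the smallest to the largest Rv.
- **Families beat trials at matched total observations.** The estimator
  variance at matched N = 2FT behaves like T(1 + Rv²/T)²/N, which is
  *increasing* in T only while Rv² ≲ T; for Rv ≫ √T additional trials
  rival additional families. The verdict is therefore evaluated on cells
  with Rv ≤ 2 by default (configurable) — the regime in which the claim is
  a theorem rather than a tendency.
- **Attenuation matches U.** Observed ratios are compared to U within 3
  Monte-Carlo SEs per zygosity, at the largest family count in the grid:
  r̃̂ is a ratio of variance estimates with its own O(1/F) finite-sample
  bias, which at F = 100 and U = 1/6 exceeds Monte-Carlo resolution even
  though the population law is exact.

## Numerical choices and limitations

- Variance floor 1e−8 × empirical total variance in all optimizations;
  boundary hits flagged, never hidden.
- ω̂₀² is pooled across zygosities (a single trial-level variance is
  posited); per-zygosity values are kept as diagnostics. Unbalanced trial
  counts use the harmonic-mean T in the adjustment.
- Two-condition fits are moment-based (the bivariate between/within-family
  mean-square matrices); the direct-difference and effect-coded routes are
  algebraically identical and their numerical gap is reported as an
  internal consistency diagnostic. A full bivariate likelihood for
  two-condition data is out of scope.
- The log-transform flag applies log before all fitting; estimates are then
  defined on the log scale.
- No dominance/ADE decomposition, no assortative-mating or G×E corrections,
  no multiple-testing machinery: the tool reports estimates and intervals.
- Adjustment restores the *point* estimate but not the uncertainty lost to
  aggregation; when precision matters and Rv is large, fit the trial level
  directly.
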