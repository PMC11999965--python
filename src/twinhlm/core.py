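"""Closed-form algebra for twin-study variance components.

This module connects the three classical representations of a twin design:

* **ACE components** (:class:`SemComponents`): additive-genetic variance
  ``var_a`` (sigma_A^2), shared-environment variance ``var_c`` (sigma_C^2) and
  nonshared-environment variance ``var_e`` (sigma_E^2), under the homogeneity
  assumption (equal component variances across zygosities).
* **Hierarchical (multilevel) variances** (:class:`HlmVariances`): per-zygosity
  family-level variance tau_z^2 and individual-level variance sigma_z^2, plus
  the trial-level (intra-individual) variance omega_0^2 when the trait is
  measured with repeated trials.
* **Twin correlations** (:class:`TwinCorrelations`): the within-family
  correlations r_MZ and r_DZ, from which Falconer's formula produces the
  variance proportions h^2, c^2, e^2.

It also provides the measurement-error algebra: the variability ratio Rv
(intra-individual SD relative to the combined family+individual SD), the
attenuation factor U = 1/(1 + Rv^2/T) by which aggregating T trials into a
per-individual mean biases the twin correlations (and hence h^2 and c^2)
downward, and the disattenuation adjustments that undo this bias when an
estimate of omega_0^2 is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import DegenerateInputError, OverAdjustmentError

__all__ = [
    "RELATEDNESS",
    "SemComponents",
    "HlmVariances",
    "Proportions",
    "TwinCorrelations",
    "AttenuationContext",
    "falconer",
    "proportions_from_sem",
    "expected_twin_correlation",
    "twin_correlation_from_hlm",
    "sem_from_hlm",
    "hlm_from_sem",
    "homogeneity_discrepancy",
    "variability_ratio",
    "attenuation_factor",
    "adjusted_correlation",
    "adjusted_proportions",
]

#: Additive-genetic relatedness of a twin pair: MZ twins share all segregating
#: genes, DZ twins on average half of them.
RELATEDNESS = {"MZ": 1.0, "DZ": 0.5}


def _check_zygosity(zygosity: str) -> str:
    z = str(zygosity).upper()
    if z not in RELATEDNESS:
        raise ValueError(f"unknown zygosity label {zygosity!r}; expected MZ or DZ")
    return z


@dataclass(frozen=True)
class SemComponents:
    """ACE variance components (trait-units squared).

    A *generating* model requires all components nonnegative; estimated
    components may stray below zero (moment estimators are unbiased but not
    range-respecting) and are carried untruncated — check :attr:`nonnegative`.
    """

    var_a: float
    var_c: float
    var_e: float

    @property
    def total(self) -> float:
        return self.var_a + self.var_c + self.var_e

    @property
    def nonnegative(self) -> bool:
        return self.var_a >= 0 and self.var_c >= 0 and self.var_e >= 0

    def as_dict(self) -> dict:
        return {"var_a": self.var_a, "var_c": self.var_c, "var_e": self.var_e}


@dataclass(frozen=True)
class HlmVariances:
    """Per-zygosity hierarchical variances.

    ``tau2_*`` are family-level variances, ``sigma2_*`` individual-level
    variances, and ``omega02`` the trial-level (intra-individual) variance —
    ``None`` for aggregated-only fits where the trial level is unavailable.
    The cross-trial sampling variance omega^2 = omega_0^2 / T is always
    derived at the point of use, never stored.
    """

    tau2_mz: float
    tau2_dz: float
    sigma2_mz: float
    sigma2_dz: float
    omega02: float | None = None

    def total(self, zygosity: str) -> float:
        z = _check_zygosity(zygosity)
        if z == "MZ":
            return self.tau2_mz + self.sigma2_mz
        return self.tau2_dz + self.sigma2_dz

    def as_dict(self) -> dict:
        return {
            "tau2_mz": self.tau2_mz,
            "tau2_dz": self.tau2_dz,
            "sigma2_mz": self.sigma2_mz,
            "sigma2_dz": self.sigma2_dz,
            "omega02": self.omega02,
        }


@dataclass(frozen=True)
class Proportions:
    """Variance proportions (h^2, c^2, e^2), summing to 1.

    Raw estimates may lie outside [0, 1]; :meth:`clipped` gives a
    presentation view clipped to the simplex. :attr:`in_bounds` reports
    whether clipping would change anything.
    """

    h2: float
    c2: float
    e2: float

    @property
    def in_bounds(self) -> bool:
        return all(0.0 <= v <= 1.0 for v in (self.h2, self.c2, self.e2))

    def clipped(self) -> "Proportions":
        """Clip h2 and c2 to [0, 1], set e2 = 1 - h2 - c2, renormalizing if needed."""
        h2 = min(max(self.h2, 0.0), 1.0)
        c2 = min(max(self.c2, 0.0), 1.0)
        e2 = 1.0 - h2 - c2
        if e2 < 0.0:
            s = h2 + c2
            h2, c2, e2 = h2 / s, c2 / s, 0.0
        return Proportions(h2, c2, e2)

    def as_dict(self) -> dict:
        return {"h2": self.h2, "c2": self.c2, "e2": self.e2}


@dataclass(frozen=True)
class TwinCorrelations:
    """Within-family trait correlations per zygosity."""

    r_mz: float
    r_dz: float

    def as_dict(self) -> dict:
        return {"r_mz": self.r_mz, "r_dz": self.r_dz}


@dataclass(frozen=True)
class AttenuationContext:
    """Inputs of the aggregation-bias factor.

    ``rv`` is the variability ratio on the standard-deviation scale
    (intra-individual SD omega_0 over the combined family+individual SD);
    ``rv2`` exposes the corresponding variance ratio. ``k_conditions`` is 1
    for a single condition and 2 for a two-condition contrast, where the
    effective trial variance doubles (the contrast of two independent
    T-trial means carries 2*omega_0^2/T sampling variance).
    """

    rv: float
    n_trials: int
    k_conditions: int = 1

    def __post_init__(self):
        if self.rv < 0:
            raise ValueError("rv must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.k_conditions not in (1, 2):
            raise ValueError("k_conditions must be 1 or 2")

    @property
    def rv2(self) -> float:
        """The variability ratio on the variance scale, Rv^2."""
        return self.rv**2


def falconer(r: TwinCorrelations) -> Proportions:
    """Falconer's formula: h2 = 2(r_MZ - r_DZ), c2 = 2 r_DZ - r_MZ, e2 = 1 - r_MZ.

    The three proportions sum to 1 exactly for any real correlations. Values
    are returned untruncated (moment estimates legitimately stray outside
    [0, 1]); use :meth:`Proportions.clipped` for a presentation view.
    """
    h2 = 2.0 * (r.r_mz - r.r_dz)
    c2 = 2.0 * r.r_dz - r.r_mz
    e2 = 1.0 - r.r_mz
    return Proportions(h2, c2, e2)


def proportions_from_sem(s: SemComponents) -> Proportions:
    """Variance proportions h2, c2, e2 = each ACE component over the total."""
    total = s.total
    if total <= 0:
        raise DegenerateInputError("total variance must be > 0 to form proportions")
    return Proportions(s.var_a / total, s.var_c / total, s.var_e / total)


def expected_twin_correlation(s: SemComponents, zygosity: str) -> float:
    """Model-implied twin correlation r_z = rho_z * h^2 + c^2.

    rho_z is the additive-genetic relatedness (1 for MZ, 0.5 for DZ).
    """
    z = _check_zygosity(zygosity)
    p = proportions_from_sem(s)
    return RELATEDNESS[z] * p.h2 + p.c2


def twin_correlation_from_hlm(tau2: float, sigma2: float) -> float:
    """Twin correlation implied by hierarchical variances: r = tau^2 / (tau^2 + sigma^2)."""
    denom = tau2 + sigma2
    if denom <= 0:
        raise DegenerateInputError("tau2 + sigma2 must be > 0")
    return tau2 / denom


def homogeneity_discrepancy(v: HlmVariances) -> float:
    """Total-variance homogeneity gap |(tau2_mz + sigma2_mz) - (tau2_dz + sigma2_dz)|.

    Zero whenever the hierarchical variances are consistent with equal ACE
    components across zygosities.
    """
    return abs((v.tau2_mz + v.sigma2_mz) - (v.tau2_dz + v.sigma2_dz))


def sem_from_hlm(v: HlmVariances, *, warn_tol: float = 0.05) -> SemComponents:
    """Map hierarchical variances to ACE components under homogeneity.

    sigma_A^2 = 2(tau_MZ^2 - tau_DZ^2), sigma_C^2 = 2 tau_DZ^2 - tau_MZ^2,
    sigma_E^2 = sigma_MZ^2. The mapping is overdetermined — sigma_A^2 also
    equals 2(sigma_DZ^2 - sigma_MZ^2) and sigma_E^2 equals
    sigma_DZ^2 - (tau_MZ^2 - tau_DZ^2) — so a homogeneity violation in the
    input shows up as a discrepancy between the redundant routes; a warning
    is emitted when it exceeds ``warn_tol`` relative to the total variance
    (the default tolerates the sampling noise of estimated inputs; pass a
    smaller value for exact algebra).
    Negative outputs are possible for estimated inputs and are not truncated.
    """
    var_a = 2.0 * (v.tau2_mz - v.tau2_dz)
    var_c = 2.0 * v.tau2_dz - v.tau2_mz
    var_e = v.sigma2_mz
    var_a_alt = 2.0 * (v.sigma2_dz - v.sigma2_mz)
    var_e_alt = v.sigma2_dz - (v.tau2_mz - v.tau2_dz)
    total = v.tau2_mz + v.sigma2_mz
    scale = abs(total) if total != 0 else 1.0
    gap = max(abs(var_a - var_a_alt), abs(var_e - var_e_alt))
    if gap > warn_tol * scale:
        warnings.warn(
            "hierarchical variances violate total-variance homogeneity "
            f"(redundant-identity discrepancy {gap:.3g}); ACE components use "
            "the family-level (tau^2) route",
            UserWarning,
            stacklevel=2,
        )
    return SemComponents(var_a, var_c, var_e)


def hlm_from_sem(s: SemComponents) -> HlmVariances:
    """Map ACE components to hierarchical variances (exact inverse of :func:`sem_from_hlm`).

    tau_MZ^2 = sigma_A^2 + sigma_C^2, tau_DZ^2 = sigma_A^2/2 + sigma_C^2,
    sigma_MZ^2 = sigma_E^2, sigma_DZ^2 = sigma_A^2/2 + sigma_E^2. The output
    satisfies total-variance homogeneity exactly.
    """
    if not s.nonnegative:
        raise ValueError("ACE components must be nonnegative for a generating model")
    return HlmVariances(
        tau2_mz=s.var_a + s.var_c,
        tau2_dz=0.5 * s.var_a + s.var_c,
        sigma2_mz=s.var_e,
        sigma2_dz=0.5 * s.var_a + s.var_e,
    )


def variability_ratio(omega02: float, tau2: float, sigma2: float) -> float:
    """Variability ratio Rv = omega_0 / sqrt(tau^2 + sigma^2) (SD scale).

    Quantifies intra-individual (trial-to-trial) spread relative to the
    combined inter-family + inter-individual spread. When reporting a single
    Rv for a fit, the per-zygosity values are averaged.
    """
    if omega02 < 0:
        raise ValueError("omega02 must be >= 0")
    denom = tau2 + sigma2
    if denom <= 0:
        raise DegenerateInputError("tau2 + sigma2 must be > 0")
    return math.sqrt(omega02 / denom)


def attenuation_factor(ctx: AttenuationContext) -> float:
    """Aggregation-bias factor U = 1 / (1 + k * Rv^2 / T), in (0, 1].

    Averaging T trials before fitting inflates the individual-level variance
    by omega_0^2/T, shrinking the fitted twin correlations to r_tilde = r * U
    and hence underestimating h^2 and c^2 by the factor U. U = 1 iff Rv = 0;
    it decreases in Rv and increases in T. For a two-condition contrast
    (k = 2) the effective trial variance doubles.
    """
    return 1.0 / (1.0 + ctx.k_conditions * ctx.rv2 / ctx.n_trials)


def adjusted_correlation(
    tau2: float,
    sigma2_tilde: float,
    omega02_hat: float,
    n_trials: int,
    k_conditions: int = 1,
) -> float:
    """Disattenuated twin correlation r_hat = tau^2 / (tau^2 + sigma_tilde^2 - k*omega0_hat^2/T).

    ``sigma2_tilde`` is the inflated individual-level variance fitted from
    aggregated data; subtracting the estimated cross-trial sampling variance
    restores the latent-trait correlation. Raises
    :class:`~twinhlm.errors.OverAdjustmentError` (carrying the unadjusted
    value) when the subtraction empties the denominator.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if omega02_hat < 0:
        raise ValueError("omega02_hat must be >= 0")
    correction = k_conditions * omega02_hat / n_trials
    denom = tau2 + sigma2_tilde - correction
    if denom <= 0:
        raise OverAdjustmentError(
            f"adjusted denominator {denom:.4g} <= 0: estimated trial variance "
            "removes the entire individual-level variance",
            raw_value=twin_correlation_from_hlm(tau2, sigma2_tilde),
        )
    return tau2 / denom


def adjusted_proportions(
    s_fitted: SemComponents,
    omega02_hat: float,
    n_trials: int,
    k_conditions: int = 1,
) -> Proportions:
    """Disattenuated variance proportions from aggregated-data ACE estimates.

    h2 and c2 keep their numerators over the deflated total
    (sigma_A^2 + sigma_C^2 + sigma_E^2 - k*omega0_hat^2/T); e2 additionally
    deflates its numerator by the same correction, so the three proportions
    sum to 1 exactly. A negative e2 numerator (over-adjustment of the
    nonshared component) is flagged via a warning but returned raw so that
    the sum-to-one identity holds; use :meth:`Proportions.clipped` for a
    bounded view.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    correction = k_conditions * omega02_hat / n_trials
    denom = s_fitted.total - correction
    if denom <= 0:
        raise OverAdjustmentError(
            f"adjusted total variance {denom:.4g} <= 0",
            raw_value=None,
        )
    e2_num = s_fitted.var_e - correction
    if e2_num < 0:
        warnings.warn(
            "adjusted nonshared-environment numerator is negative "
            f"({e2_num:.4g}); the estimated trial variance exceeds the fitted "
            "sigma_E^2 — raw value returned, consider the clipped view",
            UserWarning,
            stacklevel=2,
        )
    return Proportions(s_fitted.var_a / denom, s_fitted.var_c / denom, e2_num / denom)
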