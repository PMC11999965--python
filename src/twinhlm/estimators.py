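"""Fit hierarchical twin models to trial-level or aggregated data.

Three routes to the per-zygosity variances (family-level tau_z^2,
individual-level sigma_z^2, trial-level omega_0^2):

* ``anova_moments`` — the balanced nested-ANOVA moment solution (expected
  mean squares inverted); unbiased, closed-form, may yield negative
  estimates.
* ``fit_hlm_ml`` — exact marginal maximum likelihood; the Gaussian
  per-family covariance is marginalized analytically through per-individual
  sufficient statistics (trial mean + within-individual sum of squares), so
  unbalanced trial counts and singleton families are handled.
* ``fit_hlm_bayes`` — ensemble MCMC (emcee) with weakly-informative
  half-normal priors on the standard deviations, reporting posterior modes
  and 95% highest-density intervals.

``fit_aggregated`` fits the two-level model to per-individual means — the
conventional approach that absorbs the cross-trial sampling variance
omega_0^2/T into the individual level, yielding *attenuated* correlations
r_tilde = r * U. ``fit_adjusted`` disattenuates it using the mean
per-individual cross-trial sample variance as an estimate of omega_0^2.

Fits are performed separately per zygosity: only proportionality of the
variance fractions across zygosities (not full variance homogeneity) is
needed for Falconer's formula, so no homogeneity constraint is imposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    HlmVariances,
    Proportions,
    SemComponents,
    TwinCorrelations,
    falconer,
    sem_from_hlm,
    twin_correlation_from_hlm,
    variability_ratio,
)
from .errors import (
    IdentifiabilityError,
    OverAdjustmentError,
    SchemaError,
    UnbalancedDataError,
)
from .simulate import simulate_hlm_structure

__all__ = [
    "EstimatorOptions",
    "FitResult",
    "TwoConditionFit",
    "NestedMoments",
    "aggregate",
    "estimate_omega0",
    "anova_moments",
    "fit_hlm_ml",
    "fit_aggregated",
    "fit_adjusted",
    "fit_two_condition",
    "parametric_bootstrap",
    "residualize_covariates",
    "sem_components_from_fit",
]

_KEYS = ["family_id", "zygosity", "individual_id"]


@dataclass
class EstimatorOptions:
    """Tuning knobs shared by the fitting routines.

    ``boundary_policy`` controls over-adjustment handling in
    :func:`fit_adjusted`: ``"error"`` raises, ``"clip"`` floors the adjusted
    denominator at ``floor_frac`` times the total variance and flags the fit.
    """

    method: str = "moments"  # moments | ml | bayes
    uncertainty: str = "none"  # none | parametric_bootstrap | posterior
    n_boot: int = 200
    walkers: int = 16
    warmup: int = 500
    draws: int = 3000
    seed: int = 0
    prior_scale: float = 2.5  # half-normal SD prior scale, x empirical total SD
    floor_frac: float = 1e-8
    log_transform: bool = False
    boundary_policy: str = "error"


class NestedMoments(NamedTuple):
    """Moment estimates of the three nested variances (may be negative)."""

    tau2: float
    sigma2: float
    omega02: float

    @property
    def has_negative(self) -> bool:
        return any(v < 0 for v in self)


@dataclass
class FitResult:
    """Fitted variances and the heritability quantities they imply.

    ``correlations`` come from the fitted variances via
    r_z = tau_z^2/(tau_z^2 + sigma_z^2) (attenuated when ``level`` is
    ``"aggregated"``), and ``proportions`` from the correlations via
    Falconer's formula; ``proportions_clipped`` is the presentation view.
    ``rv`` is the MZ/DZ-averaged variability ratio (None when the trial
    variance is unavailable).
    """

    method: str
    level: str  # trial | aggregated | adjusted
    hlm: HlmVariances
    correlations: TwinCorrelations
    proportions: Proportions
    proportions_clipped: Proportions
    rv: float | None = None
    rv_by_zygosity: dict = field(default_factory=dict)
    loglik: float | None = None
    intervals: dict | None = None
    draws: dict | None = None
    diagnostics: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Flat JSON-serializable summary (posterior draws omitted)."""
        out = {
            "method": self.method,
            "level": self.level,
            "hlm": self.hlm.as_dict(),
            "correlations": self.correlations.as_dict(),
            "proportions": self.proportions.as_dict(),
            "proportions_clipped": self.proportions_clipped.as_dict(),
            "rv": self.rv,
            "rv_by_zygosity": self.rv_by_zygosity,
            "loglik": self.loglik,
            "intervals": self.intervals,
            "diagnostics": _jsonable(self.diagnostics),
            "design": self.design,
        }
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# aggregation and the trial-variance estimate


def _group_keys(table: pd.DataFrame) -> list[str]:
    keys = list(_KEYS)
    if "condition" in table.columns:
        keys.append("condition")
    return keys


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse trials to per-individual sample means and variances.

    Returns one row per individual (and condition) with ``mean_y`` (the
    trial mean), ``var_y`` (unbiased cross-trial sample variance, missing
    when only one trial exists) and ``n_trials``. Pass-through when the
    input is already aggregated.
    """
    if "mean_y" in table.columns:
        return table.copy()
    if "y" not in table.columns:
        raise SchemaError("expected a trial-level table with a 'y' column")
    keys = _group_keys(table)
    out = (
        table.groupby(keys, sort=True, observed=True)["y"]
        .agg(mean_y="mean", var_y="var", n_trials="count")
        .reset_index()
    )
    return out


def estimate_omega0(agg: pd.DataFrame) -> float:
    """Estimate the trial-level variance as the mean per-individual cross-trial variance.

    Individuals with a single trial carry no information and are skipped;
    with none left the trial variance is unidentifiable.
    """
    agg = aggregate(agg)
    usable = agg.loc[agg["n_trials"] >= 2, "var_y"].dropna()
    if usable.empty:
        raise IdentifiabilityError(
            "no individual has >= 2 trials; the trial-level variance omega_0^2 "
            "cannot be estimated"
        )
    return float(usable.mean())


# ---------------------------------------------------------------------------
# balanced sufficient statistics and the moment estimator


def _zygosity_slice(table: pd.DataFrame, zygosity: str) -> pd.DataFrame:
    z = str(zygosity).upper()
    sub = table[table["zygosity"].astype(str).str.upper() == z]
    if sub.empty:
        raise ValueError(f"no rows for zygosity {zygosity!r}")
    return sub


def _balanced_stats(sub: pd.DataFrame):
    """Means matrix (F, 2), common trial count T and within-individual SS for balanced data."""
    agg = aggregate(sub)
    counts = agg.groupby("family_id", observed=True)["individual_id"].count()
    if not (counts == 2).all():
        raise UnbalancedDataError(
            "balanced moment estimation needs exactly 2 twins per family; "
            "use the ml method for incomplete families"
        )
    t_vals = agg["n_trials"].unique()
    if len(t_vals) != 1:
        raise UnbalancedDataError(
            "balanced moment estimation needs a common trial count; use the ml method"
        )
    t = int(t_vals[0])
    agg = agg.sort_values(["family_id", "individual_id"])
    means = agg["mean_y"].to_numpy().reshape(-1, 2)
    ss_within = float(((t - 1) * agg["var_y"].fillna(0.0)).sum())
    return means, t, ss_within


def anova_moments(table: pd.DataFrame, zygosity: str) -> NestedMoments:
    """Balanced nested-ANOVA moment estimates of (tau^2, sigma^2, omega_0^2).

    Inverts the expected mean squares of the family/individual/trial nesting:
    omega_0^2 = MS_trial, sigma^2 = (MS_individual - MS_trial)/T,
    tau^2 = (MS_family - MS_individual)/(2T). Unbiased for the generating
    variances; estimates may be negative (see
    :attr:`NestedMoments.has_negative`).
    """
    sub = _zygosity_slice(table, zygosity)
    means, t, ss_within = _balanced_stats(sub)
    if t < 2:
        raise IdentifiabilityError(
            "single-trial data cannot separate omega_0^2 from sigma^2; "
            "fit the aggregated two-level model instead"
        )
    n_fam = means.shape[0]
    if n_fam < 2:
        raise ValueError("need at least 2 families")
    fam_means = means.mean(axis=1)
    grand = means.mean()
    ms_trial = ss_within / (2 * n_fam * (t - 1))
    ms_ind = t * float(((means - fam_means[:, None]) ** 2).sum()) / n_fam
    ms_fam = 2 * t * float(((fam_means - grand) ** 2).sum()) / (n_fam - 1)
    return NestedMoments(
        tau2=(ms_fam - ms_ind) / (2 * t),
        sigma2=(ms_ind - ms_trial) / t,
        omega02=ms_trial,
    )


def _pair_moments(agg_sub: pd.DataFrame) -> tuple[float, float, int]:
    """Two-level moment estimates (tau2, sigma_tilde2) from per-individual means."""
    counts = agg_sub.groupby("family_id", observed=True)["individual_id"].count()
    complete = counts[counts == 2].index
    dropped = len(counts) - len(complete)
    if dropped:
        warnings.warn(
            f"{dropped} incomplete families excluded from moment estimation",
            UserWarning,
            stacklevel=2,
        )
    sub = agg_sub[agg_sub["family_id"].isin(complete)].sort_values(
        ["family_id", "individual_id"]
    )
    means = sub["mean_y"].to_numpy().reshape(-1, 2)
    n_fam = means.shape[0]
    if n_fam < 2:
        raise ValueError("need at least 2 complete families")
    fam_means = means.mean(axis=1)
    msb = 2.0 * float(((fam_means - fam_means.mean()) ** 2).sum()) / (n_fam - 1)
    msw = float(((means[:, 0] - means[:, 1]) ** 2).sum()) / (2.0 * n_fam)
    return (msb - msw) / 2.0, msw, n_fam


# ---------------------------------------------------------------------------
# marginal maximum likelihood

_LOG2PI = np.log(2.0 * np.pi)


def _ml_suffstats(sub: pd.DataFrame):
    """Sufficient statistics for the marginal likelihood of one zygosity.

    Trials enter only through each individual's mean, trial count and
    within-individual sum of squares; individual means enter through
    family pairs (or singletons).
    """
    agg = aggregate(sub)
    agg = agg.sort_values(["family_id", "individual_id"])
    ss_within = float(((agg["n_trials"] - 1) * agg["var_y"].fillna(0.0)).sum())
    df_within = int((agg["n_trials"] - 1).sum())
    fam_sizes = agg.groupby("family_id", observed=True)["individual_id"].count()
    pair_fams = fam_sizes[fam_sizes == 2].index
    single_fams = fam_sizes[fam_sizes == 1].index
    if (fam_sizes > 2).any():
        raise SchemaError("families with more than 2 individuals; run the reader first")
    pairs = agg[agg["family_id"].isin(pair_fams)]
    m = pairs["mean_y"].to_numpy().reshape(-1, 2)
    tt = pairs["n_trials"].to_numpy(dtype=float).reshape(-1, 2)
    singles = agg[agg["family_id"].isin(single_fams)]
    return {
        "ss_within": ss_within,
        "df_within": df_within,
        "m": m,
        "t_pair": tt,
        "m_single": singles["mean_y"].to_numpy(),
        "t_single": singles["n_trials"].to_numpy(dtype=float),
        "n_individuals": len(agg),
    }


def _trial_loglik(alpha, tau2, sigma2, omega02, st) -> float:
    """Exact marginal Gaussian log-likelihood of the three-level model."""
    if tau2 < 0 or sigma2 < 0 or omega02 <= 0:
        return -np.inf
    ll = -0.5 * (st["ss_within"] / omega02 + st["df_within"] * (np.log(omega02) + _LOG2PI))
    m, tt = st["m"], st["t_pair"]
    if m.size:
        v1 = tau2 + sigma2 + omega02 / tt[:, 0]
        v2 = tau2 + sigma2 + omega02 / tt[:, 1]
        det = v1 * v2 - tau2 * tau2
        if np.any(det <= 0):
            return -np.inf
        d1 = m[:, 0] - alpha
        d2 = m[:, 1] - alpha
        quad = (v2 * d1 * d1 - 2.0 * tau2 * d1 * d2 + v1 * d2 * d2) / det
        ll += -0.5 * float((np.log(det) + quad + 2.0 * _LOG2PI).sum())
    if st["m_single"].size:
        v = tau2 + sigma2 + omega02 / st["t_single"]
        d = st["m_single"] - alpha
        ll += -0.5 * float((np.log(v) + d * d / v + _LOG2PI).sum())
    return float(ll)


def _pair_loglik(alpha, tau2, sigma2, st) -> float:
    """Two-level marginal log-likelihood (aggregated means, no trial term)."""
    if tau2 < 0 or sigma2 <= 0:
        return -np.inf
    ll = 0.0
    m = st["m"]
    if m.size:
        v = tau2 + sigma2
        det = v * v - tau2 * tau2
        if det <= 0:
            return -np.inf
        d1 = m[:, 0] - alpha
        d2 = m[:, 1] - alpha
        quad = (v * d1 * d1 - 2.0 * tau2 * d1 * d2 + v * d2 * d2) / det
        ll += -0.5 * float((np.log(det) + quad + 2.0 * _LOG2PI).sum())
    if st["m_single"].size:
        v = tau2 + sigma2
        d = st["m_single"] - alpha
        ll += -0.5 * float((np.log(v) + d * d / v + _LOG2PI).sum())
    return float(ll)


def _ml_one_zygosity(sub: pd.DataFrame, opts: EstimatorOptions):
    st = _ml_suffstats(sub)
    if st["df_within"] == 0:
        raise IdentifiabilityError(
            "all individuals have a single trial: omega_0^2 and sigma^2 are not "
            "separately identifiable; aggregate and use fit_aggregated"
        )
    all_means = np.concatenate([st["m"].ravel(), st["m_single"]])
    total_var = float(np.var(all_means)) or 1.0
    floor = opts.floor_frac * total_var
    # moment-flavored initial values
    omega0_init = max(st["ss_within"] / max(st["df_within"], 1), floor)
    half = max(total_var / 2.0, floor)
    x0 = np.array([float(all_means.mean()), half, half, omega0_init])

    def nll(x):
        return -_trial_loglik(x[0], x[1], x[2], x[3], st)

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None), (floor, None), (floor, None), (floor, None)],
    )
    alpha, tau2, sigma2, omega02 = res.x
    boundary = bool(tau2 <= 2 * floor or sigma2 <= 2 * floor)
    return {
        "alpha": float(alpha),
        "tau2": float(tau2),
        "sigma2": float(sigma2),
        "omega02": float(omega02),
        "loglik": -float(res.fun),
        "converged": bool(res.success),
        "boundary": boundary,
        "floor": floor,
        "message": str(res.message),
    }


def _agg_ml_one_zygosity(agg_sub: pd.DataFrame, opts: EstimatorOptions):
    st = _ml_suffstats(agg_sub)
    all_means = np.concatenate([st["m"].ravel(), st["m_single"]])
    total_var = float(np.var(all_means)) or 1.0
    floor = opts.floor_frac * total_var
    half = max(total_var / 2.0, floor)
    x0 = np.array([float(all_means.mean()), half, half])

    def nll(x):
        return -_pair_loglik(x[0], x[1], x[2], st)

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None), (floor, None), (floor, None)],
    )
    alpha, tau2, sigma2 = res.x
    return {
        "alpha": float(alpha),
        "tau2": float(tau2),
        "sigma2": float(sigma2),
        "loglik": -float(res.fun),
        "converged": bool(res.success),
        "boundary": bool(tau2 <= 2 * floor or sigma2 <= 2 * floor),
        "floor": floor,
    }


# ---------------------------------------------------------------------------
# public fitting entry points


def _prepare_trial_table(table: pd.DataFrame, opts: EstimatorOptions) -> pd.DataFrame:
    if "condition" in table.columns and table["condition"].nunique() > 1:
        raise ValueError(
            "table has multiple conditions; use fit_two_condition for contrasts "
            "or filter to one condition"
        )
    if opts.log_transform:
        if (table["y"] <= 0).any():
            raise ValueError("log_transform requires strictly positive trait values")
        table = table.copy()
        table["y"] = np.log(table["y"])
    return table


def _design_info(table: pd.DataFrame) -> dict:
    agg = aggregate(table)
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = agg[agg["zygosity"].astype(str).str.upper() == zyg]
        out[f"n_fam_{zyg.lower()}"] = int(sub["family_id"].nunique())
    out["n_trials"] = int(agg["n_trials"].max()) if "n_trials" in agg.columns else 1
    return out


def _assemble(
    method: str,
    level: str,
    per_zyg: dict,
    *,
    omega02: float | None,
    loglik: float | None,
    diagnostics: dict,
    design: dict,
) -> FitResult:
    hlm = HlmVariances(
        tau2_mz=per_zyg["MZ"]["tau2"],
        tau2_dz=per_zyg["DZ"]["tau2"],
        sigma2_mz=per_zyg["MZ"]["sigma2"],
        sigma2_dz=per_zyg["DZ"]["sigma2"],
        omega02=omega02,
    )
    corr = TwinCorrelations(
        r_mz=twin_correlation_from_hlm(hlm.tau2_mz, hlm.sigma2_mz),
        r_dz=twin_correlation_from_hlm(hlm.tau2_dz, hlm.sigma2_dz),
    )
    props = falconer(corr)
    rv = None
    rv_by_zyg: dict = {}
    if omega02 is not None:
        for zyg, tau2, sigma2 in (
            ("MZ", hlm.tau2_mz, hlm.sigma2_mz),
            ("DZ", hlm.tau2_dz, hlm.sigma2_dz),
        ):
            denom = tau2 + sigma2
            rv_by_zyg[zyg] = variability_ratio(omega02, tau2, sigma2) if denom > 0 else np.nan
        rv = float(np.mean(list(rv_by_zyg.values())))
    return FitResult(
        method=method,
        level=level,
        hlm=hlm,
        correlations=corr,
        proportions=props,
        proportions_clipped=props.clipped(),
        rv=rv,
        rv_by_zygosity=rv_by_zyg,
        loglik=loglik,
        diagnostics=diagnostics,
        design=design,
    )


def fit_hlm_ml(table: pd.DataFrame, opts: EstimatorOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of the three-level model to trial-level data.

    Each zygosity is fitted separately (marginal Gaussian likelihood with
    per-family covariance tau^2 between twins, tau^2 + sigma^2 between
    trials of one twin, tau^2 + sigma^2 + omega_0^2 on the diagonal).
    Unbalanced trial counts and singleton families are supported. With
    ``opts.method == "moments"`` the balanced nested-ANOVA solution is used
    instead (requires a balanced design).
    """
    opts = opts or EstimatorOptions(method="ml")
    if opts.method not in ("moments", "ml"):
        raise ValueError("fit_hlm_ml supports methods 'moments' and 'ml'; "
                         "use fit_hlm_bayes for posterior sampling")
    table = _prepare_trial_table(table, opts)
    per_zyg: dict = {}
    diagnostics: dict = {"per_zygosity": {}}
    loglik = 0.0
    omega_parts = []
    for zyg in ("MZ", "DZ"):
        sub = _zygosity_slice(table, zyg)
        if opts.method == "moments":
            mom = anova_moments(sub, zyg)
            per_zyg[zyg] = {"tau2": mom.tau2, "sigma2": mom.sigma2}
            omega_parts.append(mom.omega02)
            diagnostics["per_zygosity"][zyg] = {
                "omega02": mom.omega02,
                "negative_components": mom.has_negative,
            }
            loglik = None
        else:
            fit = _ml_one_zygosity(sub, opts)
            per_zyg[zyg] = {"tau2": fit["tau2"], "sigma2": fit["sigma2"]}
            omega_parts.append(fit["omega02"])
            diagnostics["per_zygosity"][zyg] = {
                k: fit[k] for k in ("alpha", "omega02", "converged", "boundary", "message")
            }
            if loglik is not None:
                loglik += fit["loglik"]
    # a single trial-level variance is posited, so per-zygosity estimates are pooled
    n_ind = {
        zyg: aggregate(_zygosity_slice(table, zyg)).shape[0] for zyg in ("MZ", "DZ")
    }
    weights = np.array([n_ind["MZ"], n_ind["DZ"]], dtype=float)
    omega02 = float(np.average(omega_parts, weights=weights))
    result = _assemble(
        opts.method if opts.method == "moments" else "ml",
        "trial",
        per_zyg,
        omega02=omega02,
        loglik=loglik,
        diagnostics=diagnostics,
        design={**_design_info(table), "k_conditions": 1},
    )
    if opts.uncertainty == "parametric_bootstrap":
        parametric_bootstrap(result, opts.n_boot, opts.seed, opts)
    return result


def fit_aggregated(data: pd.DataFrame, opts: EstimatorOptions | None = None) -> FitResult:
    """Fit the two-level model to per-individual means (the conventional route).

    This is the aggregated-data analysis whose individual-level variance is
    inflated to sigma_tilde^2 = sigma^2 + omega_0^2/T, so the returned
    correlations (and h^2, c^2) are attenuated by U = 1/(1 + Rv^2/T).
    Accepts a trial-level table (aggregated internally) or an aggregated one.
    """
    opts = opts or EstimatorOptions()
    if "y" in data.columns:
        data = _prepare_trial_table(data, opts)
    agg = aggregate(data)
    if "condition" in agg.columns and agg["condition"].nunique() > 1:
        raise ValueError("multiple conditions; use fit_two_condition")
    per_zyg: dict = {}
    diagnostics: dict = {"per_zygosity": {}}
    loglik: float | None = 0.0
    for zyg in ("MZ", "DZ"):
        sub = _zygosity_slice(agg, zyg)
        if opts.method in ("moments",):
            tau2, sigma2t, n_fam = _pair_moments(sub)
            per_zyg[zyg] = {"tau2": tau2, "sigma2": sigma2t}
            diagnostics["per_zygosity"][zyg] = {"n_fam": n_fam}
            loglik = None
        else:
            fit = _agg_ml_one_zygosity(sub, opts)
            per_zyg[zyg] = {"tau2": fit["tau2"], "sigma2": fit["sigma2"]}
            diagnostics["per_zygosity"][zyg] = {
                k: fit[k] for k in ("alpha", "converged", "boundary")
            }
            if loglik is not None:
                loglik += fit["loglik"]
    result = _assemble(
        opts.method,
        "aggregated",
        per_zyg,
        omega02=None,
        loglik=loglik,
        diagnostics=diagnostics,
        design={**_design_info(agg), "k_conditions": 1},
    )
    if opts.uncertainty == "parametric_bootstrap":
        parametric_bootstrap(result, opts.n_boot, opts.seed, opts)
    return result


def _harmonic_mean_trials(agg: pd.DataFrame) -> float:
    t = agg["n_trials"].to_numpy(dtype=float)
    return len(t) / float((1.0 / t).sum())


def fit_adjusted(
    data: pd.DataFrame,
    opts: EstimatorOptions | None = None,
    *,
    k_conditions: int = 1,
    omega02: float | None = None,
) -> FitResult:
    """Aggregated fit with the measurement-error adjustment applied.

    Fits the two-level model, estimates omega_0^2 as the mean per-individual
    cross-trial sample variance (unless supplied), and disattenuates the
    correlations by subtracting k * omega0_hat^2 / T from the fitted
    individual-level variance. With unbalanced trial counts the harmonic-mean
    T is used. Over-adjustment (an emptied denominator) raises
    :class:`~twinhlm.errors.OverAdjustmentError` unless
    ``opts.boundary_policy == "clip"``.
    """
    opts = opts or EstimatorOptions()
    agg = aggregate(data)
    base = fit_aggregated(agg, opts)
    omega02_hat = estimate_omega0(agg) if omega02 is None else float(omega02)
    t_eff = _harmonic_mean_trials(agg)
    correction = k_conditions * omega02_hat / t_eff
    per_zyg: dict = {}
    diagnostics = dict(base.diagnostics)
    diagnostics.update(
        {"omega02_hat": omega02_hat, "t_effective": t_eff, "correction": correction}
    )
    clipped = False
    for zyg, tau2, sigma2t in (
        ("MZ", base.hlm.tau2_mz, base.hlm.sigma2_mz),
        ("DZ", base.hlm.tau2_dz, base.hlm.sigma2_dz),
    ):
        sigma2_adj = sigma2t - correction
        if tau2 + sigma2_adj <= 0:
            if opts.boundary_policy == "clip":
                floor = opts.floor_frac * (tau2 + sigma2t)
                sigma2_adj = floor - tau2 if tau2 + sigma2_adj <= 0 else sigma2_adj
                clipped = True
            else:
                raise OverAdjustmentError(
                    f"adjustment removes the entire individual-level variance for {zyg} "
                    f"(tau2={tau2:.4g}, sigma_tilde2={sigma2t:.4g}, correction={correction:.4g})",
                    raw_value=twin_correlation_from_hlm(tau2, sigma2t),
                )
        per_zyg[zyg] = {"tau2": tau2, "sigma2": sigma2_adj}
    diagnostics["over_adjustment_clipped"] = clipped
    result = _assemble(
        base.method,
        "adjusted",
        per_zyg,
        omega02=omega02_hat,
        loglik=base.loglik,
        diagnostics=diagnostics,
        design={**base.design, "k_conditions": k_conditions},
    )
    if opts.uncertainty == "parametric_bootstrap":
        parametric_bootstrap(result, opts.n_boot, opts.seed, opts)
    return result


def sem_components_from_fit(fit: FitResult) -> SemComponents:
    """ACE components implied by a fit, via the homogeneity mapping.

    Per-zygosity fits only assume proportionality, so the mapping warns when
    the fitted variances are far from total-variance homogeneity.
    """
    return sem_from_hlm(fit.hlm)


# ---------------------------------------------------------------------------
# two-condition fits and the contrast


@dataclass
class ConditionSummary:
    """Correlations/proportions for one condition or for the contrast."""

    correlations: TwinCorrelations
    proportions: Proportions
    proportions_clipped: Proportions
    rv: float | None
    hlm: HlmVariances
    degenerate: bool = False


@dataclass
class TwoConditionFit:
    """Per-condition heritability plus the between-condition contrast.

    The contrast (first condition minus second) uses family/individual
    variances tau_d^2 = tau_1^2 + tau_2^2 - 2 tau_12 (and likewise for
    sigma), with trial-mean noise 2*omega_0^2/T; its variability ratio uses
    the doubled trial variance.
    """

    condition_labels: tuple[str, str]
    conditions: dict
    contrast: ConditionSummary
    omega02_hat: float
    n_trials: int
    diagnostics: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)


def _bivariate_moments(sub_agg: pd.DataFrame, labels) -> dict:
    """Matrix-valued between/within-family mean squares of per-condition means."""
    wide = sub_agg.pivot_table(
        index=["family_id", "individual_id"], columns="condition", values="mean_y"
    )[list(labels)]
    if wide.isna().any().any():
        raise UnbalancedDataError("every individual needs data in both conditions")
    counts = pd.Series(1, index=wide.index).groupby(level="family_id").count()
    if not (counts == 2).all():
        raise UnbalancedDataError("two-condition moments need exactly 2 twins per family")
    u = wide.to_numpy().reshape(-1, 2, 2)  # (family, twin, condition)
    n_fam = u.shape[0]
    if n_fam < 2:
        raise ValueError("need at least 2 families")
    fam_mean = u.mean(axis=1)  # (family, condition)
    grand = fam_mean.mean(axis=0)
    dev = fam_mean - grand
    msb = 2.0 * np.einsum("fi,fj->ij", dev, dev) / (n_fam - 1)
    diff = u[:, 0, :] - u[:, 1, :]
    msw = np.einsum("fi,fj->ij", diff, diff) / (2.0 * n_fam)
    return {"msb": msb, "msw": msw, "n_fam": n_fam}


def _difference_moments(sub_agg: pd.DataFrame, labels) -> tuple[float, float]:
    """Scalar two-level moments of the per-individual condition difference.

    The effect-coded route: the +-0.5-coded condition slope per individual
    equals the condition-mean difference, so its family/individual variance
    decomposition is an ordinary twin ANOVA on the differences.
    """
    wide = sub_agg.pivot_table(
        index=["family_id", "individual_id"], columns="condition", values="mean_y"
    )[list(labels)]
    d = (wide.iloc[:, 0] - wide.iloc[:, 1]).rename("mean_y").reset_index()
    tau2, sigma2t, _ = _pair_moments(d)
    return tau2, sigma2t


def fit_two_condition(
    table: pd.DataFrame, opts: EstimatorOptions | None = None
) -> TwoConditionFit:
    """Moment fit of the bivariate two-condition model on balanced trial data.

    Per zygosity, the between/within-family mean-square *matrices* of the
    per-condition trial means give the family-level covariance
    (MSB - MSW)/2 and the inflated individual-level covariance MSW; the
    pooled mean cross-trial variance estimates omega_0^2, which is subtracted
    (per condition: omega_0^2/T; contrast: 2*omega_0^2/T) to reach the
    latent-trait scale. Per-condition and contrast heritability follow from
    Falconer's formula. The direct-difference route is computed as an
    internal cross-check and its discrepancy reported in ``diagnostics``.
    """
    opts = opts or EstimatorOptions()
    if opts.method != "moments":
        raise NotImplementedError("two-condition fits are moment-based")
    if "condition" not in table.columns:
        raise ValueError("table has no condition column")
    table = table.copy()
    if opts.log_transform:
        if (table["y"] <= 0).any():
            raise ValueError("log_transform requires strictly positive trait values")
        table["y"] = np.log(table["y"])
    labels = tuple(sorted(table["condition"].astype(str).unique()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 conditions, found {len(labels)}")
    agg = aggregate(table)
    t_vals = agg["n_trials"].unique()
    if len(t_vals) != 1:
        raise UnbalancedDataError("two-condition moments need a common trial count")
    t = int(t_vals[0])
    if t < 2:
        raise IdentifiabilityError("need >= 2 trials per condition to estimate omega_0^2")
    omega02_hat = estimate_omega0(agg)

    per_zyg: dict = {}
    route_gap = 0.0
    for zyg in ("MZ", "DZ"):
        sub = _zygosity_slice(agg, zyg)
        mom = _bivariate_moments(sub, labels)
        sigma_fam = (mom["msb"] - mom["msw"]) / 2.0
        sigma_ind_tilde = mom["msw"]
        c = np.array([1.0, -1.0])
        tau2_d = float(c @ sigma_fam @ c)
        sigma2t_d = float(c @ sigma_ind_tilde @ c)
        tau2_d_alt, sigma2t_d_alt = _difference_moments(sub, labels)
        route_gap = max(
            route_gap, abs(tau2_d - tau2_d_alt), abs(sigma2t_d - sigma2t_d_alt)
        )
        per_zyg[zyg] = {
            "sigma_fam": sigma_fam,
            "sigma_ind_tilde": sigma_ind_tilde,
            "tau2_d": tau2_d,
            "sigma2_d": sigma2t_d - 2.0 * omega02_hat / t,
        }

    conditions: dict = {}
    for k, label in enumerate(labels):
        tau2 = {z: float(per_zyg[z]["sigma_fam"][k, k]) for z in ("MZ", "DZ")}
        sigma2 = {
            z: float(per_zyg[z]["sigma_ind_tilde"][k, k]) - omega02_hat / t
            for z in ("MZ", "DZ")
        }
        corr = TwinCorrelations(
            r_mz=twin_correlation_from_hlm(tau2["MZ"], sigma2["MZ"]),
            r_dz=twin_correlation_from_hlm(tau2["DZ"], sigma2["DZ"]),
        )
        props = falconer(corr)
        rv = float(
            np.mean(
                [variability_ratio(omega02_hat, tau2[z], sigma2[z]) for z in ("MZ", "DZ")]
            )
        )
        conditions[label] = ConditionSummary(
            correlations=corr,
            proportions=props,
            proportions_clipped=props.clipped(),
            rv=rv,
            hlm=HlmVariances(
                tau2["MZ"], tau2["DZ"], sigma2["MZ"], sigma2["DZ"], omega02_hat
            ),
        )

    # contrast
    tau2_d = {z: per_zyg[z]["tau2_d"] for z in ("MZ", "DZ")}
    sigma2_d = {z: per_zyg[z]["sigma2_d"] for z in ("MZ", "DZ")}
    total_scale = float(
        np.mean([per_zyg[z]["sigma_fam"].trace() + per_zyg[z]["sigma_ind_tilde"].trace()
                 for z in ("MZ", "DZ")])
    )
    degenerate = all(
        abs(tau2_d[z]) + abs(sigma2_d[z]) < 1e-8 * max(total_scale, 1e-300)
        for z in ("MZ", "DZ")
    )
    if degenerate:
        corr_d = TwinCorrelations(float("nan"), float("nan"))
        props_d = Proportions(float("nan"), float("nan"), float("nan"))
        rv_d = None
    else:
        corr_d = TwinCorrelations(
            r_mz=twin_correlation_from_hlm(tau2_d["MZ"], sigma2_d["MZ"]),
            r_dz=twin_correlation_from_hlm(tau2_d["DZ"], sigma2_d["DZ"]),
        )
        props_d = falconer(corr_d)
        rv_d = float(
            np.mean(
                [
                    variability_ratio(2.0 * omega02_hat, tau2_d[z], sigma2_d[z])
                    for z in ("MZ", "DZ")
                ]
            )
        )
    contrast = ConditionSummary(
        correlations=corr_d,
        proportions=props_d,
        proportions_clipped=props_d.clipped() if not degenerate else props_d,
        rv=rv_d,
        hlm=HlmVariances(
            tau2_d["MZ"], tau2_d["DZ"], sigma2_d["MZ"], sigma2_d["DZ"], omega02_hat
        ),
        degenerate=degenerate,
    )
    return TwoConditionFit(
        condition_labels=labels,
        conditions=conditions,
        contrast=contrast,
        omega02_hat=omega02_hat,
        n_trials=t,
        diagnostics={"route_discrepancy": route_gap, "degenerate_contrast": degenerate},
        design={**_design_info(agg), "k_conditions": 2},
    )


# ---------------------------------------------------------------------------
# uncertainty: parametric bootstrap


def parametric_bootstrap(
    fit: FitResult,
    n_boot: int = 200,
    seed: int = 0,
    opts: EstimatorOptions | None = None,
) -> dict:
    """Percentile 95% intervals for (h^2, c^2, e^2, Rv) by re-simulation.

    ``n_boot`` datasets are drawn at the fitted per-zygosity variances
    (clipped at zero), refitted with the same method and level, and the
    2.5/97.5 percentiles of each quantity collected. Refits that fail are
    counted; above 20% failures the intervals are flagged unreliable. The
    result is attached to ``fit.intervals`` and also returned.
    """
    opts = opts or EstimatorOptions(method=fit.method)
    if opts.uncertainty == "parametric_bootstrap":
        # refits inside the bootstrap must not bootstrap themselves
        opts = replace(opts, uncertainty="none")
    design = fit.design
    needed = ("n_fam_mz", "n_fam_dz", "n_trials")
    if not all(k in design for k in needed):
        raise ValueError("fit carries no design information; cannot re-simulate")
    tau2_mz = max(fit.hlm.tau2_mz, 0.0)
    tau2_dz = max(fit.hlm.tau2_dz, 0.0)
    omega02 = max(fit.hlm.omega02 or 0.0, 0.0)
    if fit.level == "aggregated":
        # the aggregated fit sees only means; re-simulate at the mean level
        sigma2_mz = max(fit.hlm.sigma2_mz, 0.0)
        sigma2_dz = max(fit.hlm.sigma2_dz, 0.0)
        sim_kwargs = dict(omega02=0.0, n_trials=1)
    else:
        sigma2_mz = max(fit.hlm.sigma2_mz, 0.0)
        sigma2_dz = max(fit.hlm.sigma2_dz, 0.0)
        sim_kwargs = dict(omega02=omega02, n_trials=int(design["n_trials"]))
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(n_boot, dtype=np.uint32)
    samples: dict[str, list] = {"h2": [], "c2": [], "e2": [], "rv": []}
    failures = 0
    for b in range(n_boot):
        data = simulate_hlm_structure(
            tau2_mz,
            tau2_dz,
            sigma2_mz,
            sigma2_dz,
            n_fam_mz=int(design["n_fam_mz"]),
            n_fam_dz=int(design["n_fam_dz"]),
            seed=int(child_seeds[b]),
            **sim_kwargs,
        )
        try:
            if fit.level == "trial":
                refit = fit_hlm_ml(data, opts)
            elif fit.level == "aggregated":
                refit = fit_aggregated(data, opts)
            else:
                refit = fit_adjusted(
                    data, opts, k_conditions=int(design.get("k_conditions", 1))
                )
        except Exception:
            failures += 1
            continue
        samples["h2"].append(refit.proportions.h2)
        samples["c2"].append(refit.proportions.c2)
        samples["e2"].append(refit.proportions.e2)
        samples["rv"].append(refit.rv if refit.rv is not None else np.nan)
    intervals: dict = {}
    for key, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size:
            lo, hi = np.percentile(arr, [2.5, 97.5])
            intervals[key] = (float(lo), float(hi))
    intervals["n_failures"] = failures
    intervals["unreliable"] = failures > 0.2 * n_boot
    fit.intervals = intervals
    return intervals


# ---------------------------------------------------------------------------
# covariate residualization


def residualize_covariates(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Replace y with OLS residuals on the given covariate columns.

    Categorical covariates are dummy-coded; an intercept is always included,
    so the output is centered. When a condition column is present the
    regression runs separately per condition. This is a linear fixed-effects
    approximation to modeling the covariates jointly with the hierarchy.
    """
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise SchemaError(f"covariate columns not found: {missing}")
    out = table.copy()

    def _resid(sub: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in covariates:
            col = sub[c]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float)[:, None])
            else:
                dummies = pd.get_dummies(col.astype(str), drop_first=True)
                if dummies.shape[1]:
                    cols.append(dummies.to_numpy(dtype=float))
        x = np.hstack([np.ones((len(sub), 1))] + cols) if cols else np.ones((len(sub), 1))
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            raise SchemaError(
                f"rank-deficient covariate design (rank {rank} < {x.shape[1]} columns)"
            )
        beta, *_ = np.linalg.lstsq(x, sub["y"].to_numpy(dtype=float), rcond=None)
        return sub["y"].to_numpy(dtype=float) - x @ beta

    if "condition" in out.columns:
        for label, idx in out.groupby("condition", observed=True).groups.items():
            out.loc[idx, "y"] = _resid(out.loc[idx])
    else:
        out["y"] = _resid(out)
    return out
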