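"""Generate trial-level twin datasets from the ACE + trial-noise mechanism.

The generating model is the three-level hierarchy used throughout the
package: each individual's latent trait is

    theta = alpha + A + C + E,

where the twin pair's additive-genetic effects (A1, A2) are bivariate normal
with correlation rho_z (1 for MZ, 0.5 for DZ) and variance sigma_A^2, the
shared-environment effect C is identical within a family with variance
sigma_C^2, and the nonshared effects E are independent with variance
sigma_E^2. Observed trials are then

    y_t ~ Normal(theta, omega_0^2),  t = 1..T,

or, in ``lognormal`` mode, ``log y_t ~ Normal(theta, omega_0^2)`` — the ACE
structure lives on the log scale, so variance-component recovery is defined
on log-trials (mirroring reaction-time-style traits).

In two-condition mode the family- and individual-level effects are bivariate
across conditions with user-set cross-condition correlations (the
covariances are nuisance structure for heritability itself but shape the
between-condition *contrast*, whose family/individual variances are
``2*v*(1 - rho)``).

Reproducibility: each zygosity/stage pair draws from its own seeded stream,
and random numbers are laid out family-major, so enlarging the family count
appends new families without reshuffling earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .core import (
    RELATEDNESS,
    SemComponents,
    falconer,
    hlm_from_sem,
    twin_correlation_from_hlm,
    TwinCorrelations,
)

__all__ = [
    "SimConfig",
    "simulate",
    "draw_latent_effects",
    "draw_trials",
    "config_from_targets",
    "simulate_hlm_structure",
    "two_condition_truth",
    "config_to_yaml",
    "config_from_yaml",
]

_ZYGOSITIES = ("MZ", "DZ")
_CONDITION_LABELS = ("c1", "c2")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated twin study.

    ``alpha`` is the population intercept (a pair in two-condition mode).
    ``cross_condition_corr`` holds the family-level and individual-level
    cross-condition correlations (two-condition mode only; default 0.5 each,
    i.e. off-diagonal covariance ``0.5 * v`` at each level).
    """

    n_fam_mz: int
    n_fam_dz: int
    n_trials: int
    components: SemComponents
    omega02: float
    alpha: float | tuple[float, float] = 0.0
    trial_family: str = "gaussian"
    n_conditions: int = 1
    cross_condition_corr: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_fam_mz < 1 or self.n_fam_dz < 1:
            raise ValueError("family counts must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.components.nonnegative:
            raise ValueError("generating ACE components must be nonnegative")
        if self.omega02 < 0:
            raise ValueError("omega02 must be >= 0")
        if self.trial_family not in ("gaussian", "lognormal"):
            raise ValueError("trial_family must be 'gaussian' or 'lognormal'")
        if self.n_conditions not in (1, 2):
            raise ValueError("n_conditions must be 1 or 2")
        for rho in self.cross_condition_corr:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("cross-condition correlations must lie in [-1, 1]")
        if self.n_conditions == 2 and np.ndim(self.alpha) == 0:
            object.__setattr__(self, "alpha", (float(self.alpha), float(self.alpha)))

    def alphas(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.alpha, dtype=float))


def _stage_rng(cfg: SimConfig, stage: int, zyg_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stage, zyg_index)))


def _pair_chol(rho: float) -> np.ndarray:
    # lower Cholesky factor of [[1, rho], [rho, 1]]
    return np.array([[1.0, 0.0], [rho, np.sqrt(max(0.0, 1.0 - rho * rho))]])


def _latent_width(cfg: SimConfig) -> int:
    # one condition: A pair (2) + C (1) + E pair (2); two conditions:
    # family bivariate (2) + two twins x individual bivariate (4)
    return 5 if cfg.n_conditions == 1 else 6


def _thetas_from_block(block: np.ndarray, cfg: SimConfig, zygosity: str) -> np.ndarray:
    """Transform a (F, width) standard-normal block into latent traits.

    Returns shape (F, 2) in one-condition mode and (F, 2, 2) —
    (family, twin, condition) — in two-condition mode.
    """
    s = cfg.components
    if cfg.n_conditions == 1:
        rho = RELATEDNESS[zygosity]
        la = _pair_chol(rho) * np.sqrt(s.var_a)
        a = block[:, 0:2] @ la.T
        c = np.sqrt(s.var_c) * block[:, 2:3]
        e = np.sqrt(s.var_e) * block[:, 3:5]
        return cfg.alphas()[0] + a + c + e
    # two conditions: hierarchical (family/individual) representation
    hlm = hlm_from_sem(s)
    tau2 = hlm.tau2_mz if zygosity == "MZ" else hlm.tau2_dz
    sigma2 = hlm.sigma2_mz if zygosity == "MZ" else hlm.sigma2_dz
    rho_f, rho_i = cfg.cross_condition_corr
    lf = _pair_chol(rho_f) * np.sqrt(tau2)
    li = _pair_chol(rho_i) * np.sqrt(sigma2)
    nu = cfg.alphas()[None, :] + block[:, 0:2] @ lf.T  # (F, cond)
    d1 = block[:, 2:4] @ li.T
    d2 = block[:, 4:6] @ li.T
    return np.stack([nu + d1, nu + d2], axis=1)  # (F, twin, cond)


def draw_latent_effects(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-individual latent traits theta for every family.

    Returns one row per individual (and per condition in two-condition mode)
    with columns ``family_id, zygosity, individual_id[, condition], theta``.
    """
    parts = []
    offset = 0
    for zi, zyg in enumerate(_ZYGOSITIES):
        n_fam = cfg.n_fam_mz if zyg == "MZ" else cfg.n_fam_dz
        g = rng if rng is not None else _stage_rng(cfg, 0, zi)
        block = g.standard_normal((n_fam, _latent_width(cfg)))
        theta = _thetas_from_block(block, cfg, zyg)
        fam = offset + np.arange(n_fam)
        if cfg.n_conditions == 1:
            df = pd.DataFrame(
                {
                    "family_id": np.repeat(fam, 2),
                    "zygosity": zyg,
                    "individual_id": np.tile([1, 2], n_fam),
                    "theta": theta.reshape(-1),
                }
            )
        else:
            df = pd.DataFrame(
                {
                    "family_id": np.repeat(fam, 4),
                    "zygosity": zyg,
                    "individual_id": np.tile(np.repeat([1, 2], 2), n_fam),
                    "condition": np.tile(_CONDITION_LABELS, 2 * n_fam),
                    "theta": theta.reshape(-1),
                }
            )
        parts.append(df)
        offset += n_fam
    return pd.concat(parts, ignore_index=True)


def draw_trials(
    theta: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Attach T noisy trials to each latent trait row.

    ``gaussian`` mode draws y ~ Normal(theta, omega_0^2); ``lognormal`` mode
    draws log y ~ Normal(theta, omega_0^2).
    """
    t = cfg.n_trials
    omega0 = np.sqrt(cfg.omega02)
    parts = []
    for zi, zyg in enumerate(_ZYGOSITIES):
        sub = theta[theta["zygosity"] == zyg]
        if sub.empty:
            continue
        n_rows = len(sub)
        g = rng if rng is not None else _stage_rng(cfg, 1, zi)
        rows_per_family = 2 * cfg.n_conditions
        if n_rows % rows_per_family == 0:
            # family-major layout: stable under changes in family count
            n_fam = n_rows // rows_per_family
            noise = g.standard_normal((n_fam, rows_per_family * t)).reshape(n_rows, t)
        else:
            noise = g.standard_normal((n_rows, t))
        y = sub["theta"].to_numpy()[:, None] + omega0 * noise
        if cfg.trial_family == "lognormal":
            y = np.exp(y)
        out = sub.loc[sub.index.repeat(t)].drop(columns="theta").reset_index(drop=True)
        out["trial"] = np.tile(np.arange(1, t + 1), n_rows)
        out["y"] = y.reshape(-1)
        parts.append(out)
    return pd.concat(parts, ignore_index=True)


def simulate(cfg: SimConfig) -> pd.DataFrame:
    """Draw a complete trial-level twin dataset, deterministic given the config seed."""
    return draw_trials(draw_latent_effects(cfg), cfg)


def config_from_targets(
    h2: float,
    c2: float,
    rv: float,
    total_var: float = 1.0,
    *,
    n_fam_mz: int,
    n_fam_dz: int,
    n_trials: int,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """Build a config from the (h^2, c^2, Rv) axes of a simulation study.

    Components are the proportions times ``total_var``; the trial variance
    follows from the SD-scale variability ratio, omega_0^2 = Rv^2 * total_var.
    """
    if h2 < 0 or c2 < 0 or h2 + c2 > 1:
        raise ValueError("need h2 >= 0, c2 >= 0 and h2 + c2 <= 1")
    if rv < 0:
        raise ValueError("rv must be >= 0")
    if total_var <= 0:
        raise ValueError("total_var must be > 0")
    components = SemComponents(
        h2 * total_var, c2 * total_var, max(1.0 - h2 - c2, 0.0) * total_var
    )
    return SimConfig(
        n_fam_mz=n_fam_mz,
        n_fam_dz=n_fam_dz,
        n_trials=n_trials,
        components=components,
        omega02=rv * rv * total_var,
        seed=seed,
        **kwargs,
    )


def simulate_hlm_structure(
    tau2_mz: float,
    tau2_dz: float,
    sigma2_mz: float,
    sigma2_dz: float,
    omega02: float,
    *,
    n_fam_mz: int,
    n_fam_dz: int,
    n_trials: int,
    alpha: float = 0.0,
    seed: int = 0,
    trial_family: str = "gaussian",
) -> pd.DataFrame:
    """Simulate directly at the hierarchical level, without homogeneity.

    Family effects are shared within a family (variance tau_z^2), individual
    deviations independent (sigma_z^2), trials Gaussian around the latent
    trait (omega_0^2). Used by the parametric bootstrap, where per-zygosity
    fitted variances need not satisfy the ACE homogeneity constraints.
    """
    for v in (tau2_mz, tau2_dz, sigma2_mz, sigma2_dz, omega02):
        if v < 0:
            raise ValueError("variances must be nonnegative")
    t = n_trials
    omega0 = np.sqrt(omega02)
    parts = []
    offset = 0
    per_zyg = {"MZ": (n_fam_mz, tau2_mz, sigma2_mz), "DZ": (n_fam_dz, tau2_dz, sigma2_dz)}
    for zi, zyg in enumerate(_ZYGOSITIES):
        n_fam, tau2, sigma2 = per_zyg[zyg]
        g = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, zi)))
        block = g.standard_normal((n_fam, 3 + 2 * t))
        nu = alpha + np.sqrt(tau2) * block[:, 0:1]
        theta = nu + np.sqrt(sigma2) * block[:, 1:3]  # (F, twin)
        y = theta.reshape(-1)[:, None] + omega0 * block[:, 3:].reshape(2 * n_fam, t)
        if trial_family == "lognormal":
            y = np.exp(y)
        parts.append(
            pd.DataFrame(
                {
                    "family_id": np.repeat(offset + np.arange(n_fam), 2 * t),
                    "zygosity": zyg,
                    "individual_id": np.tile(np.repeat([1, 2], t), n_fam),
                    "trial": np.tile(np.arange(1, t + 1), 2 * n_fam),
                    "y": y.reshape(-1),
                }
            )
        )
        offset += n_fam
    return pd.concat(parts, ignore_index=True)


def two_condition_truth(cfg: SimConfig) -> dict:
    """Generating per-condition and contrast quantities for a two-condition config.

    The contrast (condition 1 minus condition 2) has family variance
    2*tau_z^2*(1 - rho_fam) and individual variance 2*sigma_z^2*(1 - rho_ind),
    and its trial-mean noise variance is 2*omega_0^2/T.
    """
    if cfg.n_conditions != 2:
        raise ValueError("config is not two-condition")
    hlm = hlm_from_sem(cfg.components)
    rho_f, rho_i = cfg.cross_condition_corr
    out: dict = {"condition": {}, "contrast": {}}
    r_cond = {}
    r_contrast = {}
    for zyg, tau2, sigma2 in (
        ("MZ", hlm.tau2_mz, hlm.sigma2_mz),
        ("DZ", hlm.tau2_dz, hlm.sigma2_dz),
    ):
        tau2_d = 2.0 * tau2 * (1.0 - rho_f)
        sigma2_d = 2.0 * sigma2 * (1.0 - rho_i)
        out["contrast"][zyg] = {"tau2": tau2_d, "sigma2": sigma2_d}
        r_cond[zyg] = twin_correlation_from_hlm(tau2, sigma2)
        r_contrast[zyg] = (
            twin_correlation_from_hlm(tau2_d, sigma2_d) if tau2_d + sigma2_d > 0 else float("nan")
        )
        out["condition"][zyg] = {"tau2": tau2, "sigma2": sigma2}
    out["condition"]["proportions"] = falconer(TwinCorrelations(r_cond["MZ"], r_cond["DZ"]))
    out["contrast"]["proportions"] = falconer(
        TwinCorrelations(r_contrast["MZ"], r_contrast["DZ"])
    )
    return out


def config_to_yaml(cfg: SimConfig, path) -> None:
    d = {
        "n_fam_mz": cfg.n_fam_mz,
        "n_fam_dz": cfg.n_fam_dz,
        "n_trials": cfg.n_trials,
        "components": cfg.components.as_dict(),
        "omega02": cfg.omega02,
        "alpha": list(cfg.alpha) if isinstance(cfg.alpha, tuple) else cfg.alpha,
        "trial_family": cfg.trial_family,
        "n_conditions": cfg.n_conditions,
        "cross_condition_corr": list(cfg.cross_condition_corr),
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path, *, seed: int | None = None) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    comp = d.pop("components")
    components = SemComponents(comp["var_a"], comp["var_c"], comp["var_e"])
    alpha = d.pop("alpha", 0.0)
    if isinstance(alpha, list):
        alpha = tuple(alpha)
    ccc = d.pop("cross_condition_corr", (0.5, 0.5))
    cfg = SimConfig(components=components, alpha=alpha, cross_condition_corr=tuple(ccc), **d)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
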