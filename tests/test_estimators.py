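"""Estimator correctness: oracle equivalence, unbiasedness, adjustment, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import twinhlm as th
from twinhlm.errors import (
    IdentifiabilityError,
    OverAdjustmentError,
    SchemaError,
    UnbalancedDataError,
)

from oracles import brute_force_nested_moments


class TestAggregate:
    def test_hand_computed_example(self):
        table = pd.DataFrame(
            {
                "family_id": [0] * 3,
                "zygosity": ["MZ"] * 3,
                "individual_id": [1] * 3,
                "trial": [1, 2, 3],
                "y": [1.0, 2.0, 3.0],
            }
        )
        agg = th.aggregate(table)
        assert len(agg) == 1
        row = agg.iloc[0]
        assert (row["mean_y"], row["var_y"], row["n_trials"]) == (2.0, 1.0, 3)

    def test_single_trial_has_missing_variance(self):
        table = pd.DataFrame(
            {"family_id": [0], "zygosity": ["MZ"], "individual_id": [1], "y": [5.0]}
        )
        agg = th.aggregate(table)
        assert agg.iloc[0]["mean_y"] == 5.0
        assert np.isnan(agg.iloc[0]["var_y"])

    def test_idempotent_on_aggregated_input(self, small_trial_table):
        agg = th.aggregate(small_trial_table)
        again = th.aggregate(agg)
        pd.testing.assert_frame_equal(agg, again)


class TestEstimateOmega0:
    def test_mean_of_individual_variances(self):
        agg = pd.DataFrame(
            {
                "family_id": [0, 0],
                "zygosity": ["MZ", "MZ"],
                "individual_id": [1, 2],
                "mean_y": [0.0, 0.0],
                "var_y": [2.0, 4.0],
                "n_trials": [5, 5],
            }
        )
        assert th.estimate_omega0(agg) == pytest.approx(3.0)

    def test_zero_noise_data(self):
        cfg = th.config_from_targets(0.5, 0.2, 0.0, n_fam_mz=10, n_fam_dz=10,
                                     n_trials=4, seed=2)
        assert th.estimate_omega0(th.aggregate(th.simulate(cfg))) == pytest.approx(
            0.0, abs=1e-24
        )

    def test_consistency_on_simulated_data(self):
        cfg = th.config_from_targets(0.5, 0.2, 2.0, n_fam_mz=2500, n_fam_dz=2500,
                                     n_trials=20, seed=14)
        agg = th.aggregate(th.simulate(cfg))
        est = th.estimate_omega0(agg)
        se = cfg.omega02 * np.sqrt(2.0 / (cfg.n_trials - 1)) / np.sqrt(len(agg))
        assert abs(est - cfg.omega02) < 3 * se

    def test_error_when_no_repeats(self):
        agg = pd.DataFrame(
            {
                "family_id": [0], "zygosity": ["MZ"], "individual_id": [1],
                "mean_y": [1.0], "var_y": [np.nan], "n_trials": [1],
            }
        )
        with pytest.raises(IdentifiabilityError):
            th.estimate_omega0(agg)


class TestAnovaMoments:
    def test_matches_brute_force_sums_of_squares(self, small_trial_table):
        for zyg in ("MZ", "DZ"):
            mom = th.anova_moments(small_trial_table, zyg)
            oracle = brute_force_nested_moments(small_trial_table, zyg)
            assert mom.tau2 == pytest.approx(oracle[0], abs=1e-10)
            assert mom.sigma2 == pytest.approx(oracle[1], abs=1e-10)
            assert mom.omega02 == pytest.approx(oracle[2], abs=1e-10)

    def test_noise_free_tau2_is_family_mean_variance(self):
        cfg = th.config_from_targets(0.9, 0.1, 0.0, n_fam_mz=50, n_fam_dz=50,
                                     n_trials=3, seed=6)
        # sigma_E^2 = 0, omega_0^2 = 0: y is constant within each family
        table = th.simulate(cfg)
        mom = th.anova_moments(table, "MZ")
        fam_means = (
            table[table["zygosity"] == "MZ"].groupby("family_id")["y"].mean()
        )
        assert mom.tau2 == pytest.approx(float(fam_means.var(ddof=1)), abs=1e-12)
        assert mom.sigma2 == pytest.approx(0.0, abs=1e-12)
        assert mom.omega02 == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_over_replicates(self):
        # mean moment estimates across replicates track the generators
        truth = th.hlm_from_sem(th.SemComponents(0.6, 0.2, 0.2))
        omega02 = 4.0
        ests = {"tau2": [], "sigma2": [], "omega02": []}
        for rep in range(200):
            cfg = th.config_from_targets(
                0.6, 0.2, 2.0, n_fam_mz=500, n_fam_dz=2, n_trials=20, seed=50_000 + rep
            )
            mom = th.anova_moments(th.simulate(cfg), "MZ")
            ests["tau2"].append(mom.tau2)
            ests["sigma2"].append(mom.sigma2)
            ests["omega02"].append(mom.omega02)
        for key, target in (
            ("tau2", truth.tau2_mz), ("sigma2", truth.sigma2_mz), ("omega02", omega02)
        ):
            arr = np.asarray(ests[key])
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - target) < 3 * se, key

    def test_unbalanced_design_directs_to_ml(self, small_trial_table):
        broken = small_trial_table.drop(index=small_trial_table.index[0])
        with pytest.raises(UnbalancedDataError, match="ml"):
            th.anova_moments(broken, "MZ")

    def test_single_trial_not_identifiable(self):
        cfg = th.config_from_targets(0.5, 0.2, 1.0, n_fam_mz=10, n_fam_dz=10,
                                     n_trials=1, seed=3)
        with pytest.raises(IdentifiabilityError, match="aggregated"):
            th.anova_moments(th.simulate(cfg), "MZ")


class TestFitHlmMl:
    def test_agrees_with_moments_on_large_balanced_data(self):
        # ML and method-of-moments coincide up to O(1/F) mean-estimation terms
        cfg = th.config_from_targets(0.6, 0.2, 1.0, n_fam_mz=2000, n_fam_dz=2000,
                                     n_trials=5, seed=42)
        table = th.simulate(cfg)
        ml = th.fit_hlm_ml(table, th.EstimatorOptions(method="ml"))
        for zyg, tau_attr, sig_attr in (
            ("MZ", "tau2_mz", "sigma2_mz"), ("DZ", "tau2_dz", "sigma2_dz")
        ):
            mom = th.anova_moments(table, zyg)
            assert getattr(ml.hlm, tau_attr) == pytest.approx(mom.tau2, rel=1e-3)
            assert getattr(ml.hlm, sig_attr) == pytest.approx(mom.sigma2, rel=1e-3)
            # omega_0^2 is pooled across zygosities in the fit; compare per-zygosity
            assert ml.diagnostics["per_zygosity"][zyg]["omega02"] == pytest.approx(
                mom.omega02, rel=1e-3
            )
        assert all(
            d["converged"] for d in ml.diagnostics["per_zygosity"].values()
        )

    def test_moments_method_routes_through_anova(self, medium_trial_table):
        fit = th.fit_hlm_ml(medium_trial_table, th.EstimatorOptions(method="moments"))
        mom = th.anova_moments(medium_trial_table, "MZ")
        assert fit.hlm.tau2_mz == pytest.approx(mom.tau2)
        assert fit.method == "moments"
        assert fit.proportions.h2 + fit.proportions.c2 + fit.proportions.e2 == (
            pytest.approx(1.0)
        )

    def test_handles_unbalanced_trials_and_singletons(self, small_trial_table):
        # drop some trials and one twin entirely: moments would refuse
        mangled = small_trial_table.drop(index=small_trial_table.index[:7])
        fit = th.fit_hlm_ml(mangled, th.EstimatorOptions(method="ml"))
        assert np.isfinite(fit.loglik)
        assert np.isfinite(fit.proportions.h2)

    def test_single_trial_data_errors(self):
        cfg = th.config_from_targets(0.5, 0.2, 1.0, n_fam_mz=20, n_fam_dz=20,
                                     n_trials=1, seed=4)
        with pytest.raises(IdentifiabilityError, match="aggregate"):
            th.fit_hlm_ml(th.simulate(cfg), th.EstimatorOptions(method="ml"))

    def test_log_transform_requires_positive_values(self, small_trial_table):
        opts = th.EstimatorOptions(method="ml", log_transform=True)
        with pytest.raises(ValueError, match="positive"):
            th.fit_hlm_ml(small_trial_table, opts)

    def test_rv_reported_as_zygosity_average(self, medium_trial_table):
        fit = th.fit_hlm_ml(medium_trial_table, th.EstimatorOptions(method="ml"))
        assert fit.rv == pytest.approx(
            np.mean([fit.rv_by_zygosity["MZ"], fit.rv_by_zygosity["DZ"]])
        )
        assert fit.rv == pytest.approx(2.0, rel=0.1)


class TestFitAggregated:
    def test_zero_noise_limit_matches_trial_level_fit(self):
        cfg = th.config_from_targets(0.6, 0.2, 0.0, n_fam_mz=400, n_fam_dz=400,
                                     n_trials=5, seed=13)
        table = th.simulate(cfg)
        trial = th.fit_hlm_ml(table, th.EstimatorOptions(method="moments"))
        agg = th.fit_aggregated(th.aggregate(table))
        assert agg.correlations.r_mz == pytest.approx(trial.correlations.r_mz, abs=5e-3)
        assert agg.correlations.r_dz == pytest.approx(trial.correlations.r_dz, abs=5e-3)

    def test_attenuation_on_average(self):
        # mean fitted r_tilde over replicates approximates r * U
        h2, c2, rv, t = 0.5, 0.25, 2.0, 20
        u = th.attenuation_factor(th.AttenuationContext(rv, t))
        truth = th.SemComponents(h2, c2, 1 - h2 - c2)
        r_true = th.expected_twin_correlation(truth, "MZ")
        vals = []
        for rep in range(60):
            cfg = th.config_from_targets(h2, c2, rv, n_fam_mz=300, n_fam_dz=2,
                                         n_trials=t, seed=90_000 + rep)
            fit = th.fit_aggregated(th.aggregate(th.simulate(cfg)))
            vals.append(fit.correlations.r_mz)
        arr = np.asarray(vals)
        se = arr.std(ddof=1) / np.sqrt(len(arr))
        assert abs(arr.mean() - r_true * u) < 3 * se

    def test_ml_variant_close_to_moments(self, medium_trial_table):
        agg = th.aggregate(medium_trial_table)
        mom = th.fit_aggregated(agg, th.EstimatorOptions(method="moments"))
        ml = th.fit_aggregated(agg, th.EstimatorOptions(method="ml"))
        assert ml.correlations.r_mz == pytest.approx(mom.correlations.r_mz, abs=0.01)


class TestFitAdjusted:
    def test_zero_omega_reduces_to_aggregated(self):
        cfg = th.config_from_targets(0.6, 0.2, 0.0, n_fam_mz=200, n_fam_dz=200,
                                     n_trials=5, seed=17)
        agg = th.aggregate(th.simulate(cfg))
        base = th.fit_aggregated(agg)
        adj = th.fit_adjusted(agg)
        assert adj.correlations.r_mz == pytest.approx(base.correlations.r_mz)
        assert adj.correlations.r_dz == pytest.approx(base.correlations.r_dz)

    def test_true_omega_adjustment_matches_core_identity(self):
        # supplying omega_0^2 directly must reproduce the closed-form
        # disattenuation applied to the aggregated fit's variances
        cfg = th.config_from_targets(0.6, 0.2, 2.0, n_fam_mz=500, n_fam_dz=500,
                                     n_trials=10, seed=19)
        agg = th.aggregate(th.simulate(cfg))
        base = th.fit_aggregated(agg)
        adj = th.fit_adjusted(agg, omega02=cfg.omega02)
        expected_mz = th.adjusted_correlation(
            base.hlm.tau2_mz, base.hlm.sigma2_mz, cfg.omega02, cfg.n_trials
        )
        expected_dz = th.adjusted_correlation(
            base.hlm.tau2_dz, base.hlm.sigma2_dz, cfg.omega02, cfg.n_trials
        )
        assert adj.correlations.r_mz == pytest.approx(expected_mz, abs=1e-12)
        assert adj.correlations.r_dz == pytest.approx(expected_dz, abs=1e-12)
        # and at the population level the identity is exact: adjusting the
        # attenuated expected variances returns the generating correlation
        hlm = th.hlm_from_sem(cfg.components)
        sigma2_tilde = hlm.sigma2_mz + cfg.omega02 / cfg.n_trials
        assert th.adjusted_correlation(
            hlm.tau2_mz, sigma2_tilde, cfg.omega02, cfg.n_trials
        ) == pytest.approx(
            th.twin_correlation_from_hlm(hlm.tau2_mz, hlm.sigma2_mz), abs=1e-12
        )

    def test_mean_adjusted_h2_recovers_truth_over_replicates(self):
        vals = []
        for rep in range(60):
            cfg = th.config_from_targets(0.6, 0.2, 2.0, n_fam_mz=300, n_fam_dz=300,
                                         n_trials=10, seed=110_000 + rep)
            adj = th.fit_adjusted(th.aggregate(th.simulate(cfg)))
            vals.append(adj.proportions.h2)
        arr = np.asarray(vals)
        se = arr.std(ddof=1) / np.sqrt(len(arr))
        assert abs(arr.mean() - 0.6) < 3 * se

    def test_over_adjustment_raises_by_default_and_clips_on_request(self):
        agg = pd.DataFrame(
            {
                "family_id": np.repeat(np.arange(6), 2),
                "zygosity": ["MZ"] * 6 + ["DZ"] * 6,
                "individual_id": np.tile([1, 2], 6),
                "mean_y": [0.0, 0.01, -0.01, 0.02, 0.01, -0.02,
                           0.0, 0.01, -0.01, 0.02, 0.01, -0.02],
                "var_y": [50.0] * 12,
                "n_trials": [10] * 12,
            }
        )
        with pytest.raises(OverAdjustmentError):
            th.fit_adjusted(agg)
        adj = th.fit_adjusted(agg, th.EstimatorOptions(boundary_policy="clip"))
        assert adj.diagnostics["over_adjustment_clipped"]

    def test_diagnostics_carry_omega_estimate(self, medium_trial_table):
        adj = th.fit_adjusted(th.aggregate(medium_trial_table))
        assert adj.diagnostics["omega02_hat"] == pytest.approx(4.0, rel=0.05)
        assert adj.level == "adjusted"
        assert adj.rv == pytest.approx(2.0, rel=0.1)


class TestTwoCondition:
    def _config(self, **kw):
        base = dict(
            n_fam_mz=300, n_fam_dz=300, n_trials=10,
            components=th.SemComponents(0.4, 0.2, 0.4), omega02=1.0,
            n_conditions=2, seed=23,
        )
        base.update(kw)
        return th.SimConfig(**base)

    def test_effect_coding_equals_direct_difference(self):
        fit = th.fit_two_condition(th.simulate(self._config()))
        assert fit.diagnostics["route_discrepancy"] < 1e-8

    def test_perfectly_correlated_conditions_flag_degenerate_contrast(self):
        cfg = self._config(cross_condition_corr=(1.0, 1.0), omega02=0.0)
        fit = th.fit_two_condition(th.simulate(cfg))
        assert fit.contrast.degenerate
        assert np.isnan(fit.contrast.proportions.h2)

    def test_contrast_recovery_across_replicates(self):
        # generating contrast h^2 = 0.4 (equal cross-condition correlations
        # leave the contrast proportions equal to the per-condition ones)
        means = []
        for rep in range(100):
            cfg = th.SimConfig(
                n_fam_mz=1000, n_fam_dz=1000, n_trials=50,
                components=th.SemComponents(0.4, 0.2, 0.4),
                omega02=1.0, n_conditions=2, seed=70_000 + rep,
            )
            fit = th.fit_two_condition(th.simulate(cfg))
            means.append(fit.contrast.proportions.h2)
        arr = np.asarray(means)
        se = arr.std(ddof=1) / np.sqrt(len(arr))
        assert abs(arr.mean() - 0.4) < 3 * se
        # sanity: the contrast here is noisy (Rv_contrast = sqrt(2) * Rv)
        assert arr.std(ddof=1) > 0.01

    def test_contrast_rv_uses_doubled_trial_variance(self):
        cfg = self._config(seed=29)
        fit = th.fit_two_condition(th.simulate(cfg))
        hlm = fit.contrast.hlm
        expected = np.mean(
            [
                np.sqrt(2 * fit.omega02_hat / (hlm.tau2_mz + hlm.sigma2_mz)),
                np.sqrt(2 * fit.omega02_hat / (hlm.tau2_dz + hlm.sigma2_dz)),
            ]
        )
        assert fit.contrast.rv == pytest.approx(expected)

    def test_requires_exactly_two_conditions(self, small_trial_table):
        with pytest.raises(ValueError, match="condition"):
            th.fit_two_condition(small_trial_table)


@pytest.fixture(scope="module")
def bootstrap_fit():
    cfg = th.config_from_targets(0.6, 0.2, 1.0, n_fam_mz=200, n_fam_dz=200,
                                 n_trials=5, seed=33)
    return th.fit_hlm_ml(th.simulate(cfg), th.EstimatorOptions(method="moments"))


class TestParametricBootstrap:
    @pytest.fixture()
    def fitted(self, bootstrap_fit):
        return bootstrap_fit

    def test_interval_contains_point_estimate(self, fitted):
        iv = th.parametric_bootstrap(fitted, n_boot=60, seed=7)
        lo, hi = iv["h2"]
        assert lo <= fitted.proportions.h2 <= hi
        assert iv["n_failures"] == 0
        assert not iv["unreliable"]

    def test_deterministic_given_seed(self, fitted):
        a = th.parametric_bootstrap(fitted, n_boot=25, seed=11)
        b = th.parametric_bootstrap(fitted, n_boot=25, seed=11)
        assert a["h2"] == b["h2"] and a["rv"] == b["rv"]

    def test_coverage_is_loosely_calibrated(self):
        # desk-scale coverage check at nominal 95%
        truth_h2 = 0.6
        hits = 0
        n_outer = 40
        for rep in range(n_outer):
            cfg = th.config_from_targets(
                truth_h2, 0.2, 1.0, n_fam_mz=150, n_fam_dz=150, n_trials=5,
                seed=30_000 + rep,
            )
            fit = th.fit_hlm_ml(th.simulate(cfg), th.EstimatorOptions(method="moments"))
            iv = th.parametric_bootstrap(fit, n_boot=60, seed=rep)
            lo, hi = iv["h2"]
            hits += lo <= truth_h2 <= hi
        assert hits / n_outer >= 0.85


class TestResidualizeCovariates:
    def test_constant_covariate_centers_only(self, small_trial_table):
        table = small_trial_table.assign(site="one")
        out = th.residualize_covariates(table, ["site"])
        assert out["y"].mean() == pytest.approx(0.0, abs=1e-12)
        recentered = small_trial_table["y"] - small_trial_table["y"].mean()
        assert np.allclose(out["y"], recentered)

    def test_independent_covariate_leaves_estimates_unchanged(self, medium_trial_table):
        rng = np.random.default_rng(3)
        table = medium_trial_table.assign(noise=rng.standard_normal(len(medium_trial_table)))
        base = th.anova_moments(medium_trial_table, "MZ")
        resid = th.residualize_covariates(table, ["noise"])
        after = th.anova_moments(resid, "MZ")
        assert after.tau2 == pytest.approx(base.tau2, rel=0.02)
        assert after.omega02 == pytest.approx(base.omega02, rel=0.02)

    def test_injected_additive_effect_is_removed(self):
        cfg = th.config_from_targets(0.6, 0.2, 1.0, n_fam_mz=400, n_fam_dz=400,
                                     n_trials=5, seed=41)
        clean = th.simulate(cfg)
        sex = np.where(clean["individual_id"] == 1, "f", "m")
        shifted = clean.assign(sex=sex, y=clean["y"] + np.where(sex == "f", 2.0, 0.0))
        resid = th.residualize_covariates(shifted, ["sex"])
        h2_clean = th.fit_hlm_ml(clean, th.EstimatorOptions(method="moments")).proportions.h2
        h2_resid = th.fit_hlm_ml(resid, th.EstimatorOptions(method="moments")).proportions.h2
        assert h2_resid == pytest.approx(h2_clean, abs=0.03)

    def test_rank_deficient_design_reported(self, small_trial_table):
        table = small_trial_table.assign(a=1.0, b=2.0)
        with pytest.raises(SchemaError, match="rank"):
            th.residualize_covariates(table, ["a", "b"])


def test_sem_components_from_fit(medium_trial_table):
    fit = th.fit_hlm_ml(medium_trial_table, th.EstimatorOptions(method="moments"))
    sem = th.sem_components_from_fit(fit)
    assert sem.var_a == pytest.approx(0.6, abs=0.15)
    assert sem.total == pytest.approx(1.0, abs=0.15)
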