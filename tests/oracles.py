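"""Independent brute-force oracles used by the test suite.

These deliberately use explicit Python loops and first-principles formulas,
not the package's vectorized implementations, so agreement is evidence.
"""

from __future__ import annotations

import numpy as np


def brute_force_nested_moments(table, zygosity):
    """Nested-ANOVA variance components via explicit double-loop sums of squares.

    For a balanced design (F families x 2 twins x T trials) the expected
    mean squares are E[MS_trial] = w, E[MS_ind] = w + T*s,
    E[MS_fam] = w + T*s + 2*T*tau; inverting gives the moment estimates.
    """
    sub = table[table["zygosity"] == zygosity]
    families = sorted(sub["family_id"].unique())
    f_count = len(families)
    t_count = None
    ss_within = 0.0
    ss_ind = 0.0
    ss_fam = 0.0
    grand_values = [float(v) for v in sub["y"]]
    grand = sum(grand_values) / len(grand_values)
    for fam in families:
        fam_rows = sub[sub["family_id"] == fam]
        ind_means = []
        for ind in sorted(fam_rows["individual_id"].unique()):
            ys = [float(v) for v in fam_rows.loc[fam_rows["individual_id"] == ind, "y"]]
            if t_count is None:
                t_count = len(ys)
            assert len(ys) == t_count, "oracle requires balance"
            m = sum(ys) / len(ys)
            ind_means.append(m)
            for y in ys:
                ss_within += (y - m) ** 2
        assert len(ind_means) == 2, "oracle requires twin pairs"
        fam_mean = sum(ind_means) / 2.0
        for m in ind_means:
            ss_ind += t_count * (m - fam_mean) ** 2
        ss_fam += 2 * t_count * (fam_mean - grand) ** 2
    ms_trial = ss_within / (2 * f_count * (t_count - 1))
    ms_ind = ss_ind / f_count
    ms_fam = ss_fam / (f_count - 1)
    omega02 = ms_trial
    sigma2 = (ms_ind - ms_trial) / t_count
    tau2 = (ms_fam - ms_ind) / (2 * t_count)
    return tau2, sigma2, omega02


def ace_substitution_hlm(var_a, var_c, var_e):
    """Hierarchical variances implied by the twin covariance structure.

    Within a family, the shared part of the trait is rho_z*A-share + C:
    for MZ (rho=1) the family-level variance is var_a + var_c and the
    individual remainder var_e; for DZ (rho=1/2) half the genetic variance
    is shared, half individual.
    """
    return {
        "tau2_mz": var_a + var_c,
        "sigma2_mz": var_e,
        "tau2_dz": 0.5 * var_a + var_c,
        "sigma2_dz": 0.5 * var_a + var_e,
    }


def pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])
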