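import pandas as pd
import pytest
from hypothesis import settings

import twinhlm as th

settings.register_profile("suite", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_trial_table() -> pd.DataFrame:
    """Balanced 20-family-per-zygosity, 6-trial dataset with known generators."""
    cfg = th.config_from_targets(
        0.6, 0.2, 1.0, n_fam_mz=20, n_fam_dz=20, n_trials=6, seed=421
    )
    return th.simulate(cfg)


@pytest.fixture(scope="session")
def medium_trial_table() -> pd.DataFrame:
    """F=500/zygosity, T=20, Rv=2 dataset shared across estimator tests."""
    cfg = th.config_from_targets(
        0.6, 0.2, 2.0, n_fam_mz=500, n_fam_dz=500, n_trials=20, seed=97
    )
    return th.simulate(cfg)


@pytest.fixture()
def handmade_trials() -> pd.DataFrame:
    """Two families (one per zygosity), hand-enumerable values."""
    rows = []
    for fam, zyg in ((0, "MZ"), (1, "DZ")):
        for ind in (1, 2):
            for t, y in enumerate((1.0, 2.0, 3.0), start=1):
                rows.append(
                    {
                        "family_id": fam,
                        "zygosity": zyg,
                        "individual_id": ind,
                        "trial": t,
                        "y": y + ind + fam,
                    }
                )
    return pd.DataFrame(rows)
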