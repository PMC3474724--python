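import numpy as np
import pandas as pd
import pytest

import rpsurv as rs


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged default synthetic cohort (n=576, fixed seed)."""
    return rs.generate(rs.default_config(), seed=1)


@pytest.fixture(scope="session")
def big_cohort():
    """Large draw from the default configuration for calibration checks."""
    return rs.generate(rs.default_config(5000), seed=42)


@pytest.fixture(scope="session")
def lognormal_cohort():
    """Continuous (undiscretized) log-normal cohort, no covariate signal."""
    cfg = rs.GeneratorConfig(
        n=500,
        stratum_weights=(1.0, 0.0, 0.0, 0.0, 0.0),
        discretize=False,
    )
    return rs.generate(cfg, seed=7)


@pytest.fixture
def raw_frame():
    """Unpreprocessed cohort frame with raw PPS levels and missing values."""
    return pd.DataFrame(
        {
            "subject_id": range(1, 9),
            "time": [3.0, 5.0, 7.0, 2.0, 10.0, 4.0, 6.0, 9.0],
            "event": [1] * 8,
            "pps_group": pd.array(
                ["10", "20", "70", "50", "80", None, "30", "40"], dtype="string"
            ),
        }
    )


def untied_cohort(times, x):
    """Tiny single-covariate cohort helper for partial-likelihood oracles."""
    df = pd.DataFrame(
        {
            "subject_id": range(1, len(times) + 1),
            "time": np.asarray(times, dtype=float),
            "event": np.ones(len(times), dtype=int),
            "pps_group": pd.array(["10"] * len(times), dtype="string"),
            "x": np.asarray(x, dtype=float),
        }
    )
    return rs.SurvivalCohort(df, preprocessed=True)
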