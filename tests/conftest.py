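import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import densdep as dd
from densdep.data import AnnualSeries

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_survey(rows):
    """Build a SurveyDataset from (location, year, transect_id, density) tuples."""
    return dd.SurveyDataset(
        pd.DataFrame(rows, columns=["location", "year", "transect_id", "density"])
    )


def make_series(values, location="A", start_year=2004):
    values = np.asarray(values, dtype=float)
    return {
        location: AnnualSeries(
            location, np.arange(start_year, start_year + len(values)), values
        )
    }


@pytest.fixture
def tiny_survey():
    return make_survey(
        [
            ("A", 2004, "t0", 0.1),
            ("A", 2004, "t1", 0.2),
            ("A", 2005, "t0", 0.07),
            ("B", 2004, "t0", 0.05),
            ("B", 2005, "t0", 0.06),
        ]
    )


@pytest.fixture
def ricker_series():
    """Noise-free Ricker series started away from equilibrium."""
    traj = dd.simulate_trajectory(
        "ricker", {"lambda": 3.66, "beta": 19.11}, 0.0, 0.01, 11, 0
    )
    return make_series(traj)
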