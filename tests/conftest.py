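import numpy as np
import pandas as pd
import pytest

from rangeshift import SimConfig, run_analysis, simulate_experiment


def hourly_trajectory(xy, start="2018-01-01", animal_year_id="ay1", sex="F"):
    """Build a Trajectory from a coordinate list at hourly cadence."""
    from rangeshift import Trajectory

    xy = np.asarray(xy, float)
    ts = pd.date_range(start, periods=len(xy), freq="1h", tz="UTC")
    return Trajectory(
        animal_year_id=animal_year_id,
        animal_id=animal_year_id.split("-")[0],
        sex=sex,
        year=int(ts[0].year),
        fixes=pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]}),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic experiment shared by read-only tests."""
    return simulate_experiment(SimConfig(n_animal_years=6, rng_seed=5))


@pytest.fixture(scope="session")
def small_analysis(small_bundle):
    return run_analysis(
        small_bundle.trajectories,
        small_bundle.sites,
        small_bundle.schedules,
        fit_models=False,
    )
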