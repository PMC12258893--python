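import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rnai_memory as rm

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_design():
    """The default synthetic experiment: four strains spanning no-memory to
    long-memory kinetics, four blocks, three replicates, 100 scored."""
    return rm.SimulationDesign(
        strain_halflives={"JU1171": 0.7, "JU1395": 1.5, "N2": 3.0, "MY10": 5.5},
        seed=42,
    )


@pytest.fixture(scope="session")
def scoring_table(default_design):
    return rm.simulate_experiment(default_design)


@pytest.fixture(scope="session")
def halflife_df(default_design, scoring_table):
    groups = rm.group_replicates(scoring_table)
    return rm.halflife_table(
        groups, rm.schedules_of(default_design), axes=("generations", "days")
    )


@pytest.fixture(scope="session")
def model_data(halflife_df):
    sub = halflife_df[
        (halflife_df["axis"] == "generations") & (halflife_df["status"] != "censored")
    ]
    return sub.copy()


@pytest.fixture(scope="session")
def fitted_model(model_data):
    return rm.fit_glmm(model_data, rm.GlmmSpec())


def make_trajectory(pcts, generations=None, base_days=3.5, key=None):
    """Build a trajectory from raw percent values (generation axis 1..n by
    default; include a leading generation-0 point by passing generations)."""
    if generations is None:
        generations = list(range(1, len(pcts) + 1))
    key = key or rm.GroupKey("A", "N2", "20C_OP50", 1)
    points = tuple(
        rm.TrajectoryPoint(generation=g, day=g * base_days, pct_on=float(v))
        for g, v in zip(generations, pcts)
    )
    return rm.Trajectory(key=key, points=points)


@pytest.fixture
def trajectory_factory():
    return make_trajectory
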