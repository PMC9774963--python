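import numpy as np
import pytest

from beaktraj.data_model_io import (
    BeakSubsection, IndividualTrajectory, IsotopeMeasurement, PopulationSample,
)
from beaktraj.synthetic_data import make_fixture_table1


def make_trajectory(individual_id, d13c, d15n=None, sex="unknown", ml=200.0, **kw):
    """Trajectory from raw value lists; None marks a missing cell."""
    d15n = d15n if d15n is not None else [10.0] * len(d13c)
    subs = []
    for i, (a, b) in enumerate(zip(d13c, d15n), start=1):
        subs.append(BeakSubsection(
            index=i,
            measurement=IsotopeMeasurement(
                delta13c=float("nan") if a is None else a,
                delta15n=float("nan") if b is None else b,
            ),
        ))
    return IndividualTrajectory(
        individual_id=individual_id, subsections=subs, sex=sex,
        mantle_length_mm=ml, **kw)


@pytest.fixture(scope="session")
def table1():
    return make_fixture_table1()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_population():
    t1 = make_trajectory("A", [-20.5, -20.0, -19.5, -19.0], [8.0, 9.0, 10.0, 11.0])
    t2 = make_trajectory("B", [-21.0, -20.6, -20.2, -19.8], [9.5, 10.5, 11.5, 12.5])
    t3 = make_trajectory("C", [-19.8, -19.6, -19.4, -19.2], [7.0, 8.5, 10.0, 11.5])
    return PopulationSample(trajectories=[t1, t2, t3])
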