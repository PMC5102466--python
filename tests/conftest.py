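import numpy as np
import pytest

from maxratio import AmplificationCurve, LabelledResult, compute_maxratio
from maxratio.simulate import generate_plate

# Class mix used by the end-to-end fixtures: all five recurring profile
# shapes, dominated by negatives as on real screening plates.
DEFAULT_MIX = {
    "clear_positive": 60,
    "weak_positive": 30,
    "slow_riser": 40,
    "transient_negative": 30,
    "flat_negative": 200,
}


def logistic_curve(
    b0=1.0, amplitude=3.0, steepness=0.8, midpoint=25.0, n_cycles=45,
    drift=0.0, well_id="W1",
):
    """Noise-free 4PL curve used across tests."""
    c = np.arange(1, n_cycles + 1, dtype=float)
    rn = b0 + drift * c + amplitude / (1.0 + np.exp(-steepness * (c - midpoint)))
    return AmplificationCurve("P1", well_id, "T1", "S1", rn)


def labelled_results(plate):
    return [
        LabelledResult(compute_maxratio(c), plate.truth[c.well_id])
        for c in plate.curves
    ]


@pytest.fixture(scope="session")
def training_plate():
    return generate_plate(DEFAULT_MIX, master_seed=101)


@pytest.fixture(scope="session")
def query_plate():
    return generate_plate(DEFAULT_MIX, master_seed=202)


@pytest.fixture(scope="session")
def training_labelled(training_plate):
    return labelled_results(training_plate)


@pytest.fixture(scope="session")
def query_labelled(query_plate):
    return labelled_results(query_plate)
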