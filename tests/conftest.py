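import numpy as np
import pytest

from reachseq import PlantParams, two_reach_model
from reachseq.cohort import ExperimentDesign, generate_cohort

COHORT_SEED = 2024


@pytest.fixture(scope="session")
def default_params():
    return PlantParams()


@pytest.fixture(scope="session")
def go_model():
    """Terminal-cost rapid-transfer model with the printed parameters."""
    return two_reach_model("GO")


@pytest.fixture(scope="session")
def stop_model():
    return two_reach_model("STOP")


@pytest.fixture(scope="session")
def go_model_buildup():
    return two_reach_model("GO", variant="buildup")


@pytest.fixture(scope="session")
def stop_model_buildup():
    return two_reach_model("STOP", variant="buildup")


@pytest.fixture(scope="session")
def cohort_pair():
    """Five-participant GO and STOP cohorts with the full 900-trial design."""
    design = ExperimentDesign(n_participants=5)
    go = generate_cohort(design, "GO", COHORT_SEED, variant="buildup")
    stop = generate_cohort(design, "STOP", COHORT_SEED, variant="buildup")
    return go, stop


def rollout_noiseless(model, condition):
    """Convenience wrapper used across test modules."""
    return model.simulate(condition, noise_on=False)
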