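import numpy as np
import pandas as pd
import pytest

from jointcr import JointDataset, SimulationDesign, simulate_dataset


@pytest.fixture
def tiny_dataset() -> JointDataset:
    """Three subjects, five observations, hand-built and consistent."""
    obs = pd.DataFrame(
        {
            "subject_id": [1, 1, 2, 2, 3],
            "t": [0.0, 1.0, 0.0, 2.0, 0.0],
            "y": [6.0, 5.5, 7.1, 6.8, 4.9],
        }
    )
    surv = pd.DataFrame(
        {"subject_id": [1, 2, 3], "time": [4.0, 5.0, 2.5], "delta": [1, 2, 0]}
    )
    cov = pd.DataFrame(
        {
            "subject_id": [1, 2, 3],
            "treatment": [1.0, 0.0, 1.0],
            "age": [1.0, 0.0, 0.0],
            "male": [0.0, 1.0, 1.0],
            "sepsis": [1.0, 0.0, 1.0],
        }
    )
    return JointDataset(obs, surv, cov, horizon=28.0)


@pytest.fixture(scope="session")
def sim_dataset() -> JointDataset:
    """A seeded simulated dataset at the default study design, n=80."""
    return simulate_dataset(SimulationDesign(n=80, seed=42))


@pytest.fixture(scope="session")
def sim_design() -> SimulationDesign:
    return SimulationDesign(n=80, seed=42)
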