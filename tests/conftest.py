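import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from erpfa.dataset import Montage, EpochsSet

FIXTURES = Path(__file__).parent / "fixtures"

# generator warnings about singular random effects etc. are expected in
# boundary-condition simulations and would otherwise flood the output
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def reported_anova() -> pd.DataFrame:
    return pd.read_csv(FIXTURES / "reported_anova_tables.csv")


@pytest.fixture(scope="session")
def reported_model_comparison() -> pd.DataFrame:
    return pd.read_csv(FIXTURES / "reported_model_comparison.csv")


@pytest.fixture
def tiny_montage() -> Montage:
    return Montage(("Cz", "Pz", "Fz"), np.array([[0.0, 0.0], [0.0, -0.7], [0.0, 0.7]]))


def make_epochs(
    voltages,
    montage,
    participant_id="P01",
    sfreq=500.0,
    tmin=-200.0,
    events=None,
):
    """Build an EpochsSet around a (trials, electrodes, times) array."""
    voltages = np.asarray(voltages, dtype=float)
    n_tr, _, n_t = voltages.shape
    times = tmin + np.arange(n_t) * (1000.0 / sfreq)
    if events is None:
        cells = [("L1", "HC", "Face"), ("L1", "HC", "NoFace"),
                 ("L1", "LC", "Face"), ("L1", "LC", "NoFace"),
                 ("L2", "HC", "Face"), ("L2", "HC", "NoFace"),
                 ("L2", "LC", "Face"), ("L2", "LC", "NoFace")]
        rows = [cells[i % 8] for i in range(n_tr)]
        events = pd.DataFrame(rows, columns=["accent", "constraint", "face"])
        events["item"] = np.arange(n_tr)
    return EpochsSet(
        participant_id=participant_id,
        voltages=voltages,
        events=events,
        times=times,
        sfreq=sfreq,
        montage=montage,
    )


@pytest.fixture
def epochs_factory():
    return make_epochs
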