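import numpy as np
import pytest

from renalivive import datasets, simulate
from renalivive.binding import BindingMeasurement
from renalivive.domain import AlbuminCondition


@pytest.fixture(scope="session")
def binding_table():
    return datasets.load_binding_table()


@pytest.fixture(scope="session")
def clearance_table():
    return datasets.load_clearance_table()


@pytest.fixture(scope="session")
def scaler_table():
    return datasets.load_scaler_table()


@pytest.fixture(scope="session")
def binding_means():
    """Packaged binding table as substrate -> list[BindingMeasurement] of
    condition means."""
    frame = datasets.binding_measurement_frame()
    out = {}
    for sub, grp in frame.groupby("substrate"):
        out[sub] = [
            BindingMeasurement(sub, AlbuminCondition.hsa(r["albumin_g_per_dl"]),
                               [r["fu_mean"]])
            for _, r in grp.iterrows()
        ]
    return out


@pytest.fixture(scope="session")
def noiseless_panel():
    truth = simulate.paper_like_truth(seed=7, n_substrates=6,
                                      uptake_cv=0.0, fu_noise_sd=0.0)
    return simulate.generate_panel(truth)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
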