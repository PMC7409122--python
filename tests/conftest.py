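import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mobiquant.campaign import extract_features
from mobiquant.config import PipelineConfig
from mobiquant.design import build_batch_layout
from mobiquant.simulate import Acquisition, InstrumentModel, SignalModel, simulate_batch

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def instrument_w():
    return InstrumentModel(resolution_mode="W")


@pytest.fixture(scope="session")
def instrument_v():
    return InstrumentModel(resolution_mode="V")


@pytest.fixture(scope="session")
def noiseless_signal():
    return SignalModel(replicate_cv=0.0, spot_heterogeneity=0.0, baseline_noise=0.0)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def noiseless_config(noiseless_signal):
    return PipelineConfig(signal=noiseless_signal)


@pytest.fixture(scope="session")
def noiseless_batch(instrument_w, noiseless_signal, noiseless_config):
    """One noiseless validation batch, simulated once and shared."""
    layout = build_batch_layout("validation")
    acqs = simulate_batch(layout, instrument_w, noiseless_signal, seed=1)
    features = extract_features(acqs, layout, noiseless_config)
    return layout, acqs, features


def make_acquisition(centroids, dt_centers=None, n_bins=200, dt_max=4.0):
    """Acquisition from (drift_bin, mz, intensity) triples (test helper)."""
    if dt_centers is None:
        edges = np.linspace(0.0, dt_max, n_bins + 1)
        dt_centers = 0.5 * (edges[:-1] + edges[1:])
    arr = np.asarray(centroids, dtype=float).reshape(-1, 3)
    return Acquisition(
        scan_ids=arr[:, 0].astype(np.int64),
        drift_bins=arr[:, 0].astype(np.int64),
        mz=arr[:, 1],
        intensity=arr[:, 2],
        dt_centers=np.asarray(dt_centers, dtype=float),
    )
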