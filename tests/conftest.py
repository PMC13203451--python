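import numpy as np
import pandas as pd
import pytest

from morphopose.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Six individuals x two views, deterministic; shared across tests."""
    root = tmp_path_factory.mktemp("ds")
    manifest = generate_dataset(6, 2, root, seed=42)
    measurements = pd.read_csv(root / "measurements.csv").set_index("individual_id")
    return {"root": root, "manifest": manifest, "measurements": measurements}


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Zero measurement noise, zero pose jitter: annotations and the
    measurement table agree exactly up to rendering quantisation."""
    root = tmp_path_factory.mktemp("ds_clean")
    manifest = generate_dataset(4, 2, root, seed=7, measurement_noise_frac=0.0, pose_jitter=0.0)
    measurements = pd.read_csv(root / "measurements.csv").set_index("individual_id")
    return {"root": root, "manifest": manifest, "measurements": measurements}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
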