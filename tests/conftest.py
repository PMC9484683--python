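import numpy as np
import pytest

from epsckit.autoclassifier import Autoclassifier
from epsckit.synth import SyntheticSpec, generate_trace


@pytest.fixture(scope="session")
def dense_training_traces():
    """Event-dense synthetic traces for autoclassifier training.

    High event rate so a substantial fraction of random windows contains
    event structure, mirroring training on event-rich recordings.
    """
    return [
        generate_trace(SyntheticSpec(duration_s=10.0, event_rate=60.0, seed=s))[0]
        for s in range(3)
    ]


@pytest.fixture(scope="session")
def trained_autoclassifier(dense_training_traces):
    """Scaled-down trained autoclassifier shared across tests.

    5k training windows / 20 epochs instead of the full 50k / 100: enough
    for the latent states to form while keeping the suite fast.
    """
    est = Autoclassifier(
        n_train_windows=5000,
        n_val_windows=1000,
        n_cluster_windows=5000,
        ae_epochs=20,
        clf_epochs=30,
        seed=42,
    )
    est.fit(dense_training_traces)
    return est


@pytest.fixture()
def default_trace():
    """One default-condition synthetic trace with its ground truth."""
    return generate_trace(SyntheticSpec(duration_s=10.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
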