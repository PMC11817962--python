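import numpy as np
import pytest

from medetect.model import (
    EventSequence,
    GaussianChannelModel,
    MultimodalModel,
    MultimodalRecording,
    PointProcessChannelModel,
    TemporalResponse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_model(delta: float = 0.005, n_classes: int = 2) -> MultimodalModel:
    """Small 1-spike + 1-field channel model with asymmetric kernels."""
    n = int(round(0.1 / delta))
    t = np.arange(n) * delta
    r_pp = TemporalResponse(0.0, np.exp(-0.5 * ((t - 0.03) / 0.02) ** 2), delta)
    r_g = TemporalResponse(0.0, np.sin(np.pi * t / 0.1), delta)
    pp = PointProcessChannelModel(r_pp, np.array([1.2, 0.3][:n_classes]), np.log(15.0))
    gauss = GaussianChannelModel(r_g, np.array([0.8, 2.0][:n_classes]), 0.5)
    return MultimodalModel([pp], [gauss], n_classes, delta)


@pytest.fixture
def toy_model():
    return make_toy_model()


@pytest.fixture
def toy_recording(toy_model, rng):
    """2-second toy recording with one event per class, interior supports."""
    delta = toy_model.delta
    duration = 2.0
    n = int(round(duration / delta))
    spikes = (rng.random((1, n)) < 0.05).astype(np.int8)
    fields = rng.normal(0.0, 0.7, (1, n))
    return MultimodalRecording(spikes, fields, duration, delta)


@pytest.fixture
def toy_events(toy_model):
    return EventSequence(
        np.array([0.5, 1.3]), np.array([0, 1]), toy_model.n_classes, 2.0
    )
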