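"""Synthetic multimodal recordings with direction-tuned responses.

Emulates an eye-movement (saccade) experiment: events occur every ~2 s with
uniform jitter, each event has one of ``S`` direction classes, and every
channel responds with a smooth temporal bump scaled by a cosine tuning curve
peaked at the channel's preferred direction.  Spike channels are inhomogeneous
Poisson (Bernoulli per bin); field channels are the response waveform plus
white Gaussian noise.

Default settings are the study conditions used throughout the test suite:
5 spike + 5 field channels, 8 classes, 20 events with jittered 2 s gaps,
firing rates spanning 10-100 Hz, field SNR of 0.1 at unit noise variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model import (
    EventSequence,
    GaussianChannelModel,
    MultimodalModel,
    MultimodalRecording,
    PointProcessChannelModel,
    TemporalResponse,
    compute_cif,
    event_mean,
)

__all__ = [
    "SimulationConfig",
    "draw_event_sequence",
    "cosine_tuning",
    "random_bump_kernel",
    "make_pp_channel",
    "make_gauss_channel",
    "make_random_model",
    "make_null_model",
    "simulate_recording",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    n_events : number of events to place.
    mean_gap, gap_jitter : inter-event gaps are uniform on
        ``[mean_gap - gap_jitter, mean_gap + gap_jitter]`` seconds.
    n_classes : number of event classes (directions).
    n_pp, n_gauss : spike and field channel counts.
    rate_min, rate_max : spike channels run from the baseline ``rate_min`` up
        to ``rate_max`` Hz at the preferred class's response peak.
    snr : field channels' signal-to-noise ratio, defined as the mean of the
        squared preferred-class response over the kernel support divided by
        the noise variance.
    sigma2 : field noise variance (signal units squared).
    delta : bin width in seconds.
    kernel_support : temporal-response support ``[0, kernel_support]`` s.
    pad : leading/trailing quiet time around the first/last event, seconds.
    seed : master seed; all random streams derive from it.
    """

    n_events: int = 20
    mean_gap: float = 2.0
    gap_jitter: float = 0.5
    n_classes: int = 8
    n_pp: int = 5
    n_gauss: int = 5
    rate_min: float = 10.0
    rate_max: float = 100.0
    snr: float = 0.1
    sigma2: float = 1.0
    delta: float = 0.001
    kernel_support: float = 0.3
    pad: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not self.mean_gap > self.gap_jitter >= 0:
            raise ValueError("need mean_gap > gap_jitter >= 0")
        if not self.rate_max >= self.rate_min > 0:
            raise ValueError("need rate_max >= rate_min > 0")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if not (self.delta > 0 and self.kernel_support > 0 and self.pad > 0):
            raise ValueError("delta, kernel_support and pad must be > 0")


def draw_event_sequence(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> EventSequence:
    """Draw event times with uniformly jittered gaps and uniform classes."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.n_events == 0:
        return EventSequence.empty(cfg.n_classes, cfg.pad)
    gaps = rng.uniform(
        cfg.mean_gap - cfg.gap_jitter, cfg.mean_gap + cfg.gap_jitter, cfg.n_events - 1
    )
    times = cfg.pad + np.concatenate([[0.0], np.cumsum(gaps)])
    classes = rng.integers(0, cfg.n_classes, cfg.n_events)
    duration = float(times[-1] + cfg.pad)
    return EventSequence(times, classes, cfg.n_classes, duration)


def cosine_tuning(n_classes: int, preferred: int) -> np.ndarray:
    """Cosine direction tuning in [0, 1], peaked at the preferred class."""
    c = np.arange(n_classes)
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (c - preferred) / n_classes))


def random_bump_kernel(
    cfg: SimulationConfig, rng: np.random.Generator
) -> TemporalResponse:
    """Unit-L2-norm Gaussian bump with randomized latency and width.

    Support is ``[0, kernel_support]`` seconds after the event, with latency
    drawn uniformly from [0.08, 0.2] s and width (s.d.) from [0.02, 0.05] s —
    transient responses much shorter than the recording.
    """
    latency = rng.uniform(0.08, 0.20)
    width = rng.uniform(0.02, 0.05)
    t = np.arange(int(round(cfg.kernel_support / cfg.delta))) * cfg.delta
    v = np.exp(-0.5 * ((t - latency) / width) ** 2)
    v /= np.linalg.norm(v)
    return TemporalResponse(0.0, v, cfg.delta)


def make_pp_channel(
    cfg: SimulationConfig, rng: np.random.Generator
) -> PointProcessChannelModel:
    """Spike channel spanning ``rate_min`` (baseline) to ``rate_max`` (peak).

    The spatial gain is solved analytically so that the preferred-class rate
    peak equals ``rate_max``: ``gain * max(r) = log(rate_max / rate_min)``.
    """
    r = random_bump_kernel(cfg, rng)
    preferred = int(rng.integers(cfg.n_classes))
    gain = np.log(cfg.rate_max / cfg.rate_min) / float(r.values.max())
    phi = gain * cosine_tuning(cfg.n_classes, preferred)
    return PointProcessChannelModel(r, phi, float(np.log(cfg.rate_min)))


def make_gauss_channel(
    cfg: SimulationConfig, rng: np.random.Generator
) -> GaussianChannelModel:
    """Field channel whose preferred-class response hits the target SNR.

    SNR is mean(r(t)^2 * phi[preferred]^2) over the support divided by
    ``sigma2``; the gain is solved in closed form.
    """
    r = random_bump_kernel(cfg, rng)
    preferred = int(rng.integers(cfg.n_classes))
    mean_sq = float(np.mean(r.values**2))
    gain = np.sqrt(cfg.snr * cfg.sigma2 / mean_sq)
    phi = gain * cosine_tuning(cfg.n_classes, preferred)
    return GaussianChannelModel(r, phi, cfg.sigma2)


def make_random_model(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> MultimodalModel:
    """Random ground-truth model under the configured study conditions."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pp = [make_pp_channel(cfg, rng) for _ in range(cfg.n_pp)]
    gauss = [make_gauss_channel(cfg, rng) for _ in range(cfg.n_gauss)]
    return MultimodalModel(pp, gauss, cfg.n_classes, cfg.delta, k=1.0)


def make_null_model(cfg: SimulationConfig, baseline_rate: float = 20.0) -> MultimodalModel:
    """Model with zero temporal responses: constant-rate spikes, pure-noise fields."""
    n_kernel = int(round(cfg.kernel_support / cfg.delta))
    zero = TemporalResponse(0.0, np.zeros(n_kernel), cfg.delta)
    phi0 = np.zeros(cfg.n_classes)
    pp = [
        PointProcessChannelModel(zero, phi0, float(np.log(baseline_rate)))
        for _ in range(cfg.n_pp)
    ]
    gauss = [GaussianChannelModel(zero, phi0, cfg.sigma2) for _ in range(cfg.n_gauss)]
    return MultimodalModel(pp, gauss, cfg.n_classes, cfg.delta, k=1.0)


def simulate_recording(
    model: MultimodalModel,
    events: EventSequence,
    seed: int | np.random.SeedSequence = 0,
) -> MultimodalRecording:
    """Draw one recording from the model given the event sequence.

    Spikes are Bernoulli per bin with probability ``min(lambda * delta, 1)``;
    fields are the event-locked mean plus independent Gaussian noise.  Each
    channel consumes its own child stream of the seed, so channel subsets are
    reproducible regardless of the total channel count.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = ss.spawn(model.n_pp + model.n_gauss)
    n = int(np.rint(events.duration / model.delta))
    spikes = np.zeros((model.n_pp, n), dtype=np.int8)
    for i, ch in enumerate(model.pp_channels):
        rng = np.random.default_rng(streams[i])
        p = compute_cif(ch, events, events.duration, model.delta) * model.delta
        if p.max() > 0.5:
            logger.warning(
                "channel %d: per-bin spike probability %.2f exceeds 0.5; "
                "Bernoulli-bin discretization is inaccurate",
                i,
                p.max(),
            )
        spikes[i] = rng.random(n) < np.minimum(p, 1.0)
    fields = np.zeros((model.n_gauss, n))
    for j, ch in enumerate(model.gauss_channels):
        rng = np.random.default_rng(streams[model.n_pp + j])
        mean = event_mean(ch, events, events.duration, model.delta)
        fields[j] = mean + rng.normal(0.0, np.sqrt(ch.sigma2), n)
    return MultimodalRecording(spikes, fields, events.duration, model.delta)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[MultimodalModel, EventSequence, MultimodalRecording]:
    """Full draw: ground-truth model, event sequence, and one recording."""
    ss = np.random.SeedSequence(cfg.seed)
    ss_model, ss_events, ss_rec = ss.spawn(3)
    model = make_random_model(cfg, np.random.default_rng(ss_model))
    events = draw_event_sequence(cfg, np.random.default_rng(ss_events))
    rec = simulate_recording(model, events, ss_rec)
    return model, events, rec
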