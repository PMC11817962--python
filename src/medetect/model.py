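"""Encoding model and exact log-likelihoods for multimodal event data.

An event at time ``t_s`` with class ``s`` (one of ``S`` classes) drives each
recorded channel through a finite-support temporal response ``r(t)`` scaled by
a per-class spatial weight ``phi[s]``.  Spike channels are inhomogeneous
Poisson processes whose log conditional intensity is
``alpha + r(t - t_s) * phi[s]``; field channels emit the scaled waveform
``r(t - t_s) * phi[s]`` plus i.i.d. zero-mean Gaussian noise of variance
``sigma2``.  Channels are conditionally independent given the event sequence,
so the joint log-likelihood is the sum of per-channel terms.

The functions here evaluate those likelihoods exactly on the recording's bin
lattice.  They are deliberately direct (no convolution tricks) so they can
serve as the brute-force reference that the fast matched-filter detector in
:mod:`medetect.detect` is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RATE_FLOOR",
    "EventSequence",
    "TemporalResponse",
    "PointProcessChannelModel",
    "GaussianChannelModel",
    "MultimodalModel",
    "MultimodalRecording",
    "ModelError",
    "InvalidEventError",
    "InvalidModelError",
    "InvalidVarianceError",
    "NumericOverflowError",
    "ShapeError",
    "compute_cif",
    "pp_log_likelihood",
    "gauss_log_likelihood",
    "event_mean",
    "joint_log_likelihood",
]

# Rates are clipped here (spikes/s) before taking logs.
RATE_FLOOR = 1e-12


class ModelError(ValueError):
    """Base class for model/likelihood errors."""


class InvalidEventError(ModelError):
    """An event refers to a class index outside the model's class set."""


class InvalidModelError(ModelError):
    """Model assigns zero/negative rate to an observed spike."""


class InvalidVarianceError(ModelError):
    """Gaussian noise variance must be strictly positive."""


class NumericOverflowError(ModelError):
    """A rate or likelihood term overflowed double precision."""


class ShapeError(ModelError):
    """Recording and model dimensions disagree."""


def _as_bin(t: float, delta: float) -> int:
    """Snap a continuous time in seconds to the nearest bin index."""
    return int(np.rint(t / delta))


@dataclass(frozen=True)
class EventSequence:
    """Ground-truth or estimated event times and classes on ``[0, T]``.

    Attributes
    ----------
    times : ndarray
        Event times in seconds, strictly increasing, all within ``[0, T]``.
    classes : ndarray
        Integer class indices in ``{0, ..., n_classes - 1}`` (the class is a
        one-hot vector of length ``n_classes`` at the model-math boundary).
    n_classes : int
        Number of event classes ``S``.
    duration : float
        Recording duration ``T`` in seconds.
    """

    times: np.ndarray
    classes: np.ndarray
    n_classes: int
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        classes = np.asarray(self.classes, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "classes", classes)
        if times.shape != classes.shape or times.ndim != 1:
            raise ShapeError("times and classes must be 1-D and equal length")
        if self.n_classes < 1:
            raise InvalidEventError("need at least one class")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise InvalidEventError("event times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise InvalidEventError("event times must lie within [0, T]")
            if classes.min() < 0 or classes.max() >= self.n_classes:
                raise InvalidEventError(
                    f"class indices must be in [0, {self.n_classes - 1}]"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def empty(cls, n_classes: int, duration: float) -> "EventSequence":
        return cls(np.empty(0), np.empty(0, dtype=int), n_classes, duration)


@dataclass(frozen=True)
class TemporalResponse:
    """Finite-support response kernel sampled on the recording lattice.

    ``start`` is the kernel's left edge in seconds relative to the event
    (``t = 0`` is event onset); sample ``k`` sits at lag
    ``start + k * delta``.  The kernel is implicitly zero outside its support.
    """

    start: float
    values: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ShapeError("kernel values must be 1-D")
        if self.delta <= 0:
            raise ModelError("bin width must be positive")

    @property
    def stop(self) -> float:
        """Right edge of the support in seconds relative to the event."""
        return self.start + len(self.values) * self.delta

    @property
    def span(self) -> float:
        """Support length in seconds."""
        return len(self.values) * self.delta

    @property
    def lag_bins(self) -> int:
        """Bin offset of the first kernel sample relative to the event bin."""
        return _as_bin(self.start, self.delta)


@dataclass(frozen=True)
class PointProcessChannelModel:
    """Poisson spike channel: log-rate ``alpha + r(t - t_s) * phi[s]``."""

    r: TemporalResponse
    phi: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        if self.phi.ndim != 1:
            raise ShapeError("phi must be a 1-D vector of length S")
        if not np.isfinite(self.alpha):
            raise NumericOverflowError("alpha must be finite")
        if np.exp(self.alpha) * self.r.delta >= 1.0:
            raise InvalidModelError(
                "baseline per-bin spike probability exp(alpha)*delta must be < 1"
            )

    @property
    def n_classes(self) -> int:
        return len(self.phi)


@dataclass(frozen=True)
class GaussianChannelModel:
    """Gaussian field channel: ``y(t) = r(t - t_s) * phi[s] + N(0, sigma2)``."""

    r: TemporalResponse
    phi: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        if self.phi.ndim != 1:
            raise ShapeError("phi must be a 1-D vector of length S")
        if not self.sigma2 > 0:
            raise InvalidVarianceError("sigma2 must be > 0")

    @property
    def n_classes(self) -> int:
        return len(self.phi)


@dataclass(frozen=True)
class MultimodalModel:
    """Joint model of ``I`` Poisson and ``J`` Gaussian channels.

    ``k`` is the cross-modal scale weighing the Gaussian-modality contribution
    against the point-process contribution in the fused detector score
    (``k = 1`` recovers the plain joint likelihood).
    """

    pp_channels: list[PointProcessChannelModel]
    gauss_channels: list[GaussianChannelModel]
    n_classes: int
    delta: float
    k: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pp_channels", list(self.pp_channels))
        object.__setattr__(self, "gauss_channels", list(self.gauss_channels))
        if self.n_pp + self.n_gauss < 1:
            raise ShapeError("model needs at least one channel")
        if not self.k > 0:
            raise ModelError("cross-modal scale k must be > 0")
        for ch in list(self.pp_channels) + list(self.gauss_channels):
            if ch.n_classes != self.n_classes:
                raise ShapeError("all channels must share the class count S")
            if not np.isclose(ch.r.delta, self.delta):
                raise ShapeError("all channels must share the bin width delta")

    @property
    def n_pp(self) -> int:
        return len(self.pp_channels)

    @property
    def n_gauss(self) -> int:
        return len(self.gauss_channels)

    def with_k(self, k: float) -> "MultimodalModel":
        return MultimodalModel(
            self.pp_channels, self.gauss_channels, self.n_classes, self.delta, k
        )

    def subset(self, pp_idx, gauss_idx) -> "MultimodalModel":
        """Model restricted to the given channel indices (order preserved)."""
        return MultimodalModel(
            [self.pp_channels[i] for i in pp_idx],
            [self.gauss_channels[j] for j in gauss_idx],
            self.n_classes,
            self.delta,
            self.k,
        )

    @property
    def max_support(self) -> float:
        """Largest kernel span (seconds) over all channels."""
        spans = [ch.r.span for ch in self.pp_channels + self.gauss_channels]
        return max(spans) if spans else 0.0


@dataclass(frozen=True)
class MultimodalRecording:
    """Aligned spike trains and field signals on one sampling lattice.

    ``spikes`` has shape ``(I, N)`` with values in {0, 1}; ``fields`` has
    shape ``(J, N)``; ``N = round(duration / delta)``.
    """

    spikes: np.ndarray
    fields: np.ndarray
    duration: float
    delta: float

    def __post_init__(self) -> None:
        spikes = np.atleast_2d(np.asarray(self.spikes))
        fields = np.atleast_2d(np.asarray(self.fields, dtype=float))
        n = _as_bin(self.duration, self.delta)
        if spikes.size == 0:
            spikes = spikes.reshape(0, n)
        if fields.size == 0:
            fields = fields.reshape(0, n)
        object.__setattr__(self, "spikes", spikes)
        object.__setattr__(self, "fields", fields)
        for name, arr in (("spikes", spikes), ("fields", fields)):
            if arr.shape[0] and arr.shape[1] != n:
                raise ShapeError(
                    f"{name} length {arr.shape[1]} != round(T/delta) = {n}"
                )
        if spikes.size and not np.isin(spikes, (0, 1)).all():
            raise ShapeError("spike trains must contain only 0 and 1")

    @property
    def n_bins(self) -> int:
        return _as_bin(self.duration, self.delta)

    @property
    def n_pp(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_gauss(self) -> int:
        return self.fields.shape[0]

    def subset(self, pp_idx, gauss_idx) -> "MultimodalRecording":
        return MultimodalRecording(
            self.spikes[list(pp_idx)],
            self.fields[list(gauss_idx)],
            self.duration,
            self.delta,
        )


def _superpose(
    events: EventSequence,
    kernel: TemporalResponse,
    weights: np.ndarray,
    n_bins: int,
) -> np.ndarray:
    """Sum ``weights[e] * r(t - t_e)`` over events on the bin lattice.

    Multiple events superpose additively; contributions falling outside
    ``[0, n_bins)`` are truncated.
    """
    out = np.zeros(n_bins)
    vals = kernel.values
    m = len(vals)
    if m == 0:
        return out
    lag0 = kernel.lag_bins
    delta = kernel.delta
    for t, w in zip(events.times, weights):
        b = _as_bin(t, delta) + lag0
        lo, hi = max(b, 0), min(b + m, n_bins)
        if lo < hi:
            out[lo:hi] += w * vals[lo - b : hi - b]
    return out


def compute_cif(
    channel: PointProcessChannelModel,
    events: EventSequence,
    duration: float,
    delta: float,
) -> np.ndarray:
    """Conditional intensity lambda(t) in spikes/s on the bin lattice.

    ``lambda(t) = exp(alpha + sum_e r(t - t_e) * phi[class_e])``; responses of
    multiple events superpose additively in the log-rate.
    """
    if events.n_classes != channel.n_classes:
        raise InvalidEventError(
            f"events carry {events.n_classes} classes, channel expects "
            f"{channel.n_classes}"
        )
    n = _as_bin(duration, delta)
    log_rate = _superpose(events, channel.r, channel.phi[events.classes], n)
    log_rate += channel.alpha
    rate = np.exp(log_rate)
    if not np.isfinite(rate).all():
        raise NumericOverflowError("non-finite rate in compute_cif")
    return rate


def pp_log_likelihood(spikes: np.ndarray, cif: np.ndarray, delta: float) -> float:
    """Poisson log-likelihood ``-Q + sum_m log lambda(t_m)``.

    ``Q`` is the integral of the intensity, discretized as a left-Riemann sum
    on the bin lattice.  The spike-time product runs over bins containing a
    spike.
    """
    spikes = np.asarray(spikes)
    cif = np.asarray(cif, dtype=float)
    if spikes.shape != cif.shape:
        raise ShapeError("spike train and CIF must have the same length")
    spike_rates = cif[spikes == 1]
    if np.any(spike_rates <= 0):
        raise InvalidModelError("observed spike in a bin with non-positive rate")
    q = float(np.sum(cif)) * delta
    return -q + float(np.sum(np.log(np.maximum(spike_rates, RATE_FLOOR))))


def gauss_log_likelihood(y: np.ndarray, mean: np.ndarray, sigma2: float) -> float:
    """Gaussian log density of a field series around its model mean."""
    if not sigma2 > 0:
        raise InvalidVarianceError("sigma2 must be > 0")
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if y.shape != mean.shape:
        raise ShapeError("signal and mean must have the same length")
    n = y.size
    rss = float(np.sum((y - mean) ** 2))
    return -0.5 * n * float(np.log(2.0 * np.pi * sigma2)) - rss / (2.0 * sigma2)


def event_mean(
    channel: GaussianChannelModel,
    events: EventSequence,
    duration: float,
    delta: float,
) -> np.ndarray:
    """Noise-free field mean ``sum_e r(t - t_e) * phi[class_e]``."""
    if events.n_classes != channel.n_classes:
        raise InvalidEventError("event classes exceed channel class count")
    n = _as_bin(duration, delta)
    return _superpose(events, channel.r, channel.phi[events.classes], n)


def joint_log_likelihood(
    rec: MultimodalRecording,
    model: MultimodalModel,
    t_s: float,
    class_idx: int,
) -> float:
    """Joint log-likelihood of the recording given a single event ``(t_s, s)``.

    Channels are conditionally independent given the event, so this is the sum
    of the per-channel Poisson and Gaussian log-likelihoods.  Serves as the
    brute-force oracle for the matched-filter detector.
    """
    if rec.n_pp != model.n_pp or rec.n_gauss != model.n_gauss:
        raise ShapeError(
            f"recording has ({rec.n_pp}, {rec.n_gauss}) channels, model has "
            f"({model.n_pp}, {model.n_gauss})"
        )
    if not 0 <= t_s <= rec.duration:
        raise InvalidEventError("event time outside [0, T]")
    events = EventSequence(
        np.array([t_s]), np.array([class_idx]), model.n_classes, rec.duration
    )
    total = 0.0
    for train, ch in zip(rec.spikes, model.pp_channels):
        cif = compute_cif(ch, events, rec.duration, rec.delta)
        total += pp_log_likelihood(train, cif, rec.delta)
    for y, ch in zip(rec.fields, model.gauss_channels):
        mean = event_mean(ch, events, rec.duration, rec.delta)
        total += gauss_log_likelihood(y, mean, ch.sigma2)
    return total
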