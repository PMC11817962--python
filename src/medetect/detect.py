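"""Multimodal event detector (MED): matched-filter form of the ML estimator.

Maximizing the joint log-likelihood over candidate event time and class is
equivalent, up to terms constant in ``(t_s, s)``, to maximizing

``L_c(t) = sum_i [phi_i[c] * (u_i * r_i(-.))(t) - Q_i(c)]
         + k * sum_j (1/sigma_j^2) [phi_j[c] * (y_j * r_j(-.))(t) - E_j(c)]``

where ``*`` is convolution with the time-reversed kernel (a matched filter),
``Q_i(c)`` is the integrated spike intensity given one class-``c`` event
(independent of the event time when the kernel support is well inside the
recording), ``E_j(c) = phi_j[c]^2 / 2 * sum_t r_j(t)^2`` is the Gaussian
template energy, and ``k`` weighs the continuous modality against the
discrete one.  The per-bin maximum over classes, ``x(t) = max_c L_c(t)``,
peaks at maximum-likelihood event times; the argmax class at a peak is the
event-class estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .model import (
    GaussianChannelModel,
    ModelError,
    MultimodalModel,
    MultimodalRecording,
    PointProcessChannelModel,
    TemporalResponse,
)

__all__ = [
    "MedOutput",
    "Detection",
    "SupportError",
    "matched_filter",
    "compute_Q",
    "gaussian_energy",
    "med_output",
    "detect_and_classify",
]


class SupportError(ModelError):
    """Kernel support does not fit inside the recording."""


@dataclass(frozen=True)
class MedOutput:
    """Per-class detector traces on the recording lattice.

    ``traces[c, t]`` scores a candidate event of class ``c`` at time
    ``t * delta``.  In causal mode the traces are delayed by ``delay``
    seconds (the largest kernel right edge) so that every sample depends
    only on past data.
    """

    traces: np.ndarray
    delta: float
    delay: float = 0.0
    support: float = 0.0

    @property
    def n_classes(self) -> int:
        return self.traces.shape[0]

    @property
    def n_bins(self) -> int:
        return self.traces.shape[1]

    @property
    def max_trace(self) -> np.ndarray:
        """x(t): elementwise maximum of the per-class traces."""
        return self.traces.max(axis=0)

    @property
    def argmax_class(self) -> np.ndarray:
        """Per-bin argmax class; exact ties resolve to the lowest index."""
        return self.traces.argmax(axis=0)


@dataclass(frozen=True)
class Detection:
    """One detected event: time (s), class estimate, peak score, edge flag."""

    time: float
    class_idx: int
    score: float
    edge: bool = False


def matched_filter(signal: np.ndarray, kernel: TemporalResponse) -> np.ndarray:
    """Correlate a signal with a response kernel, aligned to candidate times.

    Output index ``t`` holds ``sum_k kernel[k] * signal[t + lag_k]`` — the
    matched-filter response for a candidate event at bin ``t``.  Boundaries
    are zero-padded, so values within one support of either edge are
    attenuated.
    """
    x = np.asarray(signal, dtype=float)
    vals = kernel.values
    m = len(vals)
    if m == 0:
        warnings.warn("empty kernel: matched filter returns zeros")
        return np.zeros_like(x)
    if m >= x.size:
        raise SupportError("kernel support must be shorter than the signal")
    # Full convolution with the reversed kernel; out[t] = full[t + lag0 + m - 1].
    full = sp_signal.convolve(x, vals[::-1], mode="full", method="auto")
    idx = np.arange(x.size) + kernel.lag_bins + m - 1
    out = np.zeros(x.size)
    valid = (idx >= 0) & (idx < full.size)
    out[valid] = full[idx[valid]]
    return out


def compute_Q(
    channel: PointProcessChannelModel, class_idx: int, duration: float
) -> float:
    """Integrated intensity given one class-``class_idx`` event.

    ``Q(c) = exp(alpha) * [sum_support exp(r(t) phi[c]) * delta
    + (T - support)]`` — independent of the event time as long as the kernel
    support lies inside ``[0, T]``.
    """
    r = channel.r
    if r.span > duration:
        raise SupportError("kernel support exceeds the recording duration")
    w = channel.phi[class_idx]
    bump = float(np.sum(np.exp(r.values * w))) * r.delta
    return float(np.exp(channel.alpha)) * (bump + (duration - r.span))


def gaussian_energy(channel: GaussianChannelModel, class_idx: int) -> float:
    """Template energy ``phi[c]^2 / 2 * sum_t r(t)^2`` of a field channel."""
    w = channel.phi[class_idx]
    return 0.5 * w * w * float(np.sum(channel.r.values**2))


def med_output(
    rec: MultimodalRecording, model: MultimodalModel, causal: bool = False
) -> MedOutput:
    """Compute the S per-class detector traces for a recording.

    With ``k = 1`` and kernel supports interior to the recording, differences
    ``L_c(t) - L_c'(t')`` equal the corresponding joint log-likelihood
    differences exactly.  In causal mode every trace is delayed by the
    largest kernel right edge ``t2`` so the output at time ``t`` uses only
    samples up to ``t``; reported event times compensate for the delay.
    """
    if rec.n_pp != model.n_pp or rec.n_gauss != model.n_gauss:
        raise ModelError(
            f"recording has ({rec.n_pp}, {rec.n_gauss}) channels, model has "
            f"({model.n_pp}, {model.n_gauss})"
        )
    n_cls, n = model.n_classes, rec.n_bins
    traces = np.zeros((n_cls, n))
    for train, ch in zip(rec.spikes, model.pp_channels):
        mf = matched_filter(train.astype(np.float64), ch.r)
        q = np.array([compute_Q(ch, c, rec.duration) for c in range(n_cls)])
        traces += ch.phi[:, None] * mf[None, :] - q[:, None]
    for y, ch in zip(rec.fields, model.gauss_channels):
        mf = matched_filter(y, ch.r)
        e = np.array([gaussian_energy(ch, c) for c in range(n_cls)])
        traces += (model.k / ch.sigma2) * (ch.phi[:, None] * mf[None, :] - e[:, None])
    delay = 0.0
    if causal:
        t2 = max(
            (ch.r.stop for ch in model.pp_channels + model.gauss_channels),
            default=0.0,
        )
        if t2 > 0:
            d = int(np.rint(t2 / model.delta))
            shifted = np.zeros_like(traces)
            shifted[:, d:] = traces[:, : n - d]
            traces = shifted
            delay = d * model.delta
    return MedOutput(traces, model.delta, delay=delay, support=model.max_support)


def auto_threshold(out: MedOutput) -> float:
    """Data-driven detection threshold from the peak-height distribution.

    Applies Otsu's criterion (maximal between-class variance) to the heights
    of all local maxima of ``x(t)``, splitting noise peaks from event peaks.
    A convenience for thresholded detection runs; ROC/AUC evaluation is
    threshold-free and does not use it.
    """
    x = out.max_trace
    idx, _ = sp_signal.find_peaks(x)
    if idx.size == 0:
        return float(x.max()) if x.size else 0.0
    h = np.sort(x[idx])
    if h.size == 1 or h[0] == h[-1]:
        return float(h[0])
    n = h.size
    csum = np.cumsum(h)
    k = np.arange(1, n)  # split: h[:k] below, h[k:] above
    mean_lo = csum[:-1] / k
    mean_hi = (csum[-1] - csum[:-1]) / (n - k)
    between = k * (n - k) * (mean_lo - mean_hi) ** 2
    split = int(np.argmax(between)) + 1
    return float(0.5 * (h[split - 1] + h[split]))


def detect_and_classify(
    out: MedOutput,
    threshold: float,
    min_separation: float = 0.2,
) -> list[Detection]:
    """Peak-pick the max trace into a list of detections.

    Local maxima of ``x(t)`` at or above ``threshold`` are accepted greedily
    in descending score order, suppressing any peak closer than
    ``min_separation`` seconds to an already-accepted one.  Each detection's
    class is the argmax class at the peak bin; in causal mode the fixed delay
    is subtracted from reported times.  Detections within one kernel support
    of either recording edge are flagged ``edge=True`` (the time-invariance
    of the offset terms fails there).
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    x = out.max_trace
    peaks, _ = sp_signal.find_peaks(x)
    peaks = peaks[x[peaks] >= threshold]
    if peaks.size == 0:
        return []
    order = peaks[np.argsort(-x[peaks], kind="stable")]
    sep_bins = int(np.rint(min_separation / out.delta))
    accepted: list[int] = []
    for p in order:
        if all(abs(p - q) >= sep_bins for q in accepted):
            accepted.append(int(p))
    accepted.sort()
    cls = out.argmax_class
    total = out.n_bins * out.delta
    dets = []
    for p in accepted:
        t_cand = p * out.delta - out.delay
        edge = (t_cand < out.support) or (t_cand > total - out.support)
        dets.append(
            Detection(
                time=t_cand,
                class_idx=int(cls[p]),
                score=float(x[p]),
                edge=edge,
            )
        )
    return dets
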