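"""Maximum-likelihood parameter learning from event-labeled training data.

Each channel's spatiotemporal response factorizes as ``r(t) * phi[c]`` — a
rank-one time-by-class structure.  Fitting proceeds per channel:

* Gaussian channels: the ML per-class waveform is the event-triggered
  average; the time-by-class matrix of averages is factorized to rank one by
  SVD, and the noise variance is the pooled residual variance of the epochs
  and the event-free baseline.
* Spike channels: the baseline log-rate is estimated from event-free data;
  per-class smoothed PSTH log-rates (minus baseline) are factorized to rank
  one, optionally refined by alternating damped Newton ascent on the exact
  per-bin Poisson likelihood.

The factorization is scale-ambiguous (``r * c, phi / c`` is the same model),
so the convention ``||r||_2 = 1`` with a positive peak is imposed and the
scale absorbed into ``phi``.

The cross-modal scale ``k`` is chosen by grid search on the training
recording, maximizing detection AUC plus classification accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .detect import med_output
from .evaluate import DEFAULT_TOL, accuracy_at_truth, detection_roc_auc
from .model import (
    EventSequence,
    GaussianChannelModel,
    ModelError,
    MultimodalModel,
    MultimodalRecording,
    PointProcessChannelModel,
    TemporalResponse,
)

__all__ = [
    "AlignedEpochs",
    "MissingClassError",
    "DegenerateFactorizationError",
    "BaselineError",
    "epoch_align",
    "baseline_mask",
    "fit_gaussian_channel",
    "fit_point_process_channel",
    "fit_model",
    "default_k_grid",
    "fit_cross_modal_scale",
]

logger = logging.getLogger(__name__)

PSTH_SMOOTH_SIGMA = 0.010  # s; Gaussian smoothing of PSTH rates before log
RATE_FLOOR_FIT = 0.5  # spikes/s; floor applied to PSTH rates before log


class MissingClassError(ModelError):
    """A class has no training epochs."""


class DegenerateFactorizationError(ModelError):
    """All-zero responses cannot be factorized."""


class BaselineError(ModelError):
    """Baseline rate undefined (no baseline spikes)."""


@dataclass
class AlignedEpochs:
    """Per-channel, per-class stacks of event-aligned segments.

    ``spikes[i][c]`` and ``fields[j][c]`` are ``(n_epochs_c, L)`` arrays;
    ``counts[c]`` the number of retained epochs of class ``c``.
    """

    spikes: list[dict[int, np.ndarray]]
    fields: list[dict[int, np.ndarray]]
    counts: dict[int, int]
    window: tuple[float, float]
    delta: float


def epoch_align(
    rec: MultimodalRecording,
    events: EventSequence,
    window: tuple[float, float],
) -> AlignedEpochs:
    """Slice event-aligned epochs out of a recording.

    ``window = (t1, t2)`` is relative to event onset.  Epochs extending
    beyond the recording, or overlapping an earlier retained epoch, are
    dropped with a warning.  Every class must retain at least one epoch.
    """
    t1, t2 = window
    if not t2 > t1:
        raise ValueError("window must satisfy t2 > t1")
    length = int(np.rint((t2 - t1) / rec.delta))
    off = int(np.rint(t1 / rec.delta))
    n = rec.n_bins
    starts, kept_classes = [], []
    prev_end = -1
    n_dropped = 0
    for t, c in zip(events.times, events.classes):
        b = int(np.rint(t / rec.delta)) + off
        if b < 0 or b + length > n or b < prev_end:
            n_dropped += 1
            continue
        starts.append(b)
        kept_classes.append(int(c))
        prev_end = b + length
    if n_dropped:
        logger.warning("dropped %d out-of-range or overlapping epochs", n_dropped)
    kept_classes = np.asarray(kept_classes, dtype=int)
    counts = {
        c: int(np.sum(kept_classes == c)) for c in range(events.n_classes)
    }
    for c, cnt in counts.items():
        if cnt == 0:
            raise MissingClassError(f"class {c} has no training epochs")

    def stacks(series: np.ndarray) -> dict[int, np.ndarray]:
        return {
            c: np.stack(
                [
                    series[b : b + length]
                    for b, kc in zip(starts, kept_classes)
                    if kc == c
                ]
            )
            for c in range(events.n_classes)
        }

    return AlignedEpochs(
        spikes=[stacks(s) for s in rec.spikes],
        fields=[stacks(y) for y in rec.fields],
        counts=counts,
        window=(t1, t2),
        delta=rec.delta,
    )


def baseline_mask(
    rec: MultimodalRecording,
    events: EventSequence,
    window: tuple[float, float],
) -> np.ndarray:
    """Boolean mask of bins outside every event window (event-free baseline)."""
    t1, t2 = window
    mask = np.ones(rec.n_bins, dtype=bool)
    off = int(np.rint(t1 / rec.delta))
    length = int(np.rint((t2 - t1) / rec.delta))
    for t in events.times:
        b = int(np.rint(t / rec.delta)) + off
        mask[max(b, 0) : max(b + length, 0)] = False
    return mask


def _rank_one(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-1 factorization ``matrix ~ r phi^T`` under the convention
    ``||r||_2 = 1`` with the largest-magnitude element of ``r`` positive."""
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    if s[0] == 0:
        raise DegenerateFactorizationError("all-zero response matrix")
    r = u[:, 0]
    phi = s[0] * vt[0]
    if r[np.argmax(np.abs(r))] < 0:
        r, phi = -r, -phi
    return r, phi


def fit_gaussian_channel(
    epochs: dict[int, np.ndarray],
    baseline: np.ndarray,
    delta: float,
    window_start: float = 0.0,
) -> GaussianChannelModel:
    """Fit one field channel from aligned epochs and event-free baseline.

    The per-class ML waveform is the epoch mean; the time-by-class matrix of
    means is factorized rank-1, and sigma^2 is the residual variance of the
    epochs around the rank-1 predictions pooled with the baseline samples.
    """
    classes = sorted(epochs)
    g = np.column_stack([epochs[c].mean(axis=0) for c in classes])
    r, phi = _rank_one(g)
    rss = 0.0
    n_obs = 0
    for idx, c in enumerate(classes):
        resid = epochs[c] - r[None, :] * phi[idx]
        rss += float(np.sum(resid**2))
        n_obs += resid.size
    baseline = np.asarray(baseline, dtype=float)
    rss += float(np.sum(baseline**2))
    n_obs += baseline.size
    if n_obs == 0:
        raise DegenerateFactorizationError("no samples to estimate sigma2")
    # Noise-free training data would give exactly zero residual variance,
    # which the model forbids; floor at the smallest positive double.
    sigma2 = max(rss / n_obs, float(np.finfo(float).tiny))
    return GaussianChannelModel(
        TemporalResponse(window_start, r, delta), phi, sigma2
    )


def _pp_loglik(
    counts: np.ndarray, exposures: np.ndarray, alpha: float, r: np.ndarray, phi: np.ndarray
) -> float:
    """Per-bin Poisson log-likelihood of class-summed spike counts.

    ``counts[t, c]`` spikes observed in bin ``t`` across the ``n_c`` epochs of
    class ``c``; ``exposures[c] = n_c * delta`` seconds of exposure per bin.
    """
    eta = alpha + np.outer(r, phi)
    return float(np.sum(counts * eta - exposures[None, :] * np.exp(eta)))


def _refine_pp(
    counts: np.ndarray,
    exposures: np.ndarray,
    alpha: float,
    r: np.ndarray,
    phi: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 50,
    shrink: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating damped Newton ascent on the per-bin Poisson likelihood.

    Holds ``alpha`` fixed and alternates 1-D Newton updates of each ``r[t]``
    and each ``phi[c]`` (the likelihood is concave in each coordinate).
    Steps are halved until they do not decrease the objective, so ascent is
    monotone; stops when the gain drops below ``tol``.

    ``shrink`` adds a small pseudo-exposure observed at the baseline rate
    (a conjugate-style shrinkage toward ``alpha``).  Without it, bins that
    happen to collect zero spikes in every class pull their log-rate
    coordinate to minus infinity — the unpenalized ML optimum when trials
    are few — destroying the estimate; a 2% baseline weight bounds those
    coordinates while leaving well-sampled bins essentially untouched.
    """
    if shrink > 0:
        counts = counts + shrink * exposures[None, :] * np.exp(alpha)
        exposures = (1.0 + shrink) * exposures
    ll = _pp_loglik(counts, exposures, alpha, r, phi)
    for _ in range(max_iter):
        # Update r coordinates jointly (rows are independent given phi).
        mu = exposures[None, :] * np.exp(alpha + np.outer(r, phi))
        grad = (counts - mu) @ phi
        hess = -(mu @ (phi**2))
        step = np.where(hess < 0, -grad / hess, 0.0)
        damp = 1.0
        for _ in range(30):
            cand = _pp_loglik(counts, exposures, alpha, r + damp * step, phi)
            if cand >= ll:
                r = r + damp * step
                ll = cand
                break
            damp *= 0.5
        # Update phi coordinates jointly (columns independent given r).
        mu = exposures[None, :] * np.exp(alpha + np.outer(r, phi))
        grad = ((counts - mu) * r[:, None]).sum(axis=0)
        hess = -((mu * (r**2)[:, None]).sum(axis=0))
        step = np.where(hess < 0, -grad / hess, 0.0)
        damp = 1.0
        gained = 0.0
        for _ in range(30):
            cand = _pp_loglik(counts, exposures, alpha, r, phi + damp * step)
            if cand >= ll:
                gained = cand - ll
                phi = phi + damp * step
                ll = cand
                break
            damp *= 0.5
        if gained < tol:
            break
    return r, phi


def fit_point_process_channel(
    epochs: dict[int, np.ndarray],
    baseline_spikes: np.ndarray,
    delta: float,
    window_start: float = 0.0,
    smooth_sigma: float = PSTH_SMOOTH_SIGMA,
    refine: bool = True,
) -> PointProcessChannelModel:
    """Fit one spike channel from aligned epochs and event-free baseline.

    The baseline log-rate is ``log(baseline spikes / baseline duration)``.
    Per-class PSTH rates are smoothed, floored, logged, baseline-subtracted,
    and factorized rank-1; optionally the factors are refined by exact
    Poisson ML ascent.
    """
    baseline_spikes = np.asarray(baseline_spikes)
    total = float(baseline_spikes.sum())
    if total <= 0:
        raise BaselineError("no baseline spikes; alpha undefined")
    alpha = float(np.log(total / (baseline_spikes.size * delta)))
    classes = sorted(epochs)
    counts = np.column_stack([epochs[c].sum(axis=0) for c in classes]).astype(float)
    n_per_class = np.array([epochs[c].shape[0] for c in classes], dtype=float)
    exposures = n_per_class * delta
    rates = counts / exposures[None, :]
    if smooth_sigma > 0:
        rates = gaussian_filter1d(rates, smooth_sigma / delta, axis=0)
    h = np.log(np.maximum(rates, RATE_FLOOR_FIT)) - alpha
    r, phi = _rank_one(h)
    if refine:
        # Refine on the smoothed counts: raw per-bin ML is ill-posed where a
        # bin collects zero spikes in every class (log-rate diverges).  The
        # product r * phi^T is what matters; renormalize afterwards.
        counts_s = (
            gaussian_filter1d(counts, smooth_sigma / delta, axis=0)
            if smooth_sigma > 0
            else counts
        )
        r_raw, phi_raw = _refine_pp(counts_s, exposures, alpha, r, phi)
        scale = np.linalg.norm(r_raw)
        if scale > 0:
            r, phi = r_raw / scale, phi_raw * scale
            if r[np.argmax(np.abs(r))] < 0:
                r, phi = -r, -phi
    return PointProcessChannelModel(
        TemporalResponse(window_start, r, delta), phi, alpha
    )


def fit_model(
    rec: MultimodalRecording,
    events: EventSequence,
    window: tuple[float, float] = (0.0, 0.3),
    refine: bool = True,
    smooth_sigma: float = PSTH_SMOOTH_SIGMA,
) -> MultimodalModel:
    """Fit every channel of a multimodal model from a training recording."""
    aligned = epoch_align(rec, events, window)
    mask = baseline_mask(rec, events, window)
    pp = [
        fit_point_process_channel(
            aligned.spikes[i],
            rec.spikes[i][mask],
            rec.delta,
            window_start=window[0],
            smooth_sigma=smooth_sigma,
            refine=refine,
        )
        for i in range(rec.n_pp)
    ]
    gauss = [
        fit_gaussian_channel(
            aligned.fields[j],
            rec.fields[j][mask],
            rec.delta,
            window_start=window[0],
        )
        for j in range(rec.n_gauss)
    ]
    return MultimodalModel(pp, gauss, events.n_classes, rec.delta, k=1.0)


def default_k_grid(n: int = 25) -> np.ndarray:
    """Log-spaced cross-modal scale grid on [1e-3, 1e3]."""
    return np.logspace(-3, 3, n)


def fit_cross_modal_scale(
    rec: MultimodalRecording,
    events: EventSequence,
    model: MultimodalModel,
    k_grid: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
) -> float:
    """Grid-search the cross-modal scale on training data.

    Maximizes detection AUC plus classification accuracy; exact ties break
    toward the grid value closest to 1 (unbiased fusion).
    """
    k_grid = default_k_grid() if k_grid is None else np.asarray(k_grid, dtype=float)
    if k_grid.size == 0 or np.any(k_grid <= 0):
        raise ValueError("k_grid must be non-empty with all values > 0")
    objectives = np.empty(k_grid.size)
    for idx, k in enumerate(k_grid):
        try:
            out = med_output(rec, model.with_k(float(k)))
            auc = detection_roc_auc(out, events, tol).auc
            acc = accuracy_at_truth(out, events, tol)
        except Exception as exc:  # noqa: BLE001 - annotate the grid point
            raise RuntimeError(f"evaluation failed at k = {k}") from exc
        objectives[idx] = auc + acc
    best = objectives.max()
    tied = np.flatnonzero(objectives == best)
    winner = tied[np.argmin(np.abs(np.log(k_grid[tied])))]
    return float(k_grid[winner])
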