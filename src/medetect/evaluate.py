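"""Performance metrics: tolerance-window ROC/AUC, accuracy, timing NRMSE.

Detection quality is scored with a modified ROC: every local maximum of the
detector's max trace ``x(t)`` is a candidate; a peak within a tolerance
window (default 200 ms) of an unmatched true event is a true positive, any
other peak is a false positive, and the detection threshold ``h`` sweeps the
peak heights from max(x) down to min(x).  AUC of 1 means perfect detection,
0.5 chance level.

Also provides event-class accuracy (at matched detections, or threshold-free
at the true event times), timing NRMSE (normalized by the tolerance), and a
channel-count sweep that measures how performance grows as channels of either
modality are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .detect import Detection, MedOutput, med_output
from .model import EventSequence, ModelError, MultimodalModel, MultimodalRecording

__all__ = [
    "EvaluationReport",
    "UndefinedMetricError",
    "match_peaks_to_events",
    "roc_from_peaks",
    "detection_roc_auc",
    "classification_accuracy",
    "classify_at_truth",
    "accuracy_at_truth",
    "timing_nrmse",
    "evaluate_output",
    "channel_sweep",
    "sweep_summary",
    "percent_improvement",
]

DEFAULT_TOL = 0.2


class UndefinedMetricError(ModelError):
    """Metric undefined for the given inputs (e.g. zero events)."""


@dataclass
class EvaluationReport:
    """ROC points, AUC, class accuracy, and timing NRMSE for one evaluation."""

    roc: np.ndarray  # columns: threshold, tpr, fpr
    auc: float
    accuracy: float | None = None
    nrmse: float | None = None
    n_true_events: int = 0
    n_candidate_peaks: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "nrmse": self.nrmse,
            "n_true_events": self.n_true_events,
            "n_candidate_peaks": self.n_candidate_peaks,
            "roc": [
                {"threshold": float(h), "tpr": float(t), "fpr": float(f)}
                for h, t, f in np.atleast_2d(self.roc).reshape(-1, 3)
            ],
        }


def _peak_arrays(peaks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize peaks (Detections or tuples) to time/score/class arrays."""
    times, scores, classes = [], [], []
    for p in peaks:
        if isinstance(p, Detection):
            times.append(p.time)
            scores.append(p.score)
            classes.append(p.class_idx)
        else:
            times.append(p[0])
            scores.append(p[1])
            classes.append(p[2] if len(p) > 2 else -1)
    return (
        np.asarray(times, dtype=float),
        np.asarray(scores, dtype=float),
        np.asarray(classes, dtype=int),
    )


def match_peaks_to_events(
    peaks,
    events: EventSequence,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, dict[int, int]]:
    """Greedy one-to-one matching of peaks to true events.

    Peaks are visited in descending score order; a peak within ``tol``
    seconds of a still-unmatched event is a true positive and consumes the
    nearest such event.  Returns a boolean true-positive label per peak (in
    input order) and a map event index -> matched peak index.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    times, scores, _ = _peak_arrays(peaks)
    tp = np.zeros(times.size, dtype=bool)
    event_to_peak: dict[int, int] = {}
    unmatched = set(range(len(events)))
    for k in np.argsort(-scores, kind="stable"):
        if not unmatched:
            break
        cand = [e for e in unmatched if abs(events.times[e] - times[k]) <= tol]
        if cand:
            best = min(cand, key=lambda e: abs(events.times[e] - times[k]))
            unmatched.discard(best)
            event_to_peak[best] = int(k)
            tp[k] = True
    return tp, event_to_peak


def _opportunity_scores(
    peaks, events: EventSequence, tol: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Window-max scores for event windows and equal-width control windows.

    Each true event owns the window ``[t_e - tol, t_e + tol]`` and is scored
    by the tallest peak inside it (``-inf`` if none).  Peaks outside every
    event window are false-positive candidates; the event-free time is tiled
    into control windows of the same width ``2 * tol``, each scored by its
    tallest peak.  Returns (event scores, occupied control-window scores,
    total number of control windows).  Because event and control windows have
    equal width, their score distributions coincide when no channel carries
    event-related signal — which pins the chance AUC at 0.5.
    """
    times, scores, _ = _peak_arrays(peaks)
    width = 2.0 * tol
    event_scores = np.full(len(events), -np.inf)
    for e, t in enumerate(events.times):
        near = np.abs(times - t) <= tol
        if near.any():
            event_scores[e] = scores[near].max()
    # Merge event windows into a union of intervals, then tile full-width
    # control windows inside the event-free complement (leftover fragments
    # shorter than one window are discarded, so every control window is a
    # complete 2*tol span, statistically comparable to an event window).
    merged: list[list[float]] = []
    for t in events.times:
        a, b = max(t - tol, 0.0), min(t + tol, events.duration)
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    gaps = []
    cursor = 0.0
    for a, b in merged:
        if a > cursor:
            gaps.append((cursor, a))
        cursor = b
    if cursor < events.duration:
        gaps.append((cursor, events.duration))
    control_scores = []
    n_control = 0
    for a, b in gaps:
        # epsilon guards float droop, e.g. (2.8 - 1.2) / 0.4 = 3.999...
        n_w = int(np.floor((b - a) / width + 1e-9))
        n_control += n_w
        if n_w == 0:
            continue
        sel = (times >= a) & (times < a + n_w * width)
        if sel.any():
            idx = np.floor((times[sel] - a) / width).astype(int)
            for w in np.unique(idx):
                control_scores.append(scores[sel][idx == w].max())
    n_control = max(n_control, 1)
    return event_scores, np.asarray(control_scores, dtype=float), n_control


def roc_from_peaks(
    peaks,
    events: EventSequence,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, float]:
    """Tolerance-window ROC points and AUC from candidate peaks.

    Detection opportunities are windows of width ``2 * tol``: one around each
    true event and tiled control windows over the event-free remainder, each
    scored by its tallest peak.  As the threshold ``h`` sweeps the peak
    heights, TPR(h) is the fraction of events whose window-max is >= h and
    FPR(h) the fraction of control windows whose window-max is >= h; AUC is
    the trapezoid area under (FPR, TPR), with the curve closed at
    (1, TPR at the lowest threshold).
    """
    if len(events) == 0:
        raise UndefinedMetricError("TPR undefined with zero true events")
    event_scores, control_scores, n_control = _opportunity_scores(
        peaks, events, tol
    )
    n_events = len(events)
    finite = event_scores[np.isfinite(event_scores)]
    thresholds = np.unique(np.concatenate([finite, control_scores]))[::-1]
    rows = [(np.inf, 0.0, 0.0)]
    for h in thresholds:
        tpr = float((event_scores >= h).sum()) / n_events
        fpr = float((control_scores >= h).sum()) / n_control
        rows.append((float(h), tpr, fpr))
    roc = np.array(rows)
    fpr_pts = np.append(roc[:, 2], 1.0)
    tpr_pts = np.append(roc[:, 1], roc[-1, 1])
    auc = float(np.trapezoid(tpr_pts, fpr_pts))
    return roc, auc


def _trace_peaks(out, delta: float | None = None):
    """All local maxima of the max trace as (time, score, class) Detections."""
    if isinstance(out, MedOutput):
        x = out.max_trace
        cls = out.argmax_class
        delta = out.delta
        delay = out.delay
    else:
        if delta is None:
            raise ValueError("delta required when passing a raw trace")
        x = np.asarray(out, dtype=float)
        cls = np.zeros(x.size, dtype=int)
        delay = 0.0
    idx, _ = sp_signal.find_peaks(x)
    return [
        Detection(time=i * delta - delay, class_idx=int(cls[i]), score=float(x[i]))
        for i in idx
    ]


def detection_roc_auc(
    out,
    events: EventSequence,
    tol: float = DEFAULT_TOL,
    delta: float | None = None,
) -> EvaluationReport:
    """Tolerance-window ROC/AUC from a detector output (or raw max trace)."""
    peaks = _trace_peaks(out, delta)
    if len(peaks) == 0:
        warnings.warn("max trace has no local maxima; AUC defined as 0.5")
        return EvaluationReport(
            roc=np.empty((0, 3)),
            auc=0.5,
            n_true_events=len(events),
            n_candidate_peaks=0,
        )
    roc, auc = roc_from_peaks(peaks, events, tol)
    return EvaluationReport(
        roc=roc,
        auc=auc,
        n_true_events=len(events),
        n_candidate_peaks=len(peaks),
    )


def classification_accuracy(
    detections,
    events: EventSequence,
    tol: float = DEFAULT_TOL,
) -> float:
    """Fraction of true events whose matched detection has the correct class.

    Events with no detection within the tolerance count as errors.
    """
    if len(events) == 0:
        raise UndefinedMetricError("accuracy undefined with zero events")
    _, _, classes = _peak_arrays(detections)
    _, event_to_peak = match_peaks_to_events(detections, events, tol)
    correct = sum(
        1 for e, k in event_to_peak.items() if classes[k] == events.classes[e]
    )
    return correct / len(events)


def classify_at_truth(
    out: MedOutput,
    events: EventSequence,
    tol: float = DEFAULT_TOL,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Threshold-free class estimate at each true event time.

    For each event, finds the bin where the max trace peaks within ``tol`` of
    the true time and returns the argmax class there.  Exact ties go to the
    lowest class index, or to a uniformly random tied class when ``rng`` is
    given.
    """
    x = out.max_trace
    w = int(np.rint(tol / out.delta))
    d = int(np.rint(out.delay / out.delta))
    est = np.empty(len(events), dtype=int)
    for e, t in enumerate(events.times):
        b = int(np.rint(t / out.delta)) + d
        lo, hi = max(b - w, 0), min(b + w + 1, out.n_bins)
        peak = lo + int(np.argmax(x[lo:hi]))
        v = out.traces[:, peak]
        tied = np.flatnonzero(v == v.max())
        if rng is not None and tied.size > 1:
            est[e] = int(rng.choice(tied))
        else:
            est[e] = int(tied[0])
    return est


def accuracy_at_truth(
    out: MedOutput,
    events: EventSequence,
    tol: float = DEFAULT_TOL,
    rng: np.random.Generator | None = None,
) -> float:
    """Accuracy of :func:`classify_at_truth` against the true classes."""
    if len(events) == 0:
        raise UndefinedMetricError("accuracy undefined with zero events")
    est = classify_at_truth(out, events, tol, rng)
    return float(np.mean(est == events.classes))


def timing_nrmse(
    detected_times: np.ndarray,
    true_times: np.ndarray,
    tol: float = DEFAULT_TOL,
) -> float:
    """RMS timing error of matched pairs, normalized by the tolerance.

    1.0 means errors at the edge of the matching window.
    """
    detected_times = np.asarray(detected_times, dtype=float)
    true_times = np.asarray(true_times, dtype=float)
    if detected_times.size == 0:
        raise UndefinedMetricError("NRMSE undefined with zero matched events")
    if detected_times.shape != true_times.shape:
        raise ValueError("matched pairs must have equal lengths")
    return float(np.sqrt(np.mean((detected_times - true_times) ** 2)) / tol)


def evaluate_output(
    out: MedOutput,
    events: EventSequence,
    tol: float = DEFAULT_TOL,
) -> EvaluationReport:
    """Threshold-free report: ROC/AUC, at-truth accuracy, timing NRMSE."""
    report = detection_roc_auc(out, events, tol)
    report.accuracy = accuracy_at_truth(out, events, tol)
    peaks = _trace_peaks(out)
    if peaks:
        _, event_to_peak = match_peaks_to_events(peaks, events, tol)
        if event_to_peak:
            det_t = np.array([peaks[k].time for k in event_to_peak.values()])
            true_t = events.times[list(event_to_peak.keys())]
            report.nrmse = timing_nrmse(det_t, true_t, tol)
    return report


def channel_sweep(
    rec: MultimodalRecording,
    events: EventSequence,
    model: MultimodalModel,
    n_shuffles: int = 10,
    seed: int = 0,
    pairs: list[tuple[int, int]] | None = None,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Evaluate sub-models over a grid of (spike-count, field-count).

    Channel orders are shuffled ``n_shuffles`` times; for each shuffle and
    each pair ``(i, j)`` the sub-model made of the first ``i`` spike and
    ``j`` field channels of that order is evaluated.  Returns a long-format
    frame with columns n_spike, n_field, shuffle, auc, accuracy, nrmse.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if pairs is None:
        pairs = [
            (i, j)
            for i in range(model.n_pp + 1)
            for j in range(model.n_gauss + 1)
            if i + j > 0
        ]
    rng = np.random.default_rng(seed)
    rows = []
    for sh in range(n_shuffles):
        pp_order = rng.permutation(model.n_pp)
        g_order = rng.permutation(model.n_gauss)
        for i, j in pairs:
            sub_pp, sub_g = list(pp_order[:i]), list(g_order[:j])
            sub_model = model.subset(sub_pp, sub_g)
            sub_rec = rec.subset(sub_pp, sub_g)
            out = med_output(sub_rec, sub_model)
            rep = evaluate_output(out, events, tol)
            rows.append(
                {
                    "n_spike": i,
                    "n_field": j,
                    "shuffle": sh,
                    "auc": rep.auc,
                    "accuracy": rep.accuracy,
                    "nrmse": rep.nrmse,
                }
            )
    return pd.DataFrame(rows)


def sweep_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of each metric per (n_spike, n_field) cell."""
    grouped = df.groupby(["n_spike", "n_field"])[["auc", "accuracy", "nrmse"]]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()


def percent_improvement(multimodal: float, unimodal: float) -> float:
    """Percent gain of multimodal over unimodal: 100 * (multi - uni) / uni."""
    if unimodal == 0:
        raise UndefinedMetricError("unimodal performance is zero")
    return 100.0 * (multimodal - unimodal) / unimodal
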