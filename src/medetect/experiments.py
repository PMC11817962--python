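"""Seeded end-to-end experiments under the standard study conditions.

Each function runs the full pipeline — simulate, (optionally fit), detect,
evaluate — at a fixed seed and returns summary numbers.  These drivers back
the chance/perfect anchors and the parameter-recovery and multimodal-fusion
analyses; the acceptance script and the test suite both call them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .detect import med_output
from .evaluate import (
    accuracy_at_truth,
    channel_sweep,
    classify_at_truth,
    detection_roc_auc,
)
from .fit import fit_model
from .model import GaussianChannelModel, MultimodalModel, PointProcessChannelModel
from .simulate import (
    SimulationConfig,
    draw_event_sequence,
    make_null_model,
    make_random_model,
    simulate_recording,
)

__all__ = [
    "uninformative_tuning_accuracy",
    "null_recording_auc",
    "high_snr_auc",
    "fusion_experiment",
    "recovery_experiment",
]


def _flatten_tuning(model: MultimodalModel) -> MultimodalModel:
    """Replace every spatial response by its class-mean: no class information."""
    pp = [
        PointProcessChannelModel(ch.r, np.full_like(ch.phi, ch.phi.mean()), ch.alpha)
        for ch in model.pp_channels
    ]
    gauss = [
        GaussianChannelModel(ch.r, np.full_like(ch.phi, ch.phi.mean()), ch.sigma2)
        for ch in model.gauss_channels
    ]
    return MultimodalModel(pp, gauss, model.n_classes, model.delta, model.k)


def uninformative_tuning_accuracy(
    n_events: int = 800, seed: int = 0, cfg: SimulationConfig | None = None
) -> dict:
    """Classification accuracy when spatial tuning carries no class information.

    All channels' spatial-response vectors are flattened to a constant across
    the S classes, so every per-class detector trace is identical; classes
    are assigned by uniform choice among the tied argmax classes at each true
    event.  The expectation is chance level 1/S.
    """
    cfg = cfg or SimulationConfig()
    cfg = replace(cfg, n_events=n_events, seed=seed)
    ss = np.random.SeedSequence(seed)
    ss_model, ss_events, ss_rec, ss_tie = ss.spawn(4)
    model = _flatten_tuning(make_random_model(cfg, np.random.default_rng(ss_model)))
    events = draw_event_sequence(cfg, np.random.default_rng(ss_events))
    rec = simulate_recording(model, events, ss_rec)
    out = med_output(rec, model)
    acc = float(
        np.mean(
            classify_at_truth(out, events, rng=np.random.default_rng(ss_tie))
            == events.classes
        )
    )
    p = 1.0 / cfg.n_classes
    return {
        "value": acc,
        "n": n_events,
        "chance": p,
        "se": float(np.sqrt(p * (1 - p) / n_events)),
    }


def null_recording_auc(
    n_seeds: int = 20,
    n_events: int = 100,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
) -> dict:
    """Detection AUC when no channel carries any event-related response.

    The recording holds constant-20-Hz spikes and pure-noise fields; the MED
    runs with a standard (nonzero-response) reference model, so peak heights
    are independent of event proximity and the expected AUC is 0.5.
    """
    cfg = cfg or SimulationConfig()
    cfg = replace(cfg, n_events=n_events)
    aucs = np.empty(n_seeds)
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    for idx, child in enumerate(children):
        ss_model, ss_events, ss_rec = child.spawn(3)
        reference = make_random_model(cfg, np.random.default_rng(ss_model))
        events = draw_event_sequence(cfg, np.random.default_rng(ss_events))
        null_rec = simulate_recording(make_null_model(cfg), events, ss_rec)
        out = med_output(null_rec, reference)
        aucs[idx] = detection_roc_auc(out, events).auc
    return {
        "value": float(aucs.mean()),
        "n": n_seeds,
        "per_seed": aucs.tolist(),
        "se": float(aucs.std(ddof=1) / np.sqrt(n_seeds)),
    }


def high_snr_auc(
    n_events: int = 50, snr: float = 10.0, seed: int = 0
) -> dict:
    """Detection AUC in a high signal-to-noise simulation with the true model."""
    cfg = SimulationConfig(n_events=n_events, snr=snr, seed=seed)
    ss = np.random.SeedSequence(seed)
    ss_model, ss_events, ss_rec = ss.spawn(3)
    model = make_random_model(cfg, np.random.default_rng(ss_model))
    events = draw_event_sequence(cfg, np.random.default_rng(ss_events))
    rec = simulate_recording(model, events, ss_rec)
    out = med_output(rec, model)
    return {"value": detection_roc_auc(out, events).auc, "n": n_events}


def fusion_experiment(
    n_replicates: int = 20,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Multimodal vs unimodal performance over seeded replicates.

    For each replicate a fresh dataset is drawn under the study conditions
    and the true model is evaluated on the multimodal configuration and both
    unimodal ones (default pairs).  Returns a long-format frame with columns
    replicate, n_spike, n_field, auc, accuracy, nrmse.
    """
    cfg = cfg or SimulationConfig()
    if pairs is None:
        pairs = [(cfg.n_pp, cfg.n_gauss), (cfg.n_pp, 0), (0, cfg.n_gauss)]
    frames = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep, child in enumerate(children):
        ss_model, ss_events, ss_rec = child.spawn(3)
        model = make_random_model(cfg, np.random.default_rng(ss_model))
        events = draw_event_sequence(cfg, np.random.default_rng(ss_events))
        rec = simulate_recording(model, events, ss_rec)
        df = channel_sweep(
            rec, events, model, n_shuffles=1, seed=rep, pairs=pairs
        )
        df["replicate"] = rep
        frames.append(df.drop(columns="shuffle"))
    return pd.concat(frames, ignore_index=True)


def recovery_experiment(
    events_per_class: int = 500,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    refine: bool = True,
) -> dict:
    """Parameter recovery: fit a model to one large simulated training set.

    Draws ``events_per_class * S`` events under the study conditions,
    simulates a recording from a random ground-truth model, fits every
    channel, and reports per-channel correlation between fitted and true
    temporal responses plus the fitted field noise variances.
    """
    cfg = cfg or SimulationConfig()
    cfg = replace(cfg, n_events=events_per_class * cfg.n_classes, seed=seed)
    ss = np.random.SeedSequence(seed)
    ss_model, ss_events, ss_rec = ss.spawn(3)
    model = make_random_model(cfg, np.random.default_rng(ss_model))
    events = draw_event_sequence(cfg, np.random.default_rng(ss_events))
    rec = simulate_recording(model, events, ss_rec)
    fitted = fit_model(rec, events, window=(0.0, cfg.kernel_support), refine=refine)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "pp_r_corr": [
            corr(f.r.values, t.r.values)
            for f, t in zip(fitted.pp_channels, model.pp_channels)
        ],
        "gauss_r_corr": [
            corr(f.r.values, t.r.values)
            for f, t in zip(fitted.gauss_channels, model.gauss_channels)
        ],
        "sigma2_hat": [ch.sigma2 for ch in fitted.gauss_channels],
        "sigma2_true": [ch.sigma2 for ch in model.gauss_channels],
        "alpha_hat": [ch.alpha for ch in fitted.pp_channels],
        "alpha_true": [ch.alpha for ch in model.pp_channels],
        "n_events": len(events),
    }
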