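"""Readers and writers for recordings, event tables, and model files.

* Model: JSON with schema ``{schema_version, S, delta, k, pp_channels:
  [{r: {t1, t2, values}, phi, alpha}], gauss_channels: [{r, phi, sigma2}]}``.
* Events: CSV with header ``time_s,class_index``; times serialized at 1 us
  resolution so they are bin-exact at 1 ms sampling.
* Recording: a directory with a ``meta.json`` sidecar ``{T, delta, n_pp,
  n_gauss, format}`` and the channel arrays either as CSV (one column per
  channel) or as a compressed ``.npz`` container.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    EventSequence,
    GaussianChannelModel,
    MultimodalModel,
    MultimodalRecording,
    PointProcessChannelModel,
    TemporalResponse,
)

__all__ = [
    "FormatError",
    "read_model",
    "write_model",
    "read_events",
    "write_events",
    "read_recording",
    "write_recording",
]

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Malformed or inconsistent on-disk artifact."""


def _kernel_to_json(r: TemporalResponse) -> dict:
    return {"t1": r.start, "t2": r.stop, "values": r.values.tolist()}


def _kernel_from_json(d: dict, delta: float) -> TemporalResponse:
    return TemporalResponse(float(d["t1"]), np.asarray(d["values"]), delta)


def write_model(model: MultimodalModel, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "S": model.n_classes,
        "delta": model.delta,
        "k": model.k,
        "pp_channels": [
            {
                "r": _kernel_to_json(ch.r),
                "phi": ch.phi.tolist(),
                "alpha": ch.alpha,
            }
            for ch in model.pp_channels
        ],
        "gauss_channels": [
            {
                "r": _kernel_to_json(ch.r),
                "phi": ch.phi.tolist(),
                "sigma2": ch.sigma2,
            }
            for ch in model.gauss_channels
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_model(path: str | Path) -> MultimodalModel:
    doc = json.loads(Path(path).read_text())
    if "schema_version" not in doc:
        raise FormatError(f"{path}: missing schema_version")
    delta = float(doc["delta"])
    pp = [
        PointProcessChannelModel(
            _kernel_from_json(ch["r"], delta),
            np.asarray(ch["phi"]),
            float(ch["alpha"]),
        )
        for ch in doc.get("pp_channels", [])
    ]
    gauss = [
        GaussianChannelModel(
            _kernel_from_json(ch["r"], delta),
            np.asarray(ch["phi"]),
            float(ch["sigma2"]),
        )
        for ch in doc.get("gauss_channels", [])
    ]
    return MultimodalModel(pp, gauss, int(doc["S"]), delta, float(doc.get("k", 1.0)))


def write_events(events: EventSequence, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": np.round(events.times, 6), "class_index": events.classes}
    )
    df.to_csv(path, index=False)


def read_events(
    path: str | Path,
    n_classes: int | None = None,
    duration: float | None = None,
) -> EventSequence:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "class_index"]:
        raise FormatError(f"{path}: expected header time_s,class_index")
    times = df["time_s"].to_numpy(dtype=float)
    classes = df["class_index"].to_numpy(dtype=int)
    if times.size and np.any(np.diff(times) < 0):
        warnings.warn(f"{path}: event times unsorted; sorting")
        order = np.argsort(times, kind="stable")
        times, classes = times[order], classes[order]
    if n_classes is None:
        n_classes = int(classes.max()) + 1 if classes.size else 1
    if duration is None:
        duration = float(times[-1] + 1.0) if times.size else 1.0
    return EventSequence(times, classes, n_classes, duration)


def write_recording(
    rec: MultimodalRecording, out_dir: str | Path, fmt: str = "npz"
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "T": rec.duration,
        "delta": rec.delta,
        "n_pp": rec.n_pp,
        "n_gauss": rec.n_gauss,
        "format": fmt,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta))
    if fmt == "npz":
        np.savez_compressed(
            out_dir / "recording.npz",
            spikes=rec.spikes.astype(np.int8),
            fields=rec.fields,
        )
    elif fmt == "csv":
        pd.DataFrame(
            rec.spikes.T, columns=[f"pp_{i}" for i in range(rec.n_pp)]
        ).to_csv(out_dir / "spikes.csv", index=False)
        pd.DataFrame(
            rec.fields.T, columns=[f"gauss_{j}" for j in range(rec.n_gauss)]
        ).to_csv(out_dir / "fields.csv", index=False)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


def read_recording(in_dir: str | Path) -> MultimodalRecording:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    n = int(np.rint(meta["T"] / meta["delta"]))
    fmt = meta.get("format", "npz")
    if fmt == "npz":
        with np.load(in_dir / "recording.npz") as data:
            spikes = data["spikes"]
            fields = data["fields"]
    elif fmt == "csv":
        spikes = pd.read_csv(in_dir / "spikes.csv").to_numpy().T
        fields = pd.read_csv(in_dir / "fields.csv").to_numpy(dtype=float).T
    else:
        raise FormatError(f"unknown recording format {fmt!r}")
    spikes = spikes.reshape(int(meta["n_pp"]), -1)
    fields = fields.reshape(int(meta["n_gauss"]), -1)
    for name, arr, expect in (
        ("spikes", spikes, int(meta["n_pp"])),
        ("fields", fields, int(meta["n_gauss"])),
    ):
        if arr.shape[0] != expect:
            raise FormatError(f"{name}: {arr.shape[0]} channels, sidecar says {expect}")
        if arr.shape[0] and arr.shape[1] != n:
            raise FormatError(
                f"{name}: length {arr.shape[1]} != round(T/delta) = {n}"
            )
    bad = np.argwhere(~np.isin(spikes, (0, 1)))
    if bad.size:
        ch, b = bad[0]
        raise FormatError(
            f"spike channel pp_{ch} has non-binary value at bin {b}"
        )
    return MultimodalRecording(
        spikes.astype(np.int8), fields, float(meta["T"]), float(meta["delta"])
    )
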