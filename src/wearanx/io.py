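"""Plain-text persistence: one CSV per channel plus a JSON sidecar for
recordings, and CSV + JSON metadata for feature tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    Channel,
    ConditionInterval,
    DEVICE_TAG,
    MultimodalRecording,
)

__all__ = [
    "write_recording",
    "read_recording",
    "write_feature_table",
    "read_feature_table",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_recording(rec: MultimodalRecording, outdir) -> Path:
    """Write one CSV (columns ``t_s,value``) per channel and ``meta.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ch in rec.channels.items():
        t = np.arange(ch.samples.size) / ch.fs
        pd.DataFrame({"t_s": t, "value": ch.samples}).to_csv(
            outdir / f"{name}.csv", index=False, float_format="%.6g")
    meta = {
        "subject_id": rec.subject_id,
        "fs": {name: ch.fs for name, ch in rec.channels.items()},
        "device_tag": rec.device_tag,
        "annotations": [_jsonable(iv) for iv in rec.annotations],
        "true_beats_s": _jsonable(rec.true_beats_s),
        "meta": _jsonable({k: v for k, v in rec.meta.items() if k != "profile"}),
    }
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return outdir


def read_recording(indir) -> MultimodalRecording:
    indir = Path(indir)
    with open(indir / "meta.json") as fh:
        meta = json.load(fh)
    channels = {}
    for name, fs in meta["fs"].items():
        frame = pd.read_csv(indir / f"{name}.csv")
        channels[name] = Channel(frame["value"].to_numpy(float), float(fs))
    annotations = [ConditionInterval(**iv) for iv in meta["annotations"]]
    beats = meta.get("true_beats_s")
    return MultimodalRecording(
        channels=channels,
        annotations=annotations,
        true_beats_s=np.asarray(beats, float) if beats is not None else None,
        subject_id=meta["subject_id"],
        device_tag=meta.get("device_tag", dict(DEVICE_TAG)),
        meta=meta.get("meta", {}),
    )


def write_feature_table(table: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if metadata is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(_jsonable(metadata), fh, indent=1)
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
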