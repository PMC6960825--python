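"""Readers and writers for session recordings and feature tables.

A session lives in one directory: a JSON manifest (subject id, sampling
rates, activity timeline, optional ground-truth event lists) plus one CSV
per channel with columns ``time_s,value``.  All floats are written with 9
significant digits and deterministic ordering, so two writes of the same
session are byte-identical and golden-file tests are feasible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .synth import AUX_FS, ECG_FS, SessionRecording

FLOAT_FMT = "%.9g"
CHANNELS = {"ecg": ECG_FS, "teb": AUX_FS, "eda_hand": AUX_FS, "eda_arm": AUX_FS}


def _fmt(x: float) -> float:
    return float(FLOAT_FMT % x)


def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write a session directory; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    channels = {}
    for name, fs in CHANNELS.items():
        values = getattr(session, name)
        t = np.arange(len(values)) / fs
        fname = f"{name}.csv"
        with open(path / fname, "w") as fh:
            fh.write("time_s,value\n")
            np.savetxt(fh, np.column_stack([t, values]), fmt=FLOAT_FMT,
                       delimiter=",")
        channels[name] = {"file": fname, "fs_hz": fs, "units": "a.u."}
    gt = {}
    for key, val in session.ground_truth.items():
        if isinstance(val, dict):
            gt[key] = {k: [_fmt(x) for x in np.asarray(v)]
                       for k, v in val.items()}
        else:
            gt[key] = [_fmt(x) for x in np.asarray(val)]
    manifest = {
        "subject_id": session.subject_id,
        "channels": channels,
        "timeline": [[a, _fmt(s), _fmt(e)] for a, s, e in session.timeline],
        "ground_truth": gt,
        "format_version": 1,
    }
    mpath = path / "manifest.json"
    mpath.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return mpath


def _read_channel_csv(fpath: Path) -> np.ndarray:
    try:
        df = pd.read_csv(fpath, dtype=float)
    except (ValueError, TypeError):
        raw = pd.read_csv(fpath, dtype=str)
        for i, row in raw.iterrows():
            try:
                [float(v) for v in row]
            except (ValueError, TypeError):
                raise ValueError(
                    f"{fpath.name}: non-numeric value at data row {i}")
        raise
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError(f"{fpath.name}: expected columns time_s,value")
    return df["value"].to_numpy()


def read_session(path: str | Path) -> SessionRecording:
    """Load and validate a session directory written by ``write_session``."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    manifest = json.loads(mpath.read_text())
    data = {}
    timeline = [(a, float(s), float(e)) for a, s, e in manifest["timeline"]]
    span = timeline[-1][2] - timeline[0][1]
    for name in CHANNELS:
        if name not in manifest["channels"]:
            raise ValueError(f"manifest missing channel {name!r}")
        info = manifest["channels"][name]
        fs = float(info["fs_hz"])
        if fs <= 0:
            raise ValueError(f"channel {name!r}: nonpositive sampling rate")
        fpath = path / info["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"channel {name!r}: file {info['file']} not found")
        values = _read_channel_csv(fpath)
        if abs(len(values) - span * fs) > 1.5:
            raise ValueError(
                f"channel {name!r}: {len(values)} samples inconsistent with "
                f"manifest rate {fs} Hz over {span} s")
        data[name] = values
    gt_raw = manifest.get("ground_truth", {})
    gt = {}
    for key, val in gt_raw.items():
        if isinstance(val, dict):
            gt[key] = {k: np.asarray(v, dtype=float) for k, v in val.items()}
        else:
            gt[key] = np.asarray(val, dtype=float)
    session = SessionRecording(subject_id=manifest["subject_id"],
                               ecg=data["ecg"], teb=data["teb"],
                               eda_hand=data["eda_hand"],
                               eda_arm=data["eda_arm"],
                               timeline=timeline, ground_truth=gt)
    session.validate()
    return session


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    """Feature matrix as CSV plus a JSON sidecar with the registry hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fm.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "registry_hash": fm.registry_hash,
        "n_rows": int(fm.X.shape[0]),
        "n_features": int(fm.X.shape[1]),
    }, sort_keys=True, indent=2) + "\n")
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    meta_cols = ["subject", "label", "decision_time"]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    sidecar = path.with_suffix(path.suffix + ".json")
    registry_hash = ""
    if sidecar.exists():
        registry_hash = json.loads(sidecar.read_text()).get("registry_hash", "")
    return FeatureMatrix(df[feat_cols].to_numpy(dtype=float), feat_cols,
                         df["label"].to_numpy(), df["subject"].to_numpy(),
                         df["decision_time"].to_numpy(dtype=float),
                         registry_hash)
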