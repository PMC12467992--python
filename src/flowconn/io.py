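"""Readers and writers for ROI time series, raw recordings and result tables.

On-disk conventions: numeric matrices are comma-separated with a period
decimal and no header row; metadata travels in a sidecar JSON
(``<stem>.json``) holding ``roi_labels``/``dt``/``participant_id`` for ROI
series or ``fs``/``participant_id``/``label`` for raw recordings.  ``.edf``
raw files are read through mne when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .flow import DEFAULT_ROI_LABELS, FlowMatrix, ROITimeSeries
from .preprocess import SUPPORTED_RATES, RawRecording


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_roi_series(ts: ROITimeSeries, path) -> Path:
    path = Path(path)
    np.savetxt(path, ts.values, delimiter=",")
    meta = {"roi_labels": list(ts.roi_labels), "dt": ts.dt,
            "participant_id": ts.participant_id}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_roi_series(path, canonical_order=DEFAULT_ROI_LABELS) -> ROITimeSeries:
    """Read a delimited ROI matrix + sidecar; rows reordered to canonical order."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar JSON: {side}")
    meta = json.loads(side.read_text())
    for key in ("roi_labels", "dt"):
        if key not in meta:
            raise ValueError(f"sidecar {side} lacks required key '{key}'")
    try:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    labels = list(meta["roi_labels"])
    if values.shape[0] != len(labels):
        raise ValueError(
            f"{path}: {values.shape[0]} rows but {len(labels)} labels")
    if set(labels) == set(canonical_order):
        order = [labels.index(lab) for lab in canonical_order]
        values = values[order]
        labels = list(canonical_order)
    return ROITimeSeries(values=values, roi_labels=tuple(labels),
                         dt=float(meta["dt"]),
                         participant_id=meta.get("participant_id", path.stem))


def write_raw_recording(rec: RawRecording, path) -> Path:
    path = Path(path)
    np.savetxt(path, rec.signal, delimiter=",")
    meta = {"fs": rec.fs, "participant_id": rec.participant_id,
            "label": rec.label}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raw_eeg(path, fs: float | None = None, label=None,
                 n_channels: int = 64) -> RawRecording:
    """Read a raw recording from delimited CSV (+ sidecar) or EDF."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:
            raise ImportError("reading EDF requires mne") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        rec = RawRecording(signal=raw.get_data(), fs=float(raw.info["sfreq"]),
                           participant_id=path.stem, label=label)
    else:
        side = _sidecar(path)
        meta = json.loads(side.read_text()) if side.exists() else {}
        fs = fs if fs is not None else meta.get("fs")
        if fs is None:
            raise ValueError(f"{path}: sampling rate not given and no sidecar")
        rec = RawRecording(signal=np.loadtxt(path, delimiter=",", ndmin=2),
                           fs=float(fs),
                           participant_id=meta.get("participant_id", path.stem),
                           label=label if label is not None
                           else meta.get("label"))
    if rec.n_channels != n_channels:
        raise ValueError(
            f"{path}: expected {n_channels} channels, got {rec.n_channels}")
    if rec.fs not in SUPPORTED_RATES:
        raise ValueError(
            f"{path}: unsupported sampling rate {rec.fs} Hz; allowed: "
            f"{SUPPORTED_RATES}")
    return rec


def write_flow_matrix(fm: FlowMatrix, prefix) -> tuple:
    """CSV matrix (diagonal empty) plus JSON metadata; returns both paths."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    df = pd.DataFrame(fm.tau, index=fm.roi_labels, columns=fm.roi_labels)
    df.to_csv(csv_path)
    meta_path = prefix.with_suffix(".json")
    meta_path.write_text(json.dumps(
        {"participant_id": fm.participant_id,
         "roi_labels": list(fm.roi_labels)}, indent=1))
    return csv_path, meta_path


def read_flow_matrix(csv_path) -> FlowMatrix:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    meta_path = csv_path.with_suffix(".json")
    pid = csv_path.stem
    if meta_path.exists():
        pid = json.loads(meta_path.read_text()).get("participant_id", pid)
    return FlowMatrix(tau=df.to_numpy(dtype=float),
                      roi_labels=tuple(df.columns), participant_id=pid)


def write_ranked_connections(ranked, path) -> Path:
    path = Path(path)
    pd.DataFrame(ranked, columns=["transmitter", "receiver", "mean_abs_tau"]
                 ).to_csv(path, index=False)
    return path


def write_group_stats(stats_by_group: dict, path) -> Path:
    path = Path(path)
    pd.DataFrame(stats_by_group).T.to_csv(path)
    return path
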