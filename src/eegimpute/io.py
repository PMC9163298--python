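"""File formats: the HDF5 trial container (canonical), CSV-per-trial, EDF read.

The container stores the canonical (trial, time, channel) array with NaN
artifact encoding, optional labels and held-out ground truth, channel names,
sampling rate and a provenance record. It is written without HDF5 timestamps
so identical inputs produce identical bytes.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import EEGTrialSet

__all__ = ["read_trials", "write_trials"]

_FORMAT_VERSION = 1


def write_trials(trial_set: EEGTrialSet, path, format: str = "container") -> None:
    if format == "container":
        _write_container(trial_set, path)
    elif format == "csv":
        _write_csv(trial_set, path)
    else:
        raise ValueError(f"unknown write format {format!r}")


def read_trials(path, format: str = "container", channels=None,
                epoch_window: tuple[int, int] | None = None,
                sampling_rate: float | None = None) -> EEGTrialSet:
    """Load trials in canonical (trial, time, channel) layout, microvolts.

    ``format`` is one of ``container`` (HDF5), ``csv`` (one file per trial in
    a directory) or ``edf`` (continuous recording epoched around its
    annotation markers with ``epoch_window=(start, stop)`` in samples).
    """
    if format == "container":
        return _read_container(path)
    if format == "csv":
        return _read_csv(path)
    if format == "edf":
        return _read_edf(path, channels=channels, epoch_window=epoch_window)
    raise ValueError(f"unknown read format {format!r}")


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def _write_container(ts: EEGTrialSet, path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["channel_names"] = list(ts.channel_names)
        f.attrs["sampling_rate"] = float(ts.sampling_rate)
        f.attrs["provenance"] = json.dumps(ts.provenance, sort_keys=True)
        f.create_dataset("values", data=ts.values, track_times=False)
        if ts.labels is not None:
            f.create_dataset("labels", data=ts.labels, track_times=False)
        if ts.ground_truth is not None:
            f.create_dataset("ground_truth", data=ts.ground_truth, track_times=False)


def _read_container(path) -> EEGTrialSet:
    with h5py.File(path, "r") as f:
        return EEGTrialSet(
            values=f["values"][()],
            channel_names=[str(n) for n in f.attrs["channel_names"]],
            sampling_rate=float(f.attrs["sampling_rate"]),
            labels=f["labels"][()] if "labels" in f else None,
            ground_truth=f["ground_truth"][()] if "ground_truth" in f else None,
            provenance=json.loads(f.attrs["provenance"]),
        )


# ---------------------------------------------------------------------------
# CSV (one file per trial; header row = channel names)
# ---------------------------------------------------------------------------

def _write_csv(ts: EEGTrialSet, path) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    width = max(len(str(ts.n_trials - 1)), 4)
    for i in range(ts.n_trials):
        pd.DataFrame(ts.values[i], columns=ts.channel_names).to_csv(
            root / f"trial_{i:0{width}d}.csv", index=False, na_rep="NaN"
        )
    meta = {
        "format_version": _FORMAT_VERSION,
        "sampling_rate": ts.sampling_rate,
        "channel_names": list(ts.channel_names),
        "labels": None if ts.labels is None else [int(l) for l in ts.labels],
        "provenance": ts.provenance,
    }
    (root / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _read_csv(path) -> EEGTrialSet:
    root = Path(path)
    meta = json.loads((root / "meta.json").read_text())
    files = sorted(root.glob("trial_*.csv"), key=lambda p: int(re.findall(r"\d+", p.stem)[-1]))
    if not files:
        raise FileNotFoundError(f"no trial_*.csv files under {root}")
    frames = [pd.read_csv(f, float_precision="round_trip") for f in files]
    names = meta["channel_names"]
    values = np.stack([fr[names].to_numpy(dtype=np.float64) for fr in frames])
    return EEGTrialSet(
        values=values,
        channel_names=names,
        sampling_rate=float(meta["sampling_rate"]),
        labels=meta.get("labels"),
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# EDF (read-only, epoched around annotation markers)
# ---------------------------------------------------------------------------

def _read_edf(path, channels=None, epoch_window=None) -> EEGTrialSet:
    import mne

    if epoch_window is None:
        raise ValueError("EDF reading requires epoch_window=(start, stop) in samples")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    if len(events) == 0:
        raise ValueError("EDF file has no annotation markers to epoch around")
    sfreq = raw.info["sfreq"]
    start, stop = epoch_window
    data = raw.get_data()  # (D, n_samples) in volts
    trials, labels = [], []
    for sample, _, code in events:
        a, b = sample + start, sample + stop
        if a < 0 or b > data.shape[1]:
            continue
        trials.append(data[:, a:b].T * 1e6)  # -> microvolts, (T, D)
        labels.append(code)
    if not trials:
        raise ValueError("no events with a complete epoch window inside the recording")
    return EEGTrialSet(
        values=np.stack(trials),
        channel_names=list(raw.ch_names),
        sampling_rate=float(sfreq),
        labels=np.asarray(labels) - min(labels),
        provenance={"source": str(path), "epoch_window": list(epoch_window)},
    )
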