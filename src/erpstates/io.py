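"""Epoch bundle I/O.

A bundle is a directory with one tab-separated matrix (channels x
timepoints, uV) per epoch plus a ``bundle.json`` manifest recording
subjects, conditions, montage, sampling rate, window and seed. An
equivalent single-file HDF5 container is available when h5py is installed.
BrainVision Core triplets and plain multiplexed ASCII exports can be mapped
into EpochSets for users with real recordings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .erp import EpochSet

_BUNDLE_MANIFEST = "bundle.json"


def write_bundle(epoch_sets: Sequence[EpochSet], directory: str | Path) -> Path:
    """Write EpochSets as per-epoch TSV matrices plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not epoch_sets:
        raise ValueError("nothing to write")
    ref = epoch_sets[0]
    entries = []
    for es in epoch_sets:
        if tuple(es.montage) != tuple(ref.montage):
            raise ValueError("all EpochSets in a bundle must share a montage")
        files = []
        for i in range(es.n_epochs):
            name = f"{es.subject_id}_{es.condition}_epoch{i + 1:03d}.tsv"
            np.savetxt(directory / name, es.data[i], delimiter="\t", fmt="%.6g")
            files.append(name)
        entries.append(
            {
                "subject": es.subject_id,
                "condition": es.condition,
                "epoch_files": files,
            }
        )
    manifest = {
        "montage": list(ref.montage),
        "sampling_rate_hz": ref.sampling_rate_hz,
        "time_ms": ref.time_ms.tolist(),
        "epoch_sets": entries,
    }
    (directory / _BUNDLE_MANIFEST).write_text(json.dumps(manifest, indent=1))
    return directory


def read_bundle(directory: str | Path) -> list[EpochSet]:
    """Read a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    manifest = json.loads((directory / _BUNDLE_MANIFEST).read_text())
    montage = tuple(manifest["montage"])
    time_ms = np.asarray(manifest["time_ms"], dtype=float)
    out = []
    for entry in manifest["epoch_sets"]:
        data = np.stack(
            [
                np.loadtxt(directory / name, delimiter="\t", ndmin=2)
                for name in entry["epoch_files"]
            ]
        )
        out.append(
            EpochSet(
                subject_id=entry["subject"],
                condition=entry["condition"],
                data=data,
                time_ms=time_ms,
                montage=montage,
                sampling_rate_hz=manifest["sampling_rate_hz"],
            )
        )
    return out


def write_bundle_h5(epoch_sets: Sequence[EpochSet], path: str | Path) -> Path:
    """Same schema as the TSV bundle, in one HDF5 file (requires h5py)."""
    import h5py

    path = Path(path)
    ref = epoch_sets[0]
    with h5py.File(path, "w") as f:
        f.attrs["montage"] = json.dumps(list(ref.montage))
        f.attrs["sampling_rate_hz"] = ref.sampling_rate_hz
        f.create_dataset("time_ms", data=ref.time_ms)
        for es in epoch_sets:
            g = f.create_group(f"{es.subject_id}/{es.condition}")
            g.create_dataset("epochs", data=es.data)
    return path


def read_bundle_h5(path: str | Path) -> list[EpochSet]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        montage = tuple(json.loads(f.attrs["montage"]))
        fs = float(f.attrs["sampling_rate_hz"])
        time_ms = np.asarray(f["time_ms"])
        for subject in sorted(k for k in f.keys() if k != "time_ms"):
            for condition in sorted(f[subject].keys()):
                out.append(
                    EpochSet(
                        subject_id=subject,
                        condition=condition,
                        data=np.asarray(f[subject][condition]["epochs"]),
                        time_ms=time_ms,
                        montage=montage,
                        sampling_rate_hz=fs,
                    )
                )
    return out


def read_ascii_multiplexed(
    path: str | Path,
    n_channels: int,
    time_ms: np.ndarray,
    montage: Sequence[str],
    subject_id: str,
    condition: str,
    sampling_rate_hz: float = 250.0,
) -> EpochSet:
    """Read a multiplexed ASCII export: rows are timepoints, columns are
    channels, epochs concatenated in time. The file length must be a whole
    number of epochs of ``len(time_ms)`` timepoints."""
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[1] != n_channels:
        raise ValueError(f"expected {n_channels} columns, found {raw.shape[1]}")
    n_t = len(time_ms)
    if raw.shape[0] % n_t:
        raise ValueError(
            f"{raw.shape[0]} rows is not a whole number of {n_t}-sample epochs"
        )
    data = raw.reshape(-1, n_t, n_channels).transpose(0, 2, 1)
    return EpochSet(
        subject_id=subject_id,
        condition=condition,
        data=data,
        time_ms=np.asarray(time_ms, dtype=float),
        montage=tuple(montage),
        sampling_rate_hz=sampling_rate_hz,
    )


def read_brainvision_epochs(
    vhdr_path: str | Path,
    subject_id: str,
    condition: str,
    window_ms: tuple[float, float],
    event_id: dict | None = None,
) -> EpochSet:
    """Map a BrainVision Core triplet (.vhdr/.vmrk/.eeg) into an EpochSet.

    Optional convenience for real recordings; requires mne. Epochs are cut
    around stimulus markers over the half-open window, without any
    filtering or re-referencing.
    """
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    events, found_ids = mne.events_from_annotations(raw, event_id, verbose="error")
    t0, t1 = window_ms
    step = 1000.0 / raw.info["sfreq"]
    epochs = mne.Epochs(
        raw,
        events,
        tmin=t0 / 1000.0,
        tmax=(t1 - step) / 1000.0,
        baseline=None,
        preload=True,
        verbose="error",
    )
    data_uv = epochs.get_data() * 1e6
    return EpochSet(
        subject_id=subject_id,
        condition=condition,
        data=data_uv,
        time_ms=t0 + step * np.arange(data_uv.shape[2]),
        montage=tuple(epochs.ch_names),
        sampling_rate_hz=float(raw.info["sfreq"]),
    )
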