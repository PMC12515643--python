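"""Recording and epoch containers plus CSV/EDF input-output.

All amplitudes are carried in microvolts (μV). Recordings are stored as a
``channels × samples`` float array with a sampling rate and unique channel
labels; epoched data adds a per-epoch keep mask with rejection reasons.

CSV layout: one column per channel (header row = channel labels), one row
per sample. A JSON sidecar (``<name>.json``) carries the sampling rate,
modality and provenance so a round trip is lossless. EDF files are read
through :func:`mne.io.read_raw_edf` and converted from volts to μV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: 16-channel motor-cortex montage (international 10-20 names).
EEG_CHANNELS = [
    "P4", "CP2", "FC5", "C3", "P3", "C2", "FC6", "C4",
    "CP6", "F3", "FC2", "FC1", "F4", "CP5", "C1", "CP1",
]

#: 10 upper-limb muscles recorded with surface EMG.
EMG_MUSCLES = ["FDS", "FCU", "FCR", "ECU", "ECRL", "BB", "TB", "DM", "DA", "DP"]


@dataclass
class Recording:
    """One subject's multichannel time series (EEG or EMG).

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique montage names, one per row of ``data``.
    modality : {"EEG", "EMG"}
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    modality: str = "EEG"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels × samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.modality not in ("EEG", "EMG"):
            raise ValueError("modality must be 'EEG' or 'EMG'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with ``data`` (and any other fields) replaced."""
        return dataclasses.replace(self, **changes)


@dataclass
class EpochSet:
    """Fixed-length consecutive epochs cut from a recording.

    ``kept_mask`` marks epochs that survived artifact screening;
    ``reject_reason`` holds a short string for each rejected epoch.
    """

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    epoch_length_s: float
    channel_labels: list[str]
    modality: str = "EEG"
    kept_mask: np.ndarray = field(default=None)
    reject_reason: list = field(default=None)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epoch × channel × sample")
        n_samp = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != n_samp:
            raise ValueError(
                f"epochs have {self.epochs.shape[2]} samples, expected {n_samp}"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = [None] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept(self) -> np.ndarray:
        """Array of retained epochs, shape (n_kept, n_channels, n_samples)."""
        return self.epochs[self.kept_mask]


def write_recording_csv(rec: Recording, path: str | Path, meta: dict | None = None) -> Path:
    """Write a recording as CSV (columns = channels) with a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {"fs": rec.fs, "modality": rec.modality,
               "channel_labels": rec.channel_labels, "units": "uV"}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_csv(path: str | Path, fs: float | None = None,
                       modality: str | None = None) -> Recording:
    """Read a CSV recording; fs/modality come from the sidecar unless given."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = fs if fs is not None else meta.get("fs")
        modality = modality if modality is not None else meta.get("modality", "EEG")
    if fs is None:
        raise ValueError(f"no sampling rate: pass fs= or provide sidecar {sidecar}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"could not parse recording CSV {path}: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"recording CSV {path} is empty")
    return Recording(df.to_numpy().T, fs=float(fs),
                     channel_labels=list(df.columns), modality=modality or "EEG")


def read_recording_edf(path: str | Path, modality: str = "EEG") -> Recording:
    """Read an EDF file (amplitudes converted from V to μV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), modality=modality)


def read_recording(path: str | Path, fmt: str | None = None, fs: float | None = None,
                   modality: str | None = None) -> Recording:
    """Dispatch on format ('edf' or 'csv'; inferred from suffix if omitted)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_recording_edf(path, modality=modality or "EEG")
    if fmt == "csv":
        return read_recording_csv(path, fs=fs, modality=modality)
    raise ValueError(f"unsupported recording format: {fmt!r}")
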