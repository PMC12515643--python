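"""Signal conditioning: filtering, resampling, re-referencing, epoching, rejection.

The default chain mirrors a standard resting-state protocol: zero-phase FIR
band-pass (0.5-45 Hz for EEG, 20-400 Hz for EMG), 50 Hz notch, downsampling
to 500 Hz, common average reference (EEG only), segmentation into
non-overlapping 2 s epochs, and rejection of any epoch containing a sample
exceeding ±80 μV on any electrode. Filtering is delegated to
:mod:`mne.filter` (hamming-window FIR, forward applied with delay
compensation, i.e. zero-phase).

An externally supplied per-epoch exclusion list (:func:`exclude_epochs`)
stands in for interactive ICA-based artifact screening, which is out of
scope here.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .io import EpochSet, Recording

__all__ = [
    "bandpass_filter", "notch_filter", "resample", "common_average_reference",
    "epoch", "reject_amplitude", "exclude_epochs",
    "EEG_BAND", "EMG_BAND", "NOTCH_HZ", "TARGET_FS", "EPOCH_S", "REJECT_UV",
]

EEG_BAND = (0.5, 45.0)   # Hz
EMG_BAND = (20.0, 400.0)  # Hz
NOTCH_HZ = 50.0
TARGET_FS = 500.0
EPOCH_S = 2.0
REJECT_UV = 80.0


def _mne_filter(data: np.ndarray, fs: float, low: float | None, high: float | None,
                **kw) -> np.ndarray:
    from mne.filter import filter_data

    return filter_data(np.ascontiguousarray(data, dtype=np.float64), fs,
                       l_freq=low, h_freq=high, verbose="error", **kw)


def bandpass_filter(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase FIR band-pass; passband gain within 1% of unity."""
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= rec.fs / 2:
        raise ValueError(f"high edge {high} Hz is at or above Nyquist ({rec.fs / 2} Hz)")
    return rec.copy_with(data=_mne_filter(rec.data, rec.fs, low, high))


def notch_filter(rec: Recording, freq: float = NOTCH_HZ) -> Recording:
    """Zero-phase FIR notch (≥20 dB at ``freq``, ±5 Hz neighbours untouched)."""
    if not (0 < freq < rec.fs / 2):
        raise ValueError(f"notch frequency must lie in (0, {rec.fs / 2}) Hz")
    from mne.filter import notch_filter as mne_notch

    data = mne_notch(np.ascontiguousarray(rec.data, dtype=np.float64), rec.fs,
                     freqs=freq, verbose="error")
    return rec.copy_with(data=data)


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase anti-aliased downsampling to ``target_fs``.

    The output has exactly ``floor(n_samples × target_fs / fs)`` samples;
    upsampling is not supported.
    """
    if target_fs > rec.fs:
        raise ValueError("upsampling not supported")
    if target_fs == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_out = math.floor(rec.n_samples * target_fs / rec.fs)
    return rec.copy_with(data=out[:, :n_out], fs=float(target_fs))


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference each sample to the instantaneous mean over channels (EEG only)."""
    if rec.modality != "EEG":
        raise ValueError("common average reference applies to EEG recordings")
    if rec.n_channels < 2:
        raise ValueError("common average reference needs ≥ 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def epoch(rec: Recording, length_s: float = EPOCH_S) -> EpochSet:
    """Cut consecutive non-overlapping epochs; the trailing remainder is dropped."""
    n_per = length_s * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(f"epoch length {length_s} s is not a whole number of "
                         f"samples at {rec.fs} Hz")
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        warnings.warn(f"recording shorter than one {length_s} s epoch; zero epochs",
                      RuntimeWarning)
    data = rec.data[:, : n_epochs * n_per]
    epochs = data.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(epochs, fs=rec.fs, epoch_length_s=length_s,
                    channel_labels=rec.channel_labels, modality=rec.modality)


def reject_amplitude(epochs: EpochSet, threshold_uv: float = REJECT_UV) -> EpochSet:
    """Reject epochs with any sample of absolute amplitude above ``threshold_uv``.

    'Exceeding ±threshold' is read strictly: |v| > threshold rejects, |v| =
    threshold is retained. Already-rejected epochs keep their prior reason.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    mask = epochs.kept_mask.copy()
    reasons = list(epochs.reject_reason)
    over = np.abs(epochs.epochs).max(axis=(1, 2)) > threshold_uv
    for i in np.flatnonzero(over & mask):
        mask[i] = False
        reasons[i] = f"amplitude exceeds ±{threshold_uv:g} μV"
    return EpochSet(epochs.epochs, fs=epochs.fs, epoch_length_s=epochs.epoch_length_s,
                    channel_labels=epochs.channel_labels, modality=epochs.modality,
                    kept_mask=mask, reject_reason=reasons)


def exclude_epochs(epochs: EpochSet, indices, reason: str = "manual exclusion") -> EpochSet:
    """Mark externally identified artifact epochs (e.g. from visual/ICA review)."""
    mask = epochs.kept_mask.copy()
    reasons = list(epochs.reject_reason)
    for i in indices:
        if not 0 <= i < epochs.n_epochs:
            raise IndexError(f"epoch index {i} out of range")
        mask[i] = False
        reasons[i] = reason
    return EpochSet(epochs.epochs, fs=epochs.fs, epoch_length_s=epochs.epoch_length_s,
                    channel_labels=epochs.channel_labels, modality=epochs.modality,
                    kept_mask=mask, reject_reason=reasons)
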