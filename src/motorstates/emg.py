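"""Time-domain surface-EMG features: peak-to-peak and RMS amplitude.

PTP (max − min of the segment) indexes the amplitude range of muscle
contraction; RMS (root mean square) indexes overall activation strength.
Features are computed per artifact-screened epoch and averaged across
epochs, on the 20-400 Hz filtered signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import EpochSet

__all__ = ["compute_ptp", "compute_rms", "feature_table", "delta_features"]


def compute_ptp(signal: np.ndarray) -> float:
    """Peak-to-peak amplitude: max(x) − min(x) in μV."""
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size == 0:
        raise ValueError("empty signal")
    return float(np.max(signal) - np.min(signal))


def compute_rms(signal: np.ndarray) -> float:
    """Root-mean-square amplitude: sqrt(mean(x²)) in μV."""
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size == 0:
        raise ValueError("empty signal")
    return float(np.sqrt(np.mean(signal**2)))


def feature_table(epochs: EpochSet, muscle_labels: list[str] | None = None) -> pd.DataFrame:
    """Per-muscle PTP and RMS, computed per kept epoch and averaged.

    Returns a DataFrame indexed by muscle with columns ``ptp_uV`` and
    ``rms_uV``.
    """
    kept = epochs.kept()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs")
    muscles = list(muscle_labels or epochs.channel_labels)
    if len(muscles) != kept.shape[1]:
        raise ValueError("one label per channel required")
    ptp = np.ptp(kept, axis=2).mean(axis=0)           # mean over epochs
    rms = np.sqrt(np.mean(kept**2, axis=2)).mean(axis=0)
    return pd.DataFrame({"ptp_uV": ptp, "rms_uV": rms},
                        index=pd.Index(muscles, name="muscle"))


def delta_features(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Element-wise change scores (post − pre) of two feature tables."""
    if list(pre.index) != list(post.index) or list(pre.columns) != list(post.columns):
        raise ValueError("feature tables must cover the same muscles and features")
    return post - pre
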