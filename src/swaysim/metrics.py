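"""Static-balance outcome measures: RMS sway amplitude and mean power frequency."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .types import AngularSeries

__all__ = ["rms", "mpf", "average_trials"]

#: default Welch settings: 20 s Hann segments, 50% overlap
WELCH_SEGMENT_S = 20.0
#: default lower band edge (Hz) excluding residual drift
BAND_LO_HZ = 0.05


def rms(x: np.ndarray | AngularSeries) -> float:
    """Root-mean-square amplitude of a (demeaned) sway signal."""
    v = x.values if isinstance(x, AngularSeries) else np.asarray(x, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean(v**2)))


def mpf(
    x: np.ndarray | AngularSeries,
    sample_rate: float | None = None,
    band: tuple[float, float] = (BAND_LO_HZ, 3.5),
    segment_s: float = WELCH_SEGMENT_S,
) -> float:
    """Mean power frequency of the sway spectrum.

    The power spectral density is estimated by Welch's averaged periodogram
    (Hann taper, ``segment_s``-second segments, 50% overlap) and the MPF is
    the power-weighted mean frequency over ``band``:
    sum(f * P(f)) / sum(P(f)).  The band's upper edge should match the
    low-pass cutoff applied upstream.
    """
    if isinstance(x, AngularSeries):
        v, fs = x.values, x.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        v, fs = np.asarray(x, dtype=float), sample_rate
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi > fs / 2:
        raise ValueError(f"band upper edge {hi} Hz above Nyquist {fs / 2} Hz")
    if v.size == 0:
        raise ValueError("empty series")
    nperseg = min(len(v), int(round(segment_s * fs)))
    freqs, psd = signal.welch(v, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend="constant")
    m = (freqs >= lo) & (freqs <= hi)
    total = psd[m].sum()
    if total == 0:
        return 0.0
    return float((freqs[m] * psd[m]).sum() / total)


def average_trials(metrics: pd.DataFrame) -> pd.DataFrame:
    """Average per-trial sway metrics within subject x condition x vision.

    Expects columns ``subject_id, group, condition, vision`` plus numeric
    metric columns; returns one row per cell with the arithmetic mean of
    each metric and the number of trials averaged (``n_trials``).
    """
    keys = ["subject_id", "group", "condition", "vision"]
    missing = [k for k in keys if k not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns {missing}")
    if metrics.empty:
        raise ValueError("empty metrics table")
    value_cols = [c for c in metrics.columns
                  if c not in keys and pd.api.types.is_numeric_dtype(metrics[c])]
    grouped = metrics.groupby(keys, sort=True, as_index=False)
    out = grouped[value_cols].mean()
    out["n_trials"] = grouped.size()["size"].to_numpy()
    return out
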