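"""Signal conditioning and centre-of-mass reconstruction.

Implements the measurement chain of the posturographic protocol: trapezoidal
integration of angular velocity, cubic-spline interpolation of short marker
gaps, zero-phase (dual-pass) Butterworth low-pass filtering, 80 s clipping
with demeaning, the four-segment total-body COM, and the inverse-tangent
angular COM about the ankle axis.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate as _integrate
from scipy import signal
from scipy.interpolate import CubicSpline

from .types import SEGMENTS, AngularSeries, ComTrajectory, MarkerSet

__all__ = [
    "AnthropometricTable",
    "default_anthropometry",
    "integrate_velocity",
    "interpolate_gaps",
    "GapReport",
    "lowpass_filter",
    "clip_and_demean",
    "total_body_com",
    "angular_com",
]


@dataclass(frozen=True)
class AnthropometricTable:
    """Segment mass fractions and COM locations of the four-segment model.

    ``mass_fraction`` is the segment's share of total body mass (both limbs
    combined); ``com_fraction`` locates the segment COM as a fraction of the
    proximal-to-distal segment vector.
    """

    mass_fraction: dict[str, float]
    com_fraction: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(SEGMENTS) - set(self.mass_fraction)
        if missing:
            raise ValueError(f"missing segments: {sorted(missing)}")
        total = sum(self.mass_fraction[s] for s in SEGMENTS)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, not 1")
        for s in SEGMENTS:
            f = self.com_fraction[s]
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"com_fraction for {s!r} outside [0, 1]: {f}")

    @classmethod
    def from_csv(cls, path) -> "AnthropometricTable":
        df = pd.read_csv(path)
        return cls(
            mass_fraction=dict(zip(df["segment"], df["mass_fraction"])),
            com_fraction=dict(zip(df["segment"], df["com_fraction"])),
        )


def default_anthropometry() -> AnthropometricTable:
    """The packaged segment table (Winter-style dermal fractions)."""
    res = importlib.resources.files("swaysim").joinpath("data/anthropometry.csv")
    with importlib.resources.as_file(res) as path:
        return AnthropometricTable.from_csv(path)


def integrate_velocity(v: AngularSeries) -> AngularSeries:
    """Angular displacement from angular velocity by trapezoidal integration.

    The output starts at 0 deg and has the same length and sample rate as
    the input.
    """
    if v.quantity != "velocity":
        raise ValueError("input series must carry angular velocity")
    if len(v.values) == 0:
        raise ValueError("empty series")
    pos = _integrate.cumulative_trapezoid(v.values, dx=1.0 / v.sample_rate,
                                          initial=0.0)
    return AngularSeries(v.sample_rate, pos, "position")


@dataclass(frozen=True)
class GapReport:
    marker: str
    start_index: int
    length_ms: float
    filled: bool
    reason: str = ""


def interpolate_gaps(
    m: MarkerSet, max_gap_ms: float = 40.0
) -> tuple[MarkerSet, list[GapReport]]:
    """Fill short missing runs by cubic-spline interpolation.

    Runs strictly shorter than ``max_gap_ms`` are replaced by a not-a-knot
    cubic spline fitted through the marker's non-missing samples (exact for
    trajectories that are locally cubic polynomials).  Longer runs, and runs
    touching the series boundary (no bracketing data), are left missing and
    reported.  Non-missing samples are never altered.
    """
    out = m.copy()
    reports: list[GapReport] = []
    ms_per_sample = 1000.0 / m.sample_rate
    for name, mask in m.missing.items():
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        # contiguous runs of missing samples
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        runs = np.split(idx, splits)
        good = np.flatnonzero(~mask)
        if len(good) < 4:
            for run in runs:
                reports.append(GapReport(name, int(run[0]), len(run) * ms_per_sample,
                                         False, "too few samples to fit spline"))
            continue
        spline_x = CubicSpline(good, m.markers[name][good, 0])
        spline_y = CubicSpline(good, m.markers[name][good, 1])
        for run in runs:
            length_ms = len(run) * ms_per_sample
            if run[0] == 0 or run[-1] == m.n_samples - 1:
                reports.append(GapReport(name, int(run[0]), length_ms, False,
                                         "gap at series boundary"))
                continue
            if length_ms >= max_gap_ms:
                reports.append(GapReport(name, int(run[0]), length_ms, False,
                                         f"gap >= {max_gap_ms} ms"))
                continue
            out.markers[name][run, 0] = spline_x(run)
            out.markers[name][run, 1] = spline_y(run)
            out.missing[name][run] = False
            reports.append(GapReport(name, int(run[0]), length_ms, True))
    return out, reports


def _min_length(order: int) -> int:
    # filtfilt default pad length is 3 * max(len(a), len(b)) = 3*(order+1)
    return 3 * (order + 1) + 1


def lowpass_filter(x: np.ndarray, cutoff: float, sample_rate: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The dual pass doubles the attenuation: the effective magnitude response
    is the squared single-pass Butterworth magnitude,
    ``(1 + (f/fc)^(2*order))^-1``, with no phase distortion.  Edge effects
    are controlled by odd reflection padding of three filter lengths.
    """
    x = np.asarray(x, dtype=float)
    if cutoff <= 0 or cutoff >= sample_rate / 2:
        raise ValueError(f"cutoff must lie in (0, Nyquist), got {cutoff} Hz "
                         f"at {sample_rate} Hz")
    n_min = _min_length(order)
    if x.shape[-1] < n_min:
        raise ValueError(f"series too short for order-{order} dual-pass filter: "
                         f"need at least {n_min} samples, got {x.shape[-1]}")
    b, a = signal.butter(order, cutoff, fs=sample_rate)
    return signal.filtfilt(b, a, x, axis=-1)


def filter_series(x: AngularSeries, cutoff: float, order: int = 4) -> AngularSeries:
    """``lowpass_filter`` applied to an AngularSeries."""
    return AngularSeries(x.sample_rate,
                         lowpass_filter(x.values, cutoff, x.sample_rate, order),
                         x.quantity)


def filter_markers(m: MarkerSet, cutoff: float, order: int = 4) -> MarkerSet:
    """Low-pass filter every fully observed marker channel.

    Markers must be gap-free (interpolate first); remaining missing runs
    raise, because a zero-phase filter cannot straddle NaNs.
    """
    out = m.copy()
    for name, xy in out.markers.items():
        if out.missing[name].any():
            raise ValueError(f"marker {name!r} still has missing samples; "
                             "interpolate gaps before filtering")
        out.markers[name] = lowpass_filter(xy.T, cutoff, m.sample_rate, order).T
    return out


def clip_and_demean(x: AngularSeries, clip_s: float = 80.0) -> AngularSeries:
    """Retain the first ``clip_s`` seconds and remove the mean."""
    if x.quantity != "position":
        raise ValueError("clip_and_demean expects angular position")
    n = int(round(clip_s * x.sample_rate))
    if len(x.values) < n:
        raise ValueError(f"series shorter than {clip_s} s: "
                         f"{len(x.values) / x.sample_rate:.2f} s")
    v = x.values[:n]
    return AngularSeries(x.sample_rate, v - v.mean(), "position")


def total_body_com(m: MarkerSet, table: AnthropometricTable,
                   body_mass: float = float("nan")) -> ComTrajectory:
    """Four-segment total-body centre of mass.

    Per sample, COM = sum over segments of
    ``mass_fraction * (proximal + com_fraction * (distal - proximal))``.
    Fractional weights make the result independent of body mass, which is
    retained as metadata only.  Missing (uninterpolated) samples propagate
    as NaN.
    """
    n = m.n_samples
    com = np.zeros((n, 2))
    for seg, (prox_name, dist_name) in SEGMENTS.items():
        if prox_name not in m.markers or dist_name not in m.markers:
            raise ValueError(f"segment {seg!r} endpoints missing from marker set")
        prox = np.where(m.missing[prox_name][:, None], np.nan, m.markers[prox_name])
        dist = np.where(m.missing[dist_name][:, None], np.nan, m.markers[dist_name])
        seg_com = prox + table.com_fraction[seg] * (dist - prox)
        com += table.mass_fraction[seg] * seg_com
    return ComTrajectory(m.sample_rate, com, body_mass)


def angular_com(c: ComTrajectory) -> AngularSeries:
    """Anterior-posterior angular COM displacement about the ankle axis.

    theta = arctan(forward offset / vertical offset), degrees, forward
    positive.  A non-positive vertical offset means the COM is at or below
    the axis, which is non-physical for stance and rejected.
    """
    x, y = c.xy[:, 0], c.xy[:, 1]
    finite = np.isfinite(y)
    if np.any(y[finite] <= 0):
        raise ValueError("COM vertical offset <= 0: non-physical posture")
    theta = np.degrees(np.arctan2(x, y))
    return AngularSeries(c.sample_rate, theta, "position")
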