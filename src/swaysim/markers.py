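"""Synthesis of sagittal motion-capture marker trajectories.

The generator places the five markers of the four-segment chain (ankle,
foot landmark, knee, hip, C7) along the pendulum/body axis and rotates the
whole rigid chain about the ankle by the simulated lean angle, so that in
the noise-free case the total-body centre of mass lies exactly on that
axis and the downstream angular-COM reconstruction recovers the driving
angle to numerical precision.  Optional per-joint wobble, additive
coordinate noise and injected missing-sample runs emulate real capture
imperfections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import MARKER_NAMES, AngularSeries, MarkerSet

__all__ = ["GapSpec", "default_chain", "synthesize_markers"]

#: marker distances along the body axis as fractions of standing height,
#: measured from the ankle joint (Winter-style segment statures)
_CHAIN_FRACTIONS = {
    "ankle": 0.0,
    "met": 0.077,
    "knee": 0.246,
    "hip": 0.491,
    "c7": 0.779,
}


def default_chain(height: float) -> dict[str, float]:
    """Marker distances (m) along the chain for a subject of given stature."""
    if height <= 0:
        raise ValueError("height must be positive")
    return {k: f * height for k, f in _CHAIN_FRACTIONS.items()}


@dataclass(frozen=True)
class GapSpec:
    """One missing-data run to inject.

    ``marker`` / ``start_s`` left as None are drawn at random; lengths are
    given in milliseconds (the interpolation rule downstream is phrased in
    ms as well).
    """

    duration_ms: float
    marker: str | None = None
    start_s: float | None = None


def synthesize_markers(
    theta: AngularSeries,
    segment_lengths: dict[str, float],
    noise_sd: float = 0.0,
    gap_spec: list[GapSpec] | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    wobble_sd: float = 0.0,
) -> MarkerSet:
    """Generate marker trajectories consistent with a lean-angle series.

    Parameters
    ----------
    theta : angular position series (deg, forward positive).
    segment_lengths : marker name -> distance from the ankle along the chain
        (m); see :func:`default_chain`.
    noise_sd : additive Gaussian coordinate noise, m.
    gap_spec : missing-data runs to inject (NaN + mask).
    wobble_sd : per-sample independent angular jitter (deg) added to each
        non-ankle marker, emulating soft-tissue/joint play.
    """
    if theta.quantity != "position":
        raise ValueError("theta must be an angular position series")
    missing_lengths = [g.duration_ms for g in (gap_spec or [])]
    for ms in missing_lengths:
        if ms / 1000.0 >= theta.duration:
            raise ValueError(f"gap of {ms} ms exceeds the trial duration")
    for name, r in segment_lengths.items():
        if name != "ankle" and r <= 0:
            raise ValueError(f"segment distance for {name!r} must be positive")

    rng = np.random.default_rng(seed)
    ang = np.deg2rad(theta.values)
    n = len(ang)
    markers: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for name in MARKER_NAMES:
        r = segment_lengths[name]
        a = ang
        if wobble_sd > 0 and name != "ankle":
            a = ang + np.deg2rad(wobble_sd) * rng.standard_normal(n)
        xy = np.column_stack([r * np.sin(a), r * np.cos(a)])
        if noise_sd > 0:
            xy = xy + noise_sd * rng.standard_normal((n, 2))
        markers[name] = xy
        missing[name] = np.zeros(n, dtype=bool)

    for gap in gap_spec or []:
        run = max(1, int(round(gap.duration_ms / 1000.0 * theta.sample_rate)))
        name = gap.marker
        if name is None:
            name = MARKER_NAMES[rng.integers(1, len(MARKER_NAMES))]
        if name not in markers:
            raise ValueError(f"unknown marker {name!r}")
        if gap.start_s is None:
            start = int(rng.integers(1, max(2, n - run - 1)))
        else:
            start = int(round(gap.start_s * theta.sample_rate))
        if start < 0 or start + run > n:
            raise ValueError("gap does not fit inside the trial")
        markers[name][start:start + run] = np.nan
        missing[name][start:start + run] = True

    return MarkerSet(theta.sample_rate, markers, missing)
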