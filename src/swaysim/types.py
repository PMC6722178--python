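"""Core data containers for the balance-simulator pipeline.

Conventions used throughout the package:

* the ankle (rotation) axis is the coordinate origin; ``x`` points forward
  (anterior), ``y`` points up;
* lean angles are measured about the ankle axis in the sagittal
  (anterior-posterior) plane, in degrees, forward positive;
* SI units elsewhere (kg, m, s, N, N·m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "SubjectProfile",
    "DeviceConfig",
    "ControllerParams",
    "PerturbationSchedule",
    "AngularSeries",
    "ForceTrace",
    "MarkerSet",
    "ComTrajectory",
    "SEGMENTS",
    "GRAVITY",
]

#: standard gravitational acceleration (m/s^2)
GRAVITY = 9.81

#: four-segment sagittal body model: segment -> (proximal, distal) marker names
SEGMENTS: dict[str, tuple[str, str]] = {
    "foot": ("ankle", "met"),
    "shank": ("ankle", "knee"),
    "thigh": ("knee", "hip"),
    "head_arms_trunk": ("hip", "c7"),
}

#: marker names of the sagittal chain, proximal to distal
MARKER_NAMES = ("ankle", "met", "knee", "hip", "c7")


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometry and group membership of one participant."""

    id: str
    group: Literal["PD", "control"]
    mass: float  # kg
    height: float  # m
    com_height: float  # m, estimated body COM height above the ankle axis
    sex: Literal["F", "M"] = "F"
    age: float = 68.0  # years

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not 0 < self.com_height < self.height:
            raise ValueError(
                f"com_height must lie in (0, height): got {self.com_height} "
                f"for height {self.height}"
            )
        if self.group not in ("PD", "control"):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class DeviceConfig:
    """Configuration of the supine inverted-pendulum balance device.

    The device is weighted so its gravitational toppling stiffness equals
    ``stiffness_fraction`` of the participant's upright load stiffness
    m·g·h.  Mechanical stops bound the pendulum excursion and each trial
    starts with the pendulum leaning slightly toward the participant.
    """

    stiffness_fraction: float = 0.60
    pendulum_com_height: float = 1.0  # m above the rotation axis
    stop_angle: float = 17.0  # degrees
    initial_lean: float = 3.0  # degrees, toward the participant (forward +)

    def __post_init__(self) -> None:
        if not 0 < self.stiffness_fraction <= 1:
            raise ValueError(
                f"stiffness_fraction must be in (0, 1], got {self.stiffness_fraction}"
            )
        if not self.stop_angle > self.initial_lean >= 0:
            raise ValueError(
                "require stop_angle > initial_lean >= 0, got "
                f"stop={self.stop_angle}, lean={self.initial_lean}"
            )
        if self.pendulum_com_height <= 0:
            raise ValueError("pendulum_com_height must be positive")


@dataclass(frozen=True)
class ControllerParams:
    """Delayed proportional-derivative ankle-torque controller.

    The corrective torque is ``-K·θ(t-Δ) - B·θ̇(t-Δ)`` plus additive
    low-pass-filtered Gaussian torque noise (std ``noise_gain``) and, for
    tremor-affected subjects, a sinusoidal torque in the 4-7 Hz band.
    """

    stiffness_gain: float  # K, N·m/rad
    damping_gain: float  # B, N·m·s/rad
    delay: float = 0.15  # s
    noise_gain: float = 1.0  # N·m, std of filtered torque noise
    tremor_amplitude: float = 0.0  # N·m
    tremor_freq: float = 5.0  # Hz

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.noise_gain < 0:
            raise ValueError("noise_gain must be >= 0")
        if self.tremor_amplitude > 0 and not 4.0 <= self.tremor_freq <= 7.0:
            raise ValueError(
                f"tremor_freq must lie in [4, 7] Hz, got {self.tremor_freq}"
            )


@dataclass(frozen=True)
class PerturbationSchedule:
    """Timing and shape of the manually delivered perturbation pulses.

    Pulses are half-sine force profiles; a fraction of events is delivered
    backward (negated) as catch trials to prevent anticipatory leaning.
    """

    n_events: int = 12
    catch_fraction: float = 0.12
    inter_event_interval_range: tuple[float, float] = (2.5, 8.4)  # s
    pulse_peak: float = 12.0  # N
    pulse_duration: float = 0.25  # s
    peak_sd: float = 0.0  # N, between-event variation of the peak force
    lead_in: float = 10.0  # s of unperturbed stance before the first pulse
    tail: float = 4.0  # s after the last pulse

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not 0 <= self.catch_fraction < 1:
            raise ValueError("catch_fraction must be in [0, 1)")
        lo, hi = self.inter_event_interval_range
        if not 0 < lo <= hi:
            raise ValueError("inter-event interval range must be positive and ordered")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if lo <= self.pulse_duration:
            raise ValueError("inter-event intervals must exceed the pulse duration")


@dataclass
class AngularSeries:
    """Uniformly sampled angular position (deg) or velocity (deg/s)."""

    sample_rate: float
    values: np.ndarray
    quantity: Literal["position", "velocity"] = "position"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.quantity not in ("position", "velocity"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def unit(self) -> str:
        return "deg" if self.quantity == "position" else "deg/s"

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


@dataclass
class ForceTrace:
    """Load-transducer signal from the perturbation rod.

    ``true_onsets`` holds the simulator's ground-truth pulse onset sample
    indices; it exists for validation only and is never consulted by the
    analysis stages.
    """

    sample_rate: float
    values: np.ndarray
    true_onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.values = np.asarray(self.values, dtype=float)
        self.true_onsets = np.asarray(self.true_onsets, dtype=int)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate


@dataclass
class MarkerSet:
    """2-D sagittal marker trajectories with a per-sample missing mask.

    ``markers`` maps marker name to an (n, 2) array of (x, y) coordinates in
    metres; missing samples are NaN and flagged in ``missing``.
    """

    sample_rate: float
    markers: dict[str, np.ndarray]
    missing: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = None
        for name, xy in self.markers.items():
            xy = np.asarray(xy, dtype=float)
            if xy.ndim != 2 or xy.shape[1] != 2:
                raise ValueError(f"marker {name!r} must be an (n, 2) array")
            self.markers[name] = xy
            if n is None:
                n = len(xy)
            elif len(xy) != n:
                raise ValueError("all markers must share one sample count")
            mask = np.asarray(self.missing.get(name, np.zeros(len(xy), bool)), bool)
            self.missing[name] = mask
            ok = ~mask
            if not np.all(np.isfinite(xy[ok])):
                raise ValueError(f"marker {name!r} has non-finite present samples")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.markers.values())))

    def copy(self) -> "MarkerSet":
        return MarkerSet(
            self.sample_rate,
            {k: v.copy() for k, v in self.markers.items()},
            {k: v.copy() for k, v in self.missing.items()},
        )


@dataclass
class ComTrajectory:
    """Total-body centre-of-mass path in the sagittal plane (m, ankle origin)."""

    sample_rate: float
    xy: np.ndarray
    body_mass: float = float("nan")  # kg, metadata only

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
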