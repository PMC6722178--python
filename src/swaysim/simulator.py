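"""Physics of the supine balance device and of upright quiet stance.

Both conditions are modelled as a single inverted pendulum regulated by a
delayed proportional-derivative (PD) ankle-torque controller:

    I·θ̈ = S_eff·sin(θ) − K·θ(t−Δ) − B·θ̇(t−Δ) + τ_noise(t) + τ_tremor(t) + τ_ext(t)

where ``S_eff`` is the gravitational toppling stiffness of the plant
(m·g·h for upright stance; the device fraction of it for simulated stance),
``I`` the moment of inertia of a point mass consistent with that stiffness,
``K``/``B``/``Δ`` the controller gains and neuromuscular delay, ``τ_noise``
low-pass-filtered Gaussian torque noise, ``τ_tremor`` an optional 4-7 Hz
sinusoid, and ``τ_ext`` external perturbation torque.

Integration is fixed-step semi-implicit Euler at an internal rate of at
least ten times the output sample rate; the delay is realised by indexing
the stored state history.  Excursions are clamped at the mechanical stops
(±stop_angle) and hitting a stop raises the ``fell`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import (
    GRAVITY,
    AngularSeries,
    ControllerParams,
    DeviceConfig,
    ForceTrace,
    PerturbationSchedule,
    SubjectProfile,
)

__all__ = [
    "load_stiffness",
    "device_stiffness",
    "simulate_quiet_stance",
    "simulate_perturbation_trial",
    "StanceResult",
    "PerturbationTrial",
]

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


#: internal integration runs at this multiple of the output sample rate
OVERSAMPLE = 10

#: corner frequency (Hz) of the first-order low-pass shaping the torque noise
NOISE_CUTOFF_HZ = 1.5


def load_stiffness(mass: float, com_height: float) -> float:
    """Gravitational ankle load stiffness S = m·g·h of upright stance.

    Parameters
    ----------
    mass : body mass in kg.
    com_height : height of the body centre of mass above the ankle axis, m.

    Returns
    -------
    Load stiffness in N·m/rad: the toppling torque produced per radian of
    small lean.  The balance device is weighted to a fraction of this value.
    """
    if mass < 0 or com_height < 0:
        raise ValueError(
            f"mass and com_height must be non-negative, got {mass}, {com_height}"
        )
    return mass * GRAVITY * com_height


def device_stiffness(profile: SubjectProfile, config: DeviceConfig) -> float:
    """Toppling stiffness of the device as configured for one participant."""
    return config.stiffness_fraction * load_stiffness(profile.mass, profile.com_height)


def _plant(profile: SubjectProfile, config: DeviceConfig, upright: bool):
    """Effective stiffness and inertia of the controlled pendulum.

    Upright stance: the body itself, S = m·g·h and I = m·h².  Simulated
    stance: the device pendulum, S = fraction·m·g·h with the equivalent
    point mass located at the pendulum COM height, so I = S·h_p/g.
    """
    if upright:
        s_eff = load_stiffness(profile.mass, profile.com_height)
        inertia = profile.mass * profile.com_height**2
    else:
        s_eff = device_stiffness(profile, config)
        h_p = config.pendulum_com_height
        inertia = s_eff * h_p / GRAVITY
    return s_eff, inertia


@njit(cache=True)
def _integrate(theta0, n, dt, inertia, s_eff, k_gain, b_gain, delay_steps,
               torque, stop_rad):  # pragma: no cover - compiled
    theta = np.empty(n)
    omega = np.empty(n)
    theta[0] = theta0
    omega[0] = 0.0
    fell = False
    for i in range(n - 1):
        j = i - delay_steps
        if j >= 0:
            th_d = theta[j]
            om_d = omega[j]
        else:
            th_d = theta0
            om_d = 0.0
        acc = (s_eff * np.sin(theta[i]) - k_gain * th_d - b_gain * om_d
               + torque[i]) / inertia
        omega[i + 1] = omega[i] + acc * dt
        theta[i + 1] = theta[i] + omega[i + 1] * dt
        if theta[i + 1] >= stop_rad:
            theta[i + 1] = stop_rad
            omega[i + 1] = 0.0
            fell = True
        elif theta[i + 1] <= -stop_rad:
            theta[i + 1] = -stop_rad
            omega[i + 1] = 0.0
            fell = True
    return theta, omega, fell


def _noise_torque(rng: np.random.Generator, n: int, dt: float,
                  noise_gain: float) -> np.ndarray:
    """Low-pass (< 2 Hz) Gaussian torque noise with std ``noise_gain``."""
    white = rng.standard_normal(n)
    if noise_gain == 0.0:
        return np.zeros(n)
    # first-order low-pass at NOISE_CUTOFF_HZ, rescaled to the requested std
    tau = 1.0 / (2.0 * np.pi * NOISE_CUTOFF_HZ)
    alpha = dt / (tau + dt)
    shaped = signal.lfilter([alpha], [1.0, alpha - 1.0], white)
    sd = shaped.std()
    if sd == 0.0:
        return np.zeros(n)
    return noise_gain / sd * shaped


def _internal_torque(rng, controller: ControllerParams, n: int, dt: float):
    torque = _noise_torque(rng, n, dt, controller.noise_gain)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if controller.tremor_amplitude > 0:
        t = np.arange(n) * dt
        torque = torque + controller.tremor_amplitude * np.sin(
            2.0 * np.pi * controller.tremor_freq * t + phase
        )
    return torque


@dataclass
class StanceResult:
    position: AngularSeries
    velocity: AngularSeries
    fell: bool


def _run(profile, config, controller, duration, sample_rate, seed, upright,
         theta0_deg, settle, ext_torque_fn=None):
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    s_eff, inertia = _plant(profile, config, upright)
    rate_int = sample_rate * OVERSAMPLE
    dt = 1.0 / rate_int
    total = duration + settle
    n = int(round(total * rate_int)) + 1
    rng = np.random.default_rng(seed)
    torque = _internal_torque(rng, controller, n, dt)
    if ext_torque_fn is not None:
        t = np.arange(n) * dt - settle
        torque = torque + ext_torque_fn(t)
    delay_steps = int(round(controller.delay * rate_int))
    theta, omega, fell = _integrate(
        np.deg2rad(theta0_deg), n, dt, inertia, s_eff,
        controller.stiffness_gain, controller.damping_gain, delay_steps,
        torque, np.deg2rad(config.stop_angle),
    )
    start = int(round(settle * rate_int))
    n_out = int(round(duration * sample_rate))
    idx = start + np.arange(n_out) * OVERSAMPLE
    pos = AngularSeries(sample_rate, np.rad2deg(theta[idx]), "position")
    vel = AngularSeries(sample_rate, np.rad2deg(omega[idx]), "velocity")
    return StanceResult(pos, vel, bool(fell))


def simulate_quiet_stance(
    profile: SubjectProfile,
    config: DeviceConfig,
    controller: ControllerParams,
    duration: float,
    sample_rate: float = 100.0,
    seed: int | np.random.SeedSequence | None = 0,
    *,
    upright: bool = False,
    initial_lean: float | None = None,
    settle: float = 0.0,
) -> StanceResult:
    """Simulate an unperturbed stance trial.

    Parameters
    ----------
    duration : recorded trial length, s.
    sample_rate : output rate, Hz (internal integration runs 10x faster).
    upright : if True the plant is the standing body (S = m·g·h); otherwise
        the weighted device pendulum.
    initial_lean : starting lean in degrees; defaults to the device's
        initial positioning (``config.initial_lean``).
    settle : extra seconds simulated and discarded before recording starts,
        emulating the experimenter handing over control of the device.

    Returns
    -------
    StanceResult with position (deg) and velocity (deg/s) series at
    ``sample_rate`` and a ``fell`` flag set if a mechanical stop was hit
    at any point of the simulation.
    """
    theta0 = config.initial_lean if initial_lean is None else initial_lean
    return _run(profile, config, controller, duration, sample_rate, seed,
                upright, theta0, settle)


@dataclass
class PerturbationTrial:
    position: AngularSeries
    velocity: AngularSeries
    force: ForceTrace
    fell: bool
    directions: list[str]
    onset_times: np.ndarray  # s, ground truth


def _add_half_sine(out: np.ndarray, t0: float, rate: float, onset: float,
                   duration: float, amplitude: float) -> None:
    """Add a half-sine pulse in place, touching only the pulse's samples.

    ``t0`` is the time of sample 0; samples are uniform at ``rate``.
    """
    i0 = max(0, int(np.ceil((onset - t0) * rate)))
    i1 = min(len(out), int(np.floor((onset + duration - t0) * rate)) + 1)
    if i1 <= i0:
        return
    t = t0 + np.arange(i0, i1) / rate
    out[i0:i1] += amplitude * np.sin(np.pi * (t - onset) / duration)


def simulate_perturbation_trial(
    profile: SubjectProfile,
    config: DeviceConfig,
    controller: ControllerParams,
    schedule: PerturbationSchedule,
    sample_rate: float = 125.0,
    seed: int | np.random.SeedSequence | None = 0,
    *,
    upright: bool = False,
    force_rate: float = 1000.0,
    force_noise_sd: float = 0.05,
    settle: float = 0.0,
) -> PerturbationTrial:
    """Simulate a perturbed stance trial with a transducer force trace.

    Half-sine force pulses are applied at scheduled times in the
    anterior-posterior plane; backward catch events are negated.  The pulse
    acts on the pendulum as an external torque (force x lever arm, the
    pendulum COM height for the device or the body COM height upright).
    The returned ForceTrace is sampled at ``force_rate`` with additive
    Gaussian baseline noise and carries the ground-truth onset indices.

    With ``n_events == 0`` the trial is bit-identical to
    :func:`simulate_quiet_stance` over the same duration and seed.
    """
    rng = np.random.default_rng(seed)
    n_ev = schedule.n_events
    lo, hi = schedule.inter_event_interval_range
    if n_ev > 0:
        intervals = rng.uniform(lo, hi, size=n_ev - 1) if n_ev > 1 else np.empty(0)
        onsets = schedule.lead_in + np.concatenate([[0.0], np.cumsum(intervals)])
        n_back = int(round(schedule.catch_fraction * n_ev))
        back_idx = rng.permutation(n_ev)[:n_back]
        directions = ["forward"] * n_ev
        for b in back_idx:
            directions[b] = "backward"
        peaks = schedule.pulse_peak + (
            schedule.peak_sd * rng.standard_normal(n_ev) if schedule.peak_sd > 0
            else np.zeros(n_ev)
        )
        peaks = np.maximum(peaks, 0.2 * schedule.pulse_peak)
        if np.any(np.diff(onsets) <= schedule.pulse_duration):
            raise ValueError("overlapping perturbation pulses in schedule")
        duration = onsets[-1] + schedule.pulse_duration + schedule.tail
    else:
        onsets = np.empty(0)
        directions = []
        peaks = np.empty(0)
        duration = schedule.lead_in + schedule.tail

    lever = profile.com_height if upright else config.pendulum_com_height
    signs = np.array([1.0 if d == "forward" else -1.0 for d in directions])

    def ext_torque(t: np.ndarray) -> np.ndarray:
        tq = np.zeros_like(t)
        rate = 1.0 / (t[1] - t[0])
        for onset, peak, sign in zip(onsets, peaks, signs):
            _add_half_sine(tq, t[0], rate, onset, schedule.pulse_duration,
                           sign * lever * peak)
        return tq

    # consume the remaining stream exactly as the quiet-stance path does
    child = rng.spawn(1)[0] if n_ev > 0 else rng
    res = _run(profile, config, controller, duration, sample_rate,
               rng if n_ev == 0 else child, upright,
               config.initial_lean, settle, ext_torque_fn=ext_torque)

    n_f = int(round(duration * force_rate))
    force = np.zeros(n_f)
    for onset, peak, sign in zip(onsets, peaks, signs):
        _add_half_sine(force, 0.0, force_rate, onset, schedule.pulse_duration,
                       sign * peak)
    if force_noise_sd > 0:
        # drawn after the dynamics consumed its part of the stream, so the
        # quiet-stance identity for n_events == 0 is preserved
        force_rng = np.random.default_rng(int(rng.integers(2**31)))
        force = force + force_noise_sd * force_rng.standard_normal(n_f)
    true_onsets = np.round(onsets * force_rate).astype(int)
    trace = ForceTrace(force_rate, force, true_onsets)
    return PerturbationTrial(res.position, res.velocity, trace, res.fell,
                             directions, onsets)
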