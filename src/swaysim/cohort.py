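"""Synthetic study cohorts: subjects, trials and on-disk datasets.

A cohort emulates one arm of the balance-simulator protocol: a group of
"PD-like" participants and a control group, each performing either quiet
stance (static designs: two eyes-closed trials per subject, angular
velocity recorded at 100 Hz, as with a trunk-mounted angular velocity
sensor) or perturbed stance (dynamic designs: one trial per subject with a
schedule of manual half-sine pushes, sagittal marker trajectories at
125 Hz and a 1 kHz transducer force trace).

The PD-like group differs from controls through its controller: doubled
torque-noise gain, a 40 ms longer feedback delay and a small 4-7 Hz tremor
component.  These differences produce larger quiet-stance sway and slower
perturbation responses, the direction of effect the analysis pipeline is
expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .markers import GapSpec, default_chain, synthesize_markers
from .simulator import (
    device_stiffness,
    load_stiffness,
    simulate_perturbation_trial,
    simulate_quiet_stance,
)
from .types import (
    AngularSeries,
    ControllerParams,
    DeviceConfig,
    ForceTrace,
    MarkerSet,
    PerturbationSchedule,
    SubjectProfile,
)

__all__ = [
    "GroupParams",
    "default_group_params",
    "TrialData",
    "CohortData",
    "simulate_cohort",
    "DESIGNS",
]

DESIGNS = ("static_real", "static_sim", "dyn_real", "dyn_sim")

#: trial design constants of the emulated protocol
STATIC_TRIALS = 2
STATIC_DURATION_S = 82.0  # clipped to 80 s downstream
STATIC_RATE_HZ = 100.0
DYNAMIC_RATE_HZ = 125.0
SETTLE_S = 20.0
MARKER_NOISE_SD_M = 0.0005
N_RANDOM_GAPS = 2
GAP_RANGE_MS = (8.0, 32.0)


@dataclass(frozen=True)
class GroupParams:
    """Group-level controller parameterisation, normalised to the plant.

    ``stiffness_ratio`` scales the proportional gain relative to the
    toppling stiffness of the condition's plant (K = ratio * S_eff), so a
    subject's controller is stable regardless of mass; ``damping_zeta``
    sets B as a damping ratio of the net linearised stiffness.
    """

    stiffness_ratio: float = 1.3
    damping_zeta: float = 1.2
    delay: float = 0.15  # s
    noise_gain: float = 1.0  # N·m
    tremor_amplitude: float = 0.0  # N·m
    tremor_freq_range: tuple[float, float] = (4.0, 7.0)

    def __post_init__(self) -> None:
        if self.stiffness_ratio <= 1.0:
            raise ValueError("stiffness_ratio must exceed 1 (stabilising gain)")
        if self.damping_zeta <= 0:
            raise ValueError("damping_zeta must be positive")


def default_group_params(group: str) -> GroupParams:
    """The study conditions: PD-like = doubled noise, +40 ms delay, tremor."""
    if group == "PD":
        return GroupParams(noise_gain=4.0, delay=0.19, tremor_amplitude=0.5)
    if group == "control":
        return GroupParams(noise_gain=2.0, delay=0.15, tremor_amplitude=0.0)
    raise ValueError(f"unknown group {group!r}")


def controller_for(
    profile: SubjectProfile,
    config: DeviceConfig,
    params: GroupParams,
    upright: bool,
    rng: np.random.Generator,
) -> ControllerParams:
    """Instantiate absolute controller gains for one subject and plant."""
    if upright:
        s_eff = load_stiffness(profile.mass, profile.com_height)
        inertia = profile.mass * profile.com_height**2
    else:
        s_eff = device_stiffness(profile, config)
        inertia = s_eff * config.pendulum_com_height / 9.81
    k = params.stiffness_ratio * s_eff
    b = 2.0 * params.damping_zeta * math.sqrt((k - s_eff) * inertia)
    freq = float(rng.uniform(*params.tremor_freq_range))
    return ControllerParams(
        stiffness_gain=k, damping_gain=b, delay=params.delay,
        noise_gain=params.noise_gain,
        tremor_amplitude=params.tremor_amplitude, tremor_freq=freq,
    )


@dataclass
class TrialData:
    subject_id: str
    group: str
    condition: str
    vision: str
    trial_index: int
    angular: AngularSeries  # velocity (static) or marker-free position
    velocity: AngularSeries | None = None
    markers: MarkerSet | None = None
    force: ForceTrace | None = None
    fell: bool = False


@dataclass
class CohortData:
    design: str
    subjects: list[SubjectProfile]
    trials: list[TrialData]
    device: DeviceConfig
    schedule: PerturbationSchedule | None = None
    params: dict[str, GroupParams] = field(default_factory=dict)


def _make_subject(rng: np.random.Generator, group: str, idx: int) -> SubjectProfile:
    height = float(np.clip(rng.normal(1.70, 0.08), 1.45, 1.95))
    mass = float(np.clip(rng.normal(72.0, 10.0), 45.0, 110.0))
    age = float(np.clip(rng.normal(68.0, 5.0), 50.0, 85.0))
    sex = "F" if rng.random() < 0.5 else "M"
    return SubjectProfile(
        id=f"{'pd' if group == 'PD' else 'ct'}{idx:03d}",
        group=group, mass=mass, height=height,
        com_height=0.55 * height, sex=sex, age=age,
    )


def simulate_cohort(
    n_pd: int,
    n_control: int,
    design: str,
    params_pd: GroupParams | None = None,
    params_control: GroupParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    device: DeviceConfig | None = None,
    schedule: PerturbationSchedule | None = None,
    static_duration: float = STATIC_DURATION_S,
) -> CohortData:
    """Simulate a full cohort in memory.

    Deterministic for a given (parameters, seed): per-subject random streams
    are spawned from one seed sequence, so cohorts of different sizes share
    no accidental coupling.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")
    if n_pd < 1 or n_control < 1:
        raise ValueError("need at least one subject per group")
    params = {
        "PD": params_pd or default_group_params("PD"),
        "control": params_control or default_group_params("control"),
    }
    upright = design.endswith("real")
    dynamic = design.startswith("dyn")
    device = device or DeviceConfig()
    if dynamic:
        schedule = schedule or PerturbationSchedule(peak_sd=1.0)
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else seed.entropy)
    groups = ["PD"] * n_pd + ["control"] * n_control
    children = ss.spawn(len(groups))
    subjects: list[SubjectProfile] = []
    trials: list[TrialData] = []
    for (group, child) in zip(groups, children):
        rng = np.random.default_rng(child)
        idx = len([s for s in subjects if s.group == group])
        prof = _make_subject(rng, group, idx)
        subjects.append(prof)
        ctrl = controller_for(prof, device, params[group], upright, rng)
        if not dynamic:
            for t in range(STATIC_TRIALS):
                res = simulate_quiet_stance(
                    prof, device, ctrl, static_duration, STATIC_RATE_HZ,
                    seed=rng.spawn(1)[0], upright=upright, settle=SETTLE_S,
                )
                trials.append(TrialData(
                    prof.id, group, design, "EC", t, res.velocity,
                    velocity=res.velocity, fell=res.fell,
                ))
        else:
            trial_rng_seed = rng.spawn(1)[0]
            res = simulate_perturbation_trial(
                prof, device, ctrl, schedule, DYNAMIC_RATE_HZ,
                seed=trial_rng_seed, upright=upright, settle=SETTLE_S,
            )
            chain = default_chain(prof.height)
            gaps = [GapSpec(duration_ms=float(rng.uniform(*GAP_RANGE_MS)))
                    for _ in range(N_RANDOM_GAPS)]
            mk = synthesize_markers(
                res.position, chain, noise_sd=MARKER_NOISE_SD_M,
                gap_spec=gaps, seed=rng.spawn(1)[0],
            )
            trials.append(TrialData(
                prof.id, group, design, "EC", 0, res.position,
                velocity=res.velocity, markers=mk, force=res.force,
                fell=res.fell,
            ))
    return CohortData(design, subjects, trials, device,
                      schedule if dynamic else None, params)
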