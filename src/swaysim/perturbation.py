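"""Dynamic-balance analysis: perturbation onsets, impulses, exclusion rules
and peak / time-to-peak response metrics.

Onset detection follows the transducer-threshold protocol: candidate events
are found by a robust coarse threshold, then each onset is refined to the
first sample exceeding the local baseline mean + 4 SD, with the baseline
statistics taken from the 500 ms immediately preceding the candidate.  The
perturbation impulse is the area under the baseline-corrected force from
onset to its first return to baseline.  Events whose impulse falls outside
the pooled mean ± 1 SD (over all forward events of a condition, across
participants) are excluded, and a participant enters the dynamic analysis
only with at least five surviving forward perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import AngularSeries, ForceTrace

__all__ = [
    "PerturbationEvent",
    "ResponseMetrics",
    "InclusionDecision",
    "detect_onsets",
    "impulse",
    "exclude_outliers",
    "enforce_min_events",
    "response_metrics",
]


@dataclass
class PerturbationEvent:
    onset_index: int
    onset_time: float  # s
    direction: str  # "forward" | "backward"
    baseline_mean: float  # N, local pre-onset baseline
    baseline_sd: float  # N
    peak_force: float  # N, signed deviation extremum
    impulse: float = float("nan")  # N·s, magnitude of the pulse area
    excluded: bool = False
    reason: str = ""


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [(int(r[0]), int(r[-1])) for r in np.split(idx, splits)]


def detect_onsets(
    f: ForceTrace,
    baseline_ms: float = 500.0,
    k_sd: float = 4.0,
    coarse_k: float = 6.0,
    refractory_s: float = 1.0,
    peak_window_s: float = 0.5,
) -> list[PerturbationEvent]:
    """Detect perturbation pulses on a load-transducer trace.

    Coarse candidates are excursions of |force - robust baseline| beyond
    ``coarse_k`` robust SDs (median / scaled MAD over the whole trace) with
    a refractory period; each candidate is then refined to the first sample
    whose deviation from the local 500 ms pre-candidate baseline mean
    exceeds ``k_sd`` local SDs.  Candidates without a full preceding
    baseline window are skipped.
    """
    v = f.values
    n = len(v)
    nb = int(round(baseline_ms / 1000.0 * f.sample_rate))
    med = float(np.median(v))
    sd_rob = 1.4826 * float(np.median(np.abs(v - med)))
    dev = np.abs(v - med)
    coarse = dev > coarse_k * sd_rob if sd_rob > 0 else dev > 0
    events: list[PerturbationEvent] = []
    refractory = int(round(refractory_s * f.sample_rate))
    npk = int(round(peak_window_s * f.sample_rate))
    last = -refractory - 1
    for start, _stop in _runs_above(coarse):
        if start - last <= refractory:
            continue
        last = start
        if start < nb:
            continue  # insufficient preceding baseline: skipped
        base = v[start - nb:start]
        mu, sd = float(base.mean()), float(base.std())
        thresh = k_sd * sd
        # walk back from the coarse crossing to the first suprathreshold sample
        onset = start
        while onset > start - nb and abs(v[onset - 1] - mu) > thresh:
            onset -= 1
        seg = v[onset:min(n, onset + npk)] - mu
        peak = float(seg[np.argmax(np.abs(seg))]) if seg.size else 0.0
        direction = "forward" if peak >= 0 else "backward"
        events.append(PerturbationEvent(
            onset_index=int(onset),
            onset_time=onset / f.sample_rate,
            direction=direction,
            baseline_mean=mu,
            baseline_sd=sd,
            peak_force=peak,
        ))
    return events


def impulse(f: ForceTrace, event: PerturbationEvent) -> PerturbationEvent:
    """Perturbation impulse: area from onset to the first baseline crossing.

    The local baseline mean is subtracted, the deviation is followed from
    the onset until it first changes sign (returns to baseline), and the
    trapezoidal area over that interval is recorded as a magnitude (N·s).
    If the force never returns to baseline before the trace ends the event
    is flagged unbounded.
    """
    sign = 1.0 if event.direction == "forward" else -1.0
    g = sign * (f.values[event.onset_index:] - event.baseline_mean)
    # first index after the pulse rise where the deviation is back at baseline
    above = g > 0
    if above.size == 0 or not above[0]:
        # onset sits at baseline: step to the first suprathreshold sample
        nz = np.flatnonzero(above)
        if nz.size == 0:
            return replace(event, impulse=float("nan"), excluded=True,
                           reason="no pulse after onset")
        start_rel = int(nz[0])
    else:
        start_rel = 0
    below = np.flatnonzero(~above[start_rel:])
    if below.size == 0:
        return replace(event, impulse=float("nan"), excluded=True,
                       reason="no return to baseline before trace end")
    end_rel = start_rel + int(below[0])
    area = float(np.trapezoid(g[:end_rel + 1], dx=1.0 / f.sample_rate))
    return replace(event, impulse=area)


def exclude_outliers(
    events: list[PerturbationEvent],
    measure: str = "impulse",
) -> list[PerturbationEvent]:
    """Flag events outside the pooled mean ± 1 SD of the perturbation force.

    The pool is every unexcluded forward event passed in (the caller pools
    all participants of a condition).  ``measure`` selects the force
    quantity: ``"impulse"`` (default) or ``"peak_force"``.
    """
    if measure not in ("impulse", "peak_force"):
        raise ValueError(f"unknown exclusion measure {measure!r}")
    pool = [e for e in events
            if e.direction == "forward" and not e.excluded
            and np.isfinite(getattr(e, measure))]
    if len(pool) < 2:
        return events
    pool_ids = {id(e) for e in pool}
    vals = np.array([getattr(e, measure) for e in pool])
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    out: list[PerturbationEvent] = []
    for e in events:
        if id(e) in pool_ids and sd > 0 and \
                not mu - sd <= getattr(e, measure) <= mu + sd:
            e = replace(e, excluded=True,
                        reason=f"{measure} outside pooled mean +/- 1 SD")
        out.append(e)
    return out


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    n_forward_used: int
    reason: str = ""


def enforce_min_events(events: list[PerturbationEvent],
                       min_n: int = 5) -> InclusionDecision:
    """Minimum-perturbation rule for entering the dynamic analysis."""
    n = sum(1 for e in events if e.direction == "forward" and not e.excluded)
    if n == 0:
        return InclusionDecision(False, 0, "no detected perturbations")
    if n < min_n:
        return InclusionDecision(False, n,
                                 f"only {n} surviving forward perturbations "
                                 f"(minimum {min_n})")
    return InclusionDecision(True, n)


@dataclass(frozen=True)
class ResponseMetrics:
    peak_disp: float  # deg
    ttp_disp: float  # s
    peak_vel: float  # deg/s
    ttp_vel: float  # s
    n_events_used: int
    dropped: tuple[str, ...] = field(default_factory=tuple)


def response_metrics(
    theta: AngularSeries,
    vel: AngularSeries,
    events: list[PerturbationEvent],
    window_s: float = 2.0,
) -> ResponseMetrics:
    """Peak and time-to-peak angular COM displacement and velocity.

    For each surviving forward event, displacement is re-referenced to its
    value at onset and the peak forward excursion within the response
    window (onset to the earlier of the next onset or ``window_s``) is
    taken, along with its latency; velocity is treated the same without
    re-referencing.  Per-subject metrics are the means over used events.
    Events whose window is truncated by the end of the trace are dropped.
    """
    if theta.sample_rate != vel.sample_rate:
        raise ValueError("position and velocity series must share a sample rate")
    fs = theta.sample_rate
    onsets = sorted(e.onset_time for e in events)
    use = [e for e in events if e.direction == "forward" and not e.excluded]
    peaks_d, ttps_d, peaks_v, ttps_v = [], [], [], []
    dropped: list[str] = []
    n = len(theta.values)
    for e in use:
        later = [t for t in onsets if t > e.onset_time]
        t_end = min(e.onset_time + window_s, later[0] if later else np.inf)
        i0 = int(round(e.onset_time * fs))
        i1 = int(round(t_end * fs))
        if i1 > n or i0 >= n:
            dropped.append(f"event at {e.onset_time:.3f} s: window truncated "
                           "by trace end")
            continue
        disp = theta.values[i0:i1] - theta.values[i0]
        v = vel.values[i0:i1]
        k_d = int(np.argmax(disp))
        k_v = int(np.argmax(v))
        peaks_d.append(disp[k_d])
        ttps_d.append(k_d / fs)
        peaks_v.append(v[k_v])
        ttps_v.append(k_v / fs)
    if not peaks_d:
        return ResponseMetrics(float("nan"), float("nan"), float("nan"),
                               float("nan"), 0, tuple(dropped))
    return ResponseMetrics(
        peak_disp=float(np.mean(peaks_d)),
        ttp_disp=float(np.mean(ttps_d)),
        peak_vel=float(np.mean(peaks_v)),
        ttp_vel=float(np.mean(ttps_v)),
        n_events_used=len(peaks_d),
        dropped=tuple(dropped),
    )
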