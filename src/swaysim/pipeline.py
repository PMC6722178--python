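"""End-to-end composition: generate -> condition -> metrics -> statistics.

The pipeline has two measurement chains mirroring the two instruments of
the protocol:

* static trials (angular velocity sensor, 100 Hz): trapezoidal integration
  to displacement, 3.5 Hz zero-phase low-pass, 80 s clip, demeaning, then
  RMS and MPF, averaged over a subject's trials;
* dynamic trials (motion capture at 125 Hz + 1 kHz force transducer):
  cubic-spline gap interpolation, 5 Hz zero-phase low-pass of the marker
  coordinates, four-segment total-body COM, inverse-tangent angular COM,
  onset detection on the force trace, impulse computation, pooled ±1 SD
  exclusion, the five-event minimum, and peak / time-to-peak response
  metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import metrics as met
from . import perturbation as pert
from . import stats as gstats
from .cohort import CohortData, GroupParams, TrialData, simulate_cohort
from .io import (
    RunConfig,
    read_angular,
    read_force,
    read_manifest,
    read_markers,
    read_subjects,
    write_angular,
    write_force,
    write_manifest,
    write_markers,
    write_subjects,
)
from .types import AngularSeries, DeviceConfig, PerturbationSchedule

__all__ = [
    "static_trial_metrics",
    "dynamic_trial_kinematics",
    "AnalysisResult",
    "analyze_cohort",
    "generate_dataset",
    "load_dataset",
    "run_report",
]


def static_trial_metrics(vel: AngularSeries, config: RunConfig) -> tuple[float, float]:
    """RMS (deg) and MPF (Hz) of one static trial from its velocity series."""
    pos = kin.integrate_velocity(vel)
    pos = kin.filter_series(pos, config.static_cutoff_hz, config.filter_order)
    pos = kin.clip_and_demean(pos, config.clip_s)
    return (
        met.rms(pos),
        met.mpf(pos, band=(config.mpf_band_lo_hz, config.static_cutoff_hz),
                segment_s=config.welch_segment_s),
    )


def dynamic_trial_kinematics(trial: TrialData, anthro, config: RunConfig):
    """Angular COM position and velocity of one dynamic trial.

    Gap interpolation precedes filtering; the angular velocity is obtained
    by central differences of the filtered angular COM displacement.
    """
    m, gap_reports = kin.interpolate_gaps(trial.markers, config.max_gap_ms)
    for name in m.missing:
        if m.missing[name].any():
            # long/boundary gaps survive interpolation; bridge them linearly
            # for filtering but record the report
            xy = m.markers[name]
            for col in range(2):
                v = xy[:, col]
                bad = ~np.isfinite(v)
                v[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad),
                                   v[~bad])
            m.missing[name][:] = False
    m = kin.filter_markers(m, config.dynamic_cutoff_hz, config.filter_order)
    com = kin.total_body_com(m, anthro)
    theta = kin.angular_com(com)
    vel = AngularSeries(theta.sample_rate,
                        np.gradient(theta.values, 1.0 / theta.sample_rate),
                        "velocity")
    return theta, vel, gap_reports


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclusions: list[str] = field(default_factory=list)


def analyze_cohort(cohort: CohortData, config: RunConfig | None = None,
                   anthro=None) -> AnalysisResult:
    """Run the full analysis over a cohort's trials.

    Static designs produce one row per subject with trial-averaged RMS/MPF;
    dynamic designs produce per-subject response metrics after pooled
    exclusion and the minimum-event rule, plus a per-event table.  Every
    exclusion is recorded with its reason.
    """
    config = config or RunConfig()
    dynamic = cohort.design.startswith("dyn")
    exclusions: list[str] = []
    if not dynamic:
        rows = []
        for t in cohort.trials:
            vel = t.velocity if t.velocity is not None else t.angular
            r, f = static_trial_metrics(vel, config)
            rows.append({"subject_id": t.subject_id, "group": t.group,
                         "condition": t.condition, "vision": t.vision,
                         "rms_deg": r, "mpf_hz": f})
        per_trial = pd.DataFrame(rows)
        return AnalysisResult(met.average_trials(per_trial), exclusions=exclusions)

    anthro = anthro or kin.default_anthropometry()
    per_subject: dict[str, dict] = {}
    all_events: list[tuple[str, pert.PerturbationEvent]] = []
    for t in cohort.trials:
        theta, vel, gap_reports = dynamic_trial_kinematics(t, anthro, config)
        events = pert.detect_onsets(
            t.force, config.onset_baseline_ms, config.onset_k_sd,
            config.onset_coarse_k)
        events = [pert.impulse(t.force, e) for e in events]
        for g in gap_reports:
            if not g.filled:
                exclusions.append(
                    f"{t.subject_id}: gap on {g.marker} at sample "
                    f"{g.start_index} left unfilled ({g.reason})")
        per_subject[t.subject_id] = {
            "trial": t, "theta": theta, "vel": vel, "events": events}
        all_events.extend((t.subject_id, e) for e in events)

    # pooled +/- 1 SD exclusion across all participants of the condition
    pooled = [e for _, e in all_events]
    pooled = pert.exclude_outliers(pooled, config.exclusion_measure)
    for (sid, _), e in zip(all_events, pooled):
        if e.excluded and e.reason:
            exclusions.append(f"{sid}: event at {e.onset_time:.2f} s excluded "
                              f"({e.reason})")
    by_subject: dict[str, list[pert.PerturbationEvent]] = {}
    for (sid, _), e in zip(all_events, pooled):
        by_subject.setdefault(sid, []).append(e)

    rows, event_rows = [], []
    for sid, entry in per_subject.items():
        t = entry["trial"]
        events = by_subject.get(sid, [])
        for i, e in enumerate(events):
            event_rows.append({
                "subject_id": sid, "condition": t.condition, "event_index": i,
                "onset_time_s": e.onset_time, "direction": e.direction,
                "impulse_Ns": e.impulse, "peak_force_N": e.peak_force,
                "excluded": e.excluded, "reason": e.reason,
            })
        decision = pert.enforce_min_events(events, config.min_events)
        if not decision.included:
            exclusions.append(f"{sid}: dropped from dynamic analysis "
                              f"({decision.reason})")
            continue
        rm = pert.response_metrics(entry["theta"], entry["vel"], events,
                                   config.response_window_s)
        for msg in rm.dropped:
            exclusions.append(f"{sid}: {msg}")
        rows.append({
            "subject_id": sid, "group": t.group, "condition": t.condition,
            "vision": t.vision, "peak_disp_deg": rm.peak_disp,
            "ttp_disp_s": rm.ttp_disp, "peak_vel_degs": rm.peak_vel,
            "ttp_vel_s": rm.ttp_vel, "n_events_used": rm.n_events_used,
        })
    return AnalysisResult(pd.DataFrame(rows), pd.DataFrame(event_rows),
                          exclusions)


def _cohort_from_config(config: RunConfig) -> CohortData:
    device = DeviceConfig(**config.device) if config.device else None
    schedule = (PerturbationSchedule(**config.schedule) if config.schedule
                else None)
    p_pd = (GroupParams(**config.controller_pd) if config.controller_pd
            else None)
    p_ct = (GroupParams(**config.controller_control)
            if config.controller_control else None)
    return simulate_cohort(config.n_pd, config.n_control, config.design,
                           p_pd, p_ct, seed=config.seed, device=device,
                           schedule=schedule)


def generate_dataset(config: RunConfig, out_dir, overwrite: bool = False) -> Path:
    """Simulate a cohort and write the on-disk dataset.

    Writes one series file per trial (plus a force file for dynamic
    trials), the manifest, the subject table and a provenance file echoing
    the fully resolved configuration and seed.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty "
                              "(pass overwrite to proceed)")
    cohort = _cohort_from_config(config)
    dynamic = cohort.design.startswith("dyn")
    rows = []
    for t in cohort.trials:
        stem = f"{t.subject_id}_{t.condition}_{t.vision}_t{t.trial_index}"
        if dynamic:
            fname = f"{stem}_markers.csv"
            write_markers(out / fname, t.markers)
            force_name = f"{stem}_force.csv"
            write_force(out / force_name, t.force)
        else:
            fname = f"{stem}.csv"
            write_angular(out / fname, t.velocity)
            force_name = ""
        rows.append({"subject_id": t.subject_id, "group": t.group,
                     "condition": t.condition, "vision": t.vision,
                     "trial_index": t.trial_index, "file": fname,
                     "force_file": force_name})
    manifest = out / "manifest.tsv"
    write_manifest(manifest, rows)
    write_subjects(out / "subjects.tsv", cohort.subjects)
    (out / "provenance.json").write_text(config.to_json() + "\n")
    return manifest


def load_dataset(manifest_path, config: RunConfig | None = None) -> CohortData:
    """Reconstruct a cohort from an on-disk dataset for analysis."""
    config = config or RunConfig()
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = read_manifest(manifest_path)
    subjects_df = read_subjects(root / "subjects.tsv")
    conditions = df["condition"].unique()
    if len(conditions) != 1:
        raise ValueError("manifest mixes conditions; analyze one at a time")
    design = str(conditions[0])
    dynamic = design.startswith("dyn")
    trials = []
    for _, row in df.iterrows():
        path = root / row["file"]
        if not path.exists():
            raise FileNotFoundError(f"trial file missing: {path}")
        if dynamic:
            markers = read_markers(path)
            force = read_force(root / row["force_file"])
            theta = AngularSeries(markers.sample_rate,
                                  np.zeros(markers.n_samples), "position")
            trials.append(TrialData(row["subject_id"], row["group"], design,
                                    row["vision"], int(row["trial_index"]),
                                    theta, markers=markers, force=force))
        else:
            vel = read_angular(path)
            trials.append(TrialData(row["subject_id"], row["group"], design,
                                    row["vision"], int(row["trial_index"]),
                                    vel, velocity=vel))
    profiles = []  # raw table retained separately for the baseline stage
    return CohortData(design, profiles, trials, DeviceConfig()), subjects_df


STATIC_METRICS = ["rms_deg", "mpf_hz"]
DYNAMIC_METRICS = ["peak_disp_deg", "ttp_disp_s", "peak_vel_degs", "ttp_vel_s"]


def _result_row(condition: str, metric: str, res: gstats.TestResult) -> dict:
    df_txt = (f"{res.df[0]:g},{res.df[1]:g}" if isinstance(res.df, tuple)
              else ("" if res.df is None else f"{res.df:g}"))
    return {
        "condition": condition, "metric": metric, "test": res.test_name,
        "statistic": res.statistic, "df": df_txt, "p_value": res.p_value,
        "effect_size": res.effect_size, "effect_label": res.effect_label,
        "transform": res.transform_applied, "notes": res.notes,
        **{f"summary_{k}": v for k, v in res.group_summaries.items()},
    }


def run_report(metrics: pd.DataFrame, subjects: pd.DataFrame | None,
               config: RunConfig | None = None) -> tuple[str, pd.DataFrame]:
    """Group statistics over a metrics table, plus a plain-text report.

    Static metrics with two vision levels go through the 2x2 mixed ANOVA
    (log-gated); single-vision static and all dynamic metrics go through
    the normality-gated two-group route.  The resolved configuration and
    every gating decision are embedded in the report text.
    """
    config = config or RunConfig()
    if metrics.empty:
        raise ValueError("empty metrics table")
    lines: list[str] = ["# swaysim statistics report", ""]
    results: list[dict] = []
    groups = sorted(metrics["group"].unique())
    if len(groups) < 2:
        lines.append("WARNING: single group; descriptive summaries only.")
        for cond, sub in metrics.groupby("condition"):
            lines.append(f"\n## {cond}\n")
            lines.append(sub.describe().to_string())
        return "\n".join(lines), pd.DataFrame(results)

    for cond, sub in metrics.groupby("condition"):
        lines.append(f"\n## Condition: {cond}\n")
        metric_cols = [c for c in (STATIC_METRICS + DYNAMIC_METRICS)
                       if c in sub.columns]
        two_vision = sub["vision"].nunique() == 2 if "vision" in sub else False
        for col in metric_cols:
            if two_vision:
                cells = {f"{g}/{v}": grp[col].to_numpy(float)
                         for (g, v), grp in sub.groupby(["group", "vision"])}
                gate = gstats.normality_gate(cells, config.alpha)
                vals = sub.copy()
                if gate.route == "log_transform":
                    vals[col] = np.log(vals[col])
                lines.append(f"{col}: normality route = {gate.route}"
                             + (f" ({gate.reason})" if gate.reason else ""))
                if gate.route == "nonparametric":
                    per_subj = vals.groupby(["subject_id", "group"],
                                            as_index=False)[col].mean()
                    x = per_subj.loc[per_subj["group"] == groups[0], col]
                    y = per_subj.loc[per_subj["group"] == groups[1], col]
                    res = gstats.mann_whitney(x.to_numpy(), y.to_numpy())
                    results.append(_result_row(cond, col, res))
                    lines.append(f"  {res.test_name}: U={res.statistic:g} "
                                 f"p={res.p_value:.4f}")
                    continue
                anova = gstats.mixed_anova_2x2(vals, dv=col)
                for effect, res in anova.items():
                    res = dataclasses.replace(
                        res, transform_applied=gate.route == "log_transform")
                    results.append(_result_row(cond, f"{col}:{effect}", res))
                    lines.append(
                        f"  {res.test_name}: F={res.statistic:.3f} "
                        f"df=({res.df[0]:g},{res.df[1]:g}) p={res.p_value:.4f} "
                        f"partial_eta_sq={res.effect_size:.3f}")
            else:
                x = sub.loc[sub["group"] == groups[0], col].to_numpy(float)
                y = sub.loc[sub["group"] == groups[1], col].to_numpy(float)
                res = gstats.two_group_test(x, y, alpha=config.alpha)
                results.append(_result_row(cond, col, res))
                if res.test_name == "Mann-Whitney":
                    lines.append(
                        f"{col}: {res.test_name} U={res.statistic:g} "
                        f"z={res.group_summaries['z']:.3f} p={res.p_value:.4f} "
                        f"eta_sq={res.effect_size:.3f} "
                        f"medians={res.group_summaries['median_1']:.3f}/"
                        f"{res.group_summaries['median_2']:.3f}")
                else:
                    lines.append(
                        f"{col}: {res.test_name} t={res.statistic:.3f} "
                        f"df={res.df:.1f} p={res.p_value:.4f} "
                        f"d={res.effect_size:.3f}"
                        + (" [log]" if res.transform_applied else ""))

    if subjects is not None and not subjects.empty:
        lines.append("\n## Baseline characteristics\n")
        lines.append(gstats.baseline_table(subjects).to_string(index=False))

    lines.append("\n## Resolved configuration\n")
    lines.append(config.to_json())
    return "\n".join(lines), pd.DataFrame(results)
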