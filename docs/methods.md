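# Methods

## The plant: an inverted pendulum in two guises

Both study conditions are modelled as a single-link inverted pendulum
rotating about the ankle axis in the sagittal (anterior-posterior) plane,
with forward lean positive:

```
I·θ̈ = S_eff·sin(θ) − K·θ(t−Δ) − B·θ̇(t−Δ) + τ_noise(t) + τ_tremor(t) + τ_ext(t)
```

* **Upright stance** (`*_real` designs): the plant is the standing body,
  with toppling stiffness `S_eff = m·g·h` (the *load stiffness*, body mass
  `m`, COM height `h`, `g` = 9.81 m/s²) and point-mass inertia
  `I = m·h²`.
* **Simulated stance** (`*_sim` designs): the plant is the supine device's
  balance arm, weighted to `S_eff = fraction · m·g·h` of the participant's
  upright value (default fraction 0.60), with its equivalent point mass at
  the pendulum COM height `h_p` (default 1.0 m), so `I = S_eff·h_p / g`.
  Mechanical stops clamp the excursion at ±17°; hitting a stop sets the
  trial's `fell` flag (the angular velocity is zeroed there, and the
  simulation continues, so a recoverable graze is representable). Each
  trial starts at the device's initial positioning of 3° forward lean.

The pendulum's COM height and stop/lean angles are device properties; the
body's COM height is estimated as 0.55 × stature when cohorts are drawn.

## The controller: delayed PD torque with shaped noise

Quiet stance is stabilised by a proportional-derivative ankle torque acting
on delayed state, the standard minimal model of sway regulation:
`−K·θ(t−Δ) − B·θ̇(t−Δ)`. Additive torque noise is Gaussian, low-pass
filtered by a first-order stage at 1.5 Hz and rescaled to a target standard
deviation (`noise_gain`, N·m), representing slow exploratory/motor noise;
tremor-affected subjects additionally receive a sinusoidal torque at a
per-subject frequency drawn from 4–7 Hz.

Group parameters are expressed relative to the plant so that every
simulated subject is stable regardless of anthropometry: `K = 1.3·S_eff`
and `B = 2ζ√((K−S_eff)·I)` with damping ratio ζ = 1.2. A numerical
stability scan of the delayed closed loop showed that lightly damped gains
(ζ ≲ 0.7) go unstable at physiological delays of 150–190 ms, which fixed
the heavier default damping. Group defaults:

| parameter | control | PD-like | rationale |
|---|---|---|---|
| noise_gain (N·m) | 2.0 | 4.0 | doubled motor noise produces the larger sway amplitude characteristic of the patient group; yields quiet-stance RMS ≈ 0.3–1.0° |
| delay Δ (ms) | 150 | 190 | physiological long-latency range; the +40 ms slows the perturbation response (longer time-to-peak) |
| tremor (N·m @ 4–7 Hz) | 0 | 0.5 | rest-tremor contamination; largely removed by the 3.5 Hz static filter |

These defaults are the study conditions of the generator; the effect sizes
they imply (group RMS ratio ≈ 2, time-to-peak difference ≈ 0.1 s) are in
the range the paradigm is designed to resolve with ~20 subjects per group.

## Numerical integration

Fixed-step semi-implicit Euler at an internal rate of 10× the output
sample rate (1000 Hz for 100 Hz static trials, 1250 Hz for 125 Hz dynamic
trials). The delay is realised by indexing the stored state history
(θ(t<0) = θ₀, θ̇(t<0) = 0). At these rates halving the step changes
quiet-stance RMS by well under 0.1%. Static trials discard a 20 s settle
period, emulating the experimenter handing over control; trials are 82 s
so that the analysis can clip at 80 s.

## Perturbations

Manual pushes are half-sine force pulses `F(t) = A·sin(πt/d)` (defaults:
peak 12 ± 1 N, duration 0.25 s), applied to the plant as external torque
`F × lever` (pendulum COM height for the device, body COM height upright).
A fraction (default 12%) is delivered backward as catch trials.
Inter-pulse intervals are uniform on 2.5–8.4 s; 12 pulses per trial. The
transducer trace is sampled at 1 kHz with 0.05 N additive baseline noise
and carries ground-truth onset indices used only by the validation tests.
The analytic pulse impulse is `2Ad/π ≈ 1.9 N·s` at the defaults.

## Marker synthesis and the geometry round trip

The five markers of the four-segment model (ankle, foot landmark, knee,
hip, C7) are placed along the body/pendulum axis at Winter-style fractions
of stature (0, 0.077, 0.246, 0.491, 0.779) and the whole rigid chain is
rotated about the ankle by the simulated lean angle. Because the chain is
colinear through the origin, the four-segment COM lies exactly on the
leaning axis, so `angular_com(total_body_com(markers))` recovers the
driving angle to numerical precision in the noise-free case — the
round-trip property the tests assert. Coordinate noise (default 0.5 mm),
optional per-joint wobble, and missing runs (two per dynamic trial, 8–32 ms)
emulate capture imperfections.

The segment table shipped in `swaysim/data/anthropometry.csv` (editable,
overridable) uses both-limb dermal fractions: foot 0.029 / shank 0.093 /
thigh 0.200 / head-arms-trunk 0.678 of body mass, with COM at 0.500 /
0.433 / 0.433 / 0.626 of the proximal-to-distal segment vector.

## Signal conditioning

* Integration of angular velocity: cumulative trapezoid, initial value 0.
* Gap interpolation: not-a-knot cubic splines through a marker's
  non-missing samples fill runs strictly shorter than 40 ms; longer runs
  and boundary runs are reported, never extrapolated. (Inside the dynamic
  pipeline, any surviving long gap is bridged linearly so the zero-phase
  filter can run, and the report records it.)
* Filtering: Butterworth of the stated order (4) and design cutoff
  (3.5 Hz static, 5 Hz dynamic), applied forward-backward (`filtfilt`
  with odd reflection padding of three filter lengths), giving zero phase
  and the squared magnitude response `(1+(f/fc)^(2·order))⁻¹`. No cutoff
  pre-warping is applied: the quoted cutoff is the single-pass design
  cutoff, so the dual-pass −3 dB point is slightly lower.
* Clipping and demeaning: first 80 s retained, arithmetic mean removed
  (clip first, then demean, in that order).
* Order of operations for marker data: interpolate → filter coordinates →
  COM → angular COM, i.e. filtering precedes the COM computation.

## Sway metrics

RMS is `√(mean(x²))` of the demeaned, filtered displacement. MPF is the
power-weighted mean frequency `Σ f·P(f) / Σ P(f)` over 0.05 Hz–cutoff,
with `P` from Welch's averaged periodogram (Hann taper, 20 s segments,
50% overlap) — a variance-reduced estimator standard in posturography.
The 0.05 Hz lower edge excludes residual drift; both edges and the
segment length are configurable. Trial metrics are averaged per
subject × condition × vision with the trial count recorded.

## Perturbation analysis

Onset detection is two-stage: coarse candidates are excursions of
|force − robust baseline| beyond 6 robust SDs (median/MAD over the whole
trace, so the pulses themselves cannot inflate the threshold) with a 1 s
refractory period; each onset is then refined to the first sample whose
deviation from the local baseline (mean of the 500 ms immediately
preceding the candidate) exceeds 4 local SDs. Candidates without a full
baseline window are skipped and logged. Direction comes from the sign of
the subsequent force extremum.

The impulse is the trapezoidal area of the baseline-subtracted force from
onset to its first return to baseline; events that never return before
the trace ends are flagged unbounded. The pooled exclusion flags events
whose impulse lies outside mean ± 1 SD (sample SD, ddof = 1) computed over
all forward events of the condition across participants ("perturbation
force" is read as the impulse, since the area computation immediately
precedes the rule; peak force is available via configuration). Subjects
keep their dynamic data only with ≥ 5 surviving forward events.

Response metrics use a window from each onset to the earlier of the next
onset or 2.0 s (covering the expected 0.7–0.9 s time-to-peak range with
margin). Displacement is re-referenced to its onset value; the peak is
the maximal forward excursion and time-to-peak its latency; velocity
(central differences of the filtered angular COM) is treated the same
without re-referencing. Backward catch events are detected and counted
but excluded from response averaging. Per-subject metrics are means over
used events.

## Statistics

* Normality gating: Shapiro-Wilk per cell at α = 0.05; any non-normal
  cell triggers a log transform and re-test; failure (or non-positive
  values) routes to the nonparametric tests. Every decision is logged in
  the report.
* 2×2 mixed ANOVA: direct split-plot sums of squares (between: group;
  within: vision), F against the appropriate error stratum, partial
  η² = SS_effect/(SS_effect+SS_error). Zero-error strata are reported as
  degenerate rather than silently producing F = 0/0. A pingouin
  cross-check backs the implementation in the test suite.
* Two-group tests: independent t with pooled df, switching to Welch when
  Levene (mean-centred) rejects variance equality (logged); Cohen's d with
  pooled SD, sign = group1 − group2. Mann-Whitney U counts pairs where
  the group-1 value is smaller (U + U' = n₁n₂); z is the tie-corrected
  normal approximation without continuity correction; p is exact by full
  enumeration for pooled n ≤ 12; effect size η² = z²/N.
* Levene and Box M are computed as diagnostics and never gate the
  analysis automatically. No multiple-testing correction is applied
  (single overall α = 0.05), matching the protocol being emulated.
* Baseline table: mean (SE) for continuous fields, "k (pct%)" with
  half-up integer rounding for counts, χ² with continuity correction for
  sex.

## What the generator does and does not emulate

The generator reproduces the mechanical structure of the paradigm
(stiffness scaling, stops, initial lean, pulse forces, marker geometry,
missingness, sampling rates) and the statistical structure of the group
contrast (noise- and delay-driven). It does **not** model multi-segment
upright balance, medial-lateral sway, EMG, visual-condition differences
(vision enters only as a trial label unless configured), anticipatory
postural adjustments, or fatigue/learning across trials. Passing the
paradigm-recovery tests therefore shows that the analysis chain detects
the direction of group effects under the stated model, not that the model
captures every property of real patient data.

## Problem sizes and numerical tolerances

Replicate-cohort validation uses 100 cohorts of 20 + 22 subjects per arm
(82 s static trials, 12-pulse dynamic trials), sizes chosen to estimate
the direction-of-effect rate with a ±4% standard error while keeping a
full run in minutes on one core. Oracle comparisons use 1e-12 for exact
arithmetic identities, 1e-9 for sums-of-squares and geometry identities,
and stated percentage bands for stochastic rates. Degenerate inputs
(zero-SD pools, constant data, empty cells, non-positive log inputs,
boundary gaps) are handled explicitly and logged rather than raising mid
pipeline.

## Known limitations

* The device's true moment of inertia and damping are free parameters of
  the model; the point-mass closure `I = S_eff·h_p/g` is an idealisation.
* The emitted velocity channel is the simulator's state at sample times;
  trapezoidal re-integration reproduces position to discretisation error,
  not bit-exactly.
* MPF is reported in Hz throughout.
* The split-plot ANOVA uses weighted (cell-size) sums of squares; with
  unbalanced groups this is the classical textbook decomposition, which
  can differ from unweighted-means (Type III) variants.
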