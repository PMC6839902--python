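# Methods

This note documents the models, conventions and numerical choices behind
`linc_ephys`: what each stage assumes, which parameters matter and why
their defaults are what they are, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Conventions

Times in seconds; LFP in µV; membrane potential in mV; currents in pA.
Indices are 0-based and windows half-open [start, end). Theta is 5–12 Hz,
delta 1–3 Hz. All thresholds live in `AnalysisConfig`, which hashes into
every output so a result table is traceable to the exact constants that
produced it.

## Multitaper estimation

All spectral quantities average over K orthonormal DPSS (Slepian) tapers
with time-bandwidth product NW (defaults NW = 3, K = 5). On a T-second
window this concentrates each estimate within ±NW/T Hz; on the 3 s trial
windows that is ±1 Hz, on the 1 s spectrogram windows ±3 Hz. The published
analyses this pipeline reimplements do not report their taper settings, so
the choice is explicit configuration rather than a hidden constant, and it
matters: a spectral line's power spreads over the full taper bandwidth, so
a 1 Hz integration band captures only part of it at NW = 3 (about 58 % for
a 3 s window). Two consequences are handled explicitly:

- **Closed-form checks** (sinusoid band power = A²/2, exact localization
  of a spectral line) are verified at NW = 1, K = 1, where the taper
  bandwidth fits inside the 1 Hz band. At the default setting they hold
  only up to the band-capture factor — a property of multitaper
  estimation, not an implementation error.
- **The synthetic generator calibrates through the estimator** (below), so
  that its `entrainment_gain` parameter means what it says under the
  analysis conventions.

PSDs are one-sided densities with interior bins doubled, `df = fs/n`
without padding (padding is an option and is recorded, since it moves bin
centers). With this normalization `sum(density)·df` equals the signal
variance (Parseval), which the suite asserts to 2 % on white noise.

Coherence pools the cross- and auto-spectra jointly over tapers and
trials: msc = |⟨XY*⟩|²/(⟨|X|²⟩⟨|Y|²⟩). The estimator is biased upward by
roughly 1/(n_trials·K) for independent signals — negligible at the ~100
trials per condition the trial bookkeeping targets, and measured directly
in the tests.

Band limits are closed intervals over bin centers; the stimulation band is
[f − 0.5, f + 0.5] Hz. Band power is additive across a split at an interior
bin edge by construction.

The theta bandpass for phase-alignment visualization is an even-order FIR
design applied forward-backward (zero phase, gain 1 ± 0.05 in band, ≥20 dB
stopband attenuation at 2 Hz).

### Dominant-frequency estimation

The dominant theta frequency is the argmax of the trial-mean PSD over
5–12 Hz, refined by a quadratic fit across the spectral main lobe
(±NW/T Hz) around the peak bin. A three-point parabola is the textbook
refinement but is ill-conditioned here: the multitaper composite lobe is
flat-topped, so adjacent-bin differences are dominated by leakage detail
and the vertex can land ~0.3 Hz off even for a pure tone. Fitting across
the whole lobe recovers a pure tone within half a bin. Exact ties break to
the lower frequency (logged); a flat spectrum returns the lowest bin with
a low-confidence warning.

## Trial pipeline

- **Alignment**: one row per usable onset; onsets whose 3 s pre or during
  window leaves the recording are dropped and logged.
- **Artifact QC (range rule)**: the trial trace is the concatenated
  pre+during window; its range (max − min) is compared against 2× the mean
  range of *all* input trials, computed once before any removal. A single
  pass keeps the result independent of iteration and trial order. The rule
  saturates when contamination is heavy: once artifact trials make up more
  than roughly a third of the set they inflate the mean enough that
  nothing exceeds 2× it. That is a property of the rule itself and is left
  intact; the recovery suites run at the 10 % contamination the rule is
  meant for.
- **Theta selection** uses the pre window only, with a strict > 4.5
  criterion (a ratio of exactly 4.5 is not selected). Selection is
  per-trial and therefore order-invariant.
- **Percent changes** are formed per animal × frequency × location after
  trial averaging, never pooled across animals at the trial level. Band
  power of the trial-averaged spectrum equals the average of per-trial
  band powers (the estimator is linear), so the two orderings coincide.
- **Coherence change** pairs the post-QC intersection of HI and TT trial
  indices; fewer than two common trials is an error.
- **Differential spectrograms** express each during-window time-frequency
  bin as a percent increase over the per-frequency *time-mean* of the
  pre-window spectrogram. Zero-baseline bins are NaN-flagged and excluded
  from maxima. At the default NW = 3 the ±3 Hz lobe of an entrained line,
  tilted by the 1/f baseline in the denominator, puts the maximal row 1–2
  bins above the stimulation frequency; with a single concentrated taper
  (NW = 1, K = 1) the maximal row localizes exactly. Both behaviors are
  exercised in the tests.

## Synthetic LFP sessions

The generator is the package's stand-in for animal recordings and defines
the conditions under which the pipeline is validated.

- **Background**: 1/f^α noise (α = 1) by spectral shaping of white noise —
  amplitudes below 0.5 Hz clamped to keep variance finite — normalized to
  an RMS `noise_scale`.
- **Brain states**: a two-state renewal process with exponential dwell
  times (default mean 20 s per state). Theta states carry a sinusoid at
  7.6 Hz (the typical pre-light dominant frequency); non-theta states a
  2 Hz slow oscillation. Each bout draws a fresh phase. A trial's
  ground-truth state is the majority label of its 3 s pre window; trials
  straddling a state switch are intrinsically ambiguous and bound the
  achievable selection agreement (~97–98 % at the defaults, against a 95 %
  requirement).
- **Amplitudes**: no amplitude scales are published for these recordings,
  so the defaults are realistic rodent depth-electrode values chosen once:
  theta 150 µV, delta 100 µV, noise 50 µV RMS, artifacts 2000 µV. They are
  free parameters, not calibrated to any dataset.
- **Stimulation**: epochs of `epoch_duration` (3 s) every
  `epoch_duration + inter_epoch` (33 s), cycling through the configured
  frequency list in seeded random order. The behavioral train is 50 ms
  on / 100 ms off (≈6.67 Hz, 33 % duty cycle).
- **Entrainment**: during each light epoch of an opsin+ session a sinusoid
  at the stimulation frequency is added to the shared (two-channel)
  signal. Its amplitude is set so that its *measured* multitaper band
  power in the ±0.5 Hz band — under the generator's taper configuration —
  equals `entrainment_gain` times the session's mean baseline band power
  there. Calibrating through the estimator rather than via A²/2 makes the
  expected percent power change exactly 100·gain regardless of taper
  leakage. With `phase_reset` the sinusoid's phase is zero at every pulse
  onset, so it survives trial averaging; without it each epoch draws a
  random phase and the average cancels.
- **Channels**: TT = `tt_coupling` × (shared signal) + independent noise.
  The entrained component is part of the shared signal, which is what
  makes the HI–TT coherence change positive exactly when a shared
  component is present.
- **Artifacts**: 200 ms square transients of `artifact_amp` on both
  channels at a random offset within the trial, with per-trial probability
  `artifact_prob`; injected trial indices are recorded as ground truth.

What the generator does **not** emulate: non-sinusoidal theta (asymmetric
cycles, harmonics), gradual state transitions, movement artifacts with
realistic broadband structure, electrode drift, volume-conduction
cross-talk, or any spiking origin of the LFP. Passing recovery tests shows
the pipeline correctly measures the statistical structure the analyses
assume — not that real recordings satisfy those assumptions.

## Synthetic current clamp

Sweeps are 1 s (0.25 s baseline, 0.5 s step, 0.25 s recovery) at 20 kHz,
over a ladder from −300 pA in `step_size` increments (`n_steps` rungs,
default 15 × 50 pA). Subthreshold sweeps follow RC charging with
τ = 20 ms; Ohm's law with `r_in` sets the steady state, so input
resistance is exactly recoverable from the last 100 ms of the step.

Suprathreshold sweeps superimpose a parametric spike template on a plateau
5 mV below threshold: an exponential rise (sharpness k·t_rise = 3, rise
phase 60 % of the FWHM) from threshold to peak, then a linear
repolarization whose duration is solved so the waveform's width at
half-maximum equals the requested value exactly — analytically invertible,
which is what makes the recovery tolerances sharp (threshold 1 mV,
half-width 2 sample intervals). Each spike is preceded by a 2 ms concave
exponential approach to threshold, giving the curvature sign change that
the second-derivative threshold detector keys on, as in real membrane
trajectories. A template narrower than 4 sample intervals raises
(unresolvable waveform).

Spike counts rise linearly across suprathreshold rungs from 4 (so the
near-threshold sweep — first step with more than two spikes — is the first
rung) to `n_spikes_max` (default 40 → 80 Hz). The top sweep's ISI sequence
is a geometric ramp whose first/last ratio realizes `adaptation_target`
exactly, with an alternating interior perturbation solved by bisection to
hit `cv_target` (sample SD convention, ×100). The ramp itself has an
intrinsic CV (≈21 % at adaptation 0.5 with 40 spikes); targets below it are
unreachable without breaking the adaptation ratio, in which case the ramp
is used and the ground truth records the realized CV — recovery is always
checked against what was generated.

Spike detection uses dv/dt > 20 mV/ms onsets with a peak criterion of
−10 mV and a 1 ms refractory window (no detection criteria are published;
these are configuration with logged defaults). Threshold is the last
negative-to-positive zero crossing of the Savitzky–Golay-smoothed
(0.5 ms window, order 3) second derivative before the point of maximal
dv/dt; if no crossing exists the dv/dt criterion is the flagged fallback.
Spike amplitude is referenced threshold-to-peak — threshold is the only
per-spike reference the feature definitions provide.

Persistent (barrage) firing uses repeated ≥300 pA, 500 ms, 50 %-duty
steps: any off-phase spike → yes; none after ≥100 repeats → no; fewer
repeats → indeterminate.

## Postsynaptic currents

Baseline is the mean of the 50 ms before light onset. The GABA_A peak
(inward) is searched 0–50 ms post-onset and the GABA_B peak (outward)
50–400 ms — windows chosen around the typical times-to-peak of ~6 ms and
~134 ms and exposed in configuration. Classification uses the ±10 pA
criteria inclusively (−10.0 pA is a GABA_A response; −9.999 pA is not),
with GABA_A taking precedence when both are present. The 0–63 % rise time
runs from the deflection onset (last baseline crossing before the peak) to
63 % of peak amplitude, linearly interpolated. The synthetic PSC is a
biexponential (1 − e^(−t/τ_r))·e^(−t/τ_d) whose rise constant is solved by
bisection from the requested time-to-peak and scaled to an exact peak.

## Behavior

Bout-level durations are summed per object before the DI — the score is
time, not bout counts. Exclusions: |encoding DI| strictly greater than 20
(a DI of exactly 20 is retained); total investigation below 3 s (object
tasks) or 2 s (odor task) in *either* phase, read disjunctively. The
synthetic session draws exponential bout durations (default 60 bouts of
mean 0.2 s ≈ 12 s total investigation, matching typical session totals)
and assigns each bout to the novel object with probability
(1 + preference/100)/2, making the expected retrieval DI equal to
`preference` and the expected encoding DI zero; the ratio-estimator bias is
O(1/n_bouts) and measured as negligible in the 1000-seed null.

## Problem sizes

Validation runs use sessions of 340–1000 s (12–30 light epochs at one
frequency), 50 seeds per entrainment gain level, 50 randomized synthetic
cells for the feature-recovery suite, and 50-animal cohorts per preference
level for behavior — sizes at which the Monte-Carlo error of each check is
several times smaller than its tolerance.

## Known limitations

- Exact reproduction of the published in vivo percentages is impossible in
  principle: the underlying animal recordings are unavailable and the
  original taper/padding settings are unreported. The pipeline validates
  property-based (closed forms, ground-truth recovery) instead.
- The range rule's saturation under heavy (>~1/3) artifact contamination
  is inherited from its definition; it is not corrected here.
- No jackknife confidence intervals on coherence, no spectral Granger
  causality, no spike-field coupling or phase-locking metrics, no
  sag/rebound or voltage-clamp kinetics fitting, and no inferential
  statistics — summary tables are emitted for external testing.
- Input-resistance protocol details (step sizes, steady-state window) are
  unpublished; the slope-through-origin over the last 100 ms of
  hyperpolarizing steps is an explicit configuration choice.
- Readers exist only for the package's own delimited-text formats; no
  proprietary acquisition formats, and no single-file container export.
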