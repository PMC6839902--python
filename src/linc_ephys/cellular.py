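"""Current-clamp intrinsic-property extraction and light-evoked PSC classification.

Implements the feature battery used to characterize hippocampal interneurons
from current-step protocols — resting potential, input resistance, spike
threshold, half-width, firing frequencies, spike-frequency adaptation, ISI
regularity, persistent (barrage) firing — plus classification of light-evoked
postsynaptic currents into fast GABA_A (inward) and slow GABA_B (outward)
responses.

Feature definitions:

* threshold voltage — zero of the (smoothed) second derivative of voltage
  immediately preceding the spike, measured on the first action potential
  elicited by the smallest current injection;
* half-width — full width at half-maximum voltage deflection (threshold to
  peak), averaged within a cell across all spikes in the selected sweep;
* near-threshold sweep — first current step producing more than two spikes;
  max-firing sweep — first current step producing the most spikes;
* firing frequency — spike count / step duration;
* adaptation ratio — 1 − (first ISI / last ISI) in the max-firing sweep;
* CV of ISI — sample SD / mean of the max-firing sweep's ISIs, in percent;
* persistent firing — any off-phase spike during repeated 50%-duty-cycle
  depolarizing steps; absent only after >= 100 repeats without one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

_DEFAULT_CFG = AnalysisConfig()


@dataclass
class Sweep:
    """One current-clamp step recording."""

    t: np.ndarray        # s
    v: np.ndarray        # mV
    i_cmd: np.ndarray    # pA
    step_onset: float    # s
    step_offset: float   # s
    fs: float            # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.i_cmd = np.asarray(self.i_cmd, dtype=float)
        if not (len(self.t) == len(self.v) == len(self.i_cmd)):
            raise ValueError("t, v, i_cmd must have equal length")
        if not (self.t[0] <= self.step_onset < self.step_offset <= self.t[-1] + 1 / self.fs):
            raise ValueError("step window must lie within the trace")

    @property
    def step_current(self) -> float:
        """Command current during the step (pA)."""
        mask = (self.t >= self.step_onset) & (self.t < self.step_offset)
        return float(np.median(self.i_cmd[mask]))

    @property
    def step_duration(self) -> float:
        return self.step_offset - self.step_onset


@dataclass
class SpikeEvent:
    peak_time: float            # s
    peak_v: float               # mV
    threshold_v: float | None = None   # mV
    threshold_time: float | None = None
    half_width: float | None = None    # ms
    threshold_fallback: bool = False   # dv/dt fallback used
    half_width_flagged: bool = False   # flank never recrossed half-max

    @property
    def amplitude(self) -> float | None:
        """Threshold-to-peak amplitude (mV)."""
        if self.threshold_v is None:
            return None
        return self.peak_v - self.threshold_v


@dataclass
class CellFeatures:
    """The per-cell intrinsic-property battery. None = undefined/flagged."""

    v_rest: float | None = None              # mV
    input_resistance: float | None = None    # MΩ
    threshold_v: float | None = None         # mV
    ff_near_threshold: float | None = None   # Hz
    ff_max: float | None = None              # Hz
    adaptation_ratio: float | None = None
    cv_isi: float | None = None              # %
    amp_at_threshold: float | None = None    # mV
    amp_at_max: float | None = None          # mV
    hw_at_threshold: float | None = None     # ms
    hw_at_max: float | None = None           # ms
    persistent_firing: str = "indeterminate"  # yes | no | indeterminate
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PSCResult:
    """Classified light-evoked postsynaptic current."""

    response_class: str          # GABA_A | GABA_B | none
    amplitude: float             # pA, signed peak vs baseline
    time_to_peak: float | None   # ms from light onset
    rise_time_0_63: float | None  # ms, GABA_A only


# ---------------------------------------------------------------------------
# Spike detection and per-spike features
# ---------------------------------------------------------------------------

def detect_spikes(sweep: Sweep, config: AnalysisConfig = _DEFAULT_CFG) -> list[SpikeEvent]:
    """Detect action potentials: a dv/dt upstroke followed by a peak.

    A spike is an upward dv/dt excursion exceeding the rate criterion
    (default 20 mV/ms) whose subsequent local maximum lies above the peak
    criterion (default −10 mV); events within the refractory window
    (default 1 ms) of an accepted peak are ignored. Zero spikes is a valid
    result.
    """
    if sweep.fs < 10_000:
        logger.warning("sampling rate %.0f Hz below recommended 10 kHz", sweep.fs)
    dt_ms = 1000.0 / sweep.fs
    dvdt = np.diff(sweep.v) / dt_ms  # mV/ms
    above = dvdt > config.spike_dvdt_threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        onsets = np.insert(onsets, 0, 0)
    events: list[SpikeEvent] = []
    last_peak_t = -np.inf
    search = max(int(round(5e-3 * sweep.fs)), 2)  # peak within 5 ms of upstroke
    for i0 in onsets:
        seg = sweep.v[i0:i0 + search]
        if len(seg) < 2:
            continue
        ip = i0 + int(np.argmax(seg))
        # refine to a genuine local max
        while ip + 1 < len(sweep.v) and sweep.v[ip + 1] > sweep.v[ip]:
            ip += 1
        if sweep.v[ip] < config.spike_peak_criterion:
            continue
        pt = sweep.t[ip]
        if (pt - last_peak_t) * 1000.0 < config.spike_refractory_ms:
            continue
        if events and pt == events[-1].peak_time:
            continue
        events.append(SpikeEvent(peak_time=pt, peak_v=float(sweep.v[ip])))
        last_peak_t = pt
    return events


def spike_threshold(
    sweep: Sweep, peak_time: float, config: AnalysisConfig = _DEFAULT_CFG,
    search_ms: float = 3.0,
) -> tuple[float, float, bool]:
    """Threshold voltage/time of the spike peaking at ``peak_time``.

    The threshold is the last negative-to-positive zero crossing of the
    smoothed second derivative of voltage (curvature onset) in the window
    between ``search_ms`` before the peak and the point of maximal dv/dt.
    Smoothing is a 0.5 ms, order-3 Savitzky-Golay filter: raw second
    differences are noise-dominated at patch-clamp sampling rates.

    Returns ``(threshold_v, threshold_time, fallback)``; ``fallback`` is True
    when no curvature crossing exists and the dv/dt detection criterion was
    used instead. Raises if neither method finds a threshold.
    """
    ip = int(np.argmin(np.abs(sweep.t - peak_time)))
    i_lo = max(ip - int(round(search_ms * 1e-3 * sweep.fs)), 0)
    if ip - i_lo < 4:
        raise ValueError("search window too short for threshold detection")
    dt_ms = 1000.0 / sweep.fs
    win = max(int(round(0.5e-3 * sweep.fs)) | 1, 5)  # odd, >= 5 samples
    v_seg = sweep.v[i_lo:ip + 1]
    if len(v_seg) <= win:
        win = (len(v_seg) - 1) | 1
    d2 = _signal.savgol_filter(v_seg, win, polyorder=3, deriv=2, delta=dt_ms)
    dvdt = np.gradient(v_seg, dt_ms)
    i_upstroke = int(np.argmax(dvdt))
    crossings = [
        i for i in range(i_upstroke)
        if d2[i] <= 0.0 < d2[i + 1]
    ]
    if crossings:
        ic = i_lo + crossings[-1] + 1
        return float(sweep.v[ic]), float(sweep.t[ic]), False
    # Fallback: first dv/dt criterion crossing in the window
    above = np.flatnonzero(dvdt[:max(i_upstroke, 1) + 1] > config.spike_dvdt_threshold)
    if len(above) == 0:
        raise ValueError(
            f"no threshold found before peak at {peak_time:.6f} s "
            "(no curvature or dv/dt crossing)"
        )
    ic = i_lo + int(above[0])
    logger.warning("threshold fallback to dv/dt criterion at t=%.6f s", sweep.t[ic])
    return float(sweep.v[ic]), float(sweep.t[ic]), True


def spike_half_width(sweep: Sweep, spike: SpikeEvent) -> tuple[float, bool]:
    """Full width (ms) at half-maximum deflection (threshold to peak).

    Crossing times on both flanks are linearly interpolated between samples.
    Returns ``(half_width_ms, flagged)``; ``flagged`` is True (width NaN)
    when a flank never recrosses the half-max level — such spikes are
    excluded from within-cell averages.
    """
    if spike.threshold_v is None:
        raise ValueError("threshold_v must be measured before half-width")
    level = spike.threshold_v + (spike.peak_v - spike.threshold_v) / 2.0
    ip = int(np.argmin(np.abs(sweep.t - spike.peak_time)))
    i_thr = int(np.argmin(np.abs(sweep.t - spike.threshold_time)))

    t_rise = _cross_time(sweep.t, sweep.v, i_thr, ip, level, rising=True)
    i_end = min(ip + int(round(10e-3 * sweep.fs)), len(sweep.v) - 1)
    t_fall = _cross_time(sweep.t, sweep.v, ip, i_end, level, rising=False)
    if t_rise is None or t_fall is None:
        logger.warning("spike at %.6f s never recrossed half-max; excluded",
                       spike.peak_time)
        return float("nan"), True
    return (t_fall - t_rise) * 1000.0, False


def _cross_time(t, v, i0, i1, level, rising: bool) -> float | None:
    """Linear-interpolated level-crossing time in [i0, i1]."""
    seg = v[i0:i1 + 1]
    if rising:
        idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if len(idx) == 0:
        return None
    i = i0 + int(idx[0])
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def measure_spikes(sweep: Sweep, config: AnalysisConfig = _DEFAULT_CFG) -> list[SpikeEvent]:
    """Detect spikes and fill threshold, amplitude and half-width in place."""
    events = detect_spikes(sweep, config)
    for ev in events:
        ev.threshold_v, ev.threshold_time, ev.threshold_fallback = spike_threshold(
            sweep, ev.peak_time, config
        )
        ev.half_width, ev.half_width_flagged = spike_half_width(sweep, ev)
    return events


# ---------------------------------------------------------------------------
# Train statistics
# ---------------------------------------------------------------------------

def firing_frequency(sweep: Sweep, config: AnalysisConfig = _DEFAULT_CFG) -> float:
    """Spike count during the current step divided by step duration (Hz)."""
    if sweep.step_duration <= 0:
        raise ValueError("step duration must be positive")
    events = detect_spikes(sweep, config)
    n = sum(1 for e in events if sweep.step_onset <= e.peak_time < sweep.step_offset)
    return n / sweep.step_duration


def adaptation_ratio(isis) -> float | None:
    """1 − (first ISI / last ISI); None (flagged) below two ISIs."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) < 2:
        logger.warning("adaptation ratio undefined: %d ISI(s)", len(isis))
        return None
    return float(1.0 - isis[0] / isis[-1])


def cv_isi(isis) -> float | None:
    """Coefficient of variation of the ISIs, percent (sample SD, ddof=1)."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) < 2:
        logger.warning("CV of ISI undefined: %d ISI(s)", len(isis))
        return None
    return float(100.0 * isis.std(ddof=1) / isis.mean())


def select_analysis_sweeps(spike_counts) -> tuple[int | None, int | None]:
    """Near-threshold and max-firing sweep indices from per-step spike counts.

    Counts must be ordered by ascending current. Near-threshold = first step
    with more than two spikes (strict); max-firing = first step achieving
    the maximum count. Either index is None when undefined.
    """
    counts = list(spike_counts)
    if not counts:
        raise ValueError("no sweeps supplied")
    near = next((i for i, c in enumerate(counts) if c > 2), None)
    if near is None:
        logger.warning("no sweep produced more than two spikes")
    mx = max(counts)
    max_idx = counts.index(mx) if mx > 0 else None
    return near, max_idx


def detect_persistent_firing(
    repeat_sweeps: list[Sweep], config: AnalysisConfig = _DEFAULT_CFG
) -> str:
    """Persistent (barrage) firing over repeated 50%-duty-cycle steps.

    ``yes`` if any spike occurs in an off-phase window; ``no`` after at
    least 100 repeats with none; ``indeterminate`` otherwise.
    """
    for sweep in repeat_sweeps:
        for ev in detect_spikes(sweep, config):
            if ev.peak_time >= sweep.step_offset or ev.peak_time < sweep.step_onset:
                return "yes"
    return "no" if len(repeat_sweeps) >= 100 else "indeterminate"


# ---------------------------------------------------------------------------
# Passive properties
# ---------------------------------------------------------------------------

def input_resistance(
    sweeps: list[Sweep], config: AnalysisConfig = _DEFAULT_CFG,
    steady_state_ms: float = 100.0,
) -> float | None:
    """Input resistance (MΩ) from hyperpolarizing subthreshold steps.

    Steady-state ΔV is the mean over the last ``steady_state_ms`` of the
    step minus the pre-step baseline; the resistance is the slope of ΔV
    versus injected current through the origin (exact Ohm's law for a
    single sweep). Sweeps containing spikes are rejected from the fit.
    """
    dvs, currents = [], []
    for sweep in sweeps:
        if detect_spikes(sweep, config):
            logger.warning("sweep at %g pA contains spikes; excluded from R_in fit",
                           sweep.step_current)
            continue
        i_amp = sweep.step_current
        if i_amp >= 0:
            continue
        base_mask = sweep.t < sweep.step_onset
        ss_mask = (sweep.t >= sweep.step_offset - steady_state_ms / 1000.0) & \
                  (sweep.t < sweep.step_offset)
        dv = float(sweep.v[ss_mask].mean() - sweep.v[base_mask].mean())
        dvs.append(dv)
        currents.append(i_amp)
    if not dvs:
        logger.warning("no hyperpolarizing subthreshold sweep; R_in undefined")
        return None
    dvs = np.array(dvs)
    currents = np.array(currents)
    slope = float((dvs * currents).sum() / (currents ** 2).sum())  # mV/pA = GΩ
    return slope * 1000.0  # MΩ


# ---------------------------------------------------------------------------
# Postsynaptic-current classification
# ---------------------------------------------------------------------------

def classify_psc(
    trace: np.ndarray, light_onset: float, fs: float,
    config: AnalysisConfig = _DEFAULT_CFG,
) -> PSCResult:
    """Classify a light-evoked postsynaptic current (voltage clamp, pA).

    Baseline is the mean of the 50 ms before light onset. A GABA_A response
    is an inward current >= 10 pA below baseline (peak searched 0-50 ms
    post-onset); a GABA_B response is an outward current >= 10 pA above
    baseline (peak searched 50-400 ms). GABA_A takes precedence when both
    criteria are met. The 0-63% rise time (GABA_A) runs from the onset of
    the deflection (last baseline crossing before the peak) to 63% of peak
    amplitude, linearly interpolated.
    """
    trace = np.asarray(trace, dtype=float)
    i_on = int(round(light_onset * fs))
    n_base = int(round(config.psc_baseline_ms / 1000.0 * fs))
    if i_on - n_base < 0:
        raise ValueError(
            f"need {config.psc_baseline_ms:g} ms of pre-onset baseline"
        )
    baseline = float(trace[i_on - n_base:i_on].mean())

    def _window(lo_ms: float, hi_ms: float) -> tuple[int, int]:
        a = i_on + int(round(lo_ms / 1000.0 * fs))
        b = min(i_on + int(round(hi_ms / 1000.0 * fs)), len(trace))
        return a, b

    a0, a1 = _window(*config.gabaa_search_ms)
    b0, b1 = _window(*config.gabab_search_ms)
    crit = config.psc_criterion_pa

    i_min = a0 + int(np.argmin(trace[a0:a1]))
    amp_a = trace[i_min] - baseline  # negative for inward
    i_max = b0 + int(np.argmax(trace[b0:b1])) if b1 > b0 else None
    amp_b = (trace[i_max] - baseline) if i_max is not None else 0.0

    if amp_a <= -crit:
        ttp = (i_min - i_on) / fs * 1000.0
        rise = _rise_time_0_63(trace, baseline, i_on, i_min, fs)
        return PSCResult("GABA_A", float(amp_a), ttp, rise)
    if i_max is not None and amp_b >= crit:
        ttp = (i_max - i_on) / fs * 1000.0
        return PSCResult("GABA_B", float(amp_b), ttp, None)
    extreme = amp_a if abs(amp_a) >= abs(amp_b) else amp_b
    return PSCResult("none", float(extreme), None, None)


def _rise_time_0_63(trace, baseline, i_on, i_peak, fs) -> float | None:
    """Time (ms) from deflection onset (0%) to 63% of peak amplitude."""
    amp = trace[i_peak] - baseline
    if amp == 0:
        return None
    seg = trace[i_on:i_peak + 1]
    # onset: last sample at/above baseline before the (inward) peak
    dev = (seg - baseline) / amp  # 0 at baseline, 1 at peak, sign-free
    below = np.flatnonzero(dev <= 0.0)
    i_start = i_on + (int(below[-1]) if len(below) else 0)
    t0 = i_start / fs
    target = baseline + 0.63 * amp
    t63 = None
    for i in range(i_start, i_peak):
        d0, d1 = (trace[i] - baseline) / amp, (trace[i + 1] - baseline) / amp
        if d0 < 0.63 <= d1:
            frac = (0.63 - d0) / (d1 - d0)
            t63 = (i + frac) / fs
            break
    if t63 is None:
        t63 = i_peak / fs
    return (t63 - t0) * 1000.0


# ---------------------------------------------------------------------------
# Whole-cell battery
# ---------------------------------------------------------------------------

def build_cell_features(
    sweeps: list[Sweep],
    repeat_sweeps: list[Sweep] | None = None,
    psc_traces=None,
    config: AnalysisConfig = _DEFAULT_CFG,
) -> CellFeatures:
    """Assemble the full per-cell feature battery from a step-protocol set.

    ``sweeps`` must be ordered by ascending step current. Spike-dependent
    fields are flagged undefined (None) for all-subthreshold cells.
    Amplitudes and half-widths are averaged within the cell across all
    spikes of the selected sweep.
    """
    if not sweeps:
        raise ValueError("no sweeps supplied")
    feats = CellFeatures()

    base_vals = []
    for sweep in sweeps:
        mask = sweep.t < sweep.step_onset
        if mask.any():
            base_vals.append(sweep.v[mask].mean())
    feats.v_rest = float(np.mean(base_vals)) if base_vals else None

    feats.input_resistance = input_resistance(sweeps, config)

    all_events = [measure_spikes(s, config) for s in sweeps]
    step_counts = [
        sum(1 for e in ev if s.step_onset <= e.peak_time < s.step_offset)
        for s, ev in zip(sweeps, all_events)
    ]
    near, mx = select_analysis_sweeps(step_counts)
    if near is None:
        feats.flags.append("near-threshold sweep undefined")
    if mx is None:
        feats.flags.append("no spikes in any sweep")
        return feats

    first_spiking = next(i for i, c in enumerate(step_counts) if c > 0)
    first_ev = next(
        e for e in all_events[first_spiking]
        if sweeps[first_spiking].step_onset <= e.peak_time
    )
    feats.threshold_v = first_ev.threshold_v
    if first_ev.threshold_fallback:
        feats.flags.append("threshold measured by dv/dt fallback")

    def _step_events(idx: int) -> list[SpikeEvent]:
        s = sweeps[idx]
        return [e for e in all_events[idx]
                if s.step_onset <= e.peak_time < s.step_offset]

    if near is not None:
        ev = _step_events(near)
        feats.ff_near_threshold = len(ev) / sweeps[near].step_duration
        feats.amp_at_threshold = _mean_or_none([e.amplitude for e in ev])
        feats.hw_at_threshold = _mean_or_none(
            [e.half_width for e in ev if not e.half_width_flagged]
        )

    ev_max = _step_events(mx)
    feats.ff_max = len(ev_max) / sweeps[mx].step_duration
    feats.amp_at_max = _mean_or_none([e.amplitude for e in ev_max])
    feats.hw_at_max = _mean_or_none(
        [e.half_width for e in ev_max if not e.half_width_flagged]
    )
    isis = np.diff([e.peak_time for e in ev_max]) * 1000.0
    feats.adaptation_ratio = adaptation_ratio(isis)
    feats.cv_isi = cv_isi(isis)

    if repeat_sweeps:
        feats.persistent_firing = detect_persistent_firing(repeat_sweeps, config)

    return feats


def _mean_or_none(values) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else None
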