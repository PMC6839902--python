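"""Ground-truth-labeled synthetic data for every stage of the pipeline.

Three generators:

* :func:`simulate_lfp_session` — a two-channel (hippocampus ``HI``, tenia
  tecta ``TT``) LFP session with alternating theta and non-theta brain
  states over a 1/f background, pulsed-light epochs, optional optogenetic
  entrainment (a stimulation-frequency component added during light, phase
  locked to pulse onsets) shared between channels, and occasional
  movement-artifact trials.
* :func:`simulate_current_clamp` — a current-step protocol whose
  suprathreshold sweeps carry spikes built from an analytically invertible
  parametric template, with ISI sequences realizing requested adaptation
  and CV targets.
* :func:`simulate_behavior_session` — two-object investigation-bout lists
  with a controllable novelty preference (expected discrimination index).

Every generator is a pure function of its parameters and seed: the same
seed gives bit-identical output, and each returns a :class:`GroundTruth`
carrying the labels the downstream analyses are tested against.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spectral
from .cellular import CellFeatures, Sweep
from .io import LFPRecording, StimEvent

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class StimProtocol:
    """Light-delivery schedule: pulsed epochs separated by rest intervals.

    Epoch onsets repeat every ``epoch_duration + inter_epoch`` seconds;
    within each epoch, pulses of ``pulse_width`` recur at the epoch's
    frequency. When several frequencies are listed, epochs cycle through
    them in a randomly assigned order (``order_seed``), reshuffled each
    cycle.
    """

    pulse_width: float = 0.005        # s (5 ms except the ~7 Hz train)
    epoch_duration: float = 3.0       # s
    inter_epoch: float = 30.0         # s of rest between epochs
    frequencies: tuple[float, ...] = (20.0 / 3.0,)  # Hz (~6.67: 50 ms on / 100 ms off)
    order_seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_duration >= self.inter_epoch:
            raise ValueError("epoch_duration must be shorter than inter_epoch")
        for f in self.frequencies:
            if self.pulse_width >= 1.0 / f:
                raise ValueError(
                    f"pulse width {self.pulse_width} s not shorter than the "
                    f"{f:g} Hz period"
                )

    @classmethod
    def behavioral_train(cls) -> "StimProtocol":
        """The ~7 Hz behavioral train: 50 ms on / 100 ms off for 3 s every 30 s."""
        return cls(pulse_width=0.050, frequencies=(1.0 / 0.150,))

    def schedule(self, session_duration: float, start: float = 5.0) -> list[StimEvent]:
        """Epoch onsets and frequencies fitting within the session.

        Raises if even one epoch per listed frequency cannot be scheduled.
        """
        rng = np.random.default_rng(self.order_seed)
        period = self.epoch_duration + self.inter_epoch
        events: list[StimEvent] = []
        t = start
        order: list[float] = []
        while t + self.epoch_duration <= session_duration:
            if not order:
                order = list(rng.permutation(self.frequencies))
            events.append(StimEvent(onset=t, frequency=float(order.pop(0))))
            t += period
        scheduled = {e.frequency for e in events}
        missing = [f for f in self.frequencies if f not in scheduled]
        if missing:
            raise ValueError(
                f"session of {session_duration:g} s too short: first "
                f"unschedulable epoch is the {missing[0]:g} Hz epoch at "
                f"t={t:g} s"
            )
        return events

    def pulse_onsets(self, event: StimEvent) -> np.ndarray:
        """Pulse onset times within one epoch."""
        n = int(np.floor(self.epoch_duration * event.frequency + 1e-9))
        return event.onset + np.arange(n) / event.frequency


def pulse_train_duty_cycle(on: float, off: float) -> float:
    """Duty cycle (%) of an on/off pulse train: 100·on/(on+off)."""
    if on <= 0 or off <= 0:
        raise ValueError("on and off durations must be positive")
    return 100.0 * on / (on + off)


@dataclass
class LFPSimParams:
    """Parameters of the synthetic LFP session.

    Amplitudes are in µV. The study reports no LFP amplitude scales, so the
    defaults are realistic rodent depth-electrode values, not calibrated to
    any dataset: ~150 µV theta, ~100 µV delta, 50 µV 1/f background,
    2000 µV movement artifacts.
    """

    sampling_rate: float = 1000.0      # Hz
    session_duration: float = 300.0    # s
    theta_freq: float = 7.6            # Hz, pre-light dominant theta
    theta_amp: float = 150.0           # µV
    delta_amp: float = 100.0           # µV, non-theta-state slow oscillation
    delta_freq: float = 2.0            # Hz
    noise_exponent: float = 1.0        # 1/f^alpha background
    noise_scale: float = 50.0          # µV RMS
    mean_theta_dwell: float = 20.0     # s
    mean_nontheta_dwell: float = 20.0  # s
    entrainment_gain: float = 0.0      # fractional band-power increase; 0 = opsin-
    phase_reset: bool = True
    tt_coupling: float = 0.5           # share of the HI shared signal in TT
    artifact_prob: float = 0.0         # per-trial probability
    artifact_amp: float = 2000.0       # µV
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact_prob must lie in [0, 1]")
        for name in ("theta_amp", "delta_amp", "noise_scale", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CellSimParams:
    """Parameters of the synthetic current-clamp cell."""

    v_rest: float = -58.0            # mV
    r_in: float = 180.0              # MΩ
    threshold_v: float = -44.0       # mV
    spike_peak: float = 10.0         # mV
    half_width: float = 0.9          # ms
    adaptation_target: float = 0.5   # in [0, 1)
    cv_target: float = 25.0          # %
    persistent: bool = False
    sweep_sampling_rate: float = 20000.0  # Hz
    step_start: float = -300.0       # pA
    step_size: float = 50.0          # pA
    step_duration: float = 0.5       # s
    n_steps: int = 15
    n_spikes_max: int = 40           # spike count in the top sweep
    noise_rms_mv: float = 0.0        # additive recording noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.threshold_v > self.v_rest:
            raise ValueError("threshold_v must exceed v_rest")
        if not self.spike_peak > self.threshold_v:
            raise ValueError("spike_peak must exceed threshold_v")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if not 0.0 <= self.adaptation_target < 1.0:
            raise ValueError("adaptation_target must lie in [0, 1)")


@dataclass
class BehaviorSimParams:
    """Parameters of the synthetic two-object investigation session."""

    n_bouts: int = 60
    mean_bout: float = 0.2          # s
    preference: float = 0.0         # expected retrieval DI in [-100, 100]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bouts < 0:
            raise ValueError("n_bouts must be non-negative")
        if self.mean_bout <= 0:
            raise ValueError("mean_bout must be positive")
        if not -100.0 <= self.preference <= 100.0:
            raise ValueError("preference must lie in [-100, 100]")


@dataclass
class GroundTruth:
    """Labels and expectations attached to a generated dataset."""

    state_labels: np.ndarray | None = None    # per-sample theta flags
    artifact_trials: list[int] = field(default_factory=list)
    entrainment_epochs: list[tuple[float, float]] = field(default_factory=list)
    theta_trials: list[int] = field(default_factory=list)
    expected_power_change: float | None = None  # %, at the stimulation frequency
    cell_feature_truth: CellFeatures | None = None
    expected_di: float | None = None


# ---------------------------------------------------------------------------
# LFP session
# ---------------------------------------------------------------------------

def one_over_f_noise(
    n: int, fs: float, exponent: float, scale: float, rng: np.random.Generator,
    f_min: float = 0.5,
) -> np.ndarray:
    """1/f^alpha noise by spectral shaping of white noise (inverse transform).

    Amplitudes below ``f_min`` are clamped to the ``f_min`` value to keep
    the variance finite; the result is normalized to RMS ``scale``.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaped = np.maximum(freqs, f_min) ** (-exponent / 2.0)
    shaped[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaped, n=n)
    rms = x.std()
    return x * (scale / rms) if rms > 0 else x


def _renewal_states(
    n: int, fs: float, mean_theta: float, mean_nontheta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-state renewal process with exponential dwell times → bool labels."""
    labels = np.zeros(n, dtype=bool)
    # start state drawn from the stationary occupancy
    p_theta = mean_theta / (mean_theta + mean_nontheta)
    state = bool(rng.random() < p_theta)
    i = 0
    while i < n:
        mean = mean_theta if state else mean_nontheta
        dwell = max(int(round(rng.exponential(mean) * fs)), 1)
        labels[i:i + dwell] = state
        i += dwell
        state = not state
    return labels


def _gated_oscillation(
    n: int, fs: float, freq: float, amp: float, gate: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sinusoid present only where ``gate`` is True, fresh phase per bout."""
    if amp == 0.0:
        return np.zeros(n)
    t = np.arange(n) / fs
    out = np.zeros(n)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], gate, [False]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        phase = rng.uniform(0, 2 * np.pi)
        out[start:stop] = amp * np.sin(2 * np.pi * freq * t[start:stop] + phase)
    return out


def _unit_band_capture(freq: float, fs: float, window_s: float,
                       nw: float, k: int, halfwidth: float) -> float:
    """Measured multitaper band power of a unit-amplitude sinusoid.

    A finite-length multitaper estimate spreads a line component over
    ±NW/T Hz, so only part of a sinusoid's A²/2 power lands inside the
    ±`halfwidth` band. This capture factor lets the generator scale the
    entrained component so its *measured* band power matches the requested
    gain — making ``entrainment_gain`` mean exactly what it says under the
    analysis conventions.
    """
    n = int(round(window_s * fs))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq * t)
    tapers = spectral.compute_tapers(n, nw, k)
    spec = spectral.multitaper_psd(x, fs, tapers)
    return spectral.bandpower(spec, (freq - halfwidth, freq + halfwidth))


def simulate_lfp_session(
    params: LFPSimParams,
    protocol: StimProtocol | None = None,
    animal_id: str = "sim",
    nw: float = spectral.DEFAULT_NW,
    k: int = spectral.DEFAULT_K,
) -> tuple[LFPRecording, LFPRecording, list[StimEvent], GroundTruth]:
    """Generate one two-channel LFP session with ground truth.

    Returns ``(hi, tt, events, truth)``. The shared signal (theta, delta and
    any entrained component) enters the TT channel scaled by
    ``tt_coupling``; each channel carries its own independent 1/f
    background. When ``entrainment_gain > 0`` (opsin+), every light epoch
    adds a sinusoid at the epoch's stimulation frequency whose measured
    band power in the ±0.5 Hz stimulation band equals
    ``entrainment_gain ×`` the session's mean baseline band power there;
    with ``phase_reset`` the sinusoid's phase is zero at each pulse onset.
    """
    if protocol is None:
        protocol = StimProtocol()
    fs = params.sampling_rate
    if fs <= 2 * max(protocol.frequencies):
        raise ValueError("sampling_rate must exceed twice the highest stim frequency")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.session_duration * fs))

    events = protocol.schedule(params.session_duration)

    labels = _renewal_states(
        n, fs, params.mean_theta_dwell, params.mean_nontheta_dwell, rng
    )
    shared = _gated_oscillation(n, fs, params.theta_freq, params.theta_amp,
                                labels, rng)
    shared += _gated_oscillation(n, fs, params.delta_freq, params.delta_amp,
                                 ~labels, rng)
    noise_hi = one_over_f_noise(n, fs, params.noise_exponent, params.noise_scale, rng)
    noise_tt = one_over_f_noise(n, fs, params.noise_exponent, params.noise_scale, rng)

    truth = GroundTruth(state_labels=labels)
    genotype = "opsin+" if params.entrainment_gain > 0 else "opsin-"

    n_pre = int(round(3.0 * fs))
    # ground-truth trial state: majority label of the 3 s pre-light window
    for idx, ev in enumerate(events):
        i_on = int(round(ev.onset * fs))
        if labels[i_on - n_pre:i_on].mean() > 0.5:
            truth.theta_trials.append(idx)

    if params.entrainment_gain > 0:
        t = np.arange(n) / fs
        by_freq: dict[float, list[StimEvent]] = {}
        for ev in events:
            by_freq.setdefault(ev.frequency, []).append(ev)
        base = shared + noise_hi
        for f, evs in by_freq.items():
            band = (f - 0.5, f + 0.5)
            tapers = spectral.compute_tapers(n_pre, nw, k)
            p_base = float(np.mean([
                spectral.bandpower(
                    spectral.multitaper_psd(
                        base[int(round(e.onset * fs)) - n_pre:
                             int(round(e.onset * fs))], fs, tapers),
                    band)
                for e in evs
            ]))
            capture = _unit_band_capture(f, fs, 3.0, nw, k, 0.5)
            amp = math.sqrt(params.entrainment_gain * p_base / capture)
            for ev in evs:
                i0 = int(round(ev.onset * fs))
                i1 = min(i0 + int(round(protocol.epoch_duration * fs)), n)
                if params.phase_reset:
                    phase = 0.0
                else:
                    phase = rng.uniform(0, 2 * np.pi)
                shared[i0:i1] += amp * np.sin(
                    2 * np.pi * f * (t[i0:i1] - ev.onset) + phase
                )
                truth.entrainment_epochs.append((ev.onset, i1 / fs))
        truth.expected_power_change = 100.0 * params.entrainment_gain
    else:
        truth.expected_power_change = 0.0

    hi = shared + noise_hi
    tt = params.tt_coupling * shared + noise_tt

    # movement artifacts: 200 ms square transients on both channels
    n_art = int(round(0.2 * fs))
    for idx, ev in enumerate(events):
        if rng.random() < params.artifact_prob:
            i_on = int(round(ev.onset * fs))
            off = rng.integers(-n_pre, int(round(3.0 * fs)) - n_art)
            a0 = i_on + int(off)
            hi[a0:a0 + n_art] += params.artifact_amp
            tt[a0:a0 + n_art] += params.artifact_amp
            truth.artifact_trials.append(idx)

    rec_hi = LFPRecording(hi, fs, animal_id, genotype, "HI")
    rec_tt = LFPRecording(tt, fs, animal_id, genotype, "TT")
    return rec_hi, rec_tt, events, truth


# ---------------------------------------------------------------------------
# Current clamp
# ---------------------------------------------------------------------------

def spike_template(
    threshold_v: float, peak_v: float, half_width_ms: float, fs: float,
) -> np.ndarray:
    """Parametric action-potential waveform starting and ending at threshold.

    Piecewise: an exponential rise from threshold to peak over a rise phase
    set to 60% of the requested FWHM (sharpness k·t_r = 3), then a linear
    repolarization whose duration is solved so the full width at
    half-maximum equals ``half_width_ms`` exactly. Analytically invertible,
    which is what makes parameter-recovery tests sharp. Raises when the
    FWHM is below four sample intervals (unresolvable waveform).
    """
    dt_ms = 1000.0 / fs
    if half_width_ms < 4 * dt_ms:
        raise ValueError(
            f"template half-width {half_width_ms:g} ms below four sample "
            f"intervals ({4 * dt_ms:g} ms) — waveform unresolvable at fs={fs:g} Hz"
        )
    amp = peak_v - threshold_v
    t_r = 0.6 * half_width_ms
    kk = 3.0 / t_r
    # half-max crossing on the exponential rise
    t_half_r = math.log(1.0 + (math.e ** 3 - 1.0) / 2.0) / kk
    t_f = 2.0 * (half_width_ms - (t_r - t_half_r))  # fall duration
    # evaluate the continuous piecewise waveform on the exact sample grid
    n = int(math.floor((t_r + t_f) / dt_ms)) + 1
    tt = np.arange(n) * dt_ms
    rise = threshold_v + amp * (np.exp(kk * np.minimum(tt, t_r)) - 1.0) \
        / (math.e ** 3 - 1.0)
    fall = peak_v - amp * (tt - t_r) / t_f
    return np.where(tt <= t_r, rise, fall)


def _construct_isis(
    n_spikes: int, duration_ms: float, adaptation: float, cv_pct: float,
) -> np.ndarray:
    """Deterministic ISI sequence realizing the adaptation and CV targets.

    Starts from a geometric ramp whose first/last ratio fixes the
    adaptation ratio exactly (last = first/(1−a)); the interior spread is
    then scaled by bisection until the sample CV matches ``cv_pct`` within
    0.01 points, holding the first and last ISIs fixed so adaptation is
    untouched.
    """
    n_isi = n_spikes - 1
    if n_isi < 2:
        return np.full(max(n_isi, 0), duration_ms * 0.8 / max(n_isi, 1))
    ratio = (1.0 / (1.0 - adaptation)) ** (1.0 / (n_isi - 1))
    ramp = ratio ** np.arange(n_isi)
    ramp *= (duration_ms * 0.85) / ramp.sum()

    interior = np.arange(1, n_isi - 1)
    if len(interior) == 0 or cv_pct is None:
        return ramp
    signs = np.where(interior % 2 == 0, 1.0, -1.0)
    if len(signs) % 2 == 1:
        signs[-1] = 0.0  # keep the interior sum (hence the mean) unchanged

    def cv_of(delta: float) -> float:
        isis = ramp.copy()
        isis[interior] += delta * signs * isis[interior].mean()
        return 100.0 * isis.std(ddof=1) / isis.mean()

    base_cv = cv_of(0.0)
    if cv_pct <= base_cv:
        return ramp  # the ramp's own spread already exceeds the target
    lo, hi = 0.0, 0.9
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if cv_of(mid) < cv_pct:
            lo = mid
        else:
            hi = mid
    isis = ramp.copy()
    isis[interior] += lo * signs * isis[interior].mean()
    return isis


def simulate_current_clamp(
    params: CellSimParams,
) -> tuple[list[Sweep], GroundTruth]:
    """Generate a current-step sweep ladder with ground-truth features.

    Sweeps run from ``step_start`` upward in ``step_size`` increments.
    Subthreshold sweeps show the passive exponential charging of an RC
    membrane (τ = 20 ms); suprathreshold sweeps superimpose template
    spikes. The top sweep's ISI sequence realizes ``adaptation_target``
    and ``cv_target``; intermediate sweeps use the same adaptation ramp.
    """
    fs = params.sweep_sampling_rate
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / fs
    pre, post = 0.25, 0.25
    total = pre + params.step_duration + post
    t = np.arange(int(round(total * fs))) * dt
    step_mask = (t >= pre) & (t < pre + params.step_duration)
    tau = 0.020  # s, membrane time constant

    i_rheo = (params.threshold_v - params.v_rest) / params.r_in * 1000.0  # pA
    currents = params.step_start + params.step_size * np.arange(params.n_steps)

    template = spike_template(
        params.threshold_v, params.spike_peak, params.half_width, fs
    )
    n_tmpl = len(template)
    # slow depolarizing approach to threshold before each spike (2 ms ramp)
    n_ramp = int(round(2e-3 * fs))

    supra = currents > i_rheo
    n_supra = int(supra.sum())
    sweeps: list[Sweep] = []
    max_isis_ms: np.ndarray | None = None

    for si, i_amp in enumerate(currents):
        v = np.full_like(t, params.v_rest)
        i_cmd = np.where(step_mask, i_amp, 0.0)
        if not supra[si]:
            dv_ss = i_amp * params.r_in / 1000.0  # mV
            ts = t[step_mask] - pre
            v[step_mask] += dv_ss * (1.0 - np.exp(-ts / tau))
            # relaxation after the step
            after = t >= pre + params.step_duration
            v_end = dv_ss * (1.0 - math.exp(-params.step_duration / tau))
            v[after] += v_end * np.exp(-(t[after] - (pre + params.step_duration)) / tau)
        else:
            k_supra = int(np.flatnonzero(supra).tolist().index(si))
            if n_supra > 1:
                n_spk = 4 + int(round(k_supra * (params.n_spikes_max - 4)
                                      / (n_supra - 1)))
            else:
                n_spk = params.n_spikes_max
            plateau = params.threshold_v - 5.0  # interspike baseline
            v[step_mask] = plateau
            isis = _construct_isis(
                n_spk, params.step_duration * 1000.0,
                params.adaptation_target,
                params.cv_target if si == len(currents) - 1 else None,
            )
            if si == len(currents) - 1:
                max_isis_ms = isis
            first_at = 0.010  # s after step onset
            times = pre + first_at + np.concatenate(([0.0], np.cumsum(isis) / 1000.0))
            # concave exponential approach to threshold before each spike
            # (decelerating depolarization: negative curvature, so the spike
            # onset is a clean curvature sign change)
            tau_a = n_ramp / 4.0  # samples
            approach = params.threshold_v - (params.threshold_v - plateau) \
                * np.exp(-np.arange(n_ramp) / tau_a)
            for st in times:
                i0 = int(round(st * fs))
                r0 = i0 - n_ramp
                if r0 >= 0 and i0 + n_tmpl <= len(v):
                    v[r0:i0] = approach
                    v[i0:i0 + n_tmpl] = template
        if params.noise_rms_mv > 0:
            v = v + rng.normal(0.0, params.noise_rms_mv, size=len(v))
        sweeps.append(Sweep(t=t.copy(), v=v, i_cmd=i_cmd,
                            step_onset=pre, step_offset=pre + params.step_duration,
                            fs=fs))

    # Ground truth for the feature battery
    truth_feats = CellFeatures(
        v_rest=params.v_rest,
        input_resistance=params.r_in,
        threshold_v=params.threshold_v,
        adaptation_ratio=params.adaptation_target,
        amp_at_threshold=params.spike_peak - params.threshold_v,
        amp_at_max=params.spike_peak - params.threshold_v,
        hw_at_threshold=params.half_width,
        hw_at_max=params.half_width,
        persistent_firing="yes" if params.persistent else "no",
    )
    counts = []
    for si in range(len(currents)):
        if not supra[si]:
            counts.append(0)
        else:
            k_supra = int(np.flatnonzero(supra).tolist().index(si))
            if n_supra > 1:
                counts.append(4 + int(round(k_supra * (params.n_spikes_max - 4)
                                            / (n_supra - 1))))
            else:
                counts.append(params.n_spikes_max)
    near = next((i for i, c in enumerate(counts) if c > 2), None)
    mx = counts.index(max(counts)) if max(counts, default=0) > 0 else None
    if near is not None:
        truth_feats.ff_near_threshold = counts[near] / params.step_duration
    if mx is not None:
        truth_feats.ff_max = counts[mx] / params.step_duration
    if max_isis_ms is not None and len(max_isis_ms) >= 2:
        truth_feats.cv_isi = float(
            100.0 * max_isis_ms.std(ddof=1) / max_isis_ms.mean()
        )
        truth_feats.adaptation_ratio = float(1.0 - max_isis_ms[0] / max_isis_ms[-1])
    return sweeps, GroundTruth(cell_feature_truth=truth_feats)


def simulate_persistent_protocol(
    params: CellSimParams, n_repeats: int = 100, onset_repeat: int = 40,
) -> list[Sweep]:
    """Repeated 500 ms / 50%-duty-cycle depolarizing steps (>= 300 pA).

    When ``params.persistent`` is set, off-phase spikes appear from
    ``onset_repeat`` onward; otherwise all spiking stays within the steps.
    """
    fs = params.sweep_sampling_rate
    dt = 1.0 / fs
    total = 2 * params.step_duration  # 50% duty cycle: step then equal off
    t = np.arange(int(round(total * fs))) * dt
    step_mask = t < params.step_duration
    template = spike_template(
        params.threshold_v, params.spike_peak, params.half_width, fs
    )
    i_amp = max(300.0, (params.threshold_v - params.v_rest) / params.r_in * 1000.0
                + 2 * params.step_size)
    sweeps = []
    for rep in range(n_repeats):
        v = np.full_like(t, params.v_rest)
        i_cmd = np.where(step_mask, i_amp, 0.0)
        v[step_mask] = params.threshold_v - 5.0
        on_times = np.arange(0.010, params.step_duration - 0.010, 0.025)
        spike_times = list(on_times)
        if params.persistent and rep >= onset_repeat:
            spike_times += list(
                np.arange(params.step_duration + 0.050, total - 0.010, 0.050)
            )
        for st in spike_times:
            i0 = int(round(st * fs))
            if i0 + len(template) <= len(v):
                v[i0:i0 + len(template)] = template
        sweeps.append(Sweep(t=t.copy(), v=v, i_cmd=i_cmd,
                            step_onset=0.0, step_offset=params.step_duration,
                            fs=fs))
    return sweeps


def synthetic_psc_trace(
    peak_pa: float, time_to_peak_ms: float, fs: float = 10000.0,
    light_onset: float = 0.1, duration: float = 0.6, tau_decay_ms: float = 25.0,
    baseline_pa: float = 0.0,
) -> np.ndarray:
    """Biexponential postsynaptic-current trace with an exact constructed peak.

    ``(1 − e^{−t/τ_r}) e^{−t/τ_d}`` scaled so the extremum equals
    ``peak_pa`` (signed) at ``time_to_peak_ms`` after light onset; the rise
    constant is solved from the requested time to peak.
    """
    tp = time_to_peak_ms / 1000.0
    td = tau_decay_ms / 1000.0
    # t_peak = tau_r * ln(1 + tau_d/tau_r): solve for tau_r by bisection
    lo, hi = 1e-6, td * 10
    for _ in range(200):
        mid = (lo + hi) / 2
        if mid * math.log1p(td / mid) < tp:
            lo = mid
        else:
            hi = mid
    tr = (lo + hi) / 2
    n = int(round(duration * fs))
    t = np.arange(n) / fs - light_onset
    shape = np.where(t >= 0, (1 - np.exp(-np.maximum(t, 0) / tr))
                     * np.exp(-np.maximum(t, 0) / td), 0.0)
    peak_val = (1 - math.exp(-tp / tr)) * math.exp(-tp / td)
    return baseline_pa + peak_pa * shape / peak_val


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

TASKS = ("OLM", "ORM", "OdorRM")


def simulate_behavior_session(
    params: BehaviorSimParams, task: str = "OLM",
    animal_id: str = "sim", genotype: str = "opsin+",
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate encoding and retrieval bout tables for one animal.

    Each bout's duration is exponential with mean ``mean_bout``; retrieval
    bouts attach to the novel object with probability
    ``(1 + preference/100)/2`` (so the expected retrieval DI equals
    ``preference``), encoding bouts with probability 1/2 (expected DI 0).
    Returns ``(encoding, retrieval, truth)`` as bout DataFrames with
    columns phase, object, start, duration.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    rng = np.random.default_rng(params.seed)

    def _phase(name: str, p_novel: float) -> pd.DataFrame:
        rows = []
        tcur = 10.0
        for _ in range(params.n_bouts):
            dur = float(rng.exponential(params.mean_bout))
            dur = max(dur, 0.05)
            obj = "novel" if rng.random() < p_novel else "familiar"
            rows.append({"phase": name, "object": obj,
                         "start": round(tcur, 3), "duration": dur})
            tcur += dur + float(rng.exponential(5.0))
        return pd.DataFrame(rows, columns=["phase", "object", "start", "duration"])

    p_novel = (1.0 + params.preference / 100.0) / 2.0
    encoding = _phase("encoding", 0.5)
    retrieval = _phase("retrieval", p_novel)
    truth = GroundTruth(expected_di=params.preference)
    return encoding, retrieval, truth
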