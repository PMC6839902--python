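"""Trial pipeline for optogenetic LFP stimulation sessions.

The analysis chain mirrors how pulsed-light experiments are scored: align
traces to light onsets (3 s pre / 3 s during), reject movement-artifact
trials by the range rule, optionally keep only theta-state trials, then
measure the stimulation-frequency band-power change, the inter-regional
coherence change, the dominant theta frequency, phase-locked average
traces and differential (percent-increase) spectrograms, summarized per
animal x genotype x stimulation frequency.

Ordering contracts: the artifact threshold is computed once from all input
trials (single pass — no iteration), over the full concatenated
pre+during trace; theta selection applies to the 3 s pre window only, with
a strict ratio criterion; coherence pairs the post-QC intersection of the
two channels' trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import spectral
from .config import AnalysisConfig
from .io import LFPRecording, StimEvent

logger = logging.getLogger(__name__)

_DEFAULT_CFG = AnalysisConfig()


@dataclass
class AlignedTrialSet:
    """Per-trial pre-light and during-light sample matrices."""

    pre: np.ndarray       # (n_trials, pre_window * fs)
    during: np.ndarray    # (n_trials, during_window * fs)
    fs: float
    animal_id: str
    genotype: str
    location: str
    stim_freq: float
    trial_ids: np.ndarray = field(default=None)  # indices into the onset list

    def __post_init__(self) -> None:
        self.pre = np.atleast_2d(np.asarray(self.pre, dtype=float))
        self.during = np.atleast_2d(np.asarray(self.during, dtype=float))
        if self.pre.shape != self.during.shape:
            raise ValueError("pre and during matrices must have identical shapes")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.pre.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.pre.shape[0]

    def subset(self, indices) -> "AlignedTrialSet":
        indices = np.asarray(indices, dtype=int)
        return replace(
            self, pre=self.pre[indices], during=self.during[indices],
            trial_ids=self.trial_ids[indices],
        )


@dataclass(frozen=True)
class TrialQCReport:
    """Range-rule artifact rejection bookkeeping."""

    ranges: np.ndarray
    mean_range: float
    threshold: float
    kept: np.ndarray
    removed: np.ndarray


@dataclass(frozen=True)
class ThetaSelection:
    """Theta-state trial selection by the pre-window theta/delta ratio."""

    ratios: np.ndarray
    criterion: float
    selected: np.ndarray  # positions within the (QC-kept) trial set


@dataclass(frozen=True)
class ChangeResult:
    """Percent change of a band quantity from baseline to light."""

    animal_id: str
    genotype: str
    location: str
    stim_freq: float
    measure: str            # "power" | "coherence"
    baseline_value: float
    light_value: float
    percent_change: float
    n_trials: int


@dataclass(frozen=True)
class DifferentialSpectrogram:
    """Percent power increase over the time-averaged pre-light baseline."""

    window_centers: np.ndarray
    freqs: np.ndarray
    percent_increase: np.ndarray  # (n_windows, n_freqs); NaN where baseline = 0
    flagged_bins: np.ndarray      # frequency indices with zero baseline


# ---------------------------------------------------------------------------
# Alignment and QC
# ---------------------------------------------------------------------------

def build_trials(
    recording: LFPRecording,
    onsets,
    stim_freq: float,
    pre: float = 3.0,
    during: float = 3.0,
) -> AlignedTrialSet:
    """Align the recording to light onsets into pre/during trial matrices.

    Onsets whose windows fall outside the recording are dropped and logged.
    """
    fs = recording.sampling_rate
    onsets = [o.onset if isinstance(o, StimEvent) else float(o) for o in onsets]
    if sorted(onsets) != list(onsets):
        raise ValueError("onsets must be sorted")
    n_pre = int(round(pre * fs))
    n_dur = int(round(during * fs))
    n = len(recording.samples)
    pres, durs, ids = [], [], []
    for idx, onset in enumerate(onsets):
        i_on = int(round(onset * fs))
        if i_on - n_pre < 0 or i_on + n_dur > n:
            logger.info("onset %d at %.3f s truncated; trial dropped", idx, onset)
            continue
        pres.append(recording.samples[i_on - n_pre:i_on])
        durs.append(recording.samples[i_on:i_on + n_dur])
        ids.append(idx)
    if not pres:
        raise ValueError("no usable onsets: every window falls outside the recording")
    return AlignedTrialSet(
        pre=np.array(pres), during=np.array(durs), fs=fs,
        animal_id=recording.animal_id, genotype=recording.genotype,
        location=recording.location, stim_freq=stim_freq,
        trial_ids=np.array(ids),
    )


def reject_artifact_trials(
    trials: AlignedTrialSet, config: AnalysisConfig = _DEFAULT_CFG
) -> tuple[AlignedTrialSet, TrialQCReport]:
    """Remove movement-artifact trials by the range rule, in one pass.

    Each trial's trace is the concatenated pre+during window; its range is
    max − min. The threshold — ``artifact_multiplier`` (default 2) times the
    mean range of *all* input trials — is frozen before any removal, so the
    result does not depend on iteration order. Raises if nothing survives.
    """
    if trials.n_trials < 2:
        raise ValueError("range rule needs at least two trials")
    traces = np.concatenate([trials.pre, trials.during], axis=1)
    ranges = traces.max(axis=1) - traces.min(axis=1)
    mean_range = float(ranges.mean())
    threshold = config.artifact_multiplier * mean_range
    removed = np.flatnonzero(ranges > threshold)
    kept = np.flatnonzero(ranges <= threshold)
    if len(kept) == 0:
        raise ValueError("all trials removed by the range rule")
    report = TrialQCReport(
        ranges=ranges, mean_range=mean_range, threshold=threshold,
        kept=kept, removed=removed,
    )
    logger.info("QC: kept %d / removed %d of %d trials (threshold %.1f)",
                len(kept), len(removed), trials.n_trials, threshold)
    return trials.subset(kept), report


def select_theta_trials(
    trials: AlignedTrialSet, config: AnalysisConfig = _DEFAULT_CFG
) -> ThetaSelection:
    """Select theta-state trials: pre-window theta/delta ratio strictly > 4.5.

    The ratio is computed on the 3 s pre-light window only. Selection is a
    per-trial criterion, hence invariant to trial order. An empty selection
    is allowed and logged as a warning.
    """
    ratios = np.array([
        spectral.theta_delta_ratio(
            row, trials.fs, nw=config.nw, k=config.k,
            theta=config.theta_band, delta=config.delta_band,
        )
        for row in trials.pre
    ])
    selected = np.flatnonzero(ratios > config.theta_criterion)
    if len(selected) == 0:
        logger.warning("no trial exceeds the theta/delta criterion %.1f",
                       config.theta_criterion)
    return ThetaSelection(
        ratios=ratios, criterion=config.theta_criterion, selected=selected
    )


# ---------------------------------------------------------------------------
# Change measures
# ---------------------------------------------------------------------------

def _stim_band(trials: AlignedTrialSet, config: AnalysisConfig) -> tuple[float, float]:
    hw = config.stim_band_halfwidth
    return (trials.stim_freq - hw, trials.stim_freq + hw)


def power_change_at_stim(
    trials: AlignedTrialSet, config: AnalysisConfig = _DEFAULT_CFG
) -> ChangeResult:
    """Percent change in stimulation-frequency band power, light vs baseline.

    Band power in the 1 Hz band centered on the stimulation frequency is
    computed per trial for the pre and during windows, averaged across
    trials, and the light value expressed as a percent increase over
    baseline. (Band power of the trial-averaged spectrum equals the
    trial-average of band powers — the estimator is linear.)
    """
    if trials.n_trials < 1:
        raise ValueError("no trials")
    band = _stim_band(trials, config)
    tapers = spectral.compute_tapers(trials.pre.shape[1], config.nw, config.k)
    p_pre = spectral.bandpower(
        spectral.trial_psd(trials.pre, trials.fs, tapers, pad=config.pad), band)
    p_dur = spectral.bandpower(
        spectral.trial_psd(trials.during, trials.fs, tapers, pad=config.pad), band)
    if p_pre <= 0:
        raise ValueError("zero baseline band power; percent change undefined")
    return ChangeResult(
        animal_id=trials.animal_id, genotype=trials.genotype,
        location=trials.location, stim_freq=trials.stim_freq,
        measure="power", baseline_value=p_pre, light_value=p_dur,
        percent_change=100.0 * (p_dur - p_pre) / p_pre,
        n_trials=trials.n_trials,
    )


def coherence_change_at_stim(
    hi: AlignedTrialSet, tt: AlignedTrialSet,
    config: AnalysisConfig = _DEFAULT_CFG,
) -> ChangeResult:
    """Percent change in mean HI-TT coherence at the stimulation frequency.

    Trial-averaged magnitude-squared coherence is computed separately on
    the pre and during windows over the post-QC intersection of the two
    channels' trials; the value is the mean msc over bins within ±0.5 Hz
    of the stimulation frequency.
    """
    common, hi_idx, tt_idx = np.intersect1d(
        hi.trial_ids, tt.trial_ids, return_indices=True
    )
    if len(common) < 2:
        raise ValueError(
            f"need at least two common trials across channels, got {len(common)}"
        )
    band = _stim_band(hi, config)
    tapers = spectral.compute_tapers(hi.pre.shape[1], config.nw, config.k)
    c_pre = spectral.band_mean_coherence(
        spectral.trial_coherence(hi.pre[hi_idx], tt.pre[tt_idx], hi.fs, tapers),
        band)
    c_dur = spectral.band_mean_coherence(
        spectral.trial_coherence(hi.during[hi_idx], tt.during[tt_idx], hi.fs, tapers),
        band)
    return ChangeResult(
        animal_id=hi.animal_id, genotype=hi.genotype, location="HI-TT",
        stim_freq=hi.stim_freq, measure="coherence",
        baseline_value=c_pre, light_value=c_dur,
        percent_change=100.0 * (c_dur - c_pre) / c_pre,
        n_trials=len(common),
    )


def dominant_theta_frequency(
    trials: AlignedTrialSet, window: str = "pre",
    config: AnalysisConfig = _DEFAULT_CFG,
) -> float:
    """Dominant frequency (Hz) within the theta band of the trial-mean PSD.

    The peak bin of the trial-averaged spectrum over 5-12 Hz is refined by
    three-point parabolic interpolation. Exact ties break to the lower
    frequency (logged); a flat spectrum is returned with a low-confidence
    warning.
    """
    data = trials.pre if window == "pre" else trials.during
    tapers = spectral.compute_tapers(data.shape[1], config.nw, config.k)
    spec = spectral.trial_psd(data, trials.fs, tapers, pad=config.pad)
    lo, hi = config.theta_band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    freqs = spec.freqs[mask]
    dens = spec.density[mask]
    peak = dens.max()
    if np.all(dens == dens[0]):
        logger.warning("flat spectrum in %g-%g Hz: dominant frequency is "
                       "low-confidence", lo, hi)
        return float(freqs[0])
    if (dens == peak).sum() > 1:
        logger.info("tied spectral peaks; returning the lower frequency")
    i = int(np.argmax(dens))  # first occurrence = lower frequency on ties
    # Parabolic refinement over the spectral main lobe around the peak bin.
    # The multitaper lobe is ~flat over ±NW/T Hz, so a three-point parabola
    # is ill-conditioned; fitting the quadratic across the whole lobe
    # recovers the lobe center accurately.
    lobe_hw = config.nw / (data.shape[1] / trials.fs)
    near = np.abs(freqs - freqs[i]) <= lobe_hw
    if near.sum() >= 3:
        coef = np.polyfit(freqs[near] - freqs[i], dens[near], 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2 * coef[0])
            if abs(vertex) <= lobe_hw:
                return float(np.clip(freqs[i] + vertex, lo, hi))
    return float(freqs[i])


def average_trace(
    trials: AlignedTrialSet, filtered: bool = False,
    config: AnalysisConfig = _DEFAULT_CFG,
) -> np.ndarray:
    """Point-wise trial mean of the concatenated pre+during trace.

    With ``filtered``, each trial is theta-bandpassed (zero phase) before
    averaging — the visualization used to show phase alignment to light.
    Phase-locked oscillations survive the average; phase-random ones
    cancel.
    """
    if trials.n_trials < 1:
        raise ValueError("no trials")
    traces = np.concatenate([trials.pre, trials.during], axis=1)
    if filtered:
        traces = np.array([
            spectral.bandpass_theta(row, trials.fs, config.theta_band)
            for row in traces
        ])
    return traces.mean(axis=0)


def differential_spectrogram(
    trials: AlignedTrialSet, config: AnalysisConfig = _DEFAULT_CFG
) -> DifferentialSpectrogram:
    """Percent-increase spectrogram of the during window over baseline.

    The trial-averaged moving spectrogram (1 s window, 0.1 s step) of the
    pre window is averaged over time into a per-frequency baseline vector;
    the during-window spectrogram is then expressed per bin as a percent
    increase over that vector. Zero-baseline bins are NaN-flagged and
    excluded from maxima.
    """
    if trials.n_trials < 1:
        raise ValueError("no trials")
    kwargs = dict(nw=config.nw, k=config.k,
                  window=config.spectrogram_window, step=config.spectrogram_step)
    g_pre = spectral.trial_spectrogram(trials.pre, trials.fs, **kwargs)
    g_dur = spectral.trial_spectrogram(trials.during, trials.fs, **kwargs)
    baseline = g_pre.power.mean(axis=0)  # per-frequency
    flagged = np.flatnonzero(baseline == 0)
    if len(flagged):
        logger.warning("%d zero-baseline frequency bins flagged", len(flagged))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (g_dur.power - baseline) / baseline
    pct[:, flagged] = np.nan
    return DifferentialSpectrogram(
        window_centers=g_dur.window_centers, freqs=g_dur.freqs,
        percent_increase=pct, flagged_bins=flagged,
    )


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def genotype_summary(results: list[ChangeResult]) -> pd.DataFrame:
    """Per-genotype × stimulation-frequency summary of per-animal changes.

    One input row per animal × frequency (changes are computed per animal,
    never pooled across animals at the trial level). Output columns: mean,
    SD, SEM and n per cell — a table ready for external inferential tests.
    """
    if not results:
        raise ValueError("no results")
    df = pd.DataFrame([{
        "animal_id": r.animal_id, "genotype": r.genotype,
        "location": r.location, "stim_freq": r.stim_freq,
        "measure": r.measure, "percent_change": r.percent_change,
        "n_trials": r.n_trials,
    } for r in results])
    grouped = df.groupby(["measure", "location", "genotype", "stim_freq"])
    out = grouped["percent_change"].agg(["mean", "std", "count"]).reset_index()
    out["sem"] = out["std"] / np.sqrt(out["count"])
    return out.rename(columns={"count": "n"})


# ---------------------------------------------------------------------------
# Whole-session convenience chain
# ---------------------------------------------------------------------------

def analyze_session(
    hi: LFPRecording, tt: LFPRecording, events: list[StimEvent],
    config: AnalysisConfig = _DEFAULT_CFG,
    theta_only: bool = False,
) -> dict:
    """Run the full per-animal chain for every stimulation frequency.

    Align → range-rule QC → (optional) theta selection → power change per
    channel, coherence change, dominant frequencies. Returns a dict with
    ``results`` (list of :class:`ChangeResult`), ``qc`` reports and the
    per-frequency trial funnel (aligned → kept → theta-selected).
    """
    freqs = sorted({e.frequency for e in events})
    results: list[ChangeResult] = []
    qc_reports: dict[float, dict] = {}
    funnel: list[dict] = []
    for f in freqs:
        onsets = [e for e in events if e.frequency == f]
        t_hi = build_trials(hi, onsets, stim_freq=f,
                            pre=config.pre_window, during=config.during_window)
        t_tt = build_trials(tt, onsets, stim_freq=f,
                            pre=config.pre_window, during=config.during_window)
        t_hi, qc_hi = reject_artifact_trials(t_hi, config)
        t_tt, qc_tt = reject_artifact_trials(t_tt, config)
        qc_reports[f] = {"HI": qc_hi, "TT": qc_tt}
        n_aligned = len(onsets)
        n_kept = t_hi.n_trials
        n_theta = None
        if theta_only:
            sel = select_theta_trials(t_hi, config)
            n_theta = len(sel.selected)
            if n_theta == 0:
                funnel.append({"stim_freq": f, "aligned": n_aligned,
                               "kept": n_kept, "theta": 0})
                continue
            t_hi = t_hi.subset(sel.selected)
            keep_tt = np.flatnonzero(np.isin(t_tt.trial_ids, t_hi.trial_ids))
            t_tt = t_tt.subset(keep_tt)
        results.append(power_change_at_stim(t_hi, config))
        results.append(power_change_at_stim(t_tt, config))
        if min(t_hi.n_trials, t_tt.n_trials) >= 2:
            results.append(coherence_change_at_stim(t_hi, t_tt, config))
        funnel.append({"stim_freq": f, "aligned": n_aligned,
                       "kept": n_kept, "theta": n_theta})
    for row in funnel:
        logger.info("animal %s @ %.3g Hz: aligned %d → kept %d → theta %s",
                    hi.animal_id, row["stim_freq"], row["aligned"],
                    row["kept"], row["theta"])
    return {"results": results, "qc": qc_reports, "funnel": funnel}
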