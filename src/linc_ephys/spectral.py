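"""Multitaper spectral estimation for LFP analysis.

Power spectra, trial-averaged magnitude-squared coherence, moving-window
spectrograms, band powers, the theta/delta state ratio and a zero-phase
theta bandpass. All estimates average over orthonormal DPSS (Slepian)
tapers, which trades a controlled amount of spectral bandwidth for a large
variance reduction relative to a single periodogram — the standard approach
for short (seconds-long) field-potential segments.

Conventions
-----------
* One-sided power spectral density in units²/Hz; interior bins are doubled
  so that ``sum(density) * df`` equals the signal variance (Parseval).
* ``df = fs / n`` — no zero padding by default; padding is an explicit
  argument and changes the bin centers, which is recorded in the result.
* Band limits are closed intervals over bin centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: Theta band (Hz) used for state detection and bandpass visualization.
THETA_BAND = (5.0, 12.0)
#: Delta band (Hz) used for state detection.
DELTA_BAND = (1.0, 3.0)
#: Default time-bandwidth product and taper count. The estimates in this
#: package always record the taper settings used because they determine the
#: spectral bandwidth (±NW/T Hz) of every quantity downstream.
DEFAULT_NW = 3.0
DEFAULT_K = 5


# ---------------------------------------------------------------------------
# Tapers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaperSet:
    """K orthonormal DPSS tapers of length n.

    Attributes
    ----------
    n : int
        Taper length in samples.
    nw : float
        Time-bandwidth product (NW).
    k : int
        Number of tapers.
    tapers : ndarray, shape (k, n)
        Orthonormal taper sequences, ordered by decreasing concentration.
    concentrations : ndarray, shape (k,)
        In-band energy concentration of each taper, in (0, 1), strictly
        decreasing.
    """

    n: int
    nw: float
    k: int
    tapers: np.ndarray = field(repr=False)
    concentrations: np.ndarray = field(repr=False)


def compute_tapers(n: int, nw: float = DEFAULT_NW, k: int = DEFAULT_K) -> TaperSet:
    """Compute a :class:`TaperSet` of ``k`` DPSS tapers of length ``n``.

    Tapers beyond ``2*nw - 1`` have poor in-band concentration; requesting
    more logs a warning but proceeds.
    """
    if n < 8:
        raise ValueError(f"taper length n={n} too short (need n >= 8)")
    if k < 1:
        raise ValueError(f"need at least one taper, got k={k}")
    if k > int(2 * nw) - 1:
        logger.warning(
            "k=%d exceeds 2*NW-1=%d well-concentrated tapers (NW=%g)",
            k, int(2 * nw) - 1, nw,
        )
    tapers, ratios = signal.windows.dpss(
        n, nw, Kmax=k, return_ratios=True, norm=2
    )
    tapers = np.atleast_2d(tapers)
    ratios = np.atleast_1d(ratios)
    return TaperSet(n=n, nw=float(nw), k=k, tapers=tapers, concentrations=ratios)


# ---------------------------------------------------------------------------
# Power spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided multitaper power spectral density."""

    freqs: np.ndarray
    density: np.ndarray
    df: float
    n_tapers: int
    n_trials: int = 1

    def __post_init__(self) -> None:
        if self.freqs.shape != self.density.shape:
            raise ValueError("freqs and density must have the same shape")


def _eigenspectra(x: np.ndarray, fs: float, tapers: TaperSet, nfft: int) -> np.ndarray:
    """Complex per-taper spectra of shape (..., k, n_freqs), one-sided."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != tapers.n:
        raise ValueError(
            f"series length {x.shape[-1]} does not match taper length {tapers.n}"
        )
    tapered = x[..., np.newaxis, :] * tapers.tapers
    return np.fft.rfft(tapered, n=nfft, axis=-1)


def _onesided_scale(nfft: int, fs: float) -> np.ndarray:
    """Density scale per rfft bin; interior bins doubled to fold negatives."""
    n_freqs = nfft // 2 + 1
    scale = np.full(n_freqs, 2.0 / fs)
    scale[0] = 1.0 / fs
    if nfft % 2 == 0:
        scale[-1] = 1.0 / fs
    return scale


def multitaper_psd(
    x: np.ndarray, fs: float, tapers: TaperSet, pad: int = 0
) -> PowerSpectrum:
    """Multitaper PSD of one segment: the mean of K eigenspectra.

    Parameters
    ----------
    x : array, shape (n,)
        Sample series; must match the taper length.
    fs : float
        Sampling rate in Hz.
    tapers : TaperSet
    pad : int
        Zero padding: FFT length is ``next_pow2(n) * 2**pad`` when > 0,
        else exactly ``n`` (``df = fs/n``).
    """
    nfft = tapers.n if pad <= 0 else int(2 ** (np.ceil(np.log2(tapers.n)) + pad - 1))
    if nfft < tapers.n:
        nfft = tapers.n
    spectra = _eigenspectra(x, fs, tapers, nfft)
    psd = (np.abs(spectra) ** 2).mean(axis=-2) * _onesided_scale(nfft, fs)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(
        freqs=freqs, density=psd, df=fs / nfft, n_tapers=tapers.k, n_trials=1
    )


def trial_psd(
    trials: np.ndarray, fs: float, tapers: TaperSet, pad: int = 0
) -> PowerSpectrum:
    """Trial-averaged multitaper PSD over a (n_trials, n_samples) matrix."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] == 0:
        raise ValueError("no trials supplied")
    nfft = tapers.n if pad <= 0 else int(2 ** (np.ceil(np.log2(tapers.n)) + pad - 1))
    if nfft < tapers.n:
        nfft = tapers.n
    spectra = _eigenspectra(trials, fs, tapers, nfft)
    psd = (np.abs(spectra) ** 2).mean(axis=(0, 1)) * _onesided_scale(nfft, fs)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(
        freqs=freqs, density=psd, df=fs / nfft,
        n_tapers=tapers.k, n_trials=trials.shape[0],
    )


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoherenceSpectrum:
    """Trial-averaged magnitude-squared coherence between two channels."""

    freqs: np.ndarray
    msc: np.ndarray
    n_trials: int
    n_tapers: int


def trial_coherence(
    x_trials: np.ndarray, y_trials: np.ndarray, fs: float, tapers: TaperSet
) -> CoherenceSpectrum:
    """Magnitude-squared coherence pooled over tapers and trials.

    msc(f) = |<X Y*>|² / (<|X|²> <|Y|²>), the average taken jointly over
    the K tapers and all trials. The estimator is biased upward by roughly
    1/(n_trials * k) for independent signals; trial counts matter.
    """
    x_trials = np.atleast_2d(np.asarray(x_trials, dtype=float))
    y_trials = np.atleast_2d(np.asarray(y_trials, dtype=float))
    if x_trials.shape != y_trials.shape:
        raise ValueError(
            f"trial matrices differ in shape: {x_trials.shape} vs {y_trials.shape}"
        )
    if x_trials.shape[0] == 0:
        raise ValueError("no trials supplied")
    nfft = tapers.n
    sx = _eigenspectra(x_trials, fs, tapers, nfft)
    sy = _eigenspectra(y_trials, fs, tapers, nfft)
    cross = (sx * np.conj(sy)).mean(axis=(0, 1))
    auto_x = (np.abs(sx) ** 2).mean(axis=(0, 1))
    auto_y = (np.abs(sy) ** 2).mean(axis=(0, 1))
    denom = auto_x * auto_y
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.where(denom > 0, np.abs(cross) ** 2 / denom, 0.0)
    msc = np.clip(msc, 0.0, 1.0)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return CoherenceSpectrum(
        freqs=freqs, msc=msc, n_trials=x_trials.shape[0], n_tapers=tapers.k
    )


# ---------------------------------------------------------------------------
# Band powers and state ratio
# ---------------------------------------------------------------------------

def bandpower(spec: PowerSpectrum, band: tuple[float, float]) -> float:
    """Integrated power (units²) over bins whose center lies in the closed band."""
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band [{lo}, {hi}] is empty or inverted")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"no spectral bins in band [{lo}, {hi}] Hz at resolution df={spec.df} Hz"
        )
    return float(spec.density[mask].sum() * spec.df)


def band_mean_coherence(coh: CoherenceSpectrum, band: tuple[float, float]) -> float:
    """Mean msc over bins whose center lies in the closed band."""
    lo, hi = band
    df = coh.freqs[1] - coh.freqs[0]
    mask = (coh.freqs >= lo) & (coh.freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"no coherence bins in band [{lo}, {hi}] Hz at resolution df={df} Hz"
        )
    return float(coh.msc[mask].mean())


def theta_delta_ratio(
    x: np.ndarray, fs: float,
    nw: float = DEFAULT_NW, k: int = DEFAULT_K,
    theta: tuple[float, float] = THETA_BAND,
    delta: tuple[float, float] = DELTA_BAND,
) -> float:
    """Theta (5-12 Hz) to delta (1-3 Hz) band-power ratio of one segment.

    The ratio indexes hippocampal brain state: movement/arousal theta states
    score high, quiet rest and slow-wave states score low. Returns +inf when
    the delta band carries no power.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("segment shorter than 2 s: delta band unresolvable")
    tapers = compute_tapers(len(x), nw, k)
    spec = multitaper_psd(x, fs, tapers)
    p_delta = bandpower(spec, delta)
    p_theta = bandpower(spec, theta)
    if p_delta == 0.0:
        logger.warning("zero delta-band power; theta/delta ratio is infinite")
        return float("inf")
    return p_theta / p_delta


# ---------------------------------------------------------------------------
# Spectrogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrogram:
    """Moving-window multitaper spectrogram (time x frequency power matrix)."""

    window_centers: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # shape (n_windows, n_freqs), units²/Hz
    window: float
    step: float


def moving_spectrogram(
    x: np.ndarray, fs: float,
    nw: float = DEFAULT_NW, k: int = DEFAULT_K,
    window: float = 1.0, step: float = 0.1,
) -> Spectrogram:
    """Multitaper spectrogram with a moving window (default 1 s, step 0.1 s).

    Column count is ``floor((T - window)/step) + 1`` with T the trace
    duration; each column is the multitaper PSD of its window.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_win = int(round(window * fs))
    n_step = step * fs
    if n < n_win:
        raise ValueError(
            f"trace of {n / fs:.3f} s shorter than the {window} s window"
        )
    n_cols = int(np.floor((n - n_win) / n_step + 1e-9)) + 1
    tapers = compute_tapers(n_win, nw, k)
    starts = np.round(np.arange(n_cols) * n_step).astype(int)
    rows = []
    for s in starts:
        rows.append(multitaper_psd(x[s:s + n_win], fs, tapers).density)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    centers = (starts + n_win / 2) / fs
    return Spectrogram(
        window_centers=centers, freqs=freqs, power=np.array(rows),
        window=window, step=step,
    )


def trial_spectrogram(
    trials: np.ndarray, fs: float,
    nw: float = DEFAULT_NW, k: int = DEFAULT_K,
    window: float = 1.0, step: float = 0.1,
) -> Spectrogram:
    """Trial-averaged moving spectrogram over a (n_trials, n_samples) matrix."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] == 0:
        raise ValueError("no trials supplied")
    grams = [moving_spectrogram(t, fs, nw, k, window, step) for t in trials]
    power = np.mean([g.power for g in grams], axis=0)
    g0 = grams[0]
    return Spectrogram(
        window_centers=g0.window_centers, freqs=g0.freqs, power=power,
        window=window, step=step,
    )


# ---------------------------------------------------------------------------
# Theta bandpass
# ---------------------------------------------------------------------------

def bandpass_theta(
    x: np.ndarray, fs: float, band: tuple[float, float] = THETA_BAND
) -> np.ndarray:
    """Zero-phase FIR bandpass to the theta range (default 5-12 Hz).

    An even-order FIR filter applied forward-backward (``filtfilt``), so the
    output has no phase shift — required when the filtered traces are used to
    visualize phase alignment to light pulses. Output length equals input
    length.
    """
    lo, hi = band
    nyq = fs / 2
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    if fs <= 2 * hi:
        raise ValueError("sampling rate too low for the requested band")
    # Transition width ~1 Hz: order ~ 3.3 * fs / width, rounded up to even.
    numtaps = int(np.ceil(3.3 * fs / 1.0)) // 2 * 2 + 1
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    padlen = min(len(x) - 1, 3 * numtaps)
    return signal.filtfilt(taps, [1.0], np.asarray(x, dtype=float), padlen=padlen)
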