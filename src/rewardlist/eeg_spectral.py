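"""Spectral and ERP feature extraction.

Power-scaling convention (used by both the static spectrum and the
time-frequency decomposition): with taper w over an N-sample window, the
amplitude at analysis frequency f is ``a = 2|sum_n w_n x_n e^{-i 2 pi f n /
srate}| / sum_n w_n`` (taper-gain compensated, single-sided; the factor 2 is
dropped at DC and Nyquist), and power is ``a^2 / 2`` — the mean-square power
of a sinusoid of amplitude a, so doubling the amplitude quadruples power and
a pure tone of amplitude A at a bin center yields bin power A^2/2 in µV².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_data import (
    CONDITIONS,
    EpochedEEG,
    SubjectConditionTable,
    time_window_mask,
)

__all__ = [
    "PowerSpectrum",
    "TFR",
    "ERPSet",
    "baseline_subtract",
    "psd_hanning",
    "extract_ssvep",
    "tfr_hanning",
    "db_baseline",
    "bandstop_fir",
    "erp_average",
    "find_ssvep_peak",
    "grand_average_tfr",
]


def _group_keys(eeg: EpochedEEG):
    """Sorted (subject, condition) groups with trial index arrays."""
    keys: dict[tuple[str, str], list[int]] = {}
    for i, (s, c) in enumerate(zip(eeg.trial_subject, eeg.trial_condition)):
        keys.setdefault((str(s), str(c)), []).append(i)
    return {k: np.array(v) for k, v in sorted(keys.items())}


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------


def baseline_subtract(eeg: EpochedEEG, window_ms=(-500.0, 0.0)) -> EpochedEEG:
    """Subtract the per-trial, per-channel mean of the baseline window."""
    mask = time_window_mask(eeg.times, *window_ms)
    base = eeg.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(eeg, data=(eeg.data - base).astype(np.float32))


# ---------------------------------------------------------------------------
# static power spectrum
# ---------------------------------------------------------------------------


@dataclass
class PowerSpectrum:
    """Single-sided power (µV²) and amplitude (µV) spectra per
    (subject, condition) group, channels x frequency bins."""

    freqs: np.ndarray
    power: dict[tuple[str, str], np.ndarray]  # (ch, n_freqs)
    channel_names: list[str]
    window_ms: tuple[float, float]
    taper: str = "hann"

    def amplitude(self) -> dict[tuple[str, str], np.ndarray]:
        return {k: np.sqrt(2.0 * p) for k, p in self.power.items()}


def _taper(name: str, n: int) -> np.ndarray:
    if name == "hann":
        return sps.windows.hann(n, sym=False)
    if name in ("boxcar", "rectangular"):
        return np.ones(n)
    raise ValueError(f"unknown taper {name!r}")


def _windowed_power(segments: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Single-sided power of DFT bins for real segments (..., N).

    Interior bins carry a^2/2 (sinusoid mean-square); the unpaired DC and
    Nyquist bins carry a^2, which makes the rectangular-window total equal
    the signal's mean square (Parseval).
    """
    n = segments.shape[-1]
    X = np.fft.rfft(segments * w, axis=-1)
    amp = np.abs(X) * (2.0 / w.sum())
    amp[..., 0] /= 2.0
    if n % 2 == 0:
        amp[..., -1] /= 2.0
    power = amp**2 / 2.0
    power[..., 0] *= 2.0
    if n % 2 == 0:
        power[..., -1] *= 2.0
    return power


def psd_hanning(
    eeg: EpochedEEG,
    window_ms=(1000.0, 2000.0),
    taper: str = "hann",
) -> PowerSpectrum:
    """Tapered FFT power in a fixed window, averaged per (subject, condition).

    Frequency resolution is 1 / window length; power follows the package
    scaling convention (module docstring).
    """
    mask = time_window_mask(eeg.times, *window_ms)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    w = _taper(taper, n)
    freqs = np.fft.rfftfreq(n, d=1.0 / eeg.srate)
    power = {}
    for key, idx in _group_keys(eeg).items():
        seg = eeg.data[idx][:, :, mask].astype(float)
        power[key] = _windowed_power(seg, w).mean(axis=0)
    return PowerSpectrum(freqs, power, list(eeg.channel_names), tuple(window_ms), taper)


def extract_ssvep(
    spectrum: PowerSpectrum,
    band_hz=(14.0, 15.0),
    channel: str = "Oz",
    scale: str = "amplitude",
) -> SubjectConditionTable:
    """Mean spectral value over the bins whose center lies in ``band_hz``
    (inclusive) at one channel, per subject x condition.

    ``scale`` selects amplitude (µV, default) or power (µV²) values.
    """
    try:
        ch = spectrum.channel_names.index(channel)
    except ValueError:
        raise KeyError(f"unknown channel {channel!r}") from None
    bins = np.flatnonzero(
        (spectrum.freqs >= band_hz[0] - 1e-9) & (spectrum.freqs <= band_hz[1] + 1e-9)
    )
    if bins.size == 0:
        raise ValueError(f"no frequency bins inside {band_hz}")
    values = spectrum.amplitude() if scale == "amplitude" else spectrum.power
    cells: dict[str, dict[str, float]] = {}
    for (subj, cond), arr in values.items():
        cells.setdefault(subj, {})[cond] = float(arr[ch, bins].mean())
    data = pd.DataFrame.from_dict(cells, orient="index").reindex(columns=list(CONDITIONS))
    data.index.name = "subject_id"
    units = "uV" if scale == "amplitude" else "uV^2"
    return SubjectConditionTable(f"ssvep_{scale}_{channel}", units, data.sort_index())


# ---------------------------------------------------------------------------
# time-frequency decomposition
# ---------------------------------------------------------------------------


@dataclass
class TFR:
    """channels x frequencies x times power per (subject, condition) group.

    Time points whose analysis window exceeds the epoch are NaN. ``units`` is
    ``uV^2`` (raw) or ``dB`` after baseline normalization.
    """

    freqs: np.ndarray
    times: np.ndarray  # ms
    power: dict[tuple[str, str], np.ndarray]  # (ch, n_freqs, n_times)
    channel_names: list[str]
    units: str = "uV^2"
    cycles: float = 5.0
    baseline_ms: tuple[float, float] | None = None


def tfr_hanning(
    eeg: EpochedEEG,
    freqs=None,
    step_ms: float = 50.0,
    cycles: float = 5.0,
) -> TFR:
    """Sliding-window Hann-tapered time-frequency power.

    At each analysis frequency f the window spans ``cycles / f`` seconds,
    centered on each time step; per-trial power is averaged within each
    (subject, condition) group. Defaults: 4-30 Hz in 1 Hz steps, 50 ms time
    steps, five cycles.
    """
    freqs = np.asarray(freqs if freqs is not None else np.arange(4.0, 31.0), dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= eeg.srate / 2):
        raise ValueError("frequencies must lie in (0, srate/2)")
    times_all = eeg.times
    n_samples = times_all.size
    dt_ms = 1000.0 / eeg.srate
    # time grid aligned on stimulus onset (t = 0) at step_ms spacing
    t_first = np.ceil(times_all[0] / step_ms) * step_ms
    grid = np.arange(t_first, times_all[-1] + dt_ms / 2, step_ms)
    centers = np.round((grid - times_all[0]) / dt_ms).astype(int)

    groups = _group_keys(eeg)
    power = {
        key: np.full((eeg.data.shape[1], freqs.size, grid.size), np.nan)
        for key in groups
    }
    for fi, f in enumerate(freqs):
        L = int(round(cycles * eeg.srate / f))
        w = _taper("hann", L)
        phase = np.exp(-2j * np.pi * f * np.arange(L) / eeg.srate)
        kernel = (w * phase) * (2.0 / w.sum())
        starts = centers - L // 2
        valid = (starts >= 0) & (starts + L <= n_samples)
        for key, idx in groups.items():
            block = eeg.data[idx].astype(float)  # (trials, ch, samples)
            for ti in np.flatnonzero(valid):
                seg = block[:, :, starts[ti] : starts[ti] + L]
                amp = np.abs(seg @ kernel)
                power[key][:, fi, ti] = (amp**2 / 2.0).mean(axis=0)
    return TFR(freqs, grid, power, list(eeg.channel_names), "uV^2", cycles)


def db_baseline(tfr: TFR, baseline_ms=(-700.0, -200.0)) -> TFR:
    """Normalize power to dB relative to the pre-stimulus baseline.

    Per channel x frequency (within each subject x condition group):
    ``10 * log10(P(t) / mean baseline P)``.
    """
    if tfr.units != "uV^2":
        raise ValueError("db_baseline expects raw (uV^2) power")
    mask = (tfr.times >= baseline_ms[0]) & (tfr.times < baseline_ms[1])
    if not mask.any():
        raise ValueError(f"baseline window {baseline_ms} contains no time points")
    out = {}
    for key, P in tfr.power.items():
        base = np.nanmean(P[:, :, mask], axis=2, keepdims=True)
        if np.any(np.isnan(base)) or np.any(base <= 0):
            raise ValueError("baseline power missing or non-positive")
        with np.errstate(invalid="ignore", divide="ignore"):
            out[key] = 10.0 * np.log10(P / base)
    return replace(tfr, power=out, units="dB", baseline_ms=tuple(baseline_ms))


def grand_average_tfr(tfr: TFR) -> np.ndarray:
    """Average the TFR over all (subject, condition) groups -> (ch, F, T)."""
    stack = np.stack(list(tfr.power.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge columns
        return np.nanmean(stack, axis=0)


def find_ssvep_peak(
    tfr: TFR, band_hz=(14.0, 15.0), drop_db: float = 3.0
) -> tuple[str, tuple[float, float]]:
    """Channel and contiguous time window where the flicker response peaks.

    Averages the condition-and-subject grand-average dB power over the
    stimulation band, locates the maximum (channel, time) cell, and expands a
    contiguous window around it over time points within ``drop_db`` of the
    peak. Ties are broken toward the lowest channel index, then the earliest
    window.
    """
    ga = grand_average_tfr(tfr)  # (ch, F, T)
    fmask = (tfr.freqs >= band_hz[0] - 1e-9) & (tfr.freqs <= band_hz[1] + 1e-9)
    if not fmask.any():
        raise ValueError(f"no frequencies inside {band_hz}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        band = np.nanmean(ga[:, fmask, :], axis=1)  # (ch, T)
    if np.all(np.isnan(band)):
        raise ValueError("time-frequency input is all-missing")
    flat = np.where(np.isnan(band), -np.inf, band)
    ch, t_peak = np.unravel_index(np.argmax(flat), flat.shape)
    peak = flat[ch, t_peak]
    above = flat[ch] >= peak - drop_db
    lo = t_peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = t_peak
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    return tfr.channel_names[int(ch)], (float(tfr.times[lo]), float(tfr.times[hi]))


# ---------------------------------------------------------------------------
# band-stop filtering and ERP averaging
# ---------------------------------------------------------------------------


def _bandstop_kernel(
    stopbands, srate: float, numtaps: int = 1651, edge_hz: float = 0.25
) -> np.ndarray:
    """Symmetric multiband windowed-sinc band-stop kernel (Hamming window).

    Band edges are widened by ``edge_hz`` so that the nominal stopband
    interior (e.g. the 14.17 Hz flicker line inside a 14-15 Hz stopband) sits
    past the transition region; measured attenuation there exceeds 30 dB
    while passband ripple at 5 and 40 Hz stays below 0.1 dB.
    """
    cutoffs = []
    for lo, hi in stopbands:
        if not 0 < lo < hi < srate / 2:
            raise ValueError(f"stopband ({lo}, {hi}) outside (0, Nyquist)")
        cutoffs.extend([lo - edge_hz, hi + edge_hz])
    return sps.firwin(numtaps, cutoffs, fs=srate, window="hamming", pass_zero=True)


def bandstop_fir(
    eeg: EpochedEEG,
    stopbands=((14.0, 15.0), (28.0, 29.0)),
    numtaps: int = 1651,
) -> EpochedEEG:
    """Zero-phase band-stop filtering with a symmetric windowed-sinc kernel.

    The default stopbands remove the flicker line and its resonance before
    ERP analysis. Epoch edges are reflect-padded by half the kernel length.
    """
    if numtaps % 2 == 0:
        raise ValueError("numtaps must be odd (symmetric zero-phase kernel)")
    n = eeg.data.shape[2]
    half = numtaps // 2
    if half >= n:
        raise ValueError("epoch shorter than the filter kernel")
    h = _bandstop_kernel(stopbands, eeg.srate, numtaps)
    padded = np.concatenate(
        [eeg.data[:, :, half:0:-1], eeg.data, eeg.data[:, :, -2 : -half - 2 : -1]],
        axis=2,
    ).astype(float)
    out = np.empty_like(eeg.data)
    for lo in range(0, padded.shape[0], 32):  # chunk trials to bound FFT memory
        out[lo : lo + 32] = sps.fftconvolve(
            padded[lo : lo + 32], h[None, None, :], mode="valid", axes=2
        ).astype(np.float32)
    return replace(eeg, data=out)


@dataclass
class ERPSet:
    """Per-(subject, condition) trial-average waveforms (µV), baselined."""

    times: np.ndarray
    erp: dict[tuple[str, str], np.ndarray]  # (ch, samples)
    n_trials: dict[tuple[str, str], int]
    channel_names: list[str]
    baseline_ms: tuple[float, float]


def erp_average(eeg: EpochedEEG, baseline_ms=(-200.0, 0.0)) -> ERPSet:
    """Baseline-correct and average trials per (subject, condition)."""
    corrected = baseline_subtract(eeg, baseline_ms)
    groups = _group_keys(corrected)
    if not groups:
        raise ValueError("no trials to average")
    erp = {k: corrected.data[idx].mean(axis=0) for k, idx in groups.items()}
    n = {k: int(idx.size) for k, idx in groups.items()}
    return ERPSet(corrected.times, erp, n, list(eeg.channel_names), tuple(baseline_ms))
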