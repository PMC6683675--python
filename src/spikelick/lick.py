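"""Spike-lick coherence, lick-relation cell classification, and licking
microstructure metrics.

Coherence is magnitude-squared coherence between the two point processes
binned at 1 ms, estimated with Welch segment averaging; the summary value is
the maximum over the 4-9 Hz licking band.  Phase-locking significance uses a
circular time-shift null of the spike train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    CoherenceResult,
    LickTrain,
    ResponseResult,
    Session,
    SpikeTrain,
)

BAND = (4.0, 9.0)


def _bin_events(times: np.ndarray, duration: float, fs: float) -> np.ndarray:
    n = int(round(duration * fs))
    x = np.zeros(n)
    idx = np.floor(times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(x, idx, 1.0)
    return x


def _segment_fft(x: np.ndarray, nperseg: int, noverlap: int) -> np.ndarray:
    """Hann-windowed, constant-detrended rFFT of Welch segments."""
    from scipy.signal import get_window

    step = nperseg - noverlap
    nseg = (len(x) - noverlap) // step
    if nseg < 1:
        raise ValueError("data shorter than one spectral segment")
    idx = np.arange(nperseg)[None, :] + step * np.arange(nseg)[:, None]
    segs = x[idx]
    segs = segs - segs.mean(axis=1, keepdims=True)
    win = get_window("hann", nperseg)
    return np.fft.rfft(segs * win, axis=1)


class CoherenceEstimator:
    """Welch magnitude-squared coherence against a fixed lick train.

    Caches the lick-train segment spectra, so computing coherence for many
    units (or many circular shifts) of one session costs one FFT batch per
    spike train instead of two.
    """

    def __init__(
        self,
        licks: LickTrain,
        duration: float,
        fs: float = 1000.0,
        nperseg: int = 4096,
        noverlap: int | None = None,
        band: tuple[float, float] = BAND,
    ):
        if duration < 60.0:
            raise ValueError("lick_coherence requires >= 60 s of concurrent data")
        self.fs, self.nperseg = fs, nperseg
        self.noverlap = nperseg // 2 if noverlap is None else noverlap
        self.duration, self.band = duration, band
        y = _bin_events(licks.times, duration, fs)
        self._Y = _segment_fft(y, nperseg, self.noverlap)
        self._Pyy = np.mean(np.abs(self._Y) ** 2, axis=0)
        self.freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
        self._in_band = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not np.any(self._in_band):
            raise ValueError("no frequency bins inside the licking band")

    def compute(self, spike_times: np.ndarray) -> CoherenceResult:
        x = _bin_events(spike_times, self.duration, self.fs)
        X = _segment_fft(x, self.nperseg, self.noverlap)
        Pxx = np.mean(np.abs(X) ** 2, axis=0)
        Pxy = np.mean(X * np.conj(self._Y), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cxy = np.abs(Pxy) ** 2 / (Pxx * self._Pyy)
        cxy = np.clip(np.nan_to_num(cxy), 0.0, 1.0)
        k = int(np.argmax(np.where(self._in_band, cxy, -1.0)))
        return CoherenceResult(self.freqs, cxy, float(cxy[k]), float(self.freqs[k]))


def lick_coherence(
    spikes: SpikeTrain,
    licks: LickTrain,
    duration: float,
    fs: float = 1000.0,
    nperseg: int = 4096,
    noverlap: int | None = None,
    band: tuple[float, float] = BAND,
) -> CoherenceResult:
    """Magnitude-squared spike-lick coherence with its 4-9 Hz peak."""
    est = CoherenceEstimator(licks, duration, fs, nperseg, noverlap, band)
    return est.compute(spikes.times)


def coherence_shift_null(
    spikes: SpikeTrain,
    licks: LickTrain,
    duration: float,
    n_shifts: int = 200,
    rng: np.random.Generator | int | None = None,
    min_shift: float = 1.0,
    estimator: "CoherenceEstimator | None" = None,
    **kwargs,
) -> np.ndarray:
    """In-band peak coherence under circular time shifts of the spike train."""
    rng = np.random.default_rng(rng)
    if estimator is None:
        estimator = CoherenceEstimator(licks, duration, **kwargs)
    peaks = np.empty(n_shifts)
    for i in range(n_shifts):
        s = rng.uniform(min_shift, duration - min_shift)
        shifted = np.sort(np.mod(spikes.times + s, duration))
        peaks[i] = estimator.compute(shifted).peak_value
    return peaks


# ---------------------------------------------------------------------------
# Bout-aligned rates and cell classification
# ---------------------------------------------------------------------------

@dataclass
class BoutRates:
    """Firing rate inside bouts, outside bouts, and around bout edges."""

    in_bout: float
    out_bout: float
    peri_bout: float  # +-0.5 s around bout starts/ends, outside the bout
    n_bouts: int


def bout_rates(
    spikes: SpikeTrain, licks: LickTrain, duration: float, peri: float = 0.5
) -> BoutRates:
    spans = licks.bouts()
    t = spikes.times
    if len(spans) == 0:
        rate = len(t) / duration if duration > 0 else 0.0
        return BoutRates(0.0, rate, 0.0, 0)

    in_time = float(np.sum(spans[:, 1] - spans[:, 0]))
    in_count = int(
        sum(
            np.searchsorted(t, b) - np.searchsorted(t, a)
            for a, b in spans
        )
    )
    out_time = max(duration - in_time, 1e-9)
    out_count = len(t) - in_count

    peri_count, peri_time = 0, 0.0
    for a, b in spans:
        for lo, hi in ((a - peri, a), (b, b + peri)):
            lo, hi = max(lo, 0.0), min(hi, duration)
            if hi > lo:
                peri_count += int(np.searchsorted(t, hi) - np.searchsorted(t, lo))
                peri_time += hi - lo
    return BoutRates(
        in_bout=in_count / in_time if in_time > 0 else 0.0,
        out_bout=out_count / out_time,
        peri_bout=peri_count / peri_time if peri_time > 0 else 0.0,
        n_bouts=len(spans),
    )


def classify_cell(
    detection_results: list[ResponseResult],
    coherence_peak: float,
    coherence_threshold: float,
    bouts: BoutRates,
    suppression_ratio: float = 0.75,
    elevation_ratio: float = 1.25,
    peri_ratio: float = 1.1,
    taste_exclude: tuple[str, ...] = ("AS",),
) -> str:
    """Assign one of the six firing-pattern labels.

    Precedence: any significant taste response wins (such cells are labeled
    solely taste-responsive even when lick-modulated); then phase-locked plus
    bout-suppressed -> mix; phase-locked -> lick; bout-suppressed with a
    peri-bout phasic increase -> anti-lick; bout-elevated -> lick-bout;
    otherwise nonresponsive.
    """
    taste = any(
        r.significant and r.stimulus_id not in taste_exclude
        for r in detection_results
    )
    if taste:
        return "taste"
    phase_locked = coherence_peak > coherence_threshold
    suppressed = (
        bouts.n_bouts > 0
        and bouts.out_bout > 0
        and bouts.in_bout < suppression_ratio * bouts.out_bout
    )
    elevated = (
        bouts.n_bouts > 0 and bouts.in_bout > elevation_ratio * max(bouts.out_bout, 1e-9)
    )
    peri_increase = bouts.peri_bout > peri_ratio * max(bouts.in_bout, 1e-9)
    if phase_locked and suppressed:
        return "lick_anti_mix"
    if phase_locked:
        return "lick"
    if suppressed and peri_increase:
        return "anti_lick"
    if elevated:
        return "lick_bout"
    return "nonresponsive"


# ---------------------------------------------------------------------------
# Licking microstructure (per-stimulus behavior table)
# ---------------------------------------------------------------------------

def lick_behavior_metrics(
    session: Session, pause_threshold: float = 1.0
) -> pd.DataFrame:
    """Per-stimulus licking metrics over trials.

    Columns: trials, ili_s (median inter-lick interval among the five
    stimulus licks, pauses excluded), n_pauses (intervals > threshold),
    pause_length_s (median), five_lick_time_s (median first-to-fifth time).
    """
    rows = []
    for stim in session.panel:
        trials = session.trials_for(stim)
        ilis: list[float] = []
        pauses: list[float] = []
        five_times: list[float] = []
        for tr in trials:
            gaps = np.diff(tr.stim_lick_times)
            pa = gaps[gaps > pause_threshold]
            ilis.extend(gaps[gaps <= pause_threshold])
            pauses.extend(pa)
            five_times.append(float(tr.stim_lick_times[-1] - tr.stim_lick_times[0]))
        rows.append(
            dict(
                stimulus_id=stim,
                trials=len(trials),
                ili_s=float(np.median(ilis)) if ilis else math.nan,
                n_pauses=len(pauses),
                pause_length_s=float(np.median(pauses)) if pauses else math.nan,
                five_lick_time_s=float(np.median(five_times)) if five_times else math.nan,
            )
        )
    return pd.DataFrame(rows)
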