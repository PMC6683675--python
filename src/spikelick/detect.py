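"""Firing-rate estimators and sliding-window taste-response detectors.

Two timescales share one detection rule: the trial-averaged firing rate in a
sliding window must sit beyond mean +- 2 SD of the baseline estimate, in the
same direction, for three consecutive windows.  Latency is the trailing edge
of the first significant window; the response ends at the last consecutive
significant window; magnitude is the mean evoked rate over the significant
stretch minus the baseline mean (signed).

* 5-lick responses: 100 ms window, 20 ms step, scanned over 4 s from the
  first stimulus lick of each trial; baseline from the 1 s before that lick.
* lick-by-lick responses: 10 ms window, 2 ms step, scanned over 170 ms from
  every individual stimulus lick; baseline from the 50 ms before each lick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    TRADITIONAL_QUARTET,
    LickTrain,
    RateEstimate,
    ResponseResult,
    Session,
    SpikeTrain,
    Trial,
)

FIVE_LICK = dict(window=0.100, step=0.020, span=4.0)
LICK_BY_LICK = dict(window=0.010, step=0.002, span=0.170)

#: Minimum rate SD (sps) substituted when the baseline SD is exactly zero.
SD_FLOOR_MIN = 0.5

#: Sustained-response thresholds (ms): three full windows per timescale.
#: Minimal-run threshold crossings are overwhelmingly noise at realistic
#: trial counts; cell-level decisions use only sustained responses.
SUSTAINED_MS = {"five_lick": 300.0, "lick_by_lick": 30.0}


def is_sustained(result: "ResponseResult") -> bool:
    """True for significant responses spanning >= three full windows."""
    return bool(
        result.significant
        and result.duration is not None
        and result.duration >= SUSTAINED_MS[result.timescale]
    )


# ---------------------------------------------------------------------------
# Rate estimators
# ---------------------------------------------------------------------------

def spontaneous_rate(
    spikes: SpikeTrain,
    licks: LickTrain,
    duration: float,
    span: float = 14.0,
    settle: float = 3.0,
    measure: float = 10.0,
) -> RateEstimate:
    """Firing rate from lick-free 14 s spans.

    Each lick-free span of at least ``span`` seconds is tiled with
    non-overlapping 14 s windows; the rate is counted over seconds
    [settle, settle + measure) of each window.  Returns a result with
    ``n_windows == 0`` (mean/sd NaN) when no qualifying span exists.
    """
    t = licks.times
    edges = np.concatenate([[0.0], t, [duration]])
    gaps = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    rates = []
    for lo, hi in gaps:
        n_fit = int((hi - lo) // span)
        for k in range(n_fit):
            s = lo + k * span
            c = np.searchsorted(spikes.times, s + settle + measure) - np.searchsorted(
                spikes.times, s + settle
            )
            rates.append(c / measure)
    if not rates:
        return RateEstimate(mean=math.nan, sd=math.nan, n_windows=0)
    arr = np.asarray(rates)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return RateEstimate(float(arr.mean()), sd, len(arr))


def baseline_rate(
    spikes: SpikeTrain, trials: Sequence[Trial], pre: float = 1.0
) -> RateEstimate:
    """Mean/SD of per-trial rates over the ``pre`` seconds before each t0."""
    if len(trials) == 0:
        raise ValueError("baseline_rate requires at least one trial")
    rates = []
    for tr in trials:
        c = np.searchsorted(spikes.times, tr.t0) - np.searchsorted(
            spikes.times, tr.t0 - pre
        )
        rates.append(c / pre)
    arr = np.asarray(rates, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return RateEstimate(float(arr.mean()), sd, len(arr))


# ---------------------------------------------------------------------------
# Sliding-window rule
# ---------------------------------------------------------------------------

def _window_rates(
    aligned: list[np.ndarray], window: float, step: float, span: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled rate (sps) in each [s, s+window) for starts 0, step, ..."""
    starts = np.arange(0.0, span - window + step / 2, step)
    pooled = np.sort(np.concatenate(aligned)) if aligned else np.array([])
    lo = np.searchsorted(pooled, starts)
    hi = np.searchsorted(pooled, starts + window)
    rates = (hi - lo) / (len(aligned) * window)
    return starts, rates


def _sliding_detect(
    aligned: list[np.ndarray],
    base_mean: float,
    base_sd: float,
    window: float,
    step: float,
    span: float,
    stimulus_id: str,
    timescale: str,
    n_consecutive: int = 3,
    edge: str = "trailing",
) -> ResponseResult:
    sd_floored = False
    if base_sd == 0.0:
        # Poisson floor on the window-rate SD, never below SD_FLOOR_MIN
        base_sd = max(math.sqrt(max(base_mean, 0.0) / (len(aligned) * window)),
                      SD_FLOOR_MIN)
        sd_floored = True

    starts, rates = _window_rates(aligned, window, step, span)
    hi = base_mean + 2.0 * base_sd
    lo = base_mean - 2.0 * base_sd
    sig = np.where(rates > hi, 1, np.where(rates < lo, -1, 0))

    onset = None
    for i in range(len(sig) - n_consecutive + 1):
        d = sig[i]
        if d != 0 and np.all(sig[i:i + n_consecutive] == d):
            onset, direction = i, int(d)
            break
    if onset is None:
        return ResponseResult(stimulus_id, timescale, False, sd_floored=sd_floored)

    j = onset
    while j + 1 < len(sig) and sig[j + 1] == direction:
        j += 1

    if edge == "trailing":
        latency = starts[onset] + window
    elif edge == "leading":
        latency = starts[onset]
    else:
        raise ValueError("edge must be 'trailing' or 'leading'")
    # response end: trailing edge of the last consecutive significant window
    offset = starts[j] + window
    dur = offset - latency

    # evoked rate over [latency, leading edge past the last significant
    # window]: partially covered edge windows are excluded, which keeps the
    # magnitude estimate unbiased for step-like responses; for runs shorter
    # than one window fall back to the full significant stretch
    t_lo, t_hi = latency, starts[j] + step
    if t_hi <= t_lo:
        t_lo, t_hi = starts[onset], starts[j] + window
    pooled = np.sort(np.concatenate(aligned))
    count = np.searchsorted(pooled, t_hi) - np.searchsorted(pooled, t_lo)
    evoked = count / (len(aligned) * (t_hi - t_lo))
    return ResponseResult(
        stimulus_id,
        timescale,
        True,
        sign="excitatory" if direction > 0 else "inhibitory",
        magnitude=float(evoked - base_mean),
        latency=float(latency * 1000.0),
        duration=float(dur * 1000.0),
        sd_floored=sd_floored,
    )


def _align(spikes: np.ndarray, anchors: Iterable[float], lo: float, hi: float):
    out = []
    for a in anchors:
        seg = spikes[np.searchsorted(spikes, a + lo):np.searchsorted(spikes, a + hi)]
        out.append(seg - a)
    return out


def detect_5lick_response(
    spikes: SpikeTrain,
    trials: Sequence[Trial],
    baseline: RateEstimate,
    edge: str = "trailing",
) -> ResponseResult:
    """Detect a 5-lick response for one stimulus (trials share a stimulus)."""
    if len(trials) < 2:
        raise ValueError("detect_5lick_response requires >= 2 trials")
    stim = trials[0].stimulus_id
    p = FIVE_LICK
    aligned = _align(spikes.times, [tr.t0 for tr in trials], 0.0, p["span"])
    return _sliding_detect(
        aligned, baseline.mean, baseline.sd, p["window"], p["step"], p["span"],
        stim, "five_lick", edge=edge,
    )


def detect_lickbylick_response(
    spikes: SpikeTrain,
    trials: Sequence[Trial],
    edge: str = "trailing",
    pre: float = 0.050,
) -> ResponseResult:
    """Detect a lick-by-lick response; each stimulus lick is one sweep."""
    anchors = np.concatenate([tr.stim_lick_times for tr in trials]) if trials else []
    if len(anchors) < 10:
        raise ValueError("detect_lickbylick_response requires >= 10 aligned sweeps")
    stim = trials[0].stimulus_id
    p = LICK_BY_LICK

    # Baseline: 50 ms pre-lick windows, pooled within each trial (5 sweeps
    # -> one rate per trial); mean and SD across trials.  Per-sweep 50 ms
    # rates are 0/20/40 sps by discreteness and their SD would reject every
    # genuine short-latency response.
    per_trial = []
    for tr in trials:
        c = sum(
            np.searchsorted(spikes.times, a) - np.searchsorted(spikes.times, a - pre)
            for a in tr.stim_lick_times
        )
        per_trial.append(c / (len(tr.stim_lick_times) * pre))
    arr = np.asarray(per_trial, dtype=float)
    base_mean = float(arr.mean())
    base_sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    # With few trials the SD estimate is unstable; never let it fall below
    # the Poisson sampling SD of the pooled 10 ms window estimate.
    base_sd = max(
        base_sd, math.sqrt(base_mean / (len(anchors) * p["window"]))
    )

    aligned = _align(spikes.times, anchors, 0.0, p["span"])
    return _sliding_detect(
        aligned, base_mean, base_sd, p["window"], p["step"], p["span"],
        stim, "lick_by_lick", edge=edge,
    )


# ---------------------------------------------------------------------------
# Cell-level summaries
# ---------------------------------------------------------------------------

def detect_cell(
    spikes: SpikeTrain, session: Session, edge: str = "trailing"
) -> list[ResponseResult]:
    """Run both detectors for every panel stimulus with enough trials."""
    results: list[ResponseResult] = []
    for stim in session.panel:
        trials = session.trials_for(stim)
        if len(trials) >= 2:
            base = baseline_rate(spikes, trials)
            results.append(detect_5lick_response(spikes, trials, base, edge=edge))
        if sum(len(tr.stim_lick_times) for tr in trials) >= 10:
            results.append(detect_lickbylick_response(spikes, trials, edge=edge))
    return results


def is_taste_responsive(
    results: Iterable[ResponseResult], exclude: Sequence[str] = ("AS",)
) -> bool:
    """True if any non-solvent stimulus has a significant response."""
    return any(r.significant and r.stimulus_id not in exclude for r in results)


def tuning_breadth(
    results: Iterable[ResponseResult],
    quartet: Sequence[str] = TRADITIONAL_QUARTET,
) -> int:
    """Number of quartet stimuli with a significant response at either timescale."""
    results = list(results)
    present = {r.stimulus_id for r in results}
    missing = [s for s in quartet if s not in present]
    if missing:
        raise ValueError(f"quartet stimuli missing from results: {missing}")
    return sum(
        1
        for s in quartet
        if any(r.significant for r in results if r.stimulus_id == s)
    )


def detection_table(session: Session, edge: str = "trailing") -> pd.DataFrame:
    """Per-unit, per-stimulus, per-timescale detection results."""
    rows = []
    for u in session.units:
        if len(u) == 0:
            continue
        for r in detect_cell(u, session, edge=edge):
            rows.append(
                dict(
                    unit_id=u.unit_id,
                    stimulus_id=r.stimulus_id,
                    timescale=r.timescale,
                    significant=r.significant,
                    sign=r.sign,
                    magnitude_sps=r.magnitude,
                    latency_ms=r.latency,
                    duration_ms=r.duration,
                    sd_floored=r.sd_floored,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "stimulus_id", "timescale", "significant", "sign",
            "magnitude_sps", "latency_ms", "duration_ms", "sd_floored",
        ],
    )
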