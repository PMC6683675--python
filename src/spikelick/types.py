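"""Core data containers shared across the package.

All event times are seconds from session start.  Spike timestamps are
quantized to the acquisition resolution of 25 microseconds (``TICK``); the
rest of the pipeline treats times as plain floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Timestamp resolution (seconds): 25 microseconds.
TICK = 25e-6

#: Lick labels that are not stimulus deliveries.
DRY = "dry"
RINSE = "rinse"
STIMULUS_PREFIX = "stimulus:"

#: Default 12-stimulus panel (traditional + naturalistic tastants + solvent).
DEFAULT_PANEL = (
    "Hi Su", "Lo Su", "N", "CA", "Caf",
    "Hi GJ", "Lo GJ", "Clm J", "Lm J", "Coff", "Crm", "AS",
)

#: The traditional quartet used for tuning-breadth and quality analyses.
TRADITIONAL_QUARTET = ("Lo Su", "N", "CA", "Caf")

#: The naturalistic quartet used for quality analyses.
NATURALISTIC_QUARTET = ("Lo GJ", "Clm J", "Lm J", "Coff")


class ConfigurationError(ValueError):
    """Bad generator/analysis configuration (non-positive duration, etc.)."""


class SchedulingError(RuntimeError):
    """Lick train too short to host the requested trials."""


class SpecificationError(ValueError):
    """A cell specification implies an invalid (negative) firing rate."""


class SessionParseError(ValueError):
    """Malformed session file; carries a line number when available."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def quantize(times: np.ndarray) -> np.ndarray:
    """Snap times to the 25 us grid."""
    return np.round(np.asarray(times, dtype=float) / TICK) * TICK


def stimulus_label(stimulus_id: str) -> str:
    return STIMULUS_PREFIX + stimulus_id


def parse_stimulus_label(label: str) -> str | None:
    """Return the stimulus id for a ``stimulus:<id>`` label, else ``None``."""
    if label.startswith(STIMULUS_PREFIX):
        return label[len(STIMULUS_PREFIX):]
    return None


@dataclass
class LickTrain:
    """Lick event times with per-lick labels (dry / rinse / stimulus:<id>)."""

    times: np.ndarray
    labels: np.ndarray  # dtype=object, same length as times

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.times.shape != self.labels.shape:
            raise ValueError("times and labels must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def bouts(self, max_gap: float = 1.0, min_duration: float = 1.0) -> np.ndarray:
        """Return ``(n_bouts, 2)`` array of bout (start, end) times.

        A bout is a maximal run of licks whose inter-lick intervals are all
        ``<= max_gap`` and that spans at least ``min_duration`` of continuous
        licking.
        """
        t = self.times
        if len(t) == 0:
            return np.empty((0, 2))
        breaks = np.flatnonzero(np.diff(t) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(t) - 1]])
        spans = np.column_stack([t[starts], t[ends]])
        keep = (spans[:, 1] - spans[:, 0]) >= min_duration
        return spans[keep]

    def stimulus_mask(self) -> np.ndarray:
        return np.array([lab.startswith(STIMULUS_PREFIX) for lab in self.labels])


@dataclass
class Trial:
    """One 5-lick taste presentation."""

    stimulus_id: str
    stim_lick_times: np.ndarray  # exactly five, ascending

    def __post_init__(self):
        self.stim_lick_times = np.asarray(self.stim_lick_times, dtype=float)
        if len(self.stim_lick_times) != 5:
            raise ValueError("a trial has exactly five stimulus licks")

    @property
    def t0(self) -> float:
        """First stimulus lick; time zero of the 5-lick timescale."""
        return float(self.stim_lick_times[0])


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for one unit, quantized to 25 us."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self):
        self.times = quantize(np.asarray(self.times, dtype=float))

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Session:
    """One recording day: units, licks, trials, and session metadata."""

    subject_id: str
    group: str  # "lean" or "DIO"
    units: list[SpikeTrain]
    licks: LickTrain
    trials: list[Trial]
    duration: float
    panel: Sequence[str] = DEFAULT_PANEL

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def trials_for(self, stimulus_id: str) -> list[Trial]:
        return [tr for tr in self.trials if tr.stimulus_id == stimulus_id]


@dataclass
class RateEstimate:
    """Mean/SD firing rate over a set of measurement windows."""

    mean: float
    sd: float
    n_windows: int

    @property
    def ok(self) -> bool:
        """False when no qualifying measurement window existed."""
        return self.n_windows > 0


@dataclass
class ResponseResult:
    """Output of one sliding-window response detection."""

    stimulus_id: str
    timescale: str  # "five_lick" | "lick_by_lick"
    significant: bool
    sign: str = "none"  # "excitatory" | "inhibitory" | "none"
    magnitude: float | None = None  # sps, evoked - baseline (signed)
    latency: float | None = None  # ms
    duration: float | None = None  # ms
    sd_floored: bool = False


@dataclass
class CoherenceResult:
    """Spike-lick magnitude-squared coherence with its 4-9 Hz peak."""

    freqs: np.ndarray
    coherence: np.ndarray
    peak_value: float
    peak_freq: float


@dataclass
class InfoResult:
    """Metric-space information analysis output for one cell/window."""

    q_grid: np.ndarray  # 1/s
    H_of_q: np.ndarray  # bits, one per q
    H_max: float
    q_at_max: float
    H_count: float  # H at q = 0
    H_shuffled_mean: float  # at q_at_max
    H_shuffled_sd: float
    H_exchange_mean: float | None = None  # at q_at_max; None if not run
    H_exchange_sd: float | None = None
    shuffled_by_q: np.ndarray | None = None  # (2, nq) mean/sd
    exchange_by_q: np.ndarray | None = None
    coding_class: str | None = None
    window: float | None = None

    @property
    def significant(self) -> bool:
        return self.H_max > self.H_shuffled_mean + 2.0 * self.H_shuffled_sd


@dataclass
class ResponseSet:
    """Spike-time lists aligned to trial onset, truncated to a window."""

    responses: list[np.ndarray]  # seconds relative to trial t0, in [0, window)
    labels: list[str]
    window: float

    def __post_init__(self):
        self.responses = [np.asarray(r, dtype=float) for r in self.responses]
        if len(self.responses) != len(self.labels):
            raise ValueError("responses and labels must have equal length")

    def truncated(self, window: float) -> "ResponseSet":
        if window > self.window:
            raise ValueError("cannot extend a response set beyond its window")
        return ResponseSet(
            [r[r < window] for r in self.responses], list(self.labels), window
        )
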