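"""Seeded synthetic session generator.

Produces rhythmic licking (~6-7 Hz) organized in bouts, 5-lick taste trials
separated by rinse licks on a variable-ratio-5 schedule, and spike trains
realized from an inhomogeneous Poisson intensity

    lambda(t) = base(t) * lickmod(t) + sum of response kernels(t)

where ``base`` switches between the spontaneous rate (outside lick bouts)
and the baseline rate (inside bouts), ``lickmod`` is a von-Mises-shaped
gain locked to lick phase, and the kernels are rectangular rate steps tied
to trial onsets (5-lick timescale) or to individual stimulus licks
(lick-by-lick timescale).  A 2 ms refractory period is enforced by thinning.

Two presets, ``lean`` and ``DIO``, encode group-level differences: the DIO
preset has smaller lick-by-lick response magnitudes, longer latencies,
shorter durations, and weaker lick-phase modulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import i0

from .types import (
    DEFAULT_PANEL,
    DRY,
    RINSE,
    ConfigurationError,
    LickTrain,
    SchedulingError,
    Session,
    SpecificationError,
    SpikeTrain,
    Trial,
    quantize,
    stimulus_label,
)

#: Hard floor on inter-lick intervals (s); rodent licking cannot go faster.
MIN_ILI = 0.05

#: Enforced minimum inter-spike interval (s), matching the unit-isolation rule.
REFRACTORY = 0.002

CELL_CLASSES = (
    "taste", "lick", "anti_lick", "lick_bout", "lick_anti_mix", "nonresponsive",
)

Dist = Callable[[np.random.Generator], float]


def fixed(value: float) -> Dist:
    """Distribution helper: always return ``value``."""
    return lambda rng: value


def truncnorm(mean: float, sd: float, lo: float = 0.0, hi: float = np.inf) -> Dist:
    """Normal draw clipped to [lo, hi]."""

    def draw(rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    return draw


# ---------------------------------------------------------------------------
# Lick train generation
# ---------------------------------------------------------------------------

def generate_lick_train(
    duration: float,
    ili_mean: float = 0.16,
    ili_sd: float = 0.015,
    bout_length_dist: Dist | None = None,
    pause_dist: Dist | None = None,
    rng: np.random.Generator | int | None = None,
) -> LickTrain:
    """Generate a dry lick train of ``duration`` seconds organized in bouts.

    Within a bout, inter-lick intervals are truncated-normal draws
    (floor ``MIN_ILI``).  ``bout_length_dist`` draws the number of licks per
    bout (``None`` = one continuous bout); ``pause_dist`` draws the pause
    length between bouts (``None`` = no pauses).
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if ili_mean <= MIN_ILI:
        raise ConfigurationError(f"ili_mean must exceed {MIN_ILI} s")
    if ili_sd < 0:
        raise ConfigurationError("ili_sd must be non-negative")
    rng = np.random.default_rng(rng)

    times: list[float] = []
    t = 0.0
    while t <= duration:
        n_bout = math.inf if bout_length_dist is None else int(bout_length_dist(rng))
        if n_bout is not math.inf and n_bout < 1:
            raise ConfigurationError("bout length draws must be >= 1 lick")
        k = 0
        while k < n_bout and t <= duration:
            times.append(t)
            k += 1
            ili = ili_mean if ili_sd == 0 else max(rng.normal(ili_mean, ili_sd), MIN_ILI)
            t += ili
        if pause_dist is None:
            break
        pause = float(pause_dist(rng))
        if pause < 0:
            raise ConfigurationError("pause draws must be non-negative")
        # a pause shorter than an ILI is indistinguishable from licking on
        t += max(pause, 0.0)

    times_arr = quantize(np.asarray(times))
    labels = np.array([DRY] * len(times_arr), dtype=object)
    return LickTrain(times_arr, labels)


# ---------------------------------------------------------------------------
# Trial scheduling (5 stimulus licks + VR5 rinse block)
# ---------------------------------------------------------------------------

def schedule_trials(
    lick_train: LickTrain,
    panel: Sequence[str] = DEFAULT_PANEL,
    trials_per_stimulus: int = 6,
    rng: np.random.Generator | int | None = None,
    first_stimulus: str = "Lo Su",
) -> tuple[LickTrain, list[Trial]]:
    """Assign stimulus/rinse/dry labels to a lick train, forming trials.

    Each trial is 5 consecutive stimulus-labeled licks.  After each trial
    come five rinse licks, each preceded by a uniformly drawn run of 4-6 dry
    licks (variable-ratio-5 schedule).  Trials are ordered pseudorandomly
    except that the first trial uses ``first_stimulus`` when it is in the
    panel.
    """
    if len(panel) == 0:
        raise ConfigurationError("panel must be nonempty")
    if trials_per_stimulus < 1:
        raise ConfigurationError("trials_per_stimulus must be >= 1")
    rng = np.random.default_rng(rng)

    order = [s for s in panel for _ in range(trials_per_stimulus)]
    order = list(rng.permutation(np.asarray(order, dtype=object)))
    if first_stimulus in order:
        order.remove(first_stimulus)
        order.insert(0, first_stimulus)

    labels = np.array([DRY] * len(lick_train), dtype=object)
    times = lick_train.times
    trials: list[Trial] = []
    i = 0

    def need(n: int, what: str) -> None:
        if i + n > len(times):
            short = i + n - len(times)
            raise SchedulingError(
                f"lick train too short: need {short} more licks to place {what} "
                f"(trial {len(trials) + 1} of {len(order)})"
            )

    for stim in order:
        need(5, f"stimulus licks for {stim!r}")
        lab = stimulus_label(stim)
        for k in range(5):
            labels[i + k] = lab
        trials.append(Trial(stim, times[i:i + 5].copy()))
        i += 5
        # VR5 rinse block: 5 rinse licks, each after 4-6 dry licks
        for _ in range(5):
            n_dry = int(rng.integers(4, 7))
            need(n_dry + 1, "a rinse block")
            i += n_dry  # dry licks stay labeled DRY
            labels[i] = RINSE
            i += 1

    return LickTrain(times.copy(), labels), trials


# ---------------------------------------------------------------------------
# Cell specification and presets
# ---------------------------------------------------------------------------

@dataclass
class Kernel:
    """One stimulus-response kernel (rectangular rate step)."""

    sign: int  # +1 or -1
    magnitude: float  # sps, >= 0
    latency: float  # s
    duration: float  # s
    timescale: str  # "five_lick" | "lick_by_lick"

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise SpecificationError("kernel sign must be +1 or -1")
        if self.magnitude < 0:
            raise SpecificationError("kernel magnitude must be >= 0")
        if self.latency < 0:
            raise SpecificationError("kernel latency must be >= 0")
        if self.duration <= 0:
            raise SpecificationError("kernel duration must be > 0")
        if self.timescale not in ("five_lick", "lick_by_lick"):
            raise SpecificationError(f"unknown timescale {self.timescale!r}")


@dataclass
class CellSpec:
    """Ground truth for one synthetic unit."""

    baseline_rate: float  # sps, inside lick bouts
    spont_rate: float  # sps, outside lick bouts
    lick_mod_depth: float  # von Mises concentration, >= 0
    lick_mod_phase: float  # radians
    cell_class: str
    response_kernels: dict[str, Kernel] = field(default_factory=dict)

    def __post_init__(self):
        if self.baseline_rate < 0 or self.spont_rate < 0:
            raise SpecificationError("rates must be >= 0")
        if self.lick_mod_depth < 0:
            raise SpecificationError("lick_mod_depth must be >= 0")
        if self.cell_class not in CELL_CLASSES:
            raise SpecificationError(f"unknown cell class {self.cell_class!r}")
        for stim, k in self.response_kernels.items():
            if k.sign < 0 and k.magnitude > self.min_driven_rate():
                raise SpecificationError(
                    f"inhibitory kernel for {stim!r} would drive the rate below 0"
                )

    def min_driven_rate(self) -> float:
        """Lower bound of base(t) * lickmod(t) inside bouts (kernels act there)."""
        kappa = self.lick_mod_depth
        gain_min = math.exp(-kappa) / i0(kappa) if kappa > 0 else 1.0
        return self.baseline_rate * gain_min


@dataclass
class GroupPreset:
    """Distributions for CellSpec fields plus class proportions for a group."""

    name: str
    class_proportions: dict[str, float]
    spont_rate: Dist
    baseline_rate: Dist
    lick_mod_depth: Dist
    tuning_prob: float  # P(a taste cell responds to a given stimulus)
    p_five_lick: float  # P(a kernel lives on the 5-lick timescale)
    p_excitatory: float
    magnitude_5l: Dist
    magnitude_lbl: Dist
    latency_5l: Dist
    latency_lbl: Dist
    duration_5l: Dist
    duration_lbl: Dist
    ili_mean: float = 0.16
    ili_sd: float = 0.015
    slow_gain_sd: float = 0.35

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("class proportions must sum to 1")
        for c in self.class_proportions:
            if c not in CELL_CLASSES:
                raise ConfigurationError(f"unknown cell class {c!r}")

    def draw_cell_spec(
        self, rng: np.random.Generator, panel: Sequence[str] = DEFAULT_PANEL
    ) -> CellSpec:
        classes = list(self.class_proportions)
        probs = np.array([self.class_proportions[c] for c in classes])
        cls = str(rng.choice(np.asarray(classes, dtype=object), p=probs))

        spont = self.spont_rate(rng)
        baseline = self.baseline_rate(rng)
        depth, phase = 0.0, 0.0
        kernels: dict[str, Kernel] = {}

        if cls in ("lick", "lick_anti_mix", "taste"):
            depth = self.lick_mod_depth(rng)
            phase = float(rng.uniform(0, 2 * math.pi))
        if cls == "anti_lick" or cls == "lick_anti_mix":
            # suppressed during bouts relative to surrounding rest
            baseline = 0.45 * spont
        elif cls == "lick_bout":
            baseline = max(1.6 * spont, spont + 4.0)
        elif cls == "nonresponsive":
            # no lick-related rate change at all
            baseline = spont
        if cls == "taste":
            kernels = self._draw_kernels(rng, panel, baseline, spont, depth)
            if not kernels:  # guarantee at least one response
                stim = str(rng.choice(np.asarray(panel, dtype=object)))
                kernels = {stim: self._draw_one_kernel(rng, baseline, spont, depth)}

        return CellSpec(baseline, spont, depth, phase, cls, kernels)

    def _draw_kernels(self, rng, panel, baseline, spont, depth) -> dict[str, Kernel]:
        out: dict[str, Kernel] = {}
        for stim in panel:
            if rng.random() < self.tuning_prob:
                out[stim] = self._draw_one_kernel(rng, baseline, spont, depth)
        return out

    def _draw_one_kernel(self, rng, baseline, spont, depth) -> Kernel:
        five = rng.random() < self.p_five_lick
        # inhibitory kernels only on the 5-lick timescale: lick-by-lick
        # kernels anchored to successive licks overlap, and stacked
        # inhibition could push the intensity negative
        sign = +1 if (not five or rng.random() < self.p_excitatory) else -1
        if five:
            mag = self.magnitude_5l(rng)
            lat = self.latency_5l(rng)
            dur = self.duration_5l(rng)
        else:
            mag = self.magnitude_lbl(rng)
            lat = self.latency_lbl(rng)
            dur = self.duration_lbl(rng)
        if sign < 0:
            gain_min = math.exp(-depth) / i0(depth) if depth > 0 else 1.0
            # cap at 0.45x the floor so even two overlapping kernels stay >= 0;
            # the floor includes the spontaneous rate because a pause can
            # interrupt a trial (dropping the base rate to spont mid-kernel)
            mag = min(mag, 0.45 * min(baseline * gain_min, spont))
            if mag < 2.0:  # too weak to matter; flip to excitatory
                sign, mag = +1, self.magnitude_5l(rng)
        return Kernel(sign, mag, lat, dur, "five_lick" if five else "lick_by_lick")


def _lean_preset() -> GroupPreset:
    # Class proportions follow the reported lean census (74/174/65/9/43/150
    # of 515 units).  Rates follow the printed group means; lick-phase
    # modulation depth is a calibration fixture tuned so that the coherence
    # medians land near the reported values, not a measured quantity.
    return GroupPreset(
        name="lean",
        class_proportions={
            "taste": 74 / 515, "lick": 174 / 515, "anti_lick": 65 / 515,
            "lick_bout": 9 / 515, "lick_anti_mix": 43 / 515,
            "nonresponsive": 150 / 515,
        },
        spont_rate=truncnorm(12.18, 4.0, lo=1.0),
        baseline_rate=truncnorm(18.9, 4.0, lo=1.0),
        lick_mod_depth=truncnorm(0.33, 0.10, lo=0.08),
        tuning_prob=0.75,
        p_five_lick=0.5,
        p_excitatory=0.8,
        magnitude_5l=truncnorm(24.0, 4.0, lo=10.0),
        magnitude_lbl=truncnorm(30.0, 6.0, lo=10.0),
        latency_5l=truncnorm(0.25, 0.10, lo=0.05, hi=1.0),
        latency_lbl=truncnorm(0.015, 0.006, lo=0.004, hi=0.06),
        duration_5l=truncnorm(1.4, 0.30, lo=0.4, hi=2.5),
        duration_lbl=truncnorm(0.060, 0.015, lo=0.02, hi=0.11),
        ili_mean=0.155,
        ili_sd=0.015,
    )


def _dio_preset() -> GroupPreset:
    # DIO census 49/65/12/3/19/80 of 228.  Relative to lean: smaller
    # lick-by-lick magnitudes, longer latencies, shorter durations, weaker
    # phase modulation, slower licking.
    return GroupPreset(
        name="DIO",
        class_proportions={
            "taste": 49 / 228, "lick": 65 / 228, "anti_lick": 12 / 228,
            "lick_bout": 3 / 228, "lick_anti_mix": 19 / 228,
            "nonresponsive": 80 / 228,
        },
        spont_rate=truncnorm(15.4, 5.0, lo=1.0),
        baseline_rate=truncnorm(13.7, 3.0, lo=1.0),
        lick_mod_depth=truncnorm(0.20, 0.07, lo=0.04),
        tuning_prob=0.28,
        p_five_lick=0.5,
        p_excitatory=0.8,
        magnitude_5l=truncnorm(18.0, 4.0, lo=8.0),
        magnitude_lbl=truncnorm(13.0, 3.5, lo=5.0),
        latency_5l=truncnorm(0.55, 0.15, lo=0.15, hi=1.6),
        latency_lbl=truncnorm(0.045, 0.010, lo=0.015, hi=0.08),
        duration_5l=truncnorm(0.40, 0.12, lo=0.2, hi=1.0),
        duration_lbl=truncnorm(0.040, 0.010, lo=0.015, hi=0.09),
        ili_mean=0.165,
        ili_sd=0.015,
    )


_PRESETS = {"lean": _lean_preset, "DIO": _dio_preset}


def get_preset(name: str) -> GroupPreset:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Spike train generation (thinning)
# ---------------------------------------------------------------------------

class _RateFunction:
    """Callable lambda(t) for one cell given licks/trials/bouts."""

    def __init__(self, spec: CellSpec, licks: LickTrain, trials: Sequence[Trial]):
        self.spec = spec
        self.licks = licks
        self.bout_spans = licks.bouts()
        self.kernel_edges, self.kernel_levels = self._build_kernel_steps(trials)

    def _build_kernel_steps(self, trials):
        events: list[tuple[float, float]] = []
        for stim, k in self.spec.response_kernels.items():
            delta = k.sign * k.magnitude
            for tr in trials:
                if tr.stimulus_id != stim:
                    continue
                if k.timescale == "five_lick":
                    anchors = [tr.t0]
                else:
                    anchors = list(tr.stim_lick_times)
                for a in anchors:
                    events.append((a + k.latency, delta))
                    events.append((a + k.latency + k.duration, -delta))
        if not events:
            return np.array([]), np.array([0.0])
        events.sort()
        edges = np.array([e[0] for e in events])
        levels = np.concatenate([[0.0], np.cumsum([e[1] for e in events])])
        return edges, levels

    def _in_bout(self, t: np.ndarray) -> np.ndarray:
        if len(self.bout_spans) == 0:
            return np.zeros(len(t), dtype=bool)
        idx = np.searchsorted(self.bout_spans[:, 0], t, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(t), dtype=bool)
        out[ok] = t[ok] <= self.bout_spans[idx[ok], 1]
        return out

    def _lick_gain(self, t: np.ndarray, in_bout: np.ndarray) -> np.ndarray:
        kappa = self.spec.lick_mod_depth
        gain = np.ones(len(t))
        if kappa <= 0:
            return gain
        lt = self.licks.times
        j = np.searchsorted(lt, t, side="right") - 1
        valid = in_bout & (j >= 0) & (j < len(lt) - 1)
        if not np.any(valid):
            return gain
        prev = lt[j[valid]]
        nxt = lt[j[valid] + 1]
        phase = 2 * math.pi * (t[valid] - prev) / (nxt - prev)
        gain[valid] = np.exp(
            kappa * np.cos(phase - self.spec.lick_mod_phase)
        ) / i0(kappa)
        return gain

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        in_bout = self._in_bout(t)
        base = np.where(in_bout, self.spec.baseline_rate, self.spec.spont_rate)
        rate = base * self._lick_gain(t, in_bout)
        if len(self.kernel_edges):
            k = np.searchsorted(self.kernel_edges, t, side="right")
            rate = rate + self.kernel_levels[k]
        return rate

    def upper_bound(self) -> float:
        kappa = self.spec.lick_mod_depth
        gain_max = math.exp(kappa) / i0(kappa) if kappa > 0 else 1.0
        base_max = max(self.spec.baseline_rate * gain_max, self.spec.spont_rate)
        kmax = float(np.max(self.kernel_levels)) if len(self.kernel_levels) else 0.0
        return base_max + max(kmax, 0.0)


def generate_spike_train(
    spec: CellSpec,
    licks: LickTrain,
    trials: Sequence[Trial],
    duration: float,
    rng: np.random.Generator | int | None = None,
    unit_id: str = "u0",
    slow_gain_sd: float = 0.0,
    slow_gain_block: float = 10.0,
) -> SpikeTrain:
    """Realize a spike train by thinning an inhomogeneous Poisson process.

    Enforces a 2 ms minimum inter-spike interval after thinning.  Raises
    :class:`SpecificationError` if the intensity goes negative anywhere it
    is evaluated.

    ``slow_gain_sd`` > 0 multiplies the whole intensity by a
    piecewise-constant lognormal excitability gain (one draw per
    ``slow_gain_block`` seconds, mean 1).  Real units are overdispersed
    across trials; a purely Poisson null makes the 2-SD detection rule far
    more permissive than it is on recorded data, so the presets enable this.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    rng = np.random.default_rng(rng)
    lam = _RateFunction(spec, licks, trials)
    lam_max = lam.upper_bound()
    if lam_max <= 0:
        return SpikeTrain(unit_id, np.array([]))

    if slow_gain_sd > 0:
        n_blocks = int(math.ceil(duration / slow_gain_block))
        gains = np.exp(rng.normal(0.0, slow_gain_sd, size=n_blocks))
        gains = np.clip(gains / math.exp(slow_gain_sd**2 / 2), 0.4, 2.5)
    else:
        gains = None
    g_max = float(gains.max()) if gains is not None else 1.0

    n = rng.poisson(lam_max * g_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    rates = lam(cand)
    if np.any(rates < -1e-9):
        raise SpecificationError("rate function is negative; check kernels")
    if gains is not None:
        rates = rates * gains[
            np.minimum((cand / slow_gain_block).astype(int), len(gains) - 1)
        ]
    keep = rng.random(n) < np.clip(rates, 0.0, None) / (lam_max * g_max)
    times = quantize(cand[keep])  # quantize first so the ISI floor survives it

    # enforce refractoriness (iterative deletion converges quickly at these rates)
    while len(times) > 1:
        short = np.flatnonzero(np.diff(times) < REFRACTORY)
        if len(short) == 0:
            break
        times = np.delete(times, short + 1)
    return SpikeTrain(unit_id, times)


# ---------------------------------------------------------------------------
# Whole-session generation
# ---------------------------------------------------------------------------

def generate_session(
    preset: GroupPreset | str,
    n_cells: int,
    trials_per_stimulus: int = 6,
    rng: np.random.Generator | int | None = None,
    panel: Sequence[str] = DEFAULT_PANEL,
    bout_length_dist: Dist | None = None,
    pause_dist: Dist | None = None,
    subject_id: str | None = None,
) -> tuple[Session, list[CellSpec]]:
    """Generate a fully labeled session plus its ground-truth cell specs."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = np.random.default_rng(rng)

    if bout_length_dist is None:
        bout_length_dist = lambda r: int(r.integers(80, 160))
    if pause_dist is None:
        pause_dist = truncnorm(2.0, 0.6, lo=1.1, hi=5.0)

    n_trials = len(panel) * trials_per_stimulus
    licks_needed = n_trials * (5 + 5 * 7) + 40
    duration = licks_needed * preset.ili_mean * 1.25
    for _ in range(8):
        lick_rng = np.random.default_rng(rng.integers(2**63))
        sched_rng = np.random.default_rng(rng.integers(2**63))
        train = generate_lick_train(
            duration, preset.ili_mean, preset.ili_sd,
            bout_length_dist, pause_dist, lick_rng,
        )
        try:
            labeled, trials = schedule_trials(
                train, panel, trials_per_stimulus, sched_rng
            )
            break
        except SchedulingError:
            duration *= 1.3
    else:
        raise SchedulingError("could not fit all trials after extending duration")

    duration = float(labeled.times[-1] + 45.0)  # quiet tail: 3 spontaneous windows
    specs: list[CellSpec] = []
    units: list[SpikeTrain] = []
    for i in range(n_cells):
        spec = preset.draw_cell_spec(rng, panel)
        specs.append(spec)
        units.append(
            generate_spike_train(
                spec, labeled, trials, duration,
                np.random.default_rng(rng.integers(2**63)), unit_id=f"u{i:03d}",
                slow_gain_sd=preset.slow_gain_sd,
            )
        )

    session = Session(
        subject_id=subject_id or f"{preset.name}-synth",
        group=preset.name,
        units=units,
        licks=labeled,
        trials=trials,
        duration=duration,
        panel=tuple(panel),
    )
    return session, specs
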