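"""Session file dialect: read/write, structural validation, duplicate screen.

A session is stored as a directory holding two text files:

``header.json``
    subject_id, group, duration, panel, and the unit id roster.
``events.csv``
    one row per event, columns ``time_s,kind,label``; ``kind`` is ``spike``
    (label = unit id) or ``lick`` (label = ``dry`` / ``rinse`` /
    ``stimulus:<id>``).  Times are written as exact multiples of 25 us with
    six decimals, so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DRY,
    RINSE,
    TICK,
    LickTrain,
    Session,
    SessionParseError,
    SpikeTrain,
    Trial,
    parse_stimulus_label,
    quantize,
)

_HEADER = "header.json"
_EVENTS = "events.csv"


def write_session(session: Session, path: str | Path) -> Path:
    """Write ``session`` to directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    header = {
        "subject_id": session.subject_id,
        "group": session.group,
        "duration": session.duration,
        "panel": list(session.panel),
        "units": [u.unit_id for u in session.units],
    }
    (path / _HEADER).write_text(json.dumps(header, indent=2) + "\n")

    rows = []
    for u in session.units:
        for t in u.times:
            rows.append((t, "spike", u.unit_id))
    for t, lab in zip(session.licks.times, session.licks.labels):
        rows.append((float(t), "lick", str(lab)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path / _EVENTS, "w") as fh:
        fh.write("time_s,kind,label\n")
        for t, kind, lab in rows:
            ticks = round(t / TICK)
            fh.write(f"{ticks * TICK:.6f},{kind},{lab}\n")
    return path


def _trials_from_licks(times: np.ndarray, labels: np.ndarray) -> list[Trial]:
    """Group consecutive stimulus-labeled licks into 5-lick trials."""
    trials: list[Trial] = []
    run_stim: str | None = None
    run_times: list[float] = []
    run_start_line = 0

    def flush():
        nonlocal run_stim, run_times
        if run_stim is None:
            return
        if len(run_times) % 5 != 0:
            raise SessionParseError(
                f"stimulus {run_stim!r} has a run of {len(run_times)} "
                "stimulus licks (not a multiple of 5)",
                line=run_start_line,
            )
        for k in range(0, len(run_times), 5):
            trials.append(Trial(run_stim, np.array(run_times[k:k + 5])))
        run_stim, run_times = None, []

    for i, (t, lab) in enumerate(zip(times, labels)):
        stim = parse_stimulus_label(lab)
        if stim is None:
            flush()
            continue
        if stim != run_stim:
            flush()
            run_stim = stim
            run_start_line = i
        run_times.append(float(t))
    flush()
    return trials


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    try:
        header = json.loads((path / _HEADER).read_text())
    except FileNotFoundError:
        raise SessionParseError(f"missing {_HEADER} in {path}") from None
    except json.JSONDecodeError as e:
        raise SessionParseError(f"bad header JSON: {e}") from None

    panel = set(header.get("panel", []))
    try:
        df = pd.read_csv(path / _EVENTS, dtype={"time_s": float, "kind": str, "label": str})
    except FileNotFoundError:
        raise SessionParseError(f"missing {_EVENTS} in {path}") from None
    except ValueError as e:
        raise SessionParseError(f"malformed events table: {e}") from None
    if list(df.columns) != ["time_s", "kind", "label"]:
        raise SessionParseError(
            f"expected columns time_s,kind,label, got {list(df.columns)}", line=1
        )

    spike_times: dict[str, list[float]] = {u: [] for u in header.get("units", [])}
    lick_times: list[float] = []
    lick_labels: list[str] = []
    for i, (t, kind, lab) in enumerate(
        zip(df["time_s"].to_numpy(), df["kind"], df["label"]), start=2
    ):
        if not np.isfinite(t) or t < 0:
            raise SessionParseError(f"bad timestamp {t!r}", line=i)
        if kind == "spike":
            spike_times.setdefault(lab, []).append(t)
        elif kind == "lick":
            stim = parse_stimulus_label(lab)
            if stim is not None:
                if panel and stim not in panel:
                    raise SessionParseError(
                        f"lick labeled {lab!r} names a stimulus outside the panel",
                        line=i,
                    )
            elif lab not in (DRY, RINSE):
                raise SessionParseError(f"unknown lick label {lab!r}", line=i)
            lick_times.append(t)
            lick_labels.append(lab)
        else:
            raise SessionParseError(f"unknown event kind {kind!r}", line=i)

    lt = np.asarray(lick_times)
    if np.any(np.diff(lt) < 0):
        raise SessionParseError("lick times are not sorted")
    licks = LickTrain(quantize(lt), np.asarray(lick_labels, dtype=object))
    units = [SpikeTrain(uid, np.sort(np.asarray(ts))) for uid, ts in spike_times.items()]
    trials = _trials_from_licks(licks.times, licks.labels)
    return Session(
        subject_id=header.get("subject_id", "?"),
        group=header.get("group", "?"),
        units=units,
        licks=licks,
        trials=trials,
        duration=float(header.get("duration", lt[-1] if len(lt) else 0.0)),
        panel=tuple(header.get("panel", [])),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Structural findings; the session passes iff all lists are empty."""

    refractory_violations: list[tuple[str, float, float]] = field(default_factory=list)
    ordering_violations: list[str] = field(default_factory=list)
    orphan_trial_licks: list[tuple[str, float]] = field(default_factory=list)
    out_of_range_events: list[tuple[str, float]] = field(default_factory=list)
    zero_rate_units: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.refractory_violations
            or self.ordering_violations
            or self.orphan_trial_licks
            or self.out_of_range_events
        )


def validate_session(session: Session, refractory: float = 0.002) -> ValidationReport:
    """Report refractory, ordering, range, and orphan-trial-lick problems."""
    rep = ValidationReport()

    for u in session.units:
        t = u.times
        if len(t) == 0:
            rep.zero_rate_units.append(u.unit_id)
            continue
        if np.any(np.diff(t) < 0):
            rep.ordering_violations.append(f"unit {u.unit_id}: spike times not sorted")
        isi = np.diff(t)
        for i in np.flatnonzero((isi < refractory) & (isi >= 0)):
            rep.refractory_violations.append((u.unit_id, float(t[i]), float(t[i + 1])))
        if t[0] < 0 or t[-1] > session.duration:
            rep.out_of_range_events.append((u.unit_id, float(t[-1])))

    lt = session.licks.times
    if np.any(np.diff(lt) < 0):
        rep.ordering_violations.append("lick times not sorted")
    if len(lt) and (lt[0] < 0 or lt[-1] > session.duration):
        rep.out_of_range_events.append(("licks", float(lt[-1])))

    lick_lookup = {
        (round(t / TICK), str(lab))
        for t, lab in zip(session.licks.times, session.licks.labels)
    }
    for tr in session.trials:
        lab = "stimulus:" + tr.stimulus_id
        for t in tr.stim_lick_times:
            if (round(t / TICK), lab) not in lick_lookup:
                rep.orphan_trial_licks.append((tr.stimulus_id, float(t)))
    return rep


# ---------------------------------------------------------------------------
# Duplicate-unit screen (cross-correlogram zero-lag peak)
# ---------------------------------------------------------------------------

@dataclass
class DuplicateResult:
    is_duplicate: bool
    ccf_peak_lag: float  # s
    peak_score: float  # (zero bin - off mean) / off SD


def detect_duplicate_units(
    a: SpikeTrain,
    b: SpikeTrain,
    max_lag: float = 0.05,
    bin: float = 0.001,
    k: float = 10.0,
) -> DuplicateResult:
    """Flag two trains as the same unit via a narrow zero-lag CCF peak.

    The cross-correlogram of spike-time differences is binned at ``bin``
    over +-``max_lag``; the pair is a duplicate iff the zero-lag bin both
    is the global peak and exceeds mean + ``k`` SD of the off-zero bins.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("duplicate screen undefined for an empty spike train")
    if bin > 0.001 + 1e-12:
        raise ValueError("bin must be <= 1 ms to resolve a zero-lag peak")

    n = int(round(max_lag / bin))
    edges = (np.arange(-n, n + 2) - 0.5) * bin
    counts = np.zeros(2 * n + 1)

    ta, tb = a.times, b.times
    lo = np.searchsorted(tb, ta - max_lag, side="left")
    hi = np.searchsorted(tb, ta + max_lag, side="right")
    diffs = np.concatenate(
        [tb[l:h] - t for t, l, h in zip(ta, lo, hi) if h > l]
    ) if np.any(hi > lo) else np.array([])
    if len(diffs):
        counts, _ = np.histogram(diffs, bins=edges)
    counts = counts.astype(float)

    zero = n
    off = np.delete(counts, zero)
    mu, sd = float(off.mean()), float(off.std())
    score = (counts[zero] - mu) / sd if sd > 0 else (
        np.inf if counts[zero] > mu else 0.0
    )
    peak_idx = int(np.argmax(counts))
    peak_lag = (peak_idx - n) * bin
    is_dup = bool(peak_idx == zero and score > k)
    return DuplicateResult(is_dup, float(peak_lag), float(score))


def dedupe_units(
    session: Session, max_lag: float = 0.05, bin: float = 0.001, k: float = 10.0
) -> tuple[Session, list[tuple[str, str]]]:
    """Drop the lower-spike-count member of each duplicate pair.

    Returns the filtered session and the list of (kept, dropped) unit pairs.
    """
    dropped: set[str] = set()
    pairs: list[tuple[str, str]] = []
    units = [u for u in session.units if len(u) > 0]
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            a, b = units[i], units[j]
            if a.unit_id in dropped or b.unit_id in dropped:
                continue
            res = detect_duplicate_units(a, b, max_lag, bin, k)
            if res.is_duplicate:
                keep, drop = (a, b) if len(a) >= len(b) else (b, a)
                dropped.add(drop.unit_id)
                pairs.append((keep.unit_id, drop.unit_id))
    kept_units = [u for u in session.units if u.unit_id not in dropped]
    filtered = Session(
        session.subject_id, session.group, kept_units, session.licks,
        session.trials, session.duration, session.panel,
    )
    return filtered, pairs
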