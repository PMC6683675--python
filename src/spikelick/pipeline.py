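"""End-to-end orchestration: synth/load -> validate -> dedupe -> detect ->
classify -> coherence -> behavior -> MSA -> group statistics.

``run_pipeline`` is driven by a plain dict (loadable from JSON/TOML via the
CLI) and writes all output tables plus a machine-readable report to a run
directory; every random stage is seeded from one root seed, so two runs
with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as _detect
from . import lick as _lick
from . import metric as _metric
from . import session_io as _io
from . import synth as _synth
from .stats import GroupSummary, compare_groups
from .types import (
    ConfigurationError,
    NATURALISTIC_QUARTET,
    Session,
    TRADITIONAL_QUARTET,
)

STAGES = (
    "synth", "validate", "dedupe", "detect", "classify",
    "coherence", "behavior", "msa", "group_stats",
)

DEFAULT_CONFIG = dict(
    presets=["lean", "DIO"],
    n_cells=20,
    trials_per_stimulus=6,
    seed=0,
    windows=[2.0],
    msa_panel=list(TRADITIONAL_QUARTET),
    n_shuffle=40,
    n_exchange=10,
    coherence_null_shifts=20,
    stages=list(STAGES),
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def analyze_session(
    session: Session,
    rng: np.random.Generator,
    windows=(2.0,),
    msa_panel=TRADITIONAL_QUARTET,
    n_shuffle: int = 40,
    n_exchange: int = 10,
    coherence_null_shifts: int = 20,
    msa_taste_only: bool = True,
) -> dict:
    """Run all per-session analyses; returns a dict of DataFrames/objects."""
    out: dict = {}

    detection = _detect.detection_table(session)
    out["detection"] = detection

    # coherence + classification
    coh_rows, classes = [], {}
    null_peaks = None
    estimator = _lick.CoherenceEstimator(session.licks, session.duration)
    for u in session.units:
        if len(u) == 0:
            classes[u.unit_id] = "nonresponsive"
            continue
        coh = estimator.compute(u.times)
        if null_peaks is None:
            # one shared circular-shift null per session (cost control);
            # peak coherence under independence is insensitive to which
            # unit is shifted, so the first non-empty unit serves as proxy
            null_peaks = _lick.coherence_shift_null(
                u, session.licks, session.duration,
                n_shifts=coherence_null_shifts,
                rng=np.random.default_rng(rng.integers(2**63)),
                estimator=estimator,
            )
        threshold = float(np.quantile(null_peaks, 0.95))
        bouts = _lick.bout_rates(u, session.licks, session.duration)
        unit_det = detection[detection["unit_id"] == u.unit_id]
        det_results = [
            _detect.ResponseResult(
                row.stimulus_id, row.timescale, bool(row.significant), row.sign,
                row.magnitude_sps, row.latency_ms, row.duration_ms,
            )
            for row in unit_det.itertuples()
        ]
        # taste gate uses sustained responses only (see detect.SUSTAINED_MS)
        gated = [
            _detect.ResponseResult(
                r.stimulus_id, r.timescale, _detect.is_sustained(r), r.sign,
                r.magnitude, r.latency, r.duration,
            )
            for r in det_results
        ]
        label = _lick.classify_cell(gated, coh.peak_value, threshold, bouts)
        classes[u.unit_id] = label
        coh_rows.append(
            dict(unit_id=u.unit_id, cell_class=label,
                 peak_value=coh.peak_value, peak_freq=coh.peak_freq,
                 threshold=threshold)
        )
    out["coherence"] = pd.DataFrame(
        coh_rows, columns=["unit_id", "cell_class", "peak_value", "peak_freq",
                           "threshold"]
    )
    out["classes"] = classes

    out["behavior"] = _lick.lick_behavior_metrics(session)

    # tuning breadth for taste cells
    breadth = []
    for u in session.units:
        unit_det = detection[detection["unit_id"] == u.unit_id]
        if unit_det.empty or classes.get(u.unit_id) != "taste":
            continue
        res = [
            _detect.ResponseResult(
                r.stimulus_id,
                r.timescale,
                bool(r.significant)
                and r.duration_ms is not None
                and r.duration_ms >= _detect.SUSTAINED_MS[r.timescale],
                r.sign,
            )
            for r in unit_det.itertuples()
        ]
        try:
            breadth.append(_detect.tuning_breadth(res))
        except ValueError:
            pass
    out["tuning_breadth"] = breadth

    # MSA
    msa_rows = []
    max_w = max(windows)
    for u in session.units:
        if msa_taste_only and classes.get(u.unit_id) != "taste":
            continue
        if len(u) == 0:
            continue
        rs = _metric.extract_responses(session, u, msa_panel, max_w)
        for w in windows:
            info = _metric.run_msa(
                rs.truncated(w),
                n_shuffle=n_shuffle,
                n_exchange=n_exchange,
                rng=np.random.default_rng(rng.integers(2**63)),
            )
            msa_rows.append(
                dict(
                    unit_id=u.unit_id, window_s=w,
                    H_max=info.H_max if info.significant else 0.0,
                    H_max_raw=info.H_max, q_at_max=info.q_at_max,
                    H_count=info.H_count,
                    H_shuffled_mean=info.H_shuffled_mean,
                    H_shuffled_sd=info.H_shuffled_sd,
                    H_exchange_mean=info.H_exchange_mean,
                    significant=info.significant,
                    coding_class=info.coding_class,
                )
            )
    out["msa"] = pd.DataFrame(
        msa_rows,
        columns=["unit_id", "window_s", "H_max", "H_max_raw", "q_at_max",
                 "H_count", "H_shuffled_mean", "H_shuffled_sd",
                 "H_exchange_mean", "significant", "coding_class"],
    )
    return out


def summarize(session: Session, analysis: dict, group: str) -> GroupSummary:
    classes = analysis["classes"]
    counts: dict[str, int] = {}
    for lab in classes.values():
        counts[lab] = counts.get(lab, 0) + 1
    msa = analysis["msa"]
    return GroupSummary(
        group=group,
        class_counts=counts,
        tuning_breadth=analysis["tuning_breadth"],
        detection=analysis["detection"],
        coherence=analysis["coherence"],
        msa=msa if msa is not None and len(msa) else msa,
    )


def preset_contrasts(
    seed: int,
    n_cells: int = 50,
    trials_per_stimulus: int = 8,
    msa_window: float = 2.0,
) -> dict:
    """Lean vs DIO values for the five core group contrasts.

    Returns a dict with keys ``lbl_magnitude`` (significant excitatory
    lick-by-lick response magnitude), ``latency`` and ``duration``
    (significant 5-lick responses), ``coherence`` (mean in-band peak over
    the 5-lick taste-responsive units), and ``h_max`` (mean over the same
    units at the 2 s window, zero for cells whose information does not beat
    the shuffle control); each value is a (lean, DIO) tuple.
    """
    root = np.random.default_rng(seed)
    out: dict = {}
    for preset in ("lean", "DIO"):
        rng = np.random.default_rng(root.integers(2**63))
        session, _ = _synth.generate_session(
            preset, n_cells, trials_per_stimulus,
            rng=np.random.default_rng(rng.integers(2**63)),
        )
        det = _detect.detection_table(session)
        # sustained-response filter: genuine responses span at least three
        # full windows (300 ms at the 5-lick scale, 30 ms lick-by-lick);
        # minimal-run threshold crossings at 6 trials/stimulus are noise
        sig = det[det["significant"]]
        lbl = sig[
            (sig["timescale"] == "lick_by_lick") & (sig["duration_ms"] >= 30.0)
        ]
        fl = sig[
            (sig["timescale"] == "five_lick") & (sig["duration_ms"] >= 300.0)
        ]
        exc = sig[
            (sig["timescale"] == "lick_by_lick") & (sig["sign"] == "excitatory")
        ]

        estimator = _lick.CoherenceEstimator(session.licks, session.duration)
        # MSA/coherence population: units with a sustained 5-lick response
        # to a non-solvent stimulus
        taste_units = set(fl[fl["stimulus_id"] != "AS"]["unit_id"])
        peaks = [
            estimator.compute(u.times).peak_value
            for u in session.units
            if len(u) > 0 and u.unit_id in taste_units
        ]
        # per-cell information: mean over the two 4-stimulus quality panels
        h_max = []
        msa_rng = np.random.default_rng(rng.integers(2**63))
        for u in session.units:
            if u.unit_id not in taste_units:
                continue
            vals = []
            for panel in (TRADITIONAL_QUARTET, NATURALISTIC_QUARTET):
                rs = _metric.extract_responses(session, u, panel, msa_window)
                info = _metric.run_msa(
                    rs, n_exchange=0,
                    rng=np.random.default_rng(msa_rng.integers(2**63)),
                )
                vals.append(info.H_max if info.significant else 0.0)
            h_max.append(float(np.mean(vals)))

        # magnitude over the taste-unit population: their genuine kernels
        # dominate the noise rows, which hit both groups symmetrically
        exc_taste = exc[exc["unit_id"].isin(taste_units)]
        if not len(exc_taste):
            exc_taste = exc
        out[preset] = dict(
            lbl_magnitude=float(exc_taste["magnitude_sps"].mean()),
            latency=float(fl["latency_ms"].mean()),
            duration=float(fl["duration_ms"].mean()),
            coherence=float(np.mean(peaks)) if peaks else 0.0,
            h_max=float(np.mean(h_max)) if h_max else 0.0,
        )
    lean, dio = out["lean"], out["DIO"]
    return {k: (lean[k], dio[k]) for k in lean}


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Run the configured stages for each preset and compare the groups."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown pipeline stages: {sorted(unknown)}")
    stages = set(cfg["stages"])
    root = np.random.default_rng(cfg["seed"])
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))

    report: dict = {"config": cfg, "groups": {}}
    summaries: dict[str, GroupSummary] = {}

    for preset_name in cfg["presets"]:
        grp_rng = np.random.default_rng(root.integers(2**63))
        try:
            session, specs = _synth.generate_session(
                preset_name, cfg["n_cells"], cfg["trials_per_stimulus"],
                rng=np.random.default_rng(grp_rng.integers(2**63)),
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("synth", e) from e

        if "validate" in stages:
            rep = _io.validate_session(session)
            if not rep.ok:
                raise StageError(
                    "validate", RuntimeError(f"generated session invalid: {rep}")
                )
        if "dedupe" in stages:
            session, dropped = _io.dedupe_units(session)
            report["groups"].setdefault(preset_name, {})["deduped"] = dropped

        try:
            analysis = analyze_session(
                session,
                rng=np.random.default_rng(grp_rng.integers(2**63)),
                windows=cfg["windows"],
                msa_panel=cfg["msa_panel"],
                n_shuffle=cfg["n_shuffle"],
                n_exchange=cfg["n_exchange"],
                coherence_null_shifts=cfg["coherence_null_shifts"],
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("analysis", e) from e

        summary = summarize(session, analysis, preset_name)
        summaries[preset_name] = summary
        g = report["groups"].setdefault(preset_name, {})
        g["n_units"] = summary.n_units
        g["class_counts"] = summary.class_counts
        g["n_trials"] = len(session.trials)

        if outdir is not None:
            pdir = outdir / preset_name
            pdir.mkdir(exist_ok=True)
            analysis["detection"].to_csv(pdir / "detection.csv", index=False)
            analysis["coherence"].to_csv(pdir / "fig6_coherence.csv", index=False)
            analysis["behavior"].to_csv(pdir / "table2_behavior.csv", index=False)
            analysis["msa"].to_csv(pdir / "fig10_msa.csv", index=False)
            summary.response_param_table().to_csv(
                pdir / "table1_response_magnitude.csv", index=False
            )

    if "group_stats" in stages and len(summaries) == 2:
        names = list(summaries)
        try:
            contrasts = compare_groups(summaries[names[0]], summaries[names[1]])
        except Exception as e:  # noqa: BLE001
            raise StageError("group_stats", e) from e
        report["contrasts"] = contrasts
        if outdir is not None:
            contrasts.to_csv(outdir / "group_contrasts.csv", index=False)

    report["summaries"] = summaries
    if outdir is not None:
        serializable = {
            k: v for k, v in report.items() if k in ("config", "groups")
        }
        (outdir / "report.json").write_text(
            json.dumps(serializable, indent=2, default=str)
        )
    return report
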