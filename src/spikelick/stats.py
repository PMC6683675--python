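"""Group-level summaries and statistical comparisons of pipeline outputs."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CLASS_ORDER = (
    "taste", "lick", "anti_lick", "lick_bout", "lick_anti_mix", "nonresponsive",
)


@dataclass
class GroupSummary:
    """Per-group digest of the per-cell pipeline outputs."""

    group: str
    class_counts: dict[str, int]
    tuning_breadth: list[int]
    detection: pd.DataFrame  # per unit x stimulus x timescale
    coherence: pd.DataFrame  # unit_id, cell_class, peak_value
    msa: pd.DataFrame | None = None  # per unit: H_max, H_count, significant, window

    @property
    def n_units(self) -> int:
        return sum(self.class_counts.values())

    def response_param_table(self) -> pd.DataFrame:
        """Mean +- SEM of magnitude/latency/duration per stimulus/timescale/sign."""
        sig = self.detection[self.detection["significant"]]
        rows = []
        for (stim, scale, sign), g in sig.groupby(
            ["stimulus_id", "timescale", "sign"]
        ):
            for col, unit in (
                ("magnitude_sps", "sps"),
                ("latency_ms", "ms"),
                ("duration_ms", "ms"),
            ):
                v = g[col].dropna().to_numpy(dtype=float)
                if len(v) == 0:
                    continue
                sem = v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0
                rows.append(
                    dict(
                        stimulus_id=stim, timescale=scale, sign=sign,
                        quantity=col, units=unit, mean=float(v.mean()),
                        sem=float(sem), n=len(v),
                    )
                )
        return pd.DataFrame(rows)


def _sig_values(det: pd.DataFrame, timescale: str, column: str) -> np.ndarray:
    m = det[(det["timescale"] == timescale) & det["significant"]]
    return m[column].dropna().to_numpy(dtype=float)


def compare_groups(a: GroupSummary, b: GroupSummary) -> pd.DataFrame:
    """Two-sample contrasts between group summaries.

    Each row gives one contrast with t, Mann-Whitney U, and KS statistics
    (plus a single chi-square row for class proportions); the ``mirrors``
    column names the published comparison each row corresponds to.
    """
    if a.n_units == 0 or b.n_units == 0:
        raise ValueError("compare_groups requires non-empty groups")
    rows = []

    def add(name, va, vb, mirrors):
        va, vb = np.asarray(va, dtype=float), np.asarray(vb, dtype=float)
        row = dict(contrast=name, n_a=len(va), n_b=len(vb), mirrors=mirrors,
                   mean_a=float(np.mean(va)) if len(va) else math.nan,
                   mean_b=float(np.mean(vb)) if len(vb) else math.nan)
        if len(va) >= 2 and len(vb) >= 2:
            t = sps.ttest_ind(va, vb, equal_var=False)
            u = sps.mannwhitneyu(va, vb, alternative="two-sided")
            ks = sps.ks_2samp(va, vb)
            f = sps.f_oneway(va, vb)
            row.update(
                t_stat=float(t.statistic), t_p=float(t.pvalue),
                u_stat=float(u.statistic), u_p=float(u.pvalue),
                ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
                f_stat=float(f.statistic), f_p=float(f.pvalue),
            )
        rows.append(row)

    for scale in ("five_lick", "lick_by_lick"):
        for col, nice in (
            ("magnitude_sps", "response magnitude"),
            ("latency_ms", "response latency"),
            ("duration_ms", "response duration"),
        ):
            add(
                f"{scale}:{col}",
                _sig_values(a.detection, scale, col),
                _sig_values(b.detection, scale, col),
                f"group contrast of {scale} {nice}",
            )

    for cls in ("taste", "lick", "lick_anti_mix"):
        ca = a.coherence[a.coherence["cell_class"] == cls]["peak_value"]
        cb = b.coherence[b.coherence["cell_class"] == cls]["peak_value"]
        add(
            f"coherence:{cls}", ca.to_numpy(), cb.to_numpy(),
            f"Mann-Whitney on lick coherence of {cls} cells",
        )

    add("tuning_breadth", a.tuning_breadth, b.tuning_breadth,
        "breadth of tuning over the traditional quartet")

    if a.msa is not None and b.msa is not None and len(a.msa) and len(b.msa):
        add(
            "msa:H_max", a.msa["H_max"].to_numpy(), b.msa["H_max"].to_numpy(),
            "information conveyed about taste quality (KS on coding proportions)",
        )

    out = pd.DataFrame(rows)

    counts = np.array([
        [a.class_counts.get(c, 0) for c in CLASS_ORDER],
        [b.class_counts.get(c, 0) for c in CLASS_ORDER],
    ])
    keep = counts.sum(axis=0) > 0
    chi2, p, dof, _ = sps.chi2_contingency(counts[:, keep])
    chi_row = pd.DataFrame([
        dict(contrast="class_proportions", n_a=a.n_units, n_b=b.n_units,
             mirrors="chi-square on firing-pattern class proportions",
             chi2_stat=float(chi2), chi2_p=float(p), chi2_dof=int(dof)),
    ])
    return pd.concat([out, chi_row], ignore_index=True)


def chi_square_counts(counts: np.ndarray) -> tuple[float, float, int]:
    """Standard chi-square on a contingency table of class counts."""
    chi2, p, dof, _ = sps.chi2_contingency(np.asarray(counts))
    return float(chi2), float(p), int(dof)
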