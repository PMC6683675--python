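"""Metric-space analysis of taste-evoked spike trains.

Spike-train distances (count distance and the timing-sensitive edit
distance parameterized by the temporal-precision cost ``q``), a
nearest-centroid-style classifier on distance matrices, plug-in mutual
information of the resulting confusion matrix, shuffle and exchange
controls, coding-mode classification, and the response-window sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import InfoResult, ResponseSet, Session, SpikeTrain

#: Geometric ladder of temporal-precision costs (1/s), q = 0 included.
DEFAULT_Q_GRID = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0)

#: Canonical response windows (s).
CANONICAL_WINDOWS = (0.2, 0.5, 1.0, 1.5, 2.0)

#: Default generalized-mean exponent for classifier averaging.
DEFAULT_Z = -2.0


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def count_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Absolute spike-count difference (the q = 0 metric)."""
    return float(abs(len(a) - len(b)))


def vp_distance_multi_q(
    a: np.ndarray, b: np.ndarray, qs: np.ndarray
) -> np.ndarray:
    """Edit distance for all ``qs`` at once (insert/delete 1, shift q*|dt|).

    Standard dynamic program on the sorted trains, vectorized across q and
    across the inner index via a prefix-minimum trick for the
    insertion recurrence.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    qs = np.atleast_1d(np.asarray(qs, dtype=float))
    if np.any(qs < 0):
        raise ValueError("q must be non-negative")
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return np.full(len(qs), float(n + m))

    G = qs[:, None, None] * np.abs(a[:, None] - b[None, :])  # (k, n, m)
    k = len(qs)
    prev = np.broadcast_to(np.arange(m + 1, dtype=float), (k, m + 1)).copy()
    js = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        # candidates ignoring the left (insertion) neighbor
        t = np.minimum(prev[:, 1:] + 1.0, prev[:, :-1] + G[:, i - 1, :])
        e = np.empty((k, m + 1))
        e[:, 0] = float(i)
        e[:, 1:] = t - js[1:]
        run = np.minimum.accumulate(e, axis=1)
        prev = run + js
    return prev[:, m]


def vp_distance(a: Sequence[float], b: Sequence[float], q: float) -> float:
    """Minimal edit cost between two spike trains at precision cost ``q``."""
    if q < 0:
        raise ValueError("q must be non-negative")
    return float(vp_distance_multi_q(np.asarray(a), np.asarray(b), [q])[0])


def _vp_batch(pairs_a, pairs_b, qs: np.ndarray) -> np.ndarray:
    """DP over many (a, b) pairs at once; returns (n_pairs, n_q).

    Trains are zero-padded to common lengths; rows past a pair's true
    length are masked out so the padded entries never propagate.
    """
    P = len(pairs_a)
    k = len(qs)
    na = np.array([len(a) for a in pairs_a])
    nb = np.array([len(b) for b in pairs_b])
    max_a, max_b = int(na.max(initial=0)), int(nb.max(initial=0))
    out = np.empty((P, k))
    if max_a == 0 or max_b == 0:
        out[:] = (na + nb)[:, None]
        return out

    A = np.zeros((P, max_a))
    B = np.zeros((P, max_b))
    for p in range(P):
        A[p, :len(pairs_a[p])] = pairs_a[p]
        B[p, :len(pairs_b[p])] = pairs_b[p]

    js = np.arange(max_b + 1, dtype=float)
    prev = np.broadcast_to(js, (P, k, max_b + 1)).copy()
    for i in range(1, max_a + 1):
        G = qs[None, :, None] * np.abs(A[:, None, i - 1:i] - B[:, None, :])
        t = np.minimum(prev[:, :, 1:] + 1.0, prev[:, :, :-1] + G)
        e = np.empty((P, k, max_b + 1))
        e[:, :, 0] = float(i)
        e[:, :, 1:] = t - js[1:]
        cur = np.minimum.accumulate(e, axis=2) + js
        alive = (na >= i)[:, None, None]
        prev = np.where(alive, cur, prev)
    for p in range(P):
        out[p] = prev[p, :, nb[p]]
    # pairs where one train is empty: distance is the other train's count
    empty = (na == 0) | (nb == 0)
    if np.any(empty):
        out[empty] = (na + nb)[empty, None]
    return out


def distance_matrices(
    responses: Sequence[np.ndarray], q_grid: Sequence[float]
) -> np.ndarray:
    """All pairwise distances: array of shape (len(q_grid), n, n)."""
    qs = np.asarray(q_grid, dtype=float)
    n = len(responses)
    D = np.zeros((len(qs), n, n))
    if n < 2:
        return D
    idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = _vp_batch(
        [responses[i] for i, _ in idx], [responses[j] for _, j in idx], qs
    )
    for (i, j), v in zip(idx, vals):
        D[:, i, j] = v
        D[:, j, i] = v
    return D


# ---------------------------------------------------------------------------
# Classifier confusion and mutual information
# ---------------------------------------------------------------------------

def _confusion_from_distances(
    D: np.ndarray,
    label_idx: np.ndarray,
    n_labels: int,
    z: float = DEFAULT_Z,
    tie_break: str = "split",
) -> tuple[np.ndarray, int]:
    """Assign each response to the label with the smallest generalized-mean
    distance to that label's other responses (self excluded).

    With a negative exponent ``z`` a zero distance dominates, so any zero
    distance makes the generalized mean zero.  Ties are split fractionally
    across the tied labels by default (``tie_break='split'``) or broken
    toward the smallest label index (``'first'``); the tie count is
    returned either way.
    """
    n = len(label_idx)
    conf = np.zeros((n_labels, n_labels))
    n_ties = 0
    members = [np.flatnonzero(label_idx == l) for l in range(n_labels)]
    for i in range(n):
        gms = np.empty(n_labels)
        for l in range(n_labels):
            others = members[l][members[l] != i]
            if len(others) == 0:
                raise ValueError(
                    "classification needs >= 2 responses per label "
                    "(self is excluded)"
                )
            d = D[i, others]
            if np.any(d == 0.0):
                gms[l] = 0.0
            elif z == 0.0:
                gms[l] = float(np.exp(np.mean(np.log(d))))
            else:
                gms[l] = float(np.mean(d ** z) ** (1.0 / z))
        best = np.flatnonzero(gms <= gms.min() * (1 + 1e-12))
        if len(best) > 1:
            n_ties += 1
            if tie_break == "split":
                conf[label_idx[i], best] += 1.0 / len(best)
                continue
            elif tie_break != "first":
                raise ValueError("tie_break must be 'split' or 'first'")
        conf[label_idx[i], best[0]] += 1.0
    return conf, n_ties


def classify_confusion(
    responses: ResponseSet,
    q: float,
    z: float = DEFAULT_Z,
    tie_break: str = "split",
) -> tuple[np.ndarray, int]:
    """Confusion matrix (true x inferred) at one q; rows ordered by first
    appearance of each label."""
    labels = list(dict.fromkeys(responses.labels))
    label_idx = np.array([labels.index(l) for l in responses.labels])
    D = distance_matrices(responses.responses, [q])[0]
    return _confusion_from_distances(D, label_idx, len(labels), z, tie_break)


def mutual_information(confusion: np.ndarray) -> float:
    """Plug-in mutual information (bits) of the joint (true, inferred)."""
    c = np.asarray(confusion, dtype=float)
    if np.any(c < 0) or c.sum() <= 0:
        raise ValueError("confusion must be non-negative with positive total")
    p = c / c.sum()
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pi * pj))
    return float(np.nansum(terms))


def _info_per_q(
    D_all: np.ndarray,
    label_idx: np.ndarray,
    n_labels: int,
    z: float,
    tie_break: str = "split",
) -> np.ndarray:
    H = np.empty(D_all.shape[0])
    for k in range(D_all.shape[0]):
        conf, _ = _confusion_from_distances(D_all[k], label_idx, n_labels, z, tie_break)
        H[k] = mutual_information(conf)
    return H


def info_vs_q(
    responses: ResponseSet,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    z: float = DEFAULT_Z,
    tie_break: str = "split",
    _D_all: np.ndarray | None = None,
) -> InfoResult:
    """H(q) curve with H_max, q_at_max (ties -> smallest q) and H_count."""
    qs = np.asarray(q_grid, dtype=float)
    if not np.any(qs == 0.0):
        raise ValueError("q_grid must include q = 0")
    labels = list(dict.fromkeys(responses.labels))
    label_idx = np.array([labels.index(l) for l in responses.labels])
    D_all = distance_matrices(responses.responses, qs) if _D_all is None else _D_all
    H = _info_per_q(D_all, label_idx, len(labels), z, tie_break)
    imax = int(np.argmax(H))  # argmax returns the first (smallest-q) maximum
    return InfoResult(
        q_grid=qs,
        H_of_q=H,
        H_max=float(H[imax]),
        q_at_max=float(qs[imax]),
        H_count=float(H[np.flatnonzero(qs == 0.0)[0]]),
        H_shuffled_mean=math.nan,
        H_shuffled_sd=math.nan,
        window=responses.window,
    )


# ---------------------------------------------------------------------------
# Controls
# ---------------------------------------------------------------------------

def shuffle_control(
    responses: ResponseSet,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    n: int = 40,
    rng: np.random.Generator | int | None = None,
    z: float = DEFAULT_Z,
    tie_break: str = "split",
    _D_all: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD of H per q under random label permutations (n repetitions).

    Distances are label-free, so the precomputed matrices are reused.
    """
    if n < 1:
        raise ValueError("shuffle_control requires n >= 1")
    rng = np.random.default_rng(rng)
    qs = np.asarray(q_grid, dtype=float)
    labels = list(dict.fromkeys(responses.labels))
    label_idx = np.array([labels.index(l) for l in responses.labels])
    D_all = distance_matrices(responses.responses, qs) if _D_all is None else _D_all
    H = np.empty((n, len(qs)))
    for r in range(n):
        perm = rng.permutation(label_idx)
        H[r] = _info_per_q(D_all, perm, len(labels), z, tie_break)
    return H.mean(axis=0), H.std(axis=0, ddof=0)


def exchange_responses(
    responses: ResponseSet, rng: np.random.Generator
) -> ResponseSet:
    """Redeal pooled same-label spikes across that label's responses,
    preserving each response's spike count (and hence the pooled rate
    envelope of each label exactly)."""
    out: list[np.ndarray] = [None] * len(responses.responses)
    labels = np.asarray(responses.labels, dtype=object)
    for lab in dict.fromkeys(responses.labels):
        idx = np.flatnonzero(labels == lab)
        pool = np.concatenate([responses.responses[i] for i in idx]) if len(idx) else []
        pool = rng.permutation(pool)
        pos = 0
        for i in idx:
            c = len(responses.responses[i])
            out[i] = np.sort(pool[pos:pos + c])
            pos += c
    return ResponseSet(out, list(responses.labels), responses.window)


def exchange_control(
    responses: ResponseSet,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    n: int = 10,
    rng: np.random.Generator | int | None = None,
    z: float = DEFAULT_Z,
    tie_break: str = "split",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD of H per q with spike times redealt within labels."""
    if n < 1:
        raise ValueError("exchange_control requires n >= 1")
    rng = np.random.default_rng(rng)
    qs = np.asarray(q_grid, dtype=float)
    labels = list(dict.fromkeys(responses.labels))
    label_idx = np.array([labels.index(l) for l in responses.labels])
    H = np.empty((n, len(qs)))
    for r in range(n):
        ex = exchange_responses(responses, rng)
        D_all = distance_matrices(ex.responses, qs)
        H[r] = _info_per_q(D_all, label_idx, len(labels), z, tie_break)
    return H.mean(axis=0), H.std(axis=0, ddof=0)


# ---------------------------------------------------------------------------
# Full analysis, coding class, window sweep
# ---------------------------------------------------------------------------

def coding_class(info: InfoResult, eps: float = 1e-9, rel: float = 0.0) -> str:
    """Classify the coding mode from H_max vs the controls.

    not_significant if H_max <= H_shuffled + 2 SD; else rate_count when
    H_max equals H_count (within ``eps`` absolute or ``rel`` relative);
    else rate_envelope when H_max does not exceed the exchange mean; else
    spike_timing.
    """
    if not info.significant:
        return "not_significant"
    tol = max(eps, rel * abs(info.H_max))
    if info.H_max - info.H_count <= tol:
        return "rate_count"
    if info.H_exchange_mean is None:
        raise ValueError("coding_class needs the exchange control")
    if info.H_max <= info.H_exchange_mean + eps:
        return "rate_envelope"
    return "spike_timing"


def run_msa(
    responses: ResponseSet,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    z: float = DEFAULT_Z,
    n_shuffle: int = 40,
    n_exchange: int = 10,
    rng: np.random.Generator | int | None = None,
    tie_break: str = "split",
) -> InfoResult:
    """Full metric-space analysis: H(q), shuffle and exchange controls, and
    the coding-mode label.  Set ``n_exchange=0`` to skip the exchange
    control (coding class then only distinguishes significance/rate_count)."""
    rng = np.random.default_rng(rng)
    qs = np.asarray(q_grid, dtype=float)
    D_all = distance_matrices(responses.responses, qs)
    info = info_vs_q(responses, qs, z, tie_break, _D_all=D_all)
    sh_mean, sh_sd = shuffle_control(
        responses, qs, n_shuffle, rng, z, tie_break, _D_all=D_all
    )
    iq = int(np.flatnonzero(qs == info.q_at_max)[0])
    info.shuffled_by_q = np.vstack([sh_mean, sh_sd])
    info.H_shuffled_mean = float(sh_mean[iq])
    info.H_shuffled_sd = float(sh_sd[iq])
    if n_exchange > 0:
        ex_mean, ex_sd = exchange_control(responses, qs, n_exchange, rng, z, tie_break)
        info.exchange_by_q = np.vstack([ex_mean, ex_sd])
        info.H_exchange_mean = float(ex_mean[iq])
        info.H_exchange_sd = float(ex_sd[iq])
        info.coding_class = coding_class(info)
    elif info.significant and info.H_max - info.H_count <= 1e-9:
        info.coding_class = "rate_count"
    elif not info.significant:
        info.coding_class = "not_significant"
    return info


def extract_responses(
    session: Session,
    unit: SpikeTrain,
    panel: Sequence[str],
    window: float,
) -> ResponseSet:
    """Collect per-trial spike times aligned at t0 and truncated to window."""
    resp, labs = [], []
    for tr in session.trials:
        if tr.stimulus_id not in panel:
            continue
        t0 = tr.t0
        seg = unit.times[
            np.searchsorted(unit.times, t0):np.searchsorted(unit.times, t0 + window)
        ]
        resp.append(seg - t0)
        labs.append(tr.stimulus_id)
    return ResponseSet(resp, labs, window)


def window_sweep(
    response_sets: Sequence[ResponseSet],
    windows: Sequence[float] = CANONICAL_WINDOWS,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    z: float = DEFAULT_Z,
    n_shuffle: int = 40,
    n_exchange: int = 10,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Population summary per window.

    For each window: mean H_max across all cells with non-significant cells
    set to zero, mean H at q = 0 among significant cells, and the proportion
    of significant cells.  ``response_sets`` holds one set per cell at the
    largest window; smaller windows are truncations.  Windows outside the
    canonical set are allowed but flagged.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for w in windows:
        h_max, h_count, n_sig = [], [], 0
        for rs in response_sets:
            info = run_msa(
                rs.truncated(w), q_grid, z, n_shuffle, n_exchange,
                np.random.default_rng(rng.integers(2**63)),
            )
            if info.significant:
                n_sig += 1
                h_max.append(info.H_max)
                h_count.append(info.H_count)
            else:
                h_max.append(0.0)
        n = len(response_sets)
        rows.append(
            dict(
                window_s=w,
                canonical=bool(any(abs(w - c) < 1e-12 for c in CANONICAL_WINDOWS)),
                n_cells=n,
                prop_significant=n_sig / n if n else math.nan,
                mean_H_max=float(np.mean(h_max)) if h_max else math.nan,
                mean_H_count_significant=(
                    float(np.mean(h_count)) if h_count else math.nan
                ),
            )
        )
    return pd.DataFrame(rows)
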