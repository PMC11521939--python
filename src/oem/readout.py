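"""Semantic readouts of the calyx output.

Odorant identity is carried by *which* KCs respond and in *what order*
they first spike -- not by how strongly they fire.  This module provides
the rank-curve view of KC dendritic inputs/outputs, the active-KC set, the
first-spike-sequence code (the time-ordered first spikes of all active
KCs), cumulative interspike-interval curves, and distances between
sequences used to quantify concentration invariance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from oem.neuron import SpikeTrain

__all__ = [
    "RankCurve",
    "FirstSpikeSequence",
    "CumulativeISICurve",
    "rank_curve",
    "active_set",
    "first_spike_sequence",
    "cumulative_isi",
    "sequence_distance",
    "invariance_report",
    "rank_gap_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankCurve:
    """Values sorted descending with the original index of each rank."""

    values: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        i = np.asarray(self.indices, dtype=np.int64)
        if v.shape != i.shape:
            raise ValueError("values and indices must align")
        if v.size and np.any(np.diff(v) > 0):
            raise ValueError("rank curve must be non-increasing")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "indices", i)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class FirstSpikeSequence:
    """Time-ordered (kc_id, first_spike_time) pairs of the active KCs."""

    kc_ids: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.kc_ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.float64)
        if k.shape != t.shape:
            raise ValueError("ids and times must align")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("sequence times must be non-decreasing")
        object.__setattr__(self, "kc_ids", k)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.kc_ids.size)

    def to_records(self) -> list[dict]:
        return [
            {"kc": int(k), "t": float(t)}
            for k, t in zip(self.kc_ids, self.times)
        ]


@dataclass(frozen=True)
class CumulativeISICurve:
    """Cumulative time from the first spike of the sequence, per position."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.size == 0:
            raise ValueError("cumulative ISI curve needs at least one spike")
        if np.any(np.diff(v) < 0) or v[0] != 0:
            raise ValueError("curve must start at 0 and be non-decreasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


def rank_curve(values) -> RankCurve:
    """Stable descending sort; ties broken by ascending original index."""
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("rank curve requires finite values")
    order = np.argsort(-values, kind="stable")
    return RankCurve(values[order], order)


def active_set(x_kcd, threshold: float = 0.5) -> set[int]:
    """KC ids with steady dendritic output above the spiking threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    x_kcd = np.asarray(x_kcd, dtype=np.float64)
    return set(np.nonzero(x_kcd > threshold)[0].tolist())


def first_spike_sequence(
    kc_spikes: list[SpikeTrain],
    active: set[int],
    t_origin: float = 0.0,
) -> FirstSpikeSequence:
    """Join the first spike of each active KC into one sequence.

    Spike times are reported relative to ``t_origin`` (stimulus onset).
    Active KCs that never spiked are dropped with a logged warning.  Ties
    in time are broken by ascending KC id.
    """
    ids, times = [], []
    for kc in sorted(active):
        train = kc_spikes[kc]
        after = train.times[train.times >= t_origin]
        if after.size == 0:
            logger.warning("active KC %d produced no spikes; dropped", kc)
            continue
        ids.append(kc)
        times.append(after[0] - t_origin)
    order = sorted(range(len(ids)), key=lambda i: (times[i], ids[i]))
    return FirstSpikeSequence(
        np.array([ids[i] for i in order], dtype=np.int64),
        np.array([times[i] for i in order]),
    )


def cumulative_isi(seq: FirstSpikeSequence) -> CumulativeISICurve:
    """curve[k] = t_k - t_0 for the k-th spike of the sequence."""
    if len(seq) == 0:
        raise ValueError("cumulative ISI of an empty sequence is undefined")
    return CumulativeISICurve(seq.times - seq.times[0])


def sequence_distance(
    seq_a: FirstSpikeSequence, seq_b: FirstSpikeSequence
) -> tuple[float, float]:
    """(order_distance, set_overlap) between two first-spike sequences.

    ``set_overlap`` is the Jaccard index of the active-KC sets.
    ``order_distance`` is the normalized Kendall-tau distance between the
    two orderings restricted to the shared KCs (0 = same order, 1 = fully
    reversed; 0 if fewer than 2 KCs are shared).
    """
    set_a = set(seq_a.kc_ids.tolist())
    set_b = set(seq_b.kc_ids.tolist())
    union = set_a | set_b
    overlap = len(set_a & set_b) / len(union) if union else 1.0
    shared = sorted(set_a & set_b)
    if len(shared) < 2:
        return 0.0, overlap
    pos_a = {int(k): i for i, k in enumerate(seq_a.kc_ids)}
    pos_b = {int(k): i for i, k in enumerate(seq_b.kc_ids)}
    ranks_a = [pos_a[k] for k in shared]
    ranks_b = [pos_b[k] for k in shared]
    tau = stats.kendalltau(ranks_a, ranks_b).statistic
    if np.isnan(tau):
        return 0.0, overlap
    dist = min(1.0, max(0.0, (1.0 - tau) / 2.0))
    if dist < 1e-12:
        dist = 0.0
    return float(dist), overlap


def invariance_report(
    runs: list[tuple[str, float, FirstSpikeSequence]]
) -> pd.DataFrame:
    """Within- vs between-odorant sequence distances.

    ``runs`` holds (odorant label, concentration, sequence) triples with at
    least two concentrations per label.  Returns a one-row-per-statistic
    table with the mean order distance and set overlap within odorants
    (across concentrations) and between odorants, plus the invariance
    verdict (within-distance < between-distance).  With fewer than two
    odorants the between-odorant statistics are reported as NaN and the
    verdict is missing.
    """
    by_label: dict[str, list[FirstSpikeSequence]] = {}
    for label, _conc, seq in runs:
        by_label.setdefault(label, []).append(seq)
    for label, seqs in by_label.items():
        if len(seqs) < 2:
            raise ValueError(f"odorant {label!r} needs >= 2 concentrations")

    within_d, within_o = [], []
    for seqs in by_label.values():
        for s1, s2 in itertools.combinations(seqs, 2):
            d, o = sequence_distance(s1, s2)
            within_d.append(d)
            within_o.append(o)

    between_d, between_o = [], []
    for la, lb in itertools.combinations(by_label, 2):
        for s1 in by_label[la]:
            for s2 in by_label[lb]:
                d, o = sequence_distance(s1, s2)
                between_d.append(d)
                between_o.append(o)

    has_between = len(between_d) > 0
    rows = {
        "within_order_distance": float(np.mean(within_d)),
        "within_set_overlap": float(np.mean(within_o)),
        "between_order_distance": float(np.mean(between_d)) if has_between else np.nan,
        "between_set_overlap": float(np.mean(between_o)) if has_between else np.nan,
    }
    rows["invariant"] = (
        bool(rows["within_order_distance"] < rows["between_order_distance"])
        if has_between
        else None
    )
    return pd.DataFrame([rows])


def rank_gap_ratio(values) -> float:
    """Largest adjacent-rank difference as a fraction of the curve range.

    Flags the visible gap that dominant receptors leave in the KC
    dendritic-input rank curve: a single step between the dominant-wired
    KC group and the rest concentrates most of the curve's range into one
    adjacent difference (ratio near 1 for one dominant channel, ~1/k for
    k comparable dominants), while broad profiles spread the range over
    many small steps (ratio well below 0.2).  The ratio is used instead
    of a median-normalized difference because the aggregate drives of a
    discrete spiking cascade carry exact ties, which make any
    median-of-differences statistic degenerate.
    """
    curve = rank_curve(values).values
    if curve.size < 3:
        raise ValueError("need at least 3 values for a gap ratio")
    diffs = -np.diff(curve)
    rng = curve[0] - curve[-1]
    if rng <= 0:
        return 0.0
    return float(diffs.max() / rng)
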