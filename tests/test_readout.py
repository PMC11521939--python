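"""Rank curves, first-spike sequences and sequence distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oem.neuron import SpikeTrain, rheobase, simulate_cs
from oem.readout import (
    CumulativeISICurve,
    FirstSpikeSequence,
    active_set,
    cumulative_isi,
    first_spike_sequence,
    invariance_report,
    rank_curve,
    rank_gap_ratio,
    sequence_distance,
)


def _seq(ids, times):
    return FirstSpikeSequence(np.array(ids), np.array(times, dtype=float))


# -- rank curves ------------------------------------------------------------


def test_rank_curve_examples_and_tie_break():
    curve = rank_curve([0.2, 0.9, 0.5])
    assert np.allclose(curve.values, [0.9, 0.5, 0.2])
    assert np.array_equal(curve.indices, [1, 2, 0])
    const = rank_curve([0.3, 0.3, 0.3])
    assert np.array_equal(const.indices, [0, 1, 2])  # stable tie-break
    assert len(rank_curve([])) == 0


def test_rank_curve_matches_sort_oracle():
    rng = np.random.default_rng(0)
    values = rng.normal(size=200)
    curve = rank_curve(values)
    oracle = np.sort(values)[::-1]
    assert np.array_equal(curve.values, oracle)
    assert np.array_equal(values[curve.indices], curve.values)


def test_rank_gap_ratio_flags_dominant_structure():
    gapped = np.concatenate([np.full(20, 10.0), np.full(80, 1.0)])
    smooth = np.linspace(10, 1, 100)
    assert rank_gap_ratio(gapped) > 5 * rank_gap_ratio(smooth)


# -- active sets ------------------------------------------------------------


def test_active_set_threshold_semantics():
    assert active_set([0.6, 0.4], 0.5) == {0}
    assert active_set([0.1, 0.2], 0.5) == set()
    with pytest.raises(ValueError):
        active_set([0.5], 1.5)


def test_active_fraction_non_increasing_in_threshold():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, 500)
    fractions = [len(active_set(x, thr)) for thr in np.linspace(0.05, 0.95, 10)]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


# -- first-spike sequences --------------------------------------------------


def test_first_spike_order_follows_drive_order():
    """Three deterministic neurons at descending supra-rheobase currents
    spike for the first time in descending-current order."""
    rb = rheobase()
    trains = [
        simulate_cs(current, 0.5, neuron_id=i)
        for i, current in enumerate([3 * rb, 2 * rb, 1.3 * rb])
    ]
    seq = first_spike_sequence(trains, {0, 1, 2})
    assert np.array_equal(seq.kc_ids, [0, 1, 2])
    assert np.all(np.diff(seq.times) > 0)


def test_first_spike_sequence_edge_cases(caplog):
    trains = [
        SpikeTrain("KC", 0, np.array([0.10, 0.30])),
        SpikeTrain("KC", 1, np.empty(0)),
        SpikeTrain("KC", 2, np.array([0.05])),
    ]
    assert len(first_spike_sequence(trains, set())) == 0
    seq = first_spike_sequence(trains, {0, 1, 2})
    assert np.array_equal(seq.kc_ids, [2, 0])  # silent KC 1 dropped
    assert "no spikes" in caplog.text
    aligned = first_spike_sequence(trains, {0}, t_origin=0.2)
    assert aligned.times[0] == pytest.approx(0.1)


def test_cumulative_isi_values():
    curve = cumulative_isi(_seq([5, 2, 9], [0.10, 0.12, 0.15]))
    assert np.allclose(curve.values, [0.0, 0.02, 0.05])
    single = cumulative_isi(_seq([1], [0.3]))
    assert np.allclose(single.values, [0.0])
    with pytest.raises(ValueError):
        cumulative_isi(_seq([], []))
    with pytest.raises(ValueError):
        CumulativeISICurve(np.array([0.0, -0.01]))


# -- sequence distances -----------------------------------------------------


def test_sequence_distance_extremes():
    a = _seq([1, 2, 3], [0.1, 0.2, 0.3])
    assert sequence_distance(a, a) == (0.0, 1.0)
    reversed_ = _seq([3, 2, 1], [0.1, 0.2, 0.3])
    d, o = sequence_distance(a, reversed_)
    assert d == pytest.approx(1.0) and o == pytest.approx(1.0)
    disjoint = _seq([7, 8], [0.1, 0.2])
    d, o = sequence_distance(a, disjoint)
    assert d == 0.0 and o == 0.0


def test_order_distance_matches_pair_counting_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        n = int(rng.integers(2, 12))
        ids = np.arange(n)
        perm_a = rng.permutation(ids)
        perm_b = rng.permutation(ids)
        a = _seq(perm_a, np.arange(n) * 0.01)
        b = _seq(perm_b, np.arange(n) * 0.01)
        d, o = sequence_distance(a, b)
        # O(n^2) discordant-pair count
        pos_a = {int(k): i for i, k in enumerate(perm_a)}
        pos_b = {int(k): i for i, k in enumerate(perm_b)}
        disc = sum(
            (pos_a[i] - pos_a[j]) * (pos_b[i] - pos_b[j]) < 0
            for i in range(n)
            for j in range(i + 1, n)
        )
        assert o == 1.0
        assert d == pytest.approx(disc / (n * (n - 1) / 2))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.integers(0, 30), min_size=1, max_size=12, unique=True),
    st.lists(st.integers(0, 30), min_size=1, max_size=12, unique=True),
)
def test_sequence_distance_symmetry_and_identity(ids_a, ids_b):
    a = _seq(ids_a, np.arange(len(ids_a)) * 0.01)
    b = _seq(ids_b, np.arange(len(ids_b)) * 0.01)
    assert sequence_distance(a, a)[0] == 0.0
    dab = sequence_distance(a, b)
    dba = sequence_distance(b, a)
    assert dab[0] == pytest.approx(dba[0])
    assert dab[1] == pytest.approx(dba[1])
    assert 0.0 <= dab[0] <= 1.0 and 0.0 <= dab[1] <= 1.0


# -- invariance report ------------------------------------------------------


def test_invariance_report_trivial_cases():
    seq = _seq([1, 2], [0.1, 0.2])
    runs = [("odorA", 50.0, seq), ("odorA", 100.0, seq)]
    report = invariance_report(runs)
    assert report["within_order_distance"][0] == 0.0
    assert np.isnan(report["between_order_distance"][0])
    assert report["invariant"][0] is None
    other = _seq([2, 1], [0.1, 0.2])
    runs += [("odorB", 50.0, other), ("odorB", 100.0, other)]
    report = invariance_report(runs)
    assert report["invariant"][0]
    with pytest.raises(ValueError, match="concentrations"):
        invariance_report([("x", 50.0, seq)])


def test_roundtrip_sequence_to_curve_lengths():
    seq = _seq([4, 1, 9, 2], [0.1, 0.15, 0.15, 0.4])
    curve = cumulative_isi(seq)
    assert len(curve) == len(seq)
    assert curve.values[0] == 0.0
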