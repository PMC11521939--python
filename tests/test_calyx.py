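"""Calyx wiring and DNP kinetics."""

import numpy as np
import pytest
from scipy import stats

from oem.calyx import (
    APLParams,
    BipartiteGraph,
    CalyxParams,
    KCDendriteParams,
    apl_step,
    dendritic_input,
    graph_to_edges,
    kc_dendrite_step,
    run_calyx,
    sample_pn_kc_graph,
)
from oem.neuron import SpikeTrain, rheobase


def test_graph_has_exact_q_distinct_inputs():
    g = sample_pn_kc_graph(23, 500, 6, seed=1)
    assert g.connections.shape == (500, 6)
    for row in g.connections:
        assert len(set(row.tolist())) == 6
        assert row.min() >= 0 and row.max() < 23


def test_graph_determinism_and_variability():
    a = sample_pn_kc_graph(23, 100, 6, seed=3)
    b = sample_pn_kc_graph(23, 100, 6, seed=3)
    c = sample_pn_kc_graph(23, 100, 6, seed=4)
    assert np.array_equal(a.connections, b.connections)
    assert not np.array_equal(a.connections, c.connections)


def test_graph_rejects_invalid_q():
    with pytest.raises(ValueError, match="invalid Q"):
        sample_pn_kc_graph(23, 10, 24)
    with pytest.raises(ValueError, match="invalid Q"):
        sample_pn_kc_graph(23, 10, 0)


def test_graph_degenerate_q_equals_r():
    g = sample_pn_kc_graph(5, 20, 5, seed=0)
    for row in g.connections:
        assert set(row.tolist()) == set(range(5))
    rates = np.array([10.0, 20.0, 5.0, 1.0, 7.0])
    assert np.allclose(dendritic_input(g, rates), rates.sum())


def test_wired_fraction_matches_hypergeometric_expectation():
    """P(KC samples a given PN) = 1 - C(R-1,Q)/C(R,Q) = Q/R."""
    r_pns, q = 23, 6
    fractions = [
        sample_pn_kc_graph(r_pns, 200, q, seed=s).wired_fraction(0)
        for s in range(20)
    ]
    expected = q / r_pns
    sem = np.sqrt(expected * (1 - expected) / (200 * 20))
    assert abs(np.mean(fractions) - expected) < 4 * sem


def test_bipartite_graph_validation():
    with pytest.raises(ValueError, match="distinct"):
        BipartiteGraph(np.array([[1, 1]]), n_pns=5)
    with pytest.raises(ValueError, match="out of range"):
        BipartiteGraph(np.array([[0, 7]]), n_pns=5)


def test_graph_edge_list():
    g = sample_pn_kc_graph(10, 3, 2, seed=0)
    edges = graph_to_edges(g)
    assert len(edges) == 6
    assert edges[0][0] == 0 and edges[-1][0] == 2


def test_kc_dendrite_matches_divisive_rate_equation():
    """Mean under Poisson PN drive: a*lam / (a*lam + b + k*y)."""
    params = KCDendriteParams(alpha1=0.05, beta1=5.0, kappa1=20.0)
    rng = np.random.default_rng(5)
    dt, t_total = 1e-4, 80.0
    for lam, y in [(120.0, 0.3), (60.0, 0.0), (200.0, 0.6)]:
        spikes = rng.poisson(lam * dt, size=int(t_total / dt))
        x, acc = 0.0, 0.0
        for s in spikes:
            x = kc_dendrite_step(x, int(s), y, params, dt)
            acc += x
        expected = (
            params.alpha1 * lam
            / (params.alpha1 * lam + params.beta1 + params.kappa1 * y)
        )
        assert acc / spikes.shape[0] == pytest.approx(expected, rel=0.05)


def test_apl_matches_saturating_rate_equation():
    params = APLParams(alpha1=0.002, beta1=10.0)
    rng = np.random.default_rng(6)
    dt, t_total = 1e-4, 80.0
    means = []
    for total_rate in (1000.0, 2000.0, 4000.0):
        spikes = rng.poisson(total_rate * dt, size=int(t_total / dt))
        x, acc = 0.0, 0.0
        for s in spikes:
            x = apl_step(x, int(s), params, dt)
            acc += x
        mean = acc / spikes.shape[0]
        expected = (
            params.alpha1 * total_rate
            / (params.alpha1 * total_rate + params.beta1)
        )
        assert mean == pytest.approx(expected, rel=0.05)
        means.append(mean)
    # saturation: doubling the rate less than doubles the mean
    assert means[1] < 2 * means[0] and means[2] < 2 * means[1]


def test_apl_feedback_lowers_dendritic_state():
    params = KCDendriteParams(alpha1=0.05, beta1=5.0, kappa1=20.0)
    rng = np.random.default_rng(8)
    spikes = rng.poisson(100.0 * 1e-4, size=200_000)
    means = []
    for y in (0.0, 0.4):
        x, acc = 0.0, 0.0
        for s in spikes:
            x = kc_dendrite_step(x, int(s), y, params, 1e-4)
            acc += x
        means.append(acc / spikes.shape[0])
    assert means[1] < means[0]


def test_run_calyx_silent_input():
    graph = sample_pn_kc_graph(4, 20, 2, seed=0)
    silent = [SpikeTrain("PN", r, np.empty(0)) for r in range(4)]
    kc, res = run_calyx(silent, graph, t_total=0.3)
    assert all(len(t) == 0 for t in kc)
    assert res["x_apl_steady"] == 0.0
    assert np.all(res["x_kcd_steady"] == 0.0)


def test_run_calyx_rejects_mismatched_pn_count():
    graph = sample_pn_kc_graph(4, 10, 2, seed=0)
    with pytest.raises(ValueError, match="PN trains"):
        run_calyx([SpikeTrain("PN", 0, np.empty(0))], graph, t_total=0.1)


def test_i_max_calibration_puts_threshold_at_rheobase():
    params = KCDendriteParams()
    assert params.resolved_i_max(CalyxParams().kc_bsg) == pytest.approx(
        2 * rheobase(), rel=1e-6
    )
    assert KCDendriteParams(i_max=12.0).resolved_i_max(
        CalyxParams().kc_bsg
    ) == 12.0


def test_steady_output_is_monotone_in_dendritic_drive(antenna_al_runs, calyx_runs):
    """Spearman rho ~ 1 between per-KC PN drive and steady dendritic output
    (the dendritic transfer is a monotone sigmoid).  The broad fixture is
    used because it recruits many PNs, giving graded, mostly distinct
    drives; sparse fixtures collapse the drives onto a few tied values."""
    stage = antenna_al_runs[("broad", 150.0)]
    run = calyx_runs[("broad", 150.0, 1)]
    drive = dendritic_input(run["graph"], stage["pn_rates"])
    x = run["x_on"]
    keep = drive > 1.0
    values, counts = np.unique(drive[keep], return_counts=True)
    distinct = np.isin(drive, values[counts == 1]) & keep
    assert distinct.sum() > 20
    rho = stats.spearmanr(drive[distinct], x[distinct]).statistic
    assert rho > 0.995
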