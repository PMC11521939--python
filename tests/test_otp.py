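"""Transduction cascade: closed forms, ODE oracles, reductions, bounds."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from oem.odorants import make_mixture, step_waveform, synth_affinity_profile
from oem.otp import (
    CoReceptorParams,
    OTPParams,
    PeriReceptorParams,
    bound_receptor_steady_state,
    bound_receptor_step,
    coreceptor_step,
    effective_affinity,
    peri_receptor,
    run_osn,
    transduction_current,
    transduction_traces,
)

DT = 1e-5


# -- peri-receptor ----------------------------------------------------------


def test_peri_receptor_zero_input_and_dc_gain():
    params = PeriReceptorParams(gamma=0.0)
    assert np.all(peri_receptor(np.zeros(1000), params, DT) == 0.0)
    u = np.full(50_000, 120.0)
    v = peri_receptor(u, params, DT)
    assert v[-1] == pytest.approx(120.0, rel=1e-6)


def test_peri_receptor_matches_fir_convolution_oracle():
    rng = np.random.default_rng(5)
    u = np.abs(rng.normal(50.0, 30.0, size=4000))
    params = PeriReceptorParams(tau=0.01, gamma=0.1)
    v = peri_receptor(u, params, DT)
    # independent oracle: direct FIR convolution with the discrete kernel
    # h[k] = (1 - e^{-dt/tau}) e^{-k dt/tau}, unit DC gain on infinite support
    k = np.arange(4000)
    decay = np.exp(-DT / params.tau)
    h = (1.0 - decay) * decay**k
    du = np.diff(u, prepend=0.0) / DT
    oracle = np.maximum(
        np.convolve(u, h)[:4000] + params.gamma * np.convolve(du, h)[:4000], 0.0
    )
    assert np.allclose(v, oracle, rtol=1e-9, atol=1e-9)


def test_peri_receptor_overshoots_on_step_onset_with_derivative_gain():
    u = np.zeros(30_000)
    u[5000:] = 100.0
    v = peri_receptor(u, PeriReceptorParams(tau=0.01, gamma=0.05), DT)
    assert v.max() > 100.0 * 1.05  # transient overshoot
    assert v[-1] == pytest.approx(100.0, rel=1e-3)  # settles to DC


# -- competitive binding ----------------------------------------------------


def test_steady_state_closed_form_examples():
    x1, total = bound_receptor_steady_state([1.0], [1.0])
    assert x1[0] == pytest.approx(0.5) and total == pytest.approx(0.5)
    x1, total = bound_receptor_steady_state([1.0, 1.0], [1.0, 1.0])
    assert np.allclose(x1, 1 / 3) and total == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        bound_receptor_steady_state([-1.0], [1.0])


def test_binding_ode_reaches_closed_form_steady_state():
    """Long-time integration of the competitive ODE matches the algebra."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = rng.integers(1, 5)
        a = rng.uniform(0.001, 0.2, n)
        d = rng.uniform(1.0, 20.0, n)
        b = a * d
        v = rng.uniform(0.0, 200.0, n)
        sol = solve_ivp(
            lambda _, x: b * v * (1 - x.sum()) - d * x,
            (0.0, 20.0),
            np.zeros(n),
            rtol=1e-10,
            atol=1e-12,
        )
        expected, _ = bound_receptor_steady_state(a, v)
        assert np.allclose(sol.y[:, -1], expected, atol=1e-6)


def test_bound_receptor_step_decay_and_conservation():
    x1 = np.array([0.4, 0.3])
    out = bound_receptor_step(x1, np.zeros(2), np.ones(2), np.array([2.0, 3.0]), 1e-3)
    assert np.allclose(out, x1 * (1 - np.array([2.0, 3.0]) * 1e-3))
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(1, 4)
        x = np.zeros(n)
        b = rng.uniform(0.0, 0.5, n)
        d = rng.uniform(0.5, 20.0, n)
        v = rng.uniform(0.0, 200.0, n)
        for _ in range(500):
            x = bound_receptor_step(x, v, b, d, 1e-4)
            assert np.all(x >= 0) and x.sum() <= 1.0 + 1e-9


def test_effective_affinity_mixture_equivalence():
    """Mixture binds like a pure odorant with the effective affinity."""
    assert effective_affinity([0.3], [10.0]) == pytest.approx(0.3)
    assert effective_affinity([0.1, 0.3], [5.0, 5.0]) == pytest.approx(0.2)
    rng = np.random.default_rng(9)
    for _ in range(50):
        n = rng.integers(2, 6)
        a = rng.uniform(0.0, 0.5, n)
        v = rng.uniform(0.1, 100.0, n)
        a_eff = effective_affinity(a, v)
        _, total_mix = bound_receptor_steady_state(a, v)
        _, total_pure = bound_receptor_steady_state([a_eff], [v.sum()])
        assert total_mix == pytest.approx(total_pure, abs=1e-12)
    with pytest.raises(ValueError):
        effective_affinity([0.1], [0.0])


# -- co-receptor channel ----------------------------------------------------


def test_coreceptor_zero_input_fixed_point():
    params = CoReceptorParams()
    x2, x3 = 0.0, 0.0
    for _ in range(100):
        x2, x3 = coreceptor_step(x2, x3, 0.0, params, 1e-4)
    assert x2 == 0.0 and x3 == 0.0


def test_coreceptor_equilibrium_without_calcium_feedback():
    params = CoReceptorParams(kappa=0.0)
    x2, x3 = 0.0, 0.0
    drive = 0.4
    for _ in range(2_000_000):
        x2, x3 = coreceptor_step(x2, x3, drive, params, 1e-5)
    expected = params.alpha2 * drive / (params.alpha2 * drive + params.beta2)
    assert x2 == pytest.approx(expected, abs=1e-4)


def test_calcium_feedback_suppresses_gating():
    """kappa>0 equilibrium (root-finding oracle) sits below the kappa=0 one."""
    p = CoReceptorParams()
    drive = 0.4
    no_ca = p.alpha2 * drive / (p.alpha2 * drive + p.beta2)

    def residual(x2):
        x3 = p.alpha3 * x2 / p.beta3
        return (
            p.alpha2 * drive * (1 - x2)
            - p.beta2 * x2
            - p.kappa * x2 ** (2 / 3) * x3 ** (2 / 3)
        )

    root = brentq(residual, 1e-9, 1.0)
    assert root < no_ca
    x2, x3 = 0.0, 0.0
    for _ in range(1_500_000):
        x2, x3 = coreceptor_step(x2, x3, drive, p, 1e-5)
    assert x2 == pytest.approx(root, abs=2e-3)


def test_transduction_current_hill_points_and_dynamic_convergence():
    p = CoReceptorParams()
    assert transduction_current(0.0, p) == 0.0
    assert transduction_current(p.c, p) == pytest.approx(p.i_max / 2)
    # the relaxation rates are O(0.1)/s, so dynamic mode needs ~100 s to
    # settle; integrate the kinetic ODE on a coarser grid
    x2_trace = np.full(100_000, 0.3)
    dyn = transduction_current(x2_trace, p, mode="dynamic", dt=1e-3)
    steady = transduction_current(0.3, p)
    assert abs(dyn[-1] - steady) < 1e-6 * p.i_max
    with pytest.raises(ValueError):
        transduction_current(0.3, p, mode="quantum")


# -- full OSN cascade -------------------------------------------------------


def test_zero_concentration_gives_no_spikes():
    aff = synth_affinity_profile(5, "sparse-1", seed=0)
    odor = make_mixture([(aff, 0.0)], 0.2, 0.8)
    train = run_osn(odor, receptor=0, t_total=1.0)
    assert len(train) == 0


def test_single_component_mixture_equals_pure_odorant():
    """|O|=1 mixture and the mono-molecular path are the same trajectory."""
    aff = synth_affinity_profile(8, "sparse-1", seed=4)
    dom = int(np.argmax(aff.affinity[0, :, 0]))
    pure = make_mixture([(aff, 150.0)], 0.1, 0.9)
    traces = transduction_traces(pure, dom, OTPParams(), 1.0, DT)
    assert traces["x1"].shape[0] == 1
    spikes_a = run_osn(pure, dom, t_total=1.0)
    spikes_b = run_osn(pure, dom, t_total=1.0)
    assert np.array_equal(spikes_a.times, spikes_b.times)


def test_dominant_channel_fires_fastest_and_rates_monotone():
    aff = synth_affinity_profile(23, "sparse-1", seed=7)
    dom = int(np.argmax(aff.affinity[0, :, 0]))
    others = [r for r in range(23) if r != dom][:4]
    rates = {}
    for amp in (50.0, 100.0, 150.0, 200.0):
        odor = make_mixture([(aff, amp)], 0.1, 0.9)
        train = run_osn(odor, dom, t_total=1.0)
        rates[amp] = train.rate(0.5, 0.9)
        for r in others:
            assert run_osn(odor, r, t_total=1.0).rate(0.5, 0.9) < rates[amp]
    vals = [rates[a] for a in (50.0, 100.0, 150.0, 200.0)]
    assert all(x <= y for x, y in zip(vals, vals[1:]))
    assert vals[-1] > vals[0]
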