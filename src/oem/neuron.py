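"""Noisy Connor-Stevens point neuron: the biophysical spike generator (BSG).

Every spiking population in the cascade (OSNs, Pre-LN, Post-eLN/iLN, PNs,
KCs) converts its input current into spikes through the same point-neuron
model: the classic Connor-Stevens model (Na, delayed-rectifier K, transient
A-current, leak) with additive white current noise integrated by
Euler-Maruyama.  The A-current makes the neuron Type I: the f-I curve rises
continuously from zero at rheobase, and first-spike latency to a current
step decreases monotonically with the step amplitude -- the property the
downstream first-spike-sequence code relies on.

Voltages are in mV, currents in uA/cm^2, conductances in mS/cm^2.  The
public API uses seconds; the gating kinetics are the standard per-ms forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from numba import njit

__all__ = [
    "ConnorStevensParams",
    "NeuronState",
    "SpikeTrain",
    "cs_step",
    "simulate_cs",
    "fi_curve",
    "rest_state",
    "rheobase",
    "REFRACTORY_S",
]

#: Refractory lockout applied after each detected spike (s).
REFRACTORY_S = 2e-3

#: Spike detection threshold: upward crossing of this voltage (mV).
SPIKE_THRESHOLD_MV = 0.0


@dataclass(frozen=True)
class ConnorStevensParams:
    """Maximal conductances, reversal potentials and noise scale.

    Defaults are the standard Connor-Stevens constants.  ``noise_sd`` is the
    intensity of the additive white current noise (uA/cm^2 * s^{1/2}); with
    ``noise_sd=0`` the model is deterministic.
    """

    g_na: float = 120.0
    e_na: float = 55.0
    g_k: float = 20.0
    e_k: float = -72.0
    g_a: float = 47.7
    e_a: float = -75.0
    g_leak: float = 0.3
    e_leak: float = -17.0
    capacitance: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_a", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")

    def as_array(self) -> np.ndarray:
        """Pack membrane constants for the compiled kernels."""
        return np.array(
            [
                self.g_na,
                self.e_na,
                self.g_k,
                self.e_k,
                self.g_a,
                self.e_a,
                self.g_leak,
                self.e_leak,
                self.capacitance,
            ],
            dtype=np.float64,
        )


@dataclass
class NeuronState:
    """Membrane voltage (mV) and the five gating variables, each in [0,1]."""

    v: float = -68.0
    m: float = 0.01
    h: float = 0.97
    n: float = 0.16
    a: float = 0.54
    b: float = 0.29

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.v, self.m, self.h, self.n, self.a, self.b)

    def validate(self) -> None:
        vals = self.as_tuple()
        names = ("v", "m", "h", "n", "a", "b")
        for name, val in zip(names, vals):
            if not math.isfinite(val):
                raise FloatingPointError(
                    f"Connor-Stevens integration failure: state variable "
                    f"'{name}' is {val!r}"
                )


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one neuron, tagged with population and index."""

    population: str
    neuron_id: int
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or np.any(t < 0)):
            raise ValueError("spike times must be strictly increasing and >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    def rate(self, t0: float, t1: float) -> float:
        """Mean firing rate (Hz) in the window [t0, t1)."""
        if t1 <= t0:
            raise ValueError("window must have positive length")
        count = int(np.sum((self.times >= t0) & (self.times < t1)))
        return count / (t1 - t0)


# ---------------------------------------------------------------------------
# Compiled kernels.  Gating kinetics follow the standard Connor-Stevens
# formulation (V in mV, t in ms; temperature scaling folded into the rate
# constants).  Shared by every population simulator in the package.
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x / (1 - exp(-x / y)) with the removable singularity at x = 0 filled in.
    if abs(x) < 1e-7:
        return y
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True, inline="always")
def cs_update(v, m, h, n, a, b, i_ext, dt_ms, p):
    """One forward-Euler step of the Connor-Stevens equations.

    ``p`` is ConnorStevensParams.as_array().  Returns the new state tuple;
    gating variables are clipped to [0, 1].
    """
    am = 0.38 * _vtrap(v + 29.7, 10.0)
    bm = 15.2 * math.exp(-0.0556 * (v + 54.7))
    ah = 0.266 * math.exp(-0.05 * (v + 48.0))
    bh = 3.8 / (1.0 + math.exp(-0.1 * (v + 18.0)))
    an = 0.02 * _vtrap(v + 45.7, 10.0)
    bn = 0.25 * math.exp(-0.0125 * (v + 55.7))

    a_inf = (
        0.0761
        * math.exp(0.0314 * (v + 94.22))
        / (1.0 + math.exp(0.0346 * (v + 1.17)))
    ) ** (1.0 / 3.0)
    tau_a = 0.3632 + 1.158 / (1.0 + math.exp(0.0497 * (v + 55.96)))
    b_inf = (1.0 / (1.0 + math.exp(0.0688 * (v + 53.3)))) ** 4.0
    tau_b = 1.24 + 2.678 / (1.0 + math.exp(0.0624 * (v + 50.0)))

    i_ion = (
        p[0] * m * m * m * h * (v - p[1])
        + p[2] * n * n * n * n * (v - p[3])
        + p[4] * a * a * a * b * (v - p[5])
        + p[6] * (v - p[7])
    )
    v_new = v + dt_ms * (i_ext - i_ion) / p[8]

    m_new = m + dt_ms * (am * (1.0 - m) - bm * m)
    h_new = h + dt_ms * (ah * (1.0 - h) - bh * h)
    n_new = n + dt_ms * (an * (1.0 - n) - bn * n)
    a_new = a + dt_ms * (a_inf - a) / tau_a
    b_new = b + dt_ms * (b_inf - b) / tau_b

    m_new = min(max(m_new, 0.0), 1.0)
    h_new = min(max(h_new, 0.0), 1.0)
    n_new = min(max(n_new, 0.0), 1.0)
    a_new = min(max(a_new, 0.0), 1.0)
    b_new = min(max(b_new, 0.0), 1.0)
    return v_new, m_new, h_new, n_new, a_new, b_new


@njit(cache=True)
def _simulate_current_trace(i_trace, dt_s, p, sigma, v0, m0, h0, n0, a0, b0, seed):
    """Integrate one neuron driven by a sampled current trace.

    Returns (spike_bins, state_trace) where spike_bins is an int64 array of
    time-bin indices of detected spikes (upward 0 mV crossings with a 2 ms
    refractory lockout) and state_trace the final state.
    """
    nt = i_trace.shape[0]
    dt_ms = dt_s * 1e3
    noise_scale = sigma / math.sqrt(dt_s) if sigma > 0.0 else 0.0
    np.random.seed(seed)
    v, m, h, n, a, b = v0, m0, h0, n0, a0, b0
    spikes = np.empty(nt, dtype=np.int64)
    n_spk = 0
    refrac_bins = int(round(2e-3 / dt_s))
    last_spike = -refrac_bins - 1
    for t in range(nt):
        i_ext = i_trace[t]
        if noise_scale > 0.0:
            i_ext += noise_scale * np.random.normal()
        v_new, m, h, n, a, b = cs_update(v, m, h, n, a, b, i_ext, dt_ms, p)
        if v < 0.0 and v_new >= 0.0 and t - last_spike > refrac_bins:
            spikes[n_spk] = t
            n_spk += 1
            last_spike = t
        v = v_new
    out = spikes[:n_spk].copy()
    state = np.array([v, m, h, n, a, b])
    return out, state


@njit(cache=True)
def _simulate_state_trace(i_trace, dt_s, p, v0, m0, h0, n0, a0, b0):
    """Deterministic integration returning the full gating/voltage traces."""
    nt = i_trace.shape[0]
    dt_ms = dt_s * 1e3
    out = np.empty((nt, 6))
    v, m, h, n, a, b = v0, m0, h0, n0, a0, b0
    for t in range(nt):
        v, m, h, n, a, b = cs_update(v, m, h, n, a, b, i_trace[t], dt_ms, p)
        out[t, 0] = v
        out[t, 1] = m
        out[t, 2] = h
        out[t, 3] = n
        out[t, 4] = a
        out[t, 5] = b
    return out


# ---------------------------------------------------------------------------
# Python-level operations
# ---------------------------------------------------------------------------

MAX_STABLE_DT_S = 2e-5


def cs_step(
    state: NeuronState,
    i_input: float,
    dt: float,
    params: ConnorStevensParams,
    rng: np.random.Generator | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one neuron one Euler-Maruyama step.

    Returns the new state and whether the voltage crossed the spike threshold
    upward on this step.  The refractory lockout is the caller's concern (the
    long-run simulators apply a 2 ms guard).  With ``noise_sd = 0`` the step
    is deterministic.
    """
    if dt <= 0 or dt > MAX_STABLE_DT_S:
        raise ValueError(f"dt must be in (0, {MAX_STABLE_DT_S}] s for stability")
    if not math.isfinite(i_input):
        raise ValueError("input current must be finite")
    i_ext = float(i_input)
    if params.noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        i_ext += params.noise_sd / math.sqrt(dt) * rng.standard_normal()
    new = cs_update(*state.as_tuple(), i_ext, dt * 1e3, params.as_array())
    new_state = NeuronState(*new)
    new_state.validate()
    crossed = state.v < SPIKE_THRESHOLD_MV <= new_state.v
    return new_state, crossed


def simulate_cs(
    i_input: float | np.ndarray,
    t_total: float,
    params: ConnorStevensParams | None = None,
    dt: float = 1e-5,
    state: NeuronState | None = None,
    seed: int = 0,
    population: str = "neuron",
    neuron_id: int = 0,
) -> SpikeTrain:
    """Simulate a single neuron for ``t_total`` seconds.

    ``i_input`` is either a constant current or a pre-sampled trace on the
    dt grid.  Spike times are bin-centre times of detected threshold
    crossings.
    """
    params = params or ConnorStevensParams()
    state = state or rest_state(params)
    nt = int(round(t_total / dt))
    if np.isscalar(i_input):
        trace = np.full(nt, float(i_input))
    else:
        trace = np.asarray(i_input, dtype=np.float64)
        if trace.shape[0] != nt:
            raise ValueError("current trace length does not match t_total/dt")
    bins, _ = _simulate_current_trace(
        trace, dt, params.as_array(), params.noise_sd, *state.as_tuple(),
        seed % (2**32),
    )
    return SpikeTrain(population, neuron_id, bins * dt)


@lru_cache(maxsize=8)
def _rest_state_cached(key: tuple) -> tuple:
    p = np.array(key)
    trace = _simulate_state_trace(
        np.zeros(int(0.5 / 1e-5)), 1e-5, p, -68.0, 0.01, 0.97, 0.16, 0.54, 0.29
    )
    return tuple(trace[-1])


def rest_state(params: ConnorStevensParams | None = None) -> NeuronState:
    """Resting state at zero input current (relaxed for 0.5 s)."""
    params = params or ConnorStevensParams()
    return NeuronState(*_rest_state_cached(tuple(params.as_array())))


@lru_cache(maxsize=8)
def _rheobase_cached(key: tuple) -> float:
    params = ConnorStevensParams(*key[:9])
    lo, hi = 0.0, 40.0
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        spk = simulate_cs(mid, 0.5, params, dt=1e-5)
        if len(spk) > 0:
            hi = mid
        else:
            lo = mid
    return hi


def rheobase(params: ConnorStevensParams | None = None) -> float:
    """Minimal constant current (uA/cm^2) eliciting sustained spiking.

    Found by bisection on 0.5 s noiseless simulations; cached per parameter
    set.
    """
    params = params or ConnorStevensParams()
    base = replace(params, noise_sd=0.0)
    return _rheobase_cached(tuple(base.as_array()) + (0.0,))


def fi_curve(
    i_values,
    t_total: float = 1.0,
    params: ConnorStevensParams | None = None,
    dt: float = 1e-5,
    n_trials: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Firing rate (Hz) at each input current.

    Rates are spike count / ``t_total``.  With ``noise_sd > 0`` each current
    level is averaged over ``n_trials`` independent noise realizations.
    """
    if t_total < 1.0:
        raise ValueError("t_total must be >= 1 s for a stable rate estimate")
    params = params or ConnorStevensParams()
    i_values = np.asarray(list(i_values), dtype=np.float64)
    rates = np.empty(i_values.shape)
    trials = n_trials if params.noise_sd > 0 else 1
    for idx, current in enumerate(i_values):
        counts = [
            len(simulate_cs(current, t_total, params, dt=dt, seed=seed + 7919 * k))
            for k in range(trials)
        ]
        rates[idx] = float(np.mean(counts)) / t_total
    return rates
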