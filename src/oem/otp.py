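"""Odorant Transduction Process (OTP): concentration in, OSN spikes out.

The cascade for each receptor type is

1. peri-receptor filtering of each mixture component's concentration
   waveform (low-pass kernel plus a rectified derivative term),
2. competitive (syntopic) receptor binding: all components compete for the
   same unbound receptor pool,
       dx1_o/dt = b_o v_o (1 - sum_p x1_p) - d_o x1_o,
   whose steady state is the divisive form
       x1_o* = a_o v_o / (sum_p a_p v_p + 1),   a_o = b_o / d_o,
3. the co-receptor channel with calcium feedback,
       dx2/dt = a2 * (sum_o x1_o) (1 - x2) - b2 x2 - kappa x2^{2/3} x3^{2/3}
       dx3/dt = a3 x2 - b3 x3,
4. the transduction current, a Hill function of x2 in its (fast) steady
   state, I = x2^rho / (x2^rho + c^rho) * I_max,
5. a Connor-Stevens spike generator.

A mixture at a fixed component ratio behaves like a pure odorant whose
*effective affinity* is the concentration-weighted mean of the component
affinities; identity (semantics) and concentration (syntax) enter the
transduction current multiplicatively coupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from oem.neuron import (
    ConnorStevensParams,
    SpikeTrain,
    _simulate_current_trace,
    rest_state,
)
from oem.odorants import OdorantSet

__all__ = [
    "PeriReceptorParams",
    "CoReceptorParams",
    "OTPParams",
    "OTPState",
    "peri_receptor",
    "bound_receptor_step",
    "bound_receptor_steady_state",
    "effective_affinity",
    "coreceptor_step",
    "transduction_current",
    "run_osn",
    "run_antenna",
]

_STATE_TOL = 1e-9


@dataclass(frozen=True)
class PeriReceptorParams:
    """Exponential low-pass kernel h(t) = exp(-t/tau)/tau (unit DC gain)
    with a rectified derivative term of gain ``gamma``."""

    tau: float = 0.01  # s
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("peri-receptor time constant must be > 0")


@dataclass(frozen=True)
class CoReceptorParams:
    """Co-receptor channel, calcium feedback and current constants.

    Rates in 1/s; ``i_max`` in uA/cm^2.  Defaults were chosen with the
    bundled sweep utility so that 50-200 ppm steps of the synthetic
    odorants span non-saturated OSN firing rates.
    """

    alpha2: float = 10.0
    beta2: float = 2.0
    kappa: float = 10.0
    alpha3: float = 1.0
    beta3: float = 1.0
    rho: float = 2.0
    c: float = 0.45
    i_max: float = 50.0

    def __post_init__(self) -> None:
        for name in ("alpha2", "beta2", "kappa", "alpha3", "beta3", "i_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rho <= 0 or self.c <= 0:
            raise ValueError("rho and c must be > 0")


@dataclass(frozen=True)
class OTPParams:
    peri: PeriReceptorParams = field(default_factory=PeriReceptorParams)
    coreceptor: CoReceptorParams = field(default_factory=CoReceptorParams)
    bsg: ConnorStevensParams = field(default_factory=ConnorStevensParams)
    current_mode: str = "steady"  # {"steady", "dynamic"}


@dataclass
class OTPState:
    """Kinetic state of one receptor channel processing a mixture."""

    x1: np.ndarray  # per mixture component, each in [0,1], sum <= 1
    x2: float = 0.0
    x3: float = 0.0
    current: float = 0.0

    def validate(self) -> None:
        if np.any(self.x1 < -_STATE_TOL) or self.x1.sum() > 1 + _STATE_TOL:
            raise FloatingPointError(
                "bound-receptor state escaped [0,1]/sum<=1 bounds"
            )
        for name in ("x2", "x3"):
            val = getattr(self, name)
            if val < -_STATE_TOL or val > 1 + _STATE_TOL:
                raise FloatingPointError(f"gating state {name} escaped [0,1]")


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------


def peri_receptor(
    u: np.ndarray, params: PeriReceptorParams, dt: float
) -> np.ndarray:
    """Filter sampled concentration(s): v = Re[(h*u) + gamma * (h*du)].

    ``u`` may be 1-D (one component) or 2-D (components x time).  The
    low-pass is the exact zero-order-hold discretization of the exponential
    kernel; the derivative path filters the finite-difference derivative
    with the same kernel.  The rectifier clips negatives to zero.
    """
    u = np.asarray(u, dtype=np.float64)
    single = u.ndim == 1
    u2 = u[None, :] if single else u
    decay = np.exp(-dt / params.tau)
    out = np.empty_like(u2)
    du = np.diff(u2, axis=1, prepend=0.0) / dt
    for i in range(u2.shape[0]):
        y = _exp_filter(u2[i], decay)
        ydu = _exp_filter(du[i], decay)
        out[i] = np.maximum(y + params.gamma * ydu, 0.0)
    return out[0] if single else out


@njit(cache=True)
def _exp_filter(x, decay):
    out = np.empty_like(x)
    acc = 0.0
    g = 1.0 - decay
    for k in range(x.shape[0]):
        acc = decay * acc + g * x[k]
        out[k] = acc
    return out


def bound_receptor_step(
    x1: np.ndarray, v: np.ndarray, b: np.ndarray, d: np.ndarray, dt: float
) -> np.ndarray:
    """One Euler step of the competitive binding system over components."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x1 = np.asarray(x1, dtype=np.float64)
    free = 1.0 - x1.sum()
    new = x1 + dt * (np.asarray(b) * np.asarray(v) * free - np.asarray(d) * x1)
    if np.any(new < -_STATE_TOL) or new.sum() > 1 + _STATE_TOL:
        raise FloatingPointError("bound-receptor step violated [0,1] bounds")
    return np.clip(new, 0.0, 1.0)


def bound_receptor_steady_state(
    a: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, float]:
    """Closed-form steady state of competitive binding.

    Returns (x1* per component, total bound ratio):
    x1_o* = a_o v_o / (sum_p a_p v_p + 1).
    """
    a = np.asarray(a, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if np.any(a < 0) or np.any(v < 0):
        raise ValueError("affinities and concentrations must be >= 0")
    denom = float(np.dot(a, v)) + 1.0
    x1 = a * v / denom
    return x1, float(x1.sum())


def effective_affinity(a: np.ndarray, v: np.ndarray) -> float:
    """Concentration-weighted mean affinity of a mixture (1/ppm).

    A mixture with component affinities ``a`` at concentrations ``v``
    produces the same total steady-state binding as a pure odorant with
    this affinity presented at total concentration sum(v).
    """
    a = np.asarray(a, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    total = v.sum()
    if total <= 0:
        raise ValueError("effective affinity undefined at zero concentration")
    return float(np.dot(a, v) / total)


def coreceptor_step(
    x2: float, x3: float, sum_x1: float, params: CoReceptorParams, dt: float
) -> tuple[float, float]:
    """One Euler step of the co-receptor / calcium gating pair."""
    p = params
    dx2 = (
        p.alpha2 * sum_x1 * (1.0 - x2)
        - p.beta2 * x2
        - p.kappa * x2 ** (2.0 / 3.0) * x3 ** (2.0 / 3.0)
    )
    dx3 = p.alpha3 * x2 - p.beta3 * x3
    x2n, x3n = x2 + dt * dx2, x3 + dt * dx3
    if not (-_STATE_TOL <= x2n <= 1 + _STATE_TOL and -_STATE_TOL <= x3n <= 1 + _STATE_TOL):
        raise FloatingPointError("co-receptor state escaped [0,1]")
    return min(max(x2n, 0.0), 1.0), min(max(x3n, 0.0), 1.0)


def transduction_current(
    x2, params: CoReceptorParams, mode: str = "steady", dt: float | None = None
):
    """Transduction current through the co-receptor channel (uA/cm^2).

    In ``steady`` mode the current is the Hill function
    ``I = x2^rho / (x2^rho + c^rho) * i_max`` evaluated pointwise (scalar or
    array ``x2``).  In ``dynamic`` mode ``x2`` must be a sampled trace and
    the relaxation ODE ``dI/dt = x2^rho (i_max - I) - c^rho I`` is
    integrated on the dt grid from I(0) = 0.
    """
    p = params
    if mode == "steady":
        x2 = np.asarray(x2, dtype=np.float64)
        out = x2**p.rho / (x2**p.rho + p.c**p.rho) * p.i_max
        return float(out) if out.ndim == 0 else out
    if mode == "dynamic":
        if dt is None:
            raise ValueError("dynamic mode requires dt")
        trace = np.asarray(x2, dtype=np.float64)
        return _current_ode(trace, dt, p.rho, p.c, p.i_max)
    raise ValueError(f"unknown current mode {mode!r}")


@njit(cache=True)
def _current_ode(x2, dt, rho, c, i_max):
    out = np.empty_like(x2)
    cur = 0.0
    crho = c**rho
    for k in range(x2.shape[0]):
        cur += dt * (x2[k] ** rho * (i_max - cur) - crho * cur)
        out[k] = cur
    return out


# ---------------------------------------------------------------------------
# full transduction kinetics on the simulation grid
# ---------------------------------------------------------------------------


@njit(cache=True)
def _otp_kinetics(v, b, d, dt, a2, b2, kap, a3, b3):
    """Integrate binding + co-receptor kinetics for one receptor channel.

    ``v``: (components, time) filtered concentrations.  Returns the x1
    trace, and the x2/x3 traces.
    """
    n_o, nt = v.shape
    x1 = np.zeros(n_o)
    x2 = 0.0
    x3 = 0.0
    x1_tr = np.empty((n_o, nt))
    x2_tr = np.empty(nt)
    x3_tr = np.empty(nt)
    for t in range(nt):
        s = x1.sum()
        free = 1.0 - s
        for o in range(n_o):
            x1[o] += dt * (b[o] * v[o, t] * free - d[o] * x1[o])
            if x1[o] < 0.0:
                x1[o] = 0.0
        dx2 = a2 * s * (1.0 - x2) - b2 * x2 - kap * x2 ** (2.0 / 3.0) * x3 ** (2.0 / 3.0)
        dx3 = a3 * x2 - b3 * x3
        x2 += dt * dx2
        x3 += dt * dx3
        if x2 < 0.0:
            x2 = 0.0
        elif x2 > 1.0:
            x2 = 1.0
        if x3 < 0.0:
            x3 = 0.0
        elif x3 > 1.0:
            x3 = 1.0
        for o in range(n_o):
            x1_tr[o, t] = x1[o]
        x2_tr[t] = x2
        x3_tr[t] = x3
    return x1_tr, x2_tr, x3_tr


def transduction_traces(
    odorants: OdorantSet,
    receptor: int,
    params: OTPParams | None = None,
    t_total: float = 1.5,
    dt: float = 1e-5,
    osn: int = 0,
) -> dict[str, np.ndarray]:
    """Run the transduction kinetics (no spiking) for one receptor channel."""
    params = params or OTPParams()
    u = odorants.sample_concentrations(t_total, dt)
    v = peri_receptor(u, params.peri, dt)
    b = odorants.tensor.b[:, receptor, osn].copy()
    d = odorants.tensor.d[:, receptor, osn].copy()
    cp = params.coreceptor
    x1, x2, x3 = _otp_kinetics(
        np.atleast_2d(v), b, d, dt, cp.alpha2, cp.beta2, cp.kappa, cp.alpha3, cp.beta3
    )
    if params.current_mode == "dynamic":
        current = transduction_current(x2, cp, mode="dynamic", dt=dt)
    else:
        current = transduction_current(x2, cp, mode="steady")
    return {"v": v, "x1": x1, "x2": x2, "x3": x3, "current": current}


def run_osn(
    odorants: OdorantSet,
    receptor: int,
    params: OTPParams | None = None,
    t_total: float = 1.5,
    dt: float = 1e-5,
    seed: int = 0,
    osn: int = 0,
    return_traces: bool = False,
):
    """Full OTP cascade for one OSN: concentration waveforms to spike train."""
    params = params or OTPParams()
    traces = transduction_traces(odorants, receptor, params, t_total, dt, osn)
    state = rest_state(params.bsg)
    bins, _ = _simulate_current_trace(
        traces["current"],
        dt,
        params.bsg.as_array(),
        params.bsg.noise_sd,
        *state.as_tuple(),
        (seed + 1009 * receptor + 7 * osn) % (2**32),
    )
    train = SpikeTrain("OSN", receptor, bins * dt)
    if return_traces:
        return train, traces
    return train


def run_antenna(
    odorants: OdorantSet,
    n_receptors: int | None = None,
    params: OTPParams | None = None,
    t_total: float = 1.5,
    dt: float = 1e-5,
    seed: int = 0,
) -> list[SpikeTrain]:
    """Run every receptor channel; same-type OSN outputs are pooled (N=1)."""
    params = params or OTPParams()
    n_receptors = n_receptors or odorants.tensor.n_receptors
    if n_receptors > odorants.tensor.n_receptors:
        raise ValueError("more receptors requested than the tensor defines")
    n_osns = odorants.tensor.n_osns
    trains = []
    for r in range(n_receptors):
        if n_osns == 1:
            trains.append(run_osn(odorants, r, params, t_total, dt, seed))
        else:
            # glomerular convergence: same-type OSN axons pool into one channel
            times = np.concatenate(
                [
                    run_osn(odorants, r, params, t_total, dt, seed, osn=n).times
                    for n in range(n_osns)
                ]
            )
            times = np.unique(times)
            trains.append(SpikeTrain("OSN", r, times))
    return trains
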