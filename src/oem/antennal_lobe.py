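"""Antennal Lobe: multi-channel divisive normalization of OSN input.

Each glomerular channel ``r`` receives one OSN spike train and produces one
projection-neuron (PN) spike train.  Three divisive-normalization
processors (DNPs) shape the channel:

* the **OSN axon terminal**, a feedback DNP driven impulsively by OSN
  spikes and suppressed impulsively by spikes of the global presynaptic
  local neuron (Pre-LN):
      dx/dt = a1 * s_OSN(t) * (1 - x) - b1 * x - k1 * s_L(t) * x,
  whose steady state under Poisson rates lam (OSN) and mu (Pre-LN) is the
  divisive form  x ~ a1*lam / (a1*lam + b1 + k1*mu).  The vesicle
  (neurotransmitter) output is NT = NT_max * x.
* the **Pre-LN**, a single Connor-Stevens neuron summing synaptic currents
  driven by the NT output of all R channels and feeding spikes back to
  every axon terminal -- the spatio-temporal normalization.
* **Post-eLN / Post-iLN**, feedforward DNPs extracting stimulus onset and
  offset: a kinetic rate estimate of the OSN train is low-pass filtered,
  and the rectified positive (onset) / negative (offset) rate derivative
  drives an excitatory / inhibitory local neuron, each synapsing onto the
  channel's PN.

The PN Connor-Stevens neuron integrates the axon-terminal, Post-eLN and
Post-iLN synaptic currents.  Dirac spike trains are handled as impulsive
state updates at spike times with exponential decay between events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from oem.neuron import ConnorStevensParams, NeuronState, SpikeTrain, cs_update, rest_state

__all__ = [
    "AxonTerminalParams",
    "SynapseParams",
    "PostLNParams",
    "ALParams",
    "axon_terminal_step",
    "synapse_step",
    "preln_step",
    "post_ln_drives",
    "run_al",
    "spike_trains_to_bins",
    "bins_to_spike_trains",
]


@dataclass(frozen=True)
class AxonTerminalParams:
    """Feedback DNP at the OSN axon terminal.

    ``alpha1`` and ``kappa1`` are per-spike jump fractions (dimensionless),
    ``beta1`` a decay rate (1/s), ``nt_max`` the maximal neurotransmitter
    concentration (a.u.).
    """

    alpha1: float = 0.1
    beta1: float = 10.0
    kappa1: float = 0.05
    nt_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.kappa1, self.nt_max) < 0:
            raise ValueError("axon-terminal parameters must be >= 0")


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic conductance synapse.

    For continuous drive, ``dx/dt = alpha1 * drive * (1-x) - beta1 * x``;
    for spike drive (``spike_driven=True``) each presynaptic spike applies
    ``x <- x + alpha1 * (1-x)`` and ``beta1`` is the decay rate.  The
    synaptic current is ``I = g_max * x * (V_post - e_rev)``, a positive
    outward term when V_post > e_rev; the neuron subtracts it from its
    input.
    """

    alpha1: float = 100.0
    beta1: float = 10.0
    g_max: float = 0.5
    e_rev: float = 0.0
    spike_driven: bool = False

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")


@dataclass(frozen=True)
class PostLNParams:
    """Onset/offset extraction (Post-eLN / Post-iLN feedforward DNPs).

    ``alpha_rate`` (per spike) and ``beta_rate`` (1/s) define the kinetic
    rate estimate of the OSN train; ``tau_lp`` (s) the low-pass whose
    analytic derivative is rectified; ``gain_on``/``gain_off`` convert the
    rectified derivative into local-neuron input current (uA/cm^2 per unit
    drive).
    """

    alpha_rate: float = 0.005
    beta_rate: float = 20.0
    tau_lp: float = 0.05
    gain_on: float = 40.0
    gain_off: float = 40.0


@dataclass(frozen=True)
class ALParams:
    axon_terminal: AxonTerminalParams = field(default_factory=AxonTerminalParams)
    syn_osn_preln: SynapseParams = field(
        default_factory=lambda: SynapseParams(g_max=0.04, e_rev=0.0)
    )
    syn_axt_pn: SynapseParams = field(
        default_factory=lambda: SynapseParams(alpha1=20.0, g_max=0.45, e_rev=0.0)
    )
    syn_eln_pn: SynapseParams = field(
        default_factory=lambda: SynapseParams(
            alpha1=0.1, beta1=20.0, g_max=0.15, e_rev=0.0, spike_driven=True
        )
    )
    syn_iln_pn: SynapseParams = field(
        default_factory=lambda: SynapseParams(
            alpha1=0.1, beta1=20.0, g_max=0.25, e_rev=-80.0, spike_driven=True
        )
    )
    postln: PostLNParams = field(default_factory=PostLNParams)
    preln_bsg: ConnorStevensParams = field(default_factory=ConnorStevensParams)
    pn_bsg: ConnorStevensParams = field(default_factory=ConnorStevensParams)
    ln_bsg: ConnorStevensParams = field(default_factory=ConnorStevensParams)


# ---------------------------------------------------------------------------
# single-step operations (the unit-testable surface; the compiled kernel
# below applies exactly these updates)
# ---------------------------------------------------------------------------


def axon_terminal_step(
    x: float,
    osn_spikes: int,
    preln_spikes: int,
    params: AxonTerminalParams,
    dt: float,
) -> float:
    """Advance the axon-terminal DNP one dt bin.

    Exponential decay over the bin, then one impulsive update per spike.
    """
    if not -1e-9 <= x <= 1 + 1e-9:
        raise FloatingPointError("axon-terminal state escaped [0,1]")
    x = x * math.exp(-params.beta1 * dt)
    for _ in range(osn_spikes):
        x += params.alpha1 * (1.0 - x)
    for _ in range(preln_spikes):
        x -= params.kappa1 * x
    return min(max(x, 0.0), 1.0)


def synapse_step(
    x: float,
    drive: float,
    v_post: float,
    params: SynapseParams,
    dt: float,
) -> tuple[float, float]:
    """Advance a kinetic synapse one step; returns (x', I).

    ``drive`` is the continuous presynaptic level, or the spike count in
    the bin for spike-driven synapses.  The returned current follows the
    outward-positive convention ``I = g_max * x * (V_post - e_rev)``.
    """
    if params.spike_driven:
        x = x * math.exp(-params.beta1 * dt)
        for _ in range(int(drive)):
            x += params.alpha1 * (1.0 - x)
    else:
        x = x + dt * (params.alpha1 * drive * (1.0 - x) - params.beta1 * x)
    x = min(max(x, 0.0), 1.0)
    current = params.g_max * x * (v_post - params.e_rev)
    return x, current


def preln_step(
    gates: np.ndarray,
    nt_levels: np.ndarray,
    state: NeuronState,
    params: ALParams,
    dt: float,
) -> tuple[np.ndarray, NeuronState, bool]:
    """One step of the Pre-LN: update the R input synapses and the neuron.

    Returns (updated gates, neuron state, spiked?).
    """
    gates = np.asarray(gates, dtype=np.float64).copy()
    total = 0.0
    for r in range(gates.shape[0]):
        gates[r], current = synapse_step(
            gates[r], nt_levels[r], state.v, params.syn_osn_preln, dt
        )
        total += current
    new = NeuronState(
        *cs_update(*state.as_tuple(), -total, dt * 1e3, params.preln_bsg.as_array())
    )
    return gates, new, state.v < 0.0 <= new.v


def post_ln_drives(
    osn_bins: np.ndarray, params: PostLNParams, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Onset and offset drive traces for one channel's OSN spike bins.

    The kinetic rate estimate x jumps by ``alpha_rate * (1-x)`` per spike
    and decays at ``beta_rate``; its low-pass y obeys dy/dt = (x - y) /
    tau_lp, so (x - y)/tau_lp is an analytic estimate of dx/dt.  Onset
    drive is the positive part, offset drive the negative part.
    """
    x = 0.0
    y = 0.0
    decay = math.exp(-params.beta_rate * dt)
    n = osn_bins.shape[0]
    onset = np.empty(n)
    offset = np.empty(n)
    for t in range(n):
        x *= decay
        for _ in range(int(osn_bins[t])):
            x += params.alpha_rate * (1.0 - x)
        deriv = (x - y) / params.tau_lp
        y += dt * deriv
        onset[t] = max(deriv, 0.0)
        offset[t] = max(-deriv, 0.0)
    return onset, offset


# ---------------------------------------------------------------------------
# spike-train <-> bin-grid conversion
# ---------------------------------------------------------------------------


def spike_trains_to_bins(
    trains: list[SpikeTrain], t_total: float, dt: float
) -> np.ndarray:
    """Per-bin spike counts, shape (n_trains, n_bins)."""
    nt = int(round(t_total / dt))
    out = np.zeros((len(trains), nt), dtype=np.uint8)
    for i, train in enumerate(trains):
        idx = np.minimum((train.times / dt).astype(np.int64), nt - 1)
        np.add.at(out[i], idx, 1)
    return out


def bins_to_spike_trains(
    bins: np.ndarray, dt: float, population: str
) -> list[SpikeTrain]:
    return [
        SpikeTrain(population, i, np.nonzero(bins[i])[0] * dt)
        for i in range(bins.shape[0])
    ]


# ---------------------------------------------------------------------------
# compiled multi-channel kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _al_kernel(
    osn_bins,  # (R, nt) uint8
    dt,
    axt,  # [alpha1, beta1, kappa1, nt_max]
    syn_ol,  # [alpha1, beta1, g_max, e_rev]  continuous, NT -> Pre-LN
    syn_op,  # continuous, NT -> PN
    syn_ep,  # spike-driven, eLN -> PN
    syn_ip,  # spike-driven, iLN -> PN
    postln,  # [alpha_rate, beta_rate, tau_lp, gain_on, gain_off]
    p_preln,
    p_pn,
    p_ln,
    sig_preln,
    sig_pn,
    sig_ln,
    rest,  # resting neuron state (6,)
    seed,
    trace_stride,
):
    n_ch, nt = osn_bins.shape
    dt_ms = dt * 1e3
    np.random.seed(seed)
    refrac = int(round(2e-3 / dt))

    # kinetic states
    x_axt = np.zeros(n_ch)
    g_ol = np.zeros(n_ch)
    g_op = np.zeros(n_ch)
    g_ep = np.zeros(n_ch)
    g_ip = np.zeros(n_ch)
    x_rate = np.zeros(n_ch)
    y_rate = np.zeros(n_ch)

    # neuron states: PN, eLN, iLN per channel; one Pre-LN
    pn = np.empty((n_ch, 6))
    eln = np.empty((n_ch, 6))
    iln = np.empty((n_ch, 6))
    for r in range(n_ch):
        for j in range(6):
            pn[r, j] = rest[j]
            eln[r, j] = rest[j]
            iln[r, j] = rest[j]
    prel = rest.copy()
    pn_last = np.full(n_ch, -refrac - 1)
    eln_last = np.full(n_ch, -refrac - 1)
    iln_last = np.full(n_ch, -refrac - 1)
    prel_last = -refrac - 1

    pn_bins = np.zeros((n_ch, nt), dtype=np.uint8)
    eln_bins = np.zeros((n_ch, nt), dtype=np.uint8)
    iln_bins = np.zeros((n_ch, nt), dtype=np.uint8)
    preln_bins = np.zeros(nt, dtype=np.uint8)

    n_tr = nt // trace_stride
    axt_trace = np.zeros((n_ch, n_tr))

    decay_axt = math.exp(-axt[1] * dt)
    decay_rate = math.exp(-postln[1] * dt)
    decay_ep = math.exp(-syn_ep[1] * dt)
    decay_ip = math.exp(-syn_ip[1] * dt)
    noise_preln = sig_preln / math.sqrt(dt) if sig_preln > 0 else 0.0
    noise_pn = sig_pn / math.sqrt(dt) if sig_pn > 0 else 0.0
    noise_ln = sig_ln / math.sqrt(dt) if sig_ln > 0 else 0.0

    preln_spiked = 0
    for t in range(nt):
        i_preln_total = 0.0
        for r in range(n_ch):
            n_spk = osn_bins[r, t]
            # axon-terminal feedback DNP (impulsive updates, exact decay)
            x = x_axt[r] * decay_axt
            for _ in range(n_spk):
                x += axt[0] * (1.0 - x)
            if preln_spiked:
                x -= axt[2] * x
            x_axt[r] = x
            nt_level = axt[3] * x

            # continuous synapses driven by NT
            g_ol[r] += dt * (syn_ol[0] * nt_level * (1.0 - g_ol[r]) - syn_ol[1] * g_ol[r])
            g_op[r] += dt * (syn_op[0] * nt_level * (1.0 - g_op[r]) - syn_op[1] * g_op[r])

            # onset/offset rate-derivative drives
            xr = x_rate[r] * decay_rate
            for _ in range(n_spk):
                xr += postln[0] * (1.0 - xr)
            x_rate[r] = xr
            deriv = (xr - y_rate[r]) / postln[2]
            y_rate[r] += dt * deriv

            # Post-eLN neuron
            i_on = postln[3] * deriv if deriv > 0.0 else 0.0
            if noise_ln > 0.0:
                i_on += noise_ln * np.random.normal()
            v0 = eln[r, 0]
            eln[r, 0], eln[r, 1], eln[r, 2], eln[r, 3], eln[r, 4], eln[r, 5] = cs_update(
                eln[r, 0], eln[r, 1], eln[r, 2], eln[r, 3], eln[r, 4], eln[r, 5],
                i_on, dt_ms, p_ln,
            )
            eln_spk = 0
            if v0 < 0.0 and eln[r, 0] >= 0.0 and t - eln_last[r] > refrac:
                eln_spk = 1
                eln_last[r] = t
                eln_bins[r, t] = 1

            # Post-iLN neuron
            i_off = -postln[4] * deriv if deriv < 0.0 else 0.0
            if noise_ln > 0.0:
                i_off += noise_ln * np.random.normal()
            v0 = iln[r, 0]
            iln[r, 0], iln[r, 1], iln[r, 2], iln[r, 3], iln[r, 4], iln[r, 5] = cs_update(
                iln[r, 0], iln[r, 1], iln[r, 2], iln[r, 3], iln[r, 4], iln[r, 5],
                i_off, dt_ms, p_ln,
            )
            iln_spk = 0
            if v0 < 0.0 and iln[r, 0] >= 0.0 and t - iln_last[r] > refrac:
                iln_spk = 1
                iln_last[r] = t
                iln_bins[r, t] = 1

            # spike-driven PN synapses from the local neurons
            g_ep[r] *= decay_ep
            if eln_spk:
                g_ep[r] += syn_ep[0] * (1.0 - g_ep[r])
            g_ip[r] *= decay_ip
            if iln_spk:
                g_ip[r] += syn_ip[0] * (1.0 - g_ip[r])

            # PN: sum of the three synaptic currents (outward-positive)
            v_pn = pn[r, 0]
            i_syn = (
                syn_op[2] * g_op[r] * (v_pn - syn_op[3])
                + syn_ep[2] * g_ep[r] * (v_pn - syn_ep[3])
                + syn_ip[2] * g_ip[r] * (v_pn - syn_ip[3])
            )
            i_pn = -i_syn
            if noise_pn > 0.0:
                i_pn += noise_pn * np.random.normal()
            pn[r, 0], pn[r, 1], pn[r, 2], pn[r, 3], pn[r, 4], pn[r, 5] = cs_update(
                pn[r, 0], pn[r, 1], pn[r, 2], pn[r, 3], pn[r, 4], pn[r, 5],
                i_pn, dt_ms, p_pn,
            )
            if v_pn < 0.0 and pn[r, 0] >= 0.0 and t - pn_last[r] > refrac:
                pn_last[r] = t
                pn_bins[r, t] = 1

            i_preln_total += syn_ol[2] * g_ol[r] * (prel[0] - syn_ol[3])

        # Pre-LN neuron (global); its spike feeds back on the next bin
        i_l = -i_preln_total
        if noise_preln > 0.0:
            i_l += noise_preln * np.random.normal()
        v0 = prel[0]
        prel[0], prel[1], prel[2], prel[3], prel[4], prel[5] = cs_update(
            prel[0], prel[1], prel[2], prel[3], prel[4], prel[5], i_l, dt_ms, p_preln
        )
        preln_spiked = 0
        if v0 < 0.0 and prel[0] >= 0.0 and t - prel_last > refrac:
            preln_spiked = 1
            prel_last = t
            preln_bins[t] = 1

        if t % trace_stride == 0 and t // trace_stride < n_tr:
            for r in range(n_ch):
                axt_trace[r, t // trace_stride] = x_axt[r]

    return pn_bins, preln_bins, eln_bins, iln_bins, axt_trace


def run_al(
    osn_spikes: list[SpikeTrain],
    params: ALParams | None = None,
    t_total: float = 1.5,
    dt: float = 1e-5,
    seed: int = 0,
    trace_stride: int = 100,
):
    """Run the full AL circuit on R OSN spike trains.

    Returns (pn_trains, traces) where traces holds the Pre-LN spike train,
    local-neuron spike trains and the decimated axon-terminal states.
    """
    params = params or ALParams()
    osn_bins = spike_trains_to_bins(osn_spikes, t_total, dt)
    rest = np.array(rest_state(params.pn_bsg).as_tuple())

    def _syn(p: SynapseParams) -> np.ndarray:
        return np.array([p.alpha1, p.beta1, p.g_max, p.e_rev])

    axt = params.axon_terminal
    pl = params.postln
    pn_bins, preln_bins, eln_bins, iln_bins, axt_trace = _al_kernel(
        osn_bins,
        dt,
        np.array([axt.alpha1, axt.beta1, axt.kappa1, axt.nt_max]),
        _syn(params.syn_osn_preln),
        _syn(params.syn_axt_pn),
        _syn(params.syn_eln_pn),
        _syn(params.syn_iln_pn),
        np.array([pl.alpha_rate, pl.beta_rate, pl.tau_lp, pl.gain_on, pl.gain_off]),
        params.preln_bsg.as_array(),
        params.pn_bsg.as_array(),
        params.ln_bsg.as_array(),
        params.preln_bsg.noise_sd,
        params.pn_bsg.noise_sd,
        params.ln_bsg.noise_sd,
        rest,
        seed % (2**32),
        trace_stride,
    )
    pn_trains = bins_to_spike_trains(pn_bins, dt, "PN")
    traces = {
        "preln": SpikeTrain("PreLN", 0, np.nonzero(preln_bins)[0] * dt),
        "eln": bins_to_spike_trains(eln_bins, dt, "PostELN"),
        "iln": bins_to_spike_trains(iln_bins, dt, "PostILN"),
        "x_axt": axt_trace,
        "trace_dt": dt * trace_stride,
    }
    return pn_trains, traces
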