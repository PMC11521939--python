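"""Mushroom Body Calyx: sparse expansion onto Kenyon cells with APL feedback.

PN spike trains fan out onto M Kenyon cells (KCs) through a random
bipartite graph in which every KC samples exactly Q distinct PNs (its
dendritic "claws").  Each KC dendrite is a feedback DNP,

    dx_m/dt = a1 * s_PN(t over I_m) * (1 - x_m) - b1 * x_m - k1 * x_m * x_APL,

driven impulsively by the spikes of its Q PNs and suppressed continuously
by the APL feedback signal, itself a kinetic state driven by the aggregate
KC spiking:

    dx_APL/dt = a1_APL * s_KC_total(t) * (1 - x_APL) - b1_APL * x_APL.

The KC dendritic output current I_m = I_max * x_m drives a noiseless
Connor-Stevens spike generator.  I_max is calibrated so that x_m = 0.5
corresponds to the KC rheobase: the dendritic-output threshold 0.5 and the
spiking threshold coincide, so "active KC" can be read off either from
steady x_m > 0.5 or from the spike raster.  PN-KC and KC-APL synaptic
dynamics are omitted: spikes act directly on the kinetic states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from oem.neuron import ConnorStevensParams, SpikeTrain, cs_update, rest_state, rheobase
from oem.antennal_lobe import spike_trains_to_bins

__all__ = [
    "BipartiteGraph",
    "KCDendriteParams",
    "APLParams",
    "CalyxParams",
    "sample_pn_kc_graph",
    "kc_dendrite_step",
    "apl_step",
    "run_calyx",
    "dendritic_input",
    "graph_to_edges",
]


@dataclass(frozen=True)
class BipartiteGraph:
    """PN -> KC wiring: each KC has exactly Q distinct PN inputs."""

    connections: np.ndarray  # (M, Q) int64, PN indices per KC
    n_pns: int
    seed: int | None = None

    def __post_init__(self) -> None:
        conn = np.asarray(self.connections, dtype=np.int64)
        if conn.ndim != 2:
            raise ValueError("connections must be (M, Q)")
        if conn.size and (conn.min() < 0 or conn.max() >= self.n_pns):
            raise ValueError("PN indices out of range")
        for row in conn:
            if len(set(row.tolist())) != conn.shape[1]:
                raise ValueError("each KC must sample distinct PNs")
        object.__setattr__(self, "connections", conn)

    @property
    def n_kcs(self) -> int:
        return self.connections.shape[0]

    @property
    def q(self) -> int:
        return self.connections.shape[1]

    def wired_fraction(self, pn: int) -> float:
        """Fraction of KCs wired to the given PN."""
        return float(np.mean(np.any(self.connections == pn, axis=1)))


@dataclass(frozen=True)
class KCDendriteParams:
    """Feedback DNP on each KC dendrite.

    ``alpha1`` is the per-PN-spike jump fraction, ``beta1`` the decay rate
    (1/s), ``kappa1`` the APL coupling rate (1/s, multiplies x * x_APL).
    ``i_max`` (uA/cm^2) scales the dendritic output current; ``None``
    calibrates it so x = 0.5 maps to the KC rheobase.
    """

    alpha1: float = 0.1
    beta1: float = 5.0
    kappa1: float = 25.0
    i_max: float | None = None

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.kappa1) < 0:
            raise ValueError("KC dendrite parameters must be >= 0")

    def resolved_i_max(self, bsg: ConnorStevensParams) -> float:
        if self.i_max is not None:
            return self.i_max
        return 2.0 * rheobase(bsg)


@dataclass(frozen=True)
class APLParams:
    """APL feedback kinetics: per-KC-spike jump ``alpha1``, decay ``beta1``."""

    alpha1: float = 0.001
    beta1: float = 10.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1) < 0:
            raise ValueError("APL parameters must be >= 0")


@dataclass(frozen=True)
class CalyxParams:
    dendrite: KCDendriteParams = field(default_factory=KCDendriteParams)
    apl: APLParams = field(default_factory=APLParams)
    kc_bsg: ConnorStevensParams = field(default_factory=ConnorStevensParams)
    apl_feedback: bool = True


def sample_pn_kc_graph(
    n_pns: int, n_kcs: int, q: int, seed: int = 0
) -> BipartiteGraph:
    """Sample the random PN->KC bipartite graph.

    Each KC's input set is drawn uniformly without replacement from the R
    PNs, independently across KCs; deterministic given ``seed``.
    """
    if not 1 <= q <= n_pns:
        raise ValueError(f"invalid Q: need 1 <= Q <= {n_pns}, got {q}")
    if n_kcs < 1:
        raise ValueError("need at least one KC")
    rng = np.random.default_rng(seed)
    conn = np.stack(
        [rng.choice(n_pns, size=q, replace=False) for _ in range(n_kcs)]
    )
    return BipartiteGraph(conn.astype(np.int64), n_pns, seed)


def graph_to_edges(graph: BipartiteGraph):
    """Edge list [(kc_id, pn_id), ...] for CSV serialization."""
    return [
        (m, int(pn))
        for m in range(graph.n_kcs)
        for pn in graph.connections[m]
    ]


# ---------------------------------------------------------------------------
# single-step operations
# ---------------------------------------------------------------------------


def kc_dendrite_step(
    x: float,
    pn_spikes: int,
    x_apl: float,
    params: KCDendriteParams,
    dt: float,
) -> float:
    """Advance one KC dendrite DNP one dt bin."""
    if not -1e-9 <= x <= 1 + 1e-9:
        raise FloatingPointError("KC dendrite state escaped [0,1]")
    x = x * math.exp(-(params.beta1 + params.kappa1 * x_apl) * dt)
    for _ in range(pn_spikes):
        x += params.alpha1 * (1.0 - x)
    return min(max(x, 0.0), 1.0)


def apl_step(x: float, kc_spikes: int, params: APLParams, dt: float) -> float:
    """Advance the APL kinetic state one dt bin."""
    x = x * math.exp(-params.beta1 * dt)
    for _ in range(kc_spikes):
        x += params.alpha1 * (1.0 - x)
    return min(max(x, 0.0), 1.0)


# ---------------------------------------------------------------------------
# compiled closed-loop kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _calyx_kernel(
    pn_bins,  # (R, nt) uint8
    conn,  # (M, Q) int64
    dt,
    a1,
    b1,
    k1,
    a1_apl,
    b1_apl,
    i_max,
    p_kc,
    rest,
    w0,
    w1,  # steady-state averaging window (bin indices)
    trace_stride,
):
    n_ch, nt = pn_bins.shape
    n_kc, q = conn.shape
    dt_ms = dt * 1e3
    refrac = int(round(2e-3 / dt))

    x_kcd = np.zeros(n_kc)
    x_apl = 0.0
    kc = np.empty((n_kc, 6))
    for m in range(n_kc):
        for j in range(6):
            kc[m, j] = rest[j]
    kc_last = np.full(n_kc, -refrac - 1)

    max_spikes = n_kc * (nt // refrac + 1)
    spk_neuron = np.empty(max_spikes, dtype=np.int64)
    spk_bin = np.empty(max_spikes, dtype=np.int64)
    n_spk = 0

    x_steady = np.zeros(n_kc)
    apl_steady = 0.0
    n_steady = 0

    n_tr = nt // trace_stride
    apl_trace = np.zeros(n_tr)

    decay_apl = math.exp(-b1_apl * dt)

    for t in range(nt):
        decay_kcd = math.exp(-(b1 + k1 * x_apl) * dt)
        kc_spike_count = 0
        for m in range(n_kc):
            x = x_kcd[m] * decay_kcd
            for j in range(q):
                r = conn[m, j]
                for _ in range(pn_bins[r, t]):
                    x += a1 * (1.0 - x)
            x_kcd[m] = x

            v0 = kc[m, 0]
            kc[m, 0], kc[m, 1], kc[m, 2], kc[m, 3], kc[m, 4], kc[m, 5] = cs_update(
                kc[m, 0], kc[m, 1], kc[m, 2], kc[m, 3], kc[m, 4], kc[m, 5],
                i_max * x, dt_ms, p_kc,
            )
            if v0 < 0.0 and kc[m, 0] >= 0.0 and t - kc_last[m] > refrac:
                kc_last[m] = t
                spk_neuron[n_spk] = m
                spk_bin[n_spk] = t
                n_spk += 1
                kc_spike_count += 1

        x_apl *= decay_apl
        for _ in range(kc_spike_count):
            x_apl += a1_apl * (1.0 - x_apl)

        if w0 <= t < w1:
            for m in range(n_kc):
                x_steady[m] += x_kcd[m]
            apl_steady += x_apl
            n_steady += 1
        if t % trace_stride == 0 and t // trace_stride < n_tr:
            apl_trace[t // trace_stride] = x_apl

    if n_steady > 0:
        for m in range(n_kc):
            x_steady[m] /= n_steady
        apl_steady /= n_steady
    return spk_neuron[:n_spk], spk_bin[:n_spk], x_steady, apl_steady, apl_trace


def run_calyx(
    pn_spikes: list[SpikeTrain],
    graph: BipartiteGraph,
    params: CalyxParams | None = None,
    t_total: float = 1.5,
    dt: float = 1e-5,
    steady_window: tuple[float, float] | None = None,
    trace_stride: int = 100,
):
    """Run the closed KC-dendrite <-> APL loop.

    Returns (kc_trains, result) where result holds the steady-state x_KCD
    vector averaged over ``steady_window`` (default: the last third of the
    run), the steady APL level and the decimated APL trace.  The KC spike
    generators are noiseless.
    """
    params = params or CalyxParams()
    if len(pn_spikes) != graph.n_pns:
        raise ValueError(
            f"graph expects {graph.n_pns} PN trains, got {len(pn_spikes)}"
        )
    pn_bins = spike_trains_to_bins(pn_spikes, t_total, dt)
    if steady_window is None:
        steady_window = (2 * t_total / 3, t_total)
    w0 = int(round(steady_window[0] / dt))
    w1 = int(round(steady_window[1] / dt))
    kappa1 = params.dendrite.kappa1 if params.apl_feedback else 0.0
    i_max = params.dendrite.resolved_i_max(params.kc_bsg)
    rest = np.array(rest_state(params.kc_bsg).as_tuple())
    spk_neuron, spk_bin, x_steady, apl_steady, apl_trace = _calyx_kernel(
        pn_bins,
        graph.connections,
        dt,
        params.dendrite.alpha1,
        params.dendrite.beta1,
        kappa1,
        params.apl.alpha1,
        params.apl.beta1,
        i_max,
        params.kc_bsg.as_array(),
        rest,
        w0,
        w1,
        trace_stride,
    )
    kc_trains = []
    for m in range(graph.n_kcs):
        times = spk_bin[spk_neuron == m] * dt
        kc_trains.append(SpikeTrain("KC", m, times))
    result = {
        "x_kcd_steady": x_steady,
        "x_apl_steady": apl_steady,
        "apl_trace": apl_trace,
        "trace_dt": dt * trace_stride,
        "i_max": i_max,
    }
    return kc_trains, result


def dendritic_input(graph: BipartiteGraph, pn_rates: np.ndarray) -> np.ndarray:
    """Aggregate steady PN drive per KC: sum of its Q input-PN rates (Hz)."""
    pn_rates = np.asarray(pn_rates, dtype=np.float64)
    if pn_rates.shape[0] != graph.n_pns:
        raise ValueError("one rate per PN is required")
    return pn_rates[graph.connections].sum(axis=1)
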