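"""Simulation engine: configuration, the end-to-end cascade, experiments.

The cascade runs on one shared clock (default dt = 1e-5 s) with
event-exact impulsive updates; wiring and neuron-noise randomness use two
independent seeds so the graph can be held fixed while noise varies (and
vice versa).  The default stimulus protocol is 0.3 s silence, a 1.0 s
constant-concentration odor step and a 0.2 s offset tail; steady-state
quantities are averaged over the last 0.5 s of the odor step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

import oem
from oem.antennal_lobe import ALParams, AxonTerminalParams, PostLNParams, SynapseParams, run_al
from oem.calyx import (
    APLParams,
    BipartiteGraph,
    CalyxParams,
    KCDendriteParams,
    dendritic_input,
    graph_to_edges,
    run_calyx,
    sample_pn_kc_graph,
)
from oem.neuron import ConnorStevensParams, SpikeTrain
from oem.odorants import (
    AffinityTensor,
    OdorantSet,
    make_mixture,
    step_waveform,
    synth_affinity_profile,
)
from oem.otp import CoReceptorParams, OTPParams, PeriReceptorParams, run_antenna
from oem.readout import (
    FirstSpikeSequence,
    active_set,
    first_spike_sequence,
    invariance_report,
    rank_curve,
    rank_gap_ratio,
    sequence_distance,
)

__all__ = [
    "SimulationConfig",
    "PipelineResult",
    "RunResult",
    "build_params",
    "run_pipeline",
    "run_oem",
    "experiment_concentration_sweep",
    "experiment_q_sweep",
    "experiment_mixture_sweep",
    "DEFAULT_LEVELS_PPM",
]

DEFAULT_LEVELS_PPM = (50.0, 100.0, 150.0, 200.0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class OdorantDecl(BaseModel):
    """A named synthetic odorant profile."""

    name: str
    profile: str = "sparse-1"
    seed: int = 0

    model_config = {"extra": "forbid"}


class ComponentDecl(BaseModel):
    odorant: str
    amplitude_ppm: float = Field(ge=0)

    model_config = {"extra": "forbid"}


class StimulusConfig(BaseModel):
    t_on: float = 0.3
    t_off: float = 1.3
    tail: float = 0.2

    model_config = {"extra": "forbid"}

    @model_validator(mode="after")
    def _check(self):
        if self.t_off <= self.t_on:
            raise ValueError("stimulus.t_off must exceed stimulus.t_on")
        if self.tail < 0:
            raise ValueError("stimulus.tail must be >= 0")
        return self

    @property
    def t_total(self) -> float:
        return self.t_off + self.tail


class SimulationConfig(BaseModel):
    """Everything needed for one reproducible cascade run."""

    dt: float = Field(default=1e-5, gt=0, le=2e-5)
    n_receptors: int = Field(default=23, ge=1)
    n_kcs: int = Field(default=500, ge=1)
    q: int = Field(default=6, ge=1)
    n_osns: int = Field(default=1, ge=1)
    graph_seed: int = 0
    noise_seed: int = 0
    kc_threshold: float = Field(default=0.5, gt=0, lt=1)
    apl_feedback: bool = True
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    odorants: list[OdorantDecl] = Field(default_factory=list)
    components: list[ComponentDecl] = Field(default_factory=list)
    params: dict[str, dict] = Field(default_factory=dict)
    sigma_osn: float = Field(default=0.0, ge=0)
    sigma_preln: float = Field(default=0.0, ge=0)
    sigma_pn: float = Field(default=0.0, ge=0)
    sigma_ln: float = Field(default=0.0, ge=0)

    model_config = {"extra": "forbid"}

    @model_validator(mode="after")
    def _check(self):
        if self.q > self.n_receptors:
            raise ValueError("q must not exceed n_receptors")
        names = {o.name for o in self.odorants}
        if len(names) != len(self.odorants):
            raise ValueError("odorant names must be unique")
        for comp in self.components:
            if comp.odorant not in names:
                raise ValueError(
                    f"components references undefined odorant {comp.odorant!r}"
                )
        known = {
            "peri", "coreceptor", "axon_terminal", "syn_osn_preln",
            "syn_axt_pn", "syn_eln_pn", "syn_iln_pn", "postln",
            "kc_dendrite", "apl",
        }
        unknown = set(self.params) - known
        if unknown:
            raise ValueError(f"unknown params blocks: {sorted(unknown)}")
        return self

    @property
    def t_total(self) -> float:
        return self.stimulus.t_total

    def steady_window(self) -> tuple[float, float]:
        """Last 0.5 s of the odor step (or the whole step if shorter)."""
        t0 = max(self.stimulus.t_on, self.stimulus.t_off - 0.5)
        return (t0, self.stimulus.t_off)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def build_odorant_set(self) -> OdorantSet:
        if not self.components:
            raise ValueError("config declares no stimulus components")
        tensors = {
            o.name: synth_affinity_profile(
                self.n_receptors, o.profile, seed=o.seed
            )
            for o in self.odorants
        }
        pairs = [
            (tensors[c.odorant], c.amplitude_ppm) for c in self.components
        ]
        return make_mixture(
            pairs,
            self.stimulus.t_on,
            self.stimulus.t_off,
            component_ids=tuple(c.odorant for c in self.components),
        )


def build_params(
    config: SimulationConfig,
) -> tuple[OTPParams, ALParams, CalyxParams]:
    """Materialize the module parameter sets with config overrides applied."""
    p = config.params

    def get(block: str) -> dict:
        return dict(p.get(block, {}))

    otp = OTPParams(
        peri=PeriReceptorParams(**get("peri")),
        coreceptor=CoReceptorParams(**get("coreceptor")),
        bsg=ConnorStevensParams(noise_sd=config.sigma_osn),
    )
    al = ALParams(
        axon_terminal=AxonTerminalParams(**get("axon_terminal")),
        syn_osn_preln=_syn_params("syn_osn_preln", get("syn_osn_preln")),
        syn_axt_pn=_syn_params("syn_axt_pn", get("syn_axt_pn")),
        syn_eln_pn=_syn_params("syn_eln_pn", get("syn_eln_pn")),
        syn_iln_pn=_syn_params("syn_iln_pn", get("syn_iln_pn")),
        postln=PostLNParams(**get("postln")),
        preln_bsg=ConnorStevensParams(noise_sd=config.sigma_preln),
        pn_bsg=ConnorStevensParams(noise_sd=config.sigma_pn),
        ln_bsg=ConnorStevensParams(noise_sd=config.sigma_ln),
    )
    calyx = CalyxParams(
        dendrite=KCDendriteParams(**get("kc_dendrite")),
        apl=APLParams(**get("apl")),
        kc_bsg=ConnorStevensParams(noise_sd=0.0),
        apl_feedback=config.apl_feedback,
    )
    return otp, al, calyx


def _syn_params(block: str, overrides: dict) -> SynapseParams:
    defaults = {
        "syn_osn_preln": ALParams().syn_osn_preln,
        "syn_axt_pn": ALParams().syn_axt_pn,
        "syn_eln_pn": ALParams().syn_eln_pn,
        "syn_iln_pn": ALParams().syn_iln_pn,
    }[block]
    merged = {**defaults.__dict__, **overrides}
    return SynapseParams(**merged)


# ---------------------------------------------------------------------------
# the end-to-end cascade
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """All intermediate and final signals of one cascade run."""

    osn_trains: list[SpikeTrain]
    pn_trains: list[SpikeTrain]
    kc_trains: list[SpikeTrain]
    al_traces: dict
    calyx_result: dict
    graph: BipartiteGraph
    osn_rates: np.ndarray
    pn_rates: np.ndarray
    dendritic_inputs: np.ndarray
    x_kcd_steady: np.ndarray
    x_apl_steady: float
    active: set[int]
    sequence: FirstSpikeSequence
    steady_window: tuple[float, float]
    t_on: float


def run_antenna_al(
    odorants: OdorantSet,
    otp_params: OTPParams,
    al_params: ALParams,
    t_total: float,
    dt: float,
    seed: int = 0,
):
    """Antenna + AL stages (wiring-independent half of the cascade)."""
    osn_trains = run_antenna(odorants, params=otp_params, t_total=t_total, dt=dt, seed=seed)
    pn_trains, al_traces = run_al(osn_trains, al_params, t_total, dt, seed=seed + 1)
    return osn_trains, pn_trains, al_traces


def run_pipeline(
    odorants: OdorantSet,
    n_kcs: int = 500,
    q: int = 6,
    graph: BipartiteGraph | None = None,
    graph_seed: int = 0,
    otp_params: OTPParams | None = None,
    al_params: ALParams | None = None,
    calyx_params: CalyxParams | None = None,
    t_total: float = 1.5,
    dt: float = 1e-5,
    steady_window: tuple[float, float] | None = None,
    seed: int = 0,
    kc_threshold: float = 0.5,
    t_origin: float | None = None,
    precomputed=None,
) -> PipelineResult:
    """Run Antenna -> AL -> Calyx -> readouts on one shared clock.

    ``precomputed`` may carry (osn_trains, pn_trains, al_traces) from
    :func:`run_antenna_al` to reuse the wiring-independent stages across
    graph seeds.
    """
    otp_params = otp_params or OTPParams()
    al_params = al_params or ALParams()
    calyx_params = calyx_params or CalyxParams()
    n_receptors = odorants.tensor.n_receptors
    if graph is None:
        graph = sample_pn_kc_graph(n_receptors, n_kcs, q, graph_seed)
    if precomputed is None:
        osn_trains, pn_trains, al_traces = run_antenna_al(
            odorants, otp_params, al_params, t_total, dt, seed
        )
    else:
        osn_trains, pn_trains, al_traces = precomputed

    if steady_window is None:
        steady_window = (2 * t_total / 3, t_total)
    kc_trains, calyx_result = run_calyx(
        pn_trains, graph, calyx_params, t_total, dt, steady_window
    )

    w0, w1 = steady_window
    osn_rates = np.array([t.rate(w0, w1) for t in osn_trains])
    pn_rates = np.array([t.rate(w0, w1) for t in pn_trains])
    dend = dendritic_input(graph, pn_rates)
    x_steady = calyx_result["x_kcd_steady"]
    active = active_set(x_steady, kc_threshold)
    if t_origin is None:
        t_origin = 0.0
    sequence = first_spike_sequence(kc_trains, active, t_origin)
    return PipelineResult(
        osn_trains=osn_trains,
        pn_trains=pn_trains,
        kc_trains=kc_trains,
        al_traces=al_traces,
        calyx_result=calyx_result,
        graph=graph,
        osn_rates=osn_rates,
        pn_rates=pn_rates,
        dendritic_inputs=dend,
        x_kcd_steady=x_steady,
        x_apl_steady=calyx_result["x_apl_steady"],
        active=active,
        sequence=sequence,
        steady_window=steady_window,
        t_on=t_origin,
    )


@dataclass
class RunResult:
    """A pipeline result plus provenance, serializable to an output dir."""

    pipeline: PipelineResult
    config: SimulationConfig
    seeds: dict = field(default_factory=dict)

    @property
    def provenance(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seeds": self.seeds,
            "version": oem.__version__,
        }

    def spikes_frame(self) -> pd.DataFrame:
        rows = []
        groups = [
            self.pipeline.osn_trains,
            self.pipeline.pn_trains,
            self.pipeline.kc_trains,
            [self.pipeline.al_traces["preln"]],
        ]
        for trains in groups:
            for train in trains:
                for t in train.times:
                    rows.append((train.population, train.neuron_id, t))
        return pd.DataFrame(
            rows, columns=["population", "neuron_id", "spike_time_s"]
        )

    def write(self, out_dir, dump_states: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes_frame().to_csv(out / "spikes.csv", index=False)

        pr = self.pipeline
        frames = []
        for stage, values in (
            ("kc_dendritic_input", pr.dendritic_inputs),
            ("kc_dendritic_output", pr.x_kcd_steady),
        ):
            curve = rank_curve(values)
            frames.append(
                pd.DataFrame(
                    {
                        "stage": stage,
                        "rank": np.arange(len(curve)),
                        "kc_id": curve.indices,
                        "value": curve.values,
                    }
                )
            )
        pd.concat(frames).to_csv(out / "rank_curves.csv", index=False)

        with open(out / "first_spike_sequences.json", "w") as fh:
            json.dump(pr.sequence.to_records(), fh, indent=1)
        pd.DataFrame(
            graph_to_edges(pr.graph), columns=["kc_id", "pn_id"]
        ).to_csv(out / "graph.csv", index=False)
        with open(out / "run_meta.json", "w") as fh:
            json.dump(
                {**self.provenance, "config": self.config.model_dump()},
                fh,
                indent=1,
                default=str,
            )
        if dump_states:
            import h5py

            with h5py.File(out / "states.h5", "w") as h5:
                h5.create_dataset("x_axt", data=pr.al_traces["x_axt"])
                h5.create_dataset("apl_trace", data=pr.calyx_result["apl_trace"])
                h5.create_dataset("x_kcd_steady", data=pr.x_kcd_steady)
                h5.attrs["trace_dt"] = pr.al_traces["trace_dt"]


def run_oem(config: SimulationConfig, seed: int | None = None) -> RunResult:
    """Execute a configured cascade run."""
    noise_seed = config.noise_seed if seed is None else seed
    odorants = config.build_odorant_set()
    otp_params, al_params, calyx_params = build_params(config)
    pipeline = run_pipeline(
        odorants,
        n_kcs=config.n_kcs,
        q=config.q,
        graph_seed=config.graph_seed,
        otp_params=otp_params,
        al_params=al_params,
        calyx_params=calyx_params,
        t_total=config.t_total,
        dt=config.dt,
        steady_window=config.steady_window(),
        seed=noise_seed,
        kc_threshold=config.kc_threshold,
        t_origin=config.stimulus.t_on,
    )
    return RunResult(
        pipeline,
        config,
        seeds={"graph": config.graph_seed, "noise": noise_seed},
    )


# ---------------------------------------------------------------------------
# experiments (the characterization surface)
# ---------------------------------------------------------------------------


def _scaled_config(config: SimulationConfig, **updates) -> SimulationConfig:
    return config.model_copy(update=updates)


def experiment_concentration_sweep(
    config: SimulationConfig,
    levels=DEFAULT_LEVELS_PPM,
    include_apl_off: bool = True,
    seed: int | None = None,
):
    """Steady responses and first-spike sequences across concentration steps.

    The stimulus must be a single odorant; its amplitude is swept over
    ``levels``.  Returns a dict with a per-level summary table, the rate
    and dendritic-state vectors, and the sequences (plus APL-off controls
    for the invariance comparison).
    """
    if len(levels) < 2:
        raise ValueError("need at least 2 concentration levels")
    if len(config.components) != 1:
        raise ValueError("concentration sweep expects a single-component stimulus")
    noise_seed = config.noise_seed if seed is None else seed
    otp_params, al_params, calyx_params = build_params(config)
    calyx_off = CalyxParams(
        dendrite=calyx_params.dendrite,
        apl=calyx_params.apl,
        kc_bsg=calyx_params.kc_bsg,
        apl_feedback=False,
    )
    graph = sample_pn_kc_graph(
        config.n_receptors, config.n_kcs, config.q, config.graph_seed
    )
    out = {"levels": list(levels), "runs": {}, "runs_apl_off": {}}
    rows = []
    for level in levels:
        cfg = _scaled_config(
            config,
            components=[
                ComponentDecl(
                    odorant=config.components[0].odorant, amplitude_ppm=level
                )
            ],
        )
        odorants = cfg.build_odorant_set()
        pre = run_antenna_al(
            odorants, otp_params, al_params, cfg.t_total, cfg.dt, noise_seed
        )
        common = dict(
            graph=graph,
            otp_params=otp_params,
            al_params=al_params,
            t_total=cfg.t_total,
            dt=cfg.dt,
            steady_window=cfg.steady_window(),
            seed=noise_seed,
            kc_threshold=cfg.kc_threshold,
            t_origin=cfg.stimulus.t_on,
            precomputed=pre,
        )
        run = run_pipeline(odorants, calyx_params=calyx_params, **common)
        out["runs"][level] = run
        if include_apl_off:
            out["runs_apl_off"][level] = run_pipeline(
                odorants, calyx_params=calyx_off, **common
            )
        rows.append(
            {
                "level_ppm": level,
                "mean_osn_rate_hz": float(run.osn_rates.mean()),
                "mean_pn_rate_hz": float(run.pn_rates.mean()),
                "active_kc_fraction": len(run.active) / config.n_kcs,
                "dendritic_gap_ratio": rank_gap_ratio(run.dendritic_inputs),
                "x_apl_steady": run.x_apl_steady,
            }
        )
    out["summary"] = pd.DataFrame(rows)
    return out


def experiment_q_sweep(
    config: SimulationConfig,
    q_values=(3, 6, 9),
    seed: int | None = None,
):
    """KC dendritic-input rank curves and dominant-PN wiring fraction per Q."""
    for q in q_values:
        if q > config.n_receptors:
            raise ValueError(f"Q={q} exceeds n_receptors={config.n_receptors}")
    noise_seed = config.noise_seed if seed is None else seed
    otp_params, al_params, calyx_params = build_params(config)
    odorants = config.build_odorant_set()
    pre = run_antenna_al(
        odorants, otp_params, al_params, config.t_total, config.dt, noise_seed
    )
    w0, w1 = config.steady_window()
    pn_rates = np.array([t.rate(w0, w1) for t in pre[1]])
    dominant_pn = int(np.argmax(pn_rates))
    rows = []
    curves = {}
    for q in q_values:
        graph = sample_pn_kc_graph(
            config.n_receptors, config.n_kcs, q, config.graph_seed
        )
        dend = dendritic_input(graph, pn_rates)
        curves[q] = rank_curve(dend)
        rows.append(
            {
                "q": q,
                "dominant_pn": dominant_pn,
                "wired_fraction": graph.wired_fraction(dominant_pn),
                "expected_fraction": q / config.n_receptors,
                "dendritic_gap_ratio": rank_gap_ratio(dend),
            }
        )
    return {
        "summary": pd.DataFrame(rows),
        "rank_curves": curves,
        "pn_rates": pn_rates,
    }


def experiment_mixture_sweep(
    config: SimulationConfig,
    ratios=((4, 1), (2, 1), (1, 1), (1, 2), (1, 4)),
    levels=(100.0, 200.0),
    seed: int | None = None,
):
    """Binary-mixture sweep over component ratios and total concentration.

    The config must declare exactly two stimulus components; the first
    component's amplitude takes each value in ``levels`` and the second is
    scaled by the ratio.  Returns per-(ratio, level) runs, effective
    affinities and an invariance report grouped by ratio.
    """
    if len(config.components) != 2:
        raise ValueError("mixture sweep expects a two-component stimulus")
    if len(levels) < 2:
        raise ValueError("need >= 2 total-concentration levels per ratio")
    noise_seed = config.noise_seed if seed is None else seed
    otp_params, al_params, calyx_params = build_params(config)
    graph = sample_pn_kc_graph(
        config.n_receptors, config.n_kcs, config.q, config.graph_seed
    )
    runs = {}
    labeled = []
    rows = []
    for num, den in ratios:
        label = f"{num}:{den}"
        for level in levels:
            amp_a = float(level)
            amp_b = float(level) * den / num
            cfg = _scaled_config(
                config,
                components=[
                    ComponentDecl(
                        odorant=config.components[0].odorant, amplitude_ppm=amp_a
                    ),
                    ComponentDecl(
                        odorant=config.components[1].odorant, amplitude_ppm=amp_b
                    ),
                ],
            )
            odorants = cfg.build_odorant_set()
            run = run_pipeline(
                odorants,
                graph=graph,
                otp_params=otp_params,
                al_params=al_params,
                calyx_params=calyx_params,
                t_total=cfg.t_total,
                dt=cfg.dt,
                steady_window=cfg.steady_window(),
                seed=noise_seed,
                kc_threshold=cfg.kc_threshold,
                t_origin=cfg.stimulus.t_on,
            )
            runs[(label, level)] = run
            labeled.append((label, level, run.sequence))
            aff = odorants.tensor.affinity[:, :, 0]
            amps = np.array([amp_a, amp_b])
            eff = aff.T @ amps / amps.sum()
            rows.append(
                {
                    "ratio": label,
                    "level_ppm": level,
                    "mean_effective_affinity": float(eff.mean()),
                    "active_kc_fraction": len(run.active) / config.n_kcs,
                }
            )
    report = invariance_report(labeled)
    return {
        "summary": pd.DataFrame(rows),
        "runs": runs,
        "invariance": report,
        "sequences": labeled,
    }
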