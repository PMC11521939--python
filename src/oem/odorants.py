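"""The space of odorants: identity tensors and concentration waveforms.

An odorant object is a pair of semantic and syntactic descriptors.  The
*semantics* (identity) of an odorant is its per-receptor binding-rate and
dissociation-rate tensor ``(b, d)``; the derived affinity ``a = b / d``
(1/ppm) determines how strongly each receptor responds.  The *syntax* is
the concentration waveform ``u(t)`` (ppm).  Transduction multiplicatively
couples the two, which is what the downstream circuits must disentangle.

The synthetic generator emulates the two affinity-profile regimes found in
measured receptor panels: a single dominant receptor (acetone-like) and a
few comparable receptors or broad tuning (nerol- / ethyl-butyrate-like).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AffinityTensor",
    "ConcentrationWaveform",
    "OdorantSet",
    "synth_affinity_profile",
    "step_waveform",
    "make_mixture",
    "affinity_to_csv",
    "affinity_from_csv",
]


@dataclass(frozen=True)
class AffinityTensor:
    """Binding/dissociation rate tensors over (odorant, receptor, OSN).

    ``b[o, r, n]`` in 1/(ppm*s), ``d[o, r, n]`` in 1/s.  The affinity
    ``a = b / d`` (1/ppm) is defined wherever ``b > 0`` (which requires
    ``d > 0`` there) and zero where ``b == 0``.
    """

    b: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_3d(np.asarray(self.b, dtype=np.float64))
        d = np.atleast_3d(np.asarray(self.d, dtype=np.float64))
        if b.shape != d.shape:
            raise ValueError(f"b and d shapes differ: {b.shape} vs {d.shape}")
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(d))):
            raise ValueError("rate tensors must be finite")
        if np.any(b < 0) or np.any(d < 0):
            raise ValueError("rate tensors must be non-negative")
        if np.any((b > 0) & (d <= 0)):
            raise ValueError("d must be > 0 wherever b > 0 (affinity undefined)")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "d", d)

    @property
    def n_odorants(self) -> int:
        return self.b.shape[0]

    @property
    def n_receptors(self) -> int:
        return self.b.shape[1]

    @property
    def n_osns(self) -> int:
        return self.b.shape[2]

    @property
    def affinity(self) -> np.ndarray:
        """a[o, r, n] = b / d, zero where b == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(self.b > 0, self.b / np.where(self.d > 0, self.d, 1.0), 0.0)
        return a

    def normalized_affinity(self, odorant: int = 0, osn: int = 0) -> np.ndarray:
        """Per-receptor affinity divided by its sum (display normalization)."""
        vec = self.affinity[odorant, :, osn]
        total = vec.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero affinity vector")
        return vec / total

    @classmethod
    def stack(cls, tensors: list["AffinityTensor"]) -> "AffinityTensor":
        """Stack single-odorant tensors along the odorant axis."""
        shapes = {(t.n_receptors, t.n_osns) for t in tensors}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent receptor/OSN dimensions: {shapes}")
        return cls(
            np.concatenate([t.b for t in tensors], axis=0),
            np.concatenate([t.d for t in tensors], axis=0),
        )


@dataclass(frozen=True)
class ConcentrationWaveform:
    """Piecewise-constant concentration waveform u(t) >= 0 (ppm).

    ``segments`` is a sequence of (t_on, t_off, amplitude) triples; outside
    all segments the concentration is zero.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple(
            (float(t0), float(t1), float(amp)) for t0, t1, amp in self.segments
        )
        for t0, t1, amp in segs:
            if t1 <= t0:
                raise ValueError(f"segment offset {t1} must exceed onset {t0}")
            if amp < 0:
                raise ValueError("concentration amplitude must be >= 0")
        object.__setattr__(self, "segments", segs)

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        out = np.zeros_like(t)
        for t0, t1, amp in self.segments:
            out = np.where((t >= t0) & (t < t1), out + amp, out)
        if out.ndim == 0:
            return float(out)
        return out

    def sample(self, t_total: float, dt: float) -> np.ndarray:
        """Sample on the simulation grid: u[k] = u(k * dt), k < t_total/dt."""
        nt = int(round(t_total / dt))
        return np.asarray(self(np.arange(nt) * dt))

    @property
    def peak(self) -> float:
        return max((amp for _, _, amp in self.segments), default=0.0)


@dataclass(frozen=True)
class OdorantSet:
    """A pure odorant (one component) or a mixture of components.

    Each component carries its own concentration waveform; the affinity
    tensor's odorant axis is aligned with ``component_ids``.
    """

    tensor: AffinityTensor
    waveforms: tuple[ConcentrationWaveform, ...]
    component_ids: tuple[str, ...] = ()
    ratio_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.waveforms) != self.tensor.n_odorants:
            raise ValueError("one waveform per mixture component is required")
        if self.tensor.n_odorants < 1:
            raise ValueError("an odorant set needs at least one component")
        ids = self.component_ids or tuple(
            f"component_{i}" for i in range(self.tensor.n_odorants)
        )
        object.__setattr__(self, "component_ids", tuple(ids))
        object.__setattr__(self, "waveforms", tuple(self.waveforms))

    @property
    def n_components(self) -> int:
        return self.tensor.n_odorants

    @property
    def is_pure(self) -> bool:
        return self.n_components == 1

    def sample_concentrations(self, t_total: float, dt: float) -> np.ndarray:
        """u[o, k]: sampled concentration of every component (ppm)."""
        return np.stack([w.sample(t_total, dt) for w in self.waveforms])


_PROFILE_RE = re.compile(r"^sparse-(\d+)$")


def synth_affinity_profile(
    n_receptors: int,
    profile: str = "sparse-1",
    k: int | None = None,
    seed: int = 0,
    low: float = 1e-5,
    high: float = 2.5e-4,
    broad_low: float = 2e-4,
    broad_high: float = 4e-2,
    dominant_low: float = 8e-3,
    dominant_high: float = 2e-2,
) -> AffinityTensor:
    """Generate a single-odorant affinity tensor (O=1, N=1).

    ``profile`` is ``"sparse-k"`` (k receptors dominate; ``"sparse-1"`` is
    the acetone-like single-peak regime, ``"sparse-3"`` the nerol-like
    regime) or ``"broad"`` (ethyl-butyrate-like, no dominant receptor).
    Sparse profiles draw background affinities log-uniformly from
    [low, high] 1/ppm (sub-half-saturation of the binding equilibrium over
    50-200 ppm) and the k dominant entries log-uniformly from
    [dominant_low, dominant_high] -- comparable strong peaks whose a*u
    spans sub- to supra-half-saturation across 50-200 ppm, keeping
    dominant-channel responses concentration sensitive at every level.
    If the dominant share of the summed affinity falls below 80% it is
    boosted to that floor.  Broad profiles draw every receptor from the
    wider range [broad_low, broad_high]: many comparably responsive
    receptors, none dominant.  Deterministic given ``seed``.
    """
    if n_receptors < 1:
        raise ValueError("n_receptors must be >= 1")
    match = _PROFILE_RE.match(profile)
    if match is not None:
        if k is not None and k != int(match.group(1)):
            raise ValueError(f"profile {profile!r} conflicts with k={k}")
        k = int(match.group(1))
        kind = "sparse"
    elif profile == "sparse":
        k = 1 if k is None else k
        kind = "sparse"
    elif profile == "broad":
        kind = "broad"
    else:
        raise ValueError(f"unknown affinity profile {profile!r}")

    rng = np.random.default_rng(seed)
    lo, hi = (broad_low, broad_high) if kind == "broad" else (low, high)
    a = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_receptors))
    if kind == "sparse":
        if not 1 <= k <= n_receptors:
            raise ValueError(f"invalid profile: k={k} not in [1, {n_receptors}]")
        dominant = rng.choice(n_receptors, size=k, replace=False)
        a[dominant] = np.exp(
            rng.uniform(np.log(dominant_low), np.log(dominant_high), size=k)
        )
        share = a[dominant].sum() / a.sum()
        if share < 0.8:
            # minimal extra boost so the dominant set holds exactly 80%
            rest = a.sum() - a[dominant].sum()
            a[dominant] *= 4.0 * rest / a[dominant].sum()
    d = np.exp(rng.uniform(np.log(5.0), np.log(50.0), size=n_receptors))
    b = a * d
    return AffinityTensor(b.reshape(1, -1, 1), d.reshape(1, -1, 1))


def step_waveform(
    amplitude: float, t_on: float, t_off: float
) -> ConcentrationWaveform:
    """Constant-amplitude concentration step on [t_on, t_off) ppm."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if t_off <= t_on:
        raise ValueError("t_off must exceed t_on")
    if amplitude == 0:
        return ConcentrationWaveform(())
    return ConcentrationWaveform(((t_on, t_off, amplitude),))


def make_mixture(
    components: list[tuple[AffinityTensor, float]],
    t_on: float,
    t_off: float,
    component_ids: tuple[str, ...] | None = None,
) -> OdorantSet:
    """Build an OdorantSet from (single-odorant tensor, amplitude) pairs.

    All components share the same step timing; each keeps its own amplitude.
    The ratio label records the amplitude ratio, e.g. ``"4:1"`` for 100 ppm
    and 25 ppm components.
    """
    if not components:
        raise ValueError("a mixture needs at least one component")
    tensors, amps = zip(*components)
    for t in tensors:
        if t.n_odorants != 1:
            raise ValueError("each component tensor must be single-odorant")
    stacked = AffinityTensor.stack(list(tensors))
    waveforms = tuple(step_waveform(amp, t_on, t_off) for amp in amps)
    label = None
    if len(amps) > 1 and min(amps) > 0:
        base = min(amps)
        parts = [amp / base for amp in amps]
        if all(abs(p - round(p)) < 1e-9 for p in parts):
            label = ":".join(str(int(round(p))) for p in parts)
    return OdorantSet(stacked, waveforms, component_ids or (), ratio_label=label)


def affinity_to_csv(tensor: AffinityTensor, path) -> None:
    """Write the rate tensor as a long-format CSV."""
    rows = []
    for o in range(tensor.n_odorants):
        for r in range(tensor.n_receptors):
            for n in range(tensor.n_osns):
                rows.append((o, r, n, tensor.b[o, r, n], tensor.d[o, r, n]))
    pd.DataFrame(
        rows, columns=["odorant_id", "receptor_id", "osn_id", "b", "d"]
    ).to_csv(path, index=False)


def affinity_from_csv(path) -> AffinityTensor:
    """Read a rate tensor written by :func:`affinity_to_csv`."""
    df = pd.read_csv(path)
    n_o = int(df["odorant_id"].max()) + 1
    n_r = int(df["receptor_id"].max()) + 1
    n_n = int(df["osn_id"].max()) + 1
    b = np.zeros((n_o, n_r, n_n))
    d = np.zeros((n_o, n_r, n_n))
    for row in df.itertuples(index=False):
        b[int(row.odorant_id), int(row.receptor_id), int(row.osn_id)] = row.b
        d[int(row.odorant_id), int(row.receptor_id), int(row.osn_id)] = row.d
    return AffinityTensor(b, d)
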