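"""Random E/I network construction and integrate-and-fire simulation.

The network is a directed Erdös–Rényi graph of ``N`` leaky
integrate-and-fire neurons (first 80% excitatory by index convention, the
rest inhibitory).  Each externally driven neuron receives an independent
Poisson spike train; every presynaptic spike depolarizes its target
instantaneously by the coupling strength.  Two integration modes exist:

``simulate_full``
    Euler integration with recurrent spikes delivered at the next step.
``simulate_avalanche_mode``
    Reduced-model integration in which recurrent spikes propagate
    instantaneously within a step, so that each cascade (neuronal
    avalanche) is a well-separated event with an exact size and duration.
"""
from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _kernels
from .config import NetworkConfig

__all__ = [
    "CouplingMatrix",
    "StimulusDrive",
    "SpikeRaster",
    "AvalancheRecords",
    "build_coupling",
    "draw_stimulus_set",
    "init_membrane",
    "draw_external_input",
    "simulate_full",
    "simulate_avalanche_mode",
    "write_raster",
    "read_raster",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #
@dataclasses.dataclass
class CouplingMatrix:
    """Directed binary adjacency. ``w[i, j] = 1`` iff a connection j -> i
    exists; self-connections are permitted.  Neurons ``0..n_exc-1`` are
    excitatory, the remaining ``n_inh`` inhibitory."""

    w: sp.csr_matrix
    n_exc: int
    n_inh: int
    # outgoing adjacency (per presynaptic neuron) for the kernels
    out_indptr: np.ndarray = dataclasses.field(repr=False, default=None)
    out_indices: np.ndarray = dataclasses.field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = self.w.shape[0]
        if self.w.shape != (n, n):
            raise ValueError("coupling matrix must be square")
        if self.n_exc + self.n_inh != n:
            raise ValueError("n_exc + n_inh must equal N")
        if self.out_indptr is None:
            csc = self.w.tocsc()
            self.out_indptr = csc.indptr.astype(np.int64)
            self.out_indices = csc.indices.astype(np.int64)

    @property
    def n_neurons(self) -> int:
        return self.w.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.w.nnz)


@dataclasses.dataclass(frozen=True)
class StimulusDrive:
    """Sorted indices of the externally driven neuron subset for one stimulus."""

    active_set: np.ndarray
    stimulus_id: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.active_set, dtype=np.int64)
        if idx.size != np.unique(idx).size:
            raise ValueError("active_set indices must be unique")
        if idx.size and idx.min() < 0:
            raise ValueError("active_set indices must be non-negative")
        object.__setattr__(self, "active_set", np.sort(idx))


@dataclasses.dataclass
class SpikeRaster:
    """Timestamped spikes of the recurrent (V4) layer plus the per-step
    count of delivered external (V1) input spikes.

    ``step``/``neuron`` hold one entry per recurrent spike; in avalanche
    mode all spikes of one cascade share the step at which it occurred.
    External input is stored as a per-step total count — every analysis in
    the package (notably the LFP superposition) consumes only this sum.
    """

    step: np.ndarray
    neuron: np.ndarray
    ext_count: np.ndarray
    dt: float
    t_total: float
    t_transient: float
    n_neurons: int
    mode: str  # "full" | "avalanche"

    @property
    def times(self) -> np.ndarray:
        """Spike times in ms."""
        return self.step * self.dt

    @property
    def n_steps(self) -> int:
        return self.ext_count.size

    @property
    def transient_steps(self) -> int:
        return int(round(self.t_transient / self.dt))

    def post_transient(self) -> "SpikeRaster":
        """Copy with the transient period removed (times rebased to 0)."""
        t0 = self.transient_steps
        keep = self.step >= t0
        return SpikeRaster(
            step=self.step[keep] - t0,
            neuron=self.neuron[keep],
            ext_count=self.ext_count[t0:].copy(),
            dt=self.dt,
            t_total=self.t_total - self.t_transient,
            t_transient=0.0,
            n_neurons=self.n_neurons,
            mode=self.mode,
        )

    def counts_per_step(self) -> np.ndarray:
        """Recurrent-layer spike count per integration step."""
        return np.bincount(self.step, minlength=self.n_steps).astype(np.int64)


@dataclasses.dataclass
class AvalancheRecords:
    """Raw cascade bookkeeping from an avalanche-mode run (unfiltered)."""

    step: np.ndarray
    size: np.ndarray
    duration: np.ndarray
    n_neurons: int


# --------------------------------------------------------------------------- #
# construction
# --------------------------------------------------------------------------- #
def build_coupling(n_neurons: int, p: float, eps: int = 4, seed=None) -> CouplingMatrix:
    """Draw a directed Erdös–Rényi coupling matrix.

    Each of the N² ordered entries (self-connections included) is
    independently 1 with probability ``p``.  The first
    ``N * eps / (1 + eps)`` indices are excitatory.
    """
    if n_neurons % (1 + eps) != 0:
        raise ValueError(f"n_neurons={n_neurons} not divisible by 1+eps={1 + eps}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = _rng(seed)
    n_exc = n_neurons * eps // (1 + eps)
    dense = rng.random((n_neurons, n_neurons)) < p
    w = sp.csr_matrix(dense, dtype=np.int8)
    return CouplingMatrix(w=w, n_exc=n_exc, n_inh=n_neurons - n_exc)


def draw_stimulus_set(
    n_neurons: int, n_active: int, n_stimuli: int, seed=None
) -> list[StimulusDrive]:
    """Draw ``n_stimuli`` independent uniform-random driven subsets of size
    ``n_active`` (subsets may overlap)."""
    if n_active > n_neurons:
        raise ValueError("n_active cannot exceed n_neurons")
    rng = _rng(seed)
    return [
        StimulusDrive(
            active_set=rng.choice(n_neurons, size=n_active, replace=False),
            stimulus_id=a,
        )
        for a in range(n_stimuli)
    ]


# Constant suprathreshold drive used only to set asynchronous initial
# conditions: asymptote two threshold distances above rest, so the isolated
# deterministic trajectory V(t) = V_R + mu (1 - exp(-t/tau)) fires with
# period tau * ln(mu / (mu - dv)).
_INIT_DRIVE_FACTOR = 2.0


def init_membrane(config: NetworkConfig, seed=None) -> np.ndarray:
    """Asynchronous initial membrane potentials.

    Each neuron is placed at a uniform-random phase of the periodic
    trajectory of an isolated neuron under a constant suprathreshold drive
    (asymptote ``_INIT_DRIVE_FACTOR`` threshold distances above rest), i.e.
    V_i(0) = V_R + mu (1 - exp(-t_i / tau)) with t_i uniform on one period.
    """
    rng = _rng(seed)
    dv = config.v_theta - config.v_rest
    mu = _INIT_DRIVE_FACTOR * dv
    period = config.tau_mem * np.log(mu / (mu - dv))
    t = rng.uniform(0.0, period, size=config.n_neurons)
    return config.v_rest + mu * (1.0 - np.exp(-t / config.tau_mem))


def _poisson_cdf(lam: float) -> np.ndarray:
    """Poisson CDF table truncated where the tail drops below 1e-12."""
    pmf = [np.exp(-lam)]
    k = 0
    while 1.0 - sum(pmf) > 1e-12:
        k += 1
        pmf.append(pmf[-1] * lam / k)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    return cdf


def draw_external_input(
    config: NetworkConfig, n_driven: int, seed=None
) -> np.ndarray:
    """Per-step Poisson spike counts for the driven neurons,
    shape (n_steps, n_driven), mean ``f_max * dt`` per entry.

    Sampling is done by a compiled inverse-CDF lookup (the input stream is
    by far the largest random object in a run); its stream seed is drawn
    from ``seed``, so a fixed seed fixes the realization.
    """
    rng = _rng(seed)
    lam = config.f_max * config.dt
    stream_seed = int(rng.integers(0, 2**63, dtype=np.uint64))
    return _kernels.poisson_counts(
        config.n_steps, n_driven, _poisson_cdf(lam), stream_seed
    )


# --------------------------------------------------------------------------- #
# simulation
# --------------------------------------------------------------------------- #
def _check(config: NetworkConfig, coupling: CouplingMatrix, stimulus: StimulusDrive):
    if coupling.n_neurons != config.n_neurons:
        raise ValueError("coupling matrix size does not match configuration")
    if stimulus.active_set.size and stimulus.active_set.max() >= config.n_neurons:
        raise ValueError("stimulus drives neurons outside the network")


def simulate_full(
    config: NetworkConfig,
    coupling: CouplingMatrix,
    stimulus: StimulusDrive,
    seed=None,
    v0: np.ndarray | None = None,
    ext_counts: np.ndarray | None = None,
) -> SpikeRaster:
    """Euler-integrate the full model (one-step recurrent delay).

    ``v0`` and ``ext_counts`` may be supplied explicitly (e.g. to share the
    identical external input realization between two coupling conditions);
    otherwise both are drawn from ``seed``.
    """
    _check(config, coupling, stimulus)
    rng = _rng(config.seed if seed is None else seed)
    if v0 is None:
        v0 = init_membrane(config, rng)
    if ext_counts is None:
        ext_counts = draw_external_input(config, stimulus.active_set.size, rng)
    v = np.array(v0, dtype=np.float64, copy=True)
    step, neuron, ext_total, err = _kernels.run_full(
        v,
        coupling.out_indptr,
        coupling.out_indices,
        coupling.n_exc,
        config.j_exc,
        config.j_inh,
        config.j_ext,
        config.leak,
        config.v_rest,
        config.v_theta,
        ext_counts,
        stimulus.active_set,
    )
    if err >= 0:
        raise FloatingPointError(
            f"non-finite membrane potential at step {err} (t={err * config.dt} ms)"
        )
    return SpikeRaster(
        step=step,
        neuron=neuron,
        ext_count=ext_total,
        dt=config.dt,
        t_total=config.t_total,
        t_transient=config.t_transient,
        n_neurons=config.n_neurons,
        mode="full",
    )


def simulate_avalanche_mode(
    config: NetworkConfig,
    coupling: CouplingMatrix,
    stimulus: StimulusDrive,
    seed=None,
    v0: np.ndarray | None = None,
    ext_counts: np.ndarray | None = None,
) -> tuple[SpikeRaster, AvalancheRecords]:
    """Reduced-model run with instantaneous cascades (separation of
    timescales).  Returns the raster plus one record per avalanche:
    size = distinct neurons fired, duration = number of generations."""
    _check(config, coupling, stimulus)
    rng = _rng(config.seed if seed is None else seed)
    if v0 is None:
        v0 = init_membrane(config, rng)
    if ext_counts is None:
        ext_counts = draw_external_input(config, stimulus.active_set.size, rng)
    v = np.array(v0, dtype=np.float64, copy=True)
    step, neuron, ext_total, av_step, av_size, av_dur, err = _kernels.run_avalanche(
        v,
        coupling.out_indptr,
        coupling.out_indices,
        coupling.n_exc,
        config.j_exc,
        config.j_inh,
        config.j_ext,
        config.leak,
        config.v_rest,
        config.v_theta,
        ext_counts,
        stimulus.active_set,
    )
    if err >= 0:
        raise FloatingPointError(
            f"non-finite membrane potential at step {err} (t={err * config.dt} ms)"
        )
    raster = SpikeRaster(
        step=step,
        neuron=neuron,
        ext_count=ext_total,
        dt=config.dt,
        t_total=config.t_total,
        t_transient=config.t_transient,
        n_neurons=config.n_neurons,
        mode="avalanche",
    )
    records = AvalancheRecords(
        step=av_step, size=av_size, duration=av_dur, n_neurons=config.n_neurons
    )
    return raster, records


# --------------------------------------------------------------------------- #
# raster store
# --------------------------------------------------------------------------- #
def write_raster(
    raster: SpikeRaster, base_path: str | Path, config: NetworkConfig | None = None
) -> None:
    """Persist a raster as ``<base>.spikes.csv.gz`` + ``<base>.meta.json``.

    The spike table has columns (time_ms, neuron_id, layer, count):
    recurrent-layer spikes one row each (layer='v4', count=1), external
    input aggregated per step (layer='ext', neuron_id=-1, count=n).
    """
    base = Path(base_path)
    v4 = pd.DataFrame(
        {
            "time_ms": raster.times,
            "neuron_id": raster.neuron,
            "layer": "v4",
            "count": 1,
        }
    )
    nz = np.nonzero(raster.ext_count)[0]
    ext = pd.DataFrame(
        {
            "time_ms": nz * raster.dt,
            "neuron_id": -1,
            "layer": "ext",
            "count": raster.ext_count[nz],
        }
    )
    pd.concat([v4, ext], ignore_index=True).to_csv(
        f"{base}.spikes.csv.gz", index=False, compression="gzip"
    )
    meta = {
        "dt": raster.dt,
        "t_total": raster.t_total,
        "t_transient": raster.t_transient,
        "n_neurons": raster.n_neurons,
        "mode": raster.mode,
        "n_steps": raster.n_steps,
        "config": config.to_dict() if config is not None else None,
    }
    with open(f"{base}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_raster(base_path: str | Path) -> SpikeRaster:
    base = Path(base_path)
    with open(f"{base}.meta.json") as fh:
        meta = json.load(fh)
    with gzip.open(f"{base}.spikes.csv.gz", "rt") as fh:
        df = pd.read_csv(fh)
    v4 = df[df["layer"] == "v4"]
    ext = df[df["layer"] == "ext"]
    dt = float(meta["dt"])
    ext_count = np.zeros(int(meta["n_steps"]), dtype=np.int64)
    steps_ext = np.round(ext["time_ms"].to_numpy() / dt).astype(np.int64)
    ext_count[steps_ext] = ext["count"].to_numpy()
    return SpikeRaster(
        step=np.round(v4["time_ms"].to_numpy() / dt).astype(np.int64),
        neuron=v4["neuron_id"].to_numpy(np.int64),
        ext_count=ext_count,
        dt=dt,
        t_total=float(meta["t_total"]),
        t_transient=float(meta["t_transient"]),
        n_neurons=int(meta["n_neurons"]),
        mode=str(meta["mode"]),
    )
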