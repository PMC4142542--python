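"""LFP synthesis: exponential-kernel filtering of summed spiking activity.

The model LFP is the causal convolution

    U(t) = K(t) ⊗ ( sum_k δ(t - t_k^V4) + c_mix · sum_k δ(t - t_k^ext) ),
    K(t) = (1/τ_k) exp(-t/τ_k),

computed on the per-step binned spike-count signal.  With the default
mixing constant ``c_mix = 0.2`` the external (V1) input contributes the
1/f background of the spectra; the reduced model uses ``c_mix = 0`` (the
external spikes still drive the neurons, they are just excluded from the
signal).  A 50 ms margin (~3.3 τ_k) is trimmed from both ends to avoid
filter edge effects.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import fftconvolve

from .network import SpikeRaster

__all__ = ["LFPTrace", "exponential_kernel", "generate_lfp", "write_lfp", "read_lfp"]

#: margin removed from each end of the filtered trace, ms
EDGE_MARGIN_MS = 50.0
#: causal kernel truncation, in units of tau_k
KERNEL_TRUNCATION = 10.0


@dataclasses.dataclass
class LFPTrace:
    """LFP samples (arbitrary units) at interval ``dt``; ``t0`` is the time
    of the first retained sample after margin removal."""

    u: np.ndarray
    t0: float
    dt: float

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.u.size) * self.dt

    @property
    def duration(self) -> float:
        return self.u.size * self.dt


def exponential_kernel(tau_k: float, dt: float) -> np.ndarray:
    """Sampled causal kernel (1/τ_k) e^{-t/τ_k}, truncated at 10 τ_k.

    The discrete sum times dt equals 1 up to O(dt/τ_k); no renormalization
    is applied, so a single spike reproduces the closed-form kernel exactly
    at the sample points.
    """
    t = np.arange(0.0, KERNEL_TRUNCATION * tau_k, dt)
    return np.exp(-t / tau_k) / tau_k


def generate_lfp(
    raster: SpikeRaster,
    c_mix: float = 0.2,
    tau_k: float = 15.0,
    step_range: tuple[int, int] | None = None,
) -> LFPTrace:
    """Synthesize the LFP from a spike raster.

    Parameters
    ----------
    raster
        Simulation output.  By default the post-transient portion of the
        run is used; pass ``step_range`` (start, stop) in raw step indices
        to select a sub-interval (e.g. one reduced-model trial segment).
    c_mix
        Mixing constant scaling the external-input spike train in the
        superposition (0.2 full model, 0 reduced model).
    tau_k
        Kernel time constant, ms.
    """
    if step_range is None:
        step_range = (raster.transient_steps, raster.n_steps)
    a, b = step_range
    if not 0 <= a < b <= raster.n_steps:
        raise ValueError(f"invalid step range {step_range}")
    dt = raster.dt
    margin = int(round(EDGE_MARGIN_MS / dt))
    if (b - a) <= 2 * margin:
        raise ValueError(
            f"trace of {(b - a) * dt} ms is too short for two {EDGE_MARGIN_MS} ms margins"
        )
    sel = (raster.step >= a) & (raster.step < b)
    counts = np.bincount(raster.step[sel] - a, minlength=b - a).astype(np.float64)
    if c_mix != 0.0:
        counts = counts + c_mix * raster.ext_count[a:b]
    kern = exponential_kernel(tau_k, dt)
    u = fftconvolve(counts, kern)[: b - a]
    u = u[margin : (b - a) - margin]
    return LFPTrace(u=u, t0=(a + margin) * dt, dt=dt)


# --------------------------------------------------------------------------- #
def write_lfp(trace: LFPTrace, path: str) -> None:
    """Two-column time/amplitude table; sample rate in the header line."""
    header = f"sample_interval_ms={trace.dt}\ntime_ms,amplitude"
    np.savetxt(
        path,
        np.column_stack([trace.times, trace.u]),
        delimiter=",",
        header=header,
        comments="# ",
    )


def read_lfp(path: str) -> LFPTrace:
    with open(path) as fh:
        first = fh.readline()
    dt = float(first.strip().lstrip("# ").split("=")[1])
    data = np.loadtxt(path, delimiter=",", skiprows=2)
    return LFPTrace(u=data[:, 1], t0=float(data[0, 0]), dt=dt)
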