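"""Information entropy of spike patterns under coarse-grained observation.

The per-step spike pattern of the network is reduced to an observation
scale ``K``: neurons are permuted by a fixed random channel order (drawn
once per network and reused across all K), then summed in consecutive
blocks of K, giving N/K channels with values in [0, K].  K = 1 is the raw
binary pattern, K = N the population spike count.  The plug-in Shannon
entropy H(X) = -Σ P(x) log₂ P(x) of the empirical state distribution over
post-transient time steps quantifies pattern diversity.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .network import SpikeRaster

__all__ = [
    "PatternSeries",
    "draw_channel_order",
    "coarse_grain",
    "pattern_entropy",
    "entropy_by_scale",
]


@dataclasses.dataclass
class PatternSeries:
    """Coarse-grained spike patterns: one length-(N/K) state per time step."""

    states: np.ndarray  # (n_steps, n_channels) integer counts in [0, K]
    K: int
    channel_order: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def n_channels(self) -> int:
        return self.states.shape[1]


def draw_channel_order(n_neurons: int, seed=None) -> np.ndarray:
    """Fixed random neuron-to-channel-position permutation for one network."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.permutation(n_neurons)


def coarse_grain(
    raster: SpikeRaster, K: int, channel_order: np.ndarray
) -> PatternSeries:
    """Coarse-grain the post-transient raster at observation scale K.

    Per time step the binary per-neuron activity is permuted by
    ``channel_order`` and summed in consecutive blocks of K neurons.
    """
    n = raster.n_neurons
    if n % K != 0:
        raise ValueError(f"K={K} does not divide N={n}")
    post = raster.post_transient()
    n_steps = post.n_steps
    # position of each neuron in the permuted layout -> channel index
    pos = np.empty(n, dtype=np.int64)
    pos[np.asarray(channel_order)] = np.arange(n)
    channel = pos[post.neuron] // K
    n_ch = n // K
    dtype = np.uint8 if K <= 255 else np.uint16
    states = np.zeros((n_steps, n_ch), dtype=dtype)
    np.add.at(states, (post.step, channel), 1)
    return PatternSeries(states=states, K=K, channel_order=np.asarray(channel_order))


def pattern_entropy(series: PatternSeries) -> float:
    """Plug-in Shannon entropy (bits) of the empirical state distribution."""
    states = np.ascontiguousarray(series.states)
    if states.shape[0] == 0:
        raise ValueError("entropy of an empty pattern series is undefined")
    void = states.view(np.dtype((np.void, states.dtype.itemsize * states.shape[1])))
    _, counts = np.unique(void.ravel(), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_by_scale(
    raster: SpikeRaster, k_ladder, channel_order: np.ndarray
) -> dict[int, float]:
    """Pattern entropy at each observation scale of ``k_ladder``."""
    return {
        int(k): pattern_entropy(coarse_grain(raster, int(k), channel_order))
        for k in k_ladder
    }
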