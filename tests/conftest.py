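"""Shared fixtures: tiny hand-built networks and rasters."""
import numpy as np
import pytest
import scipy.sparse as sp

from critnet.config import NetworkConfig
from critnet.network import CouplingMatrix, SpikeRaster, StimulusDrive


def coupling_from_dense(dense, n_exc=None):
    """CouplingMatrix from a dense 0/1 array (entry [i, j] = j -> i)."""
    dense = np.asarray(dense, dtype=np.int8)
    n = dense.shape[0]
    if n_exc is None:
        n_exc = n
    return CouplingMatrix(w=sp.csr_matrix(dense), n_exc=n_exc, n_inh=n - n_exc)


def empty_raster(n_neurons=10, n_steps=5000, dt=0.1, mode="full", t_transient=0.0):
    return SpikeRaster(
        step=np.array([], dtype=np.int64),
        neuron=np.array([], dtype=np.int64),
        ext_count=np.zeros(n_steps, dtype=np.int64),
        dt=dt,
        t_total=n_steps * dt,
        t_transient=t_transient,
        n_neurons=n_neurons,
        mode=mode,
    )


def raster_from_spikes(spikes, n_neurons, n_steps, dt=0.1, mode="full",
                       t_transient=0.0, ext_count=None):
    """Raster from a list of (step, neuron) pairs."""
    spikes = sorted(spikes)
    step = np.array([s for s, _ in spikes], dtype=np.int64)
    neuron = np.array([i for _, i in spikes], dtype=np.int64)
    if ext_count is None:
        ext_count = np.zeros(n_steps, dtype=np.int64)
    return SpikeRaster(step=step, neuron=neuron, ext_count=ext_count, dt=dt,
                       t_total=n_steps * dt, t_transient=t_transient,
                       n_neurons=n_neurons, mode=mode)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
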