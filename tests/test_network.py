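import numpy as np
import pytest
from scipy import stats

from critnet.config import NetworkConfig
from critnet.network import (
    StimulusDrive,
    build_coupling,
    draw_external_input,
    draw_stimulus_set,
    init_membrane,
    read_raster,
    simulate_avalanche_mode,
    simulate_full,
    write_raster,
)

from conftest import coupling_from_dense


# --------------------------------------------------------------------------- #
# coupling matrix
# --------------------------------------------------------------------------- #
def test_coupling_edge_count_in_binomial_band():
    c = build_coupling(2500, 0.02, 4, seed=0)
    mean = 2500**2 * 0.02
    sigma = np.sqrt(2500**2 * 0.02 * 0.98)
    assert abs(c.n_edges - mean) < 5 * sigma


def test_coupling_p0_and_p1():
    assert build_coupling(100, 0.0, 4, seed=0).n_edges == 0
    assert build_coupling(100, 1.0, 4, seed=0).n_edges == 100**2


def test_coupling_ei_split():
    c = build_coupling(1000, 0.02, 4, seed=1)
    assert c.n_exc == 800 and c.n_inh == 200


def test_coupling_rejects_nondivisible_n():
    with pytest.raises(ValueError):
        build_coupling(1001, 0.02, 4, seed=0)


def test_coupling_is_directed():
    c = build_coupling(200, 0.1, 4, seed=2)
    w = c.w.toarray()
    assert not np.array_equal(w, w.T)


# --------------------------------------------------------------------------- #
# stimulus sets
# --------------------------------------------------------------------------- #
def test_stimulus_sets_have_requested_size():
    stims = draw_stimulus_set(2500, 1000, 6, seed=3)
    assert len(stims) == 6
    for st in stims:
        assert st.active_set.size == 1000
        assert np.unique(st.active_set).size == 1000
        assert st.active_set.max() < 2500


def test_full_coverage_when_n_active_equals_n():
    stims = draw_stimulus_set(10, 10, 3, seed=4)
    for st in stims:
        assert np.array_equal(st.active_set, np.arange(10))


def test_stimulus_oversize_rejected():
    with pytest.raises(ValueError):
        draw_stimulus_set(100, 101, 1, seed=0)


def test_stimulus_sets_may_overlap():
    stims = draw_stimulus_set(2500, 1000, 2, seed=5)
    assert np.intersect1d(stims[0].active_set, stims[1].active_set).size > 0


# --------------------------------------------------------------------------- #
# initial conditions
# --------------------------------------------------------------------------- #
def test_init_membrane_matches_sojourn_density():
    """V(0) follows the analytic time-in-state distribution of the periodic
    constant-drive trajectory (uniform phase => log-shaped CDF in V)."""
    cfg = NetworkConfig(n_neurons=20000, n_active=1000)
    v0 = init_membrane(cfg, seed=6)
    assert v0.min() >= cfg.v_rest and v0.max() < cfg.v_theta
    dv = cfg.v_theta - cfg.v_rest
    mu = 2.0 * dv
    period = cfg.tau_mem * np.log(mu / (mu - dv))

    def cdf(v):
        t = -cfg.tau_mem * np.log(1.0 - (v - cfg.v_rest) / mu)
        return t / period

    d, p = stats.kstest(v0, cdf)
    assert p > 1e-3


def test_init_membrane_seed_contract():
    cfg = NetworkConfig()
    a = init_membrane(cfg, seed=1)
    b = init_membrane(cfg, seed=1)
    c = init_membrane(cfg, seed=2)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


# --------------------------------------------------------------------------- #
# external input
# --------------------------------------------------------------------------- #
def test_external_input_poisson_moments():
    cfg = NetworkConfig(n_neurons=100, n_active=50, t_total=1000.0, t_transient=100.0)
    x = draw_external_input(cfg, 50, seed=7).astype(float)
    lam = cfg.f_max * cfg.dt
    n = x.size
    assert x.mean() == pytest.approx(lam, abs=5 * np.sqrt(lam / n))
    assert x.var() == pytest.approx(lam, rel=0.02)


# --------------------------------------------------------------------------- #
# full-mode dynamics
# --------------------------------------------------------------------------- #
def _quiet_config(**kw):
    base = dict(
        n_neurons=5, n_active=5, p_connect=0.0, eps=4,
        t_total=100.0, t_transient=0.0, f_max=0.0,
    )
    base.update(kw)
    return NetworkConfig(**base)


def test_no_drive_no_coupling_stays_silent():
    cfg = _quiet_config()
    coup = coupling_from_dense(np.zeros((5, 5)), n_exc=4)
    stim = StimulusDrive(active_set=np.arange(5))
    v0 = np.full(5, cfg.v_rest)
    raster = simulate_full(cfg, coup, stim, v0=v0, ext_counts=np.zeros((cfg.n_steps, 5), np.uint8))
    assert raster.step.size == 0


def test_recurrent_spike_arrives_one_step_late():
    """A presynaptic spike at t0 lifts its target across threshold at t0+dt."""
    cfg = _quiet_config(j_exc=15.0)
    w = np.zeros((5, 5))
    w[1, 0] = 1  # 0 -> 1
    coup = coupling_from_dense(w, n_exc=4)
    stim = StimulusDrive(active_set=np.arange(5))
    v0 = np.full(5, cfg.v_rest)
    v0[0] = cfg.v_theta + 0.5  # above threshold even after one leak step
    raster = simulate_full(cfg, coup, stim, v0=v0, ext_counts=np.zeros((cfg.n_steps, 5), np.uint8))
    got = sorted(zip(raster.step.tolist(), raster.neuron.tolist()))
    assert got == [(0, 0), (1, 1)]


def _reference_isolated_rate(cfg, n_neurons, n_steps, seed):
    """Brute-force event-driven reference: plain per-step Euler update with
    numpy Poisson input, independent of the compiled kernel."""
    rng = np.random.default_rng(seed)
    lam = cfg.f_max * cfg.dt
    v = np.full(n_neurons, cfg.v_rest)
    spikes = 0
    for _ in range(n_steps):
        v += cfg.leak * (cfg.v_rest - v) + cfg.j_ext * rng.poisson(lam, n_neurons)
        fired = v >= cfg.v_theta
        spikes += int(fired.sum())
        v[fired] = cfg.v_rest
    return spikes / n_neurons / (n_steps * cfg.dt * 1e-3)


def test_isolated_neuron_rate_matches_reference():
    """Mean drive tau*J_ext*f_max exactly reaches threshold, so firing is
    fluctuation-driven; rate must agree with an independent reference."""
    cfg = NetworkConfig(
        n_neurons=50, n_active=50, p_connect=0.0,
        t_total=4000.0, t_transient=0.0,
    )
    assert cfg.v_rest + cfg.tau_mem * cfg.j_ext * cfg.f_max == pytest.approx(cfg.v_theta)
    coup = coupling_from_dense(np.zeros((50, 50)), n_exc=40)
    stim = StimulusDrive(active_set=np.arange(50))
    v0 = np.full(50, cfg.v_rest)
    raster = simulate_full(cfg, coup, stim, seed=8, v0=v0)
    rate = raster.step.size / 50 / (cfg.t_total * 1e-3)
    ref = _reference_isolated_rate(cfg, 50, cfg.n_steps, seed=9)
    assert rate == pytest.approx(ref, rel=0.15)


def test_full_mode_seed_reproducibility():
    cfg = NetworkConfig(n_neurons=100, n_active=50, t_total=500.0, t_transient=0.0)
    coup = build_coupling(100, 0.05, 4, seed=1)
    stim = draw_stimulus_set(100, 50, 1, seed=2)[0]
    a = simulate_full(cfg, coup, stim, seed=11)
    b = simulate_full(cfg, coup, stim, seed=11)
    assert np.array_equal(a.step, b.step)
    assert np.array_equal(a.neuron, b.neuron)
    assert np.array_equal(a.ext_count, b.ext_count)


def test_non_finite_potential_reported():
    cfg = _quiet_config()
    coup = coupling_from_dense(np.zeros((5, 5)), n_exc=4)
    stim = StimulusDrive(active_set=np.arange(5))
    v0 = np.full(5, np.nan)
    with pytest.raises(FloatingPointError, match="step"):
        simulate_full(cfg, coup, stim, v0=v0, ext_counts=np.zeros((cfg.n_steps, 5), np.uint8))


# --------------------------------------------------------------------------- #
# avalanche mode
# --------------------------------------------------------------------------- #
def test_avalanche_no_coupling_no_propagation():
    cfg = NetworkConfig(
        n_neurons=5, n_active=5, p_connect=0.0, eps=4,
        t_total=2000.0, t_transient=0.0,
    )
    coup = coupling_from_dense(np.zeros((5, 5)), n_exc=4)
    stim = StimulusDrive(active_set=np.arange(5))
    raster, rec = simulate_avalanche_mode(cfg, coup, stim, seed=12)
    assert rec.size.size > 0
    assert np.all(rec.duration == 1)  # no propagation beyond generation 1


def test_avalanche_chain_cascade():
    """Chain 0 -> 1 -> 2 with suprathreshold coupling: one avalanche of
    size 3 spanning 3 generations."""
    cfg = NetworkConfig(
        n_neurons=4, n_active=4, p_connect=0.0, eps=3, j_exc=15.0,
        t_total=10.0, t_transient=0.0, f_max=0.0,
    )
    w = np.zeros((4, 4))
    w[1, 0] = w[2, 1] = 1
    coup = coupling_from_dense(w, n_exc=3)
    stim = StimulusDrive(active_set=np.arange(4))
    v0 = np.full(4, cfg.v_rest)
    v0[0] = cfg.v_theta + 0.5
    raster, rec = simulate_avalanche_mode(
        cfg, coup, stim, v0=v0, ext_counts=np.zeros((cfg.n_steps, 4), np.uint8)
    )
    assert rec.size.tolist() == [3]
    assert rec.duration.tolist() == [3]
    assert raster.step.tolist() == [0, 0, 0]  # whole cascade in one step


def test_avalanche_complete_graph_two_generations():
    """All neurons one subthreshold increment below threshold: the trigger
    fires, everyone else follows in generation 2 (s = N, T = 2)."""
    n = 5
    cfg = NetworkConfig(
        n_neurons=n, n_active=n, p_connect=1.0, eps=4, j_exc=1.0,
        t_total=10.0, t_transient=0.0, f_max=0.0,
    )
    coup = coupling_from_dense(np.ones((n, n)), n_exc=4)
    stim = StimulusDrive(active_set=np.arange(n))
    v0 = np.full(n, cfg.v_theta - 0.5)
    v0[0] = cfg.v_theta + 0.5
    raster, rec = simulate_avalanche_mode(
        cfg, coup, stim, v0=v0, ext_counts=np.zeros((cfg.n_steps, n), np.uint8)
    )
    assert rec.size.tolist() == [n]
    assert rec.duration.tolist() == [2]


def test_avalanche_size_and_duration_bounds():
    cfg = NetworkConfig.reduced(t_total=1500.0, j_exc=0.8, j_inh_scale=0.4)
    coup = build_coupling(1000, 0.02, 4, seed=13)
    stim = StimulusDrive(active_set=np.arange(1000))
    raster, rec = simulate_avalanche_mode(cfg, coup, stim, seed=14)
    assert np.all(rec.size <= 1000)
    assert np.all(rec.duration <= rec.size)
    assert np.all(rec.duration >= 1)
    # no neuron appears twice within one cascade (= one step)
    for t in np.unique(raster.step)[:50]:
        ids = raster.neuron[raster.step == t]
        assert np.unique(ids).size == ids.size


def test_avalanche_mode_seed_reproducibility():
    cfg = NetworkConfig.reduced(t_total=800.0)
    coup = build_coupling(1000, 0.02, 4, seed=15)
    stim = StimulusDrive(active_set=np.arange(1000))
    a = simulate_avalanche_mode(cfg, coup, stim, seed=16)
    b = simulate_avalanche_mode(cfg, coup, stim, seed=16)
    assert np.array_equal(a[0].step, b[0].step)
    assert np.array_equal(a[1].size, b[1].size)
    assert np.array_equal(a[1].duration, b[1].duration)


def test_modes_agree_deeply_subcritical():
    """With negligible coupling, cascades almost never propagate and the
    two integration modes produce statistically matching spike counts."""
    common = dict(
        n_neurons=500, n_active=500, p_connect=0.02, j_exc=0.01,
        j_inh_scale=1.0, t_total=2000.0, t_transient=0.0,
    )
    cfg = NetworkConfig(**common)
    coup = build_coupling(500, 0.02, 4, seed=17)
    stim = StimulusDrive(active_set=np.arange(500))
    full = simulate_full(cfg, coup, stim, seed=18)
    aval, _ = simulate_avalanche_mode(cfg, coup, stim, seed=19)
    assert aval.step.size == pytest.approx(full.step.size, rel=0.1)


# --------------------------------------------------------------------------- #
# raster store
# --------------------------------------------------------------------------- #
def test_raster_round_trip(tmp_path):
    cfg = NetworkConfig(n_neurons=100, n_active=50, t_total=500.0, t_transient=100.0)
    coup = build_coupling(100, 0.05, 4, seed=20)
    stim = draw_stimulus_set(100, 50, 1, seed=21)[0]
    raster = simulate_full(cfg, coup, stim, seed=22)
    write_raster(raster, tmp_path / "run", cfg)
    back = read_raster(tmp_path / "run")
    assert np.array_equal(back.step, raster.step)
    assert np.array_equal(back.neuron, raster.neuron)
    assert np.array_equal(back.ext_count, raster.ext_count)
    assert back.mode == raster.mode
    assert back.t_transient == raster.t_transient
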