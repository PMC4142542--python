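"""Experiment drivers: coupling-space sweeps and the attention contrast.

The reduced-model sweep scans the (J_exc, j_inh) plane with avalanche-mode
simulations — distinct random architectures standing in for distinct
stimuli — and produces per-point result surfaces: stimulus-averaged γ
(supercriticality), KS statistic D, discriminability index of the
segment-wise LFP spectra, the fitted exponent triple, and pattern entropy
per observation scale K.  Points where 0 < ⟨γ⟩ < 1 form the transition
region between subcritical and supercritical dynamics.

The attention contrast runs the full model at a fixed excitatory coupling
(auto-tuned to the subcritical border of the transition region) under two
inhibitory scalings — non-attended j_inh = 0.80 and attended j_inh = 0.72
— with shared architectures, stimulus sets and input realizations, and
reports leave-one-out SVM accuracy and DI per condition and per LFP
mixing constant.

All drivers are pure functions of (configuration, grid, master seed):
per-run seeds are derived deterministically from the master seed and the
run coordinates, so grid points may be evaluated in any order.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .avalanche_stats import CriticalityAnalysis, CriticalityResults, collect_avalanches
from .config import NetworkConfig
from .discriminability import SpectrumSet, discriminability_index, svm_loo_accuracy
from .entropy import draw_channel_order, entropy_by_scale
from .lfp import EDGE_MARGIN_MS, generate_lfp
from .network import (
    SpikeRaster,
    StimulusDrive,
    build_coupling,
    draw_external_input,
    draw_stimulus_set,
    init_membrane,
    simulate_avalanche_mode,
    simulate_full,
)
from .spectral import default_freqs, spectrum

__all__ = [
    "ScanGrid",
    "TransitionRegion",
    "AttentionContrast",
    "run_coupling_sweep",
    "locate_transition_region",
    "tune_operating_point",
    "tune_operating_point_reduced",
    "run_attention_contrast",
    "undriven_rate",
    "oscillation_strength",
    "gamma_band_power",
]

DEFAULT_K_LADDER = (1, 2, 5, 10, 50, 100, 250, 500, 1000)
GAMMA_BAND = (35.0, 80.0)
#: mean firing rate (Hz) of undriven neurons above which a full-model point
#: is flagged as unphysiological (persistent stimulus-nonspecific activity)
UNDRIVEN_RATE_LIMIT = 1.0


def _seed_for(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


# --------------------------------------------------------------------------- #
# reduced-model sweep
# --------------------------------------------------------------------------- #
@dataclasses.dataclass
class ScanGrid:
    """Result surfaces of a reduced-model coupling sweep.

    2-D arrays are indexed ``[i_exc, i_inh]`` over ``j_exc_values`` ×
    ``j_inh_values``.  ``entropy[k]`` maps observation scale K to its
    stimulus-averaged entropy surface; ``events[(i, j)]`` (when kept)
    holds the avalanche (sizes, durations) pooled over architectures.
    """

    j_exc_values: np.ndarray
    j_inh_values: np.ndarray
    gamma_mean: np.ndarray
    ks_mean: np.ndarray
    di: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    inv_snz: np.ndarray
    n_avalanches: np.ndarray
    entropy: dict[int, np.ndarray]
    events: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    n_arch: int
    master_seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table, one row per grid point."""
        rows = []
        for i, je in enumerate(self.j_exc_values):
            for j, ji in enumerate(self.j_inh_values):
                row = {
                    "j_exc": je,
                    "j_inh_scale": ji,
                    "gamma_mean": self.gamma_mean[i, j],
                    "ks_d": self.ks_mean[i, j],
                    "di": self.di[i, j],
                    "tau": self.tau[i, j],
                    "alpha": self.alpha[i, j],
                    "inv_snz": self.inv_snz[i, j],
                    "n_avalanches": self.n_avalanches[i, j],
                }
                for k, surf in self.entropy.items():
                    row[f"H_K{k}"] = surf[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclasses.dataclass
class TransitionRegion:
    """⟨γ⟩ surface and the mask of points with 0 < ⟨γ⟩ < 1."""

    gamma_mean: np.ndarray
    mask: np.ndarray

    @property
    def points(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in np.argwhere(self.mask)]


def _segment_bounds(
    n_steps: int, transient_steps: int, n_trials: int
) -> list[tuple[int, int]]:
    """Contiguous equal-length trial segments of the post-transient run."""
    usable = n_steps - transient_steps
    seg = usable // n_trials
    return [
        (transient_steps + k * seg, transient_steps + (k + 1) * seg)
        for k in range(n_trials)
    ]


def run_coupling_sweep(
    j_exc_values: Sequence[float],
    j_inh_values: Sequence[float],
    base_config: NetworkConfig | None = None,
    n_arch: int = 5,
    n_trials: int = 36,
    k_ladder: Iterable[int] = DEFAULT_K_LADDER,
    master_seed: int = 0,
    keep_events: bool = False,
    compute_entropy: bool = True,
    compute_di: bool = True,
) -> ScanGrid:
    """Scan the (J_exc, j_inh) plane with reduced avalanche-mode runs.

    Per point and architecture: avalanche-mode simulation, criticality fit
    (τ, α, 1/σνz, D, γ), LFP (c_mix = 0) segmented into ``n_trials``
    trials for spectra and DI, and pattern entropy for every K in
    ``k_ladder``.  Architectures (≙ stimuli) are shared across grid
    points; per-run randomness is derived from the master seed and the
    point/architecture coordinates.
    """
    if base_config is None:
        base_config = NetworkConfig.reduced()
    if base_config.n_neurons != base_config.n_active:
        raise ValueError("the reduced sweep requires N = N_active")
    j_exc_values = np.asarray(list(j_exc_values), float)
    j_inh_values = np.asarray(list(j_inh_values), float)
    if j_exc_values.size == 0 or j_inh_values.size == 0:
        raise ValueError("sweep grid must be non-empty")
    k_ladder = [int(k) for k in k_ladder]
    shape = (j_exc_values.size, j_inh_values.size)
    gamma_mean = np.full(shape, np.nan)
    ks_mean = np.full(shape, np.nan)
    di = np.full(shape, np.nan)
    tau = np.full(shape, np.nan)
    alpha = np.full(shape, np.nan)
    inv_snz = np.full(shape, np.nan)
    n_av = np.zeros(shape, dtype=np.int64)
    entropy = {k: np.full(shape, np.nan) for k in k_ladder} if compute_entropy else {}
    events: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    couplings = [
        build_coupling(
            base_config.n_neurons,
            base_config.p_connect,
            base_config.eps,
            _seed_for(master_seed, 1, a),
        )
        for a in range(n_arch)
    ]
    stimulus = StimulusDrive(active_set=np.arange(base_config.n_neurons))
    orders = [
        draw_channel_order(base_config.n_neurons, _seed_for(master_seed, 2, a))
        for a in range(n_arch)
    ]
    freqs = default_freqs()

    for i, je in enumerate(j_exc_values):
        for j, ji in enumerate(j_inh_values):
            cfg = base_config.replace(j_exc=float(je), j_inh_scale=float(ji))
            gammas, kss, taus, alphas, snzs = [], [], [], [], []
            h_acc: dict[int, list[float]] = {k: [] for k in k_ladder}
            sizes_all, durs_all = [], []
            all_spectra = []
            for a in range(n_arch):
                rng = _seed_for(master_seed, 3, i, j, a)
                raster, records = simulate_avalanche_mode(
                    cfg, couplings[a], stimulus, seed=rng
                )
                av = collect_avalanches(raster, records)
                n_av[i, j] += len(av)
                if len(av):
                    res = CriticalityAnalysis(av).fit()
                    gammas.append(res.gamma)
                    if np.isfinite(res.ks_d):
                        kss.append(res.ks_d)
                    if res.tau.valid:
                        taus.append(res.tau_)
                    if res.alpha.valid:
                        alphas.append(res.alpha_)
                    if np.isfinite(res.inv_snz):
                        snzs.append(res.inv_snz)
                    sizes_all.append(av.sizes)
                    durs_all.append(av.durations)
                else:
                    gammas.append(0)
                if compute_entropy:
                    for k, h in entropy_by_scale(raster, k_ladder, orders[a]).items():
                        h_acc[k].append(h)
                if compute_di:
                    trial_spectra = []
                    for t_id, (lo, hi) in enumerate(
                        _segment_bounds(cfg.n_steps, cfg.transient_steps, n_trials)
                    ):
                        trace = generate_lfp(raster, c_mix=0.0, step_range=(lo, hi))
                        trial_spectra.append(
                            spectrum(trace, freqs, trial_id=t_id, stimulus_id=a)
                        )
                    all_spectra.append(trial_spectra)
            gamma_mean[i, j] = float(np.mean(gammas)) if gammas else np.nan
            if kss:
                ks_mean[i, j] = float(np.mean(kss))
            if taus:
                tau[i, j] = float(np.mean(taus))
            if alphas:
                alpha[i, j] = float(np.mean(alphas))
            if snzs:
                inv_snz[i, j] = float(np.mean(snzs))
            if compute_entropy:
                for k in k_ladder:
                    entropy[k][i, j] = float(np.mean(h_acc[k]))
            if compute_di and len(all_spectra) >= 2:
                sset = SpectrumSet.from_spectra(all_spectra)
                di[i, j] = discriminability_index(sset).di
            if keep_events and sizes_all:
                events[(i, j)] = (
                    np.concatenate(sizes_all),
                    np.concatenate(durs_all),
                )
    return ScanGrid(
        j_exc_values=j_exc_values,
        j_inh_values=j_inh_values,
        gamma_mean=gamma_mean,
        ks_mean=ks_mean,
        di=di,
        tau=tau,
        alpha=alpha,
        inv_snz=inv_snz,
        n_avalanches=n_av,
        entropy=entropy,
        events=events,
        n_arch=n_arch,
        master_seed=master_seed,
    )


def locate_transition_region(scan: ScanGrid) -> TransitionRegion:
    """Points with 0 < ⟨γ⟩ < 1 (strictly) define the transition region."""
    g = scan.gamma_mean
    mask = (g > 0.0) & (g < 1.0)
    return TransitionRegion(gamma_mean=g.copy(), mask=mask)


# --------------------------------------------------------------------------- #
# operating-point tuning
# --------------------------------------------------------------------------- #
def _has_gamma_band_peak(power: np.ndarray, freqs: np.ndarray, ratio: float = 1.2) -> bool:
    """True when γ-band (35–80 Hz) power rises above the 1/f trend.

    The trend is a log–log line fitted to the frequencies outside
    [30, 100] Hz; a peak is an excess of at least ``ratio`` over the trend
    at some γ-band frequency.
    """
    ok = np.isfinite(power) & (power > 0)
    f, p = freqs[ok], power[ok]
    bg = (f < 30.0) | (f > 100.0)
    if bg.sum() < 2:
        return False
    coef = np.polyfit(np.log(f[bg]), np.log(p[bg]), 1)
    trend = np.exp(np.polyval(coef, np.log(f)))
    band = (f >= GAMMA_BAND[0]) & (f <= GAMMA_BAND[1])
    return bool(band.any() and np.max(p[band] / trend[band]) >= ratio)


def tune_operating_point(
    j_exc_grid: Sequence[float],
    j_inh_scales: Sequence[float] = (0.80,),
    base_config: NetworkConfig | None = None,
    n_probe: int = 2,
    master_seed: int = 0,
    rate_limit: float = UNDRIVEN_RATE_LIMIT,
) -> float:
    """Operating point of the full model: the subcritical border of its own
    excitability transition.

    Scans the grid of excitatory couplings upward with probe runs (one
    stimulus, ``n_probe`` architectures, the non-attended inhibitory
    scaling) and returns the largest J_exc at which the
    stimulus-nonspecific (undriven) neurons stay quiescent — mean rate at
    most ``rate_limit`` Hz.  Beyond this coupling, recurrent excitation
    recruits the undriven population, the regime the sweep analyses flag
    as unphysiological; at the returned point the network sits just below
    that synchrony-driven breakdown, which is where the γ-band spectral
    peak first emerges.  Probe architectures and stimuli are drawn from
    the same seed path as :func:`run_attention_contrast`, so the tuned
    point belongs to the networks it will be used with.
    """
    if base_config is None:
        base_config = NetworkConfig()
    j_exc_grid = np.sort(np.asarray(list(j_exc_grid), float))
    couplings = [
        build_coupling(
            base_config.n_neurons,
            base_config.p_connect,
            base_config.eps,
            _seed_for(master_seed, 21, a),
        )
        for a in range(n_probe)
    ]
    stimuli = [
        draw_stimulus_set(
            base_config.n_neurons,
            base_config.n_active,
            1,
            _seed_for(master_seed, 22, a),
        )[0]
        for a in range(n_probe)
    ]
    last_ok = None
    for je in j_exc_grid:
        worst = 0.0
        for ji in j_inh_scales:
            cfg = base_config.replace(j_exc=float(je), j_inh_scale=float(ji))
            for a in range(n_probe):
                raster = simulate_full(
                    cfg, couplings[a], stimuli[a], seed=_seed_for(master_seed, 17, a)
                )
                worst = max(worst, undriven_rate(raster, stimuli[a]))
        if worst <= rate_limit:
            last_ok = float(je)
        else:
            break
    if last_ok is None:
        raise RuntimeError(
            "undriven neurons are active even at the smallest grid coupling"
        )
    return last_ok


def tune_operating_point_reduced(
    j_exc_grid: Sequence[float],
    j_inh_scale: float = 0.80,
    base_config: NetworkConfig | None = None,
    n_arch: int = 3,
    master_seed: int = 0,
    verify_peak: bool = True,
) -> float:
    """Smallest grid J_exc whose reduced-model ⟨γ⟩ first exceeds 0 at the
    given inhibitory scaling (the subcritical border of the reduced
    model's transition region), optionally verified to show a γ-band
    spectral peak.

    Note: the reduced (avalanche-mode) model is protected by cascade
    refractoriness and therefore tolerates far stronger excitation than
    the full model; its γ border generally lies deep inside the full
    model's unphysiological regime.  Use :func:`tune_operating_point` to
    place the full model's operating point.
    """
    if base_config is None:
        base_config = NetworkConfig.reduced()
    j_exc_grid = np.sort(np.asarray(list(j_exc_grid), float))
    stimulus = StimulusDrive(active_set=np.arange(base_config.n_neurons))
    couplings = [
        build_coupling(
            base_config.n_neurons,
            base_config.p_connect,
            base_config.eps,
            _seed_for(master_seed, 11, a),
        )
        for a in range(n_arch)
    ]
    freqs = default_freqs()
    candidate = None
    for je in j_exc_grid:
        cfg = base_config.replace(j_exc=float(je), j_inh_scale=float(j_inh_scale))
        gammas = []
        rasters = []
        for a in range(n_arch):
            rng = _seed_for(master_seed, 12, a)
            raster, records = simulate_avalanche_mode(
                cfg, couplings[a], stimulus, seed=rng
            )
            av = collect_avalanches(raster, records)
            if len(av):
                gammas.append(CriticalityAnalysis(av).fit().gamma)
            else:
                gammas.append(0)
            rasters.append(raster)
        if np.mean(gammas) > 0:
            if candidate is None:
                candidate = float(je)
            if not verify_peak:
                return float(je)
            sp = spectrum(generate_lfp(rasters[0], c_mix=0.0), freqs)
            if _has_gamma_band_peak(sp.power, sp.freqs):
                return float(je)
    if candidate is not None:
        return candidate
    raise RuntimeError(
        "no grid point reached the transition region; extend the J_exc grid"
    )


# --------------------------------------------------------------------------- #
# full-model attention contrast
# --------------------------------------------------------------------------- #
def undriven_rate(raster: SpikeRaster, stimulus: StimulusDrive) -> float:
    """Mean post-transient firing rate (Hz) of the undriven neurons."""
    n_undriven = raster.n_neurons - stimulus.active_set.size
    if n_undriven == 0:
        return 0.0
    post = raster.post_transient()
    undriven = np.setdiff1d(np.arange(raster.n_neurons), stimulus.active_set)
    n_spikes = np.isin(post.neuron, undriven).sum()
    return float(n_spikes / n_undriven / (post.t_total * 1e-3))


def oscillation_strength(raster: SpikeRaster, max_lag_ms: float = 50.0) -> float:
    """Oscillatory content of the population spike count: the largest
    positive peak of the autocorrelation of the per-step population count
    at lags between 3 ms and ``max_lag_ms``."""
    post = raster.post_transient()
    c = post.counts_per_step().astype(float)
    c -= c.mean()
    denom = float((c * c).sum())
    if denom == 0:
        return 0.0
    lags = np.arange(int(3.0 / post.dt), int(max_lag_ms / post.dt) + 1)
    ac = np.array([(c[: c.size - lag] * c[lag:]).sum() / denom for lag in lags])
    return float(max(ac.max(), 0.0))


def gamma_band_power(power: np.ndarray, freqs: np.ndarray) -> float:
    band = (freqs >= GAMMA_BAND[0]) & (freqs <= GAMMA_BAND[1])
    return float(np.nanmean(power[band]))


@dataclasses.dataclass
class AttentionContrast:
    """Per-condition decoding results of the full-model attention contrast.

    ``accuracy``/``di`` map (condition, c_mix) → value, condition ∈
    {"non_attended", "attended"}; accuracies are fractions in [0, 1],
    averaged over coupling-matrix realizations.
    """

    j_exc: float
    j_inh_scales: dict[str, float]
    c_mix_values: tuple[float, ...]
    accuracy: dict[tuple[str, float], float]
    di: dict[tuple[str, float], float]
    gamma_band: dict[str, float]
    undriven_rates: dict[str, float]
    excluded: bool
    n_arch: int
    n_trials: int
    n_stimuli: int
    master_seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["accuracy"] = {f"{k[0]}@cmix={k[1]}": v for k, v in self.accuracy.items()}
        d["di"] = {f"{k[0]}@cmix={k[1]}": v for k, v in self.di.items()}
        return json.dumps(d, indent=1, default=float)


def run_attention_contrast(
    j_exc: float,
    j_inh_nonattended: float = 0.80,
    j_inh_attended: float = 0.72,
    base_config: NetworkConfig | None = None,
    n_arch: int = 5,
    n_stimuli: int = 6,
    n_trials: int = 20,
    c_mix_values: Sequence[float] = (0.2, 0.0),
    master_seed: int = 0,
) -> AttentionContrast:
    """Full-model attention contrast at a fixed excitatory coupling.

    Both conditions share architectures, stimulus sets, initial states and
    external-input realizations; only the inhibitory scaling differs.
    Returns leave-one-out SVM accuracy and DI per condition and mixing
    constant, stimulus-averaged γ-band power per condition, and the
    undriven-neuron rate check used to flag unphysiological points.
    """
    if base_config is None:
        base_config = NetworkConfig()
    conditions = {
        "non_attended": float(j_inh_nonattended),
        "attended": float(j_inh_attended),
    }
    c_mix_values = tuple(float(c) for c in c_mix_values)
    freqs = default_freqs()
    n_f = freqs.size
    power = {
        (cond, cm): np.zeros((n_arch, n_stimuli, n_trials, n_f))
        for cond in conditions
        for cm in c_mix_values
    }
    valid = {
        (cond, cm): np.ones((n_arch, n_stimuli, n_trials, n_f), bool)
        for cond in conditions
        for cm in c_mix_values
    }
    rate_acc = {cond: [] for cond in conditions}
    for a in range(n_arch):
        coupling = build_coupling(
            base_config.n_neurons,
            base_config.p_connect,
            base_config.eps,
            _seed_for(master_seed, 21, a),
        )
        stimuli = draw_stimulus_set(
            base_config.n_neurons,
            base_config.n_active,
            n_stimuli,
            _seed_for(master_seed, 22, a),
        )
        for s, stim in enumerate(stimuli):
            for tr in range(n_trials):
                rng = _seed_for(master_seed, 23, a, s, tr)
                v0 = init_membrane(base_config, rng)
                ext = draw_external_input(base_config, stim.active_set.size, rng)
                for cond, ji in conditions.items():
                    cfg = base_config.replace(
                        j_exc=float(j_exc), j_inh_scale=ji
                    )
                    raster = simulate_full(
                        cfg, coupling, stim, v0=v0, ext_counts=ext
                    )
                    if tr == 0:
                        rate_acc[cond].append(undriven_rate(raster, stim))
                    for cm in c_mix_values:
                        sp = spectrum(
                            generate_lfp(raster, c_mix=cm),
                            freqs,
                            trial_id=tr,
                            stimulus_id=s,
                        )
                        power[(cond, cm)][a, s, tr] = sp.power
                        valid[(cond, cm)][a, s, tr] = sp.valid
    accuracy: dict[tuple[str, float], float] = {}
    di: dict[tuple[str, float], float] = {}
    gamma_band: dict[str, float] = {}
    for cond in conditions:
        for cm in c_mix_values:
            accs, dis = [], []
            for a in range(n_arch):
                sset = SpectrumSet(
                    power=power[(cond, cm)][a],
                    freqs=freqs,
                    valid=valid[(cond, cm)][a].all(axis=(0, 1)),
                )
                accs.append(
                    svm_loo_accuracy(sset, seed=int(master_seed % 2**31) + a)
                )
                dis.append(discriminability_index(sset).di)
            accuracy[(cond, cm)] = float(np.mean(accs))
            di[(cond, cm)] = float(np.mean(dis))
        cm0 = c_mix_values[0]
        gamma_band[cond] = float(
            np.mean(
                [
                    gamma_band_power(p, freqs)
                    for p in power[(cond, cm0)].reshape(-1, n_f)
                ]
            )
        )
    rates = {cond: float(np.mean(v)) for cond, v in rate_acc.items()}
    return AttentionContrast(
        j_exc=float(j_exc),
        j_inh_scales=conditions,
        c_mix_values=c_mix_values,
        accuracy=accuracy,
        di=di,
        gamma_band=gamma_band,
        undriven_rates=rates,
        excluded=any(r > UNDRIVEN_RATE_LIMIT for r in rates.values()),
        n_arch=n_arch,
        n_trials=n_trials,
        n_stimuli=n_stimuli,
        master_seed=master_seed,
    )
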