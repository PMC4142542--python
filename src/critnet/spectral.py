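"""Time–frequency analysis of LFP traces with complex Morlet wavelets.

Power is the squared modulus of the continuous wavelet transform,
p(t, f) = |∫ ψ(τ_w, f) U(t - τ_w) dτ_w|², evaluated at ``N_F`` (default
20) logarithmically spaced frequencies between 5 and 200 Hz.  The mother
wavelet is the standard Morlet with center frequency ω₀ = 6 rad
(admissible, and the common choice in the time–frequency literature);
per-frequency samples inside the cone of influence — within one e-folding
time √2·s of either trace edge, with s the Morlet scale — are excluded
before time averaging.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pywt

from .lfp import LFPTrace

__all__ = [
    "PowerSpectrum",
    "default_freqs",
    "morlet_power",
    "coi_mask",
    "time_average_outside_coi",
    "spectrum",
]

#: Morlet center frequency, rad (nondimensional)
OMEGA0 = 6.0
#: pywt continuous-wavelet name implementing pi^-1/4 exp(i w0 t) exp(-t^2/2):
#: bandwidth B = 2 and center frequency C = w0 / (2 pi) cycles.
_WAVELET = f"cmor2.0-{OMEGA0 / (2 * np.pi):.16f}"
#: Fourier factor: wavelength / scale for the Morlet wavelet
FOURIER_FACTOR = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))

N_F = 20
F_MIN = 5.0
F_MAX = 200.0


def default_freqs(n_f: int = N_F, f_min: float = F_MIN, f_max: float = F_MAX) -> np.ndarray:
    """Logarithmically spaced analysis frequencies, Hz."""
    return np.geomspace(f_min, f_max, n_f)


@dataclasses.dataclass
class PowerSpectrum:
    """Time-averaged wavelet power per frequency for one trial.

    ``valid[k]`` is False when every sample of frequency ``freqs[k]`` lay
    inside the cone of influence (power[k] is then NaN).
    """

    freqs: np.ndarray
    power: np.ndarray
    valid: np.ndarray
    trial_id: int = 0
    stimulus_id: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        ok = self.power[self.valid]
        if ok.size and (np.any(~np.isfinite(ok)) or np.any(ok < 0)):
            raise ValueError("valid power values must be finite and non-negative")


def morlet_power(lfp: LFPTrace, freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved wavelet power.

    Returns
    -------
    power : (n_f, n_t) array, |CWT|²
    valid : (n_f, n_t) boolean mask of samples outside the cone of influence
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    dt_s = lfp.dt * 1e-3
    center = pywt.central_frequency(_WAVELET)
    scales = center / (freqs * dt_s)
    coef, _ = pywt.cwt(lfp.u, scales, _WAVELET, sampling_period=dt_s, method="fft")
    power = np.abs(coef) ** 2
    valid = coi_mask(lfp.u.size, dt_s, freqs)
    if not valid.any(axis=1).all():
        # at least one sample must escape the cone somewhere; individual
        # all-masked frequencies are flagged, fully masked input is an error
        if not valid.any():
            raise ValueError("trace too short: every sample lies inside the cone of influence")
    return power, valid


def coi_mask(n_samples: int, dt_s: float, freqs: np.ndarray) -> np.ndarray:
    """Boolean (n_f, n_t) mask, True outside the cone of influence.

    The cone is the e-folding time of the wavelet's power envelope,
    √2 · s seconds from each edge at Morlet scale s = FOURIER_FACTOR⁻¹/f.
    """
    t_edge = np.arange(n_samples) * dt_s
    coi_time = np.sqrt(2.0) / (np.asarray(freqs) * FOURIER_FACTOR)
    dist = np.minimum(t_edge, t_edge[::-1])
    return dist[None, :] >= coi_time[:, None]


def time_average_outside_coi(
    power: np.ndarray,
    valid: np.ndarray,
    freqs: np.ndarray,
    trial_id: int = 0,
    stimulus_id: int = 0,
) -> PowerSpectrum:
    """Mean power over the retained (outside-cone) samples per frequency."""
    n_valid = valid.sum(axis=1)
    avg = np.full(power.shape[0], np.nan)
    ok = n_valid > 0
    for k in np.nonzero(ok)[0]:
        avg[k] = power[k, valid[k]].mean()
    return PowerSpectrum(
        freqs=np.asarray(freqs, float),
        power=avg,
        valid=ok,
        trial_id=trial_id,
        stimulus_id=stimulus_id,
    )


def spectrum(
    lfp: LFPTrace,
    freqs: np.ndarray | None = None,
    trial_id: int = 0,
    stimulus_id: int = 0,
) -> PowerSpectrum:
    """Convenience wrapper: time-averaged Morlet spectrum of one trace."""
    if freqs is None:
        freqs = default_freqs()
    power, valid = morlet_power(lfp, freqs)
    return time_average_outside_coi(power, valid, freqs, trial_id, stimulus_id)
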