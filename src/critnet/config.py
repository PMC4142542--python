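"""Network configuration.

All times are in milliseconds, potentials in millivolts, and the external
Poisson rate in kHz (spikes per ms), so that ``f_max * dt`` is the expected
number of external spikes a driven neuron receives per integration step.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Any, Mapping

import yaml

__all__ = ["NetworkConfig"]


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the recurrent E/I integrate-and-fire network.

    Parameters
    ----------
    n_neurons
        Total number of neurons N (2500 in the full model, 1000 in the
        reduced, avalanche-mode model).
    n_active
        Number of externally driven neurons per stimulus (1000).
    p_connect
        Erdös–Rényi connection probability for each ordered neuron pair.
    eps
        Ratio of excitatory to inhibitory neuron counts, ε = N_exc / N_inh.
    v_rest, v_theta
        Resting/reset potential and firing threshold, mV.
    tau_mem
        Membrane time constant, ms.
    j_ext
        Depolarization per external (feedforward) spike, mV.
    j_exc
        Depolarization per recurrent excitatory spike, mV (swept parameter).
    j_inh_scale
        Dimensionless inhibitory scaling factor j_inh.  The inhibitory
        coupling is always derived as ``J_inh = eps * j_exc * j_inh_scale``
        and never stored independently.
    f_max
        External Poisson rate per driven neuron, kHz.
    dt
        Euler integration step, ms.
    t_total, t_transient
        Simulated duration and discarded initial transient, ms.
    seed
        Base RNG seed for the simulation.
    """

    n_neurons: int = 2500
    n_active: int = 1000
    p_connect: float = 0.02
    eps: int = 4
    v_rest: float = -60.0
    v_theta: float = -50.0
    tau_mem: float = 10.0
    j_ext: float = 0.1
    j_exc: float = 0.2
    j_inh_scale: float = 0.8
    f_max: float = 10.0
    dt: float = 0.1
    t_total: float = 2500.0
    t_transient: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.v_rest < self.v_theta:
            raise ValueError("v_rest must lie below v_theta")
        if self.tau_mem <= 0 or self.dt <= 0 or self.t_total <= 0:
            raise ValueError("time constants and durations must be positive")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must lie in [0, 1]")
        if self.n_active > self.n_neurons:
            raise ValueError("n_active cannot exceed n_neurons")
        if self.n_neurons % (1 + self.eps) != 0:
            raise ValueError(
                f"n_neurons={self.n_neurons} must be divisible by 1+eps={1 + self.eps} "
                "so the excitatory/inhibitory split is exact"
            )
        if self.t_transient >= self.t_total:
            raise ValueError("t_transient must be shorter than t_total")

    # ------------------------------------------------------------------ #
    @property
    def j_inh(self) -> float:
        """Inhibitory coupling strength J_inh = eps * J_exc * j_inh (mV)."""
        return self.eps * self.j_exc * self.j_inh_scale

    @property
    def n_exc(self) -> int:
        return self.n_neurons * self.eps // (1 + self.eps)

    @property
    def n_inh(self) -> int:
        return self.n_neurons // (1 + self.eps)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def transient_steps(self) -> int:
        return int(round(self.t_transient / self.dt))

    @property
    def leak(self) -> float:
        """Euler leak factor dt / tau_mem (dimensionless)."""
        return self.dt / self.tau_mem

    # ------------------------------------------------------------------ #
    @classmethod
    def reduced(cls, **overrides: Any) -> "NetworkConfig":
        """Reduced, avalanche-mode configuration: every neuron is driven
        (N = N_active = 1000) and the run is extended to 12 s."""
        defaults: dict[str, Any] = dict(
            n_neurons=1000, n_active=1000, t_total=12_000.0
        )
        defaults.update(overrides)
        return cls(**defaults)

    def replace(self, **overrides: Any) -> "NetworkConfig":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(d))

    # declarative config file: flat YAML mapping, one key per field ------ #
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "NetworkConfig":
        """Load a config file; keyword arguments override file values
        (this is the hook the CLI uses for per-flag overrides)."""
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update(overrides)
        return cls.from_dict(d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
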