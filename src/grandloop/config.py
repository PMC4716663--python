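"""Model configuration.

All tunable constants of the simulator live in small frozen-by-convention
dataclasses, one per component network, plus a :class:`LoopConfig` for the
sizes and schedule of the full closed-loop model.  Defaults are the published
operating point of the model; a YAML file with the same key names can
override any subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Any

import yaml

__all__ = [
    "Layer5Config",
    "InfomaxConfig",
    "StriatumConfig",
    "DopamineConfig",
    "LoopConfig",
    "ModelConfig",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value is structurally invalid."""


@dataclass
class Layer5Config:
    """Self-organizing recurrent network of binary units (cortical layer 5).

    ``eta_iSTDP`` is the postsynaptic gating factor of the inhibitory STDP
    rule, equal to 1 + 1/mu_IP at the default homeostatic target.
    """

    N_E: int = 400
    N_I: int = 80
    N_A: int = 4
    eta_IP: float = 0.01
    TEmax: float = 1.0
    TImax: float = 0.5
    mu_IP: float = 0.1
    sigma_HIP: float = 0.0
    eta_inhib: float = 0.001
    eta_iSTDP: float = 11.0
    sigma_xi_sq: float = 0.01
    eta_STDP: float = 0.004
    # initial excitatory->excitatory connection density
    p_EE_init: float = 0.1
    # structural plasticity: per-step probability of one new candidate
    # excitatory connection (development only) and its initial weight
    p_struct: float = 0.1
    w_struct: float = 0.001
    # weights at or below freeze_tol * row-target are clamped to zero after
    # development, for the remainder of every simulation
    freeze_tol: float = 1e-6
    develop_steps: int = 200_000

    def validate(self) -> None:
        if self.N_E <= 0 or self.N_I <= 0 or self.N_A <= 0:
            raise ConfigurationError("layer-5 population sizes must be positive")
        if self.N_E % self.N_A != 0:
            raise ConfigurationError("N_E must divide evenly into N_A areas")
        for name in ("eta_IP", "TEmax", "TImax", "mu_IP", "eta_inhib",
                     "eta_STDP", "sigma_xi_sq", "p_EE_init", "p_struct"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 < self.mu_IP < 1.0:
            raise ConfigurationError("mu_IP must lie in (0, 1)")


@dataclass
class InfomaxConfig:
    """Three-stage entropy-maximizing network (cortical layer 2/3)."""

    beta_x0: float = 0.00002
    beta_w0: float = 0.0007
    beta_C: float = 0.0007
    beta_Q: float = 0.0007
    # anti-redundancy term: "direct" uses (C^T)^-1, "lateral" the recurrent
    # network estimate alpha * v_inf x_I^T
    antiredundancy_mode: str = "direct"
    # include the Hebbian (1-2y) x_I^T term of the full learning rule
    hebbian_term: bool = True
    # alpha is re-set to 1/lambda_max(Q_hat) every alpha_update_every steps
    alpha_update_every: int = 1000
    # in direct mode, (C^T)^-1 is recomputed every this many steps; C moves
    # by O(beta_C) per step so the cached inverse stays accurate between
    # refreshes (set to 1 for an exact per-step inverse)
    inverse_refresh: int = 10
    lateral_tol: float = 1e-10
    lateral_max_iter: int = 500
    cond_limit: float = 1e12
    c_init_jitter: float = 0.01

    def validate(self) -> None:
        if self.antiredundancy_mode not in ("direct", "lateral"):
            raise ConfigurationError(
                "antiredundancy_mode must be 'direct' or 'lateral'")
        for name in ("beta_x0", "beta_w0", "beta_C", "beta_Q"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class StriatumConfig:
    """Winnerless-competition FitzHugh-Nagumo network of MSNs.

    The model equations are dimensionless; one 1-ms simulator step advances
    model time by ``h`` (calibrated once so that the mean burst-potential
    positive transient lasts ~350 ms, then frozen).  ``I_bias`` is the
    constant depolarizing drive that puts each uncoupled unit on its limit
    cycle.
    """

    N_Str: int = 100
    g_max: float = 0.25
    g_min: float = 0.0
    a: float = 0.7
    b: float = 0.8
    tau_1: float = 0.08
    tau_2: float = 4.1
    nu: float = -1.5
    x_0: float = -1.2
    y_0: float = -1.62
    z_0: float = 0.0
    I_bias: float = 0.35
    # lateral inhibitory connectivity: directed Erdos-Renyi density plus a
    # boost for D1->D2 links (direct-pathway MSNs inhibit indirect-pathway)
    p_lateral: float = 0.15
    p_lateral_d1_to_d2: float = 0.30
    # model-time advanced per 1-ms step; calibrated against the ~350 ms
    # burst duration and then frozen (see docs/methods.md)
    h: float = 0.003
    n_substeps: int = 10
    # corticostriatal synapse table
    N_Cx_Str: int = 20
    w_cap: float = 0.1
    eta_CStr: float = 0.002
    p_synaptogenesis: float = 0.2
    gaba_threshold: float = 0.00707

    def validate(self) -> None:
        if self.N_Str <= 0 or self.N_Str % 2 != 0:
            raise ConfigurationError("N_Str must be a positive even number")
        if not 0.0 <= self.g_min <= self.g_max:
            raise ConfigurationError("need 0 <= g_min <= g_max")
        if self.tau_1 <= 0 or self.tau_2 <= 0 or self.h <= 0:
            raise ConfigurationError("time constants and h must be positive")
        if self.N_Cx_Str <= 0 or self.w_cap <= 0:
            raise ConfigurationError("corticostriatal table sizes invalid")


@dataclass
class DopamineConfig:
    """Adaptive-threshold integrate-and-fire neurons with two spike-induced
    currents (rebound-burst dopamine cells).  SI units: volts, seconds."""

    N_DA: int = 20
    N_Str_DA: int = 20
    b: float = 1.0
    G_over_C: float = 50.0
    k_1: float = 200.0
    k_2: float = 20.0
    Theta_inf: float = -0.05
    R_1: float = 0.0
    R_2: float = 1.0
    E_L: float = -0.07
    V_R: float = -0.07
    Theta_r: float = -0.06
    a: float = 1.0
    A_1: float = 5.0
    A_2: float = -0.3
    # MSN burst output -> DA neuron input weight
    w_str_da: float = -2.25
    dt: float = 0.001

    def validate(self) -> None:
        if self.N_DA <= 0 or self.N_Str_DA <= 0:
            raise ConfigurationError("dopamine population sizes must be positive")
        if self.k_1 < 0 or self.k_2 < 0 or self.G_over_C <= 0:
            raise ConfigurationError("rate constants must be positive")


@dataclass
class LoopConfig:
    """Full-model wiring and schedule."""

    N_Frontal: int = 2
    N_Str_Th: int = 11
    tau_X: int = 100          # ms, spiking->rate integration window
    tau_DA: int = 100         # ms, dopamine modulation window
    Ach: float = 0.5
    # schedule (steps of 1 ms)
    develop_steps: int = 200_000
    bias_steps: int = 50_000
    total_steps: int = 500_000
    # area names in feedback (traversal) ring order: activity propagates
    # M1 -> M_sup -> S_sec -> S1 -> M1; feed-forward relays run the reverse
    area_names: tuple = ("M1", "M_sup", "S_sec", "S1")
    gated_areas: tuple = ("M_sup", "M1")

    def validate(self) -> None:
        if not 0.0 <= self.Ach <= 1.0:
            raise ConfigurationError("Ach must lie in [0, 1]")
        if self.tau_X <= 0 or self.tau_DA <= 0:
            raise ConfigurationError("windows must be positive")
        if self.N_Str_Th <= 0:
            raise ConfigurationError("N_Str_Th must be positive")


@dataclass
class ModelConfig:
    layer5: Layer5Config = field(default_factory=Layer5Config)
    infomax: InfomaxConfig = field(default_factory=InfomaxConfig)
    striatum: StriatumConfig = field(default_factory=StriatumConfig)
    dopamine: DopamineConfig = field(default_factory=DopamineConfig)
    loop: LoopConfig = field(default_factory=LoopConfig)

    def validate(self) -> None:
        for sub in (self.layer5, self.infomax, self.striatum,
                    self.dopamine, self.loop):
            sub.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        kwargs = {}
        for f in fields(cls):
            sub_cls = {
                "layer5": Layer5Config, "infomax": InfomaxConfig,
                "striatum": StriatumConfig, "dopamine": DopamineConfig,
                "loop": LoopConfig,
            }[f.name]
            sub = d.get(f.name, {})
            known = {x.name for x in fields(sub_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown {f.name} keys: {sorted(unknown)}")
            if "area_names" in sub:
                sub = dict(sub, area_names=tuple(sub["area_names"]))
            if "gated_areas" in sub:
                sub = dict(sub, gated_areas=tuple(sub["gated_areas"]))
            kwargs[f.name] = sub_cls(**sub)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        d = self.to_dict()
        d["loop"]["area_names"] = list(d["loop"]["area_names"])
        d["loop"]["gated_areas"] = list(d["loop"]["gated_areas"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
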