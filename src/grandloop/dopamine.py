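"""Dopamine neurons: adaptive-threshold integrate-and-fire with two
spike-induced currents (a rebound-burst operating point).

Each of the N_DA neurons integrates, in SI units (volts, seconds) at
dt = 1 ms::

    dI_j/dt   = -k_j I_j                      (j = 1, 2)
    dV/dt     = (I_e + I_1 + I_2) - (G/C) (V - E_L)
    dTheta/dt = a (V - E_L) - b (Theta - Theta_inf)

A spike occurs on V > Theta (strict) and resets instantaneously::

    I_j <- R_j I_j + A_j,   V <- V_R,   Theta <- max(Theta_r, Theta)

The voltage dependence of Theta lets deep or prolonged hyperpolarization
drag the threshold below its resting value, so that release from striatal
inhibition produces a rebound burst; the accumulating hyperpolarizing
current I_2 (R_2 = 1, A_2 < 0) terminates the burst intrinsically after
four spikes.

Dopamine spikes stamp a "dopamine present" window of length tau_DA onto
the corticostriatal synapses assigned to the spiking neuron; overlapping
stamps extend the window rather than stack.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .config import DopamineConfig
from .striatum import CorticostriatalTable

__all__ = [
    "DopamineState",
    "init_dopamine",
    "step_dopamine",
    "stamp_dopamine",
    "striatal_input",
]


@dataclass
class DopamineState:
    V: np.ndarray
    Theta: np.ndarray
    I1: np.ndarray
    I2: np.ndarray
    msn_to_da: np.ndarray      # (N_DA, N_Str_DA) assigned MSN ids
    config: DopamineConfig

    @property
    def n(self) -> int:
        return self.V.size

    def copy(self) -> "DopamineState":
        return copy.deepcopy(self)


def init_dopamine(config: DopamineConfig, seed: int,
                  n_msn: int | None = None) -> DopamineState:
    """All neurons start at rest (V = E_L, Theta = Theta_inf, currents
    zero); each neuron is assigned N_Str_DA distinct presynaptic MSNs."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.N_DA
    if n_msn is None:
        n_msn = config.N_Str_DA
    k = min(config.N_Str_DA, n_msn)
    msn_to_da = np.stack([rng.choice(n_msn, size=k, replace=False)
                          for _ in range(n)])
    return DopamineState(
        V=np.full(n, config.E_L),
        Theta=np.full(n, config.Theta_inf),
        I1=np.zeros(n),
        I2=np.zeros(n),
        msn_to_da=msn_to_da,
        config=config,
    )


def striatal_input(state: DopamineState, P: np.ndarray) -> np.ndarray:
    """Summed burst outputs of each neuron's assigned MSNs, times the
    constant inhibitory weight."""
    return state.config.w_str_da * P[state.msn_to_da].sum(axis=1)


def _propagators(cfg: DopamineConfig) -> dict:
    """Closed-form step coefficients.  Between spikes the model is linear,
    so each dt step can be propagated exactly; this keeps the 1-ms step
    faithful to the continuous dynamics (forward Euler at 1 ms distorts the
    tightly-spaced spikes inside a rebound burst)."""
    dt, g, b = cfg.dt, cfg.G_over_C, cfg.b
    e_g, e_b = np.exp(-g * dt), np.exp(-b * dt)
    e_1, e_2 = np.exp(-cfg.k_1 * dt), np.exp(-cfg.k_2 * dt)

    def xfer(k, e_k):  # integral of e^{-k s} against leak/threshold kernels
        return (e_k - e_g) / (g - k)

    return {
        "e_g": e_g, "e_b": e_b, "e_1": e_1, "e_2": e_2,
        "gain_e": (1.0 - e_g) / g,              # constant input -> V
        "x1": xfer(cfg.k_1, e_1),               # I1 -> V
        "x2": xfer(cfg.k_2, e_2),               # I2 -> V
        # V components -> Theta (a * integral against e^{-b (dt-s)})
        "t_c": (1.0 - e_b) / b,
        "t_g": (e_g - e_b) / (b - g),
        "t_1": (e_1 - e_b) / (b - cfg.k_1),
        "t_2": (e_2 - e_b) / (b - cfg.k_2),
    }


def step_dopamine(state: DopamineState, I_e: np.ndarray | float = 0.0,
                  ) -> tuple[DopamineState, np.ndarray]:
    """Advance one dt step (exact linear propagation) and apply spike
    resets on V > Theta (strict)."""
    cfg = state.config
    if not hasattr(state, "_prop"):
        state._prop = _propagators(cfg)
    p = state._prop
    I_e = np.broadcast_to(np.asarray(I_e, dtype=float), state.V.shape)

    V, Th, I1, I2 = state.V, state.Theta, state.I1, state.I2
    g = cfg.G_over_C
    c1 = I1 / (g - cfg.k_1)
    c2 = I2 / (g - cfg.k_2)
    const = I_e / g                      # steady-state offset of V - E_L
    bmode = (V - cfg.E_L) - const - c1 - c2   # pure-leak component

    dV0 = V - cfg.E_L
    V_new = cfg.E_L + dV0 * p["e_g"] + I_e * p["gain_e"] \
        + I1 * p["x1"] + I2 * p["x2"]
    Th_new = cfg.Theta_inf + (Th - cfg.Theta_inf) * p["e_b"] + cfg.a * (
        const * p["t_c"] + bmode * p["t_g"] + c1 * p["t_1"] + c2 * p["t_2"])
    I1_new = I1 * p["e_1"]
    I2_new = I2 * p["e_2"]

    if not np.all(np.isfinite(V_new)):
        raise FloatingPointError("dopamine membrane potential is non-finite")

    spikes = (V_new > Th_new).astype(np.int8)
    fired = spikes.astype(bool)
    if fired.any():
        I1_new[fired] = cfg.R_1 * I1_new[fired] + cfg.A_1
        I2_new[fired] = cfg.R_2 * I2_new[fired] + cfg.A_2
        V_new[fired] = cfg.V_R
        Th_new[fired] = np.maximum(cfg.Theta_r, Th_new[fired])

    state.V, state.Theta, state.I1, state.I2 = V_new, Th_new, I1_new, I2_new
    return state, spikes


def stamp_dopamine(table: CorticostriatalTable, da_spikes: np.ndarray,
                   now: float, tau_DA: float) -> CorticostriatalTable:
    """Set dopamine-present on every synapse assigned to a spiking neuron
    until ``now + tau_DA``; overlapping stamps extend, never stack."""
    fired = np.flatnonzero(da_spikes)
    if fired.size:
        hit = np.isin(table.da_neuron, fired)
        table.da_expiry[hit] = np.maximum(table.da_expiry[hit], now + tau_DA)
    return table
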