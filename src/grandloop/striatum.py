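"""Striatum: winnerless-competition FitzHugh-Nagumo network of MSNs and the
dopamine/GABA-modulated corticostriatal synapse table.

Each medium spiny neuron (MSN) carries three dimensionless variables: the
burst potential ``x_f`` (a positive transient = one ~350 ms burst), the
recovery variable ``y_f``, and the inhibitory synaptic current ``z_f``
relaxing toward the Heaviside-rectified activity of the other MSNs through
the asymmetric lateral weights ``W_Str``::

    tau_1 dx/dt = x - x^3/3 - y - z (x - nu) + I_bias + I_cortex
          dy/dt = x - b y + a
    tau_2 dz/dt = sum_j W_Str[i,j] H(x_j) - z

The equations are dimensionless; one 1-ms simulator step advances model
time by ``h`` (explicit Euler in ``n_substeps`` sub-steps).  Weak asymmetric
inhibition makes the active set rotate ("winnerless competition" /
turn-taking) instead of settling on a winner.

Corticostriatal synapses undergo spike-timing-dependent plasticity gated by
the sign of the burst-output derivative (pre-post pairing: cortical spike
while P' > 0; post-pre: spike while P' < 0), with the effective direction
set by three modulatory conditions: MSN type (D1/D2), dopamine presence at
the synapse, and GABA level (``z_f`` above threshold flips the sign of
every active rule).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, StriatumConfig

__all__ = [
    "StriatalState",
    "CorticostriatalTable",
    "ModulationTable",
    "IntegrationError",
    "init_striatum",
    "build_corticostriatal",
    "step_striatum",
    "burst_output",
    "corticostriatal_stdp",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class ModulationTable:
    """Effect of each (MSN type x dopamine) condition on the two pairings.

    ``pp[d1, da]`` / ``pn[d1, da]`` give the signed gate (+1 potentiate,
    -1 depress, 0 off) for pre-post / post-pre pairings, indexed by
    d1-in-{0,1} and dopamine-present-in-{0,1}.  High GABA flips the sign of
    every active entry (STDP reversal in both pathways).
    """

    pp: np.ndarray = field(default_factory=lambda: np.array(
        [[+1.0, -1.0],   # D2: no-DA -> LTP, DA -> LTD
         [0.0, +1.0]]))  # D1: no-DA -> off, DA -> LTP
    pn: np.ndarray = field(default_factory=lambda: np.array(
        [[-1.0, 0.0],    # D2: no-DA -> LTD, DA -> off
         [0.0, -1.0]]))  # D1: no-DA -> off, DA -> LTD


@dataclass
class StriatalState:
    x_f: np.ndarray
    y_f: np.ndarray
    z_f: np.ndarray
    msn_type: np.ndarray      # bool, True = D1 (direct pathway)
    W_Str: np.ndarray         # (N, N), lateral inhibition, row i = onto MSN i
    config: StriatumConfig
    prev_P: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.x_f.size

    def copy(self) -> "StriatalState":
        return copy.deepcopy(self)


@dataclass
class CorticostriatalTable:
    """Fixed-slot corticostriatal synapse table: ``N_Cx_Str`` input slots
    per MSN.  A pruned synapse leaves an inactive slot that synaptogenesis
    may later refill; each slot keeps a fixed dopamine-neuron assignment
    (a permutation per MSN, i.e. random without replacement)."""

    pre: np.ndarray          # (N_Str, S) cortical unit ids
    w: np.ndarray            # (N_Str, S) weights >= 0
    active: np.ndarray       # (N_Str, S) bool
    da_neuron: np.ndarray    # (N_Str, S) assigned dopamine neuron per slot
    da_expiry: np.ndarray    # (N_Str, S) time until which dopamine is present
    allowed: list            # per-MSN candidate cortical inputs
    modulation: ModulationTable
    config: StriatumConfig
    rng: np.random.Generator

    def dopamine_flags(self, now: float) -> np.ndarray:
        return self.da_expiry > now

    def msn_weight_sums(self) -> np.ndarray:
        return np.where(self.active, self.w, 0.0).sum(axis=1)

    def copy(self) -> "CorticostriatalTable":
        return copy.deepcopy(self)


def init_striatum(config: StriatumConfig, seed: int) -> StriatalState:
    """Fresh winnerless network: all MSNs at the published initial point,
    directed Erdos-Renyi lateral inhibition with uniform weights in
    [g_min, g_max] and a boosted D1->D2 link probability, half the
    population D1 and half D2."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.N_Str
    msn_type = np.zeros(n, dtype=bool)
    msn_type[: n // 2] = True     # first half direct-pathway (D1)

    p = np.full((n, n), config.p_lateral)
    # rows = postsynaptic: D2 rows, D1 columns get the boosted probability
    p[np.ix_(~msn_type, msn_type)] = config.p_lateral_d1_to_d2
    conn = rng.random((n, n)) < p
    np.fill_diagonal(conn, False)
    W = np.where(conn, rng.uniform(config.g_min, config.g_max, (n, n)), 0.0)

    return StriatalState(
        x_f=np.full(n, config.x_0),
        y_f=np.full(n, config.y_0),
        z_f=np.full(n, config.z_0),
        msn_type=msn_type,
        W_Str=W,
        config=config,
    )


def build_corticostriatal(config: StriatumConfig, seed: int,
                          allowed_inputs: list[np.ndarray],
                          n_da: int) -> CorticostriatalTable:
    """Wire each MSN's input slots to cortical units drawn from its allowed
    pool, at the initial weight w_cap / N_Cx_Str (so every MSN starts
    exactly at the normalization cap), and assign dopamine neurons to slots
    randomly without replacement."""
    if len(allowed_inputs) != config.N_Str:
        raise ConfigurationError("one allowed-input pool per MSN required")
    rng = np.random.default_rng(seed)
    n, s = config.N_Str, config.N_Cx_Str
    pre = np.zeros((n, s), dtype=np.int64)
    da_neuron = np.zeros((n, s), dtype=np.int64)
    for i, pool in enumerate(allowed_inputs):
        pool = np.asarray(pool)
        if pool.size < s:
            raise ConfigurationError(
                f"MSN {i}: candidate pool smaller than N_Cx_Str")
        pre[i] = rng.choice(pool, size=s, replace=False)
        if n_da >= s:
            da_neuron[i] = rng.choice(n_da, size=s, replace=False)
        else:
            # fewer dopamine neurons than slots: spread as evenly as possible
            reps = np.tile(np.arange(n_da), s // n_da + 1)[:s]
            da_neuron[i] = rng.permutation(reps)
    w0 = config.w_cap / config.N_Cx_Str
    return CorticostriatalTable(
        pre=pre,
        w=np.full((n, s), w0),
        active=np.ones((n, s), dtype=bool),
        da_neuron=da_neuron,
        da_expiry=np.full((n, s), -np.inf),
        allowed=[np.asarray(a) for a in allowed_inputs],
        modulation=ModulationTable(),
        config=config,
        rng=rng,
    )


def cortical_drive(table: CorticostriatalTable,
                   spikes: np.ndarray) -> np.ndarray:
    """Per-MSN excitatory drive: weight-summed binary cortical spikes."""
    s = spikes[table.pre] * table.active
    return (table.w * s).sum(axis=1)


def step_striatum(state: StriatalState,
                  drive: np.ndarray | float = 0.0) -> StriatalState:
    """Advance all MSNs one 1-ms step (= ``h`` units of model time) under
    the given cortical drive, explicit Euler at ``h / n_substeps``."""
    cfg = state.config
    state.prev_P = np.maximum(state.x_f, 0.0)
    dt = cfg.h / cfg.n_substeps
    x, y, z = state.x_f, state.y_f, state.z_f
    drive = np.broadcast_to(np.asarray(drive, dtype=float), x.shape)
    for _ in range(cfg.n_substeps):
        inh_in = state.W_Str @ (x > 0.0).astype(float)
        dx = (x - x ** 3 / 3.0 - y - z * (x - cfg.nu)
              + cfg.I_bias + drive) / cfg.tau_1
        dy = x - cfg.b * y + cfg.a
        dz = (inh_in - z) / cfg.tau_2
        x = x + dt * dx
        y = y + dt * dy
        z = z + dt * dz
    if np.any(np.abs(x) > 100.0) or not np.all(np.isfinite(x)):
        raise IntegrationError(
            f"burst potential blew up (sub-step {dt:.3g} model units)")
    state.x_f, state.y_f, state.z_f = x, y, z
    return state


def burst_output(state: StriatalState) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave-rectified burst output ``P = max(x_f, 0)`` and the sign of
    its one-step difference."""
    P = np.maximum(state.x_f, 0.0)
    if state.prev_P is None:
        dP = np.zeros_like(P)
    else:
        dP = np.sign(P - state.prev_P)
    return P, dP


def corticostriatal_stdp(table: CorticostriatalTable,
                         cortical_spikes: np.ndarray,
                         dP: np.ndarray,
                         z_f: np.ndarray,
                         msn_type: np.ndarray,
                         now: float) -> CorticostriatalTable:
    """One plasticity step on the corticostriatal table.

    Classifies every synapse by (D1/D2, dopamine present, GABA high),
    applies the signed-gate weight change at the fixed learning rate, then
    renormalizes per-MSN sums to the cap, prunes zero-weight synapses, and
    attempts synaptogenesis (at most one new synapse per MSN per step).
    """
    cfg = table.config
    spk = cortical_spikes[table.pre].astype(bool) & table.active
    pp = spk & (dP[:, None] > 0)
    pn = spk & (dP[:, None] < 0)
    if pp.any() or pn.any():
        d1 = msn_type.astype(np.int64)[:, None]
        da = table.dopamine_flags(now).astype(np.int64)
        eff = (table.modulation.pp[d1, da] * pp
               + table.modulation.pn[d1, da] * pn)
        gaba = (z_f > cfg.gaba_threshold)[:, None]
        eff = np.where(gaba, -eff, eff)
        table.w += cfg.eta_CStr * eff
        np.clip(table.w, 0.0, None, out=table.w)
        # prune synapses driven to zero
        table.active &= table.w > 0.0
        _renormalize(table)

    # synaptogenesis: one candidate per MSN per step with fixed probability
    has_room = ~table.active.all(axis=1)
    candidates = np.flatnonzero(
        has_room & (table.rng.random(table.w.shape[0]) < cfg.p_synaptogenesis))
    for i in candidates:
        slot = int(np.flatnonzero(~table.active[i])[0])
        used = table.pre[i][table.active[i]]
        pool = np.setdiff1d(table.allowed[i], used)
        if pool.size == 0:
            continue
        table.pre[i, slot] = table.rng.choice(pool)
        table.w[i, slot] = cfg.w_cap / cfg.N_Cx_Str
        table.active[i, slot] = True
        table.da_expiry[i, slot] = -np.inf
    if candidates.size:
        _renormalize(table)
    return table


def _renormalize(table: CorticostriatalTable) -> None:
    """Scale each MSN's weights down so the active sum never exceeds the cap."""
    w_eff = np.where(table.active, table.w, 0.0)
    sums = w_eff.sum(axis=1)
    over = sums > table.config.w_cap
    if over.any():
        scale = np.ones_like(sums)
        scale[over] = table.config.w_cap / sums[over]
        table.w *= scale[:, None]
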