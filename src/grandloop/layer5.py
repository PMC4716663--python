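"""Cortical layer 5: self-organizing recurrent network (SORN) of binary units.

The traversal (synfire-ring) network.  N_E excitatory threshold units with
plastic excitatory recurrence and N_I inhibitory units provide, through a
combination of additive spike-timing-dependent plasticity, inhibitory STDP,
intrinsic (threshold) plasticity, per-row synaptic normalization, pruning
and synaptogenesis, the self-organization of a closed ring of feed-forward
propagation layers.  Those emergent layers are the model's four cortical
areas.

Update for excitatory unit ``i`` (time step = 1 ms)::

    x_i(t+1) = H[ U_i * sum_j W_EE[i,j] x_j(t) - sum_k W_EI[i,k] y_k(t)
                  + xi_i(t) - T_E[i] ]

with membrane noise ``xi ~ N(0, sigma_xi_sq)`` and a multiplicative gain
``U`` supplied by layer 2/3 (unity when the network runs uncoupled).
Inhibitory units respond instantaneously to the new excitatory state::

    y_k(t+1) = H[ sum_i W_IE[k,i] x_i(t+1) - T_I[k] ]

Plasticity is applied once per step, in a fixed order (STDP, inhibitory
STDP, intrinsic plasticity, row normalization, structural plasticity); the
order is part of the model definition and must not be changed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import ConfigurationError, Layer5Config

__all__ = [
    "Layer5State",
    "AreaIdentificationError",
    "init_layer5",
    "step_layer5",
    "apply_layer5_plasticity",
    "develop_ring",
    "identify_areas",
]

#: every row of W_EE (incoming excitatory weights of one unit) is rescaled
#: to this total after each plasticity step
ROW_TARGET = 1.0

#: floor applied to inhibitory->excitatory weights before renormalization
W_EI_FLOOR = 0.001


class AreaIdentificationError(RuntimeError):
    """Raised when the developed network does not decompose into the
    requested number of propagation layers.  Carries the (unsorted)
    spike-train correlation matrix for diagnosis."""

    def __init__(self, message: str, correlation: np.ndarray):
        super().__init__(message)
        self.correlation = correlation


@dataclass
class Layer5State:
    W_EE: np.ndarray          # (N_E, N_E), row i = incoming weights of unit i
    W_EI: np.ndarray          # (N_E, N_I)
    W_IE: np.ndarray          # (N_I, N_E)
    T_E: np.ndarray           # (N_E,)
    T_I: np.ndarray           # (N_I,)
    x: np.ndarray             # (N_E,) binary
    y_I: np.ndarray           # (N_I,) binary
    conn: np.ndarray          # (N_E, N_E) bool, existing synapses
    frozen_mask: np.ndarray   # (N_E, N_E) bool, clamped-at-zero entries
    area_label: np.ndarray    # (N_E,) int, -1 before development
    config: Layer5Config
    rng: np.random.Generator
    developing: bool = True
    area_names: tuple = field(default_factory=tuple)

    def copy(self) -> "Layer5State":
        return copy.deepcopy(self)


def init_layer5(config: Layer5Config, seed: int) -> Layer5State:
    """Build a fresh layer-5 network: sparse random excitatory recurrence,
    dense inhibitory loops, thresholds uniform in [0, TEmax] / [0, TImax]."""
    config.validate()
    rng = np.random.default_rng(seed)
    n_e, n_i = config.N_E, config.N_I

    conn = rng.random((n_e, n_e)) < config.p_EE_init
    np.fill_diagonal(conn, False)
    W_EE = np.where(conn, rng.random((n_e, n_e)), 0.0)
    _normalize_rows(W_EE)

    W_EI = rng.random((n_e, n_i))
    W_EI /= W_EI.sum(axis=1, keepdims=True)
    W_IE = rng.random((n_i, n_e))
    W_IE /= W_IE.sum(axis=1, keepdims=True)

    T_E = rng.uniform(0.0, config.TEmax, n_e)
    T_I = rng.uniform(0.0, config.TImax, n_i)

    x = (rng.random(n_e) < config.mu_IP).astype(np.int8)
    y_I = np.zeros(n_i, dtype=np.int8)

    return Layer5State(
        W_EE=W_EE, W_EI=W_EI, W_IE=W_IE, T_E=T_E, T_I=T_I,
        x=x, y_I=y_I, conn=conn,
        frozen_mask=np.zeros((n_e, n_e), dtype=bool),
        area_label=np.full(n_e, -1, dtype=np.int64),
        config=config, rng=rng,
    )


def _normalize_rows(W: np.ndarray, rows: np.ndarray | None = None,
                    target: float = ROW_TARGET) -> None:
    if rows is None:
        sums = W.sum(axis=1)
        nz = sums > 0
        W[nz] *= target / sums[nz, None]
    else:
        sums = W[rows].sum(axis=1)
        nz = sums > 0
        idx = rows[nz]
        W[idx] *= target / sums[nz, None]


def step_layer5(state: Layer5State, gain: np.ndarray | float = 1.0,
                ) -> tuple[Layer5State, np.ndarray]:
    """Advance the network one 1-ms step under multiplicative gain ``gain``.

    Returns the (mutated) state and the new excitatory spike vector.
    """
    cfg = state.config
    gain = np.broadcast_to(np.asarray(gain, dtype=float), (cfg.N_E,))
    if np.any(gain < 0):
        raise ValueError("gain entries must be non-negative")

    noise = state.rng.normal(0.0, np.sqrt(cfg.sigma_xi_sq), cfg.N_E) \
        if cfg.sigma_xi_sq > 0 else 0.0
    drive = gain * (state.W_EE @ state.x) - state.W_EI @ state.y_I + noise
    x_new = (drive > state.T_E).astype(np.int8)
    y_new = ((state.W_IE @ x_new) > state.T_I).astype(np.int8)
    state.x = x_new
    state.y_I = y_new
    return state, x_new


def apply_layer5_plasticity(state: Layer5State, prev_spikes: np.ndarray,
                            cur_spikes: np.ndarray,
                            prev_inhib: np.ndarray | None = None,
                            ) -> Layer5State:
    """Apply all layer-5 plasticity rules for one step, in fixed order:

    1. additive pair STDP on existing excitatory synapses,
    2. inhibitory STDP onto excitatory units (homeostatic target mu_IP),
    3. intrinsic plasticity of excitatory thresholds,
    4. row normalization of W_EE (and of W_EI),
    5. pruning of zero weights; during development, synaptogenesis.
    """
    cfg = state.config
    W = state.W_EE
    post_t = np.flatnonzero(cur_spikes)
    post_p = np.flatnonzero(prev_spikes)
    touched = set()

    # (1) STDP: potentiate pre(t-1)->post(t), depress post(t-1)->pre(t)
    if post_t.size and post_p.size:
        blk = np.ix_(post_t, post_p)
        W[blk] += cfg.eta_STDP * state.conn[blk]
        blk2 = np.ix_(post_p, post_t)
        W[blk2] -= cfg.eta_STDP * state.conn[blk2]
        touched.update(post_t.tolist())
        touched.update(post_p.tolist())

    # (2) inhibitory STDP: dW_EI[i,k] = -eta_inhib * y_k(t-1)
    #     * (1 - x_i(t) * eta_iSTDP), with eta_iSTDP = 1 + 1/mu_IP
    if prev_inhib is None:
        prev_inhib = state.y_I
    inh_p = np.flatnonzero(prev_inhib)
    if inh_p.size:
        post_factor = 1.0 - cur_spikes.astype(float) * cfg.eta_iSTDP
        state.W_EI[:, inh_p] -= cfg.eta_inhib * post_factor[:, None]
        np.clip(state.W_EI, W_EI_FLOOR, 1.0, out=state.W_EI)
        state.W_EI /= state.W_EI.sum(axis=1, keepdims=True)

    # (3) intrinsic plasticity toward target rate mu_IP
    state.T_E += cfg.eta_IP * (cur_spikes - cfg.mu_IP)
    if cfg.sigma_HIP > 0:
        state.T_E += state.rng.normal(0.0, cfg.sigma_HIP, cfg.N_E)

    # (5, first half) structural plasticity: one candidate connection
    if state.developing and state.rng.random() < cfg.p_struct:
        i = int(state.rng.integers(cfg.N_E))
        j = int(state.rng.integers(cfg.N_E))
        if i != j and not state.conn[i, j] and not state.frozen_mask[i, j]:
            state.conn[i, j] = True
            W[i, j] = cfg.w_struct
            touched.add(i)

    if touched:
        rows = np.fromiter(touched, dtype=np.int64)
        blk = W[rows]
        np.clip(blk, 0.0, None, out=blk)
        blk[state.frozen_mask[rows]] = 0.0
        W[rows] = blk
        # prune synapses that hit zero
        state.conn[rows] &= W[rows] > 0
        _normalize_rows(W, rows)
    return state


def develop_ring(state: Layer5State, n_steps: int | None = None,
                 probe_steps: int = 5000) -> Layer5State:
    """Run the self-organization phase with unit gain, freeze near-zero
    weights, and label the emergent propagation layers as cortical areas."""
    cfg = state.config
    if n_steps is None:
        n_steps = cfg.develop_steps
    prev = state.x.copy()
    for _ in range(n_steps):
        prev_inhib = state.y_I.copy()
        _, cur = step_layer5(state, 1.0)
        apply_layer5_plasticity(state, prev, cur, prev_inhib)
        prev = cur

    # freeze: weights close to zero are held at zero from here on
    tiny = state.W_EE <= cfg.freeze_tol * ROW_TARGET
    state.frozen_mask = tiny & ~np.eye(cfg.N_E, dtype=bool) | ~state.conn
    state.W_EE[tiny] = 0.0
    state.conn &= ~tiny
    _normalize_rows(state.W_EE)
    state.developing = False

    # probe raster for area identification (plasticity stays on; this is
    # ordinary post-developmental operation)
    raster = np.empty((probe_steps, cfg.N_E), dtype=np.int8)
    for t in range(probe_steps):
        prev_inhib = state.y_I.copy()
        _, cur = step_layer5(state, 1.0)
        apply_layer5_plasticity(state, prev, cur, prev_inhib)
        prev = cur
        raster[t] = cur
    state.area_label = identify_areas(raster, state.W_EE, cfg.N_A)
    return state


def identify_areas(raster: np.ndarray, W_EE: np.ndarray, n_areas: int,
                   ) -> np.ndarray:
    """Partition units into ``n_areas`` propagation layers.

    Units are clustered on their spike-train correlation matrix (average
    linkage on correlation distance); the resulting blocks are then put in
    cyclic propagation order by maximizing the total synaptic weight along
    the block-to-block ring, so that label ``k`` projects most strongly to
    label ``k+1 mod n_areas``.
    """
    n_units = raster.shape[1]
    sd = raster.std(axis=0)
    if np.any(sd == 0):
        # silent/saturated units carry no phase information; correlate with
        # jitter-free zero and let clustering place them by weight later
        sd = np.where(sd == 0, 1.0, sd)
        centered = raster - raster.mean(axis=0)
        corr = (centered.T @ centered) / (raster.shape[0] * np.outer(sd, sd))
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.corrcoef(raster.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_areas, criterion="maxclust") - 1
    sizes = np.bincount(labels, minlength=n_areas)
    if np.any(sizes == 0) or labels.max() != n_areas - 1:
        raise AreaIdentificationError(
            f"expected {n_areas} non-empty propagation layers, found "
            f"{np.count_nonzero(sizes)}", corr)

    # block weight matrix: B[a, b] = total weight of b -> a connections
    B = np.zeros((n_areas, n_areas))
    for a in range(n_areas):
        for b in range(n_areas):
            if a != b:
                B[a, b] = W_EE[np.ix_(labels == a, labels == b)].sum()

    # choose the cyclic order (anchored at block containing unit 0) with
    # the largest forward weight sum
    import itertools
    anchor = labels[0]
    rest = [a for a in range(n_areas) if a != anchor]
    best, best_score = None, -np.inf
    for perm in itertools.permutations(rest):
        order = (anchor,) + perm
        score = sum(B[order[(k + 1) % n_areas], order[k]]
                    for k in range(n_areas))
        if score > best_score:
            best, best_score = order, score
    rank = {blk: k for k, blk in enumerate(best)}
    return np.array([rank[b] for b in labels], dtype=np.int64)
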