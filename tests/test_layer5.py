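"""Layer-5 SORN: update rule, plasticity, homeostasis, ring development."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from grandloop.config import ConfigurationError, Layer5Config
from grandloop.layer5 import (
    ROW_TARGET,
    W_EI_FLOOR,
    Layer5State,
    apply_layer5_plasticity,
    develop_ring,
    init_layer5,
    step_layer5,
)


# ---------------------------------------------------------------------------
# brute-force oracle: an independent, loop-based implementation of the same
# update and plasticity rules, mirroring the package's random-stream usage

class BruteForceSorn:
    def __init__(self, cfg: Layer5Config, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        n_e, n_i = cfg.N_E, cfg.N_I
        conn_draw = rng.random((n_e, n_e))
        self.conn = [[conn_draw[i][j] < cfg.p_EE_init and i != j
                      for j in range(n_e)] for i in range(n_e)]
        w_draw = rng.random((n_e, n_e))
        self.W = [[w_draw[i][j] if self.conn[i][j] else 0.0
                   for j in range(n_e)] for i in range(n_e)]
        self._normalize_rows(range(n_e))
        self.W_EI = rng.random((n_e, n_i)).tolist()
        for i in range(n_e):
            s = sum(self.W_EI[i])
            self.W_EI[i] = [w / s for w in self.W_EI[i]]
        self.W_IE = rng.random((n_i, n_e)).tolist()
        for k in range(n_i):
            s = sum(self.W_IE[k])
            self.W_IE[k] = [w / s for w in self.W_IE[k]]
        self.T_E = rng.uniform(0.0, cfg.TEmax, n_e).tolist()
        self.T_I = rng.uniform(0.0, cfg.TImax, n_i).tolist()
        self.x = [int(v) for v in (rng.random(n_e) < cfg.mu_IP)]
        self.y = [0] * n_i
        self.frozen = [[False] * n_e for _ in range(n_e)]
        self.rng = rng

    def _normalize_rows(self, rows):
        for i in rows:
            s = sum(self.W[i])
            if s > 0:
                for j in range(len(self.W[i])):
                    self.W[i][j] *= ROW_TARGET / s

    def step(self, gain=1.0):
        cfg = self.cfg
        noise = (self.rng.normal(0.0, np.sqrt(cfg.sigma_xi_sq), cfg.N_E)
                 if cfg.sigma_xi_sq > 0 else np.zeros(cfg.N_E))
        x_new = []
        for i in range(cfg.N_E):
            exc = sum(self.W[i][j] * self.x[j] for j in range(cfg.N_E))
            inh = sum(self.W_EI[i][k] * self.y[k] for k in range(cfg.N_I))
            x_new.append(int(gain * exc - inh + noise[i] > self.T_E[i]))
        y_new = []
        for k in range(cfg.N_I):
            drive = sum(self.W_IE[k][i] * x_new[i] for i in range(cfg.N_E))
            y_new.append(int(drive > self.T_I[k]))
        prev_x, prev_y = self.x, self.y
        self.x, self.y = x_new, y_new
        return prev_x, x_new, prev_y

    def plasticity(self, prev_x, cur_x, prev_y, developing=True):
        cfg = self.cfg
        touched = set()
        # STDP
        for i in range(cfg.N_E):
            for j in range(cfg.N_E):
                if self.conn[i][j]:
                    dw = cfg.eta_STDP * (cur_x[i] * prev_x[j]
                                         - prev_x[i] * cur_x[j])
                    if dw != 0.0:
                        self.W[i][j] += dw
            if cur_x[i] or prev_x[i]:
                touched.add(i)
        if not (any(cur_x) and any(prev_x)):
            touched.clear()
        # iSTDP
        if any(prev_y):
            for i in range(cfg.N_E):
                for k in range(cfg.N_I):
                    if prev_y[k]:
                        self.W_EI[i][k] -= cfg.eta_inhib * (
                            1.0 - cur_x[i] * cfg.eta_iSTDP)
            for i in range(cfg.N_E):
                row = [min(max(w, W_EI_FLOOR), 1.0) for w in self.W_EI[i]]
                s = sum(row)
                self.W_EI[i] = [w / s for w in row]
        # IP
        for i in range(cfg.N_E):
            self.T_E[i] += cfg.eta_IP * (cur_x[i] - cfg.mu_IP)
        # structural
        if developing and self.rng.random() < cfg.p_struct:
            i = int(self.rng.integers(cfg.N_E))
            j = int(self.rng.integers(cfg.N_E))
            if i != j and not self.conn[i][j] and not self.frozen[i][j]:
                self.conn[i][j] = True
                self.W[i][j] = cfg.w_struct
                touched.add(i)
        # clip, prune, normalize touched rows
        for i in touched:
            for j in range(cfg.N_E):
                if self.W[i][j] < 0.0 or self.frozen[i][j]:
                    self.W[i][j] = max(self.W[i][j], 0.0)
                    if self.frozen[i][j]:
                        self.W[i][j] = 0.0
                if self.W[i][j] <= 0.0:
                    self.conn[i][j] = False
                    self.W[i][j] = 0.0
        self._normalize_rows(touched)


def test_brute_force_oracle_equivalence():
    """The vectorized network must match a plain-loop reimplementation of
    the same update and plasticity rules, step for step, on a 5-unit
    instance driven by identical noise streams."""
    cfg = Layer5Config(N_E=5, N_I=2, N_A=1, p_EE_init=0.5, mu_IP=0.2)
    state = init_layer5(cfg, seed=42)
    oracle = BruteForceSorn(cfg, seed=42)

    np.testing.assert_allclose(state.W_EE, np.array(oracle.W), atol=1e-12)
    np.testing.assert_array_equal(state.x, oracle.x)

    prev = state.x.copy()
    for t in range(1000):
        prev_inhib = state.y_I.copy()
        _, cur = step_layer5(state, 1.0)
        apply_layer5_plasticity(state, prev, cur, prev_inhib)
        px, cx, py = oracle.step(1.0)
        oracle.plasticity(px, cx, py)
        assert list(cur) == list(oracle.x), f"spike mismatch at step {t}"
        np.testing.assert_allclose(state.W_EE, np.array(oracle.W),
                                   atol=1e-10)
        prev = cur
    np.testing.assert_allclose(state.T_E, np.array(oracle.T_E), atol=1e-10)
    np.testing.assert_allclose(state.W_EI, np.array(oracle.W_EI), atol=1e-10)


# ---------------------------------------------------------------------------
# contracts and simple examples

def test_init_sizes_and_determinism():
    cfg = Layer5Config()
    a = init_layer5(cfg, seed=1)
    b = init_layer5(cfg, seed=1)
    assert a.W_EE.shape == (400, 400) and a.T_I.size == 80
    np.testing.assert_array_equal(a.W_EE, b.W_EE)
    np.testing.assert_array_equal(a.T_E, b.T_E)
    assert np.all(a.T_E <= cfg.TEmax) and np.all(a.T_E >= 0)
    assert np.all(a.area_label == -1)


def test_init_rejects_degenerate_sizes():
    with pytest.raises(ConfigurationError):
        init_layer5(Layer5Config(N_E=0), seed=1)
    with pytest.raises(ConfigurationError):
        init_layer5(Layer5Config(eta_STDP=-1.0), seed=1)


def test_subthreshold_network_is_silent():
    cfg = Layer5Config(N_E=10, N_I=2, N_A=1, sigma_xi_sq=0.0)
    st = init_layer5(cfg, seed=0)
    st.W_EE[:] = 0.0
    st.conn[:] = False
    st.T_E[:] = 0.5
    st.x[:] = 1
    _, spikes = step_layer5(st, 1.0)
    assert spikes.sum() == 0


def test_gain_is_multiplicative_on_excitatory_drive():
    """Doubling a unit's gain doubles its excitatory drive term exactly:
    with thresholds placed between 1x and 2x drive, the unit fires only
    under the doubled gain."""
    cfg = Layer5Config(N_E=3, N_I=1, N_A=1, sigma_xi_sq=0.0, p_EE_init=0.0)
    st = init_layer5(cfg, seed=0)
    st.W_EE[0, 1] = 0.4
    st.conn[0, 1] = True
    st.x = np.array([0, 1, 0], dtype=np.int8)
    st.y_I[:] = 0
    st.T_E[:] = 0.6          # between 0.4 and 0.8
    st2 = st.copy()
    _, s1 = step_layer5(st, np.ones(3))
    _, s2 = step_layer5(st2, np.array([2.0, 1.0, 1.0]))
    assert s1[0] == 0 and s2[0] == 1


def test_negative_gain_rejected():
    cfg = Layer5Config(N_E=4, N_I=1, N_A=1)
    st = init_layer5(cfg, 0)
    with pytest.raises(ValueError):
        step_layer5(st, np.array([1.0, -0.1, 1.0, 1.0]))


def test_ip_fixed_point():
    """Firing exactly at the target rate leaves thresholds unchanged."""
    cfg = Layer5Config(N_E=6, N_I=2, N_A=1)
    st = init_layer5(cfg, 0)
    T_before = st.T_E.copy()
    x_target = np.full(6, cfg.mu_IP)
    apply_layer5_plasticity(st, np.zeros(6, dtype=np.int8), x_target,
                            np.zeros(2, dtype=np.int8))
    np.testing.assert_allclose(st.T_E, T_before, atol=1e-15)


def test_repeated_pairing_potentiates_until_normalization_binds():
    """Pre-then-post pairing grows the paired synapse monotonically; row
    normalization caps it at the row target."""
    cfg = Layer5Config(N_E=3, N_I=1, N_A=1, sigma_xi_sq=0.0)
    st = init_layer5(cfg, 3)
    st.W_EE[:] = 0.0
    st.W_EE[0, 1] = st.W_EE[0, 2] = 0.5   # unit 0 reads units 1 and 2
    st.conn[:] = st.W_EE > 0
    pre = np.array([0, 1, 0], dtype=np.int8)    # unit 1 fired at t-1
    post = np.array([1, 0, 0], dtype=np.int8)   # unit 0 fires at t
    w_prev = st.W_EE[0, 1]
    for _ in range(1500):
        apply_layer5_plasticity(st, pre, post, np.zeros(1, dtype=np.int8))
        assert st.W_EE[0, 1] >= w_prev - 1e-12
        assert st.W_EE[0].sum() == pytest.approx(ROW_TARGET, abs=1e-9)
        w_prev = st.W_EE[0, 1]
    # the unpaired competitor decays toward zero; the paired synapse
    # saturates at the whole row budget
    assert w_prev > 0.99 * ROW_TARGET


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hst.integers(0, 2 ** 20 - 1), hst.integers(0, 2 ** 20 - 1),
       hst.integers(0, 10_000))
def test_row_sums_invariant_under_plasticity(bits_prev, bits_cur, seed):
    """W_EE row sums equal the normalization target after any plasticity
    call, for arbitrary spike patterns."""
    cfg = Layer5Config(N_E=20, N_I=4, N_A=1, p_EE_init=0.3)
    st = init_layer5(cfg, seed)
    prev = np.array([(bits_prev >> i) & 1 for i in range(20)], dtype=np.int8)
    cur = np.array([(bits_cur >> i) & 1 for i in range(20)], dtype=np.int8)
    apply_layer5_plasticity(st, prev, cur, st.y_I)
    sums = st.W_EE.sum(axis=1)
    has = st.conn.any(axis=1)
    np.testing.assert_allclose(sums[has], ROW_TARGET, atol=1e-9)


def test_homeostatic_rate_small_network():
    """Intrinsic plasticity drives the mean firing probability per step to
    mu_IP (within 5%) in a scaled-down network."""
    cfg = Layer5Config(N_E=100, N_I=20, N_A=1)
    st = init_layer5(cfg, 5)
    prev = st.x.copy()
    rates = []
    for t in range(15_000):
        prev_inhib = st.y_I.copy()
        _, cur = step_layer5(st, 1.0)
        apply_layer5_plasticity(st, prev, cur, prev_inhib)
        prev = cur
        if t >= 5000:
            rates.append(cur.mean())
    assert np.mean(rates) == pytest.approx(cfg.mu_IP, rel=0.05)


def test_determinism_over_long_run():
    """Identical (config, seed) produce identical rasters over 10,000
    steps."""
    cfg = Layer5Config(N_E=50, N_I=10, N_A=1)

    def run():
        st = init_layer5(cfg, 99)
        prev = st.x.copy()
        raster = []
        for _ in range(10_000):
            prev_inhib = st.y_I.copy()
            _, cur = step_layer5(st, 1.0)
            apply_layer5_plasticity(st, prev, cur, prev_inhib)
            prev = cur
            raster.append(cur.copy())
        return np.array(raster)

    np.testing.assert_array_equal(run(), run())


# ---------------------------------------------------------------------------
# ring development (shared full-size developed model)

def test_developed_areas_partition_units(ring_model):
    labels = ring_model.layer5.area_label
    cfg = ring_model.config.layer5
    assert labels.min() == 0 and labels.max() == cfg.N_A - 1
    sizes = np.bincount(labels, minlength=cfg.N_A)
    assert np.all(sizes > 0) and sizes.sum() == cfg.N_E


def test_within_layer_correlation_exceeds_between(ring_model):
    """The self-organized propagation layers fire together: mean pairwise
    spike-train correlation within a layer exceeds that between layers."""
    import copy
    m = copy.deepcopy(ring_model)
    rec = m.run_phase(4000, ach=0.0, record_last=4000)
    raster = rec.layer5.astype(float)
    sd = raster.std(axis=0)
    keep = sd > 0
    corr = np.corrcoef(raster[:, keep].T)
    labels = m.layer5.area_label[keep]
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(corr.shape[0], dtype=bool)
    assert corr[same & off].mean() > corr[~same].mean()


def test_ring_weights_dominate_cyclic_direction(ring_model):
    """Summed area-to-area weight along the propagation ring exceeds the
    anti-cyclic direction."""
    labels = ring_model.layer5.area_label
    W = ring_model.layer5.W_EE
    n_a = ring_model.config.layer5.N_A
    fwd = sum(W[np.ix_(labels == (k + 1) % n_a, labels == k)].sum()
              for k in range(n_a))
    bwd = sum(W[np.ix_(labels == (k - 1) % n_a, labels == k)].sum()
              for k in range(n_a))
    assert fwd > bwd


def test_frozen_weights_stay_zero(ring_model):
    import copy
    m = copy.deepcopy(ring_model)
    frozen = m.layer5.frozen_mask
    assert frozen.any()
    m.run_phase(500, ach=0.5)
    assert np.all(m.layer5.W_EE[frozen] == 0.0)
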