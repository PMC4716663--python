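"""Cortical layer 2/3: three-stage entropy-maximizing (Infomax) network.

Each cortical area carries one instance.  Stage one subtracts a running
input mean, stage two applies the square weight matrix ``C`` and a logistic
nonlinearity with adaptive bias ``w0``, and stage three supplies the
anti-redundancy learning term — either the direct matrix inverse
``(C^T)^-1`` or its biologically local estimate from a lateral network with
Hebbian weights ``Q_hat`` and auxiliary state ``v``:

    x_I = x_hat_I - x0
    u   = C x_I
    y   = 1 / (1 + exp(-(u + w0)))

    dx0   = beta_x0 (x_hat_I - x0)
    dw0   = beta_w0 (1 - 2y)
    dC    = beta_C  [A + (1 - 2y) x_I^T]          (Hebbian term optional)
    dQhat = beta_Q  (u u^T - Q_hat)

where ``A -> (C^T)^-1`` in the stationary limit.  The lateral estimate
iterates  v <- v + u - alpha Q_hat v  to its fixed point and returns
``alpha v_inf x_I^T``; convergence requires ``alpha < 2 / lambda_max(Q_hat)``
and the implementation keeps ``alpha = 1 / lambda_max``, refreshed
periodically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .config import InfomaxConfig

__all__ = [
    "InfomaxState",
    "init_infomax",
    "infomax_forward",
    "infomax_learn",
    "lateral_antiredundancy",
    "LateralDivergenceError",
]


class LateralDivergenceError(RuntimeError):
    """Lateral-network iteration failed to converge."""


@dataclass
class InfomaxState:
    C: np.ndarray
    w0: np.ndarray
    x0: np.ndarray
    Qhat: np.ndarray
    v: np.ndarray
    y: np.ndarray
    alpha: float
    config: InfomaxConfig
    steps: int = 0
    # forward-pass cache
    x_I: np.ndarray | None = None
    u: np.ndarray | None = None
    _A_cache: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.C.shape[0]

    def copy(self) -> "InfomaxState":
        return copy.deepcopy(self)


def init_infomax(n: int, config: InfomaxConfig, seed: int) -> InfomaxState:
    """C starts at identity plus small Gaussian jitter (full rank by
    construction); the lateral matrix starts at identity so that the very
    first lateral iterations are well-posed."""
    config.validate()
    rng = np.random.default_rng(seed)
    C = np.eye(n) + rng.normal(0.0, config.c_init_jitter, (n, n))
    return InfomaxState(
        C=C,
        w0=np.zeros(n),
        x0=np.zeros(n),
        Qhat=np.eye(n),
        v=np.zeros(n),
        y=np.full(n, 0.5),
        alpha=1.0,
        config=config,
    )


def infomax_forward(state: InfomaxState, x_hat_I: np.ndarray) -> np.ndarray:
    """Forward pass; caches (x_I, u, y) for the subsequent learning step."""
    x_hat_I = np.asarray(x_hat_I, dtype=float)
    if x_hat_I.shape != (state.n,):
        raise ValueError(
            f"input length {x_hat_I.shape} does not match C dimension {state.n}")
    x_I = x_hat_I - state.x0
    u = state.C @ x_I
    # logistic transfer; clip the exponent to keep y strictly inside (0,1)
    z = np.clip(u + state.w0, -500.0, 500.0)
    y = 1.0 / (1.0 + np.exp(-z))
    eps = np.finfo(float).tiny
    y = np.clip(y, eps, 1.0 - eps)
    state.x_I, state.u, state.y = x_I, u, y
    state._x_hat = x_hat_I
    return y


def infomax_learn(state: InfomaxState) -> InfomaxState:
    """One learning step using the cached forward pass."""
    if state.x_I is None:
        raise RuntimeError("infomax_learn requires a prior forward pass")
    cfg = state.config
    x_I, u, y = state.x_I, state.u, state.y

    if cfg.antiredundancy_mode == "direct":
        if state._A_cache is None or state.steps % cfg.inverse_refresh == 0:
            try:
                state._A_cache = np.linalg.inv(state.C.T)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"C became singular in direct mode (cond="
                    f"{np.linalg.cond(state.C):.3g})") from exc
        A = state._A_cache
    else:
        A = lateral_antiredundancy(state, x_I)

    dC = A.copy()
    if cfg.hebbian_term:
        dC += np.outer(1.0 - 2.0 * y, x_I)
    state.C += cfg.beta_C * dC

    # rank monitoring is periodic: the SVD is far more expensive than the
    # learning step itself
    if (state.steps + 1) % cfg.alpha_update_every == 0:
        cond = np.linalg.cond(state.C)
        if cond > cfg.cond_limit:
            raise np.linalg.LinAlgError(
                f"C condition number {cond:.3g} exceeds limit "
                f"{cfg.cond_limit:g}")

    state.x0 += cfg.beta_x0 * (state._x_hat - state.x0)
    state.w0 += cfg.beta_w0 * (1.0 - 2.0 * y)
    state.Qhat += cfg.beta_Q * (np.outer(u, u) - state.Qhat)
    state.Qhat = (state.Qhat + state.Qhat.T) / 2.0

    state.steps += 1
    if state.steps % cfg.alpha_update_every == 0:
        _refresh_alpha(state)
    return state


def _refresh_alpha(state: InfomaxState) -> None:
    lam = float(np.linalg.eigvalsh(state.Qhat)[-1])
    if lam > 0:
        state.alpha = 1.0 / lam


def lateral_antiredundancy(state: InfomaxState, x_I: np.ndarray) -> np.ndarray:
    """Iterate the lateral network to its fixed point and return the
    single-presentation anti-redundancy estimate ``alpha v_inf x_I^T``.

    At the fixed point ``u = alpha Q_hat v_inf``; averaged over a
    stationary input ensemble the estimate converges to ``(C^T)^-1``.
    """
    cfg = state.config
    u = state.u if state.u is not None else state.C @ x_I
    lam = float(np.linalg.eigvalsh(state.Qhat)[-1])
    if lam > 0 and state.alpha >= 2.0 / lam:
        raise LateralDivergenceError(
            f"alpha={state.alpha:.4g} >= 2/lambda_max(Qhat)={2.0 / lam:.4g}; "
            "lateral iteration diverges")
    v = np.zeros_like(u)
    for _ in range(cfg.lateral_max_iter):
        v_new = v + u - state.alpha * (state.Qhat @ v)
        if not np.all(np.isfinite(v_new)):
            raise LateralDivergenceError(
                f"lateral iteration diverged (alpha={state.alpha:.4g})")
        if np.linalg.norm(v_new - v) < cfg.lateral_tol * (1 + np.linalg.norm(v)):
            v = v_new
            break
        v = v_new
    else:
        raise LateralDivergenceError(
            f"no convergence in {cfg.lateral_max_iter} iterations "
            f"(alpha={state.alpha:.4g}, lambda_max(Qhat)={lam:.4g})")
    state.v = v
    return state.alpha * np.outer(v, x_I)
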