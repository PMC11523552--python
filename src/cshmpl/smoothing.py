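"""Automatic smoothing selection by Laplace-approximate marginal likelihood.

The roughness penalty lambda_r * theta_r' R_r theta_r is read as the log
density of a N(0, sigma_r^2 R_r^{-1}) prior with sigma_r^2 = 1 / (2 lambda_r).
Maximizing the Laplace approximation to the marginal likelihood of the
sigma_r^2 yields the fixed-point update

    sigma_r^2 = theta_r' R_r theta_r / (m_r - nu_r),

where nu_r = tr{(G_r + Q_r)^{-1} Q_r} is the effective degrees of freedom of
risk r's baseline: G_r is the negative Hessian of the (unpenalized)
log-likelihood in (beta_r, theta_r) and Q_r = blockdiag(0_pxp, R_r/sigma_r^2).
When d_r of the theta_r >= 0 constraints are active the trace is projected
onto the free coordinates (active rows/columns deleted).

Estimation alternates inner Newton-MI fits at fixed sigma^2 with outer
sigma^2 updates, warm-starting each inner fit, until the nu_r change by less
than one between consecutive outer rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .likelihood import LikelihoodWorkspace
from .optimizer import OptimizerControls, OptimizerState, fit_fixed_smoothing

__all__ = ["SmoothingState", "effective_df", "update_sigma2", "laplace_marginal", "fit_auto"]

logger = logging.getLogger(__name__)

_SIGMA2_FLOOR = 1e-10


@dataclass
class SmoothingState:
    sigma2: np.ndarray                 # (g,) prior variances, sigma_r^2 = 1/(2 lambda_r)
    nu: np.ndarray                     # (g,) effective degrees of freedom
    d: np.ndarray                      # (g,) active-constraint counts
    outer_iterations: int = 0
    stabilized: bool = False
    marginal: float = np.nan
    history: list = field(default_factory=list)

    @property
    def lambdas(self) -> np.ndarray:
        return 1.0 / (2.0 * self.sigma2)


def _risk_blocks(ws: LikelihoodWorkspace, state: OptimizerState):
    """Per-risk G_r (negative loglik Hessian in (beta_r, theta_r)) and the
    active masks mapped into the block ordering."""
    zeros = np.zeros(ws.g)
    out = []
    for r in range(ws.g):
        idx = ws.block_indices(r, order="beta_theta")
        G = -ws.hessian(state.params, zeros, indices=idx)
        act = np.concatenate([np.zeros(ws.p, dtype=bool), state.active[r]])
        out.append((G, act))
    return out


def effective_df(ws: LikelihoodWorkspace, G: np.ndarray, R: np.ndarray,
                 sigma2_r: float, active: np.ndarray | None = None) -> float:
    """nu_r = tr{(G + Q)^{-1} Q} with Q = blockdiag(0_pxp, R/sigma2), the
    trace projected onto non-active coordinates when a mask is given."""
    p = G.shape[0] - R.shape[0]
    Q = np.zeros_like(G)
    Q[p:, p:] = R / sigma2_r
    if active is not None and np.any(active):
        free = ~active
        Gf = (G + Q)[np.ix_(free, free)]
        Qf = Q[np.ix_(free, free)]
    else:
        Gf = G + Q
        Qf = Q
    try:
        sol = np.linalg.solve(Gf, Qf)
    except np.linalg.LinAlgError:
        logger.warning("singular G + Q when computing effective df; using pseudo-inverse")
        sol = np.linalg.pinv(Gf) @ Qf
    nu = float(np.trace(sol))
    return float(np.clip(nu, 0.0, R.shape[0]))


def update_sigma2(theta_r: np.ndarray, R: np.ndarray, nu_r: float, d_r: int = 0) -> float:
    """sigma_r^2 = theta_r' R_r theta_r / (m_eff - nu_r), floored away from 0.

    ``m_eff = m_r - d_r``: with d_r coordinates pinned at the boundary the
    Laplace integral runs over the (m_r - d_r)-dimensional free face, so only
    that many prior directions contribute their sigma^2 normalization.
    """
    m_eff = R.shape[0] - int(d_r)
    if nu_r >= m_eff - 0.1:
        logger.warning("effective df %.2f >= m_eff = %d; clamping", nu_r, m_eff)
        nu_r = m_eff - 0.1
    num = float(theta_r @ R @ theta_r)
    return max(num / (m_eff - nu_r), _SIGMA2_FLOOR)


def laplace_marginal(ws: LikelihoodWorkspace, state: OptimizerState,
                     sigma2: np.ndarray, blocks=None) -> float:
    """Laplace approximation to the log marginal likelihood of sigma^2.

    Diagnostic value (the sigma^2 update above is its stationary condition):
    -(1/2) sum_r [ m_r log sigma_r^2 + theta_r'R_r theta_r / sigma_r^2
    + log|G_r + Q_r| ] + loglik(beta_hat, theta_hat), determinants taken on
    the active-constraint-projected blocks via sign-stable slogdet.
    """
    if blocks is None:
        blocks = _risk_blocks(ws, state)
    ll = ws.log_likelihood(state.params)
    total = ll
    for r, (G, act) in enumerate(blocks):
        R = ws.penalties[r]
        m_r = R.shape[0]
        Q = np.zeros_like(G)
        Q[ws.p:, ws.p:] = R / sigma2[r]
        free = ~act
        sign, logdet = np.linalg.slogdet((G + Q)[np.ix_(free, free)])
        if sign <= 0:
            logger.warning("non-PD G + Q in marginal likelihood for risk %d", r)
        theta = state.params.theta[r]
        total += -0.5 * (
            m_r * np.log(sigma2[r]) + float(theta @ R @ theta) / sigma2[r] + logdet
        )
    return float(total)


def fit_auto(
    ws: LikelihoodWorkspace,
    init=None,
    sigma2_init: float | np.ndarray = 50.0,
    controls: OptimizerControls | None = None,
    outer_max: int = 20,
    nu_tol: float = 1.0,
) -> tuple[OptimizerState, SmoothingState]:
    """Inner-outer estimation: Newton-MI at fixed smoothing (inner), then
    marginal-likelihood sigma^2 updates (outer), until the effective degrees
    of freedom stabilize (max change < 1) or the outer cap is reached."""
    g = ws.g
    sigma2 = np.broadcast_to(np.asarray(sigma2_init, dtype=float), (g,)).copy()
    nu = np.zeros(g)
    state = None
    best = None  # (marginal, fit, smooth-state snapshot)
    stabilized = False
    history = []
    outer = 0
    d = np.zeros(g, dtype=int)
    for outer in range(1, outer_max + 1):
        lambdas = 1.0 / (2.0 * sigma2)
        state = fit_fixed_smoothing(ws, lambdas, init=init, controls=controls)
        init = state.params  # warm start the next inner fit
        blocks = _risk_blocks(ws, state)
        nu_new = np.array([
            effective_df(ws, G, ws.penalties[r], sigma2[r], active=act)
            for r, (G, act) in enumerate(blocks)
        ])
        d = np.array([int(a.sum()) for a in state.active])
        marg = laplace_marginal(ws, state, sigma2, blocks=blocks)
        history.append({"sigma2": sigma2.copy(), "nu": nu_new.copy(),
                        "lambdas": lambdas.copy(), "marginal": marg})
        if best is None or marg > best[0]:
            best = (marg, state, sigma2.copy(), nu_new.copy(), d.copy())
        if np.all(np.abs(nu_new - nu) < nu_tol) and outer > 1:
            nu = nu_new
            stabilized = True
            break
        nu = nu_new
        sigma2 = np.array([
            update_sigma2(state.params.theta[r], ws.penalties[r], nu[r], d_r=d[r])
            for r in range(g)
        ])
    if not stabilized:
        logger.warning("effective df did not stabilize in %d outer iterations; "
                       "returning the best marginal-likelihood round", outer_max)
        _, state, sigma2, nu, d = best
    smooth = SmoothingState(
        sigma2=sigma2, nu=nu, d=d, outer_iterations=outer,
        stabilized=stabilized,
        marginal=history[-1]["marginal"] if stabilized else best[0],
        history=history,
    )
    return state, smooth
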