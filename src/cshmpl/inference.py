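"""Active-constraint-aware large-sample covariance and Wald inference.

At the maximum penalized likelihood solution some spline coefficients sit on
the theta >= 0 boundary (active constraints).  Ignoring them when inverting
the information matrix can produce negative variance estimates; the remedy is
a selection matrix U that deletes the active coordinates, giving the sandwich

    Cov(eta_hat) ~= Ftilde^{-1} G [Ftilde^{-1}]' / n,
    Ftilde^{-1}  =  U (U' F U)^{-1} U'

with F the per-subject-scaled negative Hessian of the penalized
log-likelihood at eta_hat and G the empirical second moment of the
per-subject score contributions.  Rows/columns of the covariance at active
coordinates are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .likelihood import LikelihoodWorkspace
from .optimizer import OptimizerState

__all__ = ["CovarianceResult", "build_U", "sandwich_covariance", "wald_table"]


@dataclass
class CovarianceResult:
    cov: np.ndarray              # (D, D) covariance of eta_hat = (theta', beta')'
    active: np.ndarray           # (D,) boolean mask of active coordinates
    se_beta: np.ndarray          # (g, p)
    se_theta: list[np.ndarray]   # g x (m_r,)
    U: np.ndarray                # (D, D - d) selection matrix


def build_U(m_list, p: int, d_list) -> np.ndarray:
    """Block-diagonal selection matrix; per risk U_r = [0, I]' of shape
    (m_r + p) x (m_r + p - d_r), deleting the first d_r (active) coordinates.
    Satisfies U'U = I."""
    blocks = []
    for m_r, d_r in zip(m_list, d_list):
        if not 0 <= d_r <= m_r:
            raise ValueError(f"invalid active count d_r={d_r} for m_r={m_r}")
        size = m_r + p
        U_r = np.zeros((size, size - d_r))
        U_r[d_r:, :] = np.eye(size - d_r)
        blocks.append(U_r)
    total = sum(b.shape[0] for b in blocks)
    cols = sum(b.shape[1] for b in blocks)
    U = np.zeros((total, cols))
    i = j = 0
    for b in blocks:
        U[i:i + b.shape[0], j:j + b.shape[1]] = b
        i += b.shape[0]
        j += b.shape[1]
    return U


def _selection_from_mask(active: np.ndarray) -> np.ndarray:
    """Selection matrix deleting the coordinates flagged in ``active``."""
    D = active.size
    free = np.flatnonzero(~active)
    U = np.zeros((D, free.size))
    U[free, np.arange(free.size)] = 1.0
    return U


def sandwich_covariance(ws: LikelihoodWorkspace, state: OptimizerState,
                        lambdas) -> CovarianceResult:
    """Sandwich covariance of eta_hat with active rows/columns zeroed."""
    n = ws.data.n
    lambdas = np.asarray(lambdas, dtype=float)
    bundle = ws.score(state.params, lambdas, per_subject=True)
    scores = bundle.per_subject                       # (n, D)
    G = scores.T @ scores / n
    F = -ws.hessian(state.params, lambdas) / n

    active = np.zeros(ws.dim, dtype=bool)
    for r in range(ws.g):
        active[ws.theta_off[r]:ws.theta_off[r + 1]] = state.active[r]
    free = ~active
    Ff = F[np.ix_(free, free)]
    try:
        Finv_f = np.linalg.inv(Ff)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "information matrix singular on the free coordinates; "
            "covariance unavailable"
        )
    Ftilde_inv = np.zeros_like(F)
    Ftilde_inv[np.ix_(free, free)] = Finv_f
    cov = Ftilde_inv @ G @ Ftilde_inv.T / n
    cov = 0.5 * (cov + cov.T)
    cov[active, :] = 0.0
    cov[:, active] = 0.0

    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    off = ws.theta_off[-1]
    se_beta = se[off:].reshape(ws.g, ws.p)
    se_theta = [se[ws.theta_off[r]:ws.theta_off[r + 1]] for r in range(ws.g)]
    return CovarianceResult(
        cov=cov, active=active, se_beta=se_beta, se_theta=se_theta,
        U=_selection_from_mask(active),
    )


def wald_table(beta: np.ndarray, se_beta: np.ndarray, names=None, risk_labels=None):
    """Per-coefficient hazard ratios, standard errors and normal p-values."""
    import pandas as pd

    g, p = beta.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    if risk_labels is None:
        risk_labels = [f"risk {r + 1}" for r in range(g)]
    rows = []
    for r in range(g):
        for j in range(p):
            b, s = beta[r, j], se_beta[r, j]
            z = b / s if s > 0 else np.nan
            pval = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({
                "risk": risk_labels[r], "covariate": names[j], "coef": b,
                "HR": np.exp(b), "se(coef)": s, "z": z, "p": pval,
                "ci_low": b - 1.959963984540054 * s,
                "ci_high": b + 1.959963984540054 * s,
            })
    return pd.DataFrame(rows)
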