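"""Model quantities and the penalized log-likelihood with analytic score.

The cause-specific hazard (CSH) Cox model for risk r is

    h_r(t | X) = h_0r(t) exp(X' beta_r),   h_0r(t) = sum_u theta_ru psi_ru(t)

with M-spline baselines and theta >= 0.  Under partly interval censoring the
log-likelihood mixes four contribution types:

    event at t, risk r:      log h_r(t|X) - sum_q H_q(t|X)
    right-censored at tL:    - sum_q H_q(tL|X)
    left-censored at tR:     log Fbar_r(tR|X)
    interval (tL, tR):       log( Fbar_r(tR|X) - Fbar_r(tL|X) )

where Fbar_r(t|X) = int_0^t h_r(w|X) S(w|X) dw is the cumulative incidence
function (CIF) and S = prod_q exp(-H_q).  The CIF couples the risks, so the
likelihood does not separate by r once left/interval censoring is present.

The CIF integrals -- and the derivative integrals

    A_qr(t)  = int_0^t h_q S (1{q=r} - H_r) dw
    B1_ru(t) = int_0^t psi_ru S dw          (enters only when q = r)
    B2_qru(t)= int_0^t h_q Psi_ru S dw

-- are evaluated by fixed Gauss-Legendre quadrature.  Because the node
locations depend only on each subject's censoring times, all spline basis
values at the nodes are precomputed once per dataset in
:class:`LikelihoodWorkspace` and reused at every optimizer iteration; each
evaluation is then a handful of dense array contractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quadrature import DEFAULT_QUADRATURE_POINTS, gauss_legendre_rule

__all__ = [
    "ModelParameters",
    "LikelihoodWorkspace",
    "hazard",
    "cumulative_hazard",
    "cif",
    "cif_gradients",
]

_LOG_FLOOR = 1e-300  # floor inside logs of CIF differences / hazards


@dataclass
class ModelParameters:
    """Regression coefficients beta (g blocks of length p) and non-negative
    spline coefficients theta (g blocks of length m_r)."""

    beta: np.ndarray          # (g, p)
    theta: list[np.ndarray]   # g arrays of shape (m_r,)

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.theta = [np.asarray(t, dtype=float) for t in self.theta]
        for r, th in enumerate(self.theta):
            if np.any(th < 0):
                raise ValueError(f"theta block {r} has negative entries")

    @property
    def g(self) -> int:
        return self.beta.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[1]

    @property
    def m(self) -> list[int]:
        return [t.size for t in self.theta]

    def copy(self) -> "ModelParameters":
        return ModelParameters(self.beta.copy(), [t.copy() for t in self.theta])

    # eta ordering: (theta_1, ..., theta_g, beta_1, ..., beta_g)
    def flatten(self) -> np.ndarray:
        return np.concatenate([*self.theta, self.beta.ravel()])

    @classmethod
    def unflatten(cls, eta: np.ndarray, g: int, p: int, m: list[int]) -> "ModelParameters":
        eta = np.asarray(eta, dtype=float)
        theta, off = [], 0
        for mr in m:
            theta.append(eta[off:off + mr].copy())
            off += mr
        beta = eta[off:off + g * p].reshape(g, p).copy()
        return cls(beta, theta)


# ---------------------------------------------------------------------------
# Standalone model quantities (used by prediction and tests)
# ---------------------------------------------------------------------------

def hazard(params: ModelParameters, bases, r: int, t, X) -> np.ndarray:
    """Cause-specific hazard h_r(t | X) on a time grid (risk index 0-based)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    base = bases[r].eval_basis(t) @ params.theta[r]
    return base * np.exp(float(np.dot(np.atleast_1d(X), params.beta[r])))

def cumulative_hazard(params: ModelParameters, bases, r: int, t, X) -> np.ndarray:
    """Cumulative cause-specific hazard H_r(t | X) (closed form via I-splines)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    base = bases[r].eval_cumulative(t) @ params.theta[r]
    return base * np.exp(float(np.dot(np.atleast_1d(X), params.beta[r])))

def survival(params: ModelParameters, bases, t, X) -> np.ndarray:
    """Overall survival S(t | X) = prod_r exp(-H_r(t | X))."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    H = sum(cumulative_hazard(params, bases, r, t, X) for r in range(params.g))
    return np.exp(-H)

def _node_model(params, bases, X, nodes):
    """Hazards and survival at quadrature nodes; nodes has shape (k, V)."""
    g = params.g
    exb = np.array([np.exp(float(np.dot(np.atleast_1d(X), params.beta[r]))) for r in range(g)])
    flat = nodes.ravel()
    h = np.empty((g,) + nodes.shape)
    H = np.empty_like(h)
    for r in range(g):
        h[r] = (bases[r].eval_basis(flat) @ params.theta[r]).reshape(nodes.shape) * exb[r]
        H[r] = (bases[r].eval_cumulative(flat) @ params.theta[r]).reshape(nodes.shape) * exb[r]
    S = np.exp(-H.sum(axis=0))
    return exb, h, H, S

def cif(params: ModelParameters, bases, r: int, t, X, rule=None) -> np.ndarray:
    """Cumulative incidence Fbar_r(t | X) by Gauss-Legendre quadrature."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if rule is None:
        rule = gauss_legendre_rule()
    nodes, wts = rule.mapped(t)
    _, h, _, S = _node_model(params, bases, X, nodes)
    return np.einsum("kv,kv->k", wts, h[r] * S)

def cif_gradients(params: ModelParameters, bases, q: int, t, X, rule=None):
    """Derivative integrals of the CIF Fbar_q(t | X).

    Returns ``(A, B1, B2)`` with ``A[r]`` of shape (len(t),), ``B1[r]`` and
    ``B2[r]`` of shape (len(t), m_r);  dFbar_q/dbeta_rj = A[r] * x_j and
    dFbar_q/dtheta_ru = (1{q=r} B1[r] - B2[r])_u * exp(X'beta_r).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if rule is None:
        rule = gauss_legendre_rule()
    nodes, wts = rule.mapped(t)
    _, h, H, S = _node_model(params, bases, X, nodes)
    g = params.g
    core = wts * h[q] * S  # (k, V)
    A, B1, B2 = [], [], []
    flat = nodes.ravel()
    for r in range(g):
        A.append(np.einsum("kv,kv->k", core, 1.0 * (q == r) - H[r]))
        psi = bases[r].eval_basis(flat).reshape(nodes.shape + (-1,))
        Psi = bases[r].eval_cumulative(flat).reshape(nodes.shape + (-1,))
        B1.append(np.einsum("kv,kvu->ku", wts * S, psi))
        B2.append(np.einsum("kv,kvu->ku", core, Psi))
    return A, B1, B2


# ---------------------------------------------------------------------------
# Cached per-dataset workspace
# ---------------------------------------------------------------------------

@dataclass
class ScoreBundle:
    """Analytic score of the penalized objective and the optimizer weights."""

    grad_beta: np.ndarray          # (g, p)
    grad_theta: list[np.ndarray]   # g x (m_r,)
    tau: list[np.ndarray]          # MI denominators, g x (m_r,)
    v_diag: np.ndarray             # (n, g) pseudo-Hessian weights for beta steps
    per_subject: np.ndarray | None  # (n, D) score contributions, if requested

    def flatten(self) -> np.ndarray:
        return np.concatenate([*self.grad_theta, self.grad_beta.ravel()])


class LikelihoodWorkspace:
    """Precomputed caches for fast likelihood/score evaluation on one dataset.

    All spline basis values at exact observation times and at the Gauss-
    Legendre nodes of every censoring-interval integral are computed once at
    construction; subsequent evaluations only perform parameter-dependent
    contractions.
    """

    def __init__(self, data, bases, n_quad: int = DEFAULT_QUADRATURE_POINTS):
        self.data = data
        self.bases = list(bases)
        self.g = data.g
        self.p = data.p
        if len(self.bases) != self.g:
            raise ValueError("need one basis per risk")
        self.m = [b.m for b in self.bases]
        self.rule = gauss_legendre_rule(n_quad)

        status = data.status
        self.ev = np.flatnonzero(status == "event")
        self.le = np.flatnonzero(status == "left")
        self.iv = np.flatnonzero(status == "interval")
        self.ri = np.flatnonzero(status == "right")
        self.risk0 = data.risk - 1  # -1 for right-censored
        self.X = data.X

        # exact-time caches: psi at event times; Psi at event + right times
        t_ev = data.t_left[self.ev]
        self.psi_ev = [b.eval_basis(t_ev) for b in self.bases]          # (n_ev, m_r)
        self.h_idx = np.concatenate([self.ev, self.ri])
        t_h = np.concatenate([t_ev, data.t_left[self.ri]])
        self.Psi_h = [b.eval_cumulative(t_h) for b in self.bases]       # (n_h, m_r)

        # integral tasks: one per left upper limit, two per interval
        n_le, n_iv = self.le.size, self.iv.size
        self.task_subject = np.concatenate([self.le, self.iv, self.iv])
        uppers = np.concatenate(
            [data.t_right[self.le], data.t_left[self.iv], data.t_right[self.iv]]
        )
        self.sl_le = slice(0, n_le)
        self.sl_ivL = slice(n_le, n_le + n_iv)
        self.sl_ivR = slice(n_le + n_iv, n_le + 2 * n_iv)
        self.n_task = uppers.size
        if self.n_task:
            nodes, wts = self.rule.mapped(uppers)
        else:
            nodes = np.zeros((0, n_quad))
            wts = np.zeros((0, n_quad))
        self.wts = wts
        flat = nodes.ravel()
        self.psi_nodes = [
            b.eval_basis(flat).reshape(nodes.shape + (b.m,)) for b in self.bases
        ]
        self.Psi_nodes = [
            b.eval_cumulative(flat).reshape(nodes.shape + (b.m,)) for b in self.bases
        ]

        self.penalties = [b.penalty_matrix().R for b in self.bases]
        # eta layout offsets: theta blocks then beta blocks
        self.theta_off = np.concatenate([[0], np.cumsum(self.m)]).astype(int)
        self.dim = int(sum(self.m)) + self.g * self.p

    # -- parameter-dependent cores ------------------------------------------
    def _core(self, params: ModelParameters):
        g = self.g
        # clip the linear predictor: wild trial points during line searches
        # must yield a finite (very poor) objective, not overflow
        exb = np.exp(np.clip(self.X @ params.beta.T, -300.0, 300.0))  # (n, g)
        sub = self.task_subject
        H_nodes = np.empty((g, self.n_task, self.wts.shape[1]))
        phi_nodes = np.empty_like(H_nodes)
        for r in range(g):
            phi_nodes[r] = self.psi_nodes[r] @ params.theta[r] * exb[sub, r][:, None]
            H_nodes[r] = self.Psi_nodes[r] @ params.theta[r] * exb[sub, r][:, None]
        S_nodes = np.exp(-H_nodes.sum(axis=0))
        fbar = np.einsum("tv,rtv->rt", self.wts, phi_nodes * S_nodes)  # (g, n_task)
        return exb, phi_nodes, H_nodes, S_nodes, fbar

    def log_likelihood(self, params: ModelParameters) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            return self._log_likelihood_impl(params)

    def _log_likelihood_impl(self, params: ModelParameters) -> float:
        exb, _, _, _, fbar = self._core(params)
        ll = 0.0
        # events: log h_r(t_i | X_i)
        if self.ev.size:
            rk = self.risk0[self.ev]
            haz = np.empty(self.ev.size)
            for r in range(self.g):
                sel = rk == r
                if np.any(sel):
                    haz[sel] = (self.psi_ev[r][sel] @ params.theta[r]) * exb[self.ev[sel], r]
            ll += float(np.sum(np.log(np.maximum(haz, _LOG_FLOOR))))
        # survival terms: -sum_r H_r at event times and right-censoring times
        if self.h_idx.size:
            for r in range(self.g):
                ll -= float(np.dot(self.Psi_h[r] @ params.theta[r], exb[self.h_idx, r]))
        # left censoring: log Fbar_r(t_R)
        if self.le.size:
            f = fbar[self.risk0[self.le], np.arange(self.le.size)]
            ll += float(np.sum(np.log(np.maximum(f, _LOG_FLOOR))))
        # interval censoring: log(Fbar_r(t_R) - Fbar_r(t_L))
        if self.iv.size:
            rk = self.risk0[self.iv]
            idx = np.arange(self.iv.size)
            diff = fbar[rk, self.sl_ivR.start + idx] - fbar[rk, self.sl_ivL.start + idx]
            ll += float(np.sum(np.log(np.maximum(diff, _LOG_FLOOR))))
        return ll

    def penalty(self, params: ModelParameters, lambdas) -> float:
        return float(
            sum(l * params.theta[r] @ self.penalties[r] @ params.theta[r]
                for r, l in enumerate(lambdas))
        )

    def penalized_objective(self, params: ModelParameters, lambdas) -> float:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(lambdas < 0):
            raise ValueError("smoothing parameters must be >= 0")
        return self.log_likelihood(params) - self.penalty(params, lambdas)

    # -- score --------------------------------------------------------------
    def score(self, params: ModelParameters, lambdas, per_subject: bool = False) -> ScoreBundle:
        """Analytic gradient of the penalized objective, plus the MI
        denominators tau_ru and the diagonal beta-step weights V_r."""
        g, n, p = self.g, self.data.n, self.p
        lambdas = np.asarray(lambdas, dtype=float)
        exb, phi_nodes, H_nodes, S_nodes, fbar = self._core(params)
        sub = self.task_subject

        # derivative integrals per task
        wS = self.wts * S_nodes                       # (n_task, V)
        A = np.empty((g, g, self.n_task))             # A[q, r]
        B1 = [np.einsum("tv,tvu->tu", wS, self.psi_nodes[r]) for r in range(g)]
        B2 = np.empty((g, g), dtype=object)
        for q in range(g):
            whS = self.wts * phi_nodes[q] * S_nodes
            for r in range(g):
                A[q, r] = np.einsum("tv,tv->t", whS, 1.0 * (q == r) - H_nodes[r])
                B2[q, r] = np.einsum("tv,tvu->tu", whS, self.Psi_nodes[r])

        c_beta = np.zeros((n, g))      # grad_beta[r] = X' c_beta[:, r]
        v_diag = np.zeros((n, g))
        g_theta_subj = [np.zeros((n, self.m[r])) for r in range(g)]
        tau = [np.zeros(self.m[r]) for r in range(g)]

        # events and right censoring: survival terms -H_r
        if self.h_idx.size:
            for r in range(g):
                Hr = (self.Psi_h[r] @ params.theta[r]) * exb[self.h_idx, r]
                c_beta[self.h_idx, r] -= Hr
                v_diag[self.h_idx, r] += Hr
                contrib = self.Psi_h[r] * exb[self.h_idx, r][:, None]
                g_theta_subj[r][self.h_idx] -= contrib
                tau[r] += contrib.sum(axis=0)
        # events: log-hazard terms
        if self.ev.size:
            rk = self.risk0[self.ev]
            for r in range(g):
                sel = rk == r
                if not np.any(sel):
                    continue
                rows = self.ev[sel]
                c_beta[rows, r] += 1.0
                phi0 = self.psi_ev[r][sel] @ params.theta[r]
                g_theta_subj[r][rows] += self.psi_ev[r][sel] / np.maximum(phi0, _LOG_FLOOR)[:, None]
        # left censoring
        if self.le.size:
            idx = np.arange(self.le.size)
            rk = self.risk0[self.le]
            f = np.maximum(fbar[rk, idx], _LOG_FLOOR)
            for r in range(g):
                Aqr = A[rk, r, idx] / f
                c_beta[self.le, r] += Aqr
                v_diag[self.le, r] += (A[rk, r, idx] / f) ** 2
                b1 = np.where((rk == r)[:, None], B1[r][idx], 0.0)
                b2 = np.stack([B2[q, r][idx] for q in range(g)])[rk, np.arange(idx.size)]
                e = exb[self.le, r][:, None]
                g_theta_subj[r][self.le] += e * (b1 - b2) / f[:, None]
                tau[r] += (e * b2 / f[:, None]).sum(axis=0)
        # interval censoring
        if self.iv.size:
            idx = np.arange(self.iv.size)
            rk = self.risk0[self.iv]
            iL = self.sl_ivL.start + idx
            iR = self.sl_ivR.start + idx
            df = np.maximum(fbar[rk, iR] - fbar[rk, iL], _LOG_FLOOR)
            for r in range(g):
                dA = A[rk, r, iR] - A[rk, r, iL]
                c_beta[self.iv, r] += dA / df
                v_diag[self.iv, r] += (dA / df) ** 2
                sel_r = (rk == r)[:, None]
                b1L = np.where(sel_r, B1[r][iL], 0.0)
                b1R = np.where(sel_r, B1[r][iR], 0.0)
                b2L = np.stack([B2[q, r][iL] for q in range(g)])[rk, idx]
                b2R = np.stack([B2[q, r][iR] for q in range(g)])[rk, idx]
                e = exb[self.iv, r][:, None]
                g_theta_subj[r][self.iv] += e * ((b1R - b2R) - (b1L - b2L)) / df[:, None]
                tau[r] += (e * (b1L + b2R) / df[:, None]).sum(axis=0)

        grad_beta = (self.X.T @ c_beta).T  # (g, p)
        grad_theta = []
        for r in range(g):
            pen_grad = 2.0 * lambdas[r] * (self.penalties[r] @ params.theta[r])
            grad_theta.append(g_theta_subj[r].sum(axis=0) - pen_grad)
            tau[r] += 2.0 * lambdas[r] * np.maximum(self.penalties[r] @ params.theta[r], 0.0)

        per = None
        if per_subject:
            per = np.zeros((n, self.dim))
            for r in range(g):
                pen_grad = 2.0 * lambdas[r] * (self.penalties[r] @ params.theta[r])
                block = g_theta_subj[r] - pen_grad[None, :] / n
                per[:, self.theta_off[r]:self.theta_off[r + 1]] = block
            off = self.theta_off[-1]
            for r in range(g):
                per[:, off + r * p:off + (r + 1) * p] = c_beta[:, r][:, None] * self.X
        return ScoreBundle(grad_beta, grad_theta, tau, v_diag, per)

    # -- derivatives for smoothing / inference ------------------------------
    def score_eta(self, eta: np.ndarray, lambdas) -> np.ndarray:
        params = ModelParameters.unflatten(eta, self.g, self.p, self.m)
        return self.score(params, lambdas).flatten()

    def hessian(self, params: ModelParameters, lambdas, indices=None, step: float = 1e-5):
        """Negative of nothing -- the raw Hessian of the penalized objective,
        by central finite differences of the analytic score.

        ``indices`` restricts to a coordinate subset (e.g. one risk's
        (beta_r, theta_r) block); returned matrix is symmetric.
        """
        eta0 = params.flatten()
        idx = np.arange(eta0.size) if indices is None else np.asarray(indices)
        k = idx.size
        Hmat = np.empty((k, k))
        for col, j in enumerate(idx):
            h = step * (1.0 + abs(eta0[j]))
            ep = eta0.copy(); ep[j] += h
            em = eta0.copy(); em[j] -= h
            # theta may go slightly negative during differencing; evaluate the
            # smooth extension (all formulas are polynomial in theta)
            sp = self._score_unconstrained(ep, lambdas)[idx]
            sm = self._score_unconstrained(em, lambdas)[idx]
            Hmat[:, col] = (sp - sm) / (2.0 * h)
        return 0.5 * (Hmat + Hmat.T)

    def _score_unconstrained(self, eta, lambdas):
        params = ModelParameters.__new__(ModelParameters)
        theta, off = [], 0
        for mr in self.m:
            theta.append(np.asarray(eta[off:off + mr], dtype=float))
            off += mr
        params.beta = np.asarray(eta[off:], dtype=float).reshape(self.g, self.p)
        params.theta = theta
        return self.score(params, lambdas).flatten()

    def block_indices(self, r: int, order: str = "beta_theta") -> np.ndarray:
        """Indices of (beta_r, theta_r) within the flat eta layout."""
        p = self.p
        beta_idx = self.theta_off[-1] + r * p + np.arange(p)
        theta_idx = np.arange(self.theta_off[r], self.theta_off[r + 1])
        if order == "beta_theta":
            return np.concatenate([beta_idx, theta_idx])
        return np.concatenate([theta_idx, beta_idx])
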