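"""M-spline bases for baseline hazards, their I-spline integrals, and the
curvature penalty matrix.

An M-spline of order k is a non-negative piecewise polynomial (degree k-1)
normalized to integrate to one over its support; a non-negative linear
combination h0(t) = sum_u theta_u psi_u(t) is therefore a valid hazard for any
theta >= 0.  The integral of an M-spline is an I-spline: monotone, 0 at the
left boundary and 1 at the right, so the cumulative baseline hazard
H0(t) = sum_u theta_u Psi_u(t) is available in closed form -- no numeric
integration of the hazard is ever needed.

M-splines are scaled B-splines: with the clamped knot vector kv and the
conventional B-splines B_u (which sum to one), psi_u = k * B_u / (kv[u+k] -
kv[u]).  Evaluation goes through scipy's B-spline machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .quadrature import gauss_legendre_rule

__all__ = ["MSplineBasis", "PenaltyMatrix", "place_knots"]


@dataclass(frozen=True)
class PenaltyMatrix:
    """Roughness penalty R with R[u, v] = integral of psi_u'' psi_v''."""

    R: np.ndarray

    def quadratic_form(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        return float(theta @ self.R @ theta)


@dataclass(frozen=True)
class MSplineBasis:
    """Order-k M-spline basis on [boundary[0], boundary[1]].

    The number of basis functions is ``len(interior_knots) + order``.
    Outside the support every psi_u is 0 and Psi_u is clamped to 0 (left)
    or 1 (right).
    """

    order: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]
    _scales: np.ndarray = field(init=False, repr=False)
    _knot_vector: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        a, b = self.boundary
        if not b > a:
            raise ValueError("boundary must satisfy a < b")
        interior = np.asarray(self.interior_knots, dtype=float)
        if interior.size and (
            np.any(np.diff(interior) <= 0) or interior[0] <= a or interior[-1] >= b
        ):
            raise ValueError("interior knots must be strictly increasing inside the boundary")
        object.__setattr__(self, "interior_knots", interior)
        kv = np.concatenate([np.full(self.order, a), interior, np.full(self.order, b)])
        object.__setattr__(self, "_knot_vector", kv)
        k = self.order
        scales = k / (kv[k:] - kv[:-k])
        object.__setattr__(self, "_scales", scales)

    @property
    def m(self) -> int:
        """Number of basis functions."""
        return self.interior_knots.size + self.order

    @property
    def degree(self) -> int:
        return self.order - 1

    def _clip(self, t: np.ndarray, warn: bool = False) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a, b = self.boundary
        if warn and (np.any(t < a) or np.any(t > b)):
            warnings.warn("times outside the basis support were clamped", stacklevel=3)
        return np.clip(t, a, b)

    def eval_basis(self, t) -> np.ndarray:
        """M-spline values psi_u(t); shape (len(t), m). Zero outside support."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a, b = self.boundary
        inside = (t >= a) & (t <= b)
        out = np.zeros((t.size, self.m))
        if np.any(inside):
            dm = BSpline.design_matrix(
                np.clip(t[inside], a, b), self._knot_vector, self.degree
            ).toarray()
            out[inside] = dm * self._scales[None, :]
        return out

    def eval_cumulative(self, t) -> np.ndarray:
        """I-spline values Psi_u(t); shape (len(t), m), in [0, 1], monotone."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tc = self._clip(t)
        out = np.empty((t.size, self.m))
        for u, bu in enumerate(self._basis_elements()):
            anti = bu.antiderivative()
            out[:, u] = self._scales[u] * (anti(tc) - anti(self.boundary[0]))
        np.clip(out, 0.0, 1.0, out=out)
        return out

    def eval_deriv2(self, t) -> np.ndarray:
        """Second derivatives psi_u''(t); shape (len(t), m)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((t.size, self.m))
        if self.order < 3:
            return out
        for u, bu in enumerate(self._basis_elements()):
            out[:, u] = self._scales[u] * bu.derivative(2)(t)
        return out

    def _basis_elements(self):
        for u in range(self.m):
            c = np.zeros(self.m)
            c[u] = 1.0
            yield BSpline(self._knot_vector, c, self.degree, extrapolate=False)

    def penalty_matrix(self) -> PenaltyMatrix:
        """Exact curvature penalty R[u,v] = int psi_u'' psi_v'' dt.

        Computed span-by-span with a Gauss-Legendre rule exact for the
        piecewise-polynomial integrand (degree <= 2(order-3)); orders < 3
        have vanishing second derivatives and give R = 0.
        """
        m = self.m
        if self.order < 3:
            warnings.warn("order < 3: curvature penalty is identically zero", stacklevel=2)
            return PenaltyMatrix(R=np.zeros((m, m)))
        spans = np.unique(
            np.concatenate([[self.boundary[0]], self.interior_knots, [self.boundary[1]]])
        )
        npts = max(self.order - 2, 1)  # integrand degree 2(k-3) needs ceil((2k-5)/2)+1 pts
        rule = gauss_legendre_rule(npts)
        R = np.zeros((m, m))
        for lo, hi in zip(spans[:-1], spans[1:]):
            half = (hi - lo) / 2.0
            nodes = half * (rule.nodes + 1.0) + lo
            w = half * rule.weights
            D = self.eval_deriv2(nodes)  # (npts, m)
            R += (D * w[:, None]).T @ D
        return PenaltyMatrix(R=0.5 * (R + R.T))

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "interior_knots": self.interior_knots.tolist(),
            "boundary": list(self.boundary),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MSplineBasis":
        return cls(
            order=int(d["order"]),
            interior_knots=np.asarray(d["interior_knots"], dtype=float),
            boundary=(float(d["boundary"][0]), float(d["boundary"][1])),
        )


def default_basis_size(n: int, order: int = 4, cap: int = 15) -> int:
    """Default number of basis functions: max(order, round(n^(1/3))), capped."""
    return min(max(order, int(round(n ** (1.0 / 3.0)))), cap)


def place_knots(dataset, risk: int | None = None, m: int | None = None, order: int = 4) -> MSplineBasis:
    """Build an M-spline basis with interior knots at quantiles of proxy times.

    Proxy times summarize where the data carry information about the hazard:
    exact event times, midpoints of (left- and interval-) censoring intervals,
    and the censoring times of right-censored subjects.  The boundary is
    [0, max finite observed time].  ``risk`` selects the per-risk size only;
    the proxy-time pool is shared across risks.
    """
    proxies = dataset.proxy_times()
    if m is None:
        m = default_basis_size(dataset.n, order=order)
    if m < order:
        raise ValueError(f"m={m} must be at least the spline order {order}")
    upper = float(dataset.max_finite_time())
    n_interior = m - order
    if n_interior == 0:
        interior = np.empty(0)
    else:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(proxies, qs)
        interior = np.unique(interior[(interior > 0) & (interior < upper)])
        if interior.size < n_interior:
            warnings.warn(
                "fewer distinct proxy-time quantiles than interior knots; "
                "falling back to equally spaced knots",
                stacklevel=2,
            )
            interior = np.linspace(0, upper, n_interior + 2)[1:-1]
    return MSplineBasis(order=order, interior_knots=interior, boundary=(0.0, upper))
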