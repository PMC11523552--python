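"""Gauss-Legendre quadrature rules and the integral contract used throughout.

Every integral in the model -- cumulative incidence functions and their
derivative integrals A, B1, B2 -- is a one-dimensional integral over [0, t]
of a smooth product of spline hazards and exponentiated cumulative hazards.
A fixed-order Legendre-Gauss rule, affinely mapped to [0, t], evaluates all
of them; the node locations depend only on the upper limit, so basis-function
values at the mapped nodes can be cached once per dataset and reused across
optimizer iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuadratureRule", "gauss_legendre_rule", "integrate", "DEFAULT_QUADRATURE_POINTS"]

DEFAULT_QUADRATURE_POINTS = 30

_RULE_CACHE: dict[int, "QuadratureRule"] = {}


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes and weights of a Legendre-Gauss rule on [-1, 1].

    Integrates polynomials of degree <= 2V - 1 exactly; weights sum to 2.
    """

    nodes: np.ndarray
    weights: np.ndarray

    @property
    def n_points(self) -> int:
        return self.nodes.size

    def mapped(self, upper: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Affine map of the rule to [0, b] for each upper limit b.

        Parameters
        ----------
        upper : array of shape (k,)
            Finite, non-negative upper limits.

        Returns
        -------
        nodes, weights : arrays of shape (k, V)
        """
        upper = np.atleast_1d(np.asarray(upper, dtype=float))
        if np.any(upper < 0) or not np.all(np.isfinite(upper)):
            raise ValueError("upper limits must be finite and >= 0")
        half = upper[:, None] / 2.0
        return half * (self.nodes[None, :] + 1.0), half * self.weights[None, :]


def gauss_legendre_rule(n_points: int = DEFAULT_QUADRATURE_POINTS) -> QuadratureRule:
    """Return the (cached) V-point Legendre-Gauss rule on [-1, 1]."""
    if n_points < 1:
        raise ValueError("a quadrature rule needs at least one point")
    rule = _RULE_CACHE.get(n_points)
    if rule is None:
        x, w = np.polynomial.legendre.leggauss(n_points)
        rule = QuadratureRule(nodes=x, weights=w)
        _RULE_CACHE[n_points] = rule
    return rule


def integrate(f, b: float, rule: QuadratureRule | None = None) -> float:
    """Approximate the integral of ``f`` over [0, b] with a Legendre-Gauss rule.

    ``f`` must accept a vector of abscissae and return a vector of values.
    """
    if b < 0:
        raise ValueError("upper limit must be >= 0")
    if b == 0:
        return 0.0
    if rule is None:
        rule = gauss_legendre_rule()
    nodes, weights = rule.mapped(np.array([b]))
    return float(np.dot(weights[0], np.asarray(f(nodes[0]), dtype=float)))
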