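"""Model / Results interface for penalized cause-specific hazard Cox fits.

``CompetingRisksMPL`` is constructed from a :class:`~cshmpl.data.CompetingRisksData`
(or a DataFrame via :meth:`CompetingRisksMPL.from_dataframe`) and owns the
spline bases and the cached likelihood workspace.  ``fit`` maximizes the
penalized log-likelihood -- with automatic marginal-likelihood smoothing
selection by default, or at fixed smoothing values -- and returns an
:class:`MPLResults` carrying estimates, the active-constraint sandwich
covariance, smoothing diagnostics, Wald tables and prediction helpers.

Example
-------
>>> from cshmpl import CompetingRisksMPL, study_preset, simulate_dataset
>>> data = simulate_dataset(study_preset(1, "balanced", n=200), seed=7)
>>> res = CompetingRisksMPL(data).fit()
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .data import CompetingRisksData
from .inference import CovarianceResult, sandwich_covariance, wald_table
from .likelihood import LikelihoodWorkspace, ModelParameters
from .optimizer import OptimizerControls, fit_fixed_smoothing
from .prediction import default_grid, predict_curves
from .quadrature import DEFAULT_QUADRATURE_POINTS
from .smoothing import SmoothingState, fit_auto
from .splines import MSplineBasis, place_knots

__all__ = ["CompetingRisksMPL", "MPLResults"]


class CompetingRisksMPL:
    """Cause-specific hazard Cox model with M-spline baselines, fitted by
    constrained maximum penalized likelihood.

    Parameters
    ----------
    data : CompetingRisksData
        Partly interval-censored competing-risks data.
    n_basis : int or sequence of int, optional
        Number of M-spline basis functions per risk; default
        max(order, round(n^(1/3))) capped at 15.
    order : int
        M-spline order (k = 4: cubic pieces, the minimum with a nonvanishing
        curvature penalty).
    quadrature_points : int
        Gauss-Legendre nodes per CIF integral.
    bases : sequence of MSplineBasis, optional
        Pre-built bases override ``n_basis``/``order``.
    """

    def __init__(self, data: CompetingRisksData, n_basis=None, order: int = 4,
                 quadrature_points: int = DEFAULT_QUADRATURE_POINTS, bases=None):
        self.data = data
        if bases is None:
            if n_basis is None or np.isscalar(n_basis):
                n_basis = [n_basis] * data.g
            bases = [place_knots(data, risk=r + 1, m=n_basis[r], order=order)
                     for r in range(data.g)]
        self.bases = list(bases)
        self.workspace = LikelihoodWorkspace(data, self.bases, n_quad=quadrature_points)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates=None, n_risks=None, **kwargs):
        """Build the model from a DataFrame with columns
        id, t_left, t_right, status, risk and covariate columns."""
        data = CompetingRisksData.from_frame(df, covariates=covariates, n_risks=n_risks)
        return cls(data, **kwargs)

    def fit(self, lambdas=None, sigma2_init=50.0, controls: OptimizerControls | None = None,
            start: ModelParameters | None = None, outer_max: int = 20,
            compute_covariance: bool = True) -> "MPLResults":
        """Fit the model.

        ``lambdas=None`` (default) selects the smoothing values automatically
        by Laplace-approximate marginal likelihood; a sequence of fixed
        lambda_r skips the outer loop entirely.
        """
        ws = self.workspace
        if lambdas is None:
            state, smooth = fit_auto(ws, init=start, sigma2_init=sigma2_init,
                                     controls=controls, outer_max=outer_max)
            lambdas = smooth.lambdas
        else:
            lambdas = np.broadcast_to(np.asarray(lambdas, dtype=float), (self.data.g,)).copy()
            state = fit_fixed_smoothing(ws, lambdas, init=start, controls=controls)
            smooth = SmoothingState(
                sigma2=1.0 / (2.0 * np.maximum(lambdas, 1e-300)),
                nu=np.full(self.data.g, np.nan),
                d=np.array([int(a.sum()) for a in state.active]),
                outer_iterations=0, stabilized=True,
            )
        cov = sandwich_covariance(ws, state, lambdas) if compute_covariance else None
        return MPLResults(self, state, smooth, lambdas, cov)


class MPLResults:
    """Estimates, uncertainties and diagnostics of a fitted MPL model."""

    def __init__(self, model: CompetingRisksMPL, state, smooth: SmoothingState,
                 lambdas, cov: CovarianceResult | None):
        self.model = model
        self.state = state
        self.smooth = smooth
        self.lambdas = np.asarray(lambdas, dtype=float)
        self.covariance = cov

    # -- primary quantities --------------------------------------------------
    @property
    def params(self) -> ModelParameters:
        return self.state.params

    @property
    def beta(self) -> np.ndarray:
        return self.state.params.beta

    @property
    def theta(self) -> list[np.ndarray]:
        return self.state.params.theta

    @property
    def se_beta(self) -> np.ndarray:
        if self.covariance is None:
            raise ValueError("covariance was not computed")
        return self.covariance.se_beta

    @property
    def converged(self) -> bool:
        return self.state.converged

    @property
    def loglik(self) -> float:
        return self.model.workspace.log_likelihood(self.state.params)

    @property
    def phi(self) -> float:
        return self.state.phi

    @property
    def active_counts(self) -> np.ndarray:
        return np.array([int(a.sum()) for a in self.state.active])

    def wald_table(self) -> pd.DataFrame:
        return wald_table(self.beta, self.se_beta, names=self.model.data.covariate_names)

    def summary(self) -> str:
        data = self.model.data
        counts = data.status_counts()
        lines = [
            "Cause-specific hazard Cox model, maximum penalized likelihood",
            "=" * 72,
            f"subjects: {data.n}   risks: {data.g}   covariates: {data.p}",
            "censoring: " + ", ".join(f"{k}={v}" for k, v in counts.items()),
            f"log-likelihood: {self.loglik:.4f}   penalized objective: {self.phi:.4f}",
            "smoothing lambda: " + ", ".join(f"{l:.4g}" for l in self.lambdas)
            + "   effective df: " + ", ".join(f"{v:.2f}" for v in self.smooth.nu),
            f"active spline coefficients: {self.active_counts.tolist()}"
            + f"   converged: {self.converged} ({self.state.iterations} iterations)",
            "-" * 72,
        ]
        tab = self.wald_table()
        with pd.option_context("display.float_format", "{:8.4f}".format):
            lines.append(tab[["risk", "covariate", "coef", "HR", "se(coef)",
                              "z", "p", "ci_low", "ci_high"]].to_string(index=False))
        return "\n".join(lines)

    # -- prediction ----------------------------------------------------------
    def predict_curves(self, X=None, grid=None, bands: bool = True):
        """Baseline/profile hazard, cumulative hazard, CIF and survival curves.

        ``X=None`` evaluates at the zero covariate profile (baseline curves).
        """
        if X is None:
            X = np.zeros(self.model.data.p)
        if grid is None:
            grid = default_grid(self.model.data)
        cov = self.covariance.cov if (bands and self.covariance is not None) else None
        return predict_curves(self.params, self.model.bases, X, grid, cov=cov,
                              rule=self.model.workspace.rule)

    def plot_baseline_hazard(self, ax=None, risks=None):
        """Baseline hazard curves with 95% bands (requires matplotlib)."""
        import matplotlib.pyplot as plt

        curves = self.predict_curves()
        if ax is None:
            _, ax = plt.subplots()
        risks = range(self.model.data.g) if risks is None else risks
        for r in risks:
            ax.plot(curves.time, curves.hazard[r], label=f"risk {r + 1}")
            if curves.hazard_bands is not None:
                ax.fill_between(curves.time, curves.hazard_bands[0][r],
                                curves.hazard_bands[1][r], alpha=0.2)
        ax.set_xlabel("time")
        ax.set_ylabel("baseline hazard")
        ax.legend()
        return ax

    # -- serialization -------------------------------------------------------
    def run_summary(self) -> dict:
        return {
            "converged": bool(self.converged),
            "iterations": int(self.state.iterations),
            "loglik": float(self.loglik),
            "penalized_objective": float(self.phi),
            "lambdas": self.lambdas.tolist(),
            "effective_df": [float(v) for v in self.smooth.nu],
            "outer_iterations": int(self.smooth.outer_iterations),
            "df_stabilized": bool(self.smooth.stabilized),
            "active_counts": self.active_counts.tolist(),
            "kkt": {
                "beta": self.state.kkt.max_beta,
                "theta_free": self.state.kkt.max_theta_free,
                "theta_active": self.state.kkt.max_theta_active,
            },
            "bases": [b.to_dict() for b in self.model.bases],
            "beta": self.beta.tolist(),
            "theta": [t.tolist() for t in self.theta],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.run_summary(), fh, indent=2)
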