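"""Weibull competing-risks data generator, the midpoint-Cox comparator, and
the Monte-Carlo evaluation harness.

The generator draws two-risk survival data with Weibull cause-specific
baseline hazards h_0r(t) = lambda_r rho_r t^(rho_r - 1) and Cox covariate
effects.  An all-cause event time T is inverted from

    S(t | X) = exp( - sum_r lambda_r t^rho_r exp(X' beta_r) )

(closed form when the shapes are equal, monotone root-finding otherwise);
the risk label is drawn with probability p_r = h_r(T) / h(T).  Censoring is
then imposed: with probability pi_E the time is observed exactly; otherwise
two scaled uniforms gamma_L*U_L <= gamma_R*U_R (with U_R ~ unif(U_L, 1))
bracket the time into an interval, truncate it to left censoring, or cut it
off as right censoring.  Widening the (gamma_L, gamma_R) pair widens the
intervals and shifts mass from right censoring to interval censoring.

The midpoint-Cox comparator mimics common practice: each censoring interval
is replaced by its midpoint (a left-censored time by half its value) and a
standard right-censored Cox partial-likelihood model is fitted per risk with
all other risks right-censored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import CompetingRisksData

__all__ = [
    "ScenarioSpec", "study_preset", "simulate_dataset",
    "midpoint_transform", "midpoint_cox_fit", "run_study", "MetricsTable",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """Simulation-study configuration (two competing risks)."""

    scale: tuple        # Weibull scales lambda_r
    shape: tuple        # Weibull shapes rho_r
    beta: tuple         # true coefficient vectors, one per risk
    covariate_laws: tuple = ("normal", "normal")   # "normal" or "bernoulli"
    pi_event: float = 0.05
    gamma_left: float = 0.5
    gamma_right: float = 0.91
    n: int = 200

    def __post_init__(self):
        if not (0 < self.pi_event <= 1):
            raise ValueError("pi_event must lie in (0, 1]")
        if self.gamma_left > self.gamma_right:
            raise ValueError("gamma_left must be <= gamma_right")
        if any(s <= 0 for s in self.scale) or any(s <= 0 for s in self.shape):
            raise ValueError("Weibull scale and shape parameters must be > 0")

    @property
    def g(self) -> int:
        return len(self.scale)

    @property
    def p(self) -> int:
        return len(self.beta[0])

    @property
    def true_beta(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


# gamma pairs printed for the two censoring mixes of each study:
# "balanced" ~ 47.5% right / 47.5% interval+left; "heavy_interval" ~ 20% / 75%
_GAMMAS = {
    (1, "balanced"): (0.5, 0.91),
    (1, "heavy_interval"): (0.5, 1.34),
    (2, "balanced"): (0.5, 1.47),
    (2, "heavy_interval"): (0.5, 1.64),
    (3, "balanced"): (0.5, 0.74),
    (3, "heavy_interval"): (0.5, 1.27),
}


def study_preset(study: int, mix: str = "balanced", n: int = 200) -> ScenarioSpec:
    """Presets for the three simulation studies and two censoring mixes."""
    mix = mix.replace("-", "_")
    if (study, mix) not in _GAMMAS:
        raise ValueError(f"unknown preset: study={study}, mix={mix!r}")
    gL, gR = _GAMMAS[(study, mix)]
    if study == 1:
        spec = ScenarioSpec(scale=(1.0, 0.5), shape=(3.0, 3.0),
                            beta=((-1.0, 0.5), (1.0, -0.5)))
    elif study == 2:
        spec = ScenarioSpec(scale=(1.0, 0.5), shape=(3.0, 3.0),
                            beta=((1.0, 0.5), (0.5, 0.5)))
    else:
        spec = ScenarioSpec(scale=(1.0, 0.5), shape=(2.0, 2.0),
                            beta=((-1.0, 0.5), (1.0, -0.5)),
                            covariate_laws=("normal", "bernoulli"))
    return replace(spec, gamma_left=gL, gamma_right=gR, n=n)


def _draw_covariates(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for law in spec.covariate_laws:
        if law == "normal":
            cols.append(rng.standard_normal(spec.n))
        elif law == "bernoulli":
            cols.append(rng.binomial(1, 0.5, spec.n).astype(float))
        else:
            raise ValueError(f"unknown covariate law {law!r}")
    return np.column_stack(cols)


def _invert_event_times(spec: ScenarioSpec, X: np.ndarray, rng: np.random.Generator):
    """Draw T from S(t|X) = exp(-sum_r lambda_r t^rho_r e^{X'beta_r})."""
    rates = np.stack([
        spec.scale[r] * np.exp(X @ np.asarray(spec.beta[r])) for r in range(spec.g)
    ])  # (g, n)
    target = -np.log(rng.uniform(size=spec.n))  # total cumulative hazard at T
    shapes = np.asarray(spec.shape, dtype=float)
    if np.all(shapes == shapes[0]):
        return (target / rates.sum(axis=0)) ** (1.0 / shapes[0]), rates
    upper = 10.0 * max(spec.scale) + 10.0
    T = np.empty(spec.n)
    for i in range(spec.n):
        f = lambda t: float(np.sum(rates[:, i] * t ** shapes)) - target[i]
        hi = upper
        while f(hi) < 0:
            hi *= 2.0
        T[i] = brentq(f, 0.0, hi)
    return T, rates


def simulate_dataset(spec: ScenarioSpec, seed) -> CompetingRisksData:
    """Generate one partly interval-censored competing-risks dataset."""
    rng = np.random.default_rng(seed)
    X = _draw_covariates(spec, rng)
    T, rates = _invert_event_times(spec, X, rng)

    # risk membership from the hazard ratio at the realized time
    shapes = np.asarray(spec.shape, dtype=float)
    haz = rates * shapes[:, None] * T[None, :] ** (shapes[:, None] - 1.0)
    p1 = haz[0] / haz.sum(axis=0)
    risk = np.where(rng.uniform(size=spec.n) < p1, 1, 2)

    u_e = rng.uniform(size=spec.n)
    u_l = rng.uniform(size=spec.n)
    u_r = rng.uniform(low=u_l, high=1.0)
    lo = spec.gamma_left * u_l
    hi = spec.gamma_right * u_r

    status = np.empty(spec.n, dtype=object)
    t_left = np.empty(spec.n)
    t_right = np.empty(spec.n)
    is_event = u_e < spec.pi_event
    is_interval = ~is_event & (lo <= T) & (T <= hi)
    is_left = ~is_event & (T < lo)
    is_right = ~is_event & (hi < T)

    status[is_event] = "event"
    t_left[is_event] = t_right[is_event] = T[is_event]
    status[is_interval] = "interval"
    t_left[is_interval] = lo[is_interval]
    t_right[is_interval] = hi[is_interval]
    status[is_left] = "left"
    t_left[is_left] = 0.0
    t_right[is_left] = lo[is_left]
    status[is_right] = "right"
    t_left[is_right] = hi[is_right]
    t_right[is_right] = np.inf
    risk = np.where(is_right, 0, risk)

    return CompetingRisksData(
        t_left=t_left, t_right=t_right, status=status, risk=risk, X=X,
        n_risks=spec.g, validate=False,
    )


# ---------------------------------------------------------------------------
# Midpoint-Cox comparator
# ---------------------------------------------------------------------------

def midpoint_transform(data: CompetingRisksData) -> list[pd.DataFrame]:
    """Collapse intervals to midpoints and split into per-risk right-censored
    datasets: interval (tL, tR) -> event at (tL+tR)/2; left (0, tR) -> event
    at tR/2; for risk r's dataset, events of other risks become right
    censorings at their (transformed) times."""
    t = np.where(
        data.status == "event", data.t_left,
        np.where(data.status == "left", data.t_right / 2.0,
                 np.where(data.status == "interval",
                          0.5 * (data.t_left + data.t_right), data.t_left)),
    )
    frames = []
    for r in range(1, data.g + 1):
        ev = (data.status != "right") & (data.risk == r)
        df = pd.DataFrame({"time": t, "event": ev.astype(int)})
        for j, name in enumerate(data.covariate_names):
            df[name] = data.X[:, j]
        frames.append(df)
    return frames


def midpoint_cox_fit(frames: list[pd.DataFrame], covariates=None):
    """Standard Cox partial-likelihood fits on midpoint-transformed data.

    Returns (beta_hat, se) arrays of shape (g, p); delegated to lifelines.
    """
    from lifelines import CoxPHFitter

    betas, ses = [], []
    for df in frames:
        if df["event"].sum() < 1:
            raise ValueError("a per-risk dataset has no events")
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        betas.append(cph.params_.to_numpy())
        ses.append(cph.standard_errors_.to_numpy())
    return np.asarray(betas), np.asarray(ses)


# ---------------------------------------------------------------------------
# Monte-Carlo harness
# ---------------------------------------------------------------------------

@dataclass
class MetricsTable:
    """Per-coefficient bias, mean asymptotic SE, Monte-Carlo SD and 95%
    Wald coverage, plus the raw per-replicate estimates."""

    spec: ScenarioSpec
    method: str
    estimates: np.ndarray   # (reps, g, p)
    ses: np.ndarray         # (reps, g, p)
    n_failed: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def bias(self) -> np.ndarray:
        return self.estimates.mean(axis=0) - self.spec.true_beta

    @property
    def std_asymp(self) -> np.ndarray:
        return self.ses.mean(axis=0)

    @property
    def std_mc(self) -> np.ndarray:
        return self.estimates.std(axis=0, ddof=1)

    @property
    def cov_prob(self) -> np.ndarray:
        z = 1.959963984540054
        truth = self.spec.true_beta[None, :, :]
        lo = self.estimates - z * self.ses
        hi = self.estimates + z * self.ses
        return ((lo <= truth) & (truth <= hi)).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        g, p = self.spec.g, self.spec.p
        for metric, arr in (("bias", self.bias), ("std_asymp", self.std_asymp),
                            ("std_mc", self.std_mc), ("cov_prob", self.cov_prob)):
            row = {"method": self.method, "metric": metric}
            for r in range(g):
                for j in range(p):
                    row[f"beta{r + 1}{j + 1}"] = arr[r, j]
            rows.append(row)
        return pd.DataFrame(rows)


def replicate_seeds(master_seed, replicates: int) -> list[np.random.SeedSequence]:
    """Counter-based per-replicate seed streams from one master seed."""
    return [np.random.SeedSequence(entropy=int(master_seed), spawn_key=(k,))
            for k in range(replicates)]


def run_study(spec: ScenarioSpec, method: str = "mpl", replicates: int = 200,
              seed=0, fit_kwargs: dict | None = None,
              estimator=None, collect=None) -> MetricsTable:
    """Run a Monte-Carlo experiment and tabulate bias / SEs / coverage.

    ``method`` is "mpl" (penalized-likelihood fit with automatic smoothing)
    or "midpoint_cox"; a custom ``estimator(data) -> (beta, se)`` may be
    supplied for testing.  Replicate-level failures are logged, excluded and
    counted.  ``collect(result)`` may harvest extra per-replicate output (MPL
    only); its returns are stored in ``extras['collected']``.
    """
    fit_kwargs = dict(fit_kwargs or {})
    if estimator is None:
        if method == "midpoint_cox":
            estimator = lambda d: midpoint_cox_fit(midpoint_transform(d))
        elif method == "mpl":
            from .model import CompetingRisksMPL

            model_kwargs = fit_kwargs.pop("model", {})

            def estimator(d):
                res = CompetingRisksMPL(d, **model_kwargs).fit(**fit_kwargs)
                out = (res.params.beta, res.se_beta)
                if collect is not None:
                    collected.append(collect(res))
                return out
        else:
            raise ValueError(f"unknown method {method!r}")
    collected: list = []
    est, ses = [], []
    failed = 0
    for ss in replicate_seeds(seed, replicates):
        data = simulate_dataset(spec, ss)
        try:
            b, s = estimator(data)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failed += 1
            logger.warning("replicate failed (%s); excluded", exc)
            continue
        est.append(np.asarray(b, dtype=float))
        ses.append(np.asarray(s, dtype=float))
    if not est:
        raise RuntimeError("every replicate failed")
    table = MetricsTable(
        spec=spec, method=method,
        estimates=np.stack(est), ses=np.stack(ses), n_failed=failed,
    )
    if collected:
        table.extras["collected"] = collected
    return table
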