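"""Partly interval-censored competing-risks data.

Each subject carries a censoring interval [t_left, t_right], a censoring-type
status and, unless right-censored, the label of the risk that caused the
event:

* ``event``    -- exact observation, t_left == t_right (finite);
* ``left``     -- event before t_right, t_left == 0;
* ``interval`` -- event inside (t_left, t_right), both finite;
* ``right``    -- no event by t_left, t_right == +inf, no risk label.

Exactly one status holds per subject, and every non-right-censored subject is
linked to exactly one of the g competing risks.  The on-disk format is plain
CSV with columns ``id, t_left, t_right, status, risk, <covariates...>``;
a missing/NA/"inf" t_right denotes right censoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Subject", "CompetingRisksData", "read_dataset", "write_dataset", "STATUSES"]

STATUSES = ("event", "left", "interval", "right")

# width below this fraction of the time scale collapses an interval to an event
_ZERO_WIDTH_FRAC = 1e-12


@dataclass(frozen=True)
class Subject:
    """A single observation; ``risk`` is 1-based and None for right censoring."""

    t_left: float
    t_right: float
    status: str
    risk: int | None
    covariates: np.ndarray

    def __eq__(self, other):
        return (
            isinstance(other, Subject)
            and self.status == other.status
            and self.risk == other.risk
            and math.isclose(self.t_left, other.t_left, rel_tol=0, abs_tol=1e-12)
            and (
                (math.isinf(self.t_right) and math.isinf(other.t_right))
                or math.isclose(self.t_right, other.t_right, rel_tol=0, abs_tol=1e-12)
            )
            and np.allclose(self.covariates, other.covariates, atol=1e-12)
        )


class CompetingRisksData:
    """Column-oriented container for partly interval-censored competing risks.

    Parameters
    ----------
    t_left, t_right : float arrays, shape (n,)
        Interval endpoints; t_right is +inf for right-censored subjects.
    status : array of str, shape (n,)
        One of ``event``, ``left``, ``interval``, ``right``.
    risk : int array, shape (n,)
        1-based risk labels; 0 for right-censored subjects.
    X : float array, shape (n, p)
    covariate_names : list of str, optional
    n_risks : int, optional
        Number of competing risks g (defaults to max observed label).
    """

    def __init__(self, t_left, t_right, status, risk, X, covariate_names=None,
                 n_risks=None, ids=None, validate=True, coerce_zero_width=True):
        self.t_left = np.asarray(t_left, dtype=float)
        self.t_right = np.asarray(t_right, dtype=float)
        self.status = np.asarray(status, dtype=object)
        self.risk = np.asarray(risk, dtype=int)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.t_left.size and self.X.shape[1] == self.t_left.size:
            self.X = self.X.T
        n = self.t_left.size
        if ids is None:
            ids = np.arange(1, n + 1)
        self.ids = np.asarray(ids)
        if covariate_names is None:
            covariate_names = [f"x{j + 1}" for j in range(self.X.shape[1])]
        self.covariate_names = list(covariate_names)
        self.n_risks = int(n_risks) if n_risks is not None else int(self.risk.max(initial=0))
        if coerce_zero_width:
            self._coerce_zero_width()
        if validate:
            problems = self.validate()
            if problems:
                raise ValueError(
                    "invalid dataset:\n  " + "\n  ".join(problems[:20])
                    + ("" if len(problems) <= 20 else f"\n  ... {len(problems) - 20} more")
                )

    # -- basic shape --------------------------------------------------------
    @property
    def n(self) -> int:
        return self.t_left.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def g(self) -> int:
        return self.n_risks

    def _coerce_zero_width(self):
        scale = self.max_finite_time()
        width = self.t_right - self.t_left
        mask = (self.status == "interval") & (
            np.abs(width) < _ZERO_WIDTH_FRAC * max(scale, 1.0)
        )
        if np.any(mask):
            warnings.warn(
                f"{int(mask.sum())} zero-width censoring interval(s) coerced to events",
                stacklevel=3,
            )
            self.status[mask] = "event"
            self.t_right[mask] = self.t_left[mask]

    def max_finite_time(self) -> float:
        finite = np.concatenate(
            [self.t_left[np.isfinite(self.t_left)], self.t_right[np.isfinite(self.t_right)]]
        )
        return float(finite.max()) if finite.size else 0.0

    def proxy_times(self) -> np.ndarray:
        """One representative time per subject: exact times, interval/left
        midpoints, and right-censoring times."""
        t = np.where(
            self.status == "event",
            self.t_left,
            np.where(
                self.status == "right",
                self.t_left,
                0.5 * (self.t_left + np.where(np.isfinite(self.t_right), self.t_right, 0.0)),
            ),
        )
        return t.astype(float)

    def status_counts(self) -> dict:
        return {s: int(np.sum(self.status == s)) for s in STATUSES}

    # -- validation ---------------------------------------------------------
    def validate(self) -> list[str]:
        """Return human-readable descriptions of every violated invariant."""
        problems: list[str] = []
        n = self.n
        if self.t_right.size != n or self.status.size != n or self.risk.size != n:
            problems.append("column lengths differ")
            return problems
        if self.X.shape[0] != n:
            problems.append(f"covariate matrix has {self.X.shape[0]} rows, expected {n}")
            return problems
        if not np.all(np.isfinite(self.X)):
            problems.append("non-finite covariate values present")
        for i in range(n):
            st, tl, tr, rk = self.status[i], self.t_left[i], self.t_right[i], self.risk[i]
            row = f"row {self.ids[i]}"
            if st not in STATUSES:
                problems.append(f"{row}: unknown status {st!r} (accepted: {', '.join(STATUSES)})")
                continue
            if not np.isfinite(tl) or tl < 0:
                problems.append(f"{row}: t_left must be finite and >= 0")
                continue
            if st == "event":
                if not (np.isfinite(tr) and tr == tl):
                    problems.append(f"{row}: event requires t_left == t_right (finite)")
            elif st == "left":
                if tl != 0:
                    problems.append(f"{row}: left censoring requires t_left == 0")
                if not (np.isfinite(tr) and tr > 0):
                    problems.append(f"{row}: left censoring requires finite t_right > 0")
            elif st == "interval":
                if not (np.isfinite(tr) and 0 < tl < tr):
                    problems.append(f"{row}: interval censoring requires 0 < t_left < t_right < inf")
            elif st == "right":
                if np.isfinite(tr):
                    problems.append(f"{row}: right censoring requires t_right == +inf")
                if tl <= 0:
                    problems.append(f"{row}: right censoring requires t_left > 0")
                if rk != 0:
                    problems.append(f"{row}: right-censored subject must not carry a risk label")
            if st != "right" and not (1 <= rk <= self.n_risks):
                problems.append(f"{row}: risk label {rk} outside 1..{self.n_risks}")
        for r in range(1, self.n_risks + 1):
            if not np.any((self.risk == r) & (self.status != "right")):
                problems.append(
                    f"risk {r} has no non-right-censored subject; its baseline hazard "
                    "is unidentified"
                )
        return problems

    # -- conversion ---------------------------------------------------------
    def subjects(self) -> list[Subject]:
        out = []
        for i in range(self.n):
            out.append(
                Subject(
                    t_left=float(self.t_left[i]),
                    t_right=float(self.t_right[i]),
                    status=str(self.status[i]),
                    risk=None if self.status[i] == "right" else int(self.risk[i]),
                    covariates=self.X[i].copy(),
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "t_left": self.t_left,
                "t_right": [
                    "" if not np.isfinite(v) else v for v in self.t_right
                ],
                "status": self.status,
                "risk": ["" if s == "right" else int(r) for s, r in zip(self.status, self.risk)],
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates=None, n_risks=None, validate=True):
        """Build a dataset from a DataFrame with the standard columns."""
        required = {"t_left", "t_right", "status", "risk"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(sorted(missing))}")
        if covariates is None:
            reserved = {"id", "t_left", "t_right", "status", "risk"}
            covariates = [c for c in df.columns if c not in reserved]
        status = df["status"].astype(str).str.strip().str.lower().to_numpy(dtype=object)
        tr_raw = df["t_right"]
        tr = pd.to_numeric(
            tr_raw.replace(
                {"": np.nan, "NA": np.nan, "Inf": np.inf, "inf": np.inf, "INF": np.inf}
            ),
            errors="coerce",
        ).to_numpy(dtype=float)
        tr = np.where(np.isnan(tr), np.inf, tr)
        risk = pd.to_numeric(df["risk"], errors="coerce").fillna(0).astype(int).to_numpy()
        risk = np.where(status == "right", 0, risk)
        return cls(
            t_left=pd.to_numeric(df["t_left"], errors="coerce").to_numpy(dtype=float),
            t_right=tr,
            status=status,
            risk=risk,
            X=df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0)),
            covariate_names=covariates,
            n_risks=n_risks,
            ids=df["id"].to_numpy() if "id" in df.columns else None,
            validate=validate,
        )

    def __eq__(self, other):
        if not isinstance(other, CompetingRisksData):
            return NotImplemented
        return (
            self.n == other.n
            and self.g == other.g
            and self.covariate_names == other.covariate_names
            and np.allclose(self.t_left, other.t_left, atol=1e-12)
            and np.array_equal(np.isfinite(self.t_right), np.isfinite(other.t_right))
            and np.allclose(
                self.t_right[np.isfinite(self.t_right)],
                other.t_right[np.isfinite(other.t_right)],
                atol=1e-12,
            )
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.risk, other.risk)
            and np.allclose(self.X, other.X, atol=1e-12)
        )


def read_dataset(path, covariates=None, n_risks=None) -> CompetingRisksData:
    """Read a dataset from CSV (columns id,t_left,t_right,status,risk,...)."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    try:
        return CompetingRisksData.from_frame(df, covariates=covariates, n_risks=n_risks)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_dataset(data: CompetingRisksData, path) -> None:
    """Write a dataset to CSV; +inf t_right is serialized as an empty field."""
    data.to_frame().to_csv(path, index=False)
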