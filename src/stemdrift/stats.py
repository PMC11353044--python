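"""Statistical layer: exact 2x2 Fisher tests and GLM regressions of mutational load.

The scientific question these serve: does mutational burden in serially
passaged stem-cell lines grow because mutations *accumulate* (load increases
with sampling rank — Poisson log-linear regression of counts) or because the
*rate* of mutagenesis rises with time in culture (probability of acquiring a
new event at a passage increases — binary logistic regression)?  The 2x2
Fisher tests compare categorical proportions, e.g. de-novo-SNV carriage in
karyotypically normal vs abnormal samples.

Fisher's exact test uses the two-sided "sum of tables no more probable than
the observed one" convention, computed in log space over the hypergeometric
support.  GLMs are fit by iteratively reweighted least squares with Wald
two-sided p-values on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, norm

__all__ = [
    "Table2x2",
    "RegressionResult",
    "fisher_exact_2x2",
    "poisson_load_regression",
    "logistic_acquisition_regression",
    "refit_without_outliers",
]

#: relative slack when comparing table probabilities to the observed one
_FISHER_SLACK = 1e-12


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table entries must be non-negative")
        if self.n == 0:
            raise ValueError("all-zero 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "Table2x2":
        (a, b), (c, d) = rows
        return cls(a, b, c, d)


def _log_hypergeom_pmf(k: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(n, r1, c1) (fixed margins)."""
    return (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(n - r1 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(table: Table2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums the conditional hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's (within a 1e-12 relative slack).  Returns a value in (0, 1].
    """
    if not isinstance(table, Table2x2):
        table = Table2x2.from_rows(table)
    r1 = table.a + table.b
    c1 = table.a + table.c
    n = table.n
    k_min = max(0, r1 + c1 - n)
    k_max = min(r1, c1)
    k = np.arange(k_min, k_max + 1)
    logp = _log_hypergeom_pmf(k, r1, c1, n)
    logp_obs = _log_hypergeom_pmf(np.array([table.a]), r1, c1, n)[0]
    keep = logp <= logp_obs + np.log1p(_FISHER_SLACK)
    # log-sum-exp of the kept tables
    m = logp[keep].max()
    p = float(np.exp(m) * np.exp(logp[keep] - m).sum())
    return min(p, 1.0)


@dataclass
class RegressionResult:
    """Slope inference from a single-predictor GLM fit."""

    model: Literal["poisson_loglinear", "binary_logistic"]
    predictor: str
    slope: float
    se: float
    p: float
    n: int
    intercept: float = 0.0
    excluded_points: list = field(default_factory=list)

    @property
    def ci95(self) -> tuple[float, float]:
        z = 1.959963984540054
        return (self.slope - z * self.se, self.slope + z * self.se)


def _irls(
    x: np.ndarray,
    y: np.ndarray,
    family: Literal["poisson", "logistic"],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a canonical-link GLM with intercept + one covariate by IRLS.

    Returns (beta, covariance, deviance).  Raises on non-convergence with
    the iteration trace embedded in the message.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    if family == "poisson":
        beta[0] = np.log(max(y.mean(), 1e-8))

    def _mu_w(eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            return mu, mu
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        return mu, mu * (1.0 - mu)

    def _deviance(eta: np.ndarray) -> float:
        mu, _ = _mu_w(eta)
        if family == "poisson":
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            return float(2.0 * np.sum(term - (y - mu)))
        eps = 1e-12
        return float(-2.0 * np.sum(y * np.log(mu + eps)
                                   + (1 - y) * np.log(1 - mu + eps)))

    dev = _deviance(X @ beta)
    trace: list[float] = []
    for _ in range(max_iter):
        eta = X @ beta
        mu, w = _mu_w(eta)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        XtW = X.T * w
        new_beta = np.linalg.solve(XtW @ X, XtW @ z)
        # step-halving guard against oscillation on quasi-separated data
        full_step = new_beta - beta
        step_scale = 1.0
        new_dev = _deviance(X @ new_beta)
        for _ in range(30):
            if new_dev <= dev + 1e-12:
                break
            step_scale /= 2.0
            new_beta = beta + step_scale * full_step
            new_dev = _deviance(X @ new_beta)
        step = float(np.max(np.abs(new_beta - beta)))
        dev_change = abs(dev - new_dev)
        trace.append(dev_change)
        beta = new_beta
        dev = new_dev
        # deviance-change convergence (GLM-software standard); covers
        # quasi-separated data where the coefficient drifts but the fit
        # no longer improves
        if step < tol or dev_change < tol * (abs(dev) + 0.1):
            _, w_final = _mu_w(X @ beta)
            XtW = X.T * np.maximum(w_final, 1e-12)
            cov = np.linalg.inv(XtW @ X)
            return beta, cov, dev
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations; "
        f"deviance-change trace tail: {[f'{s:.3g}' for s in trace[-5:]]}"
    )


def _null_deviance(y: np.ndarray, family: str) -> float:
    ybar = float(y.mean())
    if family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / max(ybar, 1e-300)), 0.0)
        return float(2.0 * np.sum(term))
    eps = 1e-12
    return float(-2.0 * np.sum(y * np.log(ybar + eps)
                               + (1 - y) * np.log(1 - ybar + eps)))


def _make_result(
    model: Literal["poisson_loglinear", "binary_logistic"],
    predictor: str,
    beta: np.ndarray,
    cov: np.ndarray,
    n: int,
    p_method: str = "wald",
    deviance: float | None = None,
    null_deviance: float | None = None,
) -> RegressionResult:
    slope = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    if p_method == "lrt":
        lr = max(null_deviance - deviance, 0.0)
        p = float(chi2.sf(lr, df=1))
    elif se == 0.0:
        p = 1.0
    else:
        p = float(2.0 * norm.sf(abs(slope / se)))
    return RegressionResult(
        model=model,
        predictor=predictor,
        slope=slope,
        se=se,
        p=max(min(p, 1.0), np.nextafter(0.0, 1.0)),
        n=n,
        intercept=float(beta[0]),
    )


def _as_xy(points: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be a sequence of (predictor, response) pairs")
    return arr[:, 0], arr[:, 1]


def poisson_load_regression(
    points: Sequence[tuple[float, int]],
    predictor: str = "rank",
    p_method: Literal["wald", "lrt"] = "wald",
) -> RegressionResult:
    """Fit ``log E[count] = b0 + b1 * x`` and test H0: b1 = 0.

    *points* are (predictor value, mutation count) pairs, one per sample;
    a positive significant slope means later samples carry a higher load.
    The default p-value is the Wald test on the slope; ``p_method="lrt"``
    selects the likelihood-ratio test, which stays informative when low
    predictor levels have all-zero counts (quasi-separation, where the
    Wald statistic collapses).
    """
    x, y = _as_xy(points)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if np.all(y == 0):
        raise ValueError("all counts are zero; Poisson model is degenerate")
    beta, cov, dev = _irls(x, y, "poisson")
    return _make_result("poisson_loglinear", predictor, beta, cov, len(x),
                        p_method, dev, _null_deviance(y, "poisson"))


def _perfectly_separated(x: np.ndarray, y: np.ndarray) -> bool:
    x0, x1 = x[y == 0], x[y == 1]
    return x0.max() < x1.min() or x1.max() < x0.min()


def logistic_acquisition_regression(
    points: Sequence[tuple[float, int]],
    predictor: str = "passage",
    p_method: Literal["wald", "lrt"] = "wald",
) -> RegressionResult:
    """Fit ``logit P(event) = b0 + b1 * x`` and test H0: b1 = 0 (Wald).

    *points* are (predictor value, event in {0,1}) pairs; a null slope means
    the per-passage acquisition rate does not change with time in culture.
    """
    x, y = _as_xy(points)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("events must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both event classes must be present")
    if _perfectly_separated(x, y):
        raise ValueError(
            "perfect separation: event classes are fully split by the "
            "predictor; the MLE does not exist"
        )
    beta, cov, dev = _irls(x, y, "logistic")
    return _make_result("binary_logistic", predictor, beta, cov, len(x),
                        p_method, dev, _null_deviance(y, "logistic"))


def refit_without_outliers(
    points: Sequence[tuple[float, float]],
    exclude: Callable[[tuple[float, float]], bool],
    model: Literal["poisson_loglinear", "binary_logistic"] = "poisson_loglinear",
    predictor: str = "passage",
) -> RegressionResult:
    """Re-run a regression with points matching *exclude* removed.

    The excluded points are recorded on the result so a report can state
    exactly which samples were treated as outliers.
    """
    points = list(points)
    kept = [p for p in points if not exclude(p)]
    excluded = [p for p in points if exclude(p)]
    if len(kept) < 3:
        raise ValueError("fewer than 3 points survive exclusion")
    fit = (
        poisson_load_regression(kept, predictor=predictor)
        if model == "poisson_loglinear"
        else logistic_acquisition_regression(kept, predictor=predictor)
    )
    fit.excluded_points = excluded
    return fit
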