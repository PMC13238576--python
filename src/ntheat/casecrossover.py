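"""Space-time-stratified case-crossover regression via conditional Poisson.

Daily counts y_i within a stratum s (region x year x month x day-of-week) are
compared against each other; conditioning on the stratum total eliminates the
stratum intercept, leaving the conditional log-likelihood

    l(beta) = sum_s [ sum_{i in s} y_i x_i' beta
                      - (sum_{i in s} y_i) * log sum_{i in s} exp(x_i' beta) ]

which is the multinomial-logit likelihood of allocating each stratum's events
across its days.  It is maximized by Newton iterations from beta = 0 with
step halving.  Overdispersion is absorbed quasi-likelihood style: a Pearson
dispersion factor phi scales the inverse observed information, with degrees
of freedom charged for both the regression parameters and the implicitly
estimated stratum intercepts.

Covariates are the heatwave exposure level (reference: no heatwave; columns
for low and for severe/extreme), a public-holiday indicator and daily PM2.5.
Strata with zero total count or with no within-stratum covariate variation
carry no information under conditioning and are dropped (and counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

EXPOSURE_COLUMNS = ["hw_low", "hw_severe_extreme"]


class ConvergenceError(RuntimeError):
    """Newton iterations failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict] | None = None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(RuntimeError):
    """A covariate (near-)perfectly predicts counts within strata."""


@dataclass
class DesignMatrix:
    """Rows are stratum-days, grouped by stratum, with the response attached."""

    X: np.ndarray
    y: np.ndarray
    strata: np.ndarray  # integer codes, non-decreasing
    columns: list[str]
    n_strata_used: int
    n_strata_dropped_zero: int
    n_strata_dropped_invariant: int
    n_rows_dropped_missing: int = 0


@dataclass
class FitResult:
    """Conditional quasi-Poisson fit: coefficients, scaled covariance, rate ratios."""

    columns: list[str]
    beta: np.ndarray
    cov: np.ndarray
    dispersion: float
    n_rows: int
    n_strata_used: int
    n_strata_dropped_zero: int
    n_strata_dropped_invariant: int
    n_rows_dropped_missing: int
    n_iter: int
    loglik: float
    trace: list[dict] = field(default_factory=list, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.beta)

    def ci(self, z: float = Z_95) -> tuple[np.ndarray, np.ndarray]:
        return np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se)

    def to_dict(self) -> dict:
        lo, hi = self.ci()
        return {
            "terms": self.columns,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "rr": self.rr.tolist(),
            "ci_low": lo.tolist(),
            "ci_high": hi.tolist(),
            "dispersion": self.dispersion,
            "n_rows": self.n_rows,
            "n_strata_used": self.n_strata_used,
            "n_strata_dropped_zero": self.n_strata_dropped_zero,
            "n_strata_dropped_invariant": self.n_strata_dropped_invariant,
            "n_rows_dropped_missing": self.n_rows_dropped_missing,
        }


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(stratum_days: pd.DataFrame, use_pm25: bool = True) -> DesignMatrix:
    """Design matrix from zero-filled stratum-day rows.

    Exposure is coded as two indicators against a no-heatwave reference.
    With ``use_pm25=False`` the PM2.5 column is omitted entirely (the
    sensitivity analysis); otherwise rows with missing PM2.5 are excluded
    from their stratum and counted.
    """
    if len(stratum_days) == 0:
        raise ValueError("no stratum-days supplied")
    df = stratum_days
    n_missing = 0
    if use_pm25:
        ok = df["pm25_ugm3"].notna()
        n_missing = int((~ok).sum())
        if n_missing:
            log.info("build_design: %d row(s) with missing PM2.5 excluded", n_missing)
        df = df.loc[ok]
    level = df["exposure_level"].astype(str)
    cols = {
        "hw_low": (level == "low").to_numpy(float),
        "hw_severe_extreme": (level == "severe_extreme").to_numpy(float),
        "holiday": df["holiday"].to_numpy(float),
    }
    if use_pm25:
        cols["pm25"] = df["pm25_ugm3"].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    y = df["count"].to_numpy(float)
    key = pd.MultiIndex.from_arrays(
        [df["region_id"], df["year"], df["month"], df["dow"]]
    )
    codes, _ = pd.factorize(key, sort=True)
    order = np.argsort(codes, kind="stable")
    return _filter_design(
        X[order], y[order], codes[order], list(cols.keys()), n_missing
    )


def _filter_design(X, y, strata, columns, n_missing=0) -> DesignMatrix:
    """Drop zero-total and covariate-invariant strata (rows sorted by stratum)."""
    starts = np.flatnonzero(np.r_[True, np.diff(strata) != 0])
    totals = np.add.reduceat(y, starts)
    colmax = np.vstack([np.maximum.reduceat(X[:, j], starts) for j in range(X.shape[1])]).T
    colmin = np.vstack([np.minimum.reduceat(X[:, j], starts) for j in range(X.shape[1])]).T
    varies = (colmax - colmin > 0).any(axis=1)
    keep = (totals > 0) & varies
    n_zero = int((totals <= 0).sum())
    n_invariant = int((~varies & (totals > 0)).sum())
    keep_rows = np.repeat(keep, np.diff(np.r_[starts, len(y)]))
    Xk, yk, sk = X[keep_rows], y[keep_rows], strata[keep_rows]
    sk = pd.factorize(sk)[0]  # recode to dense, order preserved
    # a column with no within-stratum variation anywhere is unidentifiable
    # under conditioning (e.g. no holidays in the analysis span): drop it
    if len(yk):
        k_starts = _stratum_starts(sk)
        spread = np.vstack(
            [
                np.maximum.reduceat(Xk[:, j], k_starts)
                - np.minimum.reduceat(Xk[:, j], k_starts)
                for j in range(Xk.shape[1])
            ]
        )
        active = spread.max(axis=1) > 0
        if not active.all():
            dropped = [c for c, a in zip(columns, active) if not a]
            log.info("dropping covariate(s) with no within-stratum variation: %s", dropped)
            Xk = Xk[:, active]
            columns = [c for c, a in zip(columns, active) if a]
    return DesignMatrix(
        X=Xk,
        y=yk,
        strata=sk,
        columns=columns,
        n_strata_used=int(keep.sum()),
        n_strata_dropped_zero=n_zero,
        n_strata_dropped_invariant=n_invariant,
        n_rows_dropped_missing=n_missing,
    )


# ---------------------------------------------------------------------------
# Conditional Poisson Newton fit
# ---------------------------------------------------------------------------

def _stratum_starts(strata: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.r_[True, np.diff(strata) != 0])


def _loglik_parts(X, y, strata, starts, beta):
    """Conditional log-likelihood, fitted means and per-stratum event totals."""
    eta = X @ beta
    # per-stratum log-sum-exp for numerical stability
    seg_max = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - seg_max[strata])
    S = np.add.reduceat(w, starts)
    p = w / S[strata]
    Y = np.add.reduceat(y, starts)
    mu = Y[strata] * p
    ll = float(y @ eta - Y @ (np.log(S) + seg_max))
    return ll, mu, p, Y


def fit_conditional_poisson(
    design: DesignMatrix,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
) -> FitResult:
    """Maximize the conditional log-likelihood by Newton iterations from beta = 0.

    Convergence when the score's max absolute entry drops below ``score_tol``
    or the Newton step below ``step_tol``.  Step halving guards against
    likelihood decreases.  Raises SeparationError when the information matrix
    is numerically singular (a column perfectly predicting counts within
    strata) and ConvergenceError, carrying the iteration trace, otherwise.
    """
    X, y, strata = design.X, design.y, design.strata
    if design.n_strata_used < 1:
        raise ValueError("no usable strata after filtering")
    n, p = X.shape
    starts = _stratum_starts(strata)
    beta = np.zeros(p)
    ll, mu, prob, Y = _loglik_parts(X, y, strata, starts, beta)
    trace: list[dict] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score = X.T @ (y - mu)
        # observed information: sum_s Y_s * Cov_p(x) over stratum days
        B = np.vstack(
            [np.add.reduceat(prob * X[:, j], starts) for j in range(p)]
        ).T  # (n_strata, p): per-stratum mean covariate under p
        H = X.T @ (mu[:, None] * X) - (Y[:, None] * B).T @ B
        try:
            cond = np.linalg.cond(H)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            worst = design.columns[int(np.argmin(np.diag(H)))]
            raise SeparationError(
                f"information matrix singular; column {worst!r} appears separated "
                "or collinear within strata"
            )
        step = np.linalg.solve(H, score)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        # step halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, mu_new, prob_new, _ = _loglik_parts(X, y, strata, starts, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, mu, prob = cand, ll_new, mu_new, prob_new
        trace.append(
            {"iter": n_iter, "loglik": ll, "max_score": float(np.max(np.abs(score))),
             "step_norm": float(np.linalg.norm(scale * step))}
        )
        if np.linalg.norm(scale * step) < step_tol:
            converged = True
            break
    if not converged:
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
    if not converged:
        raise ConvergenceError(
            f"conditional Poisson fit did not converge in {max_iter} iterations",
            trace,
        )
    if np.max(np.abs(beta)) > 15:
        worst = design.columns[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"column {worst!r} drifts to an unbounded estimate; it perfectly "
            "predicts counts within strata (separation)"
        )
    # final information matrix at the optimum
    score = X.T @ (y - mu)
    B = np.vstack([np.add.reduceat(prob * X[:, j], starts) for j in range(p)]).T
    H = X.T @ (mu[:, None] * X) - (Y[:, None] * B).T @ B
    try:
        phi = estimate_dispersion(design, mu)
    except ValueError as err:
        # saturated design: beta remains valid, covariance left unscaled
        log.warning("dispersion unavailable (%s); covariance left unscaled", err)
        phi = float("nan")
    cov = np.linalg.inv(H) * (1.0 if np.isnan(phi) else phi)
    cov = (cov + cov.T) / 2.0
    return FitResult(
        columns=design.columns,
        beta=beta,
        cov=cov,
        dispersion=phi,
        n_rows=n,
        n_strata_used=design.n_strata_used,
        n_strata_dropped_zero=design.n_strata_dropped_zero,
        n_strata_dropped_invariant=design.n_strata_dropped_invariant,
        n_rows_dropped_missing=design.n_rows_dropped_missing,
        n_iter=n_iter,
        loglik=ll,
        trace=trace,
    )


def estimate_dispersion(design: DesignMatrix, fitted_mu: np.ndarray) -> float:
    """Pearson dispersion phi = sum (y - mu)^2 / mu over used rows / residual df.

    Degrees of freedom subtract both the p regression parameters and the
    number of conditioned-out strata (their intercepts are estimated
    implicitly).  No floor at 1 is applied.
    """
    n, p = design.X.shape
    df = n - p - design.n_strata_used
    if df <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")
    mu = fitted_mu
    if (mu <= 0).any():
        raise ValueError("fitted means must be positive for Pearson dispersion")
    pearson = float(np.sum((design.y - mu) ** 2 / mu))
    return pearson / df


def dispersion_band(df: int, level: float = 0.95) -> tuple[float, float]:
    """Theoretical band for the Pearson dispersion of exactly-Poisson data.

    Approximates phi*df ~ chi-square(df); returns the central ``level`` band
    for phi.
    """
    a = (1 - level) / 2
    return stats.chi2.ppf(a, df) / df, stats.chi2.ppf(1 - a, df) / df


# ---------------------------------------------------------------------------
# Reporting of rate ratios
# ---------------------------------------------------------------------------

def summarize_rr(fit: FitResult, percent: bool = True) -> pd.DataFrame:
    """Per-term rate ratios with 95% Wald CIs and percent changes.

    RR formatted to 3 decimals, percent change (RR - 1)*100 to 1 decimal.
    """
    lo, hi = fit.ci()
    rows = pd.DataFrame(
        {
            "term": fit.columns,
            "beta": fit.beta,
            "se": fit.se,
            "rr": np.round(fit.rr, 3),
            "ci_low": np.round(lo, 3),
            "ci_high": np.round(hi, 3),
        }
    )
    if percent:
        rows["pct_change"] = np.round((fit.rr - 1.0) * 100.0, 1)
    return rows


def fit_stratum_days(
    stratum_days: pd.DataFrame, use_pm25: bool = True, **kwargs
) -> FitResult:
    """Convenience: build the design and fit in one call."""
    return fit_conditional_poisson(build_design(stratum_days, use_pm25=use_pm25), **kwargs)
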