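"""Maximum-likelihood logistic regression (Newton/IRLS) and adjusted odds ratios.

Implemented from scratch on the Bernoulli log-likelihood with step-halving;
the covariance of the estimates is the inverse observed information at the
optimum, giving Wald intervals for the exposure coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import Z_95, EffectEstimate, wald_estimate

SEX_LEVELS = ("male", "female")
AGE_LEVELS = ("20s", "30s", "40s", "50s", "60-65")
JOB_LEVELS = ("regular", "managerial", "board", "non_regular", "self_employed")

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "age_class": AGE_LEVELS,
    "job_class": JOB_LEVELS,
}
BINARY_COVARIATES = ("night_shift", "marital")

DEFAULT_COVARIATES = (
    "sex", "age_class", "job_class", "night_shift", "marital", "baseline_score",
)


class ModelError(ValueError):
    """Raised for malformed design matrices or model specifications."""


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails and the caller asked for strictness."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one adjusted model.

    ``exposure_term`` names a boolean column of the analysis frame (one of the
    exposure definitions).  ``baseline_score`` refers to the same instrument as
    the outcome and is entered as a continuous column by default; set
    ``baseline_as_caseness`` to adjust for the dichotomy instead.
    """

    outcome: str                       # "cesd_case" | "psqi_poor"
    exposure_term: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    reference_levels: dict = field(default_factory=dict)
    baseline_as_caseness: bool = False

    BASELINE_COLUMNS = {"cesd_case": "cesd_total_w1", "psqi_poor": "psqi_global_w1"}
    BASELINE_CUTOFFS = {"cesd_case": 16, "psqi_poor": 6}

    def baseline_column(self) -> str:
        try:
            return self.BASELINE_COLUMNS[self.outcome]
        except KeyError:
            raise ModelError(f"unknown outcome {self.outcome!r}") from None


def encode_design(
    frame: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build the design matrix, response vector and column names.

    Categorical covariates are dummy coded dropping the reference level (the
    first listed level unless overridden); the baseline instrument score enters
    as one continuous column; an intercept column comes first and the exposure
    indicator second, so the exposure coefficient is always at index 1.
    """
    n = len(frame)
    if n == 0:
        raise ModelError("empty analysis set")
    required = [spec.outcome, spec.exposure_term]
    for col in required:
        if col not in frame.columns:
            raise ModelError(f"missing column {col!r}")
        if frame[col].isna().any():
            bad = frame.index[frame[col].isna()][0]
            raise ModelError(f"missing {col!r} for participant {bad!r}")

    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    columns.append(frame[spec.exposure_term].to_numpy(dtype=float))
    names.append(spec.exposure_term)

    for cov in spec.covariates:
        if cov == "baseline_score":
            col = spec.baseline_column()
            if col not in frame.columns:
                raise ModelError(f"missing column {col!r}")
            if frame[col].isna().any():
                bad = frame.index[frame[col].isna()][0]
                raise ModelError(f"missing {col!r} for participant {bad!r}")
            values = frame[col].to_numpy(dtype=float)
            if spec.baseline_as_caseness:
                values = (values >= spec.BASELINE_CUTOFFS[spec.outcome]).astype(float)
                names.append(f"{col}_case")
            else:
                names.append(col)
            columns.append(values)
        elif cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            reference = spec.reference_levels.get(cov, levels[0])
            if reference not in levels:
                raise ModelError(f"unknown reference level {reference!r} for {cov!r}")
            observed = frame[cov].astype(str)
            unseen = set(observed.unique()) - set(levels)
            if unseen:
                raise ModelError(f"unseen {cov!r} level(s): {sorted(unseen)}")
            for level in levels:
                if level == reference:
                    continue
                columns.append((observed == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
        elif cov in BINARY_COVARIATES:
            columns.append(frame[cov].to_numpy(dtype=float))
            names.append(cov)
        else:
            raise ModelError(f"unknown covariate {cov!r}")

    X = np.column_stack(columns)
    y = frame[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ModelError("response must be binary 0/1")
    return X, y, names


@dataclass
class FitResult:
    coefficients: np.ndarray
    covariance: np.ndarray
    names: list[str]
    converged: bool
    iterations: int
    log_likelihood: float
    separation_suspected: bool = False

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(math.sqrt(self.covariance[i, i]))


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FitResult:
    """Newton-Raphson MLE with step-halving on likelihood decreases.

    Convergence when the largest score component is below ``tol`` or the
    relative log-likelihood change is below ``tol``.  Rank-deficient designs
    raise; suspected complete separation is flagged, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ModelError(f"design matrix is rank deficient; collinear column(s): {bad}")

    beta = np.zeros(k)
    ll = _log_likelihood(X, y, beta)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        if np.abs(score).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the likelihood monotone
        new_ll = _log_likelihood(X, y, beta + step)
        halvings = 0
        while new_ll < ll and halvings < 50:
            step /= 2.0
            new_ll = _log_likelihood(X, y, beta + step)
            halvings += 1
        beta = beta + step
        if abs(new_ll - ll) < tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    try:
        covariance = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        covariance = np.full((k, k), np.nan)
    separation = bool(np.abs(beta).max() > 30.0 or w.min() < 1e-12)
    return FitResult(
        coefficients=beta,
        covariance=covariance,
        names=list(names),
        converged=converged,
        iterations=iterations,
        log_likelihood=_log_likelihood(X, y, beta),
        separation_suspected=separation,
    )


def adjusted_or(
    frame: pd.DataFrame,
    spec: ModelSpec,
    z: float = Z_95,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[EffectEstimate, FitResult]:
    """Fit the adjusted model and return the exposure odds ratio with Wald CI."""
    X, y, names = encode_design(frame, spec)
    fit = fit_logistic(X, y, names=names, max_iter=max_iter, tol=tol)
    if not fit.converged:
        raise ConvergenceError(
            f"logistic fit for {spec.exposure_term} vs {spec.outcome} did not "
            f"converge in {max_iter} iterations"
        )
    log_or = fit.coef(spec.exposure_term)
    se = fit.se(spec.exposure_term)
    estimate = wald_estimate(
        log_or, se, z=z, method="adjusted_wald",
        exposure_label=spec.exposure_term, outcome_label=spec.outcome,
    )
    return estimate, fit
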