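"""Per-marker logistic regression via Newton-Raphson/IRLS with Cholesky solves.

The fitting strategy mirrors how fast GWAS implementations organise the work:

* one *covariate-only* fit per phenotype, run to full convergence, whose
  coefficients warm-start every marker fit for that phenotype;
* per-marker Newton iterations starting from (warm coefficients, 0 for the
  marker term), with the normal equations solved by Cholesky factorization
  (QR fallback when the factorization fails);
* Wald chi-square statistics ``z2 = (beta_g / se)**2`` with 1-df upper-tail
  p-values.

Degenerate fits (monomorphic markers, markers collinear with a covariate,
complete separation) are reported with ``status`` set and ``p = 1`` so that
downstream rankings remain total orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, special, stats

__all__ = [
    "RegressionDesign",
    "FitState",
    "AssociationResult",
    "fit_covariate_only",
    "newton_step",
    "fit_marker",
    "chisq1_p",
]

#: default convergence tolerance on the max absolute coefficient change
DEFAULT_TOL: float = 1e-8
#: default Newton iteration cap
DEFAULT_MAX_ITER: int = 25
#: intercept magnitude reported for a completely separated (all-0/all-1) response
SEPARATION_BOUND: float = 35.0

STATUS_OK = "ok"
STATUS_SEPARATION = "separation"
STATUS_SINGULAR = "singular"
STATUS_MAX_ITER = "max_iter"


@dataclass
class RegressionDesign:
    """A response, a covariate block with leading intercept, and optionally a marker.

    ``covariates`` is N x (C+1) with the first column all ones; ``marker`` is a
    length-N dosage vector or None for covariate-only fits.
    """

    y: np.ndarray
    covariates: np.ndarray
    marker: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
        if self.covariates.shape[0] != self.y.size:
            raise ValueError("covariates and y disagree on N")
        if self.marker is not None:
            self.marker = np.asarray(self.marker, dtype=np.float64).ravel()
            if self.marker.size != self.y.size:
                raise ValueError("marker and y disagree on N")
        bad = ~np.isin(self.y, (0.0, 1.0))
        if bad.any():
            raise ValueError(f"{bad.sum()} response values outside {{0,1}}")

    @property
    def n(self) -> int:
        return self.y.size

    def matrix(self) -> np.ndarray:
        if self.marker is None:
            return self.covariates
        return np.column_stack([self.covariates, self.marker])


@dataclass
class FitState:
    """Converged (or terminated) coefficients of one logistic fit."""

    beta: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    status: str = STATUS_OK


@dataclass
class AssociationResult:
    """Marker association statistics for one marker x phenotype pair."""

    marker_index: int
    phenotype_index: int
    beta_g: float
    se: float
    z2: float
    p: float
    n_used: int
    iterations: int
    converged: bool
    status: str = STATUS_OK


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum_i [ y_i * eta_i - log(1 + exp(eta_i)) ], computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _solve_spd(H: np.ndarray, g: np.ndarray, ridge: float) -> np.ndarray:
    """Solve H x = g for symmetric positive-definite H.

    Cholesky first; on failure, one ridge retry (if enabled) and finally a QR
    solve.  Raises ``numpy.linalg.LinAlgError`` if all routes fail.
    """
    try:
        c, low = linalg.cho_factor(H, check_finite=False)
        return linalg.cho_solve((c, low), g, check_finite=False)
    except linalg.LinAlgError:
        pass
    if ridge > 0.0:
        try:
            Hj = H + ridge * np.eye(H.shape[0])
            c, low = linalg.cho_factor(Hj, check_finite=False)
            return linalg.cho_solve((c, low), g, check_finite=False)
        except linalg.LinAlgError:
            pass
    # QR on the symmetric system; rank-deficiency surfaces as non-finite or
    # an exception, both mapped to LinAlgError by the caller's guard
    q, r = np.linalg.qr(H)
    with np.errstate(divide="raise", invalid="raise"):
        try:
            x = linalg.solve_triangular(r, q.T @ g, check_finite=False)
        except (FloatingPointError, linalg.LinAlgError) as exc:
            raise np.linalg.LinAlgError(str(exc)) from exc
    if not np.all(np.isfinite(x)):
        raise np.linalg.LinAlgError("singular normal equations")
    return x


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray,
    tol: float,
    max_iter: int,
    ridge: float = 0.0,
) -> FitState:
    beta = np.array(beta0, dtype=np.float64)
    converged = False
    status = STATUS_OK
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            delta = _solve_spd(H, g, ridge)
        except np.linalg.LinAlgError:
            status = STATUS_SINGULAR
            break
        beta += delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged and status == STATUS_OK:
        status = STATUS_MAX_ITER
    return FitState(
        beta=beta,
        loglik=_loglik(X @ beta, y),
        iterations=it,
        converged=converged,
        status=STATUS_OK if converged else status,
    )


def fit_covariate_only(
    y: np.ndarray,
    covariates: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    ridge: float = 0.0,
) -> FitState:
    """Fit y on the intercept + covariate block to full convergence.

    The returned coefficients are the warm start shared by every marker fit
    for this phenotype.  An all-0 or all-1 response yields ``separation``
    status with the intercept pinned at +-SEPARATION_BOUND; a rank-deficient
    covariate block yields ``singular`` status.
    """
    design = RegressionDesign(y=y, covariates=covariates)
    X, yv = design.covariates, design.y
    k = X.shape[1]
    if yv.size < k + 1:
        raise ValueError(f"N={yv.size} too small for {k} coefficients")
    ones = yv.sum()
    if ones == 0 or ones == yv.size:
        beta = np.zeros(k)
        beta[0] = SEPARATION_BOUND if ones else -SEPARATION_BOUND
        return FitState(
            beta=beta,
            loglik=_loglik(X @ beta, yv),
            iterations=0,
            converged=False,
            status=STATUS_SEPARATION,
        )
    if np.linalg.matrix_rank(X) < k:
        return FitState(
            beta=np.zeros(k),
            loglik=_loglik(np.zeros(yv.size), yv),
            iterations=0,
            converged=False,
            status=STATUS_SINGULAR,
        )
    return _irls(X, yv, np.zeros(k), tol, max_iter, ridge)


def newton_step(
    design: RegressionDesign, beta: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, float]:
    """One Newton/IRLS update ``beta' = beta + (X'WX)^-1 X'(y - mu)``.

    Returns the updated coefficients and the max absolute coefficient change.
    The linear system is solved by Cholesky factorization with a QR fallback.
    """
    beta = np.asarray(beta, dtype=np.float64)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    X, y = design.matrix(), design.y
    mu = special.expit(X @ beta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    delta = _solve_spd(H, X.T @ (y - mu), ridge)
    beta_next = beta + delta
    return beta_next, float(np.max(np.abs(delta)))


def _degenerate_result(
    marker_index: int, phenotype_index: int, n: int, status: str
) -> AssociationResult:
    # p = 1 by convention so rankings over all markers stay total
    return AssociationResult(
        marker_index=marker_index,
        phenotype_index=phenotype_index,
        beta_g=0.0,
        se=np.nan,
        z2=0.0,
        p=1.0,
        n_used=n,
        iterations=0,
        converged=False,
        status=status,
    )


def fit_marker(
    design: RegressionDesign,
    warm: FitState,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    ridge: float = 0.0,
    marker_index: int = 0,
    phenotype_index: int = 0,
) -> AssociationResult:
    """Fit one marker's additive logistic model and report Wald statistics.

    Starts Newton iterations at (warm covariate coefficients, 0 for the
    marker term).  The marker standard error is the square root of the marker
    diagonal of ``(X'WX)^-1`` at the final coefficients.  Non-convergence
    still reports statistics (with ``converged=False``); monomorphic or
    collinear markers report ``singular`` status with ``p = 1``.
    """
    if design.marker is None:
        raise ValueError("design has no marker attached")
    g, y, Xc = design.marker, design.y, design.covariates
    n = design.n
    if np.ptp(g) == 0.0:
        return _degenerate_result(marker_index, phenotype_index, n, STATUS_SINGULAR)
    # a marker lying exactly in the covariate span makes X'WX singular by
    # construction; catch it here rather than relying on factorization failure
    coef, *_ = np.linalg.lstsq(Xc, g, rcond=None)
    resid = g - Xc @ coef
    if resid @ resid <= 1e-12 * max(float(g @ g), 1.0):
        return _degenerate_result(marker_index, phenotype_index, n, STATUS_SINGULAR)

    X = design.matrix()
    beta0 = np.append(warm.beta, 0.0)
    fit = _irls(X, y, beta0, tol, max_iter, ridge)
    if fit.status == STATUS_SINGULAR:
        return _degenerate_result(marker_index, phenotype_index, n, STATUS_SINGULAR)

    mu = special.expit(X @ fit.beta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    ek = np.zeros(X.shape[1])
    ek[-1] = 1.0
    try:
        var_g = float(_solve_spd(H, ek, ridge)[-1])
    except np.linalg.LinAlgError:
        return _degenerate_result(marker_index, phenotype_index, n, STATUS_SINGULAR)
    if var_g <= 0.0 or not np.isfinite(var_g):
        return _degenerate_result(marker_index, phenotype_index, n, STATUS_SINGULAR)

    beta_g = float(fit.beta[-1])
    se = float(np.sqrt(var_g))
    z2 = (beta_g / se) ** 2
    return AssociationResult(
        marker_index=marker_index,
        phenotype_index=phenotype_index,
        beta_g=beta_g,
        se=se,
        z2=z2,
        p=float(chisq1_p(z2)),
        n_used=n,
        iterations=fit.iterations,
        converged=fit.converged,
        status=fit.status,
    )


def chisq1_p(z2):
    """Upper-tail probability of a chi-square(1) variate.

    Accepts scalars or arrays.  The tail is computed on a survival-function
    path that stays accurate far beyond where ``1 - cdf`` underflows; results
    are floored at the smallest positive float so extreme statistics (z2 up
    to a few thousand) never collapse to exactly 0.
    """
    z2 = np.asarray(z2, dtype=np.float64)
    if np.any(z2 < 0):
        raise ValueError("chi-square statistic must be non-negative")
    p = stats.chi2.sf(z2, df=1)
    p = np.where((p == 0.0) & np.isfinite(z2), np.nextafter(0.0, 1.0), p)
    return p if p.ndim else float(p)
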