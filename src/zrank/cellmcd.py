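"""Cellwise minimum covariance determinant estimation and outlier detection.

Given an m x d matrix of z-statistics, the estimator seeks a robust center
``mu`` and covariance ``Sigma`` of the bulk of the rows while allowing
individual *cells* (single gene-phenotype entries) to be set aside as
contaminated.  The working model is multivariate normal with the flagged
cells treated as missing: the fitted parameters minimize

    F(W, mu, Sigma) = sum_g [ -log phi(z_{g,O_g}; mu_{O_g}, Sigma_{O_g O_g}) ]
                      + penalty_q * (#flagged cells)

over the center, the covariance and the binary cell-status matrix W
(1 = unflagged), subject to every column keeping at least ``ceil(alpha*m)``
unflagged cells.  ``O_g`` is the set of unflagged columns of row g and
``phi`` the Gaussian density of the corresponding sub-vector.

The optimizer alternates two exact descent steps, so the recorded objective
trace is non-increasing:

* W-step (one column at a time): a row's log-density term decomposes
  exactly into the term without cell j plus the conditional piece
  ``-log phi(z_gj | row's other unflagged cells)``, so flagging cell
  (g, j) lowers F precisely when that conditional term exceeds
  ``penalty_q`` (equivalently ``r*_gj**2 > 2*penalty_q - log(2*pi*c_gj)``,
  about |r*| > 3.4 on standardized data).  This is deliberately more
  conservative than the 2.5758 *reporting* cutoff: flagging only clearly
  gross cells keeps the estimation step nearly unbiased on clean data, so
  row-outlier p-values stay calibrated without a truncation correction.
  If a column would exceed its flag budget, only the flags with the
  largest objective gain are kept.
* Estimation step: one EM update for a multivariate normal with the flagged
  cells as missing data (impute by conditional expectation, update mu and
  Sigma with the conditional-covariance correction).

Outputs per cell are the conditional prediction ``xhat_gj``, conditional
standard deviation ``sqrt(c_gj)`` and standardized residual
``r*_gj = (z_gj - xhat_gj) / sqrt(c_gj)``.  Entries with ``|r*| > 2.5758``
(the square root of the chi-square(1) 0.99 quantile, printed as 2.57) are
reported as entry outliers.  Row outliers are scored by the squared
Mahalanobis distance of the full raw row against (mu, Sigma), referred to
chi-square with d degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import ZMatrix
from .rankers import PVALUE_FLOOR, rank_by_pvalue

_LOG_2PI = math.log(2.0 * math.pi)

#: chi-square(1 df) 0.99 quantile; its square root 2.5758 is the entry-outlier
#: reporting cutoff the literature prints as "2.57".
CHI2_1_Q99 = float(stats.chi2.ppf(0.99, df=1))

class FitSizeError(ValueError):
    """Input too small to estimate a robust d x d covariance."""


@dataclass(frozen=True)
class CellMCDParams:
    """Tuning constants of the cellwise MCD fit.

    alpha
        Minimum fraction of unflagged cells each column must keep, in
        (0.5, 1].  The default 0.75 tolerates up to 25% contamination per
        phenotype.
    penalty_q
        Per-cell flag penalty added to the missing-data likelihood
        criterion; defaults to the chi-square(1) 0.99 quantile (~6.6349).
    max_iter, tol
        Iteration cap and relative objective-change convergence tolerance.
    residual_cutoff
        Reporting threshold for |r*| in entry-outlier tables; defaults to
        sqrt(penalty_q) ~ 2.5758.
    """

    alpha: float = 0.75
    penalty_q: float = CHI2_1_Q99
    max_iter: int = 100
    tol: float = 1e-6
    residual_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0.5, 1], got {self.alpha}")
        if self.penalty_q <= 0:
            raise ValueError("penalty_q must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")

    @property
    def cutoff(self) -> float:
        if self.residual_cutoff is not None:
            return self.residual_cutoff
        return math.sqrt(self.penalty_q)


@dataclass
class CellMCDFit:
    """Robust center/covariance plus per-cell diagnostics."""

    genes: tuple[str, ...]
    phenotypes: tuple[str, ...]
    values: np.ndarray
    center: np.ndarray
    covariance: np.ndarray
    flags: np.ndarray  # m x d, 1 = unflagged ("observed"), 0 = flagged
    predictions: np.ndarray
    cond_sd: np.ndarray
    residuals: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    params: CellMCDParams = field(default_factory=CellMCDParams)


@dataclass(frozen=True)
class RowOutlierResult:
    """Row-outlier distances, chi-square p-values and consensus ranking."""

    method: str
    genes: tuple[str, ...]
    distance: np.ndarray  # squared Mahalanobis form h_g
    criterion: np.ndarray  # h*_g = sqrt(h_g / d), on the z scale
    pvalue: np.ndarray
    rank: np.ndarray
    fit: CellMCDFit | None = None

    @property
    def statistic(self) -> np.ndarray:
        return self.distance


# ---------------------------------------------------------------------------
# linear-algebra helpers


def _pd_clip(S: np.ndarray, rel: float) -> np.ndarray:
    """Symmetrize and clip eigenvalues below rel * largest eigenvalue."""
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    floor = rel * max(evals[-1], np.finfo(float).tiny)
    if evals[0] >= floor:
        return S
    evals = np.maximum(evals, floor)
    return (evecs * evals) @ evecs.T


def _row_patterns(W: np.ndarray):
    """Group rows by identical unflagged-column pattern.

    Yields (observed-index array, row-index array) pairs.
    """
    d = W.shape[1]
    weights = (1 << np.arange(d, dtype=np.uint64))
    codes = W.astype(np.uint64) @ weights
    order = np.argsort(codes, kind="stable")
    codes_sorted = codes[order]
    starts = np.flatnonzero(np.r_[True, codes_sorted[1:] != codes_sorted[:-1]])
    bounds = np.r_[starts, codes_sorted.size]
    for a, b in zip(bounds[:-1], bounds[1:]):
        rows = order[a:b]
        observed = np.flatnonzero(W[rows[0]])
        yield observed, rows


def cell_predict(center, covariance, row, observed, target):
    """Conditional mean and SD of one coordinate given observed coordinates.

    Under N(center, covariance), returns
    ``(mu_j + S_jO S_OO^-1 (row_O - mu_O), sqrt(S_jj - S_jO S_OO^-1 S_Oj))``.
    An empty observed set falls back to the marginal ``(mu_j, sqrt(S_jj))``.
    """
    center = np.asarray(center, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    row = np.asarray(row, dtype=float)
    observed = np.asarray(observed, dtype=int)
    j = int(target)
    if j in observed:
        raise ValueError("observed set must exclude the target coordinate")
    if observed.size == 0:
        return float(center[j]), float(math.sqrt(covariance[j, j]))
    S_OO = covariance[np.ix_(observed, observed)]
    try:
        b = linalg.solve(S_OO, covariance[observed, j], assume_a="pos")
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"singular observed block {observed}") from err
    if not np.all(np.isfinite(b)):
        raise np.linalg.LinAlgError(f"singular observed block {observed}")
    pred = center[j] + (row[observed] - center[observed]) @ b
    cvar = covariance[j, j] - covariance[j, observed] @ b
    if cvar <= 0:
        raise np.linalg.LinAlgError(f"non-positive conditional variance for target {j}")
    return float(pred), float(math.sqrt(cvar))


# ---------------------------------------------------------------------------
# objective and the two descent steps


def _objective(X, W, mu, Sigma, q):
    total = q * float((~W).sum())
    for observed, rows in _row_patterns(W):
        if observed.size == 0:
            continue
        S_OO = Sigma[np.ix_(observed, observed)]
        L = np.linalg.cholesky(S_OO)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        Xc = X[np.ix_(rows, observed)] - mu[observed]
        Y = linalg.solve_triangular(L, Xc.T, lower=True)
        maha = float(np.square(Y).sum())
        total += 0.5 * (rows.size * (observed.size * _LOG_2PI + logdet) + maha)
    return total


def _w_step(X, W, mu, Sigma, q, max_flags):
    """Column-wise exact descent update of the cell-status matrix."""
    m, d = X.shape
    W = W.copy()
    for j in range(d):
        cost = np.empty(m)
        W_other = W.copy()
        W_other[:, j] = False
        for observed, rows in _row_patterns(W_other):
            xj = X[rows, j]
            if observed.size == 0:
                cvar = Sigma[j, j]
                pred = np.full(rows.size, mu[j])
            else:
                S_OO = Sigma[np.ix_(observed, observed)]
                b = linalg.solve(S_OO, Sigma[observed, j], assume_a="pos")
                cvar = Sigma[j, j] - Sigma[j, observed] @ b
                cvar = max(cvar, 1e-12 * Sigma[j, j])
                pred = mu[j] + (X[np.ix_(rows, observed)] - mu[observed]) @ b
            r2 = np.square(xj - pred) / cvar
            # negative conditional log-density of the cell when unflagged
            cost[rows] = 0.5 * (_LOG_2PI + math.log(cvar) + r2)
        flag = cost > q
        n_flag = int(flag.sum())
        if n_flag > max_flags:
            keep = np.argsort(cost)[::-1][:max_flags]
            flag = np.zeros(m, dtype=bool)
            flag[keep] = True
        W[:, j] = ~flag
    return W


def _em_step(X, W, mu, Sigma):
    """One EM update treating flagged cells as missing data."""
    m, d = X.shape
    Xhat = X.astype(float).copy()
    Ccorr = np.zeros((d, d))
    for observed, rows in _row_patterns(W):
        missing = np.setdiff1d(np.arange(d), observed)
        if missing.size == 0:
            continue
        if observed.size == 0:
            Xhat[np.ix_(rows, missing)] = mu[missing]
            Ccorr += rows.size * Sigma
            continue
        S_OO = Sigma[np.ix_(observed, observed)]
        B = linalg.solve(S_OO, Sigma[np.ix_(observed, missing)], assume_a="pos")
        Xc = X[np.ix_(rows, observed)] - mu[observed]
        Xhat[np.ix_(rows, missing)] = mu[missing] + Xc @ B
        C = Sigma[np.ix_(missing, missing)] - Sigma[np.ix_(missing, observed)] @ B
        Ccorr[np.ix_(missing, missing)] += rows.size * C
    mu_new = Xhat.mean(axis=0)
    Xc = Xhat - mu_new
    Sigma_new = (Xc.T @ Xc + Ccorr) / m
    return mu_new, _pd_clip(Sigma_new, rel=1e-6)


def _cell_moments(X, W, mu, Sigma):
    """Conditional prediction and SD for every cell given the row's other
    unflagged cells (flagged cells condition on the full unflagged set)."""
    m, d = X.shape
    pred = np.empty((m, d))
    csd = np.empty((m, d))
    for observed, rows in _row_patterns(W):
        missing = np.setdiff1d(np.arange(d), observed)
        if observed.size == 0:
            pred[rows] = mu
            csd[rows] = np.sqrt(np.diag(Sigma))
            continue
        S_OO = Sigma[np.ix_(observed, observed)]
        K = linalg.inv(S_OO)
        kdiag = np.diag(K).copy()
        Xc = X[np.ix_(rows, observed)] - mu[observed]
        KX = Xc @ K
        # observed cells: leave-one-out conditional via the precision matrix
        pred[np.ix_(rows, observed)] = X[np.ix_(rows, observed)] - KX / kdiag
        csd[np.ix_(rows, observed)] = np.sqrt(1.0 / kdiag)
        if missing.size:
            B = K @ Sigma[np.ix_(observed, missing)]
            pred[np.ix_(rows, missing)] = mu[missing] + Xc @ B
            cvar = np.diag(Sigma)[missing] - np.einsum(
                "om,om->m", Sigma[np.ix_(observed, missing)], B
            )
            csd[np.ix_(rows, missing)] = np.sqrt(np.maximum(cvar, 1e-12))
    return pred, csd


# ---------------------------------------------------------------------------
# initialization


def _gaussian_rank_corr(X: np.ndarray) -> np.ndarray:
    m, d = X.shape
    scores = np.empty_like(X, dtype=float)
    for j in range(d):
        ranks = stats.rankdata(X[:, j])
        scores[:, j] = stats.norm.ppf(ranks / (m + 1))
    R = np.corrcoef(scores, rowvar=False)
    if d == 1:
        R = np.array([[1.0]])
    return R


def _initialize(X: np.ndarray, max_flags: int):
    m, d = X.shape
    med = np.median(X, axis=0)
    mad_sd = 1.4826 * np.median(np.abs(X - med), axis=0)
    fallback = X.std(axis=0, ddof=1)
    mad_sd = np.where(mad_sd > 0, mad_sd, fallback)
    U = np.abs(X - med) / mad_sd
    W = U <= 3.0
    for j in range(d):  # respect the per-column budget from the start
        flagged = np.flatnonzero(~W[:, j])
        if flagged.size > max_flags:
            order = flagged[np.argsort(U[flagged, j])[::-1]]
            W[:, j] = True
            W[order[:max_flags], j] = False
    R = _gaussian_rank_corr(X)
    Sigma = _pd_clip(R * np.outer(mad_sd, mad_sd), rel=1e-4)
    return med.copy(), Sigma, W


# ---------------------------------------------------------------------------
# public fitting interface


def fit_cellmcd(Z: ZMatrix, params: CellMCDParams | None = None) -> CellMCDFit:
    """Fit the cellwise MCD estimator to a z-statistic matrix.

    Deterministic for fixed input and parameters.  Requires m >= 5*d rows so
    the d x d covariance is estimable with a 25% cell budget; smaller inputs
    are rejected.  On non-convergence within ``max_iter`` the best (last)
    iterate is returned with ``converged=False`` and a warning.
    """
    params = params or CellMCDParams()
    X = np.asarray(Z.values, dtype=float)
    m, d = X.shape
    if m < 5 * d:
        raise FitSizeError(
            f"need at least 5*d = {5 * d} rows to fit a {d}-column covariance "
            f"robustly, got {m}; supply more genes or fewer phenotypes"
        )
    ptp = X.max(axis=0) - X.min(axis=0)
    if np.any(ptp == 0):
        j = int(np.flatnonzero(ptp == 0)[0])
        raise ValueError(f"constant column {Z.phenotypes[j]!r}")
    h_min = math.ceil(params.alpha * m)
    max_flags = m - h_min
    q = params.penalty_q

    mu, Sigma, W = _initialize(X, max_flags)
    trace = [_objective(X, W, mu, Sigma, q)]
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        W = _w_step(X, W, mu, Sigma, q, max_flags)
        mu, Sigma = _em_step(X, W, mu, Sigma)
        obj = _objective(X, W, mu, Sigma, q)
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) <= params.tol * max(1.0, abs(prev)):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"cellMCD did not converge in {params.max_iter} iterations; "
            "returning the final iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    pred, csd = _cell_moments(X, W, mu, Sigma)
    residuals = (X - pred) / csd
    return CellMCDFit(
        genes=Z.genes,
        phenotypes=Z.phenotypes,
        values=X,
        center=mu,
        covariance=Sigma,
        flags=W.astype(np.int8),
        predictions=pred,
        cond_sd=csd,
        residuals=residuals,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        params=params,
    )


def flag_entries(fit: CellMCDFit, cutoff: float | None = None) -> pd.DataFrame:
    """Entry-outlier records: all cells with |r*| above the cutoff.

    Sorted by descending |r*|.  The ``hidden`` column marks cells whose raw
    |z| sits below the cutoff, i.e. outliers that are invisible marginally
    and only show up against the row's conditional expectation.
    """
    if cutoff is None:
        cutoff = fit.params.cutoff
    resid = fit.residuals
    rows, cols = np.nonzero(np.abs(resid) > cutoff)
    records = pd.DataFrame(
        {
            "gene": [fit.genes[g] for g in rows],
            "phenotype": [fit.phenotypes[j] for j in cols],
            "z": fit.values[rows, cols],
            "prediction": fit.predictions[rows, cols],
            "cond_sd": fit.cond_sd[rows, cols],
            "residual": resid[rows, cols],
            "flagged": (1 - fit.flags[rows, cols]).astype(int),
            "hidden": (np.abs(fit.values[rows, cols]) < cutoff).astype(int),
        }
    )
    records = records.iloc[np.argsort(-np.abs(records["residual"].to_numpy()), kind="stable")]
    return records.reset_index(drop=True)


def mahalanobis_sq(values: np.ndarray, center: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each row against (center, covariance)."""
    Xc = np.atleast_2d(np.asarray(values, dtype=float)) - np.asarray(center, dtype=float)
    L = np.linalg.cholesky(np.asarray(covariance, dtype=float))
    Y = linalg.solve_triangular(L, Xc.T, lower=True)
    return np.square(Y).sum(axis=0)


def cellmcd_rank(
    Z: ZMatrix,
    params: CellMCDParams | None = None,
    fit: CellMCDFit | None = None,
) -> RowOutlierResult:
    """Row-outlier ranking by robust squared Mahalanobis distance.

    The distance uses the full raw row (cell flags are not applied) so the
    chi-square(d) reference of the p-value keeps its degrees of freedom.
    """
    if fit is None:
        fit = fit_cellmcd(Z, params)
    d = Z.d
    h = mahalanobis_sq(Z.values, fit.center, fit.covariance)
    pvalue = np.maximum(stats.chi2.sf(h, df=d), PVALUE_FLOOR)
    criterion = np.sqrt(h / d)
    return RowOutlierResult(
        method="cellmcd",
        genes=Z.genes,
        distance=h,
        criterion=criterion,
        pvalue=pvalue,
        rank=rank_by_pvalue(pvalue, h, Z.genes),
        fit=fit,
    )
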