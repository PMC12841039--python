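"""Calibration diagnostics and method-comparison summaries.

A well-calibrated row-outlier method applied to clean data yields uniform
p-values, so the empirical distribution function (EDF) of the p-values
should track the diagonal of a uniform quantile-quantile plot.  Lack of fit
is summarized by the root mean squared difference (RMSD) between the sorted
p-values and their EDF values; a restricted variant drops p-values at or
below a lower bound and compares against the uniform(lower_bound, 1)
distribution, which isolates the bulk of presumably-null genes from the
detected outliers.

Also provided: the 99% inclusion boundaries of each method in the bivariate
plane (a circle for SSz, a pointed circle for Fisher, an ellipse adapted to
the fitted center/covariance for the robust method), overlap counts of
significant genes between two methods, and top-k sub-matrices for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .cellmcd import CellMCDParams, cellmcd_rank, mahalanobis_sq
from .io import ZMatrix
from .rankers import fisher_rank, ssz_rank, two_sided_p
from .simulate import simulate_fig1


@dataclass(frozen=True)
class QQData:
    """Sorted p-values, matched EDF values and their RMSD."""

    pvalues: np.ndarray
    edf: np.ndarray
    rmsd: float
    restriction: float | None = None


@dataclass(frozen=True)
class Boundary2D:
    """Closed polyline of one method's inclusion boundary in the (z1, z2) plane."""

    method: str
    level: float
    points: np.ndarray  # (k, 2), first point == last point


def pvalue_qq(pvalues, lower_bound: float | None = None) -> QQData:
    """Uniform QQ data and RMSD lack-of-fit for a collection of p-values.

    EDF convention: ``EDF(p) = #{p_j <= p} / n`` (right-continuous).  With a
    lower bound, values <= bound are dropped and the comparison quantiles
    are rescaled into (bound, 1]: ``bound + (1 - bound) * i / k``.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0 or p[0] <= 0 or p[-1] > 1:
        raise ValueError("p-values must lie in (0, 1]")
    if lower_bound is not None:
        p = p[p > lower_bound]
        if p.size == 0:
            raise ValueError(f"no p-values above the lower bound {lower_bound}")
    counts = np.searchsorted(p, p, side="right")
    if lower_bound is None:
        edf = counts / p.size
    else:
        edf = lower_bound + (1.0 - lower_bound) * counts / p.size
    rmsd = float(np.sqrt(np.mean((edf - p) ** 2)))
    return QQData(pvalues=p, edf=edf, rmsd=rmsd, restriction=lower_bound)


def fit_rmsd_experiment(
    n: int = 10000,
    rho: float = 0.5,
    seed: int = 0,
    params: CellMCDParams | None = None,
) -> dict[str, float]:
    """Calibration RMSD of all three methods on clean bivariate normal data.

    Simulates n points with unit SDs and correlation rho, computes each
    method's row-outlier p-values and returns the unrestricted QQ RMSD per
    method.  Classical methods ignore the correlation, so their RMSD grows
    with |rho| while the covariance-adapted method stays near the sampling
    floor (~sqrt(1/(6n))).
    """
    if n < 1000:
        raise ValueError("n must be at least 1000")
    Z = simulate_fig1(n=n, rho=rho, seed=seed).as_zmatrix()
    return {
        "fisher": pvalue_qq(fisher_rank(Z).pvalue).rmsd,
        "ssz": pvalue_qq(ssz_rank(Z).pvalue).rmsd,
        "cellmcd": pvalue_qq(cellmcd_rank(Z, params=params).pvalue).rmsd,
    }


def _fisher_p_point(z1: float, z2: float) -> float:
    t = -2.0 * (np.log(two_sided_p(z1)) + np.log(two_sided_p(z2)))
    return float(stats.chi2.sf(t, df=4))


def inclusion_boundary(
    method: str,
    level: float = 0.99,
    center=None,
    covariance=None,
    n_angles: int = 720,
) -> Boundary2D:
    """Trace one method's bivariate inclusion boundary at the given level.

    SSz: circle of radius sqrt(chi2_2 quantile).  cellmcd: the ellipse
    ``(z - center)' covariance^-1 (z - center) = chi2_2 quantile`` (center
    and covariance required).  Fisher: the p = 1 - level contour traced by
    an angular sweep with root-finding in radius (the contour is star-shaped
    about the origin).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    quantile = stats.chi2.ppf(level, df=2)
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    if method == "ssz":
        pts = np.sqrt(quantile) * circle
    elif method == "cellmcd":
        if center is None or covariance is None:
            raise ValueError("cellmcd boundary needs the fitted center and covariance")
        L = np.linalg.cholesky(np.asarray(covariance, dtype=float))
        pts = np.asarray(center, dtype=float) + np.sqrt(quantile) * circle @ L.T
    elif method == "fisher":
        target = 1.0 - level
        radii = np.empty(n_angles)
        for i, (c, s) in enumerate(circle):
            radii[i] = optimize.brentq(
                lambda r: _fisher_p_point(r * c, r * s) - target,
                1e-9,
                20.0,
                xtol=1e-12,
            )
        pts = radii[:, None] * circle
    else:
        raise ValueError(f"unknown method {method!r}")
    pts = np.vstack([pts, pts[:1]])  # close the polyline
    return Boundary2D(method=method, level=level, points=pts)


def boundary_pvalues(boundary: Boundary2D, center=None, covariance=None) -> np.ndarray:
    """Row-outlier p-value of each boundary point under its own method."""
    z = boundary.points
    if boundary.method == "ssz":
        return stats.chi2.sf(np.square(z).sum(axis=1), df=2)
    if boundary.method == "cellmcd":
        h = mahalanobis_sq(z, np.asarray(center, float), np.asarray(covariance, float))
        return stats.chi2.sf(h, df=2)
    if boundary.method == "fisher":
        return np.array([_fisher_p_point(z1, z2) for z1, z2 in z])
    raise ValueError(f"unknown method {boundary.method!r}")


def overlap_counts(a, b, threshold: float = 0.01) -> tuple[int, int, int]:
    """Counts of genes significant (p < threshold) in both / only a / only b."""
    if tuple(a.genes) != tuple(b.genes):
        raise ValueError("gene lists differ between the two results")
    sig_a = np.asarray(a.pvalue) < threshold
    sig_b = np.asarray(b.pvalue) < threshold
    return (
        int((sig_a & sig_b).sum()),
        int((sig_a & ~sig_b).sum()),
        int((~sig_a & sig_b).sum()),
    )


def topk_zmatrix(result, Z: ZMatrix, k: int = 25) -> ZMatrix:
    """Sub-matrix of the k top-ranked genes, rows ordered by rank."""
    if k < 1 or k > Z.m:
        raise ValueError(f"k must be in [1, {Z.m}], got {k}")
    if tuple(result.genes) != tuple(Z.genes):
        raise ValueError("result and matrix gene lists differ")
    order = np.argsort(np.asarray(result.rank))[:k]
    return ZMatrix(
        genes=tuple(Z.genes[i] for i in order),
        phenotypes=Z.phenotypes,
        values=Z.values[order],
    )
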