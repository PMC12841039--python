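"""Classical consensus rankers: Fisher's method and the sum of squared z-statistics.

Both methods collapse a gene's row of d z-statistics into one consensus
p-value under the working assumption that the d statistics are independent
standard normal under the null:

* Fisher's method converts each z to a two-sided p-value, sums
  ``t_g = -2 * sum_j ln(p_gj)`` and refers t_g to chi-square with 2d degrees
  of freedom.  The standardized criterion is ``t*_g = t_g / (2d)``.
* SSz sums squares, ``w_g = sum_j z_gj**2``, referred to chi-square with d
  degrees of freedom; the criterion is the root mean square z,
  ``RMSZ_g = sqrt(w_g / d)``, which sits on the z scale.

Genes are ranked by ascending consensus p-value; ties break by descending
statistic, then lexicographic gene identifier, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ZMatrix

#: p-values are floored here before logs and in reports; preserves ranking
#: while keeping -2*ln(p) finite.
PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class RankResult:
    """Per-gene consensus statistic, standardized criterion, p-value and rank."""

    method: str
    genes: tuple[str, ...]
    statistic: np.ndarray
    criterion: np.ndarray
    pvalue: np.ndarray
    rank: np.ndarray


def two_sided_p(z):
    """Two-sided standard-normal p-value, ``2 * P(N(0,1) > |z|)``.

    Symmetric in the sign of z; accepts scalars or arrays; rejects
    non-finite input.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-statistics must be finite")
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def rank_by_pvalue(pvalue: np.ndarray, statistic: np.ndarray, genes) -> np.ndarray:
    """Ranks 1..m: ascending p, ties by descending statistic, then gene ID."""
    genes = np.asarray(genes, dtype=str)
    order = np.lexsort((genes, -np.asarray(statistic, float), np.asarray(pvalue, float)))
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    return rank


def _floor(p: np.ndarray) -> np.ndarray:
    return np.maximum(p, PVALUE_FLOOR)


def fisher_rank(Z: ZMatrix) -> RankResult:
    """Fisher's method: combine two-sided per-column p-values per gene."""
    d = Z.d
    p_cells = _floor(2.0 * stats.norm.sf(np.abs(Z.values)))
    t = -2.0 * np.log(p_cells).sum(axis=1)
    pvalue = _floor(stats.chi2.sf(t, df=2 * d))
    criterion = t / (2.0 * d)
    return RankResult(
        method="fisher",
        genes=Z.genes,
        statistic=t,
        criterion=criterion,
        pvalue=pvalue,
        rank=rank_by_pvalue(pvalue, t, Z.genes),
    )


def ssz_rank(Z: ZMatrix) -> RankResult:
    """Sum of squared z-statistics referred to chi-square with d df."""
    d = Z.d
    w = np.square(Z.values).sum(axis=1)
    pvalue = _floor(stats.chi2.sf(w, df=d))
    criterion = np.sqrt(w / d)
    return RankResult(
        method="ssz",
        genes=Z.genes,
        statistic=w,
        criterion=criterion,
        pvalue=pvalue,
        rank=rank_by_pvalue(pvalue, w, Z.genes),
    )
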