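"""Contaminated multivariate-normal benchmark datasets.

The benchmark design crosses dimension (5 or 10), contamination fraction
``perout`` (0.01 or 0.05), contamination magnitude ``gamma`` (0.25 or 0.5),
contamination mechanism (whole rows, single entries, or both) and
correlation structure (independent, ALYZ, A09) into 72 settings of n = 1000
rows each.

Correlation structures
    * independent: identity.
    * A09: entries ``(-0.9)**|j-k|`` — strong alternating short-range
      correlation.
    * ALYZ: a seeded random correlation matrix with condition number 100.

Contamination geometry (this package's concrete choice; the magnitude
``gamma`` measures how far beyond the 99% reference surface the
contamination sits):

    * row outliers: ``floor(perout*n)`` rows are replaced by draws from
      ``N(+-v, Sigma)`` where ``v = (1+gamma) * sqrt(chi2_{d,0.99}) * u``
      and u is the least-detectable direction (smallest-eigenvalue
      eigenvector of Sigma, scaled to unit Mahalanobis norm, u' Sigma^-1
      u = 1; the equiangular direction when Sigma is isotropic).  The
      displaced cluster keeps the population covariance, so its
      noncentrality ``v' Sigma^-1 v = (1+gamma)^2 * chi2_{d,0.99}`` is
      exact while classical per-column statistics see only the (possibly
      tiny) Euclidean component of the shift.
    * entry outliers: each cell of a non-replaced row is independently
      contaminated with probability perout and set to
      ``+-(1+gamma) * sqrt(chi2_{1,0.99}) * sqrt(Sigma_jj)``.
    * both: half the budget to each mechanism (``floor(perout*n/2)`` rows,
      per-cell probability ``perout/2``).

One root seed drives three decoupled sub-streams (structure, placement,
noise) so changing the mechanism never perturbs the clean draw, and
identical settings reproduce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy import stats

from .io import ZMatrix

CORRELATIONS = ("independent", "ALYZ", "A09")
MECHANISMS = ("rows", "entries", "both")


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of the benchmark design."""

    d: int
    correlation: str
    mechanism: str
    perout: float
    gamma: float
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("d must be at least 2")
        if self.correlation not in CORRELATIONS:
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 < self.perout < 0.5:
            raise ValueError(f"perout must be in (0, 0.5), got {self.perout}")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.n < 1:
            raise ValueError("n must be positive")

    def key(self) -> str:
        """Seedless identifier of the design cell."""
        return (
            f"d={self.d}|corr={self.correlation}|mech={self.mechanism}"
            f"|perout={self.perout:g}|gamma={self.gamma:g}|n={self.n}"
        )


@dataclass
class SimulatedDataset:
    """Simulated rows plus ground-truth contamination bookkeeping."""

    values: np.ndarray
    sigma_true: np.ndarray
    row_labels: np.ndarray  # 1 = replaced row OR contains >=1 contaminated entry
    cell_labels: np.ndarray  # n x d contamination mask (entry mechanism)
    row_replaced: np.ndarray = field(default=None)  # rows replaced wholesale

    def as_zmatrix(self, gene_prefix: str = "g", phen_prefix: str = "p") -> ZMatrix:
        n, d = self.values.shape
        width = len(str(n))
        genes = tuple(f"{gene_prefix}{i + 1:0{width}d}" for i in range(n))
        phen = tuple(f"{phen_prefix}{j + 1}" for j in range(d))
        return ZMatrix(genes=genes, phenotypes=phen, values=self.values)


def make_sigma(correlation: str, d: int, seed: int = 0) -> np.ndarray:
    """Generating covariance for one correlation structure.

    ``independent`` is the identity; ``A09`` has entries (-0.9)**|j-k|;
    ``ALYZ`` is a seeded random correlation matrix iterated to condition
    number 100 +- 1 with unit diagonal.
    """
    if d < 2:
        raise ValueError("d must be at least 2")
    if correlation == "independent":
        return np.eye(d)
    if correlation == "A09":
        idx = np.arange(d)
        return (-0.9) ** np.abs(idx[:, None] - idx[None, :])
    if correlation == "ALYZ":
        return _alyz_sigma(d, seed)
    raise ValueError(f"unknown correlation {correlation!r}")


def _alyz_sigma(d: int, seed: int, target: float = 100.0, max_iter: int = 50) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, d))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))  # deterministic sign convention
    lam = np.geomspace(target, 1.0, d)
    S = (Q * lam) @ Q.T
    for _ in range(max_iter):
        scale = 1.0 / np.sqrt(np.diag(S))
        S = S * np.outer(scale, scale)
        np.fill_diagonal(S, 1.0)
        evals, evecs = np.linalg.eigh(S)
        cond = evals[-1] / evals[0]
        if abs(cond - target) <= 1.0:
            break
        # re-spread eigenvalues geometrically to the target condition number
        log_l = np.log(evals)
        stretch = np.log(target) / (log_l[-1] - log_l[0])
        new = np.exp((log_l - log_l[-1]) * stretch + log_l[-1])
        S = (evecs * new) @ evecs.T
    return S


def least_favorable_direction(sigma: np.ndarray) -> np.ndarray:
    """Direction of smallest variance, scaled to unit Mahalanobis norm.

    Returns u with u' Sigma^-1 u = 1 along the smallest-eigenvalue
    eigenvector; when Sigma is isotropic the eigenbasis is arbitrary and the
    equiangular direction (1,...,1)/sqrt(d) is used by convention.
    """
    sigma = np.asarray(sigma, dtype=float)
    d = sigma.shape[0]
    evals, evecs = np.linalg.eigh(sigma)
    if evals[-1] - evals[0] <= 1e-12 * evals[-1]:
        u0 = np.ones(d) / np.sqrt(d)
    else:
        u0 = evecs[:, 0]
    nz = np.flatnonzero(np.abs(u0) > 1e-12)
    if u0[nz[0]] < 0:
        u0 = -u0
    scale = u0 @ np.linalg.solve(sigma, u0)
    return u0 / np.sqrt(scale)


def simulate_dataset(setting: SimulationSetting) -> SimulatedDataset:
    """Generate one contaminated dataset for a design cell."""
    n, d = setting.n, setting.d
    root = np.random.SeedSequence([int(setting.seed), 0x5A])
    s_struct, s_place, s_noise = root.spawn(3)
    sigma_seed = int(s_struct.generate_state(1)[0] % (2**31))
    sigma = make_sigma(setting.correlation, d, seed=sigma_seed)
    L = np.linalg.cholesky(sigma)
    rng_noise = np.random.default_rng(s_noise)
    rng_place = np.random.default_rng(s_place)
    X = rng_noise.standard_normal((n, d)) @ L.T

    row_replaced = np.zeros(n, dtype=bool)
    cell_labels = np.zeros((n, d), dtype=bool)

    if setting.mechanism in ("rows", "both"):
        budget = setting.perout if setting.mechanism == "rows" else setting.perout / 2.0
        k = int(np.floor(budget * n))
        if k > 0:
            idx = rng_place.choice(n, size=k, replace=False)
            u = least_favorable_direction(sigma)
            v = (1.0 + setting.gamma) * np.sqrt(stats.chi2.ppf(0.99, df=d)) * u
            signs = rng_place.choice([-1.0, 1.0], size=k)
            X[idx] = signs[:, None] * v + rng_place.standard_normal((k, d)) @ L.T
            row_replaced[idx] = True

    if setting.mechanism in ("entries", "both"):
        prob = setting.perout if setting.mechanism == "entries" else setting.perout / 2.0
        mask = rng_place.random((n, d)) < prob
        mask[row_replaced] = False
        if mask.any():
            signs = rng_place.choice([-1.0, 1.0], size=int(mask.sum()))
            sd = np.sqrt(np.diag(sigma))
            magnitude = (1.0 + setting.gamma) * np.sqrt(stats.chi2.ppf(0.99, df=1))
            cols = np.nonzero(mask)[1]
            X[mask] = signs * magnitude * sd[cols]
        cell_labels = mask

    row_labels = row_replaced | cell_labels.any(axis=1)
    return SimulatedDataset(
        values=X,
        sigma_true=sigma,
        row_labels=row_labels,
        cell_labels=cell_labels,
        row_replaced=row_replaced,
    )


def simulate_fig1(n: int = 10000, rho: float = 0.5, seed: int = 0) -> SimulatedDataset:
    """Clean bivariate normal fixture: mean (0,0), unit SDs, correlation rho."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1]))
    sigma = np.array([[1.0, rho], [rho, 1.0]])
    X = rng.standard_normal((n, 2)) @ np.linalg.cholesky(sigma).T
    return SimulatedDataset(
        values=X,
        sigma_true=sigma,
        row_labels=np.zeros(n, dtype=bool),
        cell_labels=np.zeros((n, 2), dtype=bool),
        row_replaced=np.zeros(n, dtype=bool),
    )


def full_grid(n: int = 1000, seed: int = 0) -> list[SimulationSetting]:
    """The complete 72-setting design (2 dims x 2 perout x 2 gamma x 3
    mechanisms x 3 correlations)."""
    grid = []
    for d, perout, gamma, mech, corr in product(
        (5, 10), (0.01, 0.05), (0.25, 0.5), MECHANISMS, CORRELATIONS
    ):
        grid.append(
            SimulationSetting(
                d=d, correlation=corr, mechanism=mech, perout=perout, gamma=gamma, n=n, seed=seed
            )
        )
    return grid


def with_seed(setting: SimulationSetting, seed: int) -> SimulationSetting:
    return replace(setting, seed=seed)
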