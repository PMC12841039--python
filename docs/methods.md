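# Methods

## Model and scope

The input is an m × d matrix **Z** of association z-statistics (genes by
phenotypes).  The working null model is that the bulk of the rows are draws
from a multivariate normal N(μ, Σ): each gene's d statistics may be
correlated (phenotypes share mechanisms and samples) but are jointly
unremarkable.  Interesting genes are *row outliers* — far from the bulk in
the metric of Σ — and interesting single associations are *entry outliers*
— cells inconsistent with their row's other values under Σ.

Three row rankers are provided.  Fisher's method and SSz additionally
assume the d columns are independent standard normal under the null; both
reduce the row to a symmetric function of |z_gj| and refer it to a central
chi-square (2d and d df).  The robust ranking estimates (μ̂, Σ̂) cellwise-
robustly and refers the squared Mahalanobis distance of each *full raw* row
to χ²(d).  The distance deliberately uses the raw row without masking
flagged cells: masking would change the reference distribution's degrees of
freedom gene by gene.

Per-column p-values for Fisher's method are two-sided.  Both tail
directions (drug resistance and drug sensitivity) are treated as signal,
and the choice makes Fisher's method sign-invariant like SSz, so all three
boundaries in the (z₁, z₂) plane are symmetric about the origin.  Both
standardized criteria carry a square root (RMSZ_g = √(w_g/d),
h\*_g = √(h_g/d)) so they sit on the z scale and are comparable across d.
Reported p-values are floored at 1e−300; ranks break ties by descending
statistic, then gene identifier, so output is deterministic.

## The cellwise-robust fit

The estimator treats flagged cells as missing data and minimizes

    F(W, μ, Σ) = Σ_g [ −log φ(z_{g,O_g}; μ_{O_g}, Σ_{O_g O_g}) ] + q · #flags,

over the cell-status matrix W (O_g = unflagged columns of row g) and the
parameters, subject to every column retaining at least ⌈α·m⌉ unflagged
cells.  Defaults: α = 0.75 (tolerates 25% contamination per phenotype),
q = χ²₁(0.99) ≈ 6.6349, convergence when the relative objective change
falls below 1e−6, at most 100 iterations.

Two alternating steps, each an exact descent step, so the recorded
objective trace is non-increasing by construction:

* **W-step** (column by column): a row's log-density splits exactly into
  the term without cell j plus the conditional term
  −log φ(z_gj | other unflagged cells) = ½[log(2πc) + r*²].  Flagging cell
  (g, j) therefore lowers F precisely when that term exceeds q, i.e. when
  r*² > 2q − log(2πc) — about |r*| > 3.4 when the conditional variance c is
  near 1.  Over-budget columns keep only the flags with the largest gain.
* **Estimation step**: one EM update for a multivariate normal with
  missing data — impute flagged cells by their conditional expectation,
  update μ as the mean of completed rows and Σ as the completed second
  moment plus the per-row conditional covariance of the flagged block.

The estimation flag threshold (~3.4σ) is intentionally stricter than the
2.5758 *reporting* cutoff used by `flag_entries`.  Flagging at ~2.58σ
removes about 1% of genuinely null cells per iteration, and imputing them
biases Σ̂ downward by a few percent — enough to visibly break the
uniformity of the row p-values that is the method's central diagnostic
property (measured here: the QQ RMSD of clean-data row p-values degrades
from ~0.004 to ~0.025).  With the conservative threshold only clearly
gross cells are excluded from estimation, the clean-data fit is nearly the
MLE, and calibration holds without any truncation-bias correction.  The
reporting cutoff |r*| > 2.5758 (√χ²₁(0.99), displayed 2.57) is unchanged
and applies to the final residual matrix.

Initialization is deterministic: per-column robust standardization by
median and 1.4826·MAD (falling back to the sample SD for zero-MAD
columns); initial flags where |standardized value| > 3 (budget enforced);
initial μ = columnwise medians; initial Σ = Gaussian-rank correlations
scaled by the MAD SDs.  Σ is kept positive definite throughout by clipping
eigenvalues below 1e−4 (initialization) / 1e−6 (updates) of the largest.
Rows whose cells are all flagged fall back to marginal predictions
(μ_j, √Σ_jj).  A fit that reaches the iteration cap returns its last
iterate with `converged=False` and a warning; downstream consumers proceed.

Inputs need m ≥ 5d rows; with fewer genes than five per phenotype a robust
d × d covariance is not meaningfully estimable and the fit refuses.

## Calibration diagnostics

`pvalue_qq` uses the right-continuous EDF(p) = #{p_j ≤ p}/n, which makes
the RMSD of an exact uniform grid zero.  With a lower bound b (used to
inspect the presumably-null bulk after removing detections), values ≤ b
are dropped and the comparison quantiles are b + (1−b)·i/k, i.e. the
uniform(b, 1) distribution.  For a calibrated method on clean data the
expected RMSD is the sampling floor √(1/(6n)) — 0.0041 at n = 10,000.

Inclusion boundaries at level 0.99 in the bivariate plane: SSz is the
circle of radius √χ²₂(0.99) ≈ 3.035; the robust boundary is the ellipse
(z−μ̂)ᵀΣ̂⁻¹(z−μ̂) = χ²₂(0.99); Fisher's contour is traced by a polar sweep
(720 angles, Brent root-finding in radius to 1e−12; the contour is
star-shaped about the origin by sign symmetry).  Every emitted point
satisfies its method's p = 0.01 within 1e−6 by direct evaluation.

## Synthetic data

The benchmark crosses dimension d ∈ {5, 10}, contamination fraction
perout ∈ {0.01, 0.05}, magnitude γ ∈ {0.25, 0.5}, mechanism
{rows, entries, both} and correlation {independent, ALYZ, A09} — 72
settings of n = 1000 rows.  A09 has entries (−0.9)^|j−k|; ALYZ is a seeded
random correlation matrix iterated to condition number 100 ± 1 with unit
diagonal (random orthogonal basis, geometrically spaced eigenvalues,
alternating re-spread and diagonal normalization).

Contamination geometry.  γ measures how far beyond the 99% reference
surface the contamination sits:

* Row outliers are draws from N(±v, Σ) with v along the least-detectable
  direction (smallest-eigenvalue eigenvector of Σ, equiangular for
  isotropic Σ) scaled so vᵀΣ⁻¹v = (1+γ)²·χ²_d(0.99) exactly.  The
  displaced cluster keeps the population covariance, so its noncentrality
  is known exactly, while per-column methods see only the Euclidean
  component of the shift — tiny under correlated Σ (λ_min ≈ 0.02–0.06),
  equal to the full shift under independence.
* Entry outliers replace random cells (probability perout, outside
  replaced rows) with ±(1+γ)·√χ²₁(0.99)·√Σ_jj — marginally gross values.
* "both" gives half the budget to each mechanism.

One root seed drives decoupled structure/placement/noise sub-streams, so
changing the mechanism never perturbs the clean draw and datasets are
bit-reproducible.  Two aspects of real screens are *not* emulated: genes
truly associated with all phenotypes in proportion to the bulk correlation
(which no row-outlier method should flag), and heavy-tailed or skewed
score distributions; passing benchmarks therefore demonstrate behavior
under the multivariate normal contamination model, not distributional
robustness.

Stochastic row outliers (rather than replicated fixed points) are a
deliberate choice: with deterministic replacement every contaminated row
receives a single constant score per method, and a method's AUC collapses
to its null CDF evaluated at that constant — making comparisons between
Fisher's method and SSz an artifact of where one point falls in two
different null distributions.  Drawing outliers as a displaced cluster
keeps the two classical methods' scores tightly coupled, which matches how
they behave on real screens.

## Benchmark

AUC is the Mann–Whitney probability that a random contaminated row
outranks a random clean row (ties ½); scores are −log₁₀ consensus p for
the classical methods and the Mahalanobis distance for the robust method
(AUC is rank-based, so any monotone transform is equivalent).  Replicate k
of a setting uses seed crc32(setting key) + k·0x9E3779B9 mod 2³¹.
Summaries report mean and SD of AUC per method, the replicate count, fit
failures (a setting is marked unreliable above 5%), and the between-method
SD of mean AUC used to order settings from agreement to divergence.

The default evaluation in the test suite uses a 12-setting subgrid
(3 correlations × {rows, entries} × d ∈ {5, 10} at perout = 0.05,
γ = 0.5) at 100 replicates — about two minutes on one CPU — chosen to span
the regimes where the methods agree (independence) and diverge
(correlated structures); the full 72-setting grid at any replicate count
is available through `run_grid`/`zrank evaluate`.

Measured behavior at that scale: under correlated structures with row
outliers the robust ranking reaches mean AUC 0.98–1.00 while Fisher/SSz
sit at 0.58–0.68; under independence all methods are nearly saturated.
Fisher's method and SSz track each other closely but not identically —
SSz is consistently the slightly stronger of the two against dense
quadratic signal, with mean-AUC gaps up to ~0.04 in mid-power regimes.
This gap is a genuine property of the two statistics, not of the
generator: it vanishes only where both methods are saturated or blind.

## Known limitations

* Casewise masking: a cluster of moderately shifted rows (each cell ~2σ)
  inflates the fitted covariance along the shift direction and partially
  masks itself — cellwise flagging cannot exclude cells that are
  individually unremarkable.  The effect is small (robust AUC 0.98 instead
  of 1.00 in the affected benchmark settings) but inherent to cellwise
  estimators confronted with structured casewise contamination.
* Exact numerical parity with other implementations of the cellwise MCD is
  not claimed: initialization and the estimation flag threshold differ,
  and fitted (μ̂, Σ̂) can differ in the third decimal on the same data.
* The input matrix must be complete; missing-value support and the
  one-sided variants of the classical rankers are out of scope.
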