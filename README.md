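# zrank

Consensus gene prioritization and cellwise-robust outlier detection for
matrices of association z-statistics.

## The problem

Modern screens associate each of thousands of genes with several phenotypes
at once — a CRISPR knockout screen run against multiple drugs, or a
multi-omic study associating gene features with several clinical endpoints.
Each analysis column yields one z-statistic per gene, giving an m × d matrix
**Z** with entries z_gj (gene g, phenotype j).  Two questions follow:

1. **Which genes** show an unusual multivariate pattern of association and
   deserve follow-up (row outliers)?
2. **Which individual gene–phenotype associations** are surprising given the
   gene's other statistics (entry outliers)?

`zrank` implements three row-outlier rankers and one entry-outlier detector:

* **Fisher's method** — per-gene t_g = −2 Σ_j ln p_gj with two-sided
  p_gj = 2Φ(−|z_gj|), referred to χ²(2d); standardized criterion
  t\*_g = t_g / 2d.
* **SSz** (sum of squared z-statistics) — w_g = Σ_j z_gj², referred to
  χ²(d); criterion RMSZ_g = √(w_g/d).
* **cellMCD ranking** — a cellwise minimum covariance determinant fit gives
  robust estimates (μ̂, Σ̂) of the center and covariance of the bulk of the
  rows while allowing individual contaminated cells to be set aside.  Genes
  are ranked by the squared Mahalanobis distance
  h_g = (z_g − μ̂)ᵀ Σ̂⁻¹ (z_g − μ̂), referred to χ²(d); criterion
  h\*_g = √(h_g/d).
* **Entry outliers** — the same fit produces, for every cell, the
  conditional prediction x̂_gj given the gene's other unflagged statistics,
  the conditional SD √c_gj and the standardized residual
  r\*_gj = (z_gj − x̂_gj)/√c_gj.  Cells with |r\*| > 2.5758 (the square
  root of the χ²(1) 0.99 quantile) are reported, including *hidden*
  outliers whose raw |z| is unremarkable.

Fisher's method and SSz assume the d statistics are independent under the
null; when phenotypes are correlated (drugs with shared mechanisms,
overlapping clinical endpoints) their consensus p-values are miscalibrated.
The robust Mahalanobis ranking models the correlation directly and stays
calibrated.  A simulation module and an AUC benchmark quantify exactly this
trade-off.

## Worked example

Analyze a tab-separated gene × phenotype z-matrix (first column `gene`,
one column per phenotype; pass `--standardize` if the file holds raw
gene-level scores such as log fold-changes, to be column-standardized
first):

```sh
zrank rank --input screen_z.tsv --out-dir results
```

On an 800-gene, 3-drug simulated screen with 61 contaminated genes
(correlated drugs, 4% contamination) this prints

```
INFO read 800 genes x 3 phenotypes from screen_z.tsv
INFO fisher: 78 genes significant at p < 0.01
INFO ssz: 75 genes significant at p < 0.01
INFO cellmcd: 65 genes significant at p < 0.01
INFO 89 entry outliers flagged (41 hidden)
```

and writes `gene_table.tsv` (per gene and method: statistic, standardized
criterion, p-value, rank), `entry_outliers.tsv`, pairwise
`overlap_counts.tsv` and per-method top-25 sub-matrices.  The first entry
outlier record reads

```
gene  phenotype  z        prediction  cond_sd  residual  flagged  hidden
g056  p2         3.8637   -1.0589     0.3074   16.0135   1        0
```

a cell whose value of +3.86 contradicts the −1.06 expected from the gene's
other two strongly correlated drug responses — 16 conditional SDs off.  A
`hidden` record is more striking still: its raw |z| is below 2.58, so no
per-column analysis would notice it.

The calibration experiment (10,000 clean bivariate normal points,
correlation 0.5) reproduces the method comparison in one command:

```sh
zrank fig1 --seed 1 --out-dir fig1_out
# INFO RMSD fisher=0.0233 ssz=0.0238 cellmcd=0.0035
```

The RMSD between each method's row-outlier p-values and their empirical
distribution function shows the classical methods miscalibrated by an order
of magnitude more than the covariance-adapted ranking.

Simulation benchmarking (`zrank simulate`, `zrank evaluate --grid grid.yaml
--reps 100`) reproduces the AUC comparison across dimension, correlation
structure (independent, ALYZ, A09), contamination mechanism (rows, entries,
both) and magnitude; see `docs/methods.md` for the design.

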