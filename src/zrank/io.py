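"""Reading, writing and standardization of gene x phenotype statistic matrices.

The central container is :class:`ZMatrix`, an m x d matrix of association
z-statistics with one row per gene and one column per phenotype (drug,
clinical endpoint, ...).  Matrices travel as plain UTF-8 tab-separated text:
first column holds the gene identifier under the literal header ``gene``,
remaining columns are phenotypes, and floats are printed with 12 significant
digits so that a write/read cycle is lossless.

Raw per-phenotype gene scores (for example gene-level log fold-changes from a
CRISPR screen) are converted to z-statistics by column standardization:
subtract the column mean, divide by the column sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENE_COLUMN = "gene"
#: float format used for every table this package writes; 12 significant
#: digits round-trip float64 values that were printed from such tables.
FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """Raised when an input matrix violates the ZMatrix contract."""


@dataclass(frozen=True)
class ZMatrix:
    """An m x d matrix of z-statistics with gene and phenotype labels.

    Invariants (checked at construction): at least one row and one column,
    unique gene identifiers, unique phenotype labels, and a fully finite
    float body.
    """

    genes: tuple[str, ...]
    phenotypes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        object.__setattr__(self, "phenotypes", tuple(str(p) for p in self.phenotypes))
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-dimensional, got shape {values.shape}")
        m, d = values.shape
        if m < 1 or d < 1:
            raise ValidationError(f"matrix must be at least 1x1, got {m}x{d}")
        if len(self.genes) != m:
            raise ValidationError(f"{len(self.genes)} gene labels for {m} rows")
        if len(self.phenotypes) != d:
            raise ValidationError(f"{len(self.phenotypes)} phenotype labels for {d} columns")
        dup_genes = _duplicates(self.genes)
        if dup_genes:
            raise ValidationError(f"duplicate gene identifiers: {', '.join(dup_genes)}")
        dup_phen = _duplicates(self.phenotypes)
        if dup_phen:
            raise ValidationError(f"duplicate phenotype labels: {', '.join(dup_phen)}")
        if not np.all(np.isfinite(values)):
            g, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value for gene {self.genes[g]!r}, phenotype {self.phenotypes[j]!r}"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.phenotypes))
        df.insert(0, GENE_COLUMN, list(self.genes))
        return df


#: Raw gene-level score matrices (e.g. MAGeCK-RRA log fold-changes) use the
#: same container as z-statistic matrices; only the interpretation differs.
ScoreMatrix = ZMatrix


def _duplicates(labels: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen and lab not in dups:
            dups.append(lab)
        seen.add(lab)
    return dups


def read_zmatrix(path: str | Path, standardize: bool = False) -> ZMatrix:
    """Read a tab-separated gene x phenotype matrix.

    The file must have a header row whose first field names the gene column
    and a numeric body.  ``standardize=True`` treats the body as raw scores
    and applies :func:`column_standardize` before returning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected a gene column plus at least one phenotype column")
    genes = [str(g) for g in df.iloc[:, 0]]
    phenotypes = [str(c) for c in df.columns[1:]]
    dup = _duplicates(genes)
    if dup:
        raise ValidationError(f"{path}: duplicate gene identifiers: {', '.join(dup)}")
    body = np.empty((len(genes), len(phenotypes)), dtype=float)
    for j, phen in enumerate(phenotypes):
        col = pd.to_numeric(df.iloc[:, j + 1], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if bad.any():
            g = int(np.flatnonzero(bad)[0])
            raw = df.iloc[g, j + 1]
            raise ValidationError(
                f"{path}: non-numeric or missing value {raw!r} for gene {genes[g]!r}, "
                f"phenotype {phen!r}"
            )
        body[:, j] = col
    Z = ZMatrix(genes=tuple(genes), phenotypes=tuple(phenotypes), values=body)
    if standardize:
        Z = column_standardize(Z)
    return Z


def write_zmatrix(Z: ZMatrix, path: str | Path) -> None:
    """Write a matrix as UTF-8 TSV with 12-significant-digit floats."""
    Z.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def column_standardize(scores: ScoreMatrix) -> ZMatrix:
    """Turn raw per-phenotype gene scores into z-statistics.

    Each column is centered by its mean and scaled by its sample standard
    deviation (n-1 denominator).  A column with zero variance has no scale
    and is rejected.
    """
    values = scores.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    zero = np.flatnonzero(~(sd > 0))
    if zero.size:
        names = ", ".join(scores.phenotypes[j] for j in zero)
        raise ValidationError(f"zero-variance column(s): {names}")
    return ZMatrix(
        genes=scores.genes,
        phenotypes=scores.phenotypes,
        values=(values - mean) / sd,
    )


def write_gene_table(results: Iterable, path: str | Path) -> pd.DataFrame:
    """Write one row per gene with each method's statistic, criterion, p and rank.

    ``results`` is a non-empty collection of per-method ranking results (any
    object with ``method``, ``genes``, ``statistic``, ``criterion``,
    ``pvalue`` and ``rank`` attributes) sharing one gene list.  Rows follow
    the input gene order; the ranking is a column, so tables stay joinable.
    Returns the assembled frame (also written to ``path``).
    """
    results = list(results)
    if not results:
        raise ValidationError("write_gene_table needs at least one method result")
    genes = results[0].genes
    for res in results[1:]:
        if tuple(res.genes) != tuple(genes):
            raise ValidationError(
                f"gene lists differ between methods {results[0].method!r} and {res.method!r}"
            )
    df = pd.DataFrame({GENE_COLUMN: list(genes)})
    for res in results:
        df[f"{res.method}_statistic"] = np.asarray(res.statistic, dtype=float)
        df[f"{res.method}_criterion"] = np.asarray(res.criterion, dtype=float)
        df[f"{res.method}_pvalue"] = np.asarray(res.pvalue, dtype=float)
        df[f"{res.method}_rank"] = np.asarray(res.rank, dtype=int)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return df
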