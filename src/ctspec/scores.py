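"""Specificity representations of expression profiles.

Three per-gene summaries used for model comparison and for comparing cell
types across datasets:

* the S score — a gene's expression in one cell type divided by its summed
  expression over all cell types (proportional specificity in [0, 1]);
* equal-count rank binning with optional zero preservation — genes with
  value zero keep bin 0 while the nonzero genes are spread over 1..n_bins,
  so 40 bins yield 41 distinct values and 100 bins yield 101;
* residual specificity — per-cell-type residuals after regressing expression
  on the dataset average, the representation used for cross-dataset
  cell-type correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiles import CellTypeProfile

logger = logging.getLogger(__name__)


@dataclass
class SpecificityScore:
    """Genes x cell-types S scores; rows with any expression sum to 1."""

    S: pd.DataFrame
    source_dataset: str

    @property
    def gene_ids(self) -> list[str]:
        return list(self.S.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.S.columns)


@dataclass
class BinnedVector:
    """Per-gene integer bins in {0, ..., n_bins}; 0 reserved for zero input
    when ``zero_preserved``."""

    values: pd.Series
    n_bins: int
    zero_preserved: bool


def s_score(profile: CellTypeProfile) -> SpecificityScore:
    """Proportional expression of each gene in each cell type.

    S[g, c] = E[g, c] / sum_j E[g, j]; genes with zero expression everywhere
    get an all-zero row rather than NaN.
    """
    E = profile.E
    row_sums = E.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = E.div(row_sums, axis=0)
    S[row_sums == 0] = 0.0
    return SpecificityScore(S=S, source_dataset=profile.dataset_id)


def bin_equal_count(values, n_bins: int, preserve_zero: bool = True) -> BinnedVector:
    """Rank values into ``n_bins`` equal-count bins.

    With ``preserve_zero`` (the default) exact zeros keep bin 0 and only the
    m nonzero values are ranked ascending (average ranks on ties) and mapped
    to bin = ceil(rank * n_bins / m), giving n_bins + 1 possible output
    values.  With ``preserve_zero=False`` every value is ranked, which is the
    mode used for residual vectors where zero has no special meaning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ser = pd.Series(values, dtype=float)
    arr = ser.to_numpy()
    out = np.zeros(len(arr), dtype=int)
    mask = (arr != 0) if preserve_zero else np.ones(len(arr), dtype=bool)
    m = int(mask.sum())
    if m == 0:
        logger.warning("bin_equal_count: all values are zero; returning all-zero bins")
    else:
        ranks = rankdata(arr[mask], method="average")
        out[mask] = np.ceil(ranks * n_bins / m).astype(int)
    return BinnedVector(values=pd.Series(out, index=ser.index),
                        n_bins=n_bins, zero_preserved=preserve_zero)


def residual_specificity(profile: CellTypeProfile) -> pd.DataFrame:
    """Residuals of each cell type's expression regressed on the dataset average.

    For each cell type c, fits E[., c] = a + b * Average by least squares
    and returns the residuals; the result has zero mean and zero sample
    covariance with the average, and is the cell-type-specific component of
    expression once the shared expression level is removed.
    """
    if profile.E.shape[0] < 3:
        raise ValueError("residual_specificity needs at least 3 genes")
    avg = profile.average.to_numpy(dtype=float)
    if np.ptp(avg) == 0:
        raise ValueError("average expression is constant; regression undefined")
    X = np.column_stack([np.ones_like(avg), avg])
    Y = profile.E.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid, index=profile.E.index, columns=profile.E.columns)


def top_decile_genes(scores, fraction: float = 0.10) -> list[str]:
    """The ceil(fraction * n) genes with the highest score.

    Boundary ties are broken by gene ID ascending so the set is
    deterministic; the default fraction reproduces the common
    "top 10% most specific genes" gene-set construction.
    """
    ser = pd.Series(scores, dtype=float)
    if len(ser) < 10:
        raise ValueError("top_decile_genes needs at least 10 genes")
    k = math.ceil(fraction * len(ser))
    ordered = ser.sort_index().sort_values(ascending=False, kind="stable")
    return list(ordered.index[:k])
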