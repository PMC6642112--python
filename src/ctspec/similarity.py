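"""Similarity of expression profiles across datasets.

Absolute expression levels are not comparable across scRNA-seq protocols, so
every comparison here works on within-dataset ranks: gene vectors are binned
into 100 equal-count bins before a Spearman correlation is taken.  Dataset
similarity correlates the binned dataset averages (zeros kept at zero);
cell-type similarity correlates binned residual-specificity vectors (no zero
carve-out — a residual of zero is not special).  A t-SNE embedding with
restarts, keeping the run with minimal Kullback-Leibler divergence, gives
the 2-D overview map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiles import CellTypeProfile
from .scores import bin_equal_count, residual_specificity

logger = logging.getLogger(__name__)

MIN_SHARED_GENES = 30
N_RANK_BINS = 100


@dataclass
class SimilarityMatrix:
    """Symmetric Spearman correlation matrix over datasets or cell types."""

    rho: pd.DataFrame
    n_shared_genes: pd.DataFrame

    @property
    def entity_ids(self) -> list[str]:
        return list(self.rho.index)


@dataclass
class Embedding2D:
    """2-D t-SNE coordinates chosen as the minimal-KL run over restarts."""

    coords: pd.DataFrame  # columns x, y
    kl_divergence: float
    restart_index: int
    seed: int

    @property
    def entity_ids(self) -> list[str]:
        return list(self.coords.index)


def _shared_genes(a: CellTypeProfile, b: CellTypeProfile) -> pd.Index:
    shared = a.E.index.intersection(b.E.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between {a.dataset_id} and "
            f"{b.dataset_id} (minimum {MIN_SHARED_GENES})")
    return shared


def dataset_correlation(a: CellTypeProfile, b: CellTypeProfile,
                        n_bins: int = N_RANK_BINS) -> tuple[float, int]:
    """Spearman correlation of the two datasets' binned average expression.

    Averages are restricted to shared genes and rank-binned per dataset
    (zeros preserved at bin 0) before correlating, which removes
    protocol-driven scale differences.
    """
    shared = _shared_genes(a, b)
    va = bin_equal_count(a.average.loc[shared], n_bins).values
    vb = bin_equal_count(b.average.loc[shared], n_bins).values
    rho = float(sps.spearmanr(va, vb).statistic)
    return rho, len(shared)


def celltype_correlation(a: CellTypeProfile, ct_a: str,
                         b: CellTypeProfile, ct_b: str,
                         n_bins: int = N_RANK_BINS) -> tuple[float, int]:
    """Spearman correlation of two cell types' binned residual specificity.

    Residual specificity (expression residualized on the dataset average) is
    computed per dataset over that dataset's own genes, restricted to the
    shared genes, and rank-binned with no zero carve-out.
    """
    shared = _shared_genes(a, b)
    ra = residual_specificity(a)[ct_a].loc[shared]
    rb = residual_specificity(b)[ct_b].loc[shared]
    va = bin_equal_count(ra, n_bins, preserve_zero=False).values
    vb = bin_equal_count(rb, n_bins, preserve_zero=False).values
    rho = float(sps.spearmanr(va, vb).statistic)
    return rho, len(shared)


def similarity_matrix(profiles: list[CellTypeProfile],
                      level: str = "dataset") -> SimilarityMatrix:
    """All-pairs similarity: ``level='dataset'`` correlates averages,
    ``level='celltype'`` correlates residual-specificity vectors of every
    dataset:cell_type entity."""
    if level == "dataset":
        ids = [p.dataset_id for p in profiles]
        getters = list(profiles)
    elif level == "celltype":
        ids, getters = [], []
        for p in profiles:
            for ct in p.cell_types:
                ids.append(f"{p.dataset_id}:{ct}")
                getters.append((p, ct))
    else:
        raise ValueError("level must be 'dataset' or 'celltype'")
    rho = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    nsh = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, j in combinations(range(len(ids)), 2):
        if level == "dataset":
            r, n = dataset_correlation(getters[i], getters[j])
        else:
            (pa, ca), (pb, cb) = getters[i], getters[j]
            r, n = celltype_correlation(pa, ca, pb, cb)
        rho.iat[i, j] = rho.iat[j, i] = r
        nsh.iat[i, j] = nsh.iat[j, i] = n
    return SimilarityMatrix(rho=rho, n_shared_genes=nsh)


def group_contrast(group1, group2) -> float:
    """Two-sided Mann-Whitney U P-value comparing two groups of correlations.

    Exact enumeration for small groups (both n <= 20, no ties), normal
    approximation with tie correction otherwise.
    """
    g1 = np.asarray(list(group1), dtype=float)
    g2 = np.asarray(list(group2), dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (g1.size <= 20 and g2.size <= 20) else "asymptotic"
    try:
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    except ValueError:
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def embed(features: pd.DataFrame, perplexity: float = 30.0,
          restarts: int = 100, seed: int = 0) -> Embedding2D:
    """t-SNE of entities (rows) into 2-D, keeping the minimal-KL restart.

    The embedding is run ``restarts`` times with sub-seeds derived from
    ``seed``; the run with the smallest Kullback-Leibler divergence wins.
    With fewer than 3x perplexity entities, perplexity is reduced (with a
    warning) so the conditional distributions remain well defined.
    """
    from sklearn.manifold import TSNE

    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("embedding needs at least 4 entities")
    if n < 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3)
        warnings.warn(f"perplexity {perplexity} too large for {n} entities; "
                      f"reduced to {new_p:.1f}", stacklevel=2)
        perplexity = new_p
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=restarts)
    best = None
    for i, s in enumerate(sub_seeds):
        tsne = TSNE(n_components=2, perplexity=perplexity, init="random",
                    random_state=int(s))
        coords = tsne.fit_transform(X)
        kl = float(tsne.kl_divergence_)
        if best is None or kl < best[0]:
            best = (kl, i, coords)
    kl, idx, coords = best
    df = pd.DataFrame(coords, index=features.index, columns=["x", "y"])
    return Embedding2D(coords=df, kl_divergence=kl, restart_index=idx, seed=seed)
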