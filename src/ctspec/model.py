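"""Gene-property regression of gene-based GWAS Z-scores on cell-type expression.

The model
---------

For a cell type c of one dataset,

    Z = b0 + E_c * b_E + A * b_A + B * b_B + e

where Z is the per-gene association Z-score (probit-transformed gene-based
P-value), E_c the per-gene mean log2 expression in cell type c, A the
average of E over all cell types of the dataset, and B optional technical
covariates (e.g. gene length).  Conditioning on A means b_E measures the
relation of the trait to *specific* expression in c, not to being expressed
at all.  The test of interest is one-sided, b_E > 0 (Student t, df = n - k).

Conditional variants extend the same design: the within-dataset joint model
adds a second cell type's expression; the cross-dataset (CD) models add the
other dataset's average expression (CD marginal) and its cell type's
expression (CD conditional), which lets signals from datasets with
incomparable absolute expression scales be compared through a shared gene
axis.

A gene-gene correlation matrix (LD-induced) may be attached to the
statistics; fitting then whitens both sides by its inverse Cholesky factor,
so ordinary least squares on the transformed data equals generalized least
squares on the original.

``GenePropertyModel`` is the model object (design + response);
``GenePropertyModel.fit()`` returns :class:`GenePropertyResults` with the
coefficient table and a ``summary()``.  The module-level ``fit_*`` helpers
build the standard designs from a :class:`GeneStats` and one or two
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiles import CellTypeProfile

DEFAULT_MIN_GENES = 50
COLLINEARITY_R = 0.999


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient (or nearly so)."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


@dataclass
class GeneStats:
    """Per-gene gene-based association statistics for one trait.

    ``z`` is indexed by gene ID.  ``confounders`` (matrix B) holds technical
    covariates such as gene length; it may be None.  ``gene_corr`` is an
    optional genes x genes correlation matrix (LD-induced); when present,
    fits are GLS via Cholesky whitening.
    """

    z: pd.Series
    confounders: pd.DataFrame | None = None
    gene_corr: pd.DataFrame | None = None
    trait_id: str = "trait"
    whitener: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z = pd.Series(self.z, dtype=float)
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("gene Z-scores must be finite")
        if self.confounders is not None:
            self.confounders = self.confounders.reindex(self.z.index)
            bad = [c for c in self.confounders.columns
                   if (self.confounders[c] == 0).all()]
            if bad:
                raise ValueError(f"confounder column(s) identically zero: {bad}")
        if self.gene_corr is not None:
            R = self.gene_corr
            if not np.allclose(R.values, R.values.T, atol=1e-8):
                raise ValueError("gene_corr must be symmetric")
            if not np.allclose(np.diag(R.values), 1.0, atol=1e-6):
                raise ValueError("gene_corr must have unit diagonal")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)


def z_from_p(p) -> pd.Series | np.ndarray:
    """Convert per-gene P-values to upper-tail standard normal Z-scores.

    Smaller P means larger Z.  P-values at (or numerically beyond) the open
    interval's edges are clipped to [1e-300, 1 - 1e-16] with a warning.
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("P-values must lie in [0, 1]")
    if (arr <= 0).any() or (arr >= 1 - 1e-16).any():
        warnings.warn("P-values at the boundary clipped to [1e-300, 1-1e-16]",
                      stacklevel=2)
    clipped = np.clip(arr, 1e-300, 1 - 1e-16)
    z = sps.norm.isf(clipped)
    if isinstance(p, pd.Series):
        return pd.Series(z, index=p.index)
    return z


def decorrelate(stats: GeneStats, ridge: float = 1e-6) -> GeneStats:
    """Whiten statistics by the inverse Cholesky factor of ``gene_corr``.

    Returns a new :class:`GeneStats` whose z (and confounders) have been
    pre-multiplied by W = L^-1 where gene_corr + ridge*I = L L'.  OLS on the
    whitened data equals GLS under the original correlation.  The whitening
    matrix is kept on the result so that design columns assembled later
    (expression, averages, the intercept) receive the same transform.
    """
    if stats.gene_corr is None:
        return stats
    R = stats.gene_corr.reindex(index=stats.z.index, columns=stats.z.index)
    if R.isna().any().any():
        raise ValueError("gene_corr does not cover all genes in z")
    A = R.to_numpy(dtype=float) + ridge * np.eye(len(R))
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("gene_corr is not positive definite after ridge") from exc
    W = np.linalg.inv(L)
    z_w = pd.Series(W @ stats.z.to_numpy(), index=stats.z.index)
    conf_w = None
    if stats.confounders is not None:
        conf_w = pd.DataFrame(W @ stats.confounders.to_numpy(dtype=float),
                              index=stats.confounders.index,
                              columns=stats.confounders.columns)
    out = GeneStats(z=z_w, confounders=conf_w, gene_corr=None,
                    trait_id=stats.trait_id)
    out.whitener = W
    return out


# ---------------------------------------------------------------------------
# Model / Results


class GenePropertyModel:
    """Least-squares gene-property model: z regressed on named design columns.

    Usually constructed through one of the classmethods, which assemble the
    standard designs (marginal, within-dataset joint, cross-dataset) from a
    :class:`GeneStats` and cell-type profiles over the gene intersection.
    """

    def __init__(self, z: pd.Series, exog: pd.DataFrame,
                 tested_terms: list[str], trait_id: str = "trait",
                 check_collinear: bool = True):
        common = exog.index.intersection(z.index)
        self.z = z.loc[common].to_numpy(dtype=float)
        self.exog = exog.loc[common]
        self.gene_ids = list(common)
        self.tested_terms = list(tested_terms)
        self.trait_id = trait_id
        self.term_names = list(exog.columns)
        if check_collinear:
            self._check_rank()

    # -- design construction -------------------------------------------------

    @classmethod
    def marginal(cls, stats: GeneStats, profile: CellTypeProfile, cell_type: str,
                 min_genes: int = DEFAULT_MIN_GENES) -> "GenePropertyModel":
        """z ~ 1 + E_c + Average + B for one cell type of one dataset."""
        cols = {
            _term(profile, cell_type): profile.E[cell_type],
            _avg_term(profile): profile.average,
        }
        return cls._assemble(stats, cols, tested=[_term(profile, cell_type)],
                             min_genes=min_genes)

    @classmethod
    def joint_within(cls, stats: GeneStats, profile: CellTypeProfile,
                     ct_a: str, ct_b: str,
                     min_genes: int = DEFAULT_MIN_GENES) -> "GenePropertyModel":
        """z ~ 1 + E_a + E_b + Average + B for two cell types of one dataset."""
        cols = {
            _term(profile, ct_a): profile.E[ct_a],
            _term(profile, ct_b): profile.E[ct_b],
            _avg_term(profile): profile.average,
        }
        return cls._assemble(stats, cols,
                             tested=[_term(profile, ct_a), _term(profile, ct_b)],
                             min_genes=min_genes, soft_pair=True)

    @classmethod
    def cd_marginal(cls, stats: GeneStats, profile1: CellTypeProfile, ct: str,
                    profile2: CellTypeProfile,
                    min_genes: int = DEFAULT_MIN_GENES) -> "GenePropertyModel":
        """z ~ 1 + E_c(ds1) + Average(ds1) + Average(ds2) + B."""
        a1, a2 = _avg_terms(profile1, profile2)
        cols = {
            _term(profile1, ct): profile1.E[ct],
            a1: profile1.average,
            a2: profile2.average,
        }
        return cls._assemble(stats, cols, tested=[_term(profile1, ct)],
                             min_genes=min_genes)

    @classmethod
    def cd_conditional(cls, stats: GeneStats, profile1: CellTypeProfile, ct1: str,
                       profile2: CellTypeProfile, ct2: str,
                       min_genes: int = DEFAULT_MIN_GENES) -> "GenePropertyModel":
        """z ~ 1 + E_c1(ds1) + E_c2(ds2) + Average(ds1) + Average(ds2) + B."""
        a1, a2 = _avg_terms(profile1, profile2)
        t1 = _term(profile1, ct1)
        t2 = _term(profile2, ct2)
        if t2 == t1:
            t2 += "'"
        cols = {
            t1: profile1.E[ct1],
            t2: profile2.E[ct2],
            a1: profile1.average,
            a2: profile2.average,
        }
        return cls._assemble(stats, cols, tested=[t1, t2],
                             min_genes=min_genes, soft_pair=True)

    @classmethod
    def _assemble(cls, stats: GeneStats, cols: dict[str, pd.Series],
                  tested: list[str], min_genes: int,
                  soft_pair: bool = False) -> "GenePropertyModel":
        design = pd.DataFrame(cols)
        if stats.confounders is not None:
            for c in stats.confounders.columns:
                design[str(c)] = stats.confounders[c]
        common = design.index.intersection(stats.z.index)
        if len(common) < min_genes:
            raise ValueError(
                f"only {len(common)} genes shared between statistics and profiles "
                f"(minimum {min_genes})")
        design = design.loc[common]
        z = stats.z.loc[common]
        intercept = pd.Series(1.0, index=common)
        if stats.gene_corr is not None:
            # whiten on the intersected gene set so z and design transform
            # consistently: OLS on the whitened system == GLS on the original
            sub = GeneStats(z=z, gene_corr=stats.gene_corr.loc[common, common],
                            trait_id=stats.trait_id)
            sub = decorrelate(sub)
            z = sub.z
            W = sub.whitener
            design = pd.DataFrame(W @ design.to_numpy(dtype=float),
                                  index=common, columns=design.columns)
            intercept = pd.Series(W @ intercept.to_numpy(), index=common)
        exog = pd.concat([intercept.rename("Intercept"), design], axis=1)
        model = cls(z, exog, tested_terms=tested, trait_id=stats.trait_id,
                    check_collinear=not soft_pair)
        model._soft_pair = soft_pair
        return model

    # -- diagnostics ---------------------------------------------------------

    def _check_rank(self) -> None:
        X = self.exog.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            cols = _dependent_columns(self.exog)
            raise CollinearityError(
                f"rank-deficient design (rank {rank} < {X.shape[1]} terms); "
                f"dependent columns: {cols}", columns=cols)

    def _pair_collinear(self) -> bool:
        """True when the two tested expression terms are (near-)collinear
        after residualizing on the remaining covariates."""
        if len(self.tested_terms) != 2:
            return False
        others = [c for c in self.term_names if c not in self.tested_terms]
        Xo = self.exog[others].to_numpy(dtype=float)
        resid = {}
        for t in self.tested_terms:
            y = self.exog[t].to_numpy(dtype=float)
            coef, *_ = np.linalg.lstsq(Xo, y, rcond=None)
            resid[t] = y - Xo @ coef
        a, b = (resid[t] for t in self.tested_terms)
        sa, sb = np.linalg.norm(a), np.linalg.norm(b)
        if sa == 0 or sb == 0:
            return True
        r = float(a @ b / (sa * sb))
        if abs(r) > COLLINEARITY_R:
            return True
        X = self.exog.to_numpy(dtype=float)
        return np.linalg.matrix_rank(X) < X.shape[1]

    # -- fitting -------------------------------------------------------------

    def fit(self) -> "GenePropertyResults":
        """Ordinary least squares with one-sided t-tests on the tested terms."""
        collinear = getattr(self, "_soft_pair", False) and self._pair_collinear()
        X = self.exog.to_numpy(dtype=float)
        y = self.z
        n, k = X.shape
        df = n - k
        if df <= 0:
            raise ValueError(f"non-positive degrees of freedom (n={n}, k={k})")
        if collinear:
            return GenePropertyResults(
                model=self, params=pd.Series(np.nan, index=self.term_names),
                bse=pd.Series(np.nan, index=self.term_names),
                tvalues=pd.Series(np.nan, index=self.term_names),
                p_one_sided=pd.Series(np.nan, index=self.tested_terms),
                df_resid=df, n_genes_used=n, collinear=True,
                focus=self.tested_terms[0])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / df
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p1 = pd.Series({term: float(sps.t.sf(t[self.term_names.index(term)], df))
                        for term in self.tested_terms})
        return GenePropertyResults(
            model=self,
            params=pd.Series(beta, index=self.term_names),
            bse=pd.Series(se, index=self.term_names),
            tvalues=pd.Series(t, index=self.term_names),
            p_one_sided=p1, df_resid=df, n_genes_used=n,
            collinear=False, focus=self.tested_terms[0])


@dataclass
class GenePropertyResults:
    """Fit results: coefficient table plus one-sided P for the tested term(s).

    ``focus`` names the term whose scalar accessors (``beta``, ``se``,
    ``t_stat``, ``p_value``) are exposed; for joint fits, ``for_term``
    returns a view focused on the other tested term.
    """

    model: GenePropertyModel
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    p_one_sided: pd.Series
    df_resid: int
    n_genes_used: int
    collinear: bool
    focus: str

    @property
    def term_names(self) -> list[str]:
        return list(self.params.index)

    @property
    def beta(self) -> float:
        return float(self.params[self.focus]) if not self.collinear else float("nan")

    @property
    def se(self) -> float:
        return float(self.bse[self.focus]) if not self.collinear else float("nan")

    @property
    def t_stat(self) -> float:
        return float(self.tvalues[self.focus]) if not self.collinear else float("nan")

    @property
    def p_value(self) -> float:
        """One-sided (upper-tail) P for the focus term; NaN when collinear."""
        if self.collinear:
            return float("nan")
        return float(self.p_one_sided[self.focus])

    def for_term(self, term: str) -> "GenePropertyResults":
        if term not in self.p_one_sided.index:
            raise KeyError(f"{term!r} is not a tested term")
        return replace(self, focus=term)

    def summary(self) -> str:
        lines = [
            f"Gene-property regression ({self.model.trait_id})",
            f"  genes used: {self.n_genes_used}   df: {self.df_resid}"
            + ("   [collinear pair — estimates withheld]" if self.collinear else ""),
            f"  {'term':<28}{'beta':>12}{'se':>12}{'t':>10}{'P(one-sided)':>14}",
        ]
        for term in self.term_names:
            p = (f"{self.p_one_sided[term]:>14.3g}"
                 if term in self.p_one_sided.index and not self.collinear else " " * 14)
            b = self.params[term]
            s = self.bse[term]
            t = self.tvalues[term]
            lines.append(f"  {term:<28}{b:>12.4g}{s:>12.4g}{t:>10.3f}{p}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Convenience fit functions (the surface the workflow consumes)


def fit_marginal(stats: GeneStats, profile: CellTypeProfile, cell_type: str,
                 min_genes: int = DEFAULT_MIN_GENES) -> GenePropertyResults:
    """Marginal association of one cell type (one-sided test of b_E > 0)."""
    return GenePropertyModel.marginal(stats, profile, cell_type,
                                      min_genes=min_genes).fit()


def fit_joint_within(stats: GeneStats, profile: CellTypeProfile,
                     ct_a: str, ct_b: str,
                     min_genes: int = DEFAULT_MIN_GENES,
                     ) -> tuple[GenePropertyResults, GenePropertyResults]:
    """Joint within-dataset fit; returns (a conditioned on b, b conditioned on a)."""
    res = GenePropertyModel.joint_within(stats, profile, ct_a, ct_b,
                                         min_genes=min_genes).fit()
    ta, tb = res.model.tested_terms
    return res.for_term(ta), res.for_term(tb)


def fit_cd_marginal(stats: GeneStats, profile1: CellTypeProfile, ct: str,
                    profile2: CellTypeProfile,
                    min_genes: int = DEFAULT_MIN_GENES) -> GenePropertyResults:
    """Cross-dataset marginal fit: conditions on both datasets' averages."""
    return GenePropertyModel.cd_marginal(stats, profile1, ct, profile2,
                                         min_genes=min_genes).fit()


def fit_cd_conditional(stats: GeneStats, profile1: CellTypeProfile, ct1: str,
                       profile2: CellTypeProfile, ct2: str,
                       min_genes: int = DEFAULT_MIN_GENES,
                       ) -> tuple[GenePropertyResults, GenePropertyResults]:
    """Cross-dataset conditional fit of two cell types from two datasets."""
    res = GenePropertyModel.cd_conditional(stats, profile1, ct1, profile2, ct2,
                                           min_genes=min_genes).fit()
    t1, t2 = res.model.tested_terms
    return res.for_term(t1), res.for_term(t2)


# ---------------------------------------------------------------------------
# helpers / I/O


def _term(profile: CellTypeProfile, cell_type: str) -> str:
    if cell_type not in profile.E.columns:
        raise KeyError(f"cell type {cell_type!r} not in dataset {profile.dataset_id}")
    return f"{profile.dataset_id}:{cell_type}"


def _avg_term(profile: CellTypeProfile) -> str:
    return f"Average[{profile.dataset_id}]"


def _avg_terms(profile1: CellTypeProfile, profile2: CellTypeProfile) -> tuple[str, str]:
    """Distinct Average-term names even when the dataset ids coincide, so an
    exact duplicate average column is caught by the rank check rather than
    silently collapsed in the design."""
    a1, a2 = _avg_term(profile1), _avg_term(profile2)
    if a2 == a1:
        a2 += "'"
    return a1, a2


def _dependent_columns(exog: pd.DataFrame) -> list[str]:
    """Greedy scan for the columns that do not extend the design's rank."""
    X = exog.to_numpy(dtype=float)
    dep, basis = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(exog.columns):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            basis = cand
        else:
            dep.append(name)
    return dep


def read_gene_stats(path, trait_id: str | None = None,
                    length_confounders: bool = True) -> GeneStats:
    """Read gene statistics TSV (GENE plus Z or P; MAGMA dialect accepted).

    Accepts a plain GENE/Z(/P) table or the MAGMA gene-analysis layout
    (GENE CHR START STOP NSNPS NPARAM N ZSTAT P).  When a LENGTH column is
    present (or derivable from START/STOP), gene length and log length are
    attached as default technical confounders.
    """
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    df.columns = [c.upper() for c in df.columns]
    if "GENE" not in df.columns:
        raise ValueError("gene statistics file needs a GENE column")
    df = df.set_index("GENE")
    df.index = df.index.astype(str)
    if "ZSTAT" in df.columns:
        z = df["ZSTAT"].astype(float)
    elif "Z" in df.columns:
        z = df["Z"].astype(float)
    elif "P" in df.columns:
        z = z_from_p(df["P"].astype(float))
    else:
        raise ValueError("gene statistics file needs a Z, ZSTAT or P column")
    conf = None
    if length_confounders:
        if "LENGTH" in df.columns:
            length = df["LENGTH"].astype(float)
        elif {"START", "STOP"}.issubset(df.columns):
            length = (df["STOP"] - df["START"]).astype(float).abs()
        else:
            length = None
        if length is not None and (length > 0).all():
            conf = pd.DataFrame({"length": length, "log_length": np.log(length)})
    return GeneStats(z=pd.Series(z, index=df.index),
                     confounders=conf,
                     trait_id=trait_id if trait_id is not None else "trait")
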