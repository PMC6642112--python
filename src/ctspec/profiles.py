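"""Per-cell-type expression profiles.

Raw single-cell matrices (counts, UMI, CPM, RPKM or TPM) are reduced to a
genes x cell-types matrix of mean log2 expression: expression is converted to
CPM when it arrives as counts, log2(x+1)-transformed per cell, and averaged
over the cells of each type.  Every profile carries an ``Average`` column,
the arithmetic mean over its cell types, which downstream models use as the
covariate that turns "expression" into "specificity".  Tissue-level TPM
matrices (GTEx-style) pass through the same container after winsorizing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = ("count", "umi", "cpm", "rpkm", "tpm")

AVERAGE_COL = "Average"


@dataclass
class RawExpressionMatrix:
    """A genes x cells expression matrix with per-cell type labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression values, genes in rows (index = gene IDs),
        cells in columns (columns = cell IDs).
    unit : str
        One of ``count``, ``umi``, ``cpm``, ``rpkm``, ``tpm``.  Counts/UMI
        are normalised to CPM before profiling; the rest are used as-is.
    labels : pandas.Series
        Maps cell ID -> cell-type name.  Cells without a label are ignored
        by :func:`build_profile`.
    """

    values: pd.DataFrame
    unit: str
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        vals = np.asarray(self.values.values, dtype=float)
        if (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene IDs: {dups[:5]}")
        self.labels = pd.Series(self.labels)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CellTypeProfile:
    """Genes x cell-types matrix of mean log2 expression plus the dataset average.

    ``E`` holds one column per cell type; ``average`` is the arithmetic mean
    of ``E`` across cell types (recomputed whenever cell types are subset).
    """

    dataset_id: str
    E: pd.DataFrame
    average: pd.Series = field(default=None)  # type: ignore[assignment]
    species: str = "other"

    def __post_init__(self) -> None:
        if self.average is None:
            self.average = self.E.mean(axis=1)
        self.average = pd.Series(self.average).reindex(self.E.index)
        if len(self.E.columns) != len(set(self.E.columns)):
            raise ValueError(f"duplicate cell-type names in dataset {self.dataset_id}")
        if (np.asarray(self.E.values, dtype=float) < 0).any():
            raise ValueError("profile expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.E.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.E.columns)

    @property
    def n_cell_types(self) -> int:
        return self.E.shape[1]


@dataclass
class GeneMapping:
    """Source -> target gene-ID mapping (ortholog or symbol/alias table).

    Under the ``one_to_one_ortholog`` policy a source and a target gene may
    each appear at most once; violations of either side are dropped rather
    than arbitrated, mirroring the standard exclusion of genes with
    duplicated target IDs.
    """

    pairs: dict[str, str]
    policy: str = "one_to_one_ortholog"

    @classmethod
    def from_table(cls, path, policy: str = "one_to_one_ortholog") -> "GeneMapping":
        """Read a two-column (source, target) whitespace/tab table."""
        df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"],
                         dtype=str, comment="#")
        pairs = dict(zip(df["source"], df["target"]))
        return cls(pairs=pairs, policy=policy)


def to_cpm(raw: RawExpressionMatrix) -> RawExpressionMatrix:
    """Normalise each cell's counts to counts-per-million.

    Only valid for ``count``/``umi`` input; every cell column is rescaled to
    sum to 1e6.  A cell with zero total is an error (it carries no signal and
    would divide by zero).
    """
    if raw.unit not in ("count", "umi"):
        raise ValueError(f"to_cpm expects count or UMI input, got {raw.unit!r}")
    totals = raw.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"cell(s) with zero total count: {list(zero.index[:5])}")
    cpm = raw.values.div(totals, axis=1) * 1e6
    return RawExpressionMatrix(values=cpm, unit="cpm", labels=raw.labels)


def log_transform(values):
    """Element-wise log2(x + 1); accepts arrays or DataFrames, shape preserved."""
    arr = np.asarray(values, dtype=float) if not isinstance(values, (pd.DataFrame, pd.Series)) else values
    if (np.asarray(arr) < 0).any():
        raise ValueError("log_transform requires non-negative input")
    return np.log2(arr + 1.0)


def build_profile(
    raw: RawExpressionMatrix,
    dataset_id: str = "dataset",
    species: str = "other",
    min_cells_per_type: int = 1,
) -> CellTypeProfile:
    """Collapse a raw matrix into a per-cell-type log-average profile.

    Counts/UMI are first CPM-normalised; values are log2(x+1)-transformed per
    cell and then averaged over the cells of each labelled type (log first,
    then average).  Cell types with fewer than ``min_cells_per_type``
    labelled cells are dropped.  The ``Average`` column is the mean of the
    per-type columns.
    """
    if raw.unit in ("count",):
        raw = to_cpm(raw)
    labels = raw.labels.dropna()
    labels = labels[labels.index.isin(raw.values.columns)]
    if labels.empty:
        raise ValueError("no labeled cells: every profile needs at least one labelled cell")
    logged = log_transform(raw.values[labels.index])
    cols = {}
    for ct, cells in labels.groupby(labels).groups.items():
        if len(cells) < min_cells_per_type:
            logger.info("dropping cell type %r (%d cells < %d)", ct, len(cells), min_cells_per_type)
            continue
        cols[str(ct)] = logged[list(cells)].mean(axis=1)
    if not cols:
        raise ValueError("no cell type survived the min-cells filter")
    E = pd.DataFrame(cols)
    return CellTypeProfile(dataset_id=dataset_id, E=E, species=species)


def subset_profile(profile: CellTypeProfile, keep: list[str]) -> CellTypeProfile:
    """Restrict a profile to ``keep`` cell types, recomputing the average.

    Used to condition on the average over a subset of cell types (e.g. brain
    cell types only), which redefines what "specific" means for the model.
    """
    if not keep:
        raise ValueError("keep must be non-empty")
    unknown = [ct for ct in keep if ct not in profile.E.columns]
    if unknown:
        raise KeyError(f"unknown cell type(s) in dataset {profile.dataset_id}: {unknown}")
    E = profile.E[list(keep)].copy()
    return CellTypeProfile(dataset_id=profile.dataset_id, E=E, species=profile.species)


def map_genes(profile: CellTypeProfile, mapping: GeneMapping) -> CellTypeProfile:
    """Rename profile genes through a mapping table, dropping the unmapped.

    Genes absent from the mapping are dropped; when two source genes map to
    the same target, both are excluded (duplicated target IDs are
    uninterpretable for a gene-keyed regression).
    """
    src = pd.Series(mapping.pairs)
    mapped = src[src.index.isin(profile.E.index)]
    counts = mapped.value_counts()
    dup_targets = set(counts[counts > 1].index)
    keep = mapped[~mapped.isin(dup_targets)]
    if keep.empty:
        raise ValueError("gene mapping has empty intersection with the profile")
    E = profile.E.loc[keep.index].copy()
    E.index = keep.values
    n_in, n_out = profile.E.shape[0], E.shape[0]
    logger.info("map_genes (%s): %d of %d genes mapped (%d dropped, %d duplicated targets)",
                profile.dataset_id, n_out, n_in, n_in - n_out, len(dup_targets))
    return CellTypeProfile(dataset_id=profile.dataset_id, E=E, species="human")


def tissue_profile(
    tpm: pd.DataFrame,
    dataset_id: str = "tissue",
    min_avg_tpm: float = 1.0,
    winsor: float = 50.0,
) -> CellTypeProfile:
    """Build a tissue profile from a genes x tissues TPM matrix.

    Keeps genes whose per-tissue average TPM exceeds ``min_avg_tpm`` in at
    least one tissue, winsorizes values above ``winsor`` down to ``winsor``,
    then log2(x+1)-transforms.  The input may be per-sample averages already;
    columns are treated as tissues.
    """
    vals = np.asarray(tpm.values, dtype=float)
    if (vals < 0).any():
        raise ValueError("TPM values must be non-negative")
    keep = (tpm > min_avg_tpm).any(axis=1)
    capped = tpm[keep].clip(upper=winsor)
    E = np.log2(capped + 1.0)
    return CellTypeProfile(dataset_id=dataset_id, E=E, species="human")


# ---------------------------------------------------------------------------
# I/O


def write_profile(profile: CellTypeProfile, path) -> None:
    """Write a profile as TSV: GENE, <cell types...>, Average."""
    out = profile.E.copy()
    out[AVERAGE_COL] = profile.average
    out.index.name = "GENE"
    out.to_csv(path, sep="\t")


def read_profile(path, dataset_id: str | None = None, species: str = "other") -> CellTypeProfile:
    """Read a profile TSV (GENE + per-cell-type columns, optional Average).

    If an ``Average`` column is present it is dropped and recomputed from
    the cell-type columns so the container invariant holds exactly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if AVERAGE_COL in df.columns:
        df = df.drop(columns=[AVERAGE_COL])
    ds = dataset_id if dataset_id is not None else _stem(path)
    return CellTypeProfile(dataset_id=ds, E=df, species=species)


def read_expression(path, labels_path, unit: str) -> RawExpressionMatrix:
    """Read raw expression (dense or sparse-triplet TSV) plus a label table.

    Dense: genes in rows, header row of cell IDs.  Sparse: three columns
    (gene, cell, value), no header requirement beyond column count.
    """
    head = pd.read_csv(path, sep="\t", nrows=5)
    if head.shape[1] == 3 and head.columns[2] not in ("",):
        probe = pd.read_csv(path, sep="\t", header=None, nrows=1)
        has_header = not _is_number(probe.iloc[0, 2])
        df = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                         names=None if has_header else ["gene", "cell", "value"])
        df.columns = ["gene", "cell", "value"]
        values = df.pivot_table(index="gene", columns="cell", values="value",
                                fill_value=0.0, aggfunc="sum")
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", header=None, names=["cell", "cell_type"],
                         dtype=str, comment="#").set_index("cell")["cell_type"]
    return RawExpressionMatrix(values=values, unit=unit, labels=labels)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def _stem(path) -> str:
    import os
    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base
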