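"""Synthetic expression profiles and gene statistics with known ground truth.

The generator emulates exactly the statistical structure the gene-property
regression consumes: per-gene baseline expression shared by all cell types
(log-normal), sparse "expression programs" that shift a subset of genes up
in their member cell types (log-scale additive shifts), per-cell noise, and
optional zero inflation.  Gene-based Z-scores are then drawn from the
model's generative direction — a sum of causal-program loadings
(standardized across genes) plus standard-normal noise — so planted signals
are recoverable and null fixtures are exactly null.

Everything is a pure function of the spec (seed included), so fixtures are
reproducible bit-for-bit and truth records can be matched to workflow
output for recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import GeneStats
from .profiles import CellTypeProfile, RawExpressionMatrix

DEFAULT_LOADING_FRACTION = 0.05
DEFAULT_LOADING_SCALE = 2.0  # log2 units


@dataclass
class DatasetSpec:
    """One synthetic dataset: its cell types and cells per type."""

    dataset_id: str
    n_cell_types: int
    cells_per_type: int = 30

    @property
    def cell_types(self) -> list[str]:
        return [f"ct{i}" for i in range(self.n_cell_types)]


@dataclass
class ProgramSpec:
    """A cell-type-specific expression program.

    ``members`` lists the (dataset_id, cell_type) pairs that express the
    program; the same program placed in several datasets models a shared
    biological cell identity observed by independent studies.  Loadings are
    sparse (``loading_fraction`` of genes) additive shifts on the log2
    scale, scaled by ``loading_scale``.
    """

    program_id: str
    members: list[tuple[str, str]]
    loading_fraction: float = DEFAULT_LOADING_FRACTION
    loading_scale: float = DEFAULT_LOADING_SCALE


@dataclass
class FixtureSpec:
    """Full description of a synthetic study; all generators key off this.

    ``causal_programs`` maps program_id -> effect size on the gene Z-scores.
    ``noise_sd`` is the per-cell log2 expression noise; ``z_noise_sd`` the
    residual scale of the Z-scores (1.0 = exactly null-calibrated);
    ``zero_inflation`` the fraction of expression entries dropped to zero.
    ``length_leakage`` optionally lets the simulated gene-length confounder
    leak into z, to exercise the technical-covariate correction.
    """

    n_genes: int
    datasets: list[DatasetSpec]
    programs: list[ProgramSpec] = field(default_factory=list)
    causal_programs: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    zero_inflation: float = 0.2
    z_noise_sd: float = 1.0
    length_leakage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must lie in [0, 1)")
        declared = {(d.dataset_id, ct) for d in self.datasets for ct in d.cell_types}
        for prog in self.programs:
            missing = [m for m in prog.members if tuple(m) not in declared]
            if missing:
                raise ValueError(
                    f"program {prog.program_id!r} references undeclared "
                    f"cell types: {missing}")
        unknown = [p for p in self.causal_programs
                   if p not in {pr.program_id for pr in self.programs}]
        if unknown:
            raise ValueError(f"causal_programs reference unknown programs: {unknown}")
        for eff in self.causal_programs.values():
            if not np.isfinite(eff):
                raise ValueError("causal effect sizes must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


def _materialize(spec: FixtureSpec):
    """Deterministic gene-level structure shared by profile and Z generators:
    baseline log2 means and per-program loading vectors."""
    rng = np.random.default_rng(spec.seed)
    baseline = rng.normal(1.0, 1.0, size=spec.n_genes)  # log2 of log-normal(1,1)
    loadings: dict[str, np.ndarray] = {}
    for prog in spec.programs:
        n_loaded = max(1, int(round(prog.loading_fraction * spec.n_genes)))
        idx = rng.choice(spec.n_genes, size=n_loaded, replace=False)
        vec = np.zeros(spec.n_genes)
        vec[idx] = prog.loading_scale * rng.uniform(0.5, 1.5, size=n_loaded)
        loadings[prog.program_id] = vec
    return baseline, loadings


def simulate_profiles(spec: FixtureSpec) -> list[RawExpressionMatrix]:
    """Generate one raw genes x cells matrix per declared dataset.

    A cell of type t in dataset d has log2 expression
    baseline + sum(member-program loadings) + N(0, noise_sd) per gene,
    exponentiated to a CPM-like positive scale; ``zero_inflation`` of the
    entries are then set to zero.
    """
    baseline, loadings = _materialize(spec)
    members: dict[tuple[str, str], list[str]] = {}
    for prog in spec.programs:
        for m in prog.members:
            members.setdefault(tuple(m), []).append(prog.program_id)
    out = []
    for ds_i, ds in enumerate(spec.datasets):
        rng = np.random.default_rng([spec.seed, 1000 + ds_i])
        cols, cells, labels = [], [], {}
        for ct in ds.cell_types:
            shift = np.zeros(spec.n_genes)
            for pid in members.get((ds.dataset_id, ct), []):
                shift = shift + loadings[pid]
            for j in range(ds.cells_per_type):
                log2_expr = (baseline + shift
                             + rng.normal(0.0, spec.noise_sd, size=spec.n_genes))
                expr = np.exp2(log2_expr)
                if spec.zero_inflation > 0:
                    drop = rng.random(spec.n_genes) < spec.zero_inflation
                    expr[drop] = 0.0
                cell_id = f"{ds.dataset_id}.{ct}.c{j}"
                cols.append(expr)
                cells.append(cell_id)
                labels[cell_id] = ct
        values = pd.DataFrame(np.column_stack(cols), index=spec.gene_ids,
                              columns=cells)
        out.append(RawExpressionMatrix(values=values, unit="cpm",
                                       labels=pd.Series(labels)))
    return out


def simulate_gene_stats(spec: FixtureSpec, profiles=None,
                        z_seed: int | None = None) -> tuple[GeneStats, dict]:
    """Generate gene-based Z-scores loading on the causal programs.

    z = sum over causal programs of effect * standardized loading vector
    plus N(0, z_noise_sd^2), plus an optional weak leakage of log gene
    length.  ``z_seed`` reseeds only the Z-score noise, yielding a second
    trait that shares the planted expression programs (the program loadings
    stay tied to ``spec.seed``).  Returns (stats, truth) where truth records
    the planted causal programs, their effects and member cell types for
    recovery scoring.
    """
    _, loadings = _materialize(spec)
    rng = np.random.default_rng([spec.seed if z_seed is None else z_seed, 7])
    z = rng.normal(0.0, spec.z_noise_sd, size=spec.n_genes)
    for pid, effect in spec.causal_programs.items():
        vec = loadings[pid]
        std = (vec - vec.mean()) / vec.std()
        z = z + effect * std
    length = np.exp(rng.normal(np.log(1e4), 1.0, size=spec.n_genes))
    if spec.length_leakage:
        log_len = np.log(length)
        z = z + spec.length_leakage * (log_len - log_len.mean()) / log_len.std()
    conf = pd.DataFrame({"length": length, "log_length": np.log(length)},
                        index=spec.gene_ids)
    stats = GeneStats(z=pd.Series(z, index=spec.gene_ids), confounders=conf,
                      trait_id=f"synthetic_seed{spec.seed}")
    truth = {
        "seed": spec.seed,
        "causal_programs": [
            {"program_id": pid, "effect": float(eff),
             "members": [list(m) for m in prog.members]}
            for prog in spec.programs
            for pid, eff in spec.causal_programs.items()
            if pid == prog.program_id
        ],
    }
    return stats, truth


def make_confounded_fixture(n_genes: int, coupling: float,
                            zero_inflation: float = 0.0,
                            n_cell_types: int = 10,
                            seed: int = 0) -> CellTypeProfile:
    """A profile whose apparent specificity is confounded with mean expression.

    Each gene favors one cell type with a concentration weight; the weight's
    rank correlation with the gene's mean expression is set by ``coupling``
    in the direction real data show — ubiquitously high-expressed
    (housekeeping-like) genes spread evenly across cell types while specific
    genes sit lower — so, for any one cell type, the S score of the
    non-favored majority of genes rises with mean expression and binned S
    scores correlate positively with average-expression bins.
    ``zero_inflation`` adds mean-independent dropout, which reproduces the
    same confounding through the zeros alone: a dropped entry lowers both
    the gene's S (to 0, bin 0) and its recomputed average.  At
    coupling = 0 with no zero inflation the binned S score carries no mean
    information.
    """
    if not (0 <= coupling <= 1):
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    C = n_cell_types
    log2_mean = rng.normal(1.0, 1.0, size=n_genes)
    favored = rng.integers(0, C, size=n_genes)
    # latent concentration: anticorrelated with mean-expression rank
    z_rank = sps.norm.ppf((sps.rankdata(log2_mean) - 0.5) / n_genes)
    u = (-coupling * z_rank
         + math.sqrt(1.0 - coupling ** 2) * rng.normal(0.0, 1.0, size=n_genes))
    gamma = np.exp(1.0 + u)
    weights = np.ones((n_genes, C))
    weights[np.arange(n_genes), favored] += gamma
    weights /= weights.sum(axis=1, keepdims=True)
    E = np.exp2(log2_mean)[:, None] * C * weights  # row mean == 2**log2_mean
    if zero_inflation > 0:
        drop = rng.random((n_genes, C)) < zero_inflation
        E[drop] = 0.0
    genes = [f"g{i:05d}" for i in range(n_genes)]
    df = pd.DataFrame(E, index=genes, columns=[f"ct{i}" for i in range(C)])
    return CellTypeProfile(dataset_id=f"confounded_c{coupling}", E=df)
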