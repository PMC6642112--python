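"""Three-step cell-type association workflow.

Step 1 fits the marginal gene-property regression for every cell type of
every dataset and applies a Bonferroni threshold over the total number of
dataset-cell-type tests.  Step 2 runs a within-dataset stepwise conditional
analysis: candidates (ordered by marginal P) are kept only when their signal
survives conditioning on each already-retained cell type, judged through
proportional significance (PS) — the ratio of -log10 conditional P to
-log10 marginal P.  Step 3 compares the survivors across datasets with
cross-dataset (CD) conditional models and clusters them into independent
signals by forward selection: a cell type founds a new cluster only when its
CD PS against every existing founder exceeds the independence threshold in
both directions.

The pairwise PS rules classify each conditioned pair into eight scenarios
(independent, partially joint, jointly explained, driver with or without
residual signal, their mirrored forms after the flip rule, and an ambiguous
remainder), which determine whether both, or only the stronger, cell type
survives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    GeneStats,
    fit_marginal,
    fit_joint_within,
    fit_cd_marginal,
    fit_cd_conditional,
)
from .profiles import CellTypeProfile

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class Thresholds:
    """PS / P-value thresholds of the pairwise decision rules.

    ps_joint: below this in both directions the pair is jointly explained.
    ps_driver: at/above this (with a non-significant reverse conditional P)
        one cell type fully drives the other.
    ps_strong: at/above this in both directions the pair is independent.
    p_nominal: nominal significance used for the reverse conditional P.
    ps_independent: step-3 mutual-PS threshold for founding a new cluster.
    collinearity: residualized-correlation level treated as collinear.
    """

    ps_joint: float = 0.2
    ps_driver: float = 0.5
    ps_strong: float = 0.8
    p_nominal: float = 0.05
    ps_independent: float = 0.5
    collinearity: float = 0.999

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        import yaml
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**{k: float(v) for k, v in cfg.items()})


@dataclass
class ConditionalPairResult:
    """Within-dataset conditioned pair: P-values, PS, scenario and action.

    Convention: ``ct_a`` is the cell type with the smaller marginal P.
    ``scenario`` is 1-8 (None when the pair is collinear); ``action`` is one
    of retain_both / retain_a_drop_b / retain_b_drop_a / flagged_colinear /
    ambiguous (ambiguous retains a).
    """

    ct_a: str
    ct_b: str
    p_a: float
    p_b: float
    p_ab: float | None
    p_ba: float | None
    ps_ab: float | None
    ps_ba: float | None
    scenario: int | None
    action: str

    @property
    def retains_b(self) -> bool:
        return self.action in ("retain_both", "retain_b_drop_a")

    @property
    def retains_a(self) -> bool:
        return self.action != "retain_b_drop_a"

    def retains(self, cell_type: str) -> bool:
        """Whether the named cell type survives this pairwise comparison."""
        if cell_type == self.ct_a:
            return self.retains_a
        if cell_type == self.ct_b:
            return self.retains_b
        raise KeyError(f"{cell_type!r} is not part of this pair")


@dataclass
class CrossDatasetPairResult:
    """Cross-dataset pair: CD marginal/conditional P and CD PS per entity."""

    entity_1: str
    entity_2: str
    cd_marginal_p: tuple[float, float]
    cd_conditional_p: tuple[float, float]
    cd_ps: tuple[float, float]
    avg_explained: tuple[bool, bool]
    colinear: bool = False


@dataclass
class WorkflowSummary:
    """Per-trait counts and identities at each workflow step.

    step3_independent maps each cluster founder to its cluster members
    (founder included); the step-wise subset relation
    step3 founders <= step2 <= step1 holds by construction.
    """

    trait_id: str
    step1_significant: list[tuple[str, str, float]]
    step2_retained: list[tuple[str, str]]
    step3_independent: dict[tuple[str, str], list[tuple[str, str]]]
    n_datasets: int
    threshold: float

    @property
    def counts(self) -> dict[str, int]:
        return {
            "datasets": self.n_datasets,
            "step1": len(self.step1_significant),
            "step2": len(self.step2_retained),
            "step3": len(self.step3_independent),
        }


def proportional_significance(p_marginal: float, p_conditional: float) -> float:
    """PS = -log10(p_conditional) / -log10(p_marginal), P floored at 1e-300.

    PS near 0 means the association is explained away by the conditioning
    term; near 1 means it is unaffected; above 1 the conditional signal is
    stronger than the marginal one.
    """
    if not (0 < p_marginal <= 1) or not (0 < p_conditional <= 1):
        raise ValueError("P-values must lie in (0, 1]")
    if p_marginal == 1:
        raise ValueError("PS undefined for marginal P = 1")
    pm = max(p_marginal, P_FLOOR)
    pc = max(p_conditional, P_FLOOR)
    return float(-math.log10(pc) / -math.log10(pm))


def classify_pair(p_a: float, p_b: float, p_ab: float, p_ba: float,
                  ct_a: str = "a", ct_b: str = "b",
                  thresholds: Thresholds | None = None,
                  colinear: bool = False) -> ConditionalPairResult:
    """Classify a conditioned pair of cell types into one of eight scenarios.

    ``p_a``/``p_b`` are marginal P-values; ``p_ab`` is a's P conditioned on
    b and vice versa.  Arguments are canonicalized so the cell type with the
    smaller marginal P plays the "a" role, making the classification
    symmetric in argument order.  When PS_ab < ps_joint while
    PS_ba >= ps_joint the roles are flipped before classification (the
    nominally weaker cell type is the driver), yielding the mirrored
    scenarios 6-7.
    """
    th = thresholds or Thresholds()
    if p_b < p_a:
        # canonicalize: the smaller marginal P plays the "a" role; the
        # returned result names the roles through ct_a / ct_b
        return classify_pair(p_b, p_a, p_ba, p_ab, ct_a=ct_b, ct_b=ct_a,
                             thresholds=th, colinear=colinear)
    if colinear or any(x is None or (isinstance(x, float) and math.isnan(x))
                       for x in (p_ab, p_ba)):
        return ConditionalPairResult(ct_a=ct_a, ct_b=ct_b, p_a=p_a, p_b=p_b,
                                     p_ab=None, p_ba=None, ps_ab=None,
                                     ps_ba=None, scenario=None,
                                     action="flagged_colinear")
    ps_ab = proportional_significance(p_a, p_ab)
    ps_ba = proportional_significance(p_b, p_ba)

    flipped = ps_ab < th.ps_joint and ps_ba >= th.ps_joint
    if flipped:
        c_ab, c_ba = ps_ba, ps_ab
        c_pab, c_pba = p_ba, p_ab
    else:
        c_ab, c_ba = ps_ab, ps_ba
        c_pab, c_pba = p_ab, p_ba

    # decision table on the (possibly flipped) driver-first orientation
    if c_ab >= th.ps_strong and c_ba >= th.ps_strong:
        scenario, retain = 1, "both"
    elif c_ab >= th.ps_driver and c_ba >= th.ps_driver:
        scenario, retain = 2, "both"
    elif c_ab < th.ps_joint and c_ba < th.ps_joint:
        scenario, retain = 3, "first"
    elif c_ab > th.ps_strong and c_ba < th.ps_driver and c_pba < th.p_nominal:
        scenario, retain = 4, "first"
    elif c_ab >= th.ps_driver and c_pba >= th.p_nominal:
        scenario, retain = 5, "first"
    else:
        scenario, retain = 8, "first"

    if flipped:
        if scenario in (4, 5):
            scenario += 2          # mirrored driver scenarios
            action = "retain_b_drop_a"
        else:                      # remaining flipped combinations are ambiguous
            scenario = 8
            action = "ambiguous"
    else:
        if retain == "both":
            action = "retain_both"
        elif scenario == 8:
            action = "ambiguous"
        else:
            action = "retain_a_drop_b"
    return ConditionalPairResult(ct_a=ct_a, ct_b=ct_b, p_a=p_a, p_b=p_b,
                                 p_ab=p_ab, p_ba=p_ba, ps_ab=ps_ab,
                                 ps_ba=ps_ba, scenario=scenario, action=action)


# ---------------------------------------------------------------------------
# Step 1: Bonferroni-corrected marginal scan


@dataclass
class Step1Result:
    """Marginal scan over all dataset-cell-type combinations."""

    table: pd.DataFrame   # dataset, cell_type, beta, se, t, p, n_genes, significant
    threshold: float
    alpha: float
    n_tests: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def step1(stats: GeneStats, profiles: list[CellTypeProfile],
          alpha: float = 0.05, min_genes: int = 50) -> Step1Result:
    """Marginal gene-property fit for every cell type of every dataset.

    The Bonferroni threshold is alpha divided by the total number of
    dataset-cell-type combinations tested.
    """
    if not profiles:
        raise ValueError("step1 needs at least one profile")
    n_tests = sum(p.n_cell_types for p in profiles)
    threshold = alpha / n_tests
    rows = []
    for prof in profiles:
        for ct in prof.cell_types:
            res = fit_marginal(stats, prof, ct, min_genes=min_genes)
            rows.append({
                "dataset": prof.dataset_id, "cell_type": ct,
                "beta": res.beta, "se": res.se, "t": res.t_stat,
                "p": res.p_value, "n_genes": res.n_genes_used,
            })
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < threshold
    table = table.sort_values(["p", "dataset", "cell_type"],
                              kind="stable").reset_index(drop=True)
    return Step1Result(table=table, threshold=threshold, alpha=alpha,
                       n_tests=n_tests)


# ---------------------------------------------------------------------------
# Step 2: within-dataset stepwise conditional analysis


@dataclass
class Step2Result:
    retained: list[tuple[str, str]]          # (dataset, cell_type)
    pair_log: list[tuple[str, ConditionalPairResult]]  # (dataset, result)


def step2(step1_result: Step1Result, stats: GeneStats,
          profiles: list[CellTypeProfile],
          thresholds: Thresholds | None = None,
          min_genes: int = 50) -> Step2Result:
    """Stepwise conditional selection among significant cell types per dataset.

    Within each dataset, significant cell types are visited by ascending
    marginal P.  The retained list starts with the top cell type; each
    candidate is conditioned pairwise against every retained cell type and
    kept only if every classification retains it.  When a flipped driver
    scenario says the candidate drives a previously retained cell type, that
    cell type is removed (logged in the pair log).
    """
    th = thresholds or Thresholds()
    by_id = {p.dataset_id: p for p in profiles}
    sig = step1_result.significant()
    retained_all: list[tuple[str, str]] = []
    pair_log: list[tuple[str, ConditionalPairResult]] = []
    for ds, sub in sig.groupby("dataset", sort=True):
        prof = by_id[ds]
        order = sub.sort_values(["p", "cell_type"], kind="stable")
        cts = list(order["cell_type"])
        pvals = dict(zip(order["cell_type"], order["p"]))
        retained = [cts[0]]
        for cand in cts[1:]:
            keep = True
            drops: list[str] = []
            for r in retained:
                res_a, res_b = fit_joint_within(stats, prof, r, cand,
                                                min_genes=min_genes)
                pair = classify_pair(pvals[r], pvals[cand],
                                     res_a.p_value, res_b.p_value,
                                     ct_a=r, ct_b=cand, thresholds=th,
                                     colinear=res_a.collinear)
                pair_log.append((ds, pair))
                if not pair.retains(cand):
                    keep = False
                if not pair.retains(r):
                    drops.append(r)
            if keep:
                retained = [r for r in retained if r not in drops]
                retained.append(cand)
        retained_all.extend((ds, ct) for ct in cts if ct in retained)
    return Step2Result(retained=retained_all, pair_log=pair_log)


# ---------------------------------------------------------------------------
# Step 3: cross-dataset conditional analysis and independence clustering


@dataclass
class Step3Result:
    clusters: dict[tuple[str, str], list[tuple[str, str]]]
    pair_results: list[CrossDatasetPairResult]
    ps_grid: pd.DataFrame   # asymmetric: [i, j] = PS of j conditioned on i


def step3(step2_result: Step2Result, stats: GeneStats,
          profiles: list[CellTypeProfile], step1_result: Step1Result,
          thresholds: Thresholds | None = None,
          min_genes: int = 50) -> Step3Result:
    """Cross-dataset conditional analysis of the step-2 survivors.

    Every cross-dataset pair is fitted with the CD marginal and CD
    conditional models; within-dataset pairs reuse the within-dataset joint
    model.  Forward selection by step-1 marginal P then assigns each cell
    type either to a new cluster (mutual PS with every founder above the
    independence threshold) or to the first founder that explains it.
    Collinear pairs are treated as dependent.
    """
    th = thresholds or Thresholds()
    by_id = {p.dataset_id: p for p in profiles}
    marg = step1_result.table.set_index(["dataset", "cell_type"])["p"]
    entities = sorted(step2_result.retained,
                      key=lambda e: (marg.loc[e], e[0], e[1]))
    names = [f"{ds}:{ct}" for ds, ct in entities]
    ps_grid = pd.DataFrame(np.nan, index=names, columns=names)
    np.fill_diagonal(ps_grid.values, 1.0)
    pair_results: list[CrossDatasetPairResult] = []
    # ps[(i, j)] = PS of entity j after conditioning on entity i (None => collinear)
    ps: dict[tuple[int, int], float | None] = {}
    for i in range(len(entities)):
        for j in range(i + 1, len(entities)):
            (ds1, ct1), (ds2, ct2) = entities[i], entities[j]
            if ds1 == ds2:
                prof = by_id[ds1]
                res_a, res_b = fit_joint_within(stats, prof, ct1, ct2,
                                                min_genes=min_genes)
                if res_a.collinear:
                    ps[(j, i)] = ps[(i, j)] = None
                    pair_results.append(CrossDatasetPairResult(
                        entity_1=names[i], entity_2=names[j],
                        cd_marginal_p=(marg.loc[entities[i]], marg.loc[entities[j]]),
                        cd_conditional_p=(math.nan, math.nan),
                        cd_ps=(math.nan, math.nan),
                        avg_explained=(False, False), colinear=True))
                    continue
                ps1 = proportional_significance(marg.loc[entities[i]], res_a.p_value)
                ps2 = proportional_significance(marg.loc[entities[j]], res_b.p_value)
                ps[(j, i)], ps[(i, j)] = ps1, ps2
                ps_grid.loc[names[j], names[i]] = ps1
                ps_grid.loc[names[i], names[j]] = ps2
                pair_results.append(CrossDatasetPairResult(
                    entity_1=names[i], entity_2=names[j],
                    cd_marginal_p=(marg.loc[entities[i]], marg.loc[entities[j]]),
                    cd_conditional_p=(res_a.p_value, res_b.p_value),
                    cd_ps=(ps1, ps2), avg_explained=(False, False)))
                continue
            p1, p2 = by_id[ds1], by_id[ds2]
            cdm1 = fit_cd_marginal(stats, p1, ct1, p2, min_genes=min_genes)
            cdm2 = fit_cd_marginal(stats, p2, ct2, p1, min_genes=min_genes)
            res1, res2 = fit_cd_conditional(stats, p1, ct1, p2, ct2,
                                            min_genes=min_genes)
            if res1.collinear:
                ps[(j, i)] = ps[(i, j)] = None
                pair_results.append(CrossDatasetPairResult(
                    entity_1=names[i], entity_2=names[j],
                    cd_marginal_p=(cdm1.p_value, cdm2.p_value),
                    cd_conditional_p=(math.nan, math.nan),
                    cd_ps=(math.nan, math.nan),
                    avg_explained=_avg_explained(cdm1, cdm2, marg, entities[i],
                                                 entities[j]),
                    colinear=True))
                continue
            ps1 = proportional_significance(cdm1.p_value, res1.p_value)
            ps2 = proportional_significance(cdm2.p_value, res2.p_value)
            ps[(j, i)], ps[(i, j)] = ps1, ps2
            ps_grid.loc[names[j], names[i]] = ps1
            ps_grid.loc[names[i], names[j]] = ps2
            pair_results.append(CrossDatasetPairResult(
                entity_1=names[i], entity_2=names[j],
                cd_marginal_p=(cdm1.p_value, cdm2.p_value),
                cd_conditional_p=(res1.p_value, res2.p_value),
                cd_ps=(ps1, ps2),
                avg_explained=_avg_explained(cdm1, cdm2, marg, entities[i],
                                             entities[j])))
    # forward selection over founders
    clusters: dict[int, list[int]] = {}
    for j in range(len(entities)):
        placed = False
        for f in clusters:
            pair_ps = (ps.get((f, j)), ps.get((j, f)))
            independent = (pair_ps[0] is not None and pair_ps[1] is not None
                           and pair_ps[0] > th.ps_independent
                           and pair_ps[1] > th.ps_independent)
            if not independent:
                clusters[f].append(j)
                placed = True
                break
        if not placed:
            clusters[j] = [j]
    out = {entities[f]: [entities[m] for m in members]
           for f, members in clusters.items()}
    return Step3Result(clusters=out, pair_results=pair_results, ps_grid=ps_grid)


def _avg_explained(cdm1, cdm2, marg, e1, e2) -> tuple[bool, bool]:
    """Flag entities whose CD marginal signal is under half the step-1 signal
    (in -log10 scale): the other dataset's average expression alone explains
    >= 50% of the marginal association."""
    out = []
    for cdm, e in ((cdm1, e1), (cdm2, e2)):
        step1_log = -math.log10(max(marg.loc[e], P_FLOOR))
        cd_log = -math.log10(max(cdm.p_value, P_FLOOR))
        out.append(bool(cd_log < 0.5 * step1_log))
    return tuple(out)


# ---------------------------------------------------------------------------
# Orchestration and trait similarity


def run_workflow(stats: GeneStats, profiles: list[CellTypeProfile],
                 alpha: float = 0.05, thresholds: Thresholds | None = None,
                 min_genes: int = 50):
    """Run steps 1-3 and return (summary, step1, step2, step3)."""
    s1 = step1(stats, profiles, alpha=alpha, min_genes=min_genes)
    sig = s1.significant()
    if sig.empty:
        summary = WorkflowSummary(
            trait_id=stats.trait_id, step1_significant=[], step2_retained=[],
            step3_independent={}, n_datasets=0, threshold=s1.threshold)
        return summary, s1, Step2Result([], []), Step3Result({}, [], pd.DataFrame())
    s2 = step2(s1, stats, profiles, thresholds=thresholds, min_genes=min_genes)
    s3 = step3(s2, stats, profiles, s1, thresholds=thresholds, min_genes=min_genes)
    summary = WorkflowSummary(
        trait_id=stats.trait_id,
        step1_significant=[(r.dataset, r.cell_type, r.p)
                           for r in sig.itertuples()],
        step2_retained=list(s2.retained),
        step3_independent=s3.clusters,
        n_datasets=sig["dataset"].nunique(),
        threshold=s1.threshold)
    return summary, s1, s2, s3


def trait_similarity(step1_results: dict[str, Step1Result],
                     annotation: dict[str, str] | None = None):
    """Similarity of cell-type association patterns across traits.

    Returns (rho, order, proportions, no_signal): Spearman correlations of
    the -log10 marginal P vectors over the shared dataset:cell_type axis,
    the average-linkage dendrogram leaf order on 1 - rho, per-trait
    proportions of significant cell types per annotation category (None
    without an annotation), and the traits with no significant cell type.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    if len(step1_results) < 2:
        raise ValueError("trait_similarity needs at least 2 traits")
    vecs = {}
    axis = None
    for trait, s1 in step1_results.items():
        t = s1.table.copy()
        t["entity"] = t["dataset"] + ":" + t["cell_type"]
        t = t.set_index("entity").sort_index()
        if axis is None:
            axis = t.index
        elif not axis.equals(t.index):
            raise ValueError(f"trait {trait!r} was scanned over a different "
                             "dataset/cell-type collection")
        vecs[trait] = -np.log10(np.maximum(t["p"].to_numpy(), P_FLOOR))
    traits = list(vecs)
    mat = np.column_stack([vecs[t] for t in traits])
    rho_arr = sps.spearmanr(mat).statistic
    if np.isscalar(rho_arr):  # two traits
        rho_arr = np.array([[1.0, rho_arr], [rho_arr, 1.0]])
    rho = pd.DataFrame(rho_arr, index=traits, columns=traits)
    dist = squareform(np.clip(1.0 - rho.values, 0.0, None), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = [traits[i] for i in hierarchy.leaves_list(link)]
    no_signal = [t for t, s1 in step1_results.items()
                 if not s1.table["significant"].any()]
    proportions = None
    if annotation is not None:
        cats = sorted(set(annotation.values()))
        rows = {}
        for trait, s1 in step1_results.items():
            sig = s1.significant()
            ents = sig["dataset"] + ":" + sig["cell_type"]
            labels = [annotation.get(e) for e in ents]
            n = len(labels)
            rows[trait] = {c: (labels.count(c) / n if n else 0.0) for c in cats}
        proportions = pd.DataFrame(rows).T.reindex(columns=cats).fillna(0.0)
    return rho, order, proportions, no_signal
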