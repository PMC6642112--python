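import itertools

import numpy as np
import pandas as pd
import pytest

from ctspec import (
    build_profile,
    classify_pair,
    proportional_significance,
    run_workflow,
    simulate_gene_stats,
    simulate_profiles,
    step1,
    step2,
    step3,
    trait_similarity,
)
from ctspec.simulate import DatasetSpec, FixtureSpec, ProgramSpec
from conftest import null_stats, random_profile


def fixture_profiles(spec):
    raws = simulate_profiles(spec)
    return [build_profile(r, dataset_id=d.dataset_id)
            for r, d in zip(raws, spec.datasets)]


def replicated_program_spec(seed, n_datasets=3, effect=0.4):
    datasets = [DatasetSpec(f"d{i}", 5, 20) for i in range(n_datasets)]
    members = [(f"d{i}", f"ct{i % 5}") for i in range(n_datasets)]
    return FixtureSpec(n_genes=1500, datasets=datasets,
                       programs=[ProgramSpec("P1", members)],
                       causal_programs={"P1": effect}, seed=seed)


class TestProportionalSignificance:
    @pytest.mark.parametrize("pm, pc, expected", [
        (1e-10, 1e-5, 0.5),
        (1e-7, 1e-7, 1.0),
        (1e-8, 1e-2, 0.25),
    ])
    def test_log_ratio(self, pm, pc, expected):
        assert proportional_significance(pm, pc) == pytest.approx(expected)

    def test_marginal_one_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            proportional_significance(1.0, 0.5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            proportional_significance(0.0, 0.5)


class TestClassifyPair:
    def test_independent(self):
        r = classify_pair(1e-10, 1e-10, 1e-9, 1e-9)
        assert r.scenario == 1 and r.action == "retain_both"

    def test_jointly_explained(self):
        r = classify_pair(1e-10, 1e-10, 1e-1, 1e-1)
        assert r.scenario == 3 and r.action == "retain_a_drop_b"

    def test_full_driver(self):
        # PS_ab = 0.6, PS_ba = 0.3 with p_ba = 0.2 >= 0.05
        r = classify_pair(1e-10, 10 ** (-0.69897 / 0.3), 1e-6, 0.2)
        assert r.scenario == 5 and r.action == "retain_a_drop_b"

    def test_partial_joint(self):
        r = classify_pair(1e-10, 1e-10, 1e-6, 1e-6)
        assert r.scenario == 2 and r.action == "retain_both"

    def test_driver_with_residual_signal(self):
        # PS_ab = 0.9, PS_ba = 0.3 with p_ba < 0.05
        r = classify_pair(1e-10, 1e-10, 1e-9, 1e-3)
        assert r.scenario == 4 and r.action == "retain_a_drop_b"

    def test_flip_produces_mirrored_scenario(self):
        # a is nominally stronger but fully explained by b
        r = classify_pair(1e-10, 1e-8, 1e-1, 10 ** -7.2)
        assert r.scenario == 7 and r.action == "retain_b_drop_a"
        assert r.retains_b and not r.retains_a

    def test_colinear_flag(self):
        r = classify_pair(1e-10, 1e-8, None, None, colinear=True)
        assert r.action == "flagged_colinear" and r.scenario is None
        assert r.retains_a and not r.retains_b

    def test_totality_over_grid(self):
        """Every PS x P combination maps to exactly one scenario."""
        ps_grid = np.arange(0, 1.3, 0.1)
        p_b_grid = [1e-10, 1e-3, 4e-2]
        p_a = 1e-12
        for ps_ab, ps_ba, p_b in itertools.product(ps_grid, ps_grid, p_b_grid):
            p_ab = p_a ** ps_ab if ps_ab > 0 else 1.0
            p_ba = p_b ** ps_ba if ps_ba > 0 else 1.0
            r = classify_pair(p_a, p_b, p_ab, p_ba)
            assert r.scenario in range(1, 9)
            assert r.action in ("retain_both", "retain_a_drop_b",
                                "retain_b_drop_a", "ambiguous")

    def test_argument_swap_symmetry(self):
        """The retained set does not depend on argument order."""
        ps_grid = np.arange(0, 1.3, 0.2)
        p_a, p_b = 1e-12, 1e-6
        for ps_ab, ps_ba in itertools.product(ps_grid, ps_grid):
            p_ab = p_a ** ps_ab if ps_ab > 0 else 1.0
            p_ba = p_b ** ps_ba if ps_ba > 0 else 1.0
            r1 = classify_pair(p_a, p_b, p_ab, p_ba, ct_a="A", ct_b="B")
            r2 = classify_pair(p_b, p_a, p_ba, p_ab, ct_a="B", ct_b="A")
            kept1 = {n for n in ("A", "B") if r1.retains(n)}
            kept2 = {n for n in ("A", "B") if r2.retains(n)}
            assert kept1 == kept2


class TestStep1:
    def test_single_cell_type_threshold_is_alpha(self, rng):
        prof = random_profile(rng, n_genes=300, n_cell_types=2)
        stats = null_stats(rng, prof.gene_ids)
        res = step1(stats, [prof], alpha=0.05)
        assert res.threshold == pytest.approx(0.05 / 2)
        assert res.n_tests == 2

    def test_counts_all_datasets(self, rng):
        profs = [random_profile(rng, n_genes=300, n_cell_types=k,
                                dataset_id=f"d{k}") for k in (2, 3, 4)]
        genes = profs[0].gene_ids
        stats = null_stats(rng, genes)
        res = step1(stats, profs)
        assert res.n_tests == 9
        assert len(res.table) == 9

    def test_planted_program_is_significant(self):
        spec = replicated_program_spec(seed=2)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        res = step1(stats, profs)
        sig = {(r.dataset, r.cell_type) for r in res.significant().itertuples()}
        assert {("d0", "ct0"), ("d1", "ct1"), ("d2", "ct2")} <= sig


class TestStep2:
    def test_single_significant_passes_through(self):
        spec = replicated_program_spec(seed=3, n_datasets=1)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        s1 = step1(stats, profs)
        s2 = step2(s1, stats, profs)
        assert s2.retained == [("d0", "ct0")]
        assert s2.pair_log == []

    def test_duplicate_program_keeps_one(self):
        spec = FixtureSpec(
            n_genes=1500, datasets=[DatasetSpec("d0", 5, 20)],
            programs=[ProgramSpec("P1", [("d0", "ct0"), ("d0", "ct1")])],
            causal_programs={"P1": 0.4}, seed=4)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        s1 = step1(stats, profs)
        sig = {(r.dataset, r.cell_type) for r in s1.significant().itertuples()}
        assert {("d0", "ct0"), ("d0", "ct1")} <= sig
        s2 = step2(s1, stats, profs)
        kept = [e for e in s2.retained if e[1] in ("ct0", "ct1")]
        assert len(kept) == 1
        top = s1.significant().iloc[0]
        assert kept[0] == (top.dataset, top.cell_type)

    def test_independent_programs_both_retained(self):
        spec = FixtureSpec(
            n_genes=1500, datasets=[DatasetSpec("d0", 5, 20)],
            programs=[ProgramSpec("P1", [("d0", "ct0")]),
                      ProgramSpec("P2", [("d0", "ct1")])],
            causal_programs={"P1": 0.4, "P2": 0.4}, seed=5)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        s2 = step2(step1(stats, profs), stats, profs)
        assert set(s2.retained) >= {("d0", "ct0"), ("d0", "ct1")}


class TestStep3:
    def test_single_retained_single_cluster(self):
        spec = replicated_program_spec(seed=6, n_datasets=1)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        s1 = step1(stats, profs)
        s2 = step2(s1, stats, profs)
        s3 = step3(s2, stats, profs, s1)
        assert len(s3.clusters) == 1

    def test_replicated_program_collapses_to_one_cluster(self):
        spec = replicated_program_spec(seed=7)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        summary, s1, s2, s3 = run_workflow(stats, profs)
        assert len(s3.clusters) == 1
        members = next(iter(s3.clusters.values()))
        assert set(members) == set(s2.retained)

    def test_disjoint_programs_two_clusters(self):
        spec = FixtureSpec(
            n_genes=1500,
            datasets=[DatasetSpec("d0", 5, 20), DatasetSpec("d1", 5, 20)],
            programs=[ProgramSpec("P1", [("d0", "ct0"), ("d1", "ct0")]),
                      ProgramSpec("P2", [("d0", "ct3"), ("d1", "ct3")])],
            causal_programs={"P1": 0.4, "P2": 0.4}, seed=8)
        profs = fixture_profiles(spec)
        summary, s1, s2, s3 = run_workflow(*(simulate_gene_stats(spec)[0],),
                                           profiles=profs)
        assert len(s3.clusters) == 2

    def test_subset_chain_and_counts(self):
        spec = replicated_program_spec(seed=9)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        summary, s1, s2, s3 = run_workflow(stats, profs)
        step1_set = {(d, c) for d, c, _ in summary.step1_significant}
        step2_set = set(summary.step2_retained)
        step3_set = set(summary.step3_independent)
        assert step3_set <= step2_set <= step1_set
        assert summary.counts["step1"] == len(step1_set)
        assert summary.counts["step2"] == len(step2_set)
        assert summary.counts["step3"] == len(step3_set)

    def test_ps_grid_is_asymmetric_with_unit_diagonal(self):
        spec = replicated_program_spec(seed=10)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        _, _, _, s3 = run_workflow(stats, profs)
        grid = s3.ps_grid
        np.testing.assert_allclose(np.diag(grid.values), 1.0)
        assert grid.shape[0] == grid.shape[1] >= 2


class TestWorkflowDeterminism:
    def test_rerun_is_bitwise_identical(self):
        spec = replicated_program_spec(seed=11)
        profs = fixture_profiles(spec)
        stats, _ = simulate_gene_stats(spec)
        a = run_workflow(stats, profs)
        b = run_workflow(stats, profs)
        pd.testing.assert_frame_equal(a[1].table, b[1].table)
        assert a[0].step3_independent == b[0].step3_independent


class TestTraitSimilarity:
    def _two_traits(self, shared, seed=12, rho_z=0.95):
        """Two traits scanned over ~200 dataset:cell-type combinations.

        ``shared``: trait 2 has genetically correlated gene Z-scores
        (correlation rho_z) so it carries the same planted drivers;
        otherwise trait 2 loads on a disjoint program with fresh noise.
        """
        import numpy as np
        from ctspec import GeneStats

        datasets = [DatasetSpec(f"d{i}", 20, 10) for i in range(10)]
        programs = [
            ProgramSpec("P1", [(f"d{i}", "ct0") for i in range(3)]),
            ProgramSpec("P2", [(f"d{i}", "ct9") for i in range(3)]),
        ]
        spec = FixtureSpec(n_genes=1000, datasets=datasets, programs=programs,
                           causal_programs={"P1": 0.4}, seed=seed)
        profs = fixture_profiles(spec)
        stats1, _ = simulate_gene_stats(spec)
        if shared:
            fresh = np.random.default_rng(seed + 100).normal(0, 1, 1000)
            z2 = rho_z * stats1.z.to_numpy() + np.sqrt(1 - rho_z ** 2) * fresh
            stats2 = GeneStats(z=pd.Series(z2, index=stats1.gene_ids),
                               trait_id="t2")
        else:
            spec2 = FixtureSpec(n_genes=1000, datasets=datasets,
                                programs=programs,
                                causal_programs={"P2": 0.4}, seed=seed)
            stats2, _ = simulate_gene_stats(spec2, z_seed=seed + 100)
        s1a = step1(stats1, profs)
        s1b = step1(stats2, profs)
        return {"t1": s1a, "t2": s1b}

    def test_self_correlation(self):
        tables = self._two_traits(shared=True)
        rho, order, props, no_sig = trait_similarity(tables)
        assert rho.loc["t1", "t1"] == pytest.approx(1.0)
        assert set(order) == {"t1", "t2"}

    def test_shared_drivers_high_similarity(self):
        tables = self._two_traits(shared=True)
        rho, *_ = trait_similarity(tables)
        assert rho.loc["t1", "t2"] > 0.9

    def test_disjoint_drivers_low_similarity(self):
        tables = self._two_traits(shared=False)
        rho, *_ = trait_similarity(tables)
        assert abs(rho.loc["t1", "t2"]) < 0.2

    def test_category_proportions(self):
        tables = self._two_traits(shared=True)
        annotation = {f"d{i}:ct{j}": ("neuron" if j < 3 else "glia")
                      for i in range(3) for j in range(5)}
        rho, order, props, no_sig = trait_similarity(tables, annotation)
        assert set(props.columns) == {"neuron", "glia"}
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_mismatched_axes_rejected(self, rng):
        profs_a = [random_profile(rng, n_genes=300, dataset_id="dA")]
        profs_b = [random_profile(rng, n_genes=300, dataset_id="dB")]
        stats = null_stats(rng, profs_a[0].gene_ids)
        with pytest.raises(ValueError, match="different"):
            trait_similarity({"t1": step1(stats, profs_a),
                              "t2": step1(stats, profs_b)})
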