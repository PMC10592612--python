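"""Synthetic-data generator: trees, traits, pools and their invariants."""

import numpy as np
import pandas as pd
import pytest

from trnatherm import (
    GeneticCode,
    SimConfig,
    WobbleRuleTable,
    minimal_core,
    raw_rates,
    recognized_codons,
    simulate_bm,
    simulate_dataset,
    simulate_tgcn,
    simulate_traits,
    simulate_tree,
)
from trnatherm.trna_pool import AnticodonPool, diversity, diversity_by_ending


class TestSimulateTree:
    def test_tip_count_and_unit_depth(self):
        tree = simulate_tree(50, seed=1)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert len(depths) == 50
        assert max(depths) == pytest.approx(1.0)
        assert np.ptp(depths) < 1e-9  # ultrametric

    def test_three_tips(self):
        tree = simulate_tree(3, seed=2)
        assert len(tree.leaf_nodes()) == 3
        assert sum(1 for n in tree.preorder_internal_node_iter()) == 2

    def test_deterministic_given_seed(self):
        a = simulate_tree(20, seed=9).as_string(schema="newick")
        b = simulate_tree(20, seed=9).as_string(schema="newick")
        assert a == b
        c = simulate_tree(20, seed=10).as_string(schema="newick")
        assert a != c

    def test_positive_branch_lengths(self):
        tree = simulate_tree(100, seed=4)
        assert all(
            e.length > 0 for e in tree.preorder_edge_iter() if e.length is not None
        )

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(2, seed=0)


class TestMinimalCore:
    def test_core_covers_every_sense_codon(self, code, rules):
        core = minimal_core(code, rules)
        covered = set()
        for anticodon in core:
            covered |= recognized_codons(anticodon, rules) & set(code.sense_codons)
        assert covered == set(code.sense_codons)

    def test_default_core_size(self, code, rules):
        # GNN for pyrimidine-ending codons in all 16 boxes, UNN for
        # purine-ending in 14, plus CCA for Trp
        assert len(minimal_core(code, rules)) == 31

    def test_wc_only_core_needs_all_61(self, code):
        assert len(minimal_core(code, WobbleRuleTable.wc_only())) == 61


class TestSimulateTraits:
    def test_zero_effects_zero_noise_constant(self):
        cfg = SimConfig(n_species=30, seed=3, beta_gc=0, beta_thermo=0,
                        beta_psychro=0, intercept=40.0, residual_sigma2=1e-12)
        tree = simulate_tree(30, seed=3)
        traits = simulate_traits(tree, cfg)
        assert (traits["diversity"] == 40).all()

    def test_gc_within_range_and_classes_valid(self):
        cfg = SimConfig(n_species=200, seed=5)
        traits = simulate_traits(simulate_tree(200, seed=5), cfg)
        lo, hi = cfg.gc_range
        assert traits["gc"].between(lo, hi).all()
        assert set(traits["temp_class"]) <= {"psychrophile", "mesophile", "thermophile"}
        assert traits["diversity"].between(20, 61).all()

    def test_ogt_consistent_with_class(self):
        from trnatherm import classify_temperature

        traits = simulate_traits(simulate_tree(100, seed=6), SimConfig(n_species=100, seed=6))
        for row in traits.itertuples():
            assert classify_temperature(row.ogt_celsius) == row.temp_class

    def test_exact_class_counts(self):
        cfg = SimConfig(n_species=300, seed=7, exact_class_counts=True)
        traits = simulate_traits(simulate_tree(300, seed=7), cfg)
        counts = traits["temp_class"].value_counts()
        assert counts["psychrophile"] == round(300 * 5 / 406)
        assert counts["thermophile"] == round(300 * 67 / 406)

    def test_class_proportions_in_expectation(self):
        hits = []
        for seed in range(6):
            cfg = SimConfig(n_species=400, seed=seed)
            traits = simulate_traits(simulate_tree(400, seed=seed), cfg)
            hits.append((traits["temp_class"] == "thermophile").mean())
        # clumped assignment is high-variance per tree; the mean should be near 67/406
        assert 0.05 < np.mean(hits) < 0.35

    def test_star_tree_bm_residual_variance(self, rng):
        import dendropy

        newick = "(" + ",".join(f"t{i}:1.0" for i in range(400)) + ");"
        star = dendropy.Tree.get(data=newick, schema="newick")
        values = np.array(list(simulate_bm(star, sigma2=4.0, rng=rng).values()))
        # i.i.d. residuals on a star tree: sample variance ~ sigma^2 * depth
        assert values.var() == pytest.approx(4.0, rel=0.25)


class TestSimulateTgcn:
    @pytest.fixture()
    def traits(self):
        cfg = SimConfig(n_species=40, seed=11)
        return simulate_traits(simulate_tree(40, seed=11), cfg)

    def test_realized_diversity_exact(self, traits, code):
        pools = simulate_tgcn(traits, seed=1)
        by_id = {p.species_id: p for p in pools}
        for row in traits.itertuples():
            assert diversity(by_id[row.species_id]) == row.diversity

    def test_no_undecodable_codons(self, traits, code, rules):
        for pool in simulate_tgcn(traits, seed=2):
            assert raw_rates(pool, code, rules).undecodable == []

    def test_requested_61_gives_complete_pool(self, code):
        traits = pd.DataFrame(
            [{"species_id": "s", "gc": 0.5, "diversity": 61}]
        )
        (pool,) = simulate_tgcn(traits, seed=3)
        assert diversity(pool) == 61

    def test_core_diversity_gives_exactly_core(self, code, rules):
        core = minimal_core(code, rules)
        traits = pd.DataFrame(
            [{"species_id": "s", "gc": 0.5, "diversity": len(core)}]
        )
        (pool,) = simulate_tgcn(traits, seed=4)
        assert sorted(pool.present()) == core

    def test_below_core_rejected(self):
        traits = pd.DataFrame([{"species_id": "s", "gc": 0.5, "diversity": 25}])
        with pytest.raises(ValueError, match="core"):
            simulate_tgcn(traits, seed=5)

    def test_higher_diversity_raises_gc_ending_count(self):
        """At equal GC, a diversity-45 pool carries more GC-ending anticodons
        than a diversity-30+core pool, on average across seeds."""
        lo = pd.DataFrame([{"species_id": "s", "gc": 0.5, "diversity": 33}])
        hi = pd.DataFrame([{"species_id": "s", "gc": 0.5, "diversity": 45}])
        gc_lo = np.mean(
            [diversity_by_ending(simulate_tgcn(lo, seed=s)[0])[0] for s in range(20)]
        )
        gc_hi = np.mean(
            [diversity_by_ending(simulate_tgcn(hi, seed=s)[0])[0] for s in range(20)]
        )
        assert gc_hi > gc_lo

    def test_gc_preference_shapes_pool_composition(self):
        """Extras lean GC-ending for GC-rich genomes and AT-ending for
        AT-rich ones."""
        rich = pd.DataFrame([{"species_id": "s", "gc": 0.74, "diversity": 45}])
        poor = pd.DataFrame([{"species_id": "s", "gc": 0.26, "diversity": 45}])
        gc_rich = np.mean(
            [diversity_by_ending(simulate_tgcn(rich, seed=s)[0])[0] for s in range(20)]
        )
        gc_poor = np.mean(
            [diversity_by_ending(simulate_tgcn(poor, seed=s)[0])[0] for s in range(20)]
        )
        assert gc_rich > gc_poor


def test_full_pipeline_recovers_thermophile_sign(code, rules):
    """Simulate 300 species with the empirical-scale effect structure, run
    tGCN → error model → phylogenetic regression, and check the thermophile
    diversity effect comes out positive in ≥ 95% of 50 replicates."""
    from trnatherm.phylo_regression import design_matrix, ml_fit, select_model
    from trnatherm.translation_model import species_error_summary, species_rates

    positive = 0
    n_reps = 50
    for rep in range(n_reps):
        cfg = SimConfig(n_species=300, seed=1000 + rep, exact_class_counts=True)
        tree, traits, pools, metas = simulate_dataset(cfg)
        # error model runs on every pool; its summary joins the trait table
        eps = {
            p.species_id: species_error_summary(species_rates(p, code, rules))[
                "median_epsilon_m"
            ]
            for p in pools
        }
        traits = traits.assign(median_epsilon_m=traits["species_id"].map(eps))
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        df = traits.set_index("species_id").loc[tips]
        X, names = design_matrix(df, ["temp_class", "gc"])
        y = df["diversity"].to_numpy(float)
        fits = [ml_fit(y, X, tree, m, names, tip_order=tips) for m in ("BM", "OU")]
        chosen = select_model(fits)
        if chosen.coefficients.loc["thermophile", "estimate"] > 0:
            positive += 1
    assert positive / n_reps >= 0.95


class TestSimulateDataset:
    def test_components_align(self):
        cfg = SimConfig(n_species=25, seed=21)
        tree, traits, pools, metas = simulate_dataset(cfg)
        tips = {l.taxon.label for l in tree.leaf_node_iter()}
        assert tips == set(traits["species_id"])
        assert tips == {p.species_id for p in pools}
        assert tips == {m.species_id for m in metas}

    def test_deterministic(self):
        cfg = SimConfig(n_species=15, seed=22)
        _, t1, p1, _ = simulate_dataset(cfg)
        _, t2, p2, _ = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert [p.counts for p in p1] == [p.counts for p in p2]
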