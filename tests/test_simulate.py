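import io as _io

import numpy as np
import pandas as pd
import pytest
import skbio

from phyloassembly import io as pio
from phyloassembly.simulate import (
    Scenario,
    assemble_site,
    generate_study,
    lognormal_pool,
    plant_clades,
    scenario_preset,
    simulate_group,
    simulate_traits,
    simulate_tree,
    taxonomy_from_tree,
)
from phyloassembly.turnover import cophenetic_distances, group_beta_nti


class TestSimulateTree:
    def test_two_tips_single_cherry(self):
        tree = simulate_tree(2, seed=0)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert tips[0].parent is tips[1].parent

    def test_same_seed_identical_newick(self):
        assert str(simulate_tree(50, seed=9)) == str(simulate_tree(50, seed=9))

    def test_different_seeds_differ(self):
        assert str(simulate_tree(50, seed=9)) != str(simulate_tree(50, seed=10))

    def test_ultrametric_root_to_tip_distances(self):
        tree = simulate_tree(128, seed=4, ultrametric=True)
        depths = []
        for tip in tree.tips():
            depth, node = 0.0, tip
            while node.parent is not None:
                depth += node.length
                node = node.parent
            depths.append(depth)
        assert max(depths) - min(depths) < 1e-9

    def test_unique_labels_and_positive_lengths(self):
        tree = simulate_tree(64, seed=1)
        names = [t.name for t in tree.tips()]
        assert len(set(names)) == 64
        assert all(
            n.length >= 0 for n in tree.traverse(include_self=False)
        )


class TestSimulateTraits:
    def test_white_noise_signal_ratio_near_one(self):
        """Clade-wise variance ≈ pool variance without phylogeny in the model."""
        ratios = []
        for seed in range(100):
            tree = simulate_tree(64, seed=seed, ultrametric=True)
            traits = simulate_traits(tree, "white_noise", seed=seed + 1000)
            clade_vars = []
            for node in tree.non_tips(include_self=False):
                tips = [t.name for t in node.tips()]
                if 8 <= len(tips) <= 32:
                    clade_vars.append(traits[tips].var())
            if clade_vars:
                ratios.append(np.mean(clade_vars) / traits.var())
        assert 0.8 <= np.mean(ratios) <= 1.25

    def test_brownian_sister_tips_more_similar_than_random(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            tree = simulate_tree(64, seed=seed, ultrametric=True)
            traits = simulate_traits(tree, "brownian", seed=seed + 500)
            rng = np.random.default_rng(seed)
            sister_d, random_d = [], []
            for node in tree.non_tips(include_self=False):
                kids = node.children
                if len(kids) == 2 and all(k.is_tip() for k in kids):
                    sister_d.append(abs(traits[kids[0].name] - traits[kids[1].name]))
            names = list(traits.index)
            for _ in range(len(sister_d)):
                a, b = rng.choice(names, 2, replace=False)
                random_d.append(abs(traits[a] - traits[b]))
            if sister_d and np.mean(sister_d) < np.mean(random_d):
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_zero_length_edges_give_equal_traits(self):
        tree = skbio.TreeNode.read(_io.StringIO("((A:0,B:0):1,C:2);"))
        traits = simulate_traits(tree, "brownian", seed=3)
        assert traits["A"] == traits["B"]


class TestAssembleSite:
    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        pool = lognormal_pool(30, 1)
        traits = rng.normal(size=30)
        counts = assemble_site(pool, traits, 0.0, 1.0, 0.3, 500, rng)
        assert counts.sum() == 500

    def test_infinite_niche_width_is_neutral(self):
        """sigma -> inf: sampling proportions converge to the pool."""
        rng = np.random.default_rng(1)
        pool = lognormal_pool(20, 2)
        traits = rng.normal(size=20)
        counts = assemble_site(pool, traits, 0.0, np.inf, 0.0, 200_000, rng)
        assert np.allclose(counts / counts.sum(), pool, atol=0.01)

    def test_vanishing_niche_width_fixes_on_optimum_tip(self):
        rng = np.random.default_rng(2)
        pool = np.ones(10) / 10
        traits = np.arange(10.0)
        counts = assemble_site(pool, traits, 4.0, 1e-9, 0.0, 100, rng)
        assert counts[4] == 100

    def test_invalid_parameters_rejected(self):
        rng = np.random.default_rng(3)
        pool = np.ones(5) / 5
        traits = np.zeros(5)
        with pytest.raises(ValueError):
            assemble_site(pool, traits, 0, -1.0, 0.0, 10, rng)
        with pytest.raises(ValueError):
            assemble_site(pool, traits, 0, 1.0, 1.5, 10, rng)
        with pytest.raises(ValueError):
            assemble_site(pool, traits, 0, 1.0, 0.0, 0, rng)
        with pytest.raises(ValueError, match="zero"):
            assemble_site(np.zeros(5), traits, 0, 1.0, 0.0, 10, rng)

    def test_shared_strong_selection_lowers_bray_curtis(self):
        """Two sites under one strong filter are compositionally closer
        than two neutral sites, in most seeds."""
        from phyloassembly.raupcrick import bray_curtis

        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pool = lognormal_pool(100, seed)
            traits = rng.normal(size=100)
            sel = [
                assemble_site(pool, traits, 0.0, 0.2, 0.0, 300, rng)
                for _ in range(2)
            ]
            neu = [
                assemble_site(pool, traits, 0.0, np.inf, 0.0, 300, rng)
                for _ in range(2)
            ]
            if bray_curtis(*sel) < bray_curtis(*neu):
                hits += 1
        assert hits / n_seeds >= 0.8


class TestScenarios:
    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown truth label"):
            Scenario(truth_label="magic")

    def test_presets_stochastic_scenarios_drop_selection(self):
        for label in ("neutral_drift", "dispersal_limitation", "homogenizing_dispersal"):
            s = scenario_preset(label)
            assert np.isinf(s.selection_sigma)
            assert s.site_noise == 0.0

    def test_group_determinism_and_conservation(self):
        tree = simulate_tree(128, seed=6, ultrametric=True)
        traits = simulate_traits(tree, "brownian", seed=7)
        pool = lognormal_pool(128, 8)
        scen = scenario_preset("homogeneous_selection", 5)
        c1, t1 = simulate_group(tree, traits, pool, scen, seed=9)
        c2, t2 = simulate_group(tree, traits, pool, scen, seed=9)
        pd.testing.assert_frame_equal(c1, c2)
        assert t1.planted_clade == t2.planted_clade
        assert (c1.sum(axis=1) == scen.community_size).all()

    def test_plant_clades_disjoint_and_sized(self):
        tree = simulate_tree(256, seed=11, ultrametric=True)
        ids, d = cophenetic_distances(tree)
        clades = plant_clades(tree, d, ids, n_clades=3, min_frac=0.05, max_frac=0.15)
        assert len(clades) == 3
        for i, a in enumerate(clades):
            assert 0.05 * 256 <= len(a) <= 0.15 * 256
            for b in clades[i + 1:]:
                assert not (a & b)

    def test_scenario_separability_mean_bnti_ordering(self):
        """mean betaNTI: homogeneous < neutral < variable, over seeds."""
        means = {"homogeneous_selection": [], "neutral_drift": [], "variable_selection": []}
        for seed in range(6):
            ss = np.random.SeedSequence(seed)
            s1, s2, s3, s4, s5 = ss.spawn(5)
            tree = simulate_tree(256, s1, ultrametric=True)
            traits = simulate_traits(tree, "brownian", s2)
            pool = lognormal_pool(256, s3)
            ids, d = cophenetic_distances(tree)
            for label in means:
                scen = scenario_preset(label, 6)
                counts, _ = simulate_group(
                    tree, traits, pool, scen, s4, cophenetic=(ids, d)
                )
                rel = counts.div(counts.sum(axis=1), axis=0).reindex(columns=ids)
                z = group_beta_nti(rel, d, ids, n_reps=99, seed=s5)
                means[label].append(z.beta_nti.mean())
        assert (
            np.mean(means["homogeneous_selection"])
            < np.mean(means["neutral_drift"])
            < np.mean(means["variable_selection"])
        )


class TestTaxonomyFromTree:
    def test_lineages_nested_and_complete(self):
        tree = simulate_tree(64, seed=13, ultrametric=True)
        tax = taxonomy_from_tree(tree)
        assert len(tax) == 64
        assert (tax["domain"] == "Bacteria").all()
        assert tax.notna().all().all()
        # nestedness: same genus implies same family
        for genus, sub in tax.groupby("genus"):
            assert sub["family"].nunique() == 1


class TestGenerateStudy:
    @pytest.fixture(scope="class")
    def bundle(self):
        return generate_study(n_tips=256, sites_per_group=4, seed=5)

    def test_shape_and_design_columns(self, bundle):
        meta = bundle.metadata
        assert len(meta) == 3 * 2 * 4
        assert set(meta.floodplain) == {"OTE", "VAR", "SOY"}
        assert set(meta.stream_type) == {"GFS", "TRIB"}
        assert set(meta.region) == {"UP", "DN"}
        assert (meta.chlorophyll_a > 0).all()
        assert (meta.bacterial_abundance > 0).all()

    def test_round_trips_through_io_with_zero_drops(self, bundle, tmp_path):
        from phyloassembly.simulate import write_study

        manifest = write_study(bundle, tmp_path)
        tree = pio.read_tree(tmp_path / "tree.nwk")
        counts = pio.read_counts(tmp_path / "counts.tsv")
        tax = pio.read_taxonomy(tmp_path / "taxonomy.tsv")
        meta = pio.read_metadata(tmp_path / "metadata.tsv")
        aligned = pio.align_inputs(tree, counts, tax, meta)
        assert all(not v for v in aligned.dropped.values())
        assert set(manifest["groups"]) == {
            f"{fp}_{st}" for fp in ("OTE", "VAR", "SOY") for st in ("GFS", "TRIB")
        }

    def test_determinism(self):
        b1 = generate_study(n_tips=128, sites_per_group=3, seed=17)
        b2 = generate_study(n_tips=128, sites_per_group=3, seed=17)
        pd.testing.assert_frame_equal(b1.counts.counts, b2.counts.counts)
        pd.testing.assert_frame_equal(b1.metadata, b2.metadata)

    def test_nested_planted_structure(self, bundle):
        """Within a floodplain the stream types share the floodplain clade
        but keep stream-specific exclusives."""
        gfs = bundle.truth[("OTE", "GFS")].planted_clade
        trib = bundle.truth[("OTE", "TRIB")].planted_clade
        assert gfs & trib, "floodplain-wide clade should be shared"
        assert gfs - trib and trib - gfs, "stream-specific clades should differ"

    def test_zero_coupling_chla_uncorrelated(self):
        """With the coupling switched off, chlorophyll a is independent of
        the planted clade abundance (slope centred on zero across seeds)."""
        from phyloassembly.simulate import sample_chlorophyll
        from scipy import stats

        slopes = []
        for seed in range(12):
            ss = np.random.SeedSequence(seed)
            s1, s2, s3, s4, s5 = ss.spawn(5)
            tree = simulate_tree(128, s1, ultrametric=True)
            traits = simulate_traits(tree, "brownian", s2)
            pool = lognormal_pool(128, s3)
            scen = scenario_preset("homogeneous_selection", 12, chla_coupling=0.0)
            counts, gt = simulate_group(tree, traits, pool, scen, s4)
            chla = sample_chlorophyll(gt, np.random.default_rng(s5), scen)
            slope = stats.linregress(chla, gt.clade_abundance).slope
            slopes.append(slope)
        t = stats.ttest_1samp(slopes, 0.0)
        assert t.pvalue > 0.05
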