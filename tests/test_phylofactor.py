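import numpy as np
import pandas as pd
import pytest

from phyloassembly.phylofactor import (
    annotate_clades,
    clades_table,
    consensus_taxonomy,
    hos_filter,
    membership_table,
    phylofactorize,
    presence_categories,
)
from phyloassembly.phyloscore import asv_phyloscores
from phyloassembly.simulate import simulate_tree
from phyloassembly.turnover import cophenetic_distances, tip_permutations


def _tree_and_clade(n_tips=100, target=20, seed=1):
    tree = simulate_tree(n_tips, seed, ultrametric=True)
    node = min(
        tree.non_tips(include_self=False),
        key=lambda nd: abs(len(list(nd.tips())) - target),
    )
    return tree, frozenset(t.name for t in node.tips())


def _scores(tree, clade, shift, seed):
    tips = [t.name for t in tree.tips()]
    rng = np.random.default_rng(seed)
    s = pd.Series(rng.normal(0, 1, len(tips)), index=tips)
    s[list(clade)] += shift
    return s


class TestPhylofactorize:
    def test_planted_shift_recovered_first(self):
        tree, clade = _tree_and_clade()
        factors = phylofactorize(tree, _scores(tree, clade, -5.0, seed=2))
        assert factors, "no factor accepted"
        first = factors[0]
        jac = len(first.asv_members & clade) / len(first.asv_members | clade)
        assert jac >= 0.8
        assert first.direction == "lower"

    def test_min_clade_gate_blocks_small_clades(self):
        tree, clade = _tree_and_clade(target=20)
        factors = phylofactorize(
            tree, _scores(tree, clade, -5.0, seed=2), min_clade=len(clade) + 1
        )
        assert all(f.asv_members != clade for f in factors)

    def test_no_structure_no_factors(self):
        tree, _ = _tree_and_clade()
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(3)
        s = pd.Series(rng.normal(0, 1, len(tips)), index=tips)
        assert phylofactorize(tree, s, alpha=0.001) == []

    def test_determinism(self):
        tree, clade = _tree_and_clade()
        s = _scores(tree, clade, -3.0, seed=4)
        f1 = phylofactorize(tree, s)
        f2 = phylofactorize(tree, s)
        assert [f.asv_members for f in f1] == [f.asv_members for f in f2]

    def test_factor_clades_disjoint(self):
        tree, clade = _tree_and_clade()
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(5)
        s = pd.Series(rng.normal(0, 1, len(tips)), index=tips)
        s[list(clade)] -= 4.0
        other = [t for t in tips if t not in clade][:15]
        s[other] += 4.0
        factors = phylofactorize(tree, s, alpha=0.01)
        seen = set()
        for f in factors:
            assert not (f.asv_members & seen)
            seen |= f.asv_members
        assert len(seen) <= len(tips)

    def test_hos_filter_keeps_lower_only(self):
        tree, clade = _tree_and_clade()
        s = _scores(tree, clade, -5.0, seed=2)
        # also plant a higher clade
        tree2, clade2 = _tree_and_clade(seed=1, target=15)
        factors = phylofactorize(tree, s, alpha=0.01)
        hos = hos_filter(factors)
        assert all(f.direction == "lower" for f in hos)
        assert hos, "planted lower clade survived the filter"

    def test_wilcoxon_option(self):
        tree, clade = _tree_and_clade()
        factors = phylofactorize(
            tree, _scores(tree, clade, -5.0, seed=2), method="wilcoxon"
        )
        assert factors and factors[0].direction == "lower"

    def test_report_gate_on_clade_size(self):
        tree, clade = _tree_and_clade(target=20)
        factors = phylofactorize(tree, _scores(tree, clade, -5.0, seed=2))
        full = clades_table(factors)
        gated = clades_table(factors, report_min_clade=len(factors[0].asv_members))
        assert len(full) >= 1 and gated.empty
        members = membership_table(factors)
        assert set(members.asv_id) == set().union(*(f.asv_members for f in factors))


class TestPhyloscores:
    def test_absent_asv_gets_no_scores(self):
        tree = simulate_tree(16, seed=6)
        ids, d = cophenetic_distances(tree)
        rel = pd.DataFrame(
            np.zeros((3, 16)), index=["S1", "S2", "S3"], columns=ids
        )
        rel.iloc[0, :4] = 0.25
        rel.iloc[1, 2:6] = 0.25
        rel.iloc[2, 4:8] = 0.25
        table = asv_phyloscores(rel, d, ids, n_reps=99, seed=1)
        never = ids[10]
        assert table.n_pairs_scored[never] == 0
        assert table.totals[never] == 0.0

    def test_shared_asvs_not_scored(self):
        tree = simulate_tree(8, seed=7)
        ids, d = cophenetic_distances(tree)
        rel = pd.DataFrame(
            [[0.5, 0.5, 0, 0, 0, 0, 0, 0], [0.5, 0.5, 0, 0, 0, 0, 0, 0]],
            index=["S1", "S2"],
            columns=ids,
        )
        table = asv_phyloscores(rel, d, ids, n_reps=99, seed=1)
        assert (table.n_pairs_scored == 0).all()

    def test_totals_equal_sum_of_pair_scores(self):
        tree = simulate_tree(24, seed=8)
        ids, d = cophenetic_distances(tree)
        rng = np.random.default_rng(2)
        rel = pd.DataFrame(
            (rng.random((4, 24)) < 0.3).astype(float),
            index=[f"S{i}" for i in range(4)],
            columns=ids,
        )
        table = asv_phyloscores(rel, d, ids, n_reps=199, seed=3)
        sums = table.pair_scores.groupby("asv_id").phyloscore.sum()
        for asv, total in table.totals.items():
            assert total == pytest.approx(sums.get(asv, 0.0), abs=1e-9)

    def test_planted_coselected_clade_scores_negative(self):
        """A clade recurring across all sites scores below the background."""
        tree = simulate_tree(64, seed=9, ultrametric=True)
        ids, d = cophenetic_distances(tree)
        clade = None
        for node in tree.non_tips(include_self=False):
            tips = [t.name for t in node.tips()]
            if 10 <= len(tips) <= 14:
                clade = tips
                break
        rng = np.random.default_rng(4)
        pos = {t: i for i, t in enumerate(ids)}
        rows = []
        for s in range(6):
            v = np.zeros(len(ids))
            # half the clade per site (turnover within the clade)...
            chosen = rng.choice(clade, size=len(clade) // 2, replace=False)
            for t in chosen:
                v[pos[t]] = 1.0
            # ...plus a few scattered background taxa
            bg = rng.choice(
                [t for t in ids if t not in clade], size=6, replace=False
            )
            for t in bg:
                v[pos[t]] = 1.0
            rows.append(v / v.sum())
        rel = pd.DataFrame(rows, index=[f"S{i}" for i in range(6)], columns=ids)
        perms = tip_permutations(len(ids), 199, 11)
        table = asv_phyloscores(rel, d, ids, permutations=perms)
        tot = table.totals[table.n_pairs_scored > 0]
        in_clade = tot.index.isin(clade)
        assert in_clade.any() and (~in_clade).any()
        assert tot[in_clade].mean() < tot[~in_clade].mean()

    def test_consistent_with_shared_permutation_stream(self):
        tree = simulate_tree(16, seed=10)
        ids, d = cophenetic_distances(tree)
        rng = np.random.default_rng(5)
        rel = pd.DataFrame(
            (rng.random((3, 16)) < 0.4).astype(float),
            index=["S1", "S2", "S3"],
            columns=ids,
        )
        perms = tip_permutations(16, 99, 77)
        t1 = asv_phyloscores(rel, d, ids, permutations=perms)
        t2 = asv_phyloscores(rel, d, ids, permutations=perms)
        pd.testing.assert_series_equal(t1.totals, t2.totals)


class TestConsensusTaxonomy:
    @pytest.fixture
    def taxonomy(self):
        return pd.DataFrame(
            {
                "domain": ["Bacteria"] * 4,
                "phylum": ["Proteobacteria"] * 3 + ["Bacteroidota"],
                "class": ["Gamma"] * 3 + ["Bacteroidia"],
                "order": ["Burkholderiales"] * 3 + ["Cytophagales"],
                "family": ["Comamonadaceae"] * 2 + ["Oxalobacteraceae", "X"],
                "genus": ["Rhodoferax", "Rhodoferax", "Janthinobacterium", "Y"],
            },
            index=["a1", "a2", "a3", "a4"],
        )

    def test_unanimous_genus(self, taxonomy):
        name, rank = consensus_taxonomy(["a1", "a2"], taxonomy)
        assert (name, rank) == ("Rhodoferax", "genus")

    def test_split_genera_fall_back_to_shared_order(self, taxonomy):
        # a1,a2,a3: genus 2/3 < 0.8; family 2/3 < 0.8; order unanimous
        name, rank = consensus_taxonomy(["a1", "a2", "a3"], taxonomy)
        assert (name, rank) == ("Burkholderiales", "order")

    def test_cross_phylum_mixture_resolves_at_domain(self, taxonomy):
        name, rank = consensus_taxonomy(["a1", "a2", "a3", "a4"], taxonomy)
        assert (name, rank) == ("Bacteria", "domain")

    def test_no_taxonomy_unclassified(self, taxonomy):
        name, rank = consensus_taxonomy(["zz"], taxonomy)
        assert name == "Unclassified" and rank is None

    def test_annotate_clades_fills_fields(self, taxonomy):
        tree, clade = _tree_and_clade(n_tips=30, target=6, seed=12)
        factors = phylofactorize(tree, _scores(tree, clade, -6.0, seed=1), alpha=0.05)
        if factors:
            annotate_clades(factors, taxonomy)
            assert factors[0].consensus_name is not None


class TestPresenceCategories:
    def test_set_algebra_and_percentages(self):
        out = presence_categories({"a", "b", "c"}, {"b", "c", "d"}, {"a", "b", "c", "d", "e"})
        cats = out.set_index("asv_id").category
        assert cats["a"] == "group1_exclusive"
        assert cats["d"] == "group2_exclusive"
        assert cats["b"] == cats["c"] == "shared"
        assert cats["e"] == "none"
        assert out.attrs["summary"]["shared"]["percent_of_union"] == pytest.approx(50.0)

    def test_disjoint_sets_no_shared(self):
        out = presence_categories({"a"}, {"b"}, {"a", "b"})
        assert "shared" not in set(out.category)

    def test_subset_leaves_no_group2_exclusive(self):
        out = presence_categories({"a", "b"}, {"a"}, {"a", "b"})
        assert "group2_exclusive" not in set(out.category)
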