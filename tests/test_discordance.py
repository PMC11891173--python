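"""RF distances (against brute-force and dendropy oracles), distance
distributions, chi-square comparison, concordance counting."""

import dendropy
import numpy as np
import pytest

from paleodup.discordance import (
    DistanceDistribution,
    chi_square_compare,
    count_concordance,
    distance_distribution,
    filter_concordant_genes,
    rf_distance,
)
from paleodup.simulate import simulate_msc_gene_trees
from paleodup.trees import as_newick, leaf_labels, read_newick


def _random_binary_tree(rng, taxa):
    """Random binary tree by sequential leaf attachment."""
    nodes = list(taxa)
    newicks = {t: t for t in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({newicks[a]},{newicks[b]})"
        key = a + b
        newicks[key] = merged
        nodes = [n for n in nodes if n not in (a, b)] + [key]
    return read_newick(newicks[nodes[0]] + ";")


def _brute_force_rf(t1, t2):
    """Independent oracle: explicit bipartition sets via leaf-subset scan."""
    shared = set(leaf_labels(t1)) & set(leaf_labels(t2))

    def biparts(tree):
        out = set()
        for nd in tree.postorder_internal_node_iter():
            below = frozenset(
                lf.taxon.label for lf in nd.leaf_iter()
            ) & frozenset(shared)
            other = frozenset(shared) - below
            if len(below) >= 2 and len(other) >= 2:
                out.add(frozenset({below, other}))
        return out

    return len(biparts(t1) ^ biparts(t2))


class TestRFDistance:
    def test_identical_trees_zero(self):
        t = read_newick("((A,B),(C,(D,E)));")
        u = read_newick("((A,B),(C,(D,E)));")
        assert rf_distance(t, u) == 0

    def test_single_nni_is_two(self):
        t = read_newick("(((A,B),C),(D,E));")
        u = read_newick("(((A,C),B),(D,E));")
        assert rf_distance(t, u) == 2

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for n_taxa in (5, 7, 10):
            taxa = [f"t{i}" for i in range(n_taxa)]
            for _ in range(30):
                a = _random_binary_tree(rng, taxa)
                b = _random_binary_tree(rng, taxa)
                assert rf_distance(a, b) == _brute_force_rf(a, b)

    def test_matches_dendropy_oracle(self):
        rng = np.random.default_rng(1)
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(20):
            a = _random_binary_tree(rng, taxa)
            b = _random_binary_tree(rng, taxa)
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=as_newick(a) + ";", schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=as_newick(b) + ";", schema="newick",
                                   taxon_namespace=tns)
            da.encode_bipartitions()
            db.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
            assert rf_distance(a, b) == expected

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(2)
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(30):
            a, b, c = (_random_binary_tree(rng, taxa) for _ in range(3))
            dab, dba = rf_distance(a, b), rf_distance(b, a)
            assert dab == dba
            assert rf_distance(a, c) <= dab + rf_distance(b, c)
            assert rf_distance(a, a) == 0

    def test_upper_bound_and_maximally_different(self):
        # caterpillar vs "reversed-pairing" balanced tree on 6 taxa
        a = read_newick("(((((A,B),C),D),E),F);")
        b = read_newick("(((A,D),(B,F)),(C,E));")
        d = rf_distance(a, b)
        assert d <= 2 * (6 - 3)
        assert d == 2 * (6 - 3)

    def test_pruning_to_shared_leaves(self):
        a = read_newick("(((A,B),(C,D)),(E,F));")
        b = read_newick("((A,B),(C,D));")
        assert rf_distance(a, b) == 0

    def test_too_few_shared_leaves_rejected(self):
        a = read_newick("((A,B),(C,X));")
        b = read_newick("((A,B),(Y,Z));")
        with pytest.raises(ValueError, match="shared"):
            rf_distance(a, b)


class TestDistanceDistribution:
    def test_identical_trees_single_bin(self, balanced8_coalescent_tree):
        sp = balanced8_coalescent_tree
        trees = [read_newick(as_newick(sp) + ";") for _ in range(5)]
        dist = distance_distribution(trees, sp)
        assert dist.counts == {0: 5}

    def test_constructed_distances(self):
        sp = read_newick("(((A,B),C),((D,E),F));")
        trees = [
            read_newick("(((A,B),C),((D,E),F));"),   # 0
            read_newick("(((A,C),B),((D,E),F));"),   # 2
            read_newick("(((A,C),B),((D,E),F));"),   # 2
            read_newick("(((A,C),B),((D,F),E));"),   # 4
        ]
        dist = distance_distribution(trees, sp)
        assert dist.counts == {0: 1, 2: 2, 4: 1}

    def test_long_branch_mass_at_zero(self):
        sp = read_newick("(((A:1,B:1):20,(C:0.5,D:0.5):20.5):20,(E:2,F:2):39.5):5;")
        trees = simulate_msc_gene_trees(sp, 300, seed=3)
        dist = distance_distribution(trees, sp)
        assert dist.counts.get(0, 0) >= 295


class TestChiSquare:
    def test_exact_match_statistic_zero(self):
        emp = DistanceDistribution({0: 50, 2: 30, 4: 20}, 100)
        sim = DistanceDistribution({0: 500, 2: 300, 4: 200}, 1000, "simulated")
        report = chi_square_compare(emp, sim)
        assert report.statistic == pytest.approx(0.0)
        assert report.p_value == pytest.approx(1.0)

    def test_pooling_small_expected_counts(self):
        emp = DistanceDistribution({0: 78, 2: 12, 4: 4, 6: 6}, 100)
        sim = DistanceDistribution({0: 800, 2: 100, 4: 30, 6: 70}, 1000, "simulated")
        report = chi_square_compare(emp, sim)
        assert report.pooled
        assert report.df == 2  # the two small tail bins pooled into one

    def test_degenerate_single_bin_signalled(self):
        emp = DistanceDistribution({0: 10}, 10)
        sim = DistanceDistribution({0: 100}, 100, "simulated")
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_compare(emp, sim)

    def test_type_one_error_calibrated(self, balanced8_coalescent_tree):
        """Null calibration: empirical and simulated from one MSC process."""
        sp = balanced8_coalescent_tree
        n_rep, rejections = 200, 0
        for rep in range(n_rep):
            emp = simulate_msc_gene_trees(sp, 114, seed=10000 + rep)
            sim = simulate_msc_gene_trees(sp, 2000, seed=50000 + rep)
            report = chi_square_compare(
                distance_distribution(emp, sp),
                distance_distribution(sim, sp, "simulated"),
            )
            rejections += report.p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.10


def _concordance_fixture_trees(n_total, n_concordant):
    """Balanced 8-taxon trees: concordant vs one focal-clade rearrangement."""
    concordant = "(((A,B),(C,D)),((E,F),(G,H)));"
    conflicting = "(((A,C),(B,D)),((E,F),(G,H)));"
    return (
        [read_newick(concordant) for _ in range(n_concordant)]
        + [read_newick(conflicting) for _ in range(n_total - n_concordant)]
    )


class TestCountConcordance:
    @pytest.mark.parametrize(
        "n_conc,expected_pct",
        [(105, 92.1), (29, 25.4), (45, 39.5), (114, 100.0)],
    )
    def test_percentages_match_hand_arithmetic(self, n_conc, expected_pct):
        sp = read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        trees = _concordance_fixture_trees(114, n_conc)
        summary = count_concordance(trees, sp)
        universe = set("ABCDEFGH")
        focal = next(
            nc for nc in summary.nodes
            if nc.bipartition in (frozenset("AB"), frozenset(universe - {"A", "B"}))
        )
        assert focal.percent_concordant == pytest.approx(expected_pct)
        assert focal.concordant + focal.conflicting + focal.uninformative == 114

    def test_all_concordant_everywhere(self):
        sp = read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        trees = _concordance_fixture_trees(10, 10)
        summary = count_concordance(trees, sp)
        for nc in summary.nodes:
            assert nc.percent_concordant == 100.0

    def test_matches_bipartition_scan_oracle(self):
        rng = np.random.default_rng(4)
        taxa = [f"t{i}" for i in range(7)]
        sp = _random_binary_tree(rng, taxa)
        trees = [_random_binary_tree(rng, taxa) for _ in range(25)]

        from paleodup.trees import bipartitions

        sp_bips = bipartitions(sp, taxa)
        summary = count_concordance(trees, sp)
        for nc in summary.nodes:
            conc = sum(1 for t in trees if nc.bipartition in bipartitions(t, taxa))
            assert nc.concordant == conc
            # binary, complete-taxon gene trees: never uninformative
            assert nc.uninformative == 0
            assert nc.conflicting == len(trees) - conc


class TestFilterConcordantGenes:
    def test_constructed_subset(self):
        sp = read_newick("(((A,B),C),((D,E),F));")
        concordant = [read_newick("(((A,B),C),((D,E),F));") for _ in range(4)]
        other = [read_newick("(((A,C),B),((D,E),F));") for _ in range(6)]
        trees = concordant + other
        kept = filter_concordant_genes(trees, sp)
        assert kept == concordant

    def test_all_concordant_all_kept(self):
        sp = read_newick("((A,B),(C,D));")
        trees = [read_newick("((A,B),(C,D));") for _ in range(3)]
        assert len(filter_concordant_genes(trees, sp)) == 3

    def test_empty_input(self):
        sp = read_newick("((A,B),(C,D));")
        assert filter_concordant_genes([], sp) == []
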