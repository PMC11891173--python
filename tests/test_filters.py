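"""SCOG extraction, column stripping, informative-site counting and
informative-tree selection, including boundary semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodup.filters import (
    DEFAULT_MISSING,
    FilterConfig,
    OrthogroupTable,
    alignment_from_dict,
    count_parsimony_informative,
    extract_scogs,
    filter_informative_trees,
    read_orthogroup_table,
    strip_columns,
)
from paleodup.simulate import make_orthogroup_table, write_orthogroup_table
from paleodup.trees import read_newick


def _table(clusters, n_samples):
    return OrthogroupTable(
        sample_ids=[f"s{i}" for i in range(n_samples)], clusters=clusters
    )


class TestExtractScogs:
    def test_single_copy_in_12_of_20_retained(self):
        row = [["g"]] * 12 + [[]] * 8
        assert extract_scogs(_table([row], 20), min_taxa=12) == [0]

    def test_eleven_of_twenty_dropped(self):
        row = [["g"]] * 11 + [[]] * 9
        assert extract_scogs(_table([row], 20), min_taxa=12) == []

    def test_multi_copy_cell_excludes_cluster(self):
        row = [["g1", "g2"]] + [["g"]] * 19
        assert extract_scogs(_table([row], 20), min_taxa=12) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        n_samples, clusters = 8, []
        for _ in range(10):
            row = []
            for j in range(n_samples):
                k = rng.choice([0, 1, 1, 1, 2])
                row.append([f"g{j}_{i}" for i in range(k)])
            clusters.append(row)
        table = _table(clusters, n_samples)
        expected = [
            i for i, row in enumerate(clusters)
            if all(len(c) <= 1 for c in row)
            and sum(bool(c) for c in row) >= 5
        ]
        assert extract_scogs(table, min_taxa=5) == expected

    def test_row_permutation_invariance(self):
        rows = [
            [["a"]] * 6 + [[]] * 2,
            [["b", "b2"]] + [["b3"]] * 7,
            [["c"]] * 8,
        ]
        kept = extract_scogs(_table(rows, 8), min_taxa=6)
        perm = [rows[2], rows[0], rows[1]]
        kept_perm = extract_scogs(_table(perm, 8), min_taxa=6)
        assert sorted(str(perm[i]) for i in kept_perm) == sorted(
            str(rows[i]) for i in kept
        )

    def test_cell_count_mismatch_reported(self):
        with pytest.raises(ValueError, match="row 1"):
            _table([[["a"]] * 3, [["b"]] * 2], 3)

    def test_round_trip_through_proteinortho_file(self, tmp_path):
        df = make_orthogroup_table(6, 8, "coverage_ladder", seed=4)
        path = tmp_path / "po.tsv"
        write_orthogroup_table(df, path)
        table = read_orthogroup_table(path)
        assert len(table.clusters) == 8
        assert extract_scogs(table, min_taxa=4) == [3, 4, 5, 6, 7]


class TestStripColumns:
    def test_boundary_semantics_at_20_percent(self):
        # 10 rows; col 0: 3 missing (0.30) removed; col 1: 2 missing (0.20) kept
        seqs = {}
        for i in range(10):
            c0 = "-" if i < 3 else "A"
            c1 = "-" if i < 2 else "C"
            seqs[f"s{i}"] = c0 + c1
        stripped, kept = strip_columns(alignment_from_dict(seqs), 0.20)
        assert kept == [1]
        assert stripped.get_alignment_length() == 1

    def test_threshold_one_keeps_everything(self):
        aln = alignment_from_dict({"a": "--N?", "b": "ACGT"})
        stripped, kept = strip_columns(aln, 1.0)
        assert kept == [0, 1, 2, 3]

    def test_threshold_zero_keeps_only_complete(self):
        aln = alignment_from_dict({"a": "A-CN", "b": "ACGT"})
        _, kept = strip_columns(aln, 0.0)
        assert kept == [0, 2]  # columns 1 and 3 each contain missing data

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        chars = np.array(list("ACGT-N?"))
        seqs = {
            f"s{i}": "".join(rng.choice(chars, size=30)) for i in range(6)
        }
        once, _ = strip_columns(alignment_from_dict(seqs), 0.20)
        twice, kept2 = strip_columns(once, 0.20)
        assert [str(r.seq) for r in twice] == [str(r.seq) for r in once]
        assert kept2 == list(range(once.get_alignment_length()))

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            strip_columns(alignment_from_dict({"a": "", "b": ""}), 0.2)


class TestParsimonyInformative:
    def test_by_definition_examples(self):
        # (A,A,T,T) informative; (A,T,C,G) not
        aln = alignment_from_dict(
            {"a": "AA", "b": "AT", "c": "TC", "d": "TG"}
        )
        assert count_parsimony_informative(aln) == 1

    def test_invariant_alignment_zero(self):
        aln = alignment_from_dict({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
        assert count_parsimony_informative(aln) == 0

    def test_singleton_state_with_missing_not_informative(self):
        # column (A,A,T,N): T occurs once among non-missing
        aln = alignment_from_dict({"a": "A", "b": "A", "c": "T", "d": "N"})
        assert count_parsimony_informative(aln) == 0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        chars = np.array(list("ACGT-N?"))
        mat = rng.choice(chars, size=(5, 20))
        aln = alignment_from_dict(
            {f"s{i}": "".join(mat[i]) for i in range(5)}
        )
        brute = 0
        for j in range(20):
            col = [c for c in mat[:, j] if c not in DEFAULT_MISSING]
            states = {s: col.count(s) for s in set(col)}
            if sum(1 for v in states.values() if v >= 2) >= 2:
                brute += 1
        assert count_parsimony_informative(aln) == brute


def _random_binary_alignment(rng, ids, n_informative, n_pad):
    """Alignment with exactly n_informative informative columns."""
    n = len(ids)
    cols = []
    for _ in range(n_informative):
        col = ["A"] * (n // 2) + ["T"] * (n - n // 2)
        cols.append(col)
    for _ in range(n_pad):
        cols.append(["C"] * n)  # invariant
    mat = np.array(cols).T
    return alignment_from_dict({i: "".join(row) for i, row in zip(ids, mat)})


class TestFilterInformativeTrees:
    def _make_pairs(self, n_total, n_pass, full_taxa, config):
        rng = np.random.default_rng(1)
        newick = "((" + ",".join(full_taxa[:2]) + "),(" + ",".join(full_taxa[2:]) + "));"
        pairs, expected = [], []
        for i in range(n_total):
            passing = i < n_pass
            n_inf = config.min_informative_sites + (1 if passing else 0)
            aln = _random_binary_alignment(rng, full_taxa, n_inf, 5)
            tree = read_newick(newick)
            pairs.append((tree, aln))
            if passing:
                expected.append(i)
        return pairs, expected

    def test_constructed_114_of_200(self):
        full = ["t1", "t2", "t3", "t4"]
        config = FilterConfig(min_informative_sites=10)
        pairs, expected = self._make_pairs(200, 114, full, config)
        kept = filter_informative_trees(pairs, config, full_taxon_set=full)
        assert len(kept) == 114
        assert [pairs.index(p) for p in kept] == expected

    def test_exactly_at_threshold_excluded(self):
        full = ["t1", "t2", "t3", "t4"]
        config = FilterConfig(min_informative_sites=600)
        rng = np.random.default_rng(2)
        aln = _random_binary_alignment(rng, full, 600, 3)
        tree = read_newick("((t1,t2),(t3,t4));")
        assert filter_informative_trees([(tree, aln)], config, full) == []

    def test_missing_taxa_excluded_when_required(self):
        full = ["t1", "t2", "t3", "t4", "t5"]
        config = FilterConfig(min_informative_sites=5, require_complete_taxa=True)
        rng = np.random.default_rng(3)
        aln = _random_binary_alignment(rng, full[:4], 10, 2)
        tree = read_newick("((t1,t2),(t3,t4));")
        assert filter_informative_trees([(tree, aln)], config, full) == []

    def test_tree_alignment_mismatch_reported(self):
        config = FilterConfig(min_informative_sites=1)
        rng = np.random.default_rng(4)
        aln = _random_binary_alignment(rng, ["a", "b", "c", "d"], 5, 0)
        tree = read_newick("((a,b),(c,x));")
        with pytest.raises(ValueError, match="pair 0"):
            filter_informative_trees([(tree, aln)], config, ["a", "b", "c", "d"])

    def test_empty_input(self):
        assert filter_informative_trees([], FilterConfig()) == []
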