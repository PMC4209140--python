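"""Codon-alignment container, sequence QC, tree pruning, block filter."""

import numpy as np
import pytest

from codonsel import (
    CodonAlignment,
    conserved_block_filter,
    filter_sequences,
    prune_tree,
    read_newick,
)


class TestCodonAlignment:
    def test_validation(self):
        with pytest.raises(ValueError):
            CodonAlignment(["a"], ["ATGA"])  # not multiple of 3
        with pytest.raises(ValueError):
            CodonAlignment(["a", "b"], ["ATG", "ATGATG"])  # ragged
        with pytest.raises(ValueError):
            CodonAlignment(["a", "a"], ["ATG", "ATG"])  # duplicate names
        with pytest.raises(ValueError):
            CodonAlignment(["a"], ["TAA"])  # in-frame stop

    def test_stop_codon_allowed_when_ambiguous(self):
        # TA- and TAN are missing-data codons, not stops
        aln = CodonAlignment(["a"], ["TA-TANATG"])
        assert aln.n_sites == 3

    def test_state_matrix_missing_codes(self, small_alignment):
        states = small_alignment.state_matrix()
        assert states.shape == (4, 6)
        assert states[2, 3] == -1  # gap codon
        assert states[3, 4] == -1  # NNN codon
        assert (states >= -1).all()

    def test_fasta_roundtrip(self, small_alignment, tmp_path):
        path = tmp_path / "aln.fasta"
        small_alignment.to_fasta(path)
        back = CodonAlignment.from_fasta(path)
        assert back.taxa == small_alignment.taxa
        assert back.sequences == small_alignment.sequences


class TestFilterSequences:
    def _aln(self, n_ambig, length=300):
        clean = ("ATGAAACCT" * 100)[:length]
        dirty = "N" * n_ambig + clean[n_ambig:]
        return CodonAlignment(["clean", "dirty"], [clean, dirty])

    def test_above_threshold_removed(self):
        filtered, report = filter_sequences(self._aln(4))  # 4/300 = 1.33%
        assert filtered.taxa == ["clean"]
        assert "dirty" in report.removed_taxa

    def test_clean_row_kept(self):
        filtered, _ = filter_sequences(self._aln(0))
        assert set(filtered.taxa) == {"clean", "dirty"}

    def test_exactly_one_percent_kept(self):
        # 3/300 = 1.00%: the rule is strictly greater-than
        filtered, _ = filter_sequences(self._aln(3))
        assert set(filtered.taxa) == {"clean", "dirty"}

    def test_gap_positions_excluded_from_denominator(self):
        # 3 N over 150 non-gap positions = 2% -> removed
        half_gap = "N" * 3 + "ATGAAACCT" * 16 + "ATG" + "-" * 150
        clean = "ATGAAACCT" * 33 + "ATG"
        aln = CodonAlignment(["clean", "gappy"], [clean, half_gap])
        filtered, report = filter_sequences(aln)
        assert filtered.taxa == ["clean"]

    def test_all_removed_is_error(self):
        aln = CodonAlignment(["x", "y"], ["NNNATG", "NNNATG"])
        with pytest.raises(ValueError):
            filter_sequences(aln)


class TestPruneTree:
    def test_keep_all_is_identity(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        pruned = prune_tree(tree, ["A", "B", "C", "D"])
        assert sorted(l.taxon.label for l in pruned.leaf_node_iter()) == list("ABCD")

    def test_collapse_sums_branch_lengths(self):
        """Dropping B leaves A on a degree-2 path whose lengths merge:
        ((A:1,B:1):1,(C:1,D:1):1) -> (A:2,(C:1,D:1):1)."""
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        pruned = prune_tree(tree, ["A", "C", "D"])
        lengths = {
            l.taxon.label: l.edge.length for l in pruned.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(1.0)
        cd_parent = [
            n for n in pruned.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert len(cd_parent) == 1
        assert cd_parent[0].edge.length == pytest.approx(1.0)

    def test_too_few_taxa_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            prune_tree(tree, ["A"])

    def test_unknown_taxon_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(KeyError):
            prune_tree(tree, ["A", "Z"])


def _noise_rows(rng, n_taxa, n_codons):
    """Gap-free codon columns with every row different (non-conserved)."""
    from codonsel import standard_genetic_code

    senses = list(standard_genetic_code().sense_codons)
    rows = [[] for _ in range(n_taxa)]
    for _ in range(n_codons):
        picks = rng.choice(len(senses), size=n_taxa, replace=False)
        for i, p in enumerate(picks):
            rows[i].append(senses[p])
    return ["".join(r) for r in rows]


class TestConservedBlockFilter:
    def test_identical_rows_all_kept(self):
        aln = CodonAlignment(
            [f"t{i}" for i in range(4)], ["ATGAAACCTTGGGAGTTT"] * 4
        )
        filtered, report = conserved_block_filter(aln)
        assert filtered.n_sites == aln.n_sites
        assert report.column_map == [1, 2, 3, 4, 5, 6]

    def test_gap_majority_column_removed(self):
        base = "ATGAAACCTTGGGAG"  # 5 conserved codons
        rows = [base + "AAA", base + "---", base + "---", base + "---"]
        aln = CodonAlignment([f"t{i}" for i in range(4)], rows)
        filtered, report = conserved_block_filter(aln, min_block_length=2)
        assert 6 not in report.column_map  # 3 of 4 rows gapped
        assert filtered.n_sites == 5

    def test_short_conserved_island_removed(self):
        rng = np.random.default_rng(12)
        noise_left = _noise_rows(rng, 4, 5)
        noise_right = _noise_rows(rng, 4, 5)
        island = ["ATGAAA"] * 4  # 2 conserved codons only
        rows = [l + i + r for l, i, r in zip(noise_left, island, noise_right)]
        aln = CodonAlignment([f"t{i}" for i in range(4)], rows)
        with pytest.raises(ValueError):
            # the 2-column island is below the 4-codon minimum block: nothing
            # survives anywhere
            conserved_block_filter(aln, min_block_length=4)

    def test_island_survives_when_long_enough(self):
        rng = np.random.default_rng(12)
        rows = [
            l + i + r
            for l, i, r in zip(
                _noise_rows(rng, 4, 5), ["ATGAAACCTTGG"] * 4, _noise_rows(rng, 4, 5)
            )
        ]
        aln = CodonAlignment([f"t{i}" for i in range(4)], rows)
        filtered, report = conserved_block_filter(aln, min_block_length=4)
        assert filtered.n_sites == 4
        assert report.column_map == [6, 7, 8, 9]

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        rows = [
            a + b + c
            for a, b, c in zip(
                ["ATGAAACCTTGGGAGTTT"] * 5,
                _noise_rows(rng, 5, 6),
                ["GAGTTTATGAAACCTTGG"] * 5,
            )
        ]
        aln = CodonAlignment([f"t{i}" for i in range(5)], rows)
        once, report1 = conserved_block_filter(aln)
        twice, report2 = conserved_block_filter(once)
        assert once.sequences == twice.sequences
        assert report2.column_map == list(range(1, once.n_sites + 1))

    def test_column_map_roundtrip(self):
        rng = np.random.default_rng(3)
        rows = [
            a + b
            for a, b in zip(["ATGAAACCTTGG"] * 4, _noise_rows(rng, 4, 4))
        ]
        aln = CodonAlignment([f"t{i}" for i in range(4)], rows)
        filtered, report = conserved_block_filter(aln)
        re_extracted = aln.subset_sites([c - 1 for c in report.column_map])
        assert re_extracted.sequences == filtered.sequences

    def test_needs_four_taxa(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATG"] * 3)
        with pytest.raises(ValueError):
            conserved_block_filter(aln)
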