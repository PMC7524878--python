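"""Barcode authentication: merging, trimming, distances, NJ, flagging."""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

import mintscreen as ms
from mintscreen.barcoding import (
    PSBA_PRIMER,
    TRNH_PRIMER,
    MergeError,
    SequenceRecord,
    TreeNode,
    TrimError,
    reverse_complement,
)

from conftest import random_additive_tree


# ---------------------------------------------------------------------------
# read merging
# ---------------------------------------------------------------------------

class TestMergeReads:
    def test_identical_full_overlap_returns_the_read(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        fwd = SequenceRecord("x", seq)
        rev = SequenceRecord("x", reverse_complement(seq))
        assert ms.merge_reads(fwd, rev, min_overlap=10).residues == seq

    def test_single_disagreement_in_overlap_becomes_one_N(self):
        rng = np.random.default_rng(7)
        left = "".join(rng.choice(list("ACGT"), 30))
        overlap = "".join(rng.choice(list("ACGT"), 20))
        right = "".join(rng.choice(list("ACGT"), 25))
        # mutate one overlap position as seen by the reverse read
        mut = ("A" if overlap[10] != "A" else "C")
        overlap_rev = overlap[:10] + mut + overlap[11:]
        fwd = SequenceRecord("x", left + overlap)
        rev = SequenceRecord("x", reverse_complement(overlap_rev + right))
        merged = ms.merge_reads(fwd, rev, min_overlap=15).residues
        assert merged.count("N") == 1
        assert len(merged) == 30 + 20 + 25
        assert merged[30 + 10] == "N"

    def test_disjoint_reads_fail(self):
        fwd = SequenceRecord("x", "A" * 30)
        rev = SequenceRecord("x", "C" * 30)
        with pytest.raises(MergeError):
            ms.merge_reads(fwd, rev, min_overlap=10)


# ---------------------------------------------------------------------------
# primer trimming
# ---------------------------------------------------------------------------

class TestTrimToPrimers:
    def test_exact_primers_bracket_the_insert(self):
        insert = "ACGTACGT"
        seq = SequenceRecord(
            "x", PSBA_PRIMER + insert + reverse_complement(TRNH_PRIMER)
        )
        assert ms.trim_to_primers(seq, max_mismatch=0).residues == insert

    def test_one_mismatch_still_found_within_budget(self):
        insert = "TTTTGGGGCCCC"
        fwd_mut = "A" + PSBA_PRIMER[1:]  # 1 mismatch vs the true primer
        assert fwd_mut != PSBA_PRIMER
        seq = SequenceRecord(
            "x", fwd_mut + insert + reverse_complement(TRNH_PRIMER)
        )
        assert ms.trim_to_primers(seq, max_mismatch=1).residues == insert
        with pytest.raises(TrimError) as err:
            ms.trim_to_primers(seq, max_mismatch=0)
        assert err.value.primer_role == "forward"

    def test_absent_reverse_primer_fails_naming_it(self):
        seq = SequenceRecord("x", PSBA_PRIMER + "ACGT" * 20)
        with pytest.raises(TrimError) as err:
            ms.trim_to_primers(seq, max_mismatch=1)
        assert err.value.primer_role == "reverse"


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestPairwiseDistance:
    def aln(self, *seqs):
        return ms.Alignment(
            [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        )

    def test_identity_and_simple_mismatch(self):
        dm = ms.pairwise_distance(self.aln("ACGT", "ACGT", "ACGA"))
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s2"] == pytest.approx(0.25)

    def test_pairwise_deletion_excludes_gap_sites(self):
        dm = ms.pairwise_distance(self.aln("AC-T", "ACGT"))
        assert dm["s0", "s1"] == 0.0  # 3 comparable sites, 0 mismatches

    def test_no_comparable_sites_is_an_error_naming_the_pair(self):
        with pytest.raises(ValueError, match="s0.*s1"):
            ms.pairwise_distance(self.aln("AC--", "--GT"))

    def test_k2p_matches_hand_formula(self):
        # 20 sites: 2 transitions (A<->G), 1 transversion (A<->C)
        s0 = "A" * 20
        s1 = "GG" + "C" + "A" * 17
        p, q = 2 / 20, 1 / 20
        expected = -0.5 * np.log(1 - 2 * p - q) - 0.25 * np.log(1 - 2 * q)
        dm = ms.pairwise_distance(self.aln(s0, s1), model="K2P")
        assert dm["s0", "s1"] == pytest.approx(expected, rel=1e-12)

    def test_k2p_log_domain_violation_raises(self):
        with pytest.raises(ValueError, match="divergent"):
            ms.pairwise_distance(self.aln("A" * 8, "G" * 8), model="K2P")

    def test_metric_properties_on_simulated_alignment(self, alignment):
        dm = ms.pairwise_distance(alignment)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values >= 0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def least_squares_best_topology(dm: ms.DistanceMatrix):
    """Brute-force oracle: enumerate all unrooted binary topologies, fit
    branch lengths by non-negative least squares, return the bipartition set
    of the minimum-RSS topology."""
    labels = dm.labels

    def topologies(taxa):
        # list of edge-sets; each tree is a list of frozenset bipartitions
        # built by sequential insertion; represent trees as nested tuples
        if len(taxa) == 3:
            yield (taxa[0], taxa[1], taxa[2])
            return
        head, rest = taxa[-1], taxa[:-1]
        for t in topologies(rest):
            for edited in insert_all(t, head):
                yield edited

    def insert_all(tree, leaf):
        # tree is a tuple whose root has 3 children; every node position
        # below the root is an edge the new leaf can be grafted onto
        def edges(node, path):
            if isinstance(node, tuple):
                for i, child in enumerate(node):
                    yield path + (i,)
                    yield from edges(child, path + (i,))

        def splice(node, path):
            if not path:
                return (node, leaf)
            i, rest = path[0], path[1:]
            return tuple(
                splice(c, rest) if j == i else c for j, c in enumerate(node)
            )

        for path in edges(tree, ()):
            yield splice(tree, path)

    def bipartitions_of(tree):
        n = len(labels)
        ref = min(labels)
        all_set = frozenset(labels)
        out = set()

        def walk(node):
            if isinstance(node, str):
                return frozenset([node])
            below = frozenset().union(*(walk(c) for c in node))
            if 2 <= len(below) <= n - 2:
                side = below if ref not in below else all_set - below
                out.add(side)
            return below

        walk(tree)
        return frozenset(out)

    def rss_of(tree):
        # edges: pendant per leaf + one per non-trivial bipartition
        bps = sorted(bipartitions_of(tree), key=sorted)
        edge_index = {("leaf", l): k for k, l in enumerate(labels)}
        for k, bp in enumerate(bps):
            edge_index[("split", bp)] = len(labels) + k
        pairs = list(itertools.combinations(range(len(labels)), 2))
        A = np.zeros((len(pairs), len(edge_index)))
        y = np.zeros(len(pairs))
        for row, (i, j) in enumerate(pairs):
            A[row, edge_index[("leaf", labels[i])]] = 1
            A[row, edge_index[("leaf", labels[j])]] = 1
            for bp in bps:
                if (labels[i] in bp) != (labels[j] in bp):
                    A[row, edge_index[("split", bp)]] = 1
            y[row] = dm.values[i, j]
        _, rnorm = nnls(A, y)
        return rnorm

    best_bps, best_rss = None, None
    for t in topologies(tuple(labels)):
        bps = bipartitions_of(t)
        r = rss_of(t)
        if best_rss is None or r < best_rss - 1e-9:
            best_rss, best_bps = r, bps
    return best_bps


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = ms.neighbor_joining(ms.DistanceMatrix(["A", "B", "C"], d))
        bl = {lf.name: lf.branch_length for lf in tree.root.leaves()}
        assert bl["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert bl["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert bl["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive path distances
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        labels = ["A", "B", "C", "D"]
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            m[i, j] = m[j, i] = v
        dm = ms.DistanceMatrix(labels, m)
        tree = ms.neighbor_joining(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        for x, y in itertools.combinations(labels, 2):
            assert tree.path_length(x, y) == pytest.approx(d[(x, y)])

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (5, 2), (6, 3), (6, 4)])
    def test_additive_matrices_recover_source_and_ls_topology(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        true_tree, dm = random_additive_tree(n_taxa, rng)
        nj = ms.neighbor_joining(dm)
        assert nj.bipartitions() == true_tree.bipartitions()
        assert nj.bipartitions() == least_squares_best_topology(dm)

    def test_agrees_with_skbio_on_noisy_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        _, dm = random_additive_tree(6, rng)
        noisy = dm.values + rng.uniform(0, 0.05, dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        dm2 = ms.DistanceMatrix(dm.labels, noisy)
        ours = ms.neighbor_joining(dm2)
        sk = skbio.tree.nj(skbio.DistanceMatrix(noisy, dm.labels))
        sk_bps = set()
        ref = min(dm.labels)
        allset = frozenset(dm.labels)
        for node in sk.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(dm.labels) - 2:
                side = below if ref not in below else allset - below
                if 2 <= len(side) <= len(dm.labels) - 2:
                    sk_bps.add(side)
        assert ours.bipartitions() == sk_bps

    def test_too_few_taxa_rejected(self):
        dm = ms.DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            ms.neighbor_joining(dm)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_supports_bounded_and_deterministic(self, alignment):
        t1 = ms.bootstrap_support(alignment, n_reps=50, rng_seed=3)
        t2 = ms.bootstrap_support(alignment, n_reps=50, rng_seed=3)
        assert t1.support_table == t2.support_table
        assert all(0 <= s <= 100 for s in t1.support_table.values())

    def test_two_divergent_blocks_get_full_support(self):
        # every informative column supports the same split
        block_a, block_b = "A" * 40, "C" * 40
        aln = ms.Alignment(
            [
                ms.SequenceRecord("a1", block_a),
                ms.SequenceRecord("a2", block_a),
                ms.SequenceRecord("b1", block_b),
                ms.SequenceRecord("b2", block_b),
            ]
        )
        tree = ms.bootstrap_support(aln, n_reps=100, rng_seed=0)
        assert tree.support_table[frozenset({"b1", "b2"})] == 100.0

    def test_invariant_under_record_order_permutation(self, alignment):
        shuffled = ms.Alignment(list(reversed(alignment.records)))
        t1 = ms.bootstrap_support(alignment, n_reps=30, rng_seed=5)
        t2 = ms.bootstrap_support(shuffled, n_reps=30, rng_seed=5)
        assert t1.support_table == t2.support_table

    def test_bad_arguments(self, alignment):
        with pytest.raises(ValueError):
            ms.bootstrap_support(alignment, n_reps=0)
        with pytest.raises(ValueError):
            ms.bootstrap_support(alignment, n_reps=5, outgroup="nope")


# ---------------------------------------------------------------------------
# mislabel flagging
# ---------------------------------------------------------------------------

def build_supported_tree(newick: str) -> ms.PhyloTree:
    return ms.PhyloTree.from_newick(newick)


class TestFlagMislabels:
    def consistent_tree(self):
        nwk = ("((A1:1,A2:1,A3:1)100:5,(B1:1,B2:1,B3:1)100:5,OG:20);")
        return build_supported_tree(nwk)

    def declared(self, swap=False):
        d = {"A1": "spA", "A2": "spA", "A3": "spA",
             "B1": "spB", "B2": "spB", "B3": "spB", "OG": "out"}
        if swap:
            d["A3"], d["B3"] = d["B3"], d["A3"]
        return d

    def test_consistent_labels_flag_nothing(self):
        reports = ms.flag_mislabels(
            self.consistent_tree(), self.declared(), 65, outgroup="OG"
        )
        assert [r.status for r in reports] == ["ok"] * 6

    def test_swapped_pair_flagged_exactly(self):
        reports = ms.flag_mislabels(
            self.consistent_tree(), self.declared(swap=True), 65, outgroup="OG"
        )
        flagged = {r.accession: r.inferred for r in reports if r.status == "flagged"}
        assert flagged == {"A3": "spA", "B3": "spB"}
        assert all(
            r.status == "ok" for r in reports if r.accession not in flagged
        )

    def test_unreachable_support_threshold_leaves_all_unresolved(self):
        reports = ms.flag_mislabels(
            self.consistent_tree(), self.declared(), 101, outgroup="OG"
        )
        assert {r.status for r in reports} == {"unresolved"}

    def test_singleton_species_in_foreign_clade_is_untestable(self):
        nwk = "((A1:1,A2:1,C1:1)100:5,(B1:1,B2:1)100:5,OG:20);"
        declared = {"A1": "spA", "A2": "spA", "C1": "spC",
                    "B1": "spB", "B2": "spB", "OG": "out"}
        reports = ms.flag_mislabels(
            build_supported_tree(nwk), declared, 65, outgroup="OG"
        )
        by_acc = {r.accession: r for r in reports}
        assert by_acc["C1"].status == "untestable"

    def test_planted_mislabels_recovered_without_false_positives(
        self, scenario, panel, alignment
    ):
        tree = ms.bootstrap_support(
            alignment, n_reps=100, rng_seed=0, outgroup=scenario.outgroup
        )
        declared = {a.id: a.declared_species for a in panel}
        reports = ms.flag_mislabels(tree, declared, 65, outgroup=scenario.outgroup)
        flagged = {r.accession for r in reports if r.status == "flagged"}
        planted = {acc for pair in scenario.mislabel_pairs for acc in pair}
        assert flagged == planted
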