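import numpy as np
import pytest

from _oracles import random_additive_tree
from gh13csr import SyntheticConfig, generate_family, generate_truth_msa
from gh13csr.csr import extract_fingerprints, locate_anchors
from gh13csr.phylo import (
    DistanceMatrix,
    bootstrap_tree,
    build_both_trees,
    fingerprint_msa,
    neighbor_joining,
    p_distance,
    split_support,
    tree_splits,
)
from gh13csr.seqio import Msa
from gh13csr.synthetic_data import reference_annotation, truth_fingerprints


class TestPDistance:
    def test_identical_rows(self):
        d = p_distance(Msa(["A", "B"], ["AAAA", "AAAA"]))
        assert d.matrix[0, 1] == 0.0

    def test_single_mismatch(self):
        d = p_distance(Msa(["A", "B"], ["AAAA", "AAAT"]))
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_counts_comparable_columns_only(self):
        d = p_distance(Msa(["A", "B"], ["A-AA", "AT-A"]))
        # columns 1 and 4 are comparable, both match
        assert d.matrix[0, 1] == 0.0

    def test_complete_deletion_drops_gapped_columns_globally(self):
        msa = Msa(["A", "B", "C"], ["A-AT", "ATAT", "ATAA"])
        d = p_distance(msa, deletion="complete")
        # only columns 1, 3, 4 survive; B vs C differ at column 4
        assert d.matrix[1, 2] == pytest.approx(1 / 3)

    def test_no_overlap_pair_warns_and_maxes_out(self):
        msa = Msa(["A", "B"], ["A--A", "-AA-"])
        with pytest.warns(UserWarning):
            d = p_distance(msa)
        assert d.matrix[0, 1] == 1.0

    def test_symmetry_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), D))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)

    def test_four_taxon_additive_split_recovered(self):
        # tree ((A,B),(C,D)) with internal edge 2
        D = np.array(
            [[0, 3, 7, 6], [3, 0, 8, 7], [7, 8, 0, 5], [6, 7, 5, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), D))
        assert tree_splits(tree) == {frozenset({"C", "D"})}

    def test_additive_matrices_recover_generating_topology(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            labels, D, want = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(tuple(labels), D))
            assert tree_splits(tree) == want

    def test_matches_reference_nj_on_random_matrix(self):
        # cross-check topology against the independent scikit-bio NJ
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        labels, D, _ = random_additive_tree(7, rng)
        D_noisy = D + rng.uniform(0, 0.01, D.shape)
        D_noisy = (D_noisy + D_noisy.T) / 2
        np.fill_diagonal(D_noisy, 0.0)
        mine = neighbor_joining(DistanceMatrix(tuple(labels), D_noisy))
        theirs = skbio_nj(SkbioDM(D_noisy, labels))
        assert tree_splits(mine) == tree_splits(theirs)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    def test_total_length_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        labels, D, _ = random_additive_tree(6, rng)
        perm = rng.permutation(len(labels))
        t1 = neighbor_joining(DistanceMatrix(tuple(labels), D))
        t2 = neighbor_joining(
            DistanceMatrix(tuple(labels[k] for k in perm), D[np.ix_(perm, perm)])
        )
        total1 = sum(n.length or 0 for n in t1.traverse())
        total2 = sum(n.length or 0 for n in t2.traverse())
        assert total1 == pytest.approx(total2)

    def test_negative_branch_lengths_clamped(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 6
            D = rng.uniform(0.2, 1.0, (n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = neighbor_joining(
                DistanceMatrix(tuple(f"T{k}" for k in range(n)), D)
            )
            assert all((node.length or 0) >= 0 for node in tree.traverse())


@pytest.fixture(scope="module")
def two_clade_msa():
    fps = []
    for k, sub in enumerate(("GH13_1", "GH13_24")):
        cfg = SyntheticConfig(
            seed=k, n_sequences=5, subfamily=sub, accession_prefix=f"C{k}X",
            substitution_rate=0.3, protect_csr=False,
        )
        _, truths = generate_family(cfg)
        fps.extend(truth_fingerprints(truths))
    return fingerprint_msa(fps)


class TestBootstrap:
    def test_reproducible_bit_for_bit(self, two_clade_msa):
        t1 = bootstrap_tree(two_clade_msa, n_replicates=20, seed=7)
        t2 = bootstrap_tree(two_clade_msa, n_replicates=20, seed=7)
        assert str(t1) == str(t2)

    def test_single_replicate_supports_are_binary(self, two_clade_msa):
        tree = bootstrap_tree(two_clade_msa, n_replicates=1, seed=1)
        supports = [
            int(n.name) for n in tree.non_tips(include_self=False)
            if n.name and n.name.isdigit()
        ]
        assert supports and all(s in (0, 1) for s in supports)

    def test_strong_clade_gets_high_support(self, two_clade_msa):
        tree = bootstrap_tree(two_clade_msa, n_replicates=100, seed=5)
        clade = frozenset(f"C1X{k:04d}" for k in range(5))
        support = split_support(tree, clade)
        assert support is not None and support >= 95

    def test_duplicated_columns_leave_point_estimate_unchanged(self, two_clade_msa):
        doubled = Msa(
            list(two_clade_msa.row_ids), [r + r for r in two_clade_msa.rows]
        )
        t1 = neighbor_joining(p_distance(two_clade_msa))
        t2 = neighbor_joining(p_distance(doubled))
        assert tree_splits(t1) == tree_splits(t2)


class TestBuildBothTrees:
    def _family(self, seeds=(0, 1), n=6, rate=0.02):
        """Two groups sharing CSR motifs but with distinct linker content."""
        groups = []
        for k, seed in enumerate(seeds):
            cfg = SyntheticConfig(
                seed=seed, n_sequences=n, subfamily="GH13_24",
                substitution_rate=rate, accession_prefix=f"G{k}X",
            )
            groups.append(generate_family(cfg))
        records = groups[0][0] + groups[1][0]
        truths = groups[0][1] + groups[1][1]
        return records, truths

    def test_fingerprint_alignment_is_55_columns(self, small_fingerprints):
        msa = fingerprint_msa(small_fingerprints)
        assert msa.width == 55

    def test_identical_inputs_give_identical_trees(self, small_fingerprints):
        msa = fingerprint_msa(small_fingerprints)
        seg, fp_tree, report = build_both_trees(
            msa, small_fingerprints, n_replicates=10, seed=3
        )
        assert tree_splits(seg) == tree_splits(fp_tree)
        assert report["unique_segment_splits"] == 0
        assert report["unique_csr_splits"] == 0
        assert report["fingerprint_columns"] == 55

    def test_taxon_mismatch_rejected(self, small_fingerprints):
        msa = fingerprint_msa(small_fingerprints[:-1])
        with pytest.raises(ValueError, match="taxa"):
            build_both_trees(msa, small_fingerprints, n_replicates=5)

    def test_linker_signal_separates_groups_better_in_segment_tree(self):
        from gh13csr.aligner import progressive_msa
        from gh13csr.csr import trim_beta_segment

        records, truths = self._family()
        msa = progressive_msa(records)
        anchors = locate_anchors(msa, reference_annotation(truths[0]))
        segment = trim_beta_segment(msa, anchors)
        fps = extract_fingerprints(msa, anchors)
        seg_tree, csr_tree, _ = build_both_trees(
            segment, fps, n_replicates=50, seed=2
        )
        group = frozenset(t.accession for t in truths[: len(truths) // 2])
        seg_support = split_support(seg_tree, group) or 0
        csr_support = split_support(csr_tree, group) or 0
        # identical CSR content cannot separate the groups; the linkers can
        assert seg_support >= 45
        assert seg_support >= csr_support
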