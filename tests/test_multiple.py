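"""Guide tree and consensus-weighted progressive multiple alignment."""

import numpy as np
import pytest

from stralign.dp import GAP
from stralign.multiple import (
    AlignmentNode,
    build_guide_tree,
    combine_nodes,
    leaf_node,
    multiple_align,
)
from stralign.pairwise import AlignmentParams
from stralign.synthetic import (
    FixtureSpec,
    delete_residues,
    make_structure,
    perturb,
    random_rigid,
)
from conftest import MIXED_BLOCKS


def family(base, k, seed0=300, noise=0.0):
    out = []
    for i in range(k):
        s = random_rigid(base, seed=seed0 + i, new_id=f"f{i}")
        if noise > 0:
            s = perturb(s, noise, seed=seed0 + 50 + i, new_id=s.id)
        out.append(s)
    return out


class TestGuideTree:
    def test_most_similar_pair_merges_first(self):
        scores = {
            frozenset(("A", "B")): 0.9,
            frozenset(("A", "C")): 0.2,
            frozenset(("B", "C")): 0.2,
        }
        tree = build_guide_tree(scores, ids=["A", "B", "C"])
        assert tree.merge_order[0][:2] == ("A", "B")
        assert len(tree.merge_order) == 2

    def test_identical_structures_deterministic_order(self):
        ids = ["d", "b", "a", "c"]
        scores = {frozenset(p): 1.0 for p in
                  [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]}
        tree = build_guide_tree(scores, ids=ids)
        assert [m[:2] for m in tree.merge_order[:1]] == [("a", "b")]
        assert all(h == 0.0 for h in tree.heights)

    def test_four_leaves_three_merges(self):
        rng = np.random.default_rng(1)
        ids = list("wxyz")
        scores = {
            frozenset((a, b)): float(rng.uniform(0, 1))
            for k, a in enumerate(ids)
            for b in ids[k + 1:]
        }
        tree = build_guide_tree(scores, ids=ids)
        assert len(tree.merge_order) == 3
        assert tree.to_newick().endswith(";")

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            build_guide_tree({}, ids=["only"])


class TestCombineNodes:
    def test_two_copies_merge_gap_free(self, mixed_structure):
        cw = 1.0
        moved = random_rigid(mixed_structure, seed=77, new_id="b")
        a = leaf_node(mixed_structure, cw)
        b = leaf_node(moved, cw)
        node = combine_nodes(a, b)
        n = len(mixed_structure)
        assert len(node) == n
        assert (node.counts == 2).all()
        assert np.allclose(node.consensus, 2 * cw)
        assert node.n_structures == 2
        # averaged coordinates coincide with the originals (in the frame of
        # the second input) after superposition
        assert np.abs(node.coords - moved.ca_coords).max() < 1e-6

    def test_deletion_member_counts(self, mixed_structure):
        shorter = delete_residues(mixed_structure, 20, 5, new_id="short")
        node = combine_nodes(leaf_node(mixed_structure), leaf_node(shorter))
        n = len(mixed_structure)
        assert len(node) == n
        assert (node.counts == 2).sum() == n - 5
        assert (node.counts == 1).sum() == 5

    def test_leaf_node_invariants(self, mixed_structure):
        leaf = leaf_node(mixed_structure, cw=2.5)
        assert leaf.n_structures == 1
        assert (leaf.counts == 1).all()
        assert np.allclose(leaf.consensus, 2.5)
        assert np.array_equal(leaf.members[mixed_structure.id], np.arange(len(mixed_structure)))

    def test_equal_consensus_columns_score_like_plain_coords(self):
        """Columns with equal working consensus contribute zero to the RBF
        exponent: the score equals the consensus-free score."""
        from stralign.pairwise import score_coords

        plain = score_coords([1.0, 2.0, 3.0], [1.1, 2.1, 3.1])
        augmented = score_coords([1.0, 2.0, 3.0, 4.0], [1.1, 2.1, 3.1, 4.0])
        assert augmented == pytest.approx(plain, abs=1e-15)


class TestMultipleAlign:
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_identical_family_gap_free(self, mixed_structure, k):
        msa = multiple_align(family(mixed_structure, k))
        assert msa.column_count == len(mixed_structure)
        assert msa.gapless_column_mask().all()

    def test_noisy_family_gap_free(self, mixed_structure):
        msa = multiple_align(family(mixed_structure, 4, noise=0.5))
        assert msa.column_count == len(mixed_structure)
        assert msa.gapless_column_mask().all()

    def test_insertion_localizes_to_contiguous_gap_columns(self):
        long = make_structure(
            FixtureSpec(
                blocks=[("helix", 15), ("loop", 16), ("strand", 10),
                        ("loop", 10), ("helix", 15)],
                seed=3,
                struct_id="long",
            )
        )
        short = delete_residues(long, 20, 6, new_id="short")
        fam = [random_rigid(short, seed=i, new_id=f"m{i}") for i in range(3)]
        fam.append(random_rigid(long, seed=99, new_id="long"))
        msa = multiple_align(fam)
        gap_cols = np.flatnonzero(~msa.gapless_column_mask())
        assert len(gap_cols) == 6
        assert (np.diff(gap_cols) == 1).all()

    def test_column_conservation(self, mixed_structure):
        """Reading any structure's row and dropping gaps recovers
        0..N-1 in order."""
        fam = family(mixed_structure, 3, noise=0.8)
        msa = multiple_align(fam)
        for sid, row in msa.rows.items():
            row = np.asarray(row)
            residues = row[row != GAP]
            assert np.array_equal(residues, np.arange(len(residues)))
            assert len(residues) == len(mixed_structure)

    def test_input_order_robustness(self, mixed_structure):
        fam = family(mixed_structure, 4)
        msa1 = multiple_align(fam)
        msa2 = multiple_align(fam[::-1])
        assert msa1.column_count == msa2.column_count
        assert int((~msa1.gapless_column_mask()).sum()) == int(
            (~msa2.gapless_column_mask()).sum()
        )

    def test_consensus_weight_preserves_core(self, mixed_structure):
        """With the consensus feedback on, the aligned core (gap-less
        column count) of a 6-similar + 2-divergent family is at least as
        large as with the feedback off."""
        similar = family(mixed_structure, 6, noise=0.4)
        divergent = [
            random_rigid(
                make_structure(FixtureSpec(blocks=MIXED_BLOCKS, seed=s, struct_id=f"d{s}")),
                seed=400 + s,
            )
            for s in (77, 78)
        ]
        fam = similar + divergent
        with_cw = multiple_align(fam, AlignmentParams(consensus_weight=1.0))
        without_cw = multiple_align(fam, AlignmentParams(consensus_weight=0.0))
        assert int(with_cw.gapless_column_mask().sum()) >= int(
            without_cw.gapless_column_mask().sum()
        )

    def test_root_counts_bounded_by_family_size(self, mixed_structure):
        fam = family(mixed_structure, 4, noise=0.6)
        msa, tree, scores, root = multiple_align(fam, return_state=True)
        assert root.n_structures == 4
        assert (root.counts >= 1).all() and (root.counts <= 4).all()

    def test_duplicate_ids_rejected(self, mixed_structure):
        from stralign.multiple import MultipleAlignmentError

        with pytest.raises(MultipleAlignmentError):
            multiple_align([mixed_structure, mixed_structure])
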