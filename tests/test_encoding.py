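"""Ladderization, unit-depth scaling, CBLV+affinity matrices, standardization."""

import numpy as np
import pytest

from gcresponse import (
    AnnotatedTree,
    CENTRAL_MIMIC_PARAMS,
    InputScaler,
    LadderizationTieError,
    TreeNode,
    encode,
    ladderize_with_tiebreakers,
    run_simulation,
    scale_to_unit_depth,
    standardize_inputs,
    true_tree_fallback,
)
from gcresponse.pipeline import encode_annotated


def cherry(t_a=1.0, t_b=2.0, aff_a=0.5, aff_b=-0.3) -> AnnotatedTree:
    root = TreeNode(affinity=0.0, name="root")
    a = TreeNode(edge_length=t_a, affinity=aff_a, name="A")
    b = TreeNode(edge_length=t_b, affinity=aff_b, name="B")
    root.children = [a, b]
    return AnnotatedTree(root=root)


class TestLadderize:
    def test_deeper_leaf_goes_left(self):
        tree = cherry()
        ladderize_with_tiebreakers(tree)
        assert [c.name for c in tree.root.children] == ["B", "A"]
        # input child order must not matter
        tree2 = cherry()
        tree2.root.children = tree2.root.children[::-1]
        ladderize_with_tiebreakers(tree2)
        assert [c.name for c in tree2.root.children] == ["B", "A"]

    def test_equal_tip_depths_ordered_by_parent_depth(self):
        # two cherries, all four tips at depth 3, cherry parents at 1 and 2
        root = TreeNode(name="root")
        p1 = TreeNode(edge_length=1.0, name="p1")
        p2 = TreeNode(edge_length=2.0, name="p2")
        p1.children = [TreeNode(edge_length=2.0, affinity=0.1, name="a"),
                       TreeNode(edge_length=1.9, affinity=0.2, name="b")]
        p2.children = [TreeNode(edge_length=1.0, affinity=0.3, name="c"),
                       TreeNode(edge_length=0.9, affinity=0.4, name="d")]
        root.children = [p1, p2]
        tree = AnnotatedTree(root=root)
        ladderize_with_tiebreakers(tree)
        # deepest tips tie at depth 3; the later parent (depth 2) sorts first
        assert [c.name for c in tree.root.children] == ["p2", "p1"]

    def test_identical_leaves_tie_raises_in_strict_mode(self):
        tree = cherry(t_a=1.0, t_b=1.0, aff_a=0.5, aff_b=0.5)
        with pytest.raises(LadderizationTieError):
            ladderize_with_tiebreakers(tree, strict=True)

    def test_ambiguous_tie_raises_by_default(self):
        # two sibling cherries whose leaves carry identical (depth, parent
        # depth, affinity) keys but whose internal nodes differ in encoded
        # affinity: the order matters for the matrix, so this must raise
        root = TreeNode(name="root")
        for internal_aff, name in ((0.9, "p1"), (0.1, "p2")):
            p = TreeNode(edge_length=1.0, affinity=internal_aff, name=name)
            p.children = [TreeNode(edge_length=1.0, affinity=0.2, name=name + "x"),
                          TreeNode(edge_length=0.5, affinity=0.2, name=name + "y")]
            root.children.append(p)
        tree = AnnotatedTree(root=root)
        with pytest.raises(LadderizationTieError):
            ladderize_with_tiebreakers(tree)

    def test_exchangeable_tie_is_tolerated(self):
        # identical sister leaves: either order encodes identically
        tree = cherry(t_a=1.0, t_b=1.0, aff_a=0.5, aff_b=0.5)
        ladderize_with_tiebreakers(tree)
        m = encode(scale_to_unit_depth(tree), width=8)
        np.testing.assert_allclose(m.matrix[0, :2], [1.0, 1.0])


class TestScaleToUnitDepth:
    def test_ultrametric_divides_by_depth(self):
        tree = cherry(t_a=4.0, t_b=4.0, aff_a=0.1, aff_b=0.2)
        scale_to_unit_depth(tree)
        depths = tree.depths()
        assert all(depths[l] == pytest.approx(1.0) for l in tree.leaves())

    def test_mean_depth_one_for_nonultrametric(self):
        tree = cherry(t_a=1.0, t_b=3.0)
        scale_to_unit_depth(tree)
        depths = tree.depths()
        leaf_depths = sorted(depths[l] for l in tree.leaves())
        assert leaf_depths == pytest.approx([0.5, 1.5])

    def test_idempotent(self):
        tree = cherry(t_a=1.0, t_b=3.0)
        scale_to_unit_depth(tree)
        before = [n.edge_length for n in tree.nodes()]
        scale_to_unit_depth(tree)
        after = [n.edge_length for n in tree.nodes()]
        assert before == pytest.approx(after)

    def test_zero_depth_rejected(self):
        tree = cherry(t_a=0.0, t_b=0.0)
        with pytest.raises(ValueError):
            scale_to_unit_depth(tree)


class TestEncode:
    def test_hand_traced_cherry(self):
        # unscaled cherry: B (t=2, affinity -0.3) ladderized left of
        # A (t=1, affinity 0.5); root at distance 0
        tree = cherry()
        ladderize_with_tiebreakers(tree)
        enc = encode(tree, width=6)
        np.testing.assert_allclose(enc.matrix[0], [2, 1, 0, 0, 0, 0])
        np.testing.assert_allclose(enc.matrix[1], [0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(enc.matrix[2], [-0.3, 0.5, 0, 0, 0, 0])
        np.testing.assert_allclose(enc.matrix[3], [0, 0, 0, 0, 0, 0])
        assert enc.n_leaves == 2
        assert enc.n_internal == 1

    def test_single_leaf_after_scaling(self):
        root = TreeNode(name="root")
        root.children = [TreeNode(edge_length=7.3, affinity=0.2, name="A")]
        tree = AnnotatedTree(root=root)
        scale_to_unit_depth(tree)
        enc = encode(tree, width=4)
        np.testing.assert_allclose(enc.matrix[0], [1, 0, 0, 0])

    def test_fill_counters_and_padding(self, small_tree, amap, shm):
        atree = true_tree_fallback(small_tree, amap, shm)
        enc = encode_annotated(atree)
        assert enc.n_leaves == len(atree.leaves())
        assert enc.n_internal == len(atree.internals())
        assert np.all(enc.matrix[0, enc.n_leaves :] == 0)
        assert np.all(enc.matrix[1, enc.n_internal :] == 0)

    def test_width_overflow_rejected(self, small_tree, amap, shm):
        atree = true_tree_fallback(small_tree, amap, shm)
        with pytest.raises(ValueError, match="width"):
            encode_annotated(atree, width=4)

    def test_invariant_to_input_child_order(self, small_tree, amap, shm):
        atree = true_tree_fallback(small_tree, amap, shm)
        enc1 = encode_annotated(atree)
        # rebuild and shuffle children everywhere
        atree2 = true_tree_fallback(small_tree, amap, shm)
        rng = np.random.default_rng(0)
        for node in atree2.nodes():
            if len(node.children) > 1:
                node.children = [node.children[i] for i in rng.permutation(len(node.children))]
        enc2 = encode_annotated(atree2)
        np.testing.assert_allclose(enc1.matrix, enc2.matrix, atol=1e-12)

    def test_affinity_negation_touches_only_affinity_rows(self, small_tree, amap, shm):
        atree = true_tree_fallback(small_tree, amap, shm)
        enc1 = encode_annotated(atree)
        atree2 = true_tree_fallback(small_tree, amap, shm)
        for node in atree2.nodes():
            node.affinity = -node.affinity
        enc2 = encode_annotated(atree2)
        np.testing.assert_allclose(enc1.matrix[:2], enc2.matrix[:2], atol=1e-12)
        assert not np.allclose(enc1.matrix[2:], enc2.matrix[2:])


class TestStandardize:
    def _toy_encoded(self, n=5, seed=0):
        from gcresponse.encoding import EncodedTree

        rng = np.random.default_rng(seed)
        encs = []
        for _ in range(n):
            m = np.zeros((4, 10))
            nl, ni = 6, 5
            m[0, :nl] = rng.uniform(0.1, 2, nl)
            m[1, :ni] = rng.uniform(0.1, 2, ni)
            m[2, :nl] = rng.normal(0, 1, nl)
            m[3, :ni] = rng.normal(0, 1, ni)
            encs.append(EncodedTree(matrix=m, n_leaves=nl, n_internal=ni))
        ns = rng.uniform(0, 1, (n, 3))
        return encs, ns

    def test_groups_standardized_and_padding_zero(self):
        encs, ns = self._toy_encoded()
        X, Z, scaler = standardize_inputs(encs, ns)
        branch = np.concatenate([X[i, 0, :6] for i in range(5)] + [X[i, 1, :5] for i in range(5)])
        aff = np.concatenate([X[i, 2, :6] for i in range(5)] + [X[i, 3, :5] for i in range(5)])
        assert abs(branch.mean()) < 1e-8 and abs(branch.var() - 1) < 1e-6
        assert abs(aff.mean()) < 1e-8 and abs(aff.var() - 1) < 1e-6
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-8)
        assert np.all(X[:, 0, 6:] == 0) and np.all(X[:, 1, 5:] == 0)

    def test_persisted_scaler_reproduces_transform(self, tmp_path):
        encs, ns = self._toy_encoded()
        X, Z, scaler = standardize_inputs(encs, ns)
        path = tmp_path / "scaler.yaml"
        scaler.to_yaml(path)
        scaler2 = InputScaler.from_yaml(path)
        X2, Z2 = scaler2.transform(encs, ns)
        np.testing.assert_allclose(X2, X, atol=1e-9)
        np.testing.assert_allclose(Z2, Z, atol=1e-9)

    def test_heldout_tree_not_centered(self):
        encs, ns = self._toy_encoded(n=6)
        X, Z, scaler = standardize_inputs(encs[:5], ns[:5])
        held = scaler.transform_encoded(encs[5])
        assert abs(held[0, :6].mean()) > 1e-6  # no leakage: generally off-center

    def test_zero_variance_rejected(self):
        encs, ns = self._toy_encoded()
        ns[:, 1] = 0.7
        with pytest.raises(ValueError, match="non-sigmoid"):
            standardize_inputs(encs, ns)


class TestEncodingInjectivity:
    def test_distinct_trees_distinct_encodings(self, amap, shm):
        """Simulated trees with distinct seeds give pairwise-distinct matrices."""
        from gcresponse import SimConfig

        cfg = SimConfig(
            carrying_capacity=60,
            time_to_sampling=5.0,
            n_sample=(15, 25),
            initial_population=8,
            death_rate_functional=0.2,
            mutability_multiplier=0.68,
        )
        mats = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tree = run_simulation(cfg, CENTRAL_MIMIC_PARAMS, amap, shm, rng)
            atree = true_tree_fallback(tree, amap, shm)
            mats.append(encode_annotated(atree).matrix.tobytes())
        assert len(set(mats)) == 100
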