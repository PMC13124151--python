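"""Affinity-augmented CBLV tree encoding.

A ladderized tree is traversed inorder and flattened into a fixed-width
4-row matrix: row 0 holds each leaf's distance to the most-recently-visited
internal node, row 1 each internal node's distance to the root, and rows
2-3 the corresponding nodes' affinities (leaf affinities aligned with row
0's columns, internal affinities with row 1's).  Trees are scaled to mean
unit leaf depth first, and matrices are zero-padded to a fixed width so
trees of different sizes share one input shape.

Ladderization orders the children of every node by the key of their deepest
leaf - (leaf depth, depth of the leaf's parent, leaf affinity), all
descending, so deeper subtrees go left.  Any remaining exact tie raises:
a tie would destroy the one-to-one correspondence between trees and
encodings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .trees import AnnotatedTree, TreeNode

__all__ = [
    "EncodedTree",
    "LadderizationTieError",
    "ladderize_with_tiebreakers",
    "scale_to_unit_depth",
    "encode",
    "InputScaler",
    "standardize_inputs",
    "save_encoded_set",
    "load_encoded_set",
]

DEFAULT_WIDTH = 200


class LadderizationTieError(ValueError):
    """Two sibling subtrees have identical ladderization keys."""


@dataclass
class EncodedTree:
    """4 x W encoding matrix with column-fill counters."""

    matrix: np.ndarray  # (4, W)
    n_leaves: int
    n_internal: int

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def ladderize_with_tiebreakers(tree: AnnotatedTree, strict: bool = False) -> AnnotatedTree:
    """Sort children in place so deeper subtrees come first; raise on ties.

    The key of a subtree is the lexicographic maximum over its leaves of
    ``(leaf depth, parent depth, leaf affinity)``; children are sorted by
    that key in descending order.

    Sibling subtrees with exactly equal keys would make the node order, and
    hence the encoding, ambiguous - unless the tied subtrees are identical
    in every encoded quantity (shape, depths, affinities), in which case
    either order produces the same matrix.  Such exchangeable ties arise
    routinely in simulated genealogies (two sampled sister cells with no
    later mutation) and keep a deterministic stable order; any *ambiguous*
    exact tie raises :class:`LadderizationTieError`.  With ``strict=True``
    every exact key tie raises, exchangeable or not.
    """
    depths = tree.depths()
    key: dict[int, tuple] = {}
    sig: dict[int, tuple] = {}

    # Post-order key/signature computation (iterative).  A subtree's key is
    # the descending-sorted tuple of its leaves' (depth, parent depth,
    # affinity) triples; comparison starts at the deepest leaf's triple
    # (the stated tiebreakers) and extends through the remaining leaves.
    stack: list[tuple[TreeNode, TreeNode | None, bool]] = [(tree.root, None, False)]
    while stack:
        node, parent, expanded = stack.pop()
        if not expanded:
            stack.append((node, parent, True))
            for c in node.children:
                stack.append((c, node, False))
        else:
            d = depths[node]
            if node.is_leaf():
                pdepth = depths[parent] if parent is not None else 0.0
                key[id(node)] = ((d, pdepth, node.affinity),)
                sig[id(node)] = (d, node.affinity)
            else:
                merged = [t for c in node.children for t in key[id(c)]]
                merged.sort(reverse=True)
                key[id(node)] = tuple(merged)
                sig[id(node)] = (d, node.affinity, tuple(sorted(sig[id(c)] for c in node.children)))

    for node in tree.nodes():
        if len(node.children) > 1:
            kids = sorted(node.children, key=lambda c: key[id(c)], reverse=True)
            for a, b in zip(kids, kids[1:]):
                tied = key[id(a)] == key[id(b)] or key[id(a)][0] == key[id(b)][0] and strict
                if tied and (strict or sig[id(a)] != sig[id(b)]):
                    raise LadderizationTieError(
                        f"unresolvable ladderization tie between {a.name!r} and "
                        f"{b.name!r}: key {key[id(a)][0]}"
                    )
            node.children = kids
    return tree


def scale_to_unit_depth(tree: AnnotatedTree) -> AnnotatedTree:
    """Divide all branch lengths by the mean root-to-leaf distance (in place)."""
    depths = tree.depths()
    leaf_depths = [depths[n] for n in tree.leaves()]
    mean_depth = float(np.mean(leaf_depths))
    if mean_depth <= 0:
        raise ValueError("cannot scale a tree with zero mean leaf depth")
    for node in tree.nodes():
        node.edge_length /= mean_depth
    return tree


def encode(tree: AnnotatedTree, width: int = DEFAULT_WIDTH) -> EncodedTree:
    """Encode a ladderized, scaled tree as a 4 x width matrix.

    Inorder traversal: the left subtree, then the internal node itself,
    then the remaining subtree.  Leaves append (distance to the most
    recently visited internal node, affinity) to rows 0/2; internal nodes
    append (distance to root, affinity) to rows 1/3.  The two row pairs
    advance independent column counters and the matrix is zero padded.
    """
    depths = tree.depths()
    mat = np.zeros((4, width))
    n_leaf = 0
    n_int = 0
    last_internal_depth = 0.0

    # Iterative inorder: visit first child subtree, then the node, then the rest.
    stack: list[tuple[TreeNode, int]] = [(tree.root, 0)]
    while stack:
        node, state = stack.pop()
        if node.is_leaf():
            if n_leaf >= width:
                raise ValueError(
                    f"tree has more than {width} leaves; increase the encoding width"
                )
            mat[0, n_leaf] = depths[node] - last_internal_depth
            mat[2, n_leaf] = node.affinity
            n_leaf += 1
        elif state == 0:
            stack.append((node, 1))
            stack.append((node.children[0], 0))
        else:
            if n_int >= width:
                raise ValueError(
                    f"tree has more than {width} internal nodes; increase the "
                    "encoding width"
                )
            mat[1, n_int] = depths[node]
            mat[3, n_int] = node.affinity
            n_int += 1
            last_internal_depth = depths[node]
            for c in reversed(node.children[1:]):
                stack.append((c, 0))

    return EncodedTree(matrix=mat, n_leaves=n_leaf, n_internal=n_int)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class InputScaler:
    """Affine standardization record for encoded trees and non-sigmoid inputs.

    Statistics are computed over real (non-padding) entries only; padding
    zeros are re-inserted after the transform so padded columns stay
    exactly 0.  Groups: all branch-length entries (rows 0-1), all affinity
    entries (rows 2-3), and each non-sigmoid parameter individually.
    """

    branch_mean: float
    branch_std: float
    affinity_mean: float
    affinity_std: float
    nonsigmoid_mean: np.ndarray
    nonsigmoid_std: np.ndarray

    def transform_encoded(self, enc: EncodedTree) -> np.ndarray:
        mat = enc.matrix.copy()
        nl, ni = enc.n_leaves, enc.n_internal
        mat[0, :nl] = (mat[0, :nl] - self.branch_mean) / self.branch_std
        mat[1, :ni] = (mat[1, :ni] - self.branch_mean) / self.branch_std
        mat[2, :nl] = (mat[2, :nl] - self.affinity_mean) / self.affinity_std
        mat[3, :ni] = (mat[3, :ni] - self.affinity_mean) / self.affinity_std
        return mat

    def transform_nonsigmoid(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.nonsigmoid_mean) / self.nonsigmoid_std

    def transform(
        self, encoded: list[EncodedTree], nonsigmoid: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([self.transform_encoded(e) for e in encoded])
        Z = self.transform_nonsigmoid(np.atleast_2d(nonsigmoid))
        return X, Z

    # -- persistence --------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "branch_mean": float(self.branch_mean),
                    "branch_std": float(self.branch_std),
                    "affinity_mean": float(self.affinity_mean),
                    "affinity_std": float(self.affinity_std),
                    "nonsigmoid_mean": [float(v) for v in self.nonsigmoid_mean],
                    "nonsigmoid_std": [float(v) for v in self.nonsigmoid_std],
                }
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InputScaler":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            branch_mean=d["branch_mean"],
            branch_std=d["branch_std"],
            affinity_mean=d["affinity_mean"],
            affinity_std=d["affinity_std"],
            nonsigmoid_mean=np.asarray(d["nonsigmoid_mean"], dtype=float),
            nonsigmoid_std=np.asarray(d["nonsigmoid_std"], dtype=float),
        )


def save_encoded_set(
    encoded: list[EncodedTree],
    path_prefix: str | Path,
    index: "pd.DataFrame | None" = None,
) -> None:
    """Store encoded matrices as an .npz archive with a CSV index.

    The index (one row per tree: ids, truth parameters when simulated) is
    written alongside as ``<prefix>_index.csv``; a minimal one is generated
    if none is given.
    """
    import pandas as pd

    path_prefix = Path(path_prefix)
    np.savez(
        path_prefix.with_suffix(".npz"),
        matrices=np.stack([e.matrix for e in encoded]),
        n_leaves=np.array([e.n_leaves for e in encoded]),
        n_internal=np.array([e.n_internal for e in encoded]),
    )
    if index is None:
        index = pd.DataFrame({"tree": np.arange(len(encoded))})
    index.to_csv(path_prefix.parent / (path_prefix.name + "_index.csv"), index=False)


def load_encoded_set(path_prefix: str | Path):
    """Inverse of :func:`save_encoded_set`: (encoded list, index frame)."""
    import pandas as pd

    path_prefix = Path(path_prefix)
    with np.load(path_prefix.with_suffix(".npz")) as data:
        encoded = [
            EncodedTree(matrix=m, n_leaves=int(nl), n_internal=int(ni))
            for m, nl, ni in zip(data["matrices"], data["n_leaves"], data["n_internal"])
        ]
    index = pd.read_csv(path_prefix.parent / (path_prefix.name + "_index.csv"))
    return encoded, index


def standardize_inputs(
    encoded: list[EncodedTree], nonsigmoid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, InputScaler]:
    """Fit per-group mean-0/variance-1 scalers on a training set and apply them.

    ``nonsigmoid`` is (n_trees, k).  Returns the standardized matrix stack,
    standardized non-sigmoid values, and the fitted scaler for reuse at
    prediction time.
    """
    if len(encoded) < 2:
        raise ValueError("need at least two trees to standardize")
    branch_vals = np.concatenate(
        [e.matrix[0, : e.n_leaves] for e in encoded]
        + [e.matrix[1, : e.n_internal] for e in encoded]
    )
    aff_vals = np.concatenate(
        [e.matrix[2, : e.n_leaves] for e in encoded]
        + [e.matrix[3, : e.n_internal] for e in encoded]
    )
    nonsigmoid = np.atleast_2d(np.asarray(nonsigmoid, dtype=float))
    ns_mean = nonsigmoid.mean(axis=0)
    ns_std = nonsigmoid.std(axis=0)
    groups = {
        "branch lengths": float(branch_vals.std()),
        "affinities": float(aff_vals.std()),
        **{f"non-sigmoid[{i}]": float(s) for i, s in enumerate(ns_std)},
    }
    for name, s in groups.items():
        if s == 0:
            raise ValueError(f"zero variance in input group {name!r}")
    scaler = InputScaler(
        branch_mean=float(branch_vals.mean()),
        branch_std=float(branch_vals.std()),
        affinity_mean=float(aff_vals.mean()),
        affinity_std=float(aff_vals.std()),
        nonsigmoid_mean=ns_mean,
        nonsigmoid_std=ns_std,
    )
    X, Z = scaler.transform(encoded, nonsigmoid)
    return X, Z, scaler
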