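"""Bridge between sequences/simulations and the annotated trees used for encoding.

Trees consumed by the encoder are rooted, (mostly) bifurcating, and carry a
branch length plus an affinity for every node.  Two routes produce them:

* :func:`infer_tree_external` wraps an external maximum-likelihood program
  (IQ-TREE) run on a per-GC FASTA with the naive sequence as outgroup,
  including ancestral sequence reconstruction; it requires the binary on
  PATH and is optional.
* :func:`true_tree_fallback` converts a simulated genealogy directly: it
  prunes to sampled tips plus their ancestry, collapses unobservable
  unifurcations (mutation nodes, pruned-away divisions), converts branch
  lengths from days to expected substitutions per site under the SHM model,
  and annotates every node's affinity from its true sequence.

The simulator's instantaneous initial expansion leaves a caterpillar of
zero-length divisions at the root with no observable counterpart in data;
those edges are collapsed into a single multifurcation which is then
re-binarized deterministically (zero-length internal edges, children ordered
by subtree depth), so downstream ladderization never sees degenerate ties
among founder nodes.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .affinity import AffinityMap, affinity_of, ints_to_seq
from .shm import MutabilityModel, site_mutabilities
from .simulate import GCTree

__all__ = [
    "TreeNode",
    "AnnotatedTree",
    "ExternalToolUnavailable",
    "write_gc_fasta",
    "infer_tree_external",
    "true_tree_fallback",
    "annotate_affinities",
]

NAIVE_NAME = "naive"


class TreeNode:
    """Minimal rooted-tree node with branch length, affinity, and sequence."""

    __slots__ = ("children", "edge_length", "affinity", "sequence", "name", "sampled")

    def __init__(
        self,
        edge_length: float = 0.0,
        affinity: float = 0.0,
        sequence: str | None = None,
        name: str | None = None,
        sampled: bool = False,
    ) -> None:
        self.children: list[TreeNode] = []
        self.edge_length = edge_length
        self.affinity = affinity
        self.sequence = sequence
        self.name = name
        self.sampled = sampled

    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


@dataclass
class AnnotatedTree:
    """Rooted tree with per-node branch lengths and affinities.

    ``root`` carries the naive sequence at depth 0.  Branch lengths are in
    whatever unit the producing route emits (substitutions/site for both
    routes); the encoder's unit-depth scaling absorbs the unit.
    """

    root: TreeNode
    naive_seq: str | None = None
    outgroup: str = NAIVE_NAME

    def nodes(self) -> list[TreeNode]:
        return list(self.root.preorder())

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf()]

    def internals(self) -> list[TreeNode]:
        return [n for n in self.nodes() if not n.is_leaf()]

    def depths(self) -> dict[TreeNode, float]:
        out = {self.root: 0.0}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                out[c] = out[node] + c.edge_length
                stack.append(c)
        return out

    # -- newick I/O ---------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.name or ""
            nhx = f"[&&NHX:affinity={node.affinity:.10g}]"
            if node.is_leaf():
                return f"{label}:{node.edge_length:.12g}{nhx}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){label}:{node.edge_length:.12g}{nhx}"

        return fmt(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str | Path) -> "AnnotatedTree":
        text = Path(source).read_text() if isinstance(source, Path) else source
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=False,
            extract_comment_metadata=True,
        )

        def convert(dnode) -> TreeNode:
            aff = 0.0
            for ann in dnode.annotations:
                if ann.name == "affinity":
                    aff = float(ann.value)
            node = TreeNode(
                edge_length=float(dnode.edge.length or 0.0),
                affinity=aff,
                name=dnode.taxon.label if dnode.taxon else None,
            )
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(root=convert(dt.seed_node))

    def node_table(self) -> pd.DataFrame:
        """CSV-friendly table: node id, depth, affinity, leaf flag."""
        depths = self.depths()
        rows = []
        for i, node in enumerate(self.nodes()):
            rows.append(
                (i, node.name, depths[node], node.affinity, node.is_leaf(), node.sampled)
            )
        return pd.DataFrame(
            rows, columns=["node", "name", "depth", "affinity", "is_leaf", "sampled"]
        )


class ExternalToolUnavailable(RuntimeError):
    """The external tree-inference binary is not on PATH."""


def write_gc_fasta(
    sequences: list[str], naive_seq: str, path: str | Path, names: list[str] | None = None
) -> None:
    """Write sampled sequences plus the naive outgroup record to FASTA.

    Duplicate sequences are written as distinct records: downstream
    abundance statistics depend on multiplicity.
    """
    if not sequences:
        raise ValueError("empty sample")
    if names is None:
        names = [f"seq{i}" for i in range(len(sequences))]
    records = [SeqRecord(Seq(naive_seq), id=NAIVE_NAME, description="")]
    records += [
        SeqRecord(Seq(s), id=n, description="") for s, n in zip(sequences, names)
    ]
    SeqIO.write(records, str(path), "fasta")


def annotate_affinities(tree: AnnotatedTree, amap: AffinityMap) -> AnnotatedTree:
    """(Re-)derive every node's affinity from its sequence; idempotent."""
    for node in tree.nodes():
        if node.sequence is not None:
            node.affinity = affinity_of(amap, node.sequence)
    return tree


def infer_tree_external(
    fasta_path: str | Path,
    amap: AffinityMap,
    binary: str = "iqtree",
    seed: int = 1,
    extra_args: tuple[str, ...] = (),
) -> AnnotatedTree:
    """Run IQ-TREE with ancestral reconstruction and return the annotated tree.

    Requires the ``iqtree`` binary on PATH; otherwise raises
    :class:`ExternalToolUnavailable` directing callers to
    :func:`true_tree_fallback`.  The tree is rooted on the naive outgroup
    and every node (observed or reconstructed) gets an affinity via the
    additive map.
    """
    if shutil.which(binary) is None:
        raise ExternalToolUnavailable(
            f"external tool {binary!r} not found on PATH; use true_tree_fallback "
            "for simulation-derived trees"
        )
    fasta_path = Path(fasta_path)
    cmd = [
        binary, "-s", str(fasta_path), "-m", "GTR", "-asr",
        "-o", NAIVE_NAME, "-seed", str(seed), "-redo", *extra_args,
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"{binary} failed:\n{proc.stderr[-2000:]}")

    treefile = fasta_path.with_suffix(fasta_path.suffix + ".treefile")
    statefile = fasta_path.with_suffix(fasta_path.suffix + ".state")
    try:
        tree = AnnotatedTree.from_newick(Path(treefile))
    except Exception as e:
        raise RuntimeError(f"could not parse {treefile}: {e}") from e

    observed = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    ancestral: dict[str, dict[int, str]] = {}
    if statefile.exists():
        st = pd.read_csv(statefile, sep="\t", comment="#")
        for name, grp in st.groupby("Node"):
            ancestral[str(name)] = dict(zip(grp["Site"] - 1, grp["State"]))

    for node in tree.nodes():
        if node.name in observed:
            node.sequence = observed[node.name]
        elif node.name in ancestral:
            states = ancestral[node.name]
            node.sequence = "".join(states[i] for i in range(len(states)))
    # Root on the naive outgroup: re-root so the naive record sits adjacent
    # to the root and carries the naive sequence.
    tree.naive_seq = observed.get(NAIVE_NAME)
    if tree.root.sequence is None and tree.naive_seq is not None:
        tree.root.sequence = tree.naive_seq
    return annotate_affinities(tree, amap)


# ---------------------------------------------------------------------------
# Simulation-truth fallback
# ---------------------------------------------------------------------------


def _subtree_depth(node: TreeNode) -> float:
    best = 0.0
    stack = [(node, 0.0)]
    while stack:
        v, d = stack.pop()
        if v.is_leaf():
            best = max(best, d)
        for c in v.children:
            stack.append((c, d + c.edge_length))
    return best


def true_tree_fallback(
    gc_tree: GCTree, amap: AffinityMap, shm: MutabilityModel
) -> AnnotatedTree:
    """Convert a simulated genealogy to an encoder-ready annotated tree.

    Keeps sampled tips and their ancestry; collapses unifurcations
    (mutation nodes, pruned divisions) by summing branch lengths; converts
    branch lengths from days to expected substitutions/site using the SHM
    model rate of the lineage's sequence; collapses the zero-length initial
    expansion and re-binarizes it deterministically.
    """
    sampled = gc_tree.sampled_ids
    if len(sampled) == 0:
        raise ValueError("simulation has no sampled tips")
    keep = np.zeros(gc_tree.n_nodes, dtype=bool)
    for node in sampled:
        v = int(node)
        while v >= 0 and not keep[v]:
            keep[v] = True
            v = int(gc_tree.parent[v])

    L = len(gc_tree.seqs[0])
    mult = gc_tree.config.mutability_multiplier
    rate_cache: dict[int, float] = {}

    def per_site_rate(node: int) -> float:
        si = int(gc_tree.seq_index[node])
        if si not in rate_cache:
            rate_cache[si] = mult * float(
                site_mutabilities(shm, gc_tree.seqs[si]).sum()
            ) / L
        return rate_cache[si]

    kids: dict[int, list[int]] = {}
    for node in np.flatnonzero(keep):
        par = int(gc_tree.parent[node])
        if par >= 0:
            kids.setdefault(par, []).append(int(node))

    def build(node: int, edge_days_rate: float) -> TreeNode:
        # walk through unifurcations, accumulating substitutions/site
        length = 0.0
        v = node
        while True:
            dt = gc_tree.t_end[v] - gc_tree.t_birth[v]
            length += dt * per_site_rate(v)
            ch = kids.get(v, [])
            if len(ch) == 1 and not gc_tree.sampled[v]:
                v = ch[0]
                continue
            break
        tn = TreeNode(
            edge_length=length,
            affinity=float(gc_tree.affinity[v]),
            sequence=ints_to_seq(gc_tree.node_seq(v)),
            name=f"leaf{v}" if gc_tree.sampled[v] else f"node{v}",
            sampled=bool(gc_tree.sampled[v]),
        )
        tn.children = [build(c, 0.0) for c in kids.get(v, [])]
        return tn

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * gc_tree.n_nodes + 1000))
    try:
        root = build(0, 0.0)
    finally:
        sys.setrecursionlimit(old_limit)
    root.edge_length = 0.0
    root.name = NAIVE_NAME
    root.sequence = ints_to_seq(gc_tree.seqs[0])
    root.affinity = 0.0

    _collapse_zero_internal_edges(root)
    _binarize(root)
    return AnnotatedTree(root=root, naive_seq=root.sequence)


def _collapse_zero_internal_edges(root: TreeNode) -> None:
    """Merge children connected by zero-length edges into their parent."""
    stack = [root]
    while stack:
        node = stack.pop()
        merged = []
        queue = list(node.children)
        while queue:
            c = queue.pop(0)
            if c.edge_length == 0.0 and not c.is_leaf() and not c.sampled:
                queue = list(c.children) + queue
            else:
                merged.append(c)
        node.children = merged
        stack.extend(merged)


def _binarize(root: TreeNode) -> None:
    """Resolve multifurcations into zero-length caterpillars.

    Children are ordered by decreasing subtree depth (ties by affinity then
    name) before chaining, so the construction is deterministic and the
    inserted zero-length internal nodes never tie with real nodes during
    ladderization (their depths equal the parent's, while real children sit
    strictly deeper).
    """
    stack = [root]
    while stack:
        node = stack.pop()
        if len(node.children) > 2:
            ordered = sorted(
                node.children,
                key=lambda c: (-(c.edge_length + _subtree_depth(c)), c.affinity, c.name or ""),
            )
            current = node
            current.children = [ordered[0]]
            for c in ordered[1:-1]:
                w = TreeNode(
                    edge_length=0.0,
                    affinity=current.affinity,
                    sequence=current.sequence,
                    name=None,
                )
                current.children.append(w)
                w.children = [c]
                current = w
            current.children.append(ordered[-1])
        stack.extend(node.children)
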