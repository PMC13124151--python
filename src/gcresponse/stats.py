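"""Summary statistics of GC samples and a distance for data/simulation matching.

A sample is a collection of per-GC annotated trees (sampled sequences at
the tips, naive root).  The statistic suite covers the axes on which real
and simulated samples are compared: per-GC leaf counts, per-sequence
nucleotide mutation counts (SHM), per-cell affinities, the sequence
abundance distribution (multiplicities of identical sampled sequences),
pooled branch lengths, and mean tree depths.

The matching distance is the mean over components of the 1-D earth-mover
(Wasserstein-1) distance between the empirical distributions, with each
component pre-scaled by its pooled standard deviation so components of very
different natural scale contribute commensurably.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .trees import AnnotatedTree

__all__ = ["SummaryStatSet", "compute_summary_stats", "stat_distance"]

DEFAULT_COMPONENTS = (
    "leaf_counts",
    "shm",
    "affinities",
    "abundance",
    "branch_lengths",
    "tree_depths",
    "root_lineages",
)


@dataclass
class SummaryStatSet:
    """Empirical distributions summarizing a multi-GC sample."""

    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.components[key]

    def to_csv_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, values in self.components.items():
            pd.Series(values, name=name).to_csv(directory / f"{name}.csv", index=False)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _root_lineages(tree: AnnotatedTree, tol: float = 1e-12) -> int:
    """Number of lineages branching off the root at (numerically) zero depth.

    Surviving founder lineages appear as a burst of coalescences at the
    root; their count tracks the initial population size.  Counted as the
    leaves of the maximal root-attached subtree of zero-length internal
    edges.
    """
    count = 0
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for c in node.children:
            if c.edge_length <= tol and not c.is_leaf():
                stack.append(c)
            else:
                count += 1
    return count


def compute_summary_stats(
    trees: list[AnnotatedTree], naive_seq: str | None = None
) -> SummaryStatSet:
    """Compute the full statistic suite over a sample of annotated trees.

    SHM counts are nucleotide differences from the naive sequence (taken
    from each tree's own naive record unless given).  Abundance is the
    multiset of per-GC multiplicities of identical sampled sequences; every
    unique sequence contributes one entry.
    """
    if not trees:
        raise ValueError("empty sample")
    leaf_counts, shm, affinities, abundance, branch_lengths, depth_means = (
        [], [], [], [], [], [],
    )
    root_lineages = []
    for tree in trees:
        root_lineages.append(_root_lineages(tree))
        leaves = tree.leaves()
        leaf_counts.append(len(leaves))
        naive = naive_seq or tree.naive_seq
        seqs = []
        for leaf in leaves:
            affinities.append(leaf.affinity)
            if leaf.sequence is not None and naive is not None:
                shm.append(_hamming(leaf.sequence, naive))
                seqs.append(leaf.sequence)
        abundance.extend(Counter(seqs).values())
        depths = tree.depths()
        depth_means.append(float(np.mean([depths[l] for l in leaves])))
        branch_lengths.extend(
            n.edge_length for n in tree.nodes() if n is not tree.root
        )
    return SummaryStatSet(
        components={
            "leaf_counts": np.asarray(leaf_counts, dtype=float),
            "shm": np.asarray(shm, dtype=float),
            "affinities": np.asarray(affinities, dtype=float),
            "abundance": np.asarray(abundance, dtype=float),
            "branch_lengths": np.asarray(branch_lengths, dtype=float),
            "tree_depths": np.asarray(depth_means, dtype=float),
            "root_lineages": np.asarray(root_lineages, dtype=float),
        }
    )


def stat_distance(
    a: SummaryStatSet,
    b: SummaryStatSet,
    components: tuple[str, ...] = DEFAULT_COMPONENTS,
) -> float:
    """Scaled mean earth-mover distance between two statistic sets.

    Each component is divided by the pooled standard deviation of the two
    samples before the Wasserstein-1 distance; components with zero pooled
    spread (all values identical) contribute 0.  Zero iff every component
    distribution matches.
    """
    total = 0.0
    for name in components:
        x, y = a[name], b[name]
        if len(x) == 0 or len(y) == 0:
            continue
        scale = float(np.concatenate([x, y]).std())
        if scale == 0:
            continue
        total += wasserstein_distance(x / scale, y / scale)
    return total / len(components)
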