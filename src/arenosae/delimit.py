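"""Posterior cluster similarity matrices from species-tree samples.

Under the multispecies coalescent, a species-tree node whose height is
(approximately) zero separates individuals that belong to the same
ideal population.  Given a posterior sample of ultrametric species
trees, a *collapse height* epsilon turns each tree into a partition of
the tips: two tips fall in the same cluster iff their MRCA sits below
epsilon.  Averaging the co-clustering indicator over the sample yields
a similarity matrix of pairwise posterior co-clustering frequencies,
the standard summary used to delimit species from such posteriors
(10% burn-in and epsilon = 1e-4 in the analysis this package
re-implements).

Input is a NEXUS TREES block (translate table and bracketed
BEAST-style annotations are handled) or plain Newick, read with
dendropy.  Each sampled tree must be ultrametric within a relative
tolerance; offending trees are rejected, not repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ArenosaeError, NotUltrametricError, TreeFormatError

#: relative ultrametricity tolerance (fraction of root height)
DEFAULT_TOLERANCE = 1e-8


@dataclass
class _Node:
    height: float
    children: list["_Node"] = field(default_factory=list)
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["_Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


class UltrametricTree:
    """A rooted tree with node heights (time above the contemporaneous tips)."""

    def __init__(self, root: _Node, tolerance: float = DEFAULT_TOLERANCE):
        self.root = root
        self.tolerance = tolerance
        leaves = root.leaves()
        labels = [l.label for l in leaves]
        if any(l is None for l in labels):
            raise TreeFormatError("unlabelled tip")
        if len(set(labels)) != len(labels):
            raise TreeFormatError("duplicate tip labels")
        self.tips: tuple[str, ...] = tuple(sorted(labels))
        h = root.height
        tau = tolerance * h if h > 0 else tolerance
        for leaf in leaves:
            if abs(leaf.height) > tau:
                raise NotUltrametricError(leaf.label, abs(leaf.height))
        self._check_heights(root, tau)

    def _check_heights(self, node: _Node, tau: float) -> None:
        for c in node.children:
            if c.height > node.height + tau:
                raise TreeFormatError(
                    f"child height {c.height:g} above parent {node.height:g}"
                )
            self._check_heights(c, tau)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree,
                      tolerance: float = DEFAULT_TOLERANCE) -> "UltrametricTree":
        """Convert a dendropy tree, deriving heights from branch lengths."""
        depths: dict = {}

        def depth_of(nd) -> float:
            if nd.parent_node is None:
                return 0.0
            return depths[nd.parent_node] + (nd.edge.length or 0.0)

        for nd in tree.preorder_node_iter():
            depths[nd] = depth_of(nd)
        height = max(
            (depths[lf] for lf in tree.leaf_node_iter()), default=0.0
        )

        def build(nd) -> _Node:
            node = _Node(height=height - depths[nd])
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeFormatError("leaf without a taxon label")
                node.label = nd.taxon.label
                node.height = height - depths[nd]
            node.children = [build(c) for c in nd.child_nodes()]
            return node

        return cls(build(tree.seed_node), tolerance)

    @classmethod
    def from_newick(cls, text: str,
                    tolerance: float = DEFAULT_TOLERANCE) -> "UltrametricTree":
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(tree, tolerance)

    def to_newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    # -- queries -----------------------------------------------------------

    def mrca_height(self, a: str, b: str) -> float:
        """Height of the most recent common ancestor of two tips."""

        def walk(node: _Node) -> tuple[bool, bool, float | None]:
            if node.is_leaf:
                return (node.label == a, node.label == b, None)
            has_a = has_b = False
            for c in node.children:
                ca, cb, h = walk(c)
                if h is not None:
                    return (True, True, h)
                if ca and cb:
                    return (True, True, c.height)
                has_a |= ca
                has_b |= cb
            if has_a and has_b:
                return (True, True, node.height)
            return (has_a, has_b, None)

        _, _, h = walk(self.root)
        if h is None:
            raise ArenosaeError(f"tips {a!r}, {b!r} not both present")
        return h


@dataclass(frozen=True)
class Partition:
    """Disjoint classes of tip labels covering the whole tip set."""

    classes: frozenset[frozenset[str]]

    def __post_init__(self):
        all_tips: list[str] = []
        for cls_ in self.classes:
            all_tips.extend(cls_)
        if len(all_tips) != len(set(all_tips)):
            raise ArenosaeError("partition classes are not disjoint")

    @property
    def tips(self) -> frozenset[str]:
        return frozenset().union(*self.classes) if self.classes else frozenset()

    def together(self, a: str, b: str) -> bool:
        return any(a in c and b in c for c in self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def sorted_classes(self) -> list[tuple[str, ...]]:
        return sorted(tuple(sorted(c)) for c in self.classes)


class TreeSampleSet:
    """An ordered posterior sample of trees over one tip set."""

    def __init__(self, trees: Sequence[UltrametricTree], source: str = ""):
        trees = list(trees)
        if trees:
            tips = trees[0].tips
            for i, t in enumerate(trees):
                if t.tips != tips:
                    raise TreeFormatError(
                        f"tree {i} has a different tip set: "
                        f"{sorted(set(t.tips) ^ set(tips))}"
                    )
        self.trees = trees
        self.source = source

    @property
    def tips(self) -> tuple[str, ...]:
        return self.trees[0].tips if self.trees else ()

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def read_trees(path: str | Path, format: str = "nexus",
               tolerance: float = DEFAULT_TOLERANCE) -> TreeSampleSet:
    """Read a posterior tree file (NEXUS with translate table, or Newick).

    Bracketed metadata comments (BEAST annotations) are stripped by the
    parser; heights are computed from branch lengths.
    """
    if format not in ("nexus", "newick"):
        raise ArenosaeError(f"unknown tree format {format!r}")
    try:
        trees = dendropy.TreeList.get(path=str(path), schema=format)
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeFormatError(f"cannot parse {path}: {exc}") from exc
    return TreeSampleSet(
        [UltrametricTree.from_dendropy(t, tolerance) for t in trees],
        source=str(path),
    )


def apply_burnin(samples: TreeSampleSet, fraction: float) -> TreeSampleSet:
    """Drop the first ``floor(fraction * N)`` samples."""
    if not (0 <= fraction < 1):
        raise ArenosaeError("burn-in fraction must be in [0, 1)")
    k = math.floor(fraction * len(samples))
    return TreeSampleSet(samples.trees[k:], source=samples.source)


def collapse_partition(tree: UltrametricTree, epsilon: float) -> Partition:
    """Cluster tips whose MRCA height is strictly below ``epsilon``.

    Heights decrease from root to tips in an ultrametric tree, so the
    maximal nodes with height < epsilon induce a valid partition.
    Equality at epsilon does not cluster: epsilon approximates zero
    height and boundary mass is measure-zero in practice.
    """
    classes: list[frozenset[str]] = []

    def walk(node: _Node) -> None:
        if node.height < epsilon:
            classes.append(frozenset(l.label for l in node.leaves()))
            return
        if node.is_leaf:  # height >= epsilon can only happen at the root
            classes.append(frozenset([node.label]))
            return
        for c in node.children:
            walk(c)

    walk(tree.root)
    return Partition(frozenset(classes))


@dataclass
class SimilarityMatrix:
    """Pairwise posterior co-clustering frequencies in [0, 1]."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    n_samples: int
    epsilon: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ArenosaeError("matrix shape does not match labels")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def reorder(self, labels: Sequence[str]) -> "SimilarityMatrix":
        if sorted(labels) != sorted(self.labels):
            raise ArenosaeError("label mismatch in reorder")
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(
            tuple(labels), self.matrix[np.ix_(idx, idx)],
            self.n_samples, self.epsilon,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))

    def threshold_partition(self, cutoff: float = 0.5) -> Partition:
        """Connected components of the graph of pairs above ``cutoff``."""
        n = len(self.labels)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if self.matrix[i, j] > cutoff:
                    parent[find(i)] = find(j)
        groups: dict[int, set[str]] = {}
        for i, lab in enumerate(self.labels):
            groups.setdefault(find(i), set()).add(lab)
        return Partition(frozenset(frozenset(g) for g in groups.values()))


def similarity_matrix(samples: TreeSampleSet | Iterable[UltrametricTree],
                      epsilon: float) -> SimilarityMatrix:
    """Co-clustering frequency of every tip pair across the sample."""
    trees = list(samples)
    if not trees:
        raise ArenosaeError("empty sample set")
    labels = tuple(sorted(trees[0].tips))
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n))
    for tree in trees:
        part = collapse_partition(tree, epsilon)
        for cls_ in part.classes:
            idx = [index[t] for t in cls_]
            for a in idx:
                for b in idx:
                    counts[a, b] += 1
    return SimilarityMatrix(labels, counts / len(trees), len(trees), epsilon)


def cluster_frequency_table(samples: TreeSampleSet | Iterable[UltrametricTree],
                            epsilon: float) -> list[tuple[Partition, float]]:
    """Distinct collapse partitions with their posterior frequencies."""
    trees = list(samples)
    if not trees:
        raise ArenosaeError("empty sample set")
    counts: dict[Partition, int] = {}
    for tree in trees:
        part = collapse_partition(tree, epsilon)
        counts[part] = counts.get(part, 0) + 1
    total = len(trees)
    return sorted(
        ((p, c / total) for p, c in counts.items()),
        key=lambda item: (-item[1], item[0].sorted_classes()),
    )


def ladderized_tip_order(tree: UltrametricTree) -> list[str]:
    """Left-to-right tip order after ladderizing (larger clades last,
    ties broken by the smallest tip label)."""

    def order(node: _Node) -> list[str]:
        if node.is_leaf:
            return [node.label]
        subtrees = [order(c) for c in node.children]
        subtrees.sort(key=lambda tips: (len(tips), min(tips)))
        return [t for sub in subtrees for t in sub]

    return order(tree.root)


def sort_by_tree(m: SimilarityMatrix,
                 summary: UltrametricTree) -> SimilarityMatrix:
    """Permute rows/columns into the ladderized tip order of a summary tree."""
    if sorted(summary.tips) != sorted(m.labels):
        raise ArenosaeError("summary tree tips do not match matrix labels")
    return m.reorder(ladderized_tip_order(summary))


def write_matrix(m: SimilarityMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, float_format="%.6g")


def read_matrix(path: str | Path, epsilon: float = float("nan"),
                n_samples: int = 0) -> SimilarityMatrix:
    frame = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(
        tuple(str(c) for c in frame.columns), frame.to_numpy(dtype=float),
        n_samples, epsilon,
    )


def plot_heatmap(m: SimilarityMatrix, path: str | Path,
                 cmap: str = "viridis") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(m.labels)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.4), max(3.5, n * 0.4)))
    im = ax.imshow(m.matrix, vmin=0, vmax=1, cmap=cmap)
    ax.set_xticks(range(n), labels=m.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), labels=m.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="posterior co-clustering frequency")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
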