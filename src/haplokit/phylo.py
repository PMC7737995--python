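"""Neighbor-joining trees, nonparametric bootstrap support, support
binning, and Newick output.

The tree builder is the Saitou–Nei neighbor-joining agglomeration: at
each step the pair (i, j) minimising the rate-corrected criterion

    Q(i, j) = (k - 2) d(i, j) - R_i - R_j,      R_i = sum_m d(i, m)

is joined, with branch lengths v_i = d(i,j)/2 + (R_i - R_j)/(2(k-2))
and the reduction d(u, m) = (d(i,m) + d(j,m) - d(i,j))/2. NJ is exact
on additive (tree-realisable) matrices. Bootstrap support for an
internal edge is the percentage of column-resampled replicate trees
containing the same unrooted tip bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .distance import DistanceMatrix, UndefinedDistanceError, hamming_matrix, k80_matrix
from .seqio import Alignment

__all__ = [
    "TreeNode",
    "Tree",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "bin_support",
    "write_newick",
]

logger = logging.getLogger(__name__)

SUPPORT_BINS = ("strong", "moderate", "weak", "poor")


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None  # branch length to the parent
    support: Optional[int] = None  # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree kept in rooted form: the root is the last
    agglomeration point and carries a basal multifurcation; tips hold
    the input labels."""

    root: TreeNode

    def tips(self) -> list[str]:
        out: list[str] = []

        def walk(n: TreeNode) -> None:
            if n.is_tip:
                out.append(n.name or "")
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(n: TreeNode) -> None:
            if not n.is_tip:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def clamp_negative_lengths(self) -> None:
        """Clamp negative branch lengths to zero in place."""
        for n in self.internal_nodes():
            for c in n.children:
                if c.length is not None and c.length < 0:
                    c.length = 0.0

    def tip_distances(self) -> DistanceMatrix:
        """All-pairs path-length matrix over the tips (the additivity
        oracle: on an additive input NJ reproduces it exactly)."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def walk(n: TreeNode) -> None:
            adj.setdefault(id(n), [])
            if n.is_tip:
                names[id(n)] = n.name or ""
            for c in n.children:
                w = float(c.length or 0.0)
                adj.setdefault(id(c), [])
                adj[id(n)].append((id(c), w))
                adj[id(c)].append((id(n), w))
                walk(c)

        walk(self.root)
        tip_ids = [i for i in adj if i in names]
        labels = [names[i] for i in tip_ids]
        k = len(tip_ids)
        values = np.zeros((k, k))
        for a, start in enumerate(tip_ids):
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for b, t in enumerate(tip_ids):
                values[a, b] = dist[t]
        np.fill_diagonal(values, 0.0)
        return DistanceMatrix(labels=labels, values=values, metric="path")


def nj_tree(d: DistanceMatrix, clamp_negative: bool = False) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Ties in the Q criterion are broken by the lowest (i, j) index pair
    in the current matrix, so the result is deterministic. Negative
    branch lengths are retained unless ``clamp_negative`` is set.
    """
    k = d.k
    if k < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in d.labels]
    D = d.values.astype(float).copy()

    if k == 2:
        half = float(D[0, 1]) / 2.0
        nodes[0].length = nodes[1].length = half
        tree = Tree(root=TreeNode(children=nodes))
        if clamp_negative:
            tree.clamp_negative_lengths()
        return tree

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        iu = np.triu_indices(m, 1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # first occurrence = lowest (i, j)
        i, j = int(iu[0][best]), int(iu[1][best])
        dij = D[i, j]
        vi = dij / 2.0 + (R[i] - R[j]) / (2.0 * (m - 2))
        vj = dij - vi
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        du = (D[i] + D[j] - dij) / 2.0
        D[i, :] = du
        D[:, i] = du
        D[i, i] = 0.0
        nodes[i] = new
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        del nodes[j]

    # final trifurcation around the last internal node
    (a, b, c) = nodes
    a.length = float((D[0, 1] + D[0, 2] - D[1, 2]) / 2.0)
    b.length = float((D[0, 1] + D[1, 2] - D[0, 2]) / 2.0)
    c.length = float((D[0, 2] + D[1, 2] - D[0, 1]) / 2.0)
    tree = Tree(root=TreeNode(children=[a, b, c]))
    if clamp_negative:
        tree.clamp_negative_lengths()
    return tree


def bipartitions(tree: Tree) -> dict[int, frozenset[str]]:
    """Nontrivial unrooted bipartitions, one per internal edge, keyed
    by ``id()`` of the child node below the edge. Each bipartition is
    canonicalised as the side *not* containing the lexicographically
    smallest tip, so it is comparable across trees on the same taxa."""
    all_tips = frozenset(tree.tips())
    anchor = min(all_tips)
    out: dict[int, frozenset[str]] = {}

    def walk(n: TreeNode) -> frozenset[str]:
        if n.is_tip:
            return frozenset([n.name or ""])
        below = frozenset().union(*(walk(c) for c in n.children))
        if n is not tree.root and 2 <= len(below) <= len(all_tips) - 2:
            side = below if anchor not in below else all_tips - below
            out[id(n)] = side
        return below

    walk(tree.root)
    return out


def _builder_for(model: str) -> Callable[[Alignment], Tree]:
    if model == "hamming":
        return lambda al: nj_tree(hamming_matrix(al))
    if model == "k80":
        return lambda al: nj_tree(k80_matrix(al))
    raise ValueError(f"unknown distance model: {model!r}")


def bootstrap_support(
    al: Alignment,
    B: int = 100,
    seed: int = 0,
    model: str = "hamming",
    tree_builder: Optional[Callable[[Alignment], Tree]] = None,
    max_redraws: int = 10,
) -> Tree:
    """Reference NJ tree with bootstrap supports on internal nodes.

    ``B`` pseudo-alignments are built by sampling L columns with
    replacement (seeded); the tree builder runs on each, and each
    internal edge of the reference tree is scored with the percentage
    of replicates containing the same unrooted bipartition, rounded to
    the nearest integer. A replicate whose distance matrix is undefined
    (possible under K80 at saturation) is re-drawn up to ``max_redraws``
    times, with a log record.
    """
    if B < 1:
        raise ValueError("need B >= 1 replicates")
    if al.length < 1:
        raise ValueError("alignment has no columns")
    build = tree_builder if tree_builder is not None else _builder_for(model)
    rng = np.random.default_rng(seed)

    reference = build(al)
    ref_bip = bipartitions(reference)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in ref_bip.values()}

    L = al.length
    for _ in range(B):
        for attempt in range(max_redraws + 1):
            cols = rng.integers(0, L, size=L)
            rep = Alignment(
                labels=list(al.labels),
                sequences=["".join(s[c] for c in cols) for s in al.sequences],
            )
            try:
                rep_tree = build(rep)
                break
            except UndefinedDistanceError as exc:
                logger.warning(
                    "bootstrap replicate undefined (%s); redraw %d/%d",
                    exc,
                    attempt + 1,
                    max_redraws,
                )
        else:
            raise UndefinedDistanceError(
                f"replicate distance undefined after {max_redraws} redraws"
            )
        rep_bip = set(bipartitions(rep_tree).values())
        for bp in counts:
            if bp in rep_bip:
                counts[bp] += 1

    for node in reference.internal_nodes():
        bp = ref_bip.get(id(node))
        if bp is not None:
            node.support = int(round(100.0 * counts[bp] / B))
    return reference


def bin_support(s: float, convention: str = "code") -> str:
    """Map a bootstrap percentage to a confidence category.

    ``convention="code"`` uses left-open right-closed intervals
    (0,50] poor, (50,70] weak, (70,85] moderate, (85,100] strong
    (``cut``-style bins; 85 is moderate). ``convention="text"`` follows
    the verbal rule "strong for 85% and above ... poor for 50% and
    below", under which 85 is strong.
    """
    if not 0 <= s <= 100:
        raise ValueError(f"support {s} outside [0, 100]")
    if convention == "code":
        if s <= 50:
            return "poor"
        if s <= 70:
            return "weak"
        if s <= 85:
            return "moderate"
        return "strong"
    if convention == "text":
        if s >= 85:
            return "strong"
        if s >= 70:
            return "moderate"
        if s > 50:
            return "weak"
        return "poor"
    raise ValueError(f"unknown convention: {convention!r}")


_NEWICK_SAFE = set(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789.-|/"
)


def _quote_label(label: str) -> str:
    if label and set(label) <= _NEWICK_SAFE:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(
    tree: Tree, precision: int = 10, include_support: bool = True
) -> str:
    """Serialise to Newick. Bootstrap supports become internal node
    labels; labels containing metacharacters (spaces, underscores,
    parentheses...) are single-quoted."""

    def fmt(n: TreeNode) -> str:
        if n.is_tip:
            body = _quote_label(n.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if include_support and n.support is not None:
                body += str(n.support)
            elif n.name:
                body += _quote_label(n.name)
        if n.length is not None:
            body += f":{n.length:.{precision}g}"
        return body

    return fmt(tree.root) + ";"
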