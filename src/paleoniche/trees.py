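"""Time-calibrated phylogenies as flat arrays.

A :class:`TimeTree` is a rooted binary tree with branch lengths in millions of
years (My) and, optionally, non-contemporaneous (fossil) tips.  Node ages are
measured in Ma before present, with the youngest tip at age 0 unless an
explicit root age is supplied.  Newick parsing is delegated to dendropy; the
flat parent/children/branch-length representation exists because the
comparative and biogeographic machinery needs many custom traversals
(interpolation along branches, epoch splicing, contrasts).
"""

from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["TimeTree"]


class TimeTree:
    """Rooted tree over ``n`` nodes indexed ``0..n-1``.

    Parameters
    ----------
    parent : array of int
        Parent index per node, ``-1`` for the root.
    blen : array of float
        Branch length (My) subtending each node; 0 for the root.
    labels : sequence of str or None
        Tip labels (internal nodes may be None).
    root_age : float, optional
        Age of the root in Ma.  If omitted, the youngest tip is placed at
        age 0 and the root age is the maximum root-to-tip path length.
    """

    def __init__(self, parent, blen, labels, root_age: float | None = None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if self.blen.size != n or len(self.labels) != n:
            raise ValueError("parent, blen, labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self.tips = np.array([i for i in range(n) if not self.children[i]], dtype=np.int64)
        # depth: path length from root
        self.depth = np.zeros(n)
        for i in self._preorder():
            if i != self.root:
                self.depth[i] = self.depth[self.parent[i]] + self.blen[i]
        height = float(self.depth[self.tips].max()) if self.tips.size else 0.0
        self.root_age = float(root_age) if root_age is not None else height
        self.age = self.root_age - self.depth
        self._postorder = self._preorder()[::-1]

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tips.size

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def _preorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        return np.array(order, dtype=np.int64)

    @property
    def preorder(self) -> np.ndarray:
        return self._preorder()

    @property
    def postorder(self) -> np.ndarray:
        return self._postorder

    def tip_index(self, label: str) -> int:
        for i in self.tips:
            if self.labels[i] == label:
                return int(i)
        raise KeyError(label)

    # --------------------------------------------------------------- algebra
    def mrca_depth_matrix(self, nodes: Sequence[int] | None = None) -> np.ndarray:
        """Shared root-to-MRCA path length for every pair of the given nodes.

        The diagonal holds each node's own depth; this is the Brownian-motion
        covariance structure (up to the rate sigma^2) and makes no
        ultrametricity assumption, so fossil tips are handled naturally.
        """
        if nodes is None:
            nodes = self.tips
        nodes = np.asarray(nodes, dtype=np.int64)
        anc: list[dict[int, float]] = [dict() for _ in range(self.n_nodes)]
        for i in self.preorder:
            if i == self.root:
                anc[i] = {i: 0.0}
            else:
                d = dict(anc[self.parent[i]])
                d[i] = self.depth[i]
                anc[i] = d
        m = nodes.size
        out = np.empty((m, m))
        for a in range(m):
            da = anc[nodes[a]]
            for b in range(a, m):
                db = anc[nodes[b]]
                shared = max((v for k, v in da.items() if k in db), default=0.0)
                out[a, b] = out[b, a] = shared
        return out

    def mrca_matrix(self, nodes: Sequence[int] | None = None) -> np.ndarray:
        """Node index of the MRCA for every pair of the given nodes."""
        if nodes is None:
            nodes = self.tips
        nodes = np.asarray(nodes, dtype=np.int64)
        anc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.preorder:
            if i == self.root:
                anc[i] = [i]
            else:
                anc[i] = anc[self.parent[i]] + [i]
        sets = [set(anc[k]) for k in nodes]
        m = nodes.size
        out = np.empty((m, m), dtype=np.int64)
        for a in range(m):
            for b in range(a, m):
                common = sets[a] & sets[b]
                # deepest common ancestor
                mr = max(common, key=lambda k: self.depth[k])
                out[a, b] = out[b, a] = mr
        return out

    def vcv(self) -> np.ndarray:
        """Tip-by-tip Brownian covariance structure (shared path lengths)."""
        return self.mrca_depth_matrix(self.tips)

    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_newick(cls, newick: str, root_age: float | None = None) -> "TimeTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): k for k, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        labels: list[str | None] = [None] * n
        for k, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[k] = index[id(nd.parent_node)]
                blen[k] = float(nd.edge.length or 0.0)
            if nd.taxon is not None:
                labels[k] = nd.taxon.label
            elif nd.label:
                labels[k] = nd.label
        return cls(parent, blen, labels, root_age=root_age)

    def to_newick(self) -> str:
        buf = io.StringIO()

        def rec(i: int) -> None:
            kids = self.children[i]
            if kids:
                buf.write("(")
                for k, c in enumerate(kids):
                    if k:
                        buf.write(",")
                    rec(c)
                buf.write(")")
            if self.labels[i]:
                buf.write(str(self.labels[i]).replace(" ", "_"))
            if i != self.root:
                buf.write(f":{self.blen[i]:.10g}")

        rec(self.root)
        buf.write(";")
        return buf.getvalue()

    # --------------------------------------------------------------- pruning
    def prune_to_tips(self, keep: Sequence[int]) -> "TimeTree":
        """Induced subtree on the given tips, unifurcations suppressed."""
        keep = set(int(k) for k in keep)
        if not keep:
            raise ValueError("cannot prune to an empty tip set")
        alive = set()
        for t in keep:
            i = t
            while i >= 0 and i not in alive:
                alive.add(i)
                i = int(self.parent[i])
        # number of retained children per retained node
        def build(i: int) -> tuple | None:
            kids = [c for c in self.children[i] if c in alive]
            if not kids:
                return (i, self.blen[i], []) if i in keep else None
            sub = [build(c) for c in kids]
            sub = [s for s in sub if s is not None]
            if not sub:
                return None
            if len(sub) == 1:  # suppress unifurcation: extend child's branch
                j, bl, ch = sub[0]
                return (j, bl + self.blen[i], ch)
            return (i, self.blen[i], sub)

        top = build(self.root)
        if top is None:
            raise ValueError("pruning removed every node")
        parent, blen, labels = [], [], []

        def emit(node: tuple, par: int) -> None:
            i, bl, ch = node
            k = len(parent)
            parent.append(par)
            blen.append(bl if par >= 0 else 0.0)
            labels.append(self.labels[i])
            for c in ch:
                emit(c, k)

        emit(top, -1)
        return TimeTree(parent, blen, labels, root_age=float(self.age[top[0]]))
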