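"""Rooted time-calibrated trees with array-based traversal.

A light wrapper around dendropy for parsing/serialising Newick, exposing the
flat arrays (parent pointers, branch lengths, traversal orders) that the
comparative-method code needs for fast, vectorised covariance construction.

Node indexing convention: tips occupy indices ``0 .. n_tips-1`` in the order
of ``labels``; internal nodes follow, with the root always last in
``postorder``. Branch lengths are in the same time units as the input tree
(Myr for the trees this package targets).
"""

from __future__ import annotations

import io as _io
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Phylo", "TreeError"]


class TreeError(ValueError):
    pass


class Phylo:
    """A rooted phylogeny with branch lengths, indexed as flat arrays."""

    def __init__(self, labels: Sequence[str], parent: np.ndarray, edge_len: np.ndarray):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=int)
        self.edge_len = np.asarray(edge_len, dtype=float)
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        if np.any(self.edge_len < 0):
            raise TreeError("negative branch length")
        if len(set(self.labels)) != self.n_tips:
            raise TreeError("duplicate tip labels")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1].copy()
        self.depth = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                self.depth[v] = self.depth[p] + self.edge_len[v]
        self._vcv: np.ndarray | None = None
        self._vcv_all: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, t: dendropy.Tree) -> "Phylo":
        leaves = [lf for lf in t.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else str(id(lf)) for lf in leaves]
        order = sorted(range(len(labels)), key=lambda i: labels[i])
        leaves = [leaves[i] for i in order]
        labels = [labels[i] for i in order]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        nxt = len(leaves)
        internals = [nd for nd in t.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            index[id(nd)] = nxt
            nxt += 1
        parent = np.full(nxt, -1, dtype=int)
        edge = np.zeros(nxt)
        for nd in t.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                edge[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(labels, parent, edge)

    @classmethod
    def from_newick(cls, source: str) -> "Phylo":
        """Parse a Newick string or a path to a Newick file."""
        source = str(source)
        if "(" in source:
            t = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
        else:
            t = dendropy.Tree.get(path=source, schema="newick", preserve_underscores=True)
        return cls.from_dendropy(t)

    def to_newick(self) -> str:
        names = {i: lab for i, lab in enumerate(self.labels)}

        def render(v: int) -> str:
            if v < self.n_tips:
                body = names[v].replace(" ", "_")
            else:
                body = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            if v == self.root:
                return body
            return f"{body}:{self.edge_len[v]:.10g}"

        return render(self.root) + ";"

    # -- traversal helpers -------------------------------------------------

    def _postorder(self) -> np.ndarray:
        out, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                out.append(v)
            else:
                stack.append((v, True))
                for c in self.children[v]:
                    stack.append((c, False))
        return np.array(out, dtype=int)

    def root_path(self, v: int) -> list[int]:
        """Nodes from the root down to ``v`` inclusive."""
        path = []
        while v >= 0:
            path.append(v)
            v = self.parent[v]
        return path[::-1]

    def mrca(self, a: int, b: int) -> int:
        pa = set(self.root_path(a))
        v = b
        while v not in pa:
            v = self.parent[v]
        return v

    # -- metrics -----------------------------------------------------------

    @property
    def height(self) -> float:
        return float(self.depth[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depth[: self.n_tips]
        h = d.max()
        return bool(h == 0 or (d.max() - d.min()) <= rel_tol * h)

    def _shared_depths(self, nodes: np.ndarray) -> np.ndarray:
        """depth of the MRCA for every pair in ``nodes`` (one is allowed to
        be an ancestor of the other, in which case the shallower node wins)."""
        paths = [self.root_path(int(v)) for v in nodes]
        sets = [set(p) for p in paths]
        m = len(nodes)
        out = np.zeros((m, m))
        for i in range(m):
            out[i, i] = self.depth[nodes[i]]
            for j in range(i + 1, m):
                common = sets[i] & sets[j]
                d = max(self.depth[v] for v in common)
                out[i, j] = out[j, i] = d
        return out

    def vcv(self) -> np.ndarray:
        """Brownian-motion tip covariance: shared root-to-MRCA path lengths."""
        if self._vcv is None:
            self._vcv = self._shared_depths(np.arange(self.n_tips))
        return self._vcv

    def vcv_all(self) -> np.ndarray:
        """Shared path lengths among all nodes (tips and internals)."""
        if self._vcv_all is None:
            self._vcv_all = self._shared_depths(np.arange(self.n_nodes))
        return self._vcv_all

    def patristic(self) -> np.ndarray:
        """Tip-to-tip path-length (time) distances."""
        d = self.depth[: self.n_tips]
        return d[:, None] + d[None, :] - 2 * self.vcv()

    def tip_index(self, labels: Sequence[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [x for x in labels if x not in pos]
        if missing:
            raise TreeError(f"labels not in tree: {missing[:5]}")
        return np.array([pos[x] for x in labels], dtype=int)

    def subtree_tips(self, v: int) -> list[int]:
        if v < self.n_tips:
            return [v]
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(u)
            else:
                stack.extend(self.children[u])
        return sorted(out)

    def clade_nodes(self, v: int) -> list[int]:
        """All nodes in the clade rooted at ``v`` (including ``v``)."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            if u >= self.n_tips:
                stack.extend(self.children[u])
        return out

    def retain_tips(self, keep: Sequence[str]) -> "Phylo":
        """Prune the tree down to the given tip labels, suppressing the
        resulting unifurcations (their branch lengths are merged)."""
        keep_set = set(keep)
        missing = keep_set - set(self.labels)
        if missing:
            raise TreeError(f"cannot retain absent tips: {sorted(missing)[:5]}")
        keep_idx = {i for i, lab in enumerate(self.labels) if lab in keep_set}

        # reduced[v] = (newick fragment, edge length) or None if pruned away
        reduced: dict[int, tuple[str, float] | None] = {}
        for v in self.postorder:
            if v < self.n_tips:
                reduced[v] = ((self.labels[v], self.edge_len[v])
                              if v in keep_idx else None)
                continue
            kids = [reduced[c] for c in self.children[v] if reduced[c] is not None]
            if not kids:
                reduced[v] = None
            elif len(kids) == 1:  # unifurcation: splice the branch through
                frag, ln = kids[0]
                reduced[v] = (frag, ln + self.edge_len[v])
            else:
                body = "(" + ",".join(f"{f}:{ln:.10g}" for f, ln in kids) + ")"
                reduced[v] = (body, self.edge_len[v])
        top = reduced[self.root]
        assert top is not None
        frag, ln = top
        if not frag.startswith("("):  # single tip left: keep a stub root
            frag = f"({frag}:{ln:.10g})"
        return Phylo.from_newick(frag + ";")
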