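"""Rooted trees for likelihood computation and dating.

Internally a tree is a flat array structure (parent pointers, child lists and a
postorder) so that pruning and MCMC moves index nodes directly.  Newick text is
parsed with dendropy and converted; serialisation is deterministic so that
rebuilt files are byte-identical.

Two views share the structure:

* :class:`Tree` carries branch lengths in substitutions/site (edge above each
  non-root node);
* :class:`DatedTree` carries node ages (Ma; tips may be non-zero for serial
  sampling) and optional per-branch rates (substitutions/site/Ma).
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Tree", "DatedTree"]


class Tree:
    """Rooted tree over named tips with optional branch lengths.

    Node indices: tips are ``0 .. n_tips-1`` in the order they appear in the
    source Newick (left to right); internal nodes follow, with the root last
    in :attr:`preorder` and first built by :meth:`from_newick`.
    """

    def __init__(
        self,
        parent: Sequence[int],
        names: Sequence[str | None],
        lengths: Sequence[float] | None = None,
        children: list[list[int]] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.n_nodes = len(self.parent)
        self.names = list(names)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if children is not None:
            self.children = [list(c) for c in children]
        else:
            self.children = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    self.children[int(p)].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self.n_tips = int(self.is_tip.sum())
        if lengths is None:
            self.lengths = np.zeros(self.n_nodes)
        else:
            self.lengths = np.asarray(lengths, dtype=float).copy()
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1].copy()

    def _postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self.children[node]):
                    stack.append((c, False))
        return np.array(order, dtype=int)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=False, preserve_underscores=True,
        )
        nodes = list(dt.preorder_node_iter())
        # tips first, in left-to-right (preorder) encounter order, then internals
        tips = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        index = {id(n): i for i, n in enumerate(tips)}
        for j, n in enumerate(internals):
            index[id(n)] = len(tips) + j
        parent = np.full(len(nodes), -1, dtype=int)
        names: list[str | None] = [None] * len(nodes)
        lengths = np.zeros(len(nodes))
        children: list[list[int]] = [[] for _ in nodes]
        for n in nodes:
            i = index[id(n)]
            label = None
            if n.taxon is not None:
                label = n.taxon.label
            elif n.label:
                label = n.label
            names[i] = label
            children[i] = [index[id(c)] for c in n.child_nodes()]
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                lengths[i] = n.edge.length if n.edge.length is not None else 0.0
        return cls(parent, names, lengths, children=children)

    def to_newick(self, lengths: bool = True, comments: dict[int, str] | None = None) -> str:
        """Deterministic Newick serialisation (``%g`` lengths, trailing ``;``)."""

        def fmt(node: int) -> str:
            if self.children[node]:
                s = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
                s += self.names[node] or ""
            else:
                s = self.names[node] or ""
            if comments and node in comments:
                s += f"[&{comments[node]}]"
            if lengths and self.parent[node] >= 0:
                s += f":{self.lengths[node]:g}"
            return s

        return fmt(self.root) + ";"

    # --------------------------------------------------------------- queries
    def tip_names(self) -> list[str]:
        return [self.names[i] for i in range(self.n_nodes) if self.is_tip[i]]

    def tip_index(self, name: str) -> int:
        for i in range(self.n_nodes):
            if self.is_tip[i] and self.names[i] == name:
                return i
        raise KeyError(f"no tip named {name!r}")

    def mrca(self, tip_names: Iterable[str]) -> int:
        """Index of the most recent common ancestor of the named tips."""
        targets = {self.tip_index(n) for n in tip_names}
        below: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for node in self.postorder:
            if self.is_tip[node]:
                below[node] = {node} if node in targets else set()
            else:
                acc: set[int] = set()
                for c in self.children[node]:
                    acc |= below[c]
                below[node] = acc
            if below[node] == targets:
                return int(node)
        raise ValueError("tips not all present in tree")

    def tips_below(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), list(self.names), self.lengths.copy(),
                    children=self.children)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n_tips={self.n_tips} n_nodes={self.n_nodes}>"


class DatedTree(Tree):
    """Tree with node ages (time before present) and optional branch rates.

    Invariants: every parent is strictly older than each child; tip ages are
    non-negative.  ``rates[i]`` is the substitution rate on the edge above
    node ``i`` (ignored for the root).
    """

    def __init__(self, parent, names, ages, rates=None, children=None):
        super().__init__(parent, names, lengths=None, children=children)
        self.ages = np.asarray(ages, dtype=float).copy()
        if len(self.ages) != self.n_nodes:
            raise ValueError("ages length must match node count")
        self.rates = None if rates is None else np.asarray(rates, dtype=float).copy()
        self.validate()

    def validate(self) -> None:
        if np.any(self.ages[self.is_tip] < 0):
            raise ValueError("tip ages must be >= 0")
        for i, p in enumerate(self.parent):
            if p >= 0 and not self.ages[p] > self.ages[i]:
                raise ValueError(
                    f"parent age {self.ages[p]} not greater than child age "
                    f"{self.ages[i]} (node {i})"
                )
        if self.rates is not None and np.any(self.rates[self.parent >= 0] <= 0):
            raise ValueError("branch rates must be > 0")

    @classmethod
    def from_newick_ages(cls, newick: str, ages: dict[str, float] | None = None,
                         rates: np.ndarray | None = None) -> "DatedTree":
        """Build from Newick whose branch lengths are *durations* (Ma).

        Tip ages default to 0; pass ``ages`` to set serial tip ages (the most
        recent tip anchors time zero).
        """
        base = Tree.from_newick(newick)
        node_ages = np.zeros(base.n_nodes)
        # depth from root via preorder, then convert to age
        depth = np.zeros(base.n_nodes)
        for v in base.preorder:
            p = base.parent[v]
            if p >= 0:
                depth[v] = depth[p] + base.lengths[v]
        node_ages = depth.max() - depth
        if ages:
            for name, a in ages.items():
                node_ages[base.tip_index(name)] = a
        return cls(base.parent, base.names, node_ages, rates,
                   children=base.children)

    def durations(self) -> np.ndarray:
        """Edge duration above each node (0 for the root)."""
        d = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        d[has_parent] = self.ages[self.parent[has_parent]] - self.ages[has_parent]
        return d

    def branch_lengths(self, clock_rate: float | None = None) -> np.ndarray:
        """Expected substitutions/site per edge: duration x rate."""
        d = self.durations()
        if self.rates is not None:
            return d * np.where(self.parent >= 0, np.nan_to_num(self.rates), 0.0)
        if clock_rate is None:
            raise ValueError("no branch rates stored; pass clock_rate")
        return d * clock_rate

    def to_branch_tree(self, clock_rate: float | None = None) -> Tree:
        t = Tree(self.parent.copy(), list(self.names), children=self.children)
        t.lengths = self.branch_lengths(clock_rate)
        return t

    def copy(self) -> "DatedTree":
        return DatedTree(self.parent.copy(), list(self.names), self.ages,
                         None if self.rates is None else self.rates,
                         children=self.children)
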