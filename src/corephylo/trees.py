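"""Unrooted phylogenetic trees.

A small, dependency-light tree structure shared by the simulator, the
search engines and the constraint machinery.  Trees are stored as an
undirected adjacency map with optional branch lengths; leaves carry taxon
labels.  Newick input is parsed through dendropy so that all the usual
dialects (quoted labels, internal support labels, polytomies) are
accepted; output is written directly.

Bipartitions are represented as frozensets of taxon labels, canonicalized
to the side *not* containing the lexicographically smallest taxon of the
tree, so that two trees over the same taxa can be compared by set algebra.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

__all__ = ["Tree"]

Bipartition = FrozenSet[str]


class Tree:
    """Unrooted tree over labelled leaves; internal nodes are anonymous."""

    def __init__(self) -> None:
        self.adj: Dict[int, Dict[int, Optional[float]]] = {}
        self.labels: Dict[int, str] = {}  # leaf node -> taxon
        self.support: Dict[Bipartition, float] = {}
        self._next = 0

    # ------------------------------------------------------------------ basics

    def new_node(self, label: Optional[str] = None) -> int:
        n = self._next
        self._next += 1
        self.adj[n] = {}
        if label is not None:
            self.labels[n] = label
        return n

    def add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def set_length(self, u: int, v: int, length: Optional[float]) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def length(self, u: int, v: int) -> Optional[float]:
        return self.adj[u][v]

    def degree(self, n: int) -> int:
        return len(self.adj[n])

    @property
    def nodes(self) -> List[int]:
        return list(self.adj)

    def leaves(self) -> List[int]:
        return [n for n in self.adj if n in self.labels]

    def taxa(self) -> List[str]:
        return sorted(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> List[Tuple[int, int]]:
        out = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    def is_binary(self) -> bool:
        if self.n_leaves <= 2:
            return True
        return all(
            (n in self.labels and len(nb) == 1) or (n not in self.labels and len(nb) == 3)
            for n, nb in self.adj.items()
        )

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.labels = dict(self.labels)
        t.support = dict(self.support)
        t._next = self._next
        return t

    def total_length(self) -> float:
        return sum(l or 0.0 for _, _, l in self.iter_edges_with_length())

    def iter_edges_with_length(self) -> Iterator[Tuple[int, int, Optional[float]]]:
        for u, v in self.edges():
            yield u, v, self.adj[u][v]

    # ------------------------------------------------------------- traversal

    def rooted(self, at_edge: Optional[Tuple[int, int]] = None):
        """Root on an edge (virtual root) and return a rooted view.

        Returns ``(postorder, children, parent, blen)`` where *postorder* is
        a list of node ids ending at the virtual root (id -1), *children*
        maps node -> tuple of children and *blen* maps node -> branch length
        to its parent (the rooted-on edge's length is split arbitrarily:
        full length on one child, 0 on the other — likelihood and parsimony
        only depend on the sum).
        """
        if at_edge is None:
            at_edge = self.edges()[0]
        u, v = at_edge
        root = -1
        parent = {u: root, v: root}
        blen = {u: self.adj[u][v], v: 0.0}
        children: Dict[int, list] = {root: [u, v]}
        order = [root]
        # (node, neighbour to exclude): the rooting edge's flanks exclude
        # each other, every other node excludes its parent
        stack = [(u, v), (v, u)]
        while stack:
            n, excl = stack.pop()
            order.append(n)
            kids = [m for m in self.adj[n] if m != excl]
            children[n] = kids
            for m in kids:
                parent[m] = n
                blen[m] = self.adj[n][m]
                stack.append((m, n))
        order.reverse()  # postorder: children before parents
        return order, children, parent, blen

    # ----------------------------------------------------------- bipartitions

    def bipartitions(self, nontrivial: bool = True) -> Dict[Bipartition, Tuple[int, int]]:
        """Map canonical bipartition -> the edge inducing it."""
        taxa = self.taxa()
        if len(taxa) < 2:
            return {}
        ref = taxa[0]
        full = frozenset(taxa)
        out: Dict[Bipartition, Tuple[int, int]] = {}
        # compute leafsets below each directed edge via one rooted pass
        order, children, parent, _ = self.rooted()
        below: Dict[int, frozenset] = {}
        for n in order:
            if n == -1:
                continue
            if n in self.labels:
                below[n] = frozenset([self.labels[n]])
            else:
                below[n] = frozenset().union(*(below[c] for c in children[n]))
        for n in order:
            if n == -1 or parent[n] == -1:
                continue
            side = below[n]
            if nontrivial and (len(side) < 2 or len(side) > len(taxa) - 2):
                continue
            if ref in side:
                side = full - side
            out[side] = (parent[n], n)
        # the rooted-on edge itself
        u, v = children[-1]
        side = below[u]
        if not (nontrivial and (len(side) < 2 or len(side) > len(taxa) - 2)):
            if ref in side:
                side = full - side
            out[side] = (u, v)
        return out

    def rf_distance(self, other: "Tree") -> int:
        """Unrooted Robinson–Foulds distance (ignores lengths and support)."""
        if set(self.taxa()) != set(other.taxa()):
            raise ValueError("trees must share an identical taxon set")
        a = set(self.bipartitions())
        b = set(other.bipartitions())
        return len(a ^ b)

    def same_topology(self, other: "Tree") -> bool:
        return set(self.taxa()) == set(other.taxa()) and self.rf_distance(other) == 0

    def displays(self, constraint: "Tree") -> bool:
        """True iff this tree's induced subtree on the constraint's taxa
        shows every (nontrivial) bipartition of the constraint.

        Taxa of the constraint missing from this tree are ignored, which
        makes the check usable on partially built trees during stepwise
        addition.
        """
        common = set(constraint.labels.values()) & set(self.labels.values())
        if len(common) < 4:
            return True
        induced = self.restrict(sorted(common)).bipartitions()
        ref = min(common)
        ok_bips = set(induced)
        for side in constraint.bipartitions():
            side = frozenset(side & common)
            other = frozenset(common - side)
            if len(side) < 2 or len(other) < 2:
                continue
            if ref in side:
                side = other
            if side not in ok_bips:
                return False
        return True

    # ----------------------------------------------------------------- editing

    def add_leaf_on_edge(self, u: int, v: int, label: str,
                         leaf_length: Optional[float] = None) -> Tuple[int, int]:
        """Subdivide edge (u,v) and attach a new leaf; returns (leaf, junction)."""
        old = self.adj[u][v]
        self.remove_edge(u, v)
        w = self.new_node()
        half = None if old is None else old / 2.0
        self.add_edge(u, w, half)
        self.add_edge(w, v, half)
        leaf = self.new_node(label)
        self.add_edge(w, leaf, leaf_length)
        return leaf, w

    def remove_leaf(self, leaf: int) -> None:
        """Remove a leaf and suppress the resulting degree-2 junction."""
        (nbr,) = self.adj[leaf]
        self.remove_edge(leaf, nbr)
        del self.adj[leaf]
        del self.labels[leaf]
        self._suppress_if_degree2(nbr)

    def _suppress_if_degree2(self, n: int) -> None:
        if n in self.labels or n not in self.adj or len(self.adj[n]) != 2:
            return
        (a, la), (b, lb) = self.adj[n].items()
        self.remove_edge(n, a)
        self.remove_edge(n, b)
        del self.adj[n]
        length = None if (la is None or lb is None) else la + lb
        self.add_edge(a, b, length)

    def collapse_edge(self, u: int, v: int) -> None:
        """Contract internal edge (u,v) into a polytomy at u."""
        if u in self.labels or v in self.labels:
            raise ValueError("cannot collapse a pendant edge")
        for w, l in list(self.adj[v].items()):
            if w == u:
                continue
            self.remove_edge(v, w)
            self.add_edge(u, w, l)
        self.remove_edge(u, v)
        del self.adj[v]

    def restrict(self, taxa: Sequence[str]) -> "Tree":
        """Induced subtree on a taxon subset, degree-2 nodes suppressed."""
        keep = set(taxa)
        missing = keep - set(self.labels.values())
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")
        t = self.copy()
        t.support = {}
        changed = True
        while changed:
            changed = False
            for n in list(t.adj):
                if n in t.labels and t.labels[n] not in keep:
                    for m in list(t.adj[n]):
                        t.remove_edge(n, m)
                    del t.adj[n]
                    del t.labels[n]
                    changed = True
                elif n not in t.labels and len(t.adj[n]) <= 1:
                    for m in list(t.adj[n]):
                        t.remove_edge(n, m)
                    del t.adj[n]
                    changed = True
        for n in list(t.adj):
            t._suppress_if_degree2(n)
        return t

    # ------------------------------------------------------------ generation

    @classmethod
    def star(cls, labels: Sequence[str]) -> "Tree":
        t = cls()
        hub = t.new_node()
        for lab in labels:
            leaf = t.new_node(lab)
            t.add_edge(hub, leaf)
        return t

    @classmethod
    def random_topology(cls, labels: Sequence[str], rng: np.random.Generator) -> "Tree":
        """Uniformly distributed unrooted binary topology (stepwise addition)."""
        labels = list(labels)
        if len(labels) < 3:
            raise ValueError("need at least 3 labels")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        t = cls.star(labels[:3])
        for lab in labels[3:]:
            edges = t.edges()
            u, v = edges[rng.integers(len(edges))]
            t.add_leaf_on_edge(u, v, lab)
        return t

    @classmethod
    def enumerate_topologies(cls, labels: Sequence[str]) -> Iterator["Tree"]:
        """All (2n-5)!! unrooted binary topologies over the labels."""
        labels = list(labels)
        if len(labels) < 3:
            raise ValueError("need at least 3 labels")

        def grow(t: "Tree", rest: List[str]) -> Iterator["Tree"]:
            if not rest:
                yield t
                return
            lab, tail = rest[0], rest[1:]
            for u, v in t.edges():
                t2 = t.copy()
                t2.add_leaf_on_edge(u, v, lab)
                yield from grow(t2, tail)

        yield from grow(cls.star(labels[:3]), labels[3:])

    # -------------------------------------------------------------- rearrange

    def nni_neighbors(self) -> Iterator["Tree"]:
        """The 2(n-3) nearest-neighbour-interchange trees (binary trees)."""
        for u, v in self.edges():
            if u in self.labels or v in self.labels:
                continue
            a, b = [x for x in self.adj[u] if x != v]
            c, d = [x for x in self.adj[v] if x != u]
            for x, y in ((b, c), (b, d)):
                t = self.copy()
                lx, ly = t.adj[u][x], t.adj[v][y]
                t.remove_edge(u, x)
                t.remove_edge(v, y)
                t.add_edge(u, y, ly)
                t.add_edge(v, x, lx)
                yield t

    def tbr_neighbors(self) -> Iterator["Tree"]:
        """Tree-bisection-reconnection neighbourhood (binary trees).

        Every edge is bisected; the two fragments are reconnected between
        every pair of their edges.  Includes the SPR and NNI neighbourhoods.
        """
        for u, v in self.edges():
            base = self.copy()
            base.support = {}
            length_uv = base.adj[u][v]
            base.remove_edge(u, v)
            comp_u = base._component(u)
            comp_v = base._component(v)
            base._suppress_if_degree2(u)
            base._suppress_if_degree2(v)
            comp_u &= set(base.adj)
            comp_v &= set(base.adj)
            for att1 in base._attachment_points(comp_u):
                for att2 in base._attachment_points(comp_v):
                    t = base.copy()
                    x = t._attach(att1)
                    y = t._attach(att2)
                    t.add_edge(x, y, length_uv)
                    yield t

    def _component(self, start: int) -> set:
        seen = {start}
        stack = [start]
        while stack:
            n = stack.pop()
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return seen

    def _attachment_points(self, comp: set):
        """Attachment sites in a fragment: its edges, or the node if trivial."""
        edges = [(a, b) for a in comp for b in self.adj[a] if a < b and b in comp]
        if edges:
            return edges
        return [(next(iter(comp)),)]

    def _attach(self, att) -> int:
        if len(att) == 1:
            return att[0]
        a, b = att
        old = self.adj[a][b]
        self.remove_edge(a, b)
        w = self.new_node()
        half = None if old is None else old / 2.0
        self.add_edge(a, w, half)
        self.add_edge(w, b, half)
        return w

    # ------------------------------------------------------------------ newick

    def to_newick(self, lengths: bool = True, support: bool = False,
                  precision: int = 10) -> str:
        if self.n_leaves == 0:
            return ";"
        if self.n_leaves == 1:
            return f"{list(self.labels.values())[0]};"
        bip_edges = self.bipartitions() if support and self.support else {}
        edge_support = {}
        for bip, (a, b) in bip_edges.items():
            if bip in self.support:
                edge_support[frozenset((a, b))] = self.support[bip]
        root = next((n for n in self.adj if n not in self.labels), None)
        if root is None:  # two-leaf tree
            (a, b) = self.leaves()
            l = self.adj[a][b]
            la = f":{l:.{precision}g}" if (lengths and l is not None) else ""
            return f"({self.labels[a]}{la},{self.labels[b]});"

        def fmt(n: int, parent: int) -> str:
            l = self.adj[n][parent]
            suff = f":{l:.{precision}g}" if (lengths and l is not None) else ""
            if n in self.labels:
                return f"{self.labels[n]}{suff}"
            inner = ",".join(fmt(m, n) for m in sorted(
                self.adj[n], key=lambda m: min(self._leafset_sorted(m, n))) if m != parent)
            sup = edge_support.get(frozenset((n, parent)))
            lab = f"{sup:g}" if sup is not None else ""
            return f"({inner}){lab}{suff}"

        parts = ",".join(fmt(m, root) for m in sorted(
            self.adj[root], key=lambda m: min(self._leafset_sorted(m, root))))
        return f"({parts});"

    def _leafset_sorted(self, n: int, parent: int) -> List[str]:
        labs = []
        stack = [(n, parent)]
        while stack:
            x, p = stack.pop()
            if x in self.labels:
                labs.append(self.labels[x])
            for m in self.adj[x]:
                if m != p:
                    stack.append((m, x))
        return sorted(labs)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        dt.deroot()
        t = cls()
        node_map = {}
        for nd in dt.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else None
            node_map[nd] = t.new_node(label)
        for nd in dt.preorder_node_iter():
            if nd.parent_node is not None:
                t.add_edge(node_map[nd.parent_node], node_map[nd],
                           nd.edge.length)
        # fold dendropy internal labels into support where numeric
        for nd in dt.preorder_node_iter():
            if nd.is_internal() and nd.label is not None:
                try:
                    val = float(nd.label)
                except ValueError:
                    continue
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                taxa = sorted(t.labels.values())
                full = frozenset(taxa)
                if len(side) < 2 or len(side) > len(taxa) - 2:
                    continue
                if taxa[0] in side:
                    side = full - side
                t.support[side] = val
        return t

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n_leaves={self.n_leaves}>"
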