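"""Fitch parsimony and maximum-parsimony heuristic search.

Site patterns are scored with the Fitch set algorithm vectorized over
columns (state sets as bitmasks); missing cells ('?' or '-') carry the
full state set.  The search is random stepwise addition followed by TBR
(or NNI) branch swapping, optionally under a backbone constraint: leaf
placements and swaps producing trees that do not display the constraint
are discarded.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .._seeds import stream
from ..trees import Tree
from .encode import CharMatrix, SiteScoreVector, as_char_matrix
from .search import SearchParams

__all__ = ["parsimony_length", "mp_search", "collapse_zero_length_branches",
           "topology_id"]

log = logging.getLogger(__name__)


def topology_id(tree: Tree) -> str:
    bips = sorted(tuple(sorted(b)) for b in tree.bipartitions())
    payload = repr((sorted(tree.taxa()), bips)).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


class _FitchScorer:
    """Weighted Fitch steps over compressed site patterns."""

    def __init__(self, cm: CharMatrix) -> None:
        pats, weights, inverse = cm.patterns()
        self.weights = weights
        self.inverse = inverse
        self.n_pat = pats.shape[1]
        full = (1 << cm.n_states) - 1
        self.leaf_masks: Dict[str, np.ndarray] = {}
        for i, t in enumerate(cm.taxa):
            codes = pats[i]
            shifts = np.clip(codes, 0, None).astype(np.uint32)
            masks = np.where(codes >= 0, np.uint32(1) << shifts, np.uint32(full))
            self.leaf_masks[t] = masks.astype(np.uint32)
        self.full = np.uint32(full)

    def per_pattern(self, tree: Tree) -> np.ndarray:
        order, children, parent, _ = tree.rooted()
        steps = np.zeros(self.n_pat)
        sets: Dict[int, np.ndarray] = {}
        for n in order:
            if n != -1 and n in tree.labels:
                sets[n] = self.leaf_masks[tree.labels[n]]
                continue
            kids = children[n]
            if len(kids) != 2:
                raise ValueError("parsimony scoring requires a binary tree")
            a, b = sets.pop(kids[0]), sets.pop(kids[1])
            inter = a & b
            miss = inter == 0
            steps += miss
            sets[n] = np.where(miss, a | b, inter)
        return steps

    def score(self, tree: Tree) -> float:
        return float(self.per_pattern(tree) @ self.weights)

    def down_up_sets(self, tree: Tree):
        """Fitch state sets of both sides of every edge (for zero-length
        detection): returns (D, U, parent, children) keyed by node, where D
        is the set of the subtree below a node and U of everything above."""
        order, children, parent, _ = tree.rooted()
        D: Dict[int, np.ndarray] = {}
        for n in order:
            if n != -1 and n in tree.labels:
                D[n] = self.leaf_masks[tree.labels[n]]
                continue
            a, b = D[children[n][0]], D[children[n][1]]
            inter = a & b
            D[n] = np.where(inter == 0, a | b, inter)

        def fold(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            inter = a & b
            return np.where(inter == 0, a | b, inter)

        U: Dict[int, np.ndarray] = {}
        u, v = children[-1]
        U[u] = D[v]
        U[v] = D[u]
        for n in reversed(order):        # preorder
            if n == -1 or n in tree.labels:
                continue
            for c in children[n]:
                sib = [s for s in children[n] if s != c][0]
                if c not in U:
                    U[c] = fold(U[n], D[sib])
        return D, U, parent, children


def parsimony_length(tree: Tree, matrix, exclude_uninformative: bool = False
                     ) -> SiteScoreVector:
    """Fitch parsimony steps per column and in total.

    Missing states are fully ambiguous.  With ``exclude_uninformative``
    the parsimony-uninformative columns contribute zero (the counting mode
    used when supermatrix lengths are reported "not counting uninformative
    characters").
    """
    cm = as_char_matrix(matrix)
    tree_taxa = set(tree.taxa())
    if not tree_taxa <= set(cm.taxa):
        raise ValueError("tree contains taxa absent from the matrix")
    if tree_taxa != set(cm.taxa):
        cm = cm.subset(sorted(tree_taxa))
    scorer = _FitchScorer(cm)
    per_pat = scorer.per_pattern(tree)
    values = per_pat[scorer.inverse]
    if exclude_uninformative:
        values = np.where(cm.informative_mask(), values, 0.0)
    return SiteScoreVector(values, topology_id(tree), cm.matrix_id, "steps")


def _stepwise_addition(taxa: Sequence[str], scorer: _FitchScorer,
                       rng: np.random.Generator,
                       constraint: Optional[Tree]) -> Tree:
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    tree = Tree.star(order[:3])
    for lab in order[3:]:
        best = None
        for u, v in tree.edges():
            cand = tree.copy()
            cand.add_leaf_on_edge(u, v, lab)
            if constraint is not None and not cand.displays(constraint):
                continue
            s = scorer.score(cand)
            if best is None or s < best[0]:
                best = (s, cand)
        if best is None:
            raise RuntimeError("no constraint-compatible placement found")
        tree = best[1]
    return tree


def _swap_to_optimum(tree: Tree, scorer: _FitchScorer, swap: str,
                     constraint: Optional[Tree], max_keep: int
                     ) -> Tuple[Tree, float, Dict[str, Tree]]:
    cur = tree
    cur_len = scorer.score(tree)
    ties: Dict[str, Tree] = {}
    while True:
        if swap == "none" or tree.n_leaves < 4:
            break
        neighbors = cur.tbr_neighbors() if swap == "tbr" else cur.nni_neighbors()
        best_len = cur_len
        best_tree = None
        ties = {}
        for cand in neighbors:
            if constraint is not None and not cand.displays(constraint):
                continue
            s = scorer.score(cand)
            if s < best_len:
                best_len, best_tree = s, cand
                ties = {}
            elif s == cur_len and len(ties) < max_keep:
                tid = topology_id(cand)
                if tid not in ties:
                    ties[tid] = cand
        if best_tree is None:
            break
        cur, cur_len = best_tree, best_len
    return cur, cur_len, ties


def mp_search(matrix, params: Optional[SearchParams] = None,
              constraint: Optional[Tree] = None,
              taxa: Optional[Sequence[str]] = None
              ) -> Tuple[List[Tree], float]:
    """Maximum-parsimony search: random addition rounds plus branch swapping.

    Returns all distinct best topologies found (at most
    ``max_trees_per_round`` collected per round) and the best length.
    Seed-reproducible through ``params.seed``.
    """
    params = params or SearchParams()
    cm = as_char_matrix(matrix)
    taxa = sorted(taxa) if taxa is not None else list(cm.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    if set(taxa) != set(cm.taxa):
        cm = cm.subset(taxa)
    scorer = _FitchScorer(cm)
    rng = stream(params.seed, "mp-search")
    best_len = np.inf
    best: Dict[str, Tree] = {}
    for rnd in range(params.addition_rounds):
        start = _stepwise_addition(taxa, scorer, rng, constraint)
        tree, length, ties = _swap_to_optimum(
            start, scorer, params.swap, constraint, params.max_trees_per_round)
        log.info("round %d: length %g (%d tied)", rnd + 1, length, len(ties))
        round_trees = {topology_id(tree): tree}
        round_trees.update(ties)
        if length < best_len:
            best_len = length
            best = dict(round_trees)
        elif length == best_len:
            for tid, t in round_trees.items():
                if tid not in best and len(best) < 10 * params.max_trees_per_round:
                    best[tid] = t
    trees = sorted(best.values(), key=lambda t: t.to_newick(lengths=False))
    return trees, float(best_len)


def collapse_zero_length_branches(tree: Tree, matrix) -> Tree:
    """Collapse internal branches with a minimum of zero changes.

    A branch needs no change at a column when the Fitch state sets of its
    two sides intersect; a branch where this holds at every column (strict
    zero on integer step counts) is contracted into a polytomy.
    """
    cm = as_char_matrix(matrix)
    if set(tree.taxa()) != set(cm.taxa):
        cm = cm.subset(sorted(tree.taxa()))
    scorer = _FitchScorer(cm)
    D, U, parent, children = scorer.down_up_sets(tree)
    bips = tree.bipartitions()
    drop = set()
    for bip, (u, v) in bips.items():
        if parent.get(v) == u:
            child = v
        elif parent.get(u) == v:
            child = u
        else:                       # the rooted-on edge: U[u] is D[v]
            child = u
        disjoint = (D[child] & U[child]) == 0
        if float(disjoint @ scorer.weights) == 0.0:
            drop.add(bip)
    out = tree.copy()
    # contract one edge at a time: node ids change under each contraction
    while True:
        hit = [(u, v) for bip, (u, v) in out.bipartitions().items()
               if bip in drop]
        if not hit:
            return out
        out.collapse_edge(*hit[0])
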