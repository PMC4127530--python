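"""Pruning-algorithm likelihood and maximum-likelihood tree search.

Site likelihoods are computed by Felsenstein's pruning algorithm over
compressed site patterns, with 4-category discrete-gamma rate
heterogeneity and per-node rescaling against underflow.  Missing cells
integrate over all states.  The search starts from a parsimony tree
(branch lengths initialized from per-branch Fitch change counts),
alternates bounded univariate branch-length and gamma-shape optimization
with nearest-neighbour-interchange passes, and stops when no interchange
gains more than a tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from ..models import ModelSpec, SubstitutionModel, discrete_gamma_rates
from ..trees import Tree
from .encode import CharMatrix, SiteScoreVector, as_char_matrix
from .parsimony import _FitchScorer, mp_search, topology_id
from .search import SearchParams

__all__ = ["log_likelihood", "ml_search", "choose_model", "MlResult"]

log = logging.getLogger(__name__)

MIN_BRLEN = 1e-8
MAX_BRLEN = 20.0


class _PruningEngine:
    def __init__(self, cm: CharMatrix, model: SubstitutionModel,
                 rates: np.ndarray) -> None:
        if model.n_states != cm.n_states:
            raise ValueError(
                f"model {model.name} has {model.n_states} states but the "
                f"matrix alphabet {cm.alphabet!r} has {cm.n_states}")
        self.cm = cm
        self.model = model
        self.rates = np.asarray(rates, float)
        pats, weights, inverse = cm.patterns()
        self.weights = weights
        self.inverse = inverse
        self.n_pat = pats.shape[1]
        k = cm.n_states
        self.leaf_partials: Dict[str, np.ndarray] = {}
        for i, t in enumerate(cm.taxa):
            codes = pats[i]
            P = np.zeros((k, self.n_pat))
            miss = codes < 0
            P[:, miss] = 1.0
            ok = ~miss
            P[codes[ok], np.nonzero(ok)[0]] = 1.0
            self.leaf_partials[t] = P

    def per_pattern_lnl(self, tree: Tree) -> np.ndarray:
        order, children, parent, blen = tree.rooted()
        ncat = len(self.rates)
        k = self.model.n_states
        partials: Dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_pat)
        for n in order:
            if n != -1 and n in tree.labels:
                continue
            msgs = []
            for c in children[n]:
                t = blen[c]
                if t is None or t < 0:
                    raise ValueError("likelihood requires non-negative branch lengths")
                P = np.stack([self.model.transition_matrix(t * r)
                              for r in self.rates])
                if c in tree.labels:
                    child = self.leaf_partials[tree.labels[c]]
                    msg = np.einsum("cij,jp->cip", P, child)
                else:
                    msg = np.einsum("cij,cjp->cip", P, partials.pop(c))
                msgs.append(msg)
            part = msgs[0]
            for m in msgs[1:]:
                part = part * m
            scale = part.max(axis=(0, 1))
            scale[scale <= 0] = 1.0
            part = part / scale[None, None, :]
            logscale += np.log(scale)
            partials[n] = part
        root = partials[-1]
        site_l = np.einsum("j,cjp->p", self.model.freqs, root) / ncat
        site_l[site_l <= 0] = np.finfo(float).tiny
        return np.log(site_l) + logscale

    def total(self, tree: Tree) -> float:
        return float(self.per_pattern_lnl(tree) @ self.weights)


def _resolve(cm: CharMatrix, spec: ModelSpec) -> SubstitutionModel:
    emp = cm.empirical_freqs() if spec.empirical_freqs else None
    return spec.resolve(empirical=emp)


def log_likelihood(tree: Tree, matrix, spec: ModelSpec) -> SiteScoreVector:
    """Per-column log-likelihoods under the given model on a fixed tree."""
    cm = as_char_matrix(matrix)
    tree_taxa = set(tree.taxa())
    if not tree_taxa <= set(cm.taxa):
        raise ValueError("tree contains taxa absent from the matrix")
    if tree_taxa != set(cm.taxa):
        cm = cm.subset(sorted(tree_taxa))
    for _, _, l in tree.iter_edges_with_length():
        if l is None or l <= 0:
            raise ValueError("all branch lengths must be positive")
    engine = _PruningEngine(cm, _resolve(cm, spec), spec.rates())
    per_pat = engine.per_pattern_lnl(tree)
    values = per_pat[engine.inverse]
    if not np.isfinite(values.sum()):
        raise ValueError("non-finite log-likelihood")
    return SiteScoreVector(values, topology_id(tree), cm.matrix_id, "lnl")


# ------------------------------------------------------------- optimization

def _optimize_edge(tree: Tree, engine: _PruningEngine, u: int, v: int,
                   xatol: float = 1e-4) -> float:
    def neg(x: float) -> float:
        tree.set_length(u, v, float(x))
        return -engine.total(tree)

    res = minimize_scalar(neg, method="bounded", bounds=(MIN_BRLEN, MAX_BRLEN),
                          options={"xatol": xatol, "maxiter": 40})
    tree.set_length(u, v, float(res.x))
    return -float(res.fun)


def _optimize_all_branches(tree: Tree, engine: _PruningEngine,
                           passes: int = 2) -> float:
    best = -np.inf
    for _ in range(passes):
        for u, v in tree.edges():
            best = _optimize_edge(tree, engine, u, v)
    return best


def _optimize_alpha(tree: Tree, cm: CharMatrix, spec: ModelSpec,
                    model: SubstitutionModel) -> Tuple[float, float]:
    def neg(a: float) -> float:
        engine = _PruningEngine(cm, model, discrete_gamma_rates(a, spec.n_cat))
        return -engine.total(tree)

    res = minimize_scalar(neg, method="bounded", bounds=(0.02, 100.0),
                          options={"xatol": 1e-3, "maxiter": 30})
    return float(res.x), -float(res.fun)


def _fitch_init_lengths(tree: Tree, cm: CharMatrix) -> None:
    """Branch-length starting values from per-branch Fitch change counts."""
    scorer = _FitchScorer(cm)
    total_w = scorer.weights.sum()
    D, U, parent, children = scorer.down_up_sets(tree)
    for u, v in tree.edges():
        if parent.get(v) == u:
            child = v
        elif parent.get(u) == v:
            child = u
        else:
            child = u
        changes = float(((D[child] & U[child]) == 0) @ scorer.weights)
        tree.set_length(u, v, max(changes / total_w, 0.01))


@dataclass
class MlResult:
    tree: Tree
    site_lnl: SiteScoreVector
    alpha: float
    spec: ModelSpec

    @property
    def lnl(self) -> float:
        return self.site_lnl.total


def _nni_candidates(tree: Tree):
    """Yield (candidate, (u, v)) for both interchanges of each internal edge;
    node ids are preserved in the copies."""
    for u, v in tree.edges():
        if u in tree.labels or v in tree.labels:
            continue
        a, b = [x for x in tree.adj[u] if x != v]
        c, d = [x for x in tree.adj[v] if x != u]
        for x, y in ((b, c), (b, d)):
            t = tree.copy()
            lx, ly = t.adj[u][x], t.adj[v][y]
            t.remove_edge(u, x)
            t.remove_edge(v, y)
            t.add_edge(u, y, ly)
            t.add_edge(v, x, lx)
            yield t, (u, v)


def ml_search(matrix, spec: ModelSpec, params: Optional[SearchParams] = None,
              constraint: Optional[Tree] = None,
              start_tree: Optional[Tree] = None) -> MlResult:
    """Maximum-likelihood search.

    Starts from a parsimony tree, optimizes branch lengths and the gamma
    shape, then improves the topology by NNI passes (each candidate gets
    its central branch re-optimized) until no pass gains more than
    ``params.nni_tol`` log units.  With a constraint, incompatible
    interchanges are discarded.
    """
    params = params or SearchParams()
    cm = as_char_matrix(matrix)
    if cm.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    model = _resolve(cm, spec)
    if start_tree is None:
        mp_params = replace(params, addition_rounds=params.ml_start_rounds)
        start_trees, _ = mp_search(cm, mp_params, constraint=constraint)
        tree = start_trees[0].copy()
    else:
        tree = start_tree.copy()
    _fitch_init_lengths(tree, cm)
    alpha = spec.alpha
    engine = _PruningEngine(cm, model, discrete_gamma_rates(alpha, spec.n_cat))
    cur = _optimize_all_branches(tree, engine, params.brlen_passes)
    alpha, cur = _optimize_alpha(tree, cm, spec, model)
    engine = _PruningEngine(cm, model, discrete_gamma_rates(alpha, spec.n_cat))
    cur = engine.total(tree)

    for _ in range(params.max_nni_rounds):
        best_gain = 0.0
        best: Optional[Tree] = None
        for cand, (u, v) in _nni_candidates(tree):
            if constraint is not None and not cand.displays(constraint):
                continue
            lnl = _optimize_edge(cand, engine, u, v)
            if lnl - cur > best_gain:
                best_gain, best = lnl - cur, cand
        if best is None or best_gain <= params.nni_tol:
            break
        tree = best
        cur = _optimize_all_branches(tree, engine, 1)
        alpha, cur = _optimize_alpha(tree, cm, spec, model)
        engine = _PruningEngine(cm, model, discrete_gamma_rates(alpha, spec.n_cat))
        cur = engine.total(tree)

    cur = _optimize_all_branches(tree, engine, 1)
    fitted = replace(spec, alpha=alpha)
    site = log_likelihood(tree, cm, fitted)
    return MlResult(tree, site, alpha, fitted)


def choose_model(matrix, candidates: Sequence[ModelSpec], start_tree: Tree,
                 params: Optional[SearchParams] = None,
                 return_scores: bool = False):
    """Pick the model family maximizing the likelihood on a fixed starting
    tree (branch lengths and alpha re-optimized per candidate).  The ranking
    is independent of candidate order; all scores are logged."""
    if not candidates:
        raise ValueError("no candidate models")
    params = params or SearchParams()
    cm = as_char_matrix(matrix)
    scores: Dict[str, float] = {}
    fitted: Dict[str, ModelSpec] = {}
    for spec in candidates:
        model = _resolve(cm, spec)
        tree = start_tree.copy()
        _fitch_init_lengths(tree, cm)
        engine = _PruningEngine(cm, model, discrete_gamma_rates(spec.alpha, spec.n_cat))
        _optimize_all_branches(tree, engine, params.brlen_passes)
        alpha, lnl = _optimize_alpha(tree, cm, spec, model)
        key = spec.family + ("+F" if spec.empirical_freqs else "")
        scores[key] = lnl
        fitted[key] = replace(spec, alpha=alpha)
        log.info("model %s: lnL %.4f (alpha %.3f)", key, lnl, alpha)
    best = max(sorted(scores), key=lambda k: scores[k])
    if return_scores:
        return fitted[best], scores
    return fitted[best]
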