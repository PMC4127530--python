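"""Bootstrap replication with autoMRE bootstopping and support mapping.

Columns are resampled with replacement (partition-agnostic); each
replicate gets a fast search (one random-addition start plus NNI-only
swapping).  After every checkpoint the replicate set is split into random
halves; the weighted Robinson–Foulds distance between the halves'
majority-rule consensus trees (weights = bipartition frequencies,
normalized by the sum of the larger weights) is averaged over many splits,
and replication stops once it falls below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np

from .._seeds import stream
from ..models import ModelSpec, discrete_gamma_rates
from ..trees import Tree
from .encode import CharMatrix, as_char_matrix
from .likelihood import _PruningEngine, _fitch_init_lengths, _optimize_edge, _resolve, _nni_candidates
from .parsimony import _FitchScorer, _stepwise_addition, topology_id
from .search import SearchParams

__all__ = ["bootstrap_autoMRE", "map_support", "BootstrapResult",
           "bipartition_frequencies"]


@dataclass
class BootstrapResult:
    replicates: List[Tree]
    stopped_at: int
    converged: bool
    criterion: str

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def bipartition_frequencies(trees: Sequence[Tree]) -> Dict[FrozenSet[str], float]:
    counts: Dict[FrozenSet[str], int] = {}
    for t in trees:
        for bip in t.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    n = len(trees)
    return {b: c / n for b, c in counts.items()}


def _weighted_rf(trees_a: Sequence[Tree], trees_b: Sequence[Tree]) -> float:
    """Normalized weighted RF distance between the two halves' majority-rule
    consensus trees, using bipartition frequencies as weights."""
    fa = {b: f for b, f in bipartition_frequencies(trees_a).items() if f > 0.5}
    fb = {b: f for b, f in bipartition_frequencies(trees_b).items() if f > 0.5}
    union = set(fa) | set(fb)
    if not union:
        return 0.0
    num = sum(abs(fa.get(b, 0.0) - fb.get(b, 0.0)) for b in union)
    den = sum(max(fa.get(b, 0.0), fb.get(b, 0.0)) for b in union)
    return num / den if den > 0 else 0.0


def _nni_to_optimum_mp(tree: Tree, scorer: _FitchScorer) -> Tree:
    cur, cur_s = tree, scorer.score(tree)
    improved = True
    while improved:
        improved = False
        for cand in cur.nni_neighbors():
            s = scorer.score(cand)
            if s < cur_s:
                cur, cur_s = cand, s
                improved = True
                break
    return cur


def _fast_replicate(cm: CharMatrix, criterion: str, rng: np.random.Generator,
                    spec: Optional[ModelSpec], params: SearchParams) -> Tree:
    scorer = _FitchScorer(cm)
    rounds = 1 if params.fast_bootstrap else params.bootstrap_rounds
    best_tree, best_s = None, np.inf
    for _ in range(rounds):
        t = _stepwise_addition(cm.taxa, scorer, rng, None)
        t = _nni_to_optimum_mp(t, scorer)
        s = scorer.score(t)
        if s < best_s:
            best_tree, best_s = t, s
    tree = best_tree
    if criterion == "ml":
        model = _resolve(cm, spec)
        engine = _PruningEngine(cm, model,
                                discrete_gamma_rates(spec.alpha, spec.n_cat))
        _fitch_init_lengths(tree, cm)
        for u, v in tree.edges():
            _optimize_edge(tree, engine, u, v, xatol=1e-3)
        cur = engine.total(tree)
        improved = True
        while improved:
            improved = False
            for cand, (u, v) in _nni_candidates(tree):
                lnl = _optimize_edge(cand, engine, u, v, xatol=1e-3)
                if lnl > cur + params.nni_tol:
                    tree, cur = cand, lnl
                    improved = True
                    break
    return tree


def bootstrap_autoMRE(matrix, criterion: str = "mp",
                      spec: Optional[ModelSpec] = None,
                      params: Optional[SearchParams] = None) -> BootstrapResult:
    """Bootstrap with the autoMRE stopping rule.

    ``criterion`` is "mp" or "ml" (the latter needs a :class:`ModelSpec`).
    Replication stops at the first checkpoint where the mean half-split
    consensus distance drops below ``params.automre_threshold``, or at
    ``params.max_bootstrap`` replicates.
    """
    params = params or SearchParams()
    if criterion not in {"mp", "ml"}:
        raise ValueError("criterion must be 'mp' or 'ml'")
    if criterion == "ml" and spec is None:
        raise ValueError("ml bootstrap needs a model spec")
    cm = as_char_matrix(matrix)
    rng = stream(params.seed, f"bootstrap/{criterion}")
    split_rng = stream(params.seed, "bootstrap/splits")
    replicates: List[Tree] = []
    converged = False
    while len(replicates) < params.max_bootstrap:
        res = cm.bootstrap_resample(rng)
        replicates.append(_fast_replicate(res, criterion, rng, spec, params))
        if len(replicates) % params.automre_checkpoint == 0 and len(replicates) >= 2:
            dists = []
            n = len(replicates)
            for _ in range(params.automre_splits):
                perm = split_rng.permutation(n)
                half = n // 2
                a = [replicates[i] for i in perm[:half]]
                b = [replicates[i] for i in perm[half:2 * half]]
                dists.append(_weighted_rf(a, b))
            if float(np.mean(dists)) < params.automre_threshold:
                converged = True
                break
    return BootstrapResult(replicates, len(replicates), converged, criterion)


def map_support(best: Tree, replicates: Sequence[Tree]) -> Tree:
    """Annotate each internal branch of ``best`` with the percentage of
    replicates displaying its bipartition."""
    if not replicates:
        raise ValueError("no replicate trees")
    leafset = set(best.taxa())
    for r in replicates:
        if set(r.taxa()) != leafset:
            raise ValueError("replicate leaf set differs from the best tree")
    freqs = bipartition_frequencies(replicates)
    out = best.copy()
    out.support = {bip: 100.0 * freqs.get(bip, 0.0)
                   for bip in out.bipartitions()}
    return out
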