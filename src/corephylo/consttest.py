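"""Backbone constraints, constrained searches and paired-site tests.

A backbone constraint is a partially resolved tree over a taxon subset
built from the maximally supported bipartitions of a source analysis;
constrained searches reject candidate trees that do not display it.
Whether a constrained tree explains the data significantly worse than the
unconstrained optimum is decided by the Kishino–Hasegawa test on per-site
parsimony steps (normal approximation on site-wise differences) or by the
Shimodaira–Hasegawa test on per-site log-likelihoods with RELL resampling
and worst-case centering.  Long-branch extraction re-runs an inference
without selected taxa and compares the result against the induced subtree
of the full analysis.
"""

from __future__ import annotations

import json
import math
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from ._seeds import stream
from .models import ModelSpec
from .trees import Tree
from .treeinfer import (MlResult, SearchParams, SiteScoreVector, ml_search,
                        mp_search, parsimony_length)

__all__ = [
    "ConstraintTree",
    "PairedTestResult",
    "extract_backbone",
    "check_compatibility",
    "constrained_search",
    "kh_test_mp",
    "sh_test_rell",
    "lbe_experiment",
    "LbeReport",
]

log = logging.getLogger(__name__)


@dataclass
class ConstraintTree:
    """Partially resolved backbone over a taxon subset."""

    tree: Tree
    source: str = "supermatrix"
    threshold: float = 100.0

    @property
    def taxa(self) -> List[str]:
        return self.tree.taxa()

    def to_newick(self) -> str:
        return self.tree.to_newick(lengths=False)


@dataclass
class PairedTestResult:
    test_name: str                  # KH-MP | SH-RELL
    score_difference: float
    statistic: float
    p_value: float
    alpha: float
    candidate: str = ""

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha

    def to_json(self) -> str:
        return json.dumps({
            "test": self.test_name, "candidate": self.candidate,
            "score_difference": self.score_difference,
            "statistic": self.statistic, "p_value": self.p_value,
            "alpha": self.alpha, "significantly_worse": self.reject,
        })


def extract_backbone(tree: Tree, threshold: float = 100.0,
                     target_taxa: Optional[Sequence[str]] = None) -> ConstraintTree:
    """Backbone constraint from the maximally supported groups of a tree.

    Keeps bipartitions with support >= ``threshold``, restricted to
    ``target_taxa`` (default: all taxa); everything else is collapsed into
    polytomies.  With no qualifying branch the constraint is a star tree
    (logged).
    """
    if not tree.support:
        raise ValueError("tree carries no support values")
    target = sorted(target_taxa) if target_taxa is not None else tree.taxa()
    missing = set(target) - set(tree.labels.values())
    if missing:
        raise ValueError(f"target taxa not in tree: {sorted(missing)}")
    induced = tree.restrict(target)
    # map source support onto induced bipartitions
    common = set(target)
    ref = min(common)
    supported: Dict[frozenset, float] = {}
    full_taxa = frozenset(tree.taxa())
    for bip, sup in tree.support.items():
        side = frozenset(bip & common)
        other = frozenset(common - side)
        if len(side) < 2 or len(other) < 2:
            continue
        if ref in side:
            side = other
        supported[side] = max(supported.get(side, -np.inf), sup)
    out = induced.copy()
    while True:
        unsupported = [(u, v) for bip, (u, v) in out.bipartitions().items()
                       if supported.get(bip, -np.inf) < threshold]
        if not unsupported:
            break
        # collapse one edge at a time: node ids change under contraction
        out.collapse_edge(*unsupported[0])
    out.support = {}
    kept = len(out.bipartitions())
    if kept == 0:
        log.warning("no branch reaches support %.6g; star constraint", threshold)
    return ConstraintTree(out, threshold=threshold)


def check_compatibility(tree: Tree, constraint: ConstraintTree) -> bool:
    """True iff the tree's induced subtree on the constraint's taxa displays
    every constraint bipartition."""
    extra = set(constraint.taxa) - set(tree.labels.values())
    if extra:
        raise ValueError(f"constraint taxa missing from tree: {sorted(extra)}")
    return tree.displays(constraint.tree)


def constrained_search(matrix, constraint: ConstraintTree, criterion: str = "mp",
                       params: Optional[SearchParams] = None,
                       spec: Optional[ModelSpec] = None):
    """MP or ML search restricted to constraint-compatible trees.

    Returns ``(trees, length)`` under MP or an :class:`MlResult` under ML.
    The constrained optimum can never beat the unconstrained one.
    """
    params = params or SearchParams()
    if criterion == "mp":
        return mp_search(matrix, params, constraint=constraint.tree)
    if criterion == "ml":
        if spec is None:
            raise ValueError("ml search needs a model spec")
        return ml_search(matrix, spec, params, constraint=constraint.tree)
    raise ValueError("criterion must be 'mp' or 'ml'")


def kh_test_mp(site_steps_a: SiteScoreVector, site_steps_b: SiteScoreVector,
               alpha: float = 0.01, method: str = "normal",
               replicates: int = 1000, seed: int = 0) -> PairedTestResult:
    """Kishino–Hasegawa paired-site test on parsimony step vectors.

    The default statistic is the summed per-site step difference normalized
    by its sampling standard deviation (normal approximation, two-sided).
    ``method="rell"`` instead resamples the site differences with
    replacement and takes the two-sided proportion of centered replicate
    sums at least as extreme as the observed sum.  With identical site
    scores the difference is degenerate and p = 1.
    """
    if site_steps_a.matrix_id != site_steps_b.matrix_id:
        raise ValueError("site-score vectors come from different matrices")
    if site_steps_a.n_sites != site_steps_b.n_sites:
        raise ValueError("site-score vectors differ in length")
    if method not in {"normal", "rell"}:
        raise ValueError("method must be 'normal' or 'rell'")
    d = site_steps_a.values - site_steps_b.values
    n = len(d)
    diff = float(d.sum())
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        # degenerate: identical scores are indistinguishable (p = 1); a
        # constant nonzero difference has an unbounded statistic (p -> 0)
        stat = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    elif method == "normal":
        stat = diff / (sd * np.sqrt(n))
        p = float(2.0 * norm.sf(abs(stat)))
    else:
        rng = stream(seed, "kh-rell")
        idx = rng.integers(0, n, size=(replicates, n))
        sums = d[idx].sum(axis=1)
        centered = sums - sums.mean()
        stat = diff / (sd * np.sqrt(n))
        p = float(np.mean(np.abs(centered) >= abs(diff)))
    return PairedTestResult("KH-MP", diff, float(stat), p, alpha)


def sh_test_rell(site_lnls: Sequence[SiteScoreVector], alpha: float = 0.01,
                 replicates: int = 1000, seed: int = 0) -> List[PairedTestResult]:
    """Shimodaira–Hasegawa test with RELL resampling over candidate trees.

    Site log-likelihoods are resampled with replacement; each candidate's
    replicate totals are centered at its own mean, and the p-value for
    candidate k is the proportion of replicates in which the centered
    best-minus-k difference reaches the observed difference.  The
    maximum-likelihood candidate has p = 1 by construction.
    """
    if len(site_lnls) < 2:
        raise ValueError("need at least 2 candidate trees")
    ids = {v.matrix_id for v in site_lnls}
    if len(ids) != 1:
        raise ValueError("site-score vectors come from different matrices")
    ns = {v.n_sites for v in site_lnls}
    if len(ns) != 1:
        raise ValueError("site-score vectors differ in length")
    S = np.vstack([v.values for v in site_lnls])       # (K, n)
    totals = S.sum(axis=1)
    best = int(np.argmax(totals))
    d_obs = totals[best] - totals                      # >= 0
    n = S.shape[1]
    rng = stream(seed, "sh-rell")
    idx = rng.integers(0, n, size=(replicates, n))
    R = S[:, idx].sum(axis=2)                          # (K, B)
    Rc = R - R.mean(axis=1, keepdims=True)
    Dmax = Rc.max(axis=0)                              # (B,)
    out = []
    for k in range(S.shape[0]):
        D = Dmax - Rc[k]
        p = float(np.mean(D >= d_obs[k]))
        out.append(PairedTestResult(
            "SH-RELL", float(-d_obs[k]), float(d_obs[k]), p, alpha,
            candidate=site_lnls[k].tree_id))
    return out


@dataclass
class LbeReport:
    """Outcome of a long-branch extraction experiment."""

    dropped_taxa: List[str]
    full_tree: Tree
    reduced_tree: Tree
    induced_subtree: Tree
    rf_distance: int

    @property
    def topology_unchanged(self) -> bool:
        return self.rf_distance == 0

    def summary(self) -> str:
        return (f"dropped {','.join(self.dropped_taxa)}: RF="
                f"{self.rf_distance} ({'same' if self.topology_unchanged else 'different'})\n"
                f"reduced:  {self.reduced_tree.to_newick(lengths=False)}\n"
                f"induced:  {self.induced_subtree.to_newick(lengths=False)}")


def lbe_experiment(matrix, taxa_to_drop: Sequence[str], criterion: str = "mp",
                   params: Optional[SearchParams] = None,
                   spec: Optional[ModelSpec] = None,
                   full_tree: Optional[Tree] = None) -> LbeReport:
    """Long-branch extraction: re-infer without selected taxa and compare
    against the induced subtree of the full-data tree."""
    from .treeinfer.encode import as_char_matrix
    params = params or SearchParams()
    cm = as_char_matrix(matrix)
    drop = sorted(set(taxa_to_drop))
    missing = set(drop) - set(cm.taxa)
    if missing:
        raise ValueError(f"taxa not in matrix: {sorted(missing)}")
    remaining = [t for t in cm.taxa if t not in drop]
    if len(remaining) < 4:
        raise ValueError("fewer than 4 taxa would remain")

    def infer(sub_cm):
        if criterion == "mp":
            trees, _ = mp_search(sub_cm, params)
            return trees[0]
        if spec is None:
            raise ValueError("ml inference needs a model spec")
        return ml_search(sub_cm, spec, params).tree

    if full_tree is None:
        full_tree = infer(cm)
    if set(full_tree.taxa()) != set(cm.taxa):
        raise ValueError("full tree does not match the matrix taxa")
    reduced = infer(cm.subset(remaining))
    induced = full_tree.restrict(remaining)
    rf = reduced.rf_distance(induced)
    return LbeReport(drop, full_tree, reduced, induced, rf)
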