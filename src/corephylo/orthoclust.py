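"""Ortholog and homolog clustering.

Two graph constructions over the all-vs-all hit table, both clustered by
an internal Markov-clustering (MCL) engine:

* the ortholog graph follows the reciprocal-best-hit scheme with
  inparalog and co-ortholog edges and per-category weight normalization
  (the OrthoMCL construction);
* the homolog graph connects every pair with a significant hit, weighted
  by ``-log10`` of the better directional e-value (the TribeMCL
  construction).

Clusters containing inparalogs can be reduced to one sequence per genome
by keeping the most "central" member — the one with the highest summed
bit score against the rest of the cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .simsearch import HitTable

__all__ = [
    "ClusteringParams",
    "SequenceCluster",
    "WeightedGraph",
    "MclConvergenceError",
    "build_ortholog_graph",
    "build_homolog_graph",
    "mcl_cluster",
    "reduce_inparalogs",
    "cluster_proteomes",
]

log = logging.getLogger(__name__)

EVALUE_FLOOR = 1e-180  # keeps -log10 weights finite


@dataclass(frozen=True)
class ClusteringParams:
    inflation: float = 2.0
    evalue_threshold: float = 1e-5
    expansion: int = 2
    prune_eps: float = 1e-8
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.evalue_threshold <= 0:
            raise ValueError("e-value threshold must be positive")


@dataclass
class SequenceCluster:
    cluster_id: str
    members: List[Tuple[str, str]]          # (genome, seq_id)
    has_inparalogs: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")
        if len({sid for _, sid in self.members}) != len(self.members):
            raise ValueError("cluster members must be unique")

    @property
    def genomes(self) -> List[str]:
        return sorted({g for g, _ in self.members})

    @property
    def seq_ids(self) -> List[str]:
        return sorted(sid for _, sid in self.members)

    def __len__(self) -> int:
        return len(self.members)


class WeightedGraph:
    """Undirected weighted graph over genome-tagged sequence ids."""

    def __init__(self) -> None:
        self.node_genome: Dict[str, str] = {}
        self.edges: Dict[FrozenSet[str], float] = {}

    def add_node(self, node: str, genome: str) -> None:
        self.node_genome[node] = genome

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        if weight < 0:
            raise ValueError("weights must be non-negative")
        self.edges[frozenset((a, b))] = weight

    @property
    def nodes(self) -> List[str]:
        return sorted(self.node_genome)

    def weight(self, a: str, b: str) -> Optional[float]:
        return self.edges.get(frozenset((a, b)))

    def __len__(self) -> int:
        return len(self.node_genome)

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.edges, key=sorted):
                a, b = sorted(key)
                fh.write(f"{a}\t{b}\t{self.edges[key]:.6g}\n")


class MclConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int) -> None:
        super().__init__(
            f"MCL did not converge in {iterations} iterations "
            f"(residual {residual:.3g})")
        self.residual = residual
        self.iterations = iterations


def _neg_log10(e: float) -> float:
    return -math.log10(max(e, EVALUE_FLOOR))


def _directional_weight(hits: HitTable, a: str, b: str) -> Optional[float]:
    """Average of the two directional -log10 e-values (one if one-sided)."""
    es = [r.evalue for r in (hits.get(a, b), hits.get(b, a)) if r is not None]
    if not es:
        return None
    return float(np.mean([_neg_log10(e) for e in es]))


def build_ortholog_graph(hits: HitTable, params: Optional[ClusteringParams] = None
                         ) -> WeightedGraph:
    """Reciprocal-best-hit ortholog graph with inparalog/co-ortholog edges.

    Edge categories:

    * ortholog — cross-genome reciprocal best hits (best per target genome);
    * inparalog — within-genome reciprocal hits whose e-values beat both
      members' best cross-genome e-value;
    * co-ortholog — pairs connecting the inparalog groups of an ortholog
      pair, where any hit exists.

    Weights are averaged directional ``-log10`` e-values, normalized by the
    mean weight of the ortholog-category edges of the genome pair
    (orthologs and co-orthologs) or of the genome's inparalog edges
    (inparalogs).
    """
    params = params or ClusteringParams()
    genomes = set(hits.genome_of.values())
    if len(genomes) < 2:
        raise ValueError("hit table must span at least 2 genomes")

    graph = WeightedGraph()
    for sid, g in hits.genome_of.items():
        graph.add_node(sid, g)

    best_in_genome: Dict[Tuple[str, str], Tuple[float, float, str]] = {}
    best_cross: Dict[str, float] = {}
    for rec in hits.records():
        if rec.query == rec.subject:
            continue
        if rec.query_genome != rec.subject_genome:
            key = (rec.query, rec.subject_genome)
            cand = (rec.evalue, -rec.bit_score, rec.subject)
            if key not in best_in_genome or cand < best_in_genome[key]:
                best_in_genome[key] = cand
            if rec.evalue < best_cross.get(rec.query, math.inf):
                best_cross[rec.query] = rec.evalue

    # ortholog pairs: reciprocal per-genome best hits
    ortho_pairs: set = set()
    for (q, sg), (_, _, s) in best_in_genome.items():
        back = best_in_genome.get((s, hits.genome_of[q]))
        if back is not None and back[2] == q:
            ortho_pairs.add(frozenset((q, s)))

    # inparalog pairs: reciprocal within-genome hits beating both members'
    # best cross-genome e-value (infinite when a member has none)
    inpara_pairs: set = set()
    seen = set()
    for rec in hits.records():
        a, b = rec.query, rec.subject
        if a == b or rec.query_genome != rec.subject_genome:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        fwd, back = hits.get(a, b), hits.get(b, a)
        if fwd is None or back is None:
            continue
        if (fwd.evalue <= best_cross.get(a, math.inf)
                and back.evalue <= best_cross.get(b, math.inf)):
            inpara_pairs.add(key)

    partners: Dict[str, set] = {}
    for key in inpara_pairs:
        a, b = tuple(key)
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    # co-ortholog pairs between the inparalog groups of each ortholog pair
    coortho_pairs: set = set()
    for key in ortho_pairs:
        a, b = tuple(key)
        ga = {a} | partners.get(a, set())
        gb = {b} | partners.get(b, set())
        for x in ga:
            for y in gb:
                pk = frozenset((x, y))
                if pk in ortho_pairs or len(pk) == 1:
                    continue
                if hits.get(x, y) is not None or hits.get(y, x) is not None:
                    coortho_pairs.add(pk)

    # raw weights, then per-category normalization
    def genome_pair(key: FrozenSet[str]) -> FrozenSet[str]:
        a, b = tuple(key)
        return frozenset((hits.genome_of[a], hits.genome_of[b]))

    raw: Dict[FrozenSet[str], float] = {}
    for key in ortho_pairs | coortho_pairs | inpara_pairs:
        a, b = tuple(key)
        w = _directional_weight(hits, a, b)
        if w is not None:
            raw[key] = w

    ortho_means: Dict[FrozenSet[str], float] = {}
    for gp in {genome_pair(k) for k in ortho_pairs if k in raw}:
        ws = [raw[k] for k in ortho_pairs if k in raw and genome_pair(k) == gp]
        ortho_means[gp] = float(np.mean(ws)) if ws else 0.0
    inpara_means: Dict[str, float] = {}
    for g in genomes:
        ws = [raw[k] for k in inpara_pairs
              if k in raw and hits.genome_of[next(iter(k))] == g]
        if ws:
            inpara_means[g] = float(np.mean(ws))

    for key, w in raw.items():
        if key in inpara_pairs:
            mean = inpara_means.get(hits.genome_of[next(iter(key))], 0.0)
        else:
            mean = ortho_means.get(genome_pair(key), 0.0)
        a, b = tuple(key)
        graph.add_edge(a, b, w / mean if mean > 0 else w)
    return graph


def build_homolog_graph(hits: HitTable, params: Optional[ClusteringParams] = None
                        ) -> WeightedGraph:
    """All-pairs homolog graph: edge when the better directional e-value
    passes the threshold, weighted by its ``-log10``; no normalization."""
    params = params or ClusteringParams()
    if len(set(hits.genome_of.values())) < 2:
        raise ValueError("hit table must span at least 2 genomes")
    graph = WeightedGraph()
    for sid, g in hits.genome_of.items():
        graph.add_node(sid, g)
    seen = set()
    for rec in hits.records():
        a, b = rec.query, rec.subject
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        best = hits.best_mutual_evalue(a, b)
        if best is not None and best <= params.evalue_threshold:
            graph.add_edge(a, b, _neg_log10(best))
    return graph


def mcl_cluster(graph: WeightedGraph, params: Optional[ClusteringParams] = None
                ) -> List[SequenceCluster]:
    """Markov clustering of a weighted graph.

    Iterates expansion (matrix power), inflation (entrywise power plus
    column renormalization) and pruning until the column-stochastic matrix
    changes by less than ``tol``; clusters are the connected components of
    the converged matrix's support.  Self-loops are set to each node's
    maximum incident weight (its own weight scale) before normalization.
    """
    params = params or ClusteringParams()
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    max_inc = np.zeros(n)
    for key, w in graph.edges.items():
        a, b = tuple(key)
        i, j = idx[a], idx[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        max_inc[i] = max(max_inc[i], w)
        max_inc[j] = max(max_inc[j], w)
    loops = np.where(max_inc > 0, max_inc, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loops)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def normalize(m: sp.csr_matrix) -> sp.csr_matrix:
        colsum = np.asarray(m.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return (m @ sp.diags(1.0 / colsum)).tocsr()

    M = normalize(M)
    residual = math.inf
    for _ in range(params.max_iter):
        prev = M.copy()
        for _ in range(params.expansion - 1):
            M = (M @ M).tocsr()
        M.data = np.power(M.data, params.inflation)
        M = normalize(M)
        M.data[M.data < params.prune_eps] = 0.0
        M.eliminate_zeros()
        M = normalize(M)
        residual = abs(M - prev).max()
        if residual < params.tol:
            break
    else:
        raise MclConvergenceError(residual, params.max_iter)

    n_comp, labels = connected_components(M + M.T, directed=False)
    groups: Dict[int, List[str]] = {}
    for v, lab in zip(nodes, labels):
        groups.setdefault(int(lab), []).append(v)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), sorted(ms)))
    out = []
    for k, members in enumerate(ordered):
        tagged = sorted((graph.node_genome[m], m) for m in members)
        genomes = [g for g, _ in tagged]
        out.append(SequenceCluster(f"cluster{k + 1:05d}", tagged,
                                   has_inparalogs=len(set(genomes)) < len(genomes)))
    return out


def reduce_inparalogs(cluster: SequenceCluster, hits: HitTable) -> SequenceCluster:
    """Keep one sequence per genome: the member with the highest summed bit
    score against all other cluster members.  Ties keep the
    lexicographically smallest id (logged).  Idempotent."""
    if not cluster.has_inparalogs:
        return cluster
    members = cluster.members
    all_ids = [sid for _, sid in members]
    by_genome: Dict[str, List[str]] = {}
    for g, sid in members:
        by_genome.setdefault(g, []).append(sid)
    kept: List[Tuple[str, str]] = []
    for g, sids in sorted(by_genome.items()):
        if len(sids) == 1:
            kept.append((g, sids[0]))
            continue
        scored = []
        for sid in sids:
            total = 0.0
            n_missing = 0
            for other in all_ids:
                if other == sid:
                    continue
                rec = hits.get(sid, other) or hits.get(other, sid)
                if rec is None:
                    n_missing += 1
                else:
                    total += rec.bit_score
            if n_missing:
                log.warning("cluster %s: %d missing hits for %s; centrality "
                            "over available hits", cluster.cluster_id,
                            n_missing, sid)
            scored.append((total, sid))
        best_score = max(t for t, _ in scored)
        winners = sorted(sid for t, sid in scored if t == best_score)
        if len(winners) > 1:
            log.warning("cluster %s genome %s: centrality tie between %s; "
                        "keeping %s", cluster.cluster_id, g, winners, winners[0])
        kept.append((g, winners[0]))
    return SequenceCluster(cluster.cluster_id, sorted(kept), has_inparalogs=False)


def cluster_proteomes(hits: HitTable, params: Optional[ClusteringParams] = None,
                      mode: str = "ortholog") -> List[SequenceCluster]:
    """Graph construction plus MCL in one call (``mode`` ortholog|homolog)."""
    params = params or ClusteringParams()
    if mode == "ortholog":
        graph = build_ortholog_graph(hits, params)
    elif mode == "homolog":
        graph = build_homolog_graph(hits, params)
    else:
        raise ValueError("mode must be 'ortholog' or 'homolog'")
    return mcl_cluster(graph, params)


def write_clusters_tsv(clusters: List[SequenceCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            for g, sid in c.members:
                fh.write(f"{c.cluster_id}\t{g}\t{sid}\n")
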