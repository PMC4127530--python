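"""End-to-end orchestration: proteomes to character matrices.

Chains the stages in their canonical order — all-vs-all search, ortholog
and homolog clustering, inparalog reduction, per-cluster alignment with
orphan-row and conserved-block filtering, gene-set selection and matrix
assembly — and returns every intermediate product so any stage can be
inspected or re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .alignfilter import (BlockFilterParams, Msa, drop_orphan_rows,
                          filter_conserved_blocks, gene_information_content,
                          progressive_align)
from .matrices import (BinaryMatrix, GeneSet, Supermatrix,
                       build_content_matrix, concatenate_supermatrix,
                       reduce_supermatrix, select_gene_sets)
from .orthoclust import (ClusteringParams, SequenceCluster,
                         build_homolog_graph, build_ortholog_graph,
                         mcl_cluster, reduce_inparalogs)
from .simsearch import HitTable, ScoringScheme, all_vs_all

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    hits: HitTable
    ortholog_clusters: List[SequenceCluster]
    homolog_clusters: List[SequenceCluster]
    reduced_clusters: List[SequenceCluster]
    alignments: Dict[str, Msa]              # cluster id -> filtered alignment
    gene_scores: Dict[str, float]
    core_set: GeneSet
    full_set: GeneSet
    core_supermatrix: Supermatrix
    full_supermatrix: Supermatrix
    filtered_supermatrix: Supermatrix
    ortholog_content: BinaryMatrix
    gene_content: BinaryMatrix


def run_pipeline(proteomes: Dict[str, Dict[str, str]],
                 scheme: Optional[ScoringScheme] = None,
                 clustering: Optional[ClusteringParams] = None,
                 block_params: Optional[BlockFilterParams] = None,
                 orphan_floor: float = 0.25,
                 filter_quantile: float = 0.5,
                 min_align: int = 4,
                 seed: int = 0) -> PipelineResult:
    """Run the full matrix-building pipeline on a set of proteomes.

    ``min_align`` is the minimum cluster size that gets aligned (smaller
    clusters can never enter a gene set).  Column filtering uses the block
    filter's defaults unless overridden.
    """
    scheme = scheme or ScoringScheme()
    clustering = clustering or ClusteringParams()
    genomes = sorted(proteomes)
    seqs = {sid: s for d in proteomes.values() for sid, s in d.items()}

    hits = all_vs_all(proteomes, scheme, e_cutoff=clustering.evalue_threshold)
    log.info("all-vs-all: %d retained hits", len(hits))

    ortho_graph = build_ortholog_graph(hits, clustering)
    ortholog_clusters = mcl_cluster(ortho_graph, clustering)
    homolog_clusters = mcl_cluster(build_homolog_graph(hits, clustering),
                                   clustering)
    log.info("clusters: %d ortholog, %d homolog",
             len(ortholog_clusters), len(homolog_clusters))

    reduced = [reduce_inparalogs(c, hits) for c in ortholog_clusters]

    alignments: Dict[str, Msa] = {}
    gene_scores: Dict[str, float] = {}
    for c in reduced:
        if len(c) < min_align:
            continue
        named = {g: seqs[sid] for g, sid in c.members}
        aln = progressive_align(named)
        aln = drop_orphan_rows(aln, orphan_floor)
        aln, _ = filter_conserved_blocks(aln, block_params)
        if aln.n_cols == 0:
            log.info("cluster %s: no columns survive filtering", c.cluster_id)
            continue
        alignments[c.cluster_id] = aln
        gene_scores[c.cluster_id] = gene_information_content(aln, seed=seed)

    usable = [c for c in reduced if c.cluster_id in alignments]
    core_set, full_set = select_gene_sets(usable, genomes)
    core_sm = concatenate_supermatrix(alignments, core_set, genomes)
    full_sm = concatenate_supermatrix(alignments, full_set, genomes)
    filtered_sm = reduce_supermatrix(full_sm, gene_scores,
                                     quantile=filter_quantile)
    ortho_content = build_content_matrix(ortholog_clusters, genomes, "ortholog")
    gene_content = build_content_matrix(homolog_clusters, genomes, "homolog")
    return PipelineResult(hits, ortholog_clusters, homolog_clusters, reduced,
                          alignments, gene_scores, core_set, full_set,
                          core_sm, full_sm, filtered_sm,
                          ortho_content, gene_content)
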