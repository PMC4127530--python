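"""Character-matrix assembly.

Builds the five matrix variants of a gene-content/supermatrix phylogenomic
study: the core-gene supermatrix (clusters present in every genome), the
full supermatrix (alignments with at least four sequences), the
information-filtered supermatrix, and the binary ortholog-content and
gene-content matrices (presence/absence of a cluster per genome).  Also
computes genomic G+C from nucleotide sequences.

Supermatrices carry an exact partition map from gene to column range and
use '?' for a genome absent from a gene (fully ambiguous under both
parsimony and likelihood).  Writers cover relaxed PHYLIP, aligned FASTA
and NEXUS with character sets, plus RAxML-style partition files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .alignfilter import Msa
from .orthoclust import SequenceCluster

__all__ = [
    "GeneSet",
    "Supermatrix",
    "BinaryMatrix",
    "select_gene_sets",
    "concatenate_supermatrix",
    "reduce_supermatrix",
    "build_content_matrix",
    "gc_content",
]

MISSING = "?"


@dataclass
class GeneSet:
    cluster_ids: List[str]
    rule: str                     # core | min4 | filtered | preselected

    def __post_init__(self) -> None:
        if not self.cluster_ids:
            raise ValueError("gene set must be non-empty")
        if self.rule not in {"core", "min4", "filtered", "preselected"}:
            raise ValueError(f"unknown selection rule {self.rule!r}")

    def __len__(self) -> int:
        return len(self.cluster_ids)

    def __contains__(self, cid: str) -> bool:
        return cid in self.cluster_ids


@dataclass
class Supermatrix:
    """Concatenated alignment over genomes with a gene partition map."""

    taxa: List[str]
    rows: Dict[str, str]
    partitions: Dict[str, Tuple[int, int]]   # gene -> [start, end)
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("all rows must have the full matrix width")
        if set(self.taxa) != set(self.rows):
            raise ValueError("taxa and rows must correspond")
        spans = sorted(self.partitions.values())
        pos = 0
        for s, e in spans:
            if s != pos:
                raise ValueError("partitions must tile the columns")
            pos = e
        if self.rows and spans and pos != self.n_cols:
            raise ValueError("partitions must cover the matrix width")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def genes(self) -> List[str]:
        return sorted(self.partitions, key=lambda g: self.partitions[g])

    def gene_slice(self, gene: str) -> "Msa":
        s, e = self.partitions[gene]
        return Msa(list(self.taxa), [self.rows[t][s:e] for t in self.taxa],
                   self.alphabet)

    def to_msa(self) -> Msa:
        return Msa(list(self.taxa), [self.rows[t] for t in self.taxa],
                   self.alphabet)

    # ------------------------------------------------------------------ IO

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.n_cols}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.rows[t]}\n")

    @classmethod
    def read_phylip(cls, path, partitions: Optional[Dict[str, Tuple[int, int]]] = None,
                    alphabet: str = "aa") -> "Supermatrix":
        with open(path) as fh:
            header = fh.readline().split()
            ntax, ncols = int(header[0]), int(header[1])
            rows = {}
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                rows[name] = seq.strip()
        if len(rows) != ntax or any(len(r) != ncols for r in rows.values()):
            raise ValueError("malformed relaxed PHYLIP file")
        parts = partitions or {"all": (0, ncols)}
        return cls(sorted(rows), rows, parts, alphabet)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.rows[t]}\n")

    @classmethod
    def read_fasta(cls, path, partitions: Optional[Dict[str, Tuple[int, int]]] = None,
                   alphabet: str = "aa") -> "Supermatrix":
        msa = Msa.read_fasta(path, alphabet)
        rows = dict(zip(msa.ids, msa.rows))
        parts = partitions or {"all": (0, msa.n_cols)}
        return cls(sorted(rows), rows, parts, alphabet)

    def write_nexus(self, path) -> None:
        dt = {"aa": "protein", "nt": "dna", "binary": "standard"}[self.alphabet]
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(f"  dimensions ntax={self.n_taxa} nchar={self.n_cols};\n")
            fh.write(f"  format datatype={dt} missing=? gap=-;\n  matrix\n")
            for t in self.taxa:
                fh.write(f"    {t}  {self.rows[t]}\n")
            fh.write("  ;\nend;\nbegin sets;\n")
            for g in self.genes:
                s, e = self.partitions[g]
                fh.write(f"  charset {g} = {s + 1}-{e};\n")
            fh.write("end;\n")

    def write_partition_file(self, path, model: str = "LG") -> None:
        """RAxML-style partition text: ``MODEL, gene = start-end`` (1-based)."""
        with open(path, "w") as fh:
            for g in self.genes:
                s, e = self.partitions[g]
                fh.write(f"{model}, {g} = {s + 1}-{e}\n")


@dataclass
class BinaryMatrix:
    """Genomes x clusters presence/absence characters."""

    taxa: List[str]
    data: np.ndarray                # int8, shape (n_taxa, n_cols)
    column_ids: List[str]
    provenance: str = "ortholog-content"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.taxa), len(self.column_ids)):
            raise ValueError("data shape must be (n_taxa, n_columns)")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("states must be 0/1")

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.n_cols}\n")
            for i, t in enumerate(self.taxa):
                fh.write(f"{t}  {''.join(str(x) for x in self.data[i])}\n")

    @classmethod
    def read_phylip(cls, path, provenance: str = "ortholog-content") -> "BinaryMatrix":
        with open(path) as fh:
            ntax, ncols = map(int, fh.readline().split())
            taxa, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                taxa.append(name)
                rows.append([int(c) for c in seq.strip()])
        data = np.array(rows, dtype=np.int8) if rows else np.zeros((0, ncols), np.int8)
        cols = [f"char{i + 1:05d}" for i in range(ncols)]
        return cls(taxa, data, cols, provenance)


# -------------------------------------------------------------- operations

def select_gene_sets(clusters: Sequence[SequenceCluster], genomes: Sequence[str],
                     min_full: int = 4) -> Tuple[GeneSet, GeneSet]:
    """Core (all genomes represented) and full (>= 4 sequences) gene sets."""
    genomes = set(genomes)
    core, full = [], []
    for c in clusters:
        if len(c) >= min_full:
            full.append(c.cluster_id)
        if set(c.genomes) >= genomes:
            core.append(c.cluster_id)
    if not core or not full:
        raise ValueError("empty gene set; too few clusters")
    return GeneSet(sorted(core), "core"), GeneSet(sorted(full), "min4")


def concatenate_supermatrix(alignments: Dict[str, Msa], gene_set: GeneSet,
                            genomes: Sequence[str], alphabet: str = "aa"
                            ) -> Supermatrix:
    """Concatenate per-gene alignments (rows identified by genome).

    Gene order is canonicalized by cluster id; a genome absent from a gene
    is filled with '?' across that gene's range.
    """
    taxa = sorted(genomes)
    parts: Dict[str, Tuple[int, int]] = {}
    chunks: Dict[str, List[str]] = {t: [] for t in taxa}
    pos = 0
    for gene in sorted(gene_set.cluster_ids):
        aln = alignments[gene]
        if len(set(aln.ids)) != len(aln.ids):
            raise ValueError(f"gene {gene}: duplicate genome rows "
                             "(inparalog reduction missed)")
        unknown = set(aln.ids) - set(taxa)
        if unknown:
            raise ValueError(f"gene {gene}: rows for unknown genomes {sorted(unknown)}")
        w = aln.n_cols
        lookup = dict(zip(aln.ids, aln.rows))
        for t in taxa:
            chunks[t].append(lookup.get(t, MISSING * w))
        parts[gene] = (pos, pos + w)
        pos += w
    rows = {t: "".join(chunks[t]) for t in taxa}
    return Supermatrix(taxa, rows, parts, alphabet)


def reduce_supermatrix(sm: Supermatrix, scores: Dict[str, float],
                       threshold: Optional[float] = None,
                       quantile: float = 0.5) -> Supermatrix:
    """Keep genes whose informativeness score reaches the threshold
    (default: the given quantile of the scores).  Taxa are never removed."""
    missing = set(sm.partitions) - set(scores)
    if missing:
        raise ValueError(f"unscored genes: {sorted(missing)}")
    vals = [scores[g] for g in sm.partitions]
    if threshold is None:
        threshold = float(np.quantile(vals, quantile))
    keep = [g for g in sm.genes if scores[g] >= threshold]
    if not keep:
        raise ValueError("threshold removes every gene")
    parts: Dict[str, Tuple[int, int]] = {}
    chunks: Dict[str, List[str]] = {t: [] for t in sm.taxa}
    pos = 0
    for g in keep:
        s, e = sm.partitions[g]
        for t in sm.taxa:
            chunks[t].append(sm.rows[t][s:e])
        parts[g] = (pos, pos + (e - s))
        pos += e - s
    rows = {t: "".join(chunks[t]) for t in sm.taxa}
    return Supermatrix(list(sm.taxa), rows, parts, sm.alphabet)


def build_content_matrix(clusters: Sequence[SequenceCluster],
                         genomes: Sequence[str], mode: str = "ortholog",
                         min_genomes: int = 2) -> BinaryMatrix:
    """Presence/absence matrix over clusters (copy number ignored).

    Columns are clusters represented in at least ``min_genomes`` genomes
    (singleton-cluster columns are parsimony-uninformative; set
    ``min_genomes=1`` to keep them).
    """
    if mode not in {"ortholog", "homolog"}:
        raise ValueError("mode must be 'ortholog' or 'homolog'")
    taxa = sorted(genomes)
    tidx = {t: i for i, t in enumerate(taxa)}
    cols = []
    vectors = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        present = sorted({g for g in c.genomes if g in tidx})
        if len(present) < min_genomes:
            continue
        v = np.zeros(len(taxa), dtype=np.int8)
        for g in present:
            v[tidx[g]] = 1
        cols.append(c.cluster_id)
        vectors.append(v)
    data = np.column_stack(vectors) if vectors else np.zeros((len(taxa), 0), np.int8)
    return BinaryMatrix(taxa, data, cols, provenance=f"{mode}-content")


def gc_content(source: Union[str, Iterable[str]]) -> float:
    """Genomic G+C as a percentage, 100*(G+C)/(A+C+G+T) over all contigs.

    ``source`` is a FASTA path or an iterable of nucleotide strings.
    Ambiguity codes are excluded from numerator and denominator.  Reported
    to two decimals.
    """
    if isinstance(source, str):
        seqs: List[str] = []
        with open(source) as fh:
            cur: List[str] = []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if cur:
                        seqs.append("".join(cur))
                        cur = []
                elif line:
                    cur.append(line)
            if cur:
                seqs.append("".join(cur))
    else:
        seqs = list(source)
    gc = at = 0
    for seq in seqs:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases; G+C undefined")
    return round(100.0 * gc / (gc + at), 2)
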