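"""Per-cluster multiple alignment and alignment filtering.

The alignment stage is a deterministic progressive aligner: a UPGMA guide
tree from k-mer distances, then profile–profile global alignment with
affine gaps (Gotoh recurrences, sum-of-pairs column scores under
BLOSUM62).  Filtering removes orphan rows (low mean pairwise identity)
and poorly aligned columns via a conserved-block algorithm: columns are
classified non-conserved / conserved / highly conserved by identity
thresholds, long non-conserved stretches are rejected, surviving blocks
are trimmed to highly conserved flanks, short blocks and gap-containing
columns are dropped.

``gene_information_content`` scores a gene's phylogenetic signal as the
fraction of resolved quartets under site-wise parsimony support — the
score used for information-based supermatrix reduction (a documented
simplification of quartet-mapping matrix reduction, not equivalent to it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._seeds import stream

__all__ = [
    "Msa",
    "BlockFilterParams",
    "progressive_align",
    "drop_orphan_rows",
    "filter_conserved_blocks",
    "gene_information_content",
]

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Msa:
    """Ordered multiple alignment; all rows equal length, gap symbol '-'."""

    ids: List[str]
    rows: List[str]
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]

    def select_columns(self, cols: Sequence[int]) -> "Msa":
        return Msa(list(self.ids),
                   ["".join(r[c] for c in cols) for r in self.rows],
                   self.alphabet)

    def select_rows(self, keep: Sequence[int]) -> "Msa":
        return Msa([self.ids[i] for i in keep],
                   [self.rows[i] for i in keep], self.alphabet)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    @classmethod
    def read_fasta(cls, path, alphabet: str = "aa") -> "Msa":
        ids, rows, cur = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if cur:
                        rows.append("".join(cur))
                        cur = []
                    ids.append(line[1:].split()[0])
                elif line:
                    cur.append(line)
        if cur:
            rows.append("".join(cur))
        return cls(ids, rows, alphabet)


# ------------------------------------------------------------------ aligner

_BLOSUM = None


def _blosum() -> Tuple[np.ndarray, Dict[str, int]]:
    global _BLOSUM
    if _BLOSUM is None:
        m = substitution_matrices.load("BLOSUM62")
        letters = "ARNDCQEGHILKMFPSTWYVX"
        idx = {c: i for i, c in enumerate(letters)}
        B = np.zeros((len(letters), len(letters)))
        for a in letters:
            for b in letters:
                B[idx[a], idx[b]] = m[a, b]
        _BLOSUM = (B, idx)
    return _BLOSUM


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    sa = {a[i:i + k] for i in range(max(len(a) - k + 1, 1))}
    sb = {b[i:i + k] for i in range(max(len(b) - k + 1, 1))}
    shared = len(sa & sb)
    denom = min(len(sa), len(sb)) or 1
    return 1.0 - shared / denom


def _profile(msa_rows: List[str], idx: Dict[str, int]) -> np.ndarray:
    """(L, k) residue frequency profile; gaps contribute nothing."""
    k = len(idx)
    L = len(msa_rows[0])
    P = np.zeros((L, k))
    for row in msa_rows:
        for j, c in enumerate(row):
            if c != GAP:
                P[j, idx.get(c, idx["X"])] += 1.0
    occ = P.sum(axis=1, keepdims=True)
    occ[occ == 0] = 1.0
    return P / occ


def _gotoh_profiles(p1: np.ndarray, p2: np.ndarray, B: np.ndarray,
                    gap_open: float, gap_extend: float
                    ) -> List[Tuple[int, int]]:
    """Global affine-gap profile alignment; returns the aligned path.

    Path entries are (i, j) with -1 marking a gap in that profile.  A gap
    of length k costs ``gap_open + (k-1) * gap_extend``.
    """
    n, m = len(p1), len(p2)
    S = p1 @ B @ p2.T                     # (n, m) column-vs-column scores
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)      # gap in p2 (vertical)
    Y = np.full((n + 1, m + 1), NEG)      # gap in p1 (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        M[i, 1:] = np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1],
                                      Y[i - 1, :-1]]) + S[i - 1, :]
        X[i, 1:] = np.maximum(M[i - 1, 1:] - gap_open,
                              X[i - 1, 1:] - gap_extend)
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        # horizontal pass needs the in-row scan
        best = np.maximum(M[i, :-1], X[i, :-1]) - gap_open
        run = Y[i, 0]
        for j in range(1, m + 1):
            run = max(run - gap_extend, best[j - 1])
            Y[i, j] = run
    # traceback
    path: List[Tuple[int, int]] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            path.append((i - 1, j - 1))
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            path.append((i - 1, -1))
            if not math.isclose(X[i, j], X[i - 1, j] - gap_extend,
                                rel_tol=0, abs_tol=1e-9):
                state = 0
            i -= 1
        else:
            path.append((-1, j - 1))
            if not math.isclose(Y[i, j], Y[i, j - 1] - gap_extend,
                                rel_tol=0, abs_tol=1e-9):
                state = int(np.argmax([M[i, j - 1], X[i, j - 1]]))
            j -= 1
    path.reverse()
    return path


def _merge(rows1: List[str], rows2: List[str], path) -> Tuple[List[str], List[str]]:
    out1 = ["" for _ in rows1]
    out2 = ["" for _ in rows2]
    for i, j in path:
        for r, row in enumerate(rows1):
            out1[r] += row[i] if i >= 0 else GAP
        for r, row in enumerate(rows2):
            out2[r] += row[j] if j >= 0 else GAP
    return out1, out2


def progressive_align(sequences: Dict[str, str], gap_open: float = 10.0,
                      gap_extend: float = 1.0) -> Msa:
    """Progressive multiple alignment (UPGMA guide tree from k-mer
    distances, profile–profile Gotoh merges).  Deterministic.

    With two sequences this reduces to plain global pairwise alignment
    under the same scoring.  A single sequence is returned as-is.
    """
    items = sorted(sequences.items())
    ids = [sid for sid, _ in items]
    seqs = [s.upper() for _, s in items]
    if len(ids) == 0:
        raise ValueError("no sequences")
    if len(ids) == 1:
        log.warning("progressive_align called with a single sequence")
        return Msa(ids, seqs)
    B, idx = _blosum()
    if len(ids) == 2:
        path = _gotoh_profiles(_profile([seqs[0]], idx), _profile([seqs[1]], idx),
                               B, gap_open, gap_extend)
        r1, r2 = _merge([seqs[0]], [seqs[1]], path)
        return Msa(ids, [r1[0], r2[0]])
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        D[i, j] = D[j, i] = _kmer_distance(seqs[i], seqs[j])
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: Dict[int, Tuple[List[int], List[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)}
    nxt = n
    for a, b, _, _ in Z:
        ia, ra = clusters.pop(int(a))
        ib, rb = clusters.pop(int(b))
        path = _gotoh_profiles(_profile(ra, idx), _profile(rb, idx),
                               B, gap_open, gap_extend)
        ma, mb = _merge(ra, rb, path)
        clusters[nxt] = (ia + ib, ma + mb)
        nxt += 1
    (order, rows), = clusters.values()
    # restore input row order
    pos = {seq_i: r for r, seq_i in enumerate(order)}
    return Msa(ids, [rows[pos[i]] for i in range(n)])


# ----------------------------------------------------------------- orphans

def pairwise_identity(a: str, b: str) -> float:
    """Identity over columns where both rows are non-gap (0 if none)."""
    both = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


def drop_orphan_rows(aln: Msa, identity_floor: float = 0.25) -> Msa:
    """Remove rows whose mean pairwise identity to the rest is below the
    floor.  If removal would leave fewer than 4 rows, nothing is removed."""
    n = aln.n_rows
    if n <= 4:
        return aln
    means = []
    for i in range(n):
        vals = [pairwise_identity(aln.rows[i], aln.rows[j])
                for j in range(n) if j != i]
        means.append(float(np.mean(vals)))
    keep = [i for i in range(n) if means[i] >= identity_floor]
    if len(keep) == n:
        return aln
    if len(keep) < 4:
        log.warning("orphan removal would leave %d rows; skipping", len(keep))
        return aln
    return aln.select_rows(keep)


# ------------------------------------------------------------ block filter

@dataclass(frozen=True)
class BlockFilterParams:
    """Thresholds of the conserved-block column filter.

    ``None`` thresholds resolve to the published defaults for ``n`` rows:
    conserved = floor(n/2)+1, flank = ceil(0.85 n), at most 8 contiguous
    non-conserved positions, minimum block length 10, no gap columns.
    """

    min_conserved: Optional[int] = None
    min_flank: Optional[int] = None
    max_noncontiguous: int = 8
    min_block: int = 10
    allow_gaps: bool = False

    def resolved(self, n_rows: int) -> Tuple[int, int]:
        cons = self.min_conserved if self.min_conserved is not None \
            else n_rows // 2 + 1
        flank = self.min_flank if self.min_flank is not None \
            else math.ceil(0.85 * n_rows)
        if cons < n_rows // 2 + 1:
            raise ValueError("conserved threshold must exceed half the rows")
        if flank < cons:
            raise ValueError("flank threshold must be >= conserved threshold")
        return cons, flank


def filter_conserved_blocks(aln: Msa, params: Optional[BlockFilterParams] = None
                            ) -> Tuple[Msa, List[int]]:
    """Conserved-block column filter; returns the filtered alignment and the
    surviving original column indices."""
    params = params or BlockFilterParams()
    n = aln.n_rows
    cons_t, flank_t = params.resolved(n)
    L = aln.n_cols
    NC, C, HC = 0, 1, 2
    status = np.empty(L, dtype=int)
    gapcol = np.zeros(L, dtype=bool)
    for j in range(L):
        col = [r[j] for r in aln.rows]
        n_gap = col.count(GAP)
        if n_gap and not params.allow_gaps:
            gapcol[j] = True
        counts: Dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        top = max(counts.values()) if counts else 0
        if top >= flank_t and not gapcol[j]:
            status[j] = HC
        elif top >= cons_t and not gapcol[j]:
            status[j] = C
        else:
            status[j] = NC

    # 1) reject stretches of > max contiguous non-conserved columns
    removed = np.zeros(L, dtype=bool)
    j = 0
    while j < L:
        if status[j] == NC:
            k = j
            while k < L and status[k] == NC:
                k += 1
            if k - j > params.max_noncontiguous:
                removed[j:k] = True
            j = k
        else:
            j += 1

    # 2) split into candidate blocks, trim each to highly conserved flanks
    kept: List[int] = []
    j = 0
    while j < L:
        if removed[j]:
            j += 1
            continue
        k = j
        while k < L and not removed[k]:
            k += 1
        block = list(range(j, k))
        while block and status[block[0]] != HC:
            block.pop(0)
        while block and status[block[-1]] != HC:
            block.pop()
        # 3) drop short blocks; 4) drop gap columns inside surviving blocks
        if len(block) >= params.min_block:
            kept.extend(c for c in block if not gapcol[c])
        j = k

    if not kept:
        log.warning("block filter removed every column")
        return Msa(list(aln.ids), ["" for _ in aln.rows], aln.alphabet), []
    return aln.select_columns(kept), kept


# ---------------------------------------------------- gene informativeness

def gene_information_content(aln: Msa, max_quartets: int = 500,
                             seed: int = 0) -> float:
    """Fraction of resolved quartets under site-wise parsimony support.

    For each sampled 4-row subset {i,j,k,l}, each alignment column with
    four residues votes for the quartet topology it supports (two equal
    pairs of distinct states); the quartet is resolved if one topology
    strictly outvotes the other two.  Returns resolved / sampled in [0,1].
    """
    n = aln.n_rows
    if n < 4:
        raise ValueError("informativeness undefined for fewer than 4 rows")
    if aln.n_cols == 0:
        return 0.0
    codes = np.array([[ord(c) for c in row] for row in aln.rows])
    gap = ord(GAP)
    quartets = list(combinations(range(n), 4))
    if len(quartets) > max_quartets:
        rng = stream(seed, "quartet-sample")
        pick = rng.choice(len(quartets), size=max_quartets, replace=False)
        quartets = [quartets[p] for p in sorted(pick)]
    resolved = 0
    for i, j, k, l in quartets:
        a, b, c, d = codes[i], codes[j], codes[k], codes[l]
        ok = (a != gap) & (b != gap) & (c != gap) & (d != gap)
        t1 = ((a == b) & (c == d) & (a != c) & ok).sum()   # ij|kl
        t2 = ((a == c) & (b == d) & (a != b) & ok).sum()   # ik|jl
        t3 = ((a == d) & (b == c) & (a != b) & ok).sum()   # il|jk
        votes = sorted([int(t1), int(t2), int(t3)], reverse=True)
        if votes[0] > votes[1]:
            resolved += 1
    return resolved / len(quartets)
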