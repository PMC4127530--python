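"""Character-matrix encoding shared by the parsimony and likelihood engines.

Characters are encoded as small integers with -1 for missing ('?' and '-'
are equivalent; letters outside the state alphabet, e.g. amino-acid
ambiguity codes, are treated as missing).  Identical columns are
compressed to site patterns with weights, which both engines exploit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ..models import AA_ORDER, NT_ORDER

__all__ = ["CharMatrix", "SiteScoreVector"]

_ALPHABETS = {"aa": AA_ORDER, "nt": NT_ORDER, "binary": "01"}


@dataclass
class SiteScoreVector:
    """Per-column scores (parsimony steps or log-likelihoods) plus provenance."""

    values: np.ndarray
    tree_id: str
    matrix_id: str
    kind: str                     # "steps" | "lnl"

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} tree={self.tree_id} "
                     f"matrix={self.matrix_id} total={self.total:.6f}\n")
            for i, v in enumerate(self.values):
                fh.write(f"{i + 1}\t{v:.6f}\n")


class CharMatrix:
    """Encoded taxa-by-characters matrix with site-pattern compression."""

    def __init__(self, taxa: Sequence[str], codes: np.ndarray, alphabet: str):
        if alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        self.taxa = list(taxa)
        self.codes = np.asarray(codes, dtype=np.int16)
        self.alphabet = alphabet
        self.states = _ALPHABETS[alphabet]
        if self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must have one row per taxon")
        self._pat: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None
        h = hashlib.sha1()
        h.update(",".join(self.taxa).encode())
        h.update(self.codes.tobytes())
        self.matrix_id = h.hexdigest()[:12]

    # ------------------------------------------------------------ builders

    @classmethod
    def from_supermatrix(cls, sm) -> "CharMatrix":
        states = _ALPHABETS[sm.alphabet]
        lut = np.full(128, -1, dtype=np.int16)
        for i, c in enumerate(states):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        rows = [lut[np.frombuffer(sm.rows[t].encode(), dtype=np.uint8)]
                for t in sm.taxa]
        return cls(sm.taxa, np.vstack(rows) if rows else np.zeros((0, 0)),
                   sm.alphabet)

    @classmethod
    def from_binary(cls, bm) -> "CharMatrix":
        return cls(bm.taxa, bm.data.astype(np.int16), "binary")

    @classmethod
    def from_msa(cls, msa) -> "CharMatrix":
        states = _ALPHABETS[msa.alphabet]
        lut = np.full(128, -1, dtype=np.int16)
        for i, c in enumerate(states):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        rows = [lut[np.frombuffer(r.encode(), dtype=np.uint8)] for r in msa.rows]
        return cls(msa.ids, np.vstack(rows), msa.alphabet)

    # ------------------------------------------------------------ basic api

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def subset(self, taxa: Sequence[str]) -> "CharMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CharMatrix(list(taxa), self.codes[idx], self.alphabet)

    def patterns(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pattern codes (ntax, npat), weights, inverse col->pattern)."""
        if self._pat is None:
            cols, inverse, counts = np.unique(
                self.codes, axis=1, return_inverse=True, return_counts=True)
            self._pat = (cols, counts.astype(float), inverse.ravel())
        return self._pat

    def empirical_freqs(self) -> np.ndarray:
        """Observed state frequencies over non-missing cells (uniform prior
        pseudocount 1 to keep every state positive)."""
        k = self.n_states
        counts = np.ones(k)
        valid = self.codes >= 0
        for s in range(k):
            counts[s] += int((self.codes[valid] == s).sum())
        return counts / counts.sum()

    def bootstrap_resample(self, rng: np.random.Generator) -> "CharMatrix":
        idx = rng.integers(0, self.n_cols, size=self.n_cols)
        return CharMatrix(self.taxa, self.codes[:, idx], self.alphabet)

    def informative_mask(self) -> np.ndarray:
        """Parsimony-informative columns: >= 2 states each in >= 2 taxa."""
        out = np.zeros(self.n_cols, dtype=bool)
        for j in range(self.n_cols):
            col = self.codes[:, j]
            col = col[col >= 0]
            if len(col) < 4:
                continue
            _, counts = np.unique(col, return_counts=True)
            out[j] = (counts >= 2).sum() >= 2
        return out


def as_char_matrix(matrix) -> CharMatrix:
    """Accept a CharMatrix, Supermatrix, BinaryMatrix or Msa."""
    if isinstance(matrix, CharMatrix):
        return matrix
    kind = type(matrix).__name__
    if kind == "Supermatrix":
        return CharMatrix.from_supermatrix(matrix)
    if kind == "BinaryMatrix":
        return CharMatrix.from_binary(matrix)
    if kind == "Msa":
        return CharMatrix.from_msa(matrix)
    raise TypeError(f"cannot interpret {kind} as a character matrix")
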