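"""Synthetic proteome generator with full ground truth.

Emulates the inputs of a bacterial phylogenomics study at desk scale: a
species tree over genome labels, gene families evolving by duplication and
loss along that tree (creating orthologs, co-orthologs and inparalogs),
amino-acid sequences evolved under an empirical replacement model with
gamma rate variation, and binary presence/absence characters evolved under
a two-state gain/loss process.  Every output carries the truth needed to
score downstream recovery: the species topology, the family membership of
every sequence, and the per-genome copy counts.

Horizontal transfer, gene conversion and rate autocorrelation are not
modelled.  The default simulation is indel-free so that the true alignment
of a family is the evolved sequences themselves; a simple optional indel
process (fixed event rate, geometric lengths) is available to exercise the
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._seeds import stream
from .models import SubstitutionModel, lg_model, two_state_model, wag_model
from .trees import Tree

__all__ = [
    "SimulationParams",
    "GeneFamilyTruth",
    "SyntheticDataset",
    "simulate_species_tree",
    "evolve_gene_families",
    "evolve_sequences",
    "evolve_binary_characters",
    "simulate_dataset",
]

_MODELS = {"LG": lg_model, "WAG": wag_model}


@dataclass
class SimulationParams:
    """Knobs of the generator; a fixed seed fixes every output bit-for-bit."""

    n_taxa: int = 10
    n_families: int = 100
    duplication_rate: float = 0.05   # events per copy per branch-length unit
    loss_rate: float = 0.05
    model: str = "LG"
    gamma_shape: float = 1.0
    mean_length: int = 120
    mean_branch_length: float = 0.1
    indel_rate: float = 0.0          # events per branch-length unit (0 = indel-free)
    indel_length_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if min(self.duplication_rate, self.loss_rate, self.indel_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.model not in _MODELS:
            raise ValueError(f"unsupported model {self.model!r}; known: {sorted(_MODELS)}")
        if self.mean_length < 10:
            raise ValueError("mean_length must be at least 10")


class _GNode:
    """Rooted gene-tree node; ``length`` is the branch above it."""

    __slots__ = ("length", "children", "name")

    def __init__(self, length: float = 0.0, name: Optional[str] = None) -> None:
        self.length = length
        self.children: List["_GNode"] = []
        self.name = name

    def leaves(self) -> List["_GNode"]:
        if not self.children:
            return [self]
        out: List[_GNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def suppress_unifurcations(self) -> "_GNode":
        node = self
        while len(node.children) == 1:
            child = node.children[0]
            child.length += node.length
            node = child
        node.children = [c.suppress_unifurcations() for c in node.children]
        return node

    def newick(self) -> str:
        def fmt(n: "_GNode") -> str:
            if not n.children:
                return f"{n.name}:{n.length:.6g}"
            return "(" + ",".join(fmt(c) for c in n.children) + f"):{n.length:.6g}"
        return fmt(self) + ";"


@dataclass
class GeneFamilyTruth:
    """Ground truth for one gene family."""

    family_id: str
    copy_counts: Dict[str, int]
    seq_genome: Dict[str, str]                 # seq_id -> genome
    gene_tree: Optional[_GNode]                # None if the family went extinct

    @property
    def n_sequences(self) -> int:
        return len(self.seq_genome)

    @property
    def is_single_copy(self) -> bool:
        return all(c == 1 for c in self.copy_counts.values())

    def gene_tree_newick(self) -> str:
        if self.gene_tree is None:
            return ";"
        return self.gene_tree.newick()


def simulate_species_tree(n_taxa: int, seed: int,
                          mean_branch_length: float = 0.1,
                          min_branch_length: float = 0.02) -> Tree:
    """Random bifurcating species tree with exponential branch lengths.

    The topology is uniform over unrooted binary shapes; genome labels are
    ``G01`` … ``Gnn``.  Branch lengths are shifted-exponential,
    ``min + Exp(mean - min)`` in expected substitutions per site: the
    floor keeps every internal branch long enough that the generating
    topology is identifiable from finite data, which a ground-truth
    generator needs (an exact zero-length branch has no recoverable
    signal).
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if not 0 <= min_branch_length < mean_branch_length:
        raise ValueError("need 0 <= min_branch_length < mean_branch_length")
    rng = stream(seed, "species-tree")
    labels = [f"G{i + 1:02d}" for i in range(n_taxa)]
    tree = Tree.random_topology(labels, rng)
    for u, v in tree.edges():
        length = min_branch_length + rng.exponential(
            mean_branch_length - min_branch_length)
        tree.set_length(u, v, float(length))
    return tree


# ------------------------------------------------------------- gene families

def _evolve_lineage(t_remaining: float, dup: float, loss: float,
                    rng: np.random.Generator) -> Optional[_GNode]:
    """One gene copy evolving along a species branch; None if it dies.

    Returns a node whose leaves are the copies surviving at the branch end
    (marked by empty ``children`` and ``name`` is None until speciation).
    """
    node = _GNode()
    rate = dup + loss
    t = rng.exponential(1.0 / rate) if rate > 0 else np.inf
    if t >= t_remaining:
        node.length = t_remaining
        return node
    node.length = t
    if rng.random() < dup / rate:  # duplication
        kids = [_evolve_lineage(t_remaining - t, dup, loss, rng) for _ in range(2)]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        node.children = kids
        return node
    return None  # loss


def evolve_gene_families(tree: Tree, params: SimulationParams) -> List[GeneFamilyTruth]:
    """Evolve ``params.n_families`` families along the species tree.

    Each family starts as a single copy at the root (the species tree is
    rooted on its first edge; the process is reversible so the placement is
    immaterial).  Along every species branch each copy duplicates or dies
    with the Poisson rates of ``params``; at speciation every surviving
    copy is inherited by both descendant lineages.
    """
    order, children, parent, blen = tree.rooted()
    genomes = {n: tree.labels[n] for n in tree.leaves()}
    preorder = list(reversed(order))

    out: List[GeneFamilyTruth] = []
    for fam_idx in range(params.n_families):
        fam = f"fam{fam_idx + 1:04d}"
        rng = stream(params.seed, f"family/{fam}")
        copy_counts = {g: 0 for g in genomes.values()}
        seq_genome: Dict[str, str] = {}

        def descend(species_node: int, gnode: _GNode) -> Optional[_GNode]:
            """Carry the copies at ``gnode``'s leaves into the subtree below."""
            tips = gnode.leaves()
            if species_node in genomes:
                g = genomes[species_node]
                for tip in tips:
                    copy_counts[g] += 1
                    sid = f"{fam}_{g}_c{copy_counts[g]}"
                    tip.name = sid
                    seq_genome[sid] = g
                return gnode
            for tip in tips:
                for child in children[species_node]:
                    sub = _evolve_lineage(blen[child], params.duplication_rate,
                                          params.loss_rate, rng)
                    if sub is None:
                        continue
                    done = descend(child, sub)
                    if done is not None:
                        tip.children.append(done)
            return gnode if _has_named_leaf(gnode) else None

        root = _GNode()
        root = descend(-1, root)
        gene_tree = None
        if root is not None:
            gene_tree = root.suppress_unifurcations()
            gene_tree = _prune_dead(gene_tree)
        out.append(GeneFamilyTruth(fam, copy_counts, seq_genome, gene_tree))
    return out


def _has_named_leaf(node: _GNode) -> bool:
    return any(l.name is not None for l in node.leaves())


def _prune_dead(node: _GNode) -> Optional[_GNode]:
    """Drop subtrees without surviving copies, then re-suppress."""
    if not node.children:
        return node if node.name is not None else None
    kids = [k for k in (_prune_dead(c) for c in node.children) if k is not None]
    if not kids:
        return None
    node.children = kids
    return node.suppress_unifurcations()


# ----------------------------------------------------------------- sequences

def _sample_states(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw; probs rows sum to 1."""
    c = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])[:, None]
    return (u > c).sum(axis=1)


def evolve_sequences(truth: GeneFamilyTruth, params: SimulationParams
                     ) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Evolve protein sequences down the family's gene tree.

    Returns ``(sequences, true_alignment)`` keyed by sequence id.  With the
    default indel-free process the alignment equals the sequences; with
    ``indel_rate > 0`` insertions and deletions (geometric lengths) are
    applied and the recorded alignment carries '-' gaps.
    """
    if truth.gene_tree is None or truth.n_sequences == 0:
        return {}, {}
    model = _MODELS[params.model]()
    rng = stream(params.seed, f"seq/{truth.family_id}")
    L = max(10, int(rng.poisson(params.mean_length)))
    site_rates = rng.gamma(params.gamma_shape, 1.0 / params.gamma_shape, size=L)

    U, Uinv, evals = model._U, model._Uinv, model._evals
    root_states = _sample_states(np.tile(model.freqs, (L, 1)), rng)

    # global column registry for the (optional) indel process
    columns: List[int] = list(range(L))
    next_col = L

    def substitute(states: np.ndarray, cols: List[int], t: float) -> np.ndarray:
        if t <= 0 or len(cols) == 0:
            return states.copy()
        r = site_rates[np.asarray(cols) % L]
        E = np.exp(np.outer(t * r, evals))           # (l, k)
        probs = (U[states] * E) @ Uinv               # (l, k)
        np.clip(probs, 0.0, None, out=probs)
        probs /= probs.sum(axis=1, keepdims=True)
        return _sample_states(probs, rng)

    def apply_indels(states: np.ndarray, cols: List[int], t: float
                     ) -> Tuple[np.ndarray, List[int]]:
        nonlocal next_col
        if params.indel_rate <= 0 or t <= 0:
            return states, cols
        n_events = rng.poisson(params.indel_rate * t)
        states = list(states)
        cols = list(cols)
        for _ in range(n_events):
            if len(cols) < 5:
                break
            length = 1 + rng.geometric(1.0 / params.indel_length_mean)
            if rng.random() < 0.5:  # deletion
                start = int(rng.integers(0, len(cols)))
                del states[start:start + length]
                del cols[start:start + length]
            else:  # insertion after an anchor
                anchor = int(rng.integers(0, len(cols)))
                new_ids = list(range(next_col, next_col + length))
                next_col += length
                gpos = columns.index(cols[anchor]) + 1
                columns[gpos:gpos] = new_ids
                new_states = _sample_states(
                    np.tile(model.freqs, (length, 1)), rng)
                cols[anchor + 1:anchor + 1] = new_ids
                states[anchor + 1:anchor + 1] = list(new_states)
        return np.asarray(states, dtype=int), cols

    tip_states: Dict[str, Tuple[np.ndarray, List[int]]] = {}

    def walk(node: _GNode, states: np.ndarray, cols: List[int]) -> None:
        states = substitute(states, cols, node.length)
        states, cols = apply_indels(states, cols, node.length)
        if not node.children:
            tip_states[node.name] = (states, cols)
            return
        for child in node.children:
            walk(child, states, list(cols))

    root = truth.gene_tree
    # the root branch length positions the root inside the species tree
    walk(root, root_states, columns[:L])

    alphabet = model.states
    sequences = {sid: "".join(alphabet[s] for s in states)
                 for sid, (states, _) in tip_states.items()}
    if params.indel_rate <= 0:
        return sequences, dict(sequences)
    col_pos = {c: i for i, c in enumerate(columns)}
    width = len(columns)
    alignment = {}
    for sid, (states, cols) in tip_states.items():
        row = ["-"] * width
        for s, c in zip(states, cols):
            row[col_pos[c]] = alphabet[s]
        alignment[sid] = "".join(row)
    # drop all-gap columns (from fully deleted insertions)
    keep = [j for j in range(width)
            if any(alignment[sid][j] != "-" for sid in alignment)]
    alignment = {sid: "".join(alignment[sid][j] for j in keep) for sid in alignment}
    return sequences, alignment


# ----------------------------------------------------- binary gain/loss chars

def evolve_binary_characters(tree: Tree, n_chars: int, gain_rate: float,
                             loss_rate: float, seed: int,
                             root_state: Optional[int] = None):
    """Presence/absence characters under a two-state CTMC along the tree.

    Returns a :class:`corephylo.matrices.BinaryMatrix` with one row per
    genome.  The root state is drawn from the stationary distribution
    unless forced with ``root_state``.
    """
    from .matrices import BinaryMatrix  # deferred: matrices imports nothing from here

    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = stream(seed, "binary-characters")
    taxa = tree.taxa()
    if n_chars == 0:
        return BinaryMatrix(taxa, np.zeros((len(taxa), 0), dtype=np.int8),
                            [], provenance="simulated")
    order, children, parent, blen = tree.rooted()
    preorder = list(reversed(order))
    total = gain_rate + loss_rate

    if root_state is None:
        p1 = gain_rate / total if total > 0 else 0.5
        states = {-1: (rng.random(n_chars) < p1).astype(np.int8)}
    else:
        states = {-1: np.full(n_chars, root_state, dtype=np.int8)}

    def p_change(t: float, frm: int) -> float:
        if total == 0:
            return 0.0
        target = gain_rate / total if frm == 0 else loss_rate / total
        return target * (1.0 - np.exp(-total * t))

    for node in preorder:
        if node == -1:
            continue
        t = blen[node] or 0.0
        prev = states[parent[node]]
        change0 = p_change(t, 0)
        change1 = p_change(t, 1)
        flip = np.where(prev == 0, change0, change1)
        new = np.where(rng.random(n_chars) < flip, 1 - prev, prev)
        states[node] = new.astype(np.int8)

    leaf_by_label = {tree.labels[n]: n for n in tree.leaves()}
    data = np.vstack([states[leaf_by_label[t]] for t in taxa])
    cols = [f"char{i + 1:05d}" for i in range(n_chars)]
    return BinaryMatrix(taxa, data, cols, provenance="simulated")


# -------------------------------------------------------------- full dataset

@dataclass
class SyntheticDataset:
    """A complete simulated study: tree, truth, proteomes, true alignments."""

    params: SimulationParams
    species_tree: Tree
    families: List[GeneFamilyTruth]
    proteomes: Dict[str, Dict[str, str]] = field(default_factory=dict)
    true_alignments: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def true_partition(self) -> Dict[str, str]:
        """seq_id -> family id, the clustering ground truth."""
        out = {}
        for fam in self.families:
            for sid in fam.seq_genome:
                out[sid] = fam.family_id
        return out

    def write_fasta_dir(self, path) -> None:
        """One protein FASTA per genome, headers ``<genome>|<seq_id>``."""
        import os
        os.makedirs(path, exist_ok=True)
        for genome, seqs in sorted(self.proteomes.items()):
            with open(os.path.join(path, f"{genome}.faa"), "w") as fh:
                for sid, seq in sorted(seqs.items()):
                    fh.write(f">{genome}|{sid}\n{seq}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for fam in self.families:
                for sid in sorted(fam.seq_genome):
                    fh.write(f"{fam.family_id}\t{sid}\n")


def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """End-to-end generation: tree, families, sequences, per-genome FASTA."""
    tree = simulate_species_tree(params.n_taxa, params.seed,
                                 params.mean_branch_length)
    families = evolve_gene_families(tree, params)
    proteomes: Dict[str, Dict[str, str]] = {g: {} for g in tree.taxa()}
    true_alignments: Dict[str, Dict[str, str]] = {}
    for fam in families:
        seqs, aln = evolve_sequences(fam, params)
        true_alignments[fam.family_id] = aln
        for sid, seq in seqs.items():
            proteomes[fam.seq_genome[sid]][sid] = seq
    return SyntheticDataset(params, tree, families, proteomes, true_alignments)
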