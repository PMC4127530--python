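# Methods

`corephylo` re-creates, as a tested library, the genome-scale phylogenetic
workflow used to delimit bacterial genera from whole-proteome data: cluster
proteins into ortholog and homolog families, assemble several character
matrices from them, infer maximum-parsimony (MP) and maximum-likelihood
(ML) trees with bootstopping, and ask — via backbone constraints and
paired-site tests — whether independent data sets conflict.  This note
documents the models, the defaults and why they were chosen, what the
synthetic data do and do not emulate, and the numerical choices that affect
results.

## Similarity search

All-vs-all protein comparison uses exact Smith–Waterman local alignment
under BLOSUM62 with affine gaps (gap of length *k* costs `open + k·extend`,
default 11/1, the convention of the classical search tools).  Raw scores
are converted to expect values with the Karlin–Altschul formula
`E = K·m'·n'·e^(−λS)` using the published gapped-BLOSUM62 constants
(λ = 0.267, K = 0.041, H = 0.14) and the standard length adjustment
`l = ln(K·m·n)/H`, with the database length taken as the total residue
count over all proteomes.  No heuristic seeding is replicated; an optional
k-mer prefilter (skip pairs sharing no 4-mer) is a pure speed device and is
validated in the tests to leave the retained hit set unchanged in the
regimes exercised.  E-values below 1e−180 are floored before −log10
weighting so that graph weights stay finite.

## Ortholog and homolog graphs; MCL

The ortholog graph follows the reciprocal-best-hit construction: putative
orthologs are cross-genome reciprocal best hits (best per target genome);
recent inparalogs are within-genome reciprocal hits whose e-values beat
both members' best cross-genome e-value (taken as +∞ for genes with no
cross-genome hit); co-ortholog edges connect the inparalog groups of each
ortholog pair wherever a hit exists.  Edge weights are the mean of the two
directional −log10 e-values, normalized by the mean ortholog-edge weight of
the genome pair (ortholog and co-ortholog edges — co-orthologs share the
ortholog normalization class, following the published scheme) or by the
genome's mean inparalog-edge weight (inparalog edges).  The homolog graph
simply links every pair whose better directional e-value passes 1e−5,
weighted by its −log10, with no normalization.

Both graphs are clustered by an internal Markov-clustering engine:
column-stochastic matrix with self-loops set to each node's maximum
incident weight, alternating expansion (matrix squaring) and inflation
(entrywise power 2.0 plus renormalization), pruning entries below 1e−8,
until the maximum entry change drops below 1e−6 (at most 200 iterations;
non-convergence raises with the residual).  Clusters are the connected
components of the converged matrix's support.  Inparalog-containing
clusters are reduced to one sequence per genome by keeping the member with
the highest summed bit score against the rest of the cluster ("most
central"); ties keep the lexicographically smallest id and are logged.
The e-value threshold for the ortholog-stage search is also 1e−5 by
default (configurable); bit scores rather than e-values are summed in the
centrality rule because scores add meaningfully.

## Alignment and filtering

Per-cluster alignments come from a deterministic progressive aligner:
pairwise k-mer distances (k = 3), a UPGMA guide tree, and profile–profile
global alignment with affine gaps (Gotoh recurrences; sum-of-pairs column
scores under BLOSUM62; gap open 10, extend 1).  With two sequences this is
exactly global pairwise DP, which the tests verify against an independent
Needleman–Wunsch implementation.  Iterative refinement is not performed.

Row filtering removes "orphan" sequences whose mean pairwise identity to
the other rows (over mutually ungapped columns) falls below 0.25; removal
is skipped entirely if it would leave fewer than four rows.  The identity
floor is a package default — the cited orphan-scanning tool does not
publish its criterion — and is exposed in the API.

Column filtering implements the conserved-block algorithm with its
published defaults for *n* rows: a position is non-conserved if its top
residue count is below ⌊n/2⌋+1, highly conserved at ⌈0.85·n⌉ or more;
stretches of more than 8 contiguous non-conserved positions are rejected;
remaining blocks are trimmed to highly conserved flanks; blocks shorter
than 10 are dropped; gap-containing columns are always dropped under the
default policy.  The surviving original column indices are returned as a
mask.

## Gene informativeness and matrix reduction

The information-filtered supermatrix needs a per-gene signal score.  We
use the fraction of resolved quartets: for up to 500 sampled 4-row
subsets, each column with four residues votes for the quartet topology it
supports (two equal pairs of distinct states), and a quartet is resolved
when one topology strictly outvotes the other two.  Genes scoring at or
above a quantile threshold (default: the median) are retained; taxa are
never removed.  This is a deliberate simplification of quartet-mapping
matrix reduction — it is *not* equivalent to that method and is not
presented as such; it preserves the property the pipeline needs (star-tree
genes score near 0, tree-like genes near 1, verified in the tests).

## Character matrices

Five matrix variants are assembled: the core-gene supermatrix (clusters
with all genomes present), the full supermatrix (alignments with at least
four sequences), the information-filtered supermatrix, and binary
ortholog-content and gene-content matrices (presence/absence of a cluster
per genome, copy number ignored).  Supermatrices canonicalize gene order
by cluster id, fill absent genome×gene blocks with `?` (fully ambiguous
under both criteria), and carry an exact partition map; writers cover
relaxed PHYLIP, aligned FASTA, NEXUS with character sets and RAxML-style
partition files.  Content-matrix columns are restricted to clusters in at
least two genomes by default because singleton columns are
parsimony-uninformative; the rule is configurable (`min_genomes=1`) since
the convention is not universal.  Genomic G+C is
100·(G+C)/(A+C+G+T) over all contigs, ambiguity codes excluded, reported
to two decimals.

## Tree inference

**Parsimony.**  Fitch state sets are evaluated as bitmasks, vectorized
over compressed site patterns; `?` and `-` carry the full state set.
Supermatrix lengths can be reported with or without
parsimony-uninformative columns (both counting modes exist because
published step counts for supermatrices exclude them).  The search is
random stepwise addition followed by TBR branch swapping (NNI optionally),
default 100 addition rounds, keeping at most 10 equally best trees per
round; zero-length branches — branches whose two-sided Fitch state sets
intersect at every column — can be collapsed into polytomies for
reporting.  Desk-scale analyses in the tests and the acceptance script use
5–10 addition rounds, which exhaustive-enumeration checks at ≤ 7 taxa show
to be sufficient at these sizes.

**Likelihood.**  Felsenstein pruning over site patterns with 4-category
discrete-gamma rates (median category rates renormalized to mean 1),
per-node rescaling against underflow, and missing data integrating over
all states.  Model families: two-state (binary matrices), GTR nucleotide
(exchangeabilities supplied as parameters; the default all-equal values
give the F81 special case — full GTR rate estimation is out of scope), and
the empirical LG and WAG amino-acid models with "+F" observed frequencies
(pseudocount 1 keeps every state positive).  Branch lengths are optimized
by bounded Brent iteration per branch (bounds 1e−8 to 20, tolerance 1e−4),
the gamma shape on (0.02, 100); the topology search starts from a
parsimony tree with branch lengths initialized from per-branch Fitch
change counts and improves by NNI passes (each candidate's central branch
re-optimized) until no pass gains more than 1e−4 log units.  SPR/TBR under
likelihood is not implemented.

**Model choice** compares candidate models by log-likelihood on a fixed
MP starting tree, re-optimizing branch lengths and shape per candidate;
all scores are logged and the ranking is order-independent.

**Bootstopping.**  Bootstrap columns are resampled with replacement,
partition-agnostic.  Each replicate gets a fast search (one random
addition start plus NNI-only swapping; under ML, with the reference model
and shape fixed).  After every 50 replicates the replicate set is split
into random halves 100 times; majority-rule (> 0.5) bipartition
frequencies define each half's consensus, and the normalized weighted
Robinson–Foulds distance Σ|w₁−w₂| / Σ max(w₁,w₂) over the union of
majority bipartitions is averaged over splits.  Replication stops below
0.03 or at the replicate cap.  The normalization is this package's
choice — bounded in [0,1], zero exactly when the halves agree — because
the cited stopping criterion's exact normalization is not printed in the
sources available here.  Support values are bipartition frequencies over
the replicate set, in percent.

## Constraints and paired-site tests

A backbone constraint keeps the bipartitions of a support-annotated tree
at or above a threshold (default 100%), restricted to a target taxon set,
collapsing everything else into polytomies.  Compatibility of a candidate
tree is displayed-bipartition containment on the induced subtree; during
constrained searches, stepwise addition only inserts leaves at positions
keeping the partial tree compatible and incompatible swaps are discarded,
so a compatible tree is always reachable.  Constrained optima can never
beat unconstrained ones; this invariant is asserted in the tests.

The Kishino–Hasegawa test (MP flavour) uses the normal approximation on
per-site step differences: statistic Σd / (sd(d)·√n), two-sided.  The
degenerate sd = 0 case yields p = 1 for identical score vectors and p = 0
for a constant nonzero difference; a RELL resampling variant of the test
is available behind a flag.  The Shimodaira–Hasegawa test resamples
stored per-site log-likelihoods (RELL, default 1000 replicates), centers
each candidate's replicate totals at its own mean, and takes the p-value
of candidate k as the proportion of replicates where the centered
best-minus-k difference reaches the observed one; the best candidate has
p = 1 by construction.  Both default to α = 0.01.  Site-score vectors
carry a matrix fingerprint, and tests refuse vectors from different
matrices.  Long-branch extraction re-runs inference without selected taxa
and reports the Robinson–Foulds distance between the reduced-data tree and
the induced subtree of the full-data tree.

## Synthetic data: what it emulates and what it does not

The generator produces a uniform-topology species tree over 4+ genomes
with shifted-exponential branch lengths (floor 0.02, mean 0.1 expected
substitutions per site).  The floor is deliberate: a pure exponential
routinely yields internal branches so short that the generating topology
is statistically unidentifiable at finite sequence length, which defeats a
ground-truth generator; 0.02 with ~10⁴ concatenated sites keeps every
internal branch recoverable.  Gene families start as one copy at the root
and evolve by per-copy duplication/loss events (Poisson along each species
branch; default 0.05 events per copy per branch-length unit each, matching
the standard study conditions used in the tests); surviving copies at the
leaves define per-genome copy counts, inparalogs, and the family gene
tree.  Protein sequences evolve site-independently down the gene tree
under LG (or WAG) with continuous per-site gamma rates (shape 1.0, mean
length 120 — a deliberately compact protein length for desk-scale runs);
the root sequence is drawn from model equilibrium.  Inference uses
4-category discrete gamma, the usual simulate-continuous/infer-discrete
asymmetry.  The default process is indel-free so the true alignment is
the sequences themselves and alignment oracles are exact; an optional
indel process (Poisson events, geometric lengths, insertions tracked
through a global column registry) exercises the aligner.  Binary
presence/absence characters evolve under a two-state CTMC with closed-form
transition probabilities (default gain = loss = 1.0 per branch-length
unit, giving informative but unsaturated characters at these branch
lengths).

Not modelled: horizontal transfer, gene conversion, rate autocorrelation,
codon structure, composition heterogeneity across lineages, and genome
rearrangement.  Passing recovery tests therefore demonstrates the
pipeline's correctness under its own assumptions, not robustness to the
model violations real bacterial genomes exhibit.

All randomness flows from a single integer seed through labelled child
streams (PCG64 seeded by (seed, crc32(label))), so every stage is
bit-reproducible in isolation.

## Problem sizes and determinism

The standard validation runs 10 genomes × 100 families (~1,000 proteins,
core supermatrices around 10⁴ columns), sizes chosen so the full pipeline
plus ML inference completes in minutes on one core while keeping ≥ 80 core
genes and clear phylogenetic signal.  Oracle tests run at 4–7 taxa where
exhaustive enumeration (up to 945 topologies) is feasible.  The KH null
calibration uses 500 simulations of 300 characters on a 4-taxon star
tree.  Fixed seeds make every reported number reproducible; none of the
generator defaults were adjusted after observing test outcomes.

## Known limitations

* NNI-only topology moves under likelihood can in principle be trapped by
  local optima that TBR would escape; at the taxon counts validated here
  the exhaustive checks show it is not a limitation in practice.
* The quartet-resolution gene score is a stand-in for quartet-mapping
  matrix reduction, not a re-implementation.
* GTR exchangeabilities are taken as given, not estimated.
* E-value calibration uses fixed published Karlin–Altschul constants; no
  composition-based statistics.
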