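"""Shared fixtures.

The full-pipeline fixture simulates the standard study conditions (10
genomes, 100 gene families, duplication and loss at 0.05 events per copy
per branch-length unit) once per session; several recovery tests and the
acceptance checks share it.
"""

import numpy as np
import pytest

from corephylo.alignfilter import Msa
from corephylo.matrices import GeneSet, concatenate_supermatrix
from corephylo.pipeline import run_pipeline
from corephylo.synthdata import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    params = SimulationParams(n_taxa=10, n_families=100,
                              duplication_rate=0.05, loss_rate=0.05, seed=1)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def study_pipeline(study_dataset):
    return run_pipeline(study_dataset.proteomes)


@pytest.fixture(scope="session")
def small_dataset():
    """Six genomes, thirty single-copy families: quick, clean signal."""
    params = SimulationParams(n_taxa=6, n_families=30, duplication_rate=0.0,
                              loss_rate=0.0, seed=5, mean_length=80)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def small_supermatrix(small_dataset):
    """Supermatrix concatenated from the true alignments (no inference)."""
    ds = small_dataset
    alns = {}
    for fam in ds.families:
        aln = ds.true_alignments[fam.family_id]
        ids = [fam.seq_genome[sid] for sid in sorted(aln)]
        alns[fam.family_id] = Msa(ids, [aln[sid] for sid in sorted(aln)])
    gene_set = GeneSet(sorted(alns), "preselected")
    return concatenate_supermatrix(alns, gene_set, ds.species_tree.taxa())
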