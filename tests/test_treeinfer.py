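"""Parsimony, likelihood, searches, bootstopping, support mapping."""

import itertools
import math

import numpy as np
import pytest

from corephylo.matrices import BinaryMatrix
from corephylo.models import ModelSpec, discrete_gamma_rates, two_state_model
from corephylo.synthdata import (SimulationParams, evolve_binary_characters,
                                 simulate_dataset, simulate_species_tree)
from corephylo.treeinfer import (SearchParams, bootstrap_autoMRE,
                                 bipartition_frequencies,
                                 collapse_zero_length_branches, choose_model,
                                 log_likelihood, map_support, ml_search,
                                 mp_search, parsimony_length)
from corephylo.trees import Tree


def exhaustive_steps(tree, taxa, col, n_states=2):
    """Minimum changes for one column by enumerating internal states."""
    order, children, parent, _ = tree.rooted()
    internals = [n for n in order if n == -1 or n not in tree.labels]
    best = math.inf
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for n in tree.leaves():
            st[n] = col[taxa.index(tree.labels[n])]
        changes = sum(st[n] != st[parent[n]] for n in order if n != -1)
        best = min(best, changes)
    return best


class TestParsimony:
    def test_four_taxon_textbook_characters(self):
        bm = BinaryMatrix(list("ABCD"), np.array([[0], [0], [1], [1]]), ["c"])
        matched = Tree.from_newick("((A,B),(C,D));")
        crossed = Tree.from_newick("((A,C),(B,D));")
        assert parsimony_length(matched, bm).total == 1
        assert parsimony_length(crossed, bm).total == 2

    def test_matches_exhaustive_state_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = Tree.random_topology([f"T{i}" for i in range(6)], rng)
            taxa = sorted(t.taxa())
            data = rng.integers(0, 2, size=(6, 20)).astype(np.int8)
            bm = BinaryMatrix(taxa, data, [f"c{i}" for i in range(20)])
            expect = sum(exhaustive_steps(t, taxa, data[:, j])
                         for j in range(20))
            assert parsimony_length(t, bm).total == expect

    def test_missing_states_are_free(self):
        bm = BinaryMatrix(list("ABCD"), np.array([[0], [0], [1], [1]]), ["c"])
        t = Tree.from_newick("((A,B),(C,D));")
        rows = {"A": "0", "B": "?", "C": "1", "D": "?"}
        from corephylo.treeinfer.encode import CharMatrix
        codes = np.array([[0], [-1], [1], [-1]], dtype=np.int16)
        cm = CharMatrix(list("ABCD"), codes, "binary")
        assert parsimony_length(t, cm).total == 1

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(7)
        t = Tree.random_topology([f"T{i}" for i in range(7)], rng)
        taxa = sorted(t.taxa())
        data = rng.integers(0, 2, size=(7, 30)).astype(np.int8)
        bm = BinaryMatrix(taxa, data, [f"c{i}" for i in range(30)])
        ref = parsimony_length(t, bm).total
        # rebuild the same topology from newick (different internal ids and
        # hence a different rooting edge for the traversal)
        for _ in range(3):
            t = Tree.from_newick(t.to_newick(lengths=False))
            assert parsimony_length(t, bm).total == ref

    def test_uninformative_exclusion_drops_constant_and_singleton_sites(self):
        data = np.array([
            [0, 0, 1], [0, 0, 0], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        # col0 informative (2+2), col1 singleton, col2 autapomorphy pattern?
        bm = BinaryMatrix(list("ABCD"), data, ["c0", "c1", "c2"])
        t = Tree.from_newick("((A,B),(C,D));")
        full = parsimony_length(t, bm)
        info = parsimony_length(t, bm, exclude_uninformative=True)
        assert info.total <= full.total
        assert info.values[1] == 0.0

    def test_taxon_mismatch_rejected(self):
        bm = BinaryMatrix(list("ABCD"), np.zeros((4, 2), np.int8), ["a", "b"])
        t = Tree.from_newick("((A,B),(C,Z));")
        with pytest.raises(ValueError):
            parsimony_length(t, bm)


class TestMpSearch:
    def _random_matrix(self, n_taxa, n_cols, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"T{i}" for i in range(n_taxa)]
        data = rng.integers(0, 2, size=(n_taxa, n_cols)).astype(np.int8)
        return BinaryMatrix(taxa, data, [f"c{i}" for i in range(n_cols)])

    @pytest.mark.parametrize("n_taxa", [6, 7])
    def test_finds_global_optimum_vs_enumeration(self, n_taxa):
        bm = self._random_matrix(n_taxa, 30, seed=n_taxa)
        exhaustive = min(parsimony_length(t, bm).total
                         for t in Tree.enumerate_topologies(bm.taxa))
        trees, best = mp_search(bm, SearchParams(addition_rounds=10, seed=1))
        assert best == exhaustive

    def test_recovers_strong_signal_topology(self, small_dataset,
                                             small_supermatrix):
        trees, _ = mp_search(small_supermatrix,
                             SearchParams(addition_rounds=5, seed=2))
        assert trees[0].same_topology(small_dataset.species_tree)

    def test_seed_reproducible(self):
        bm = self._random_matrix(6, 25, seed=9)
        p = SearchParams(addition_rounds=5, seed=42)
        a, la = mp_search(bm, p)
        b, lb = mp_search(bm, p)
        assert la == lb
        assert [t.to_newick(lengths=False) for t in a] == \
            [t.to_newick(lengths=False) for t in b]

    def test_collapse_zero_length_yields_star_on_constant_data(self):
        taxa = list("ABCDEF")
        bm = BinaryMatrix(taxa, np.zeros((6, 10), np.int8),
                          [f"c{i}" for i in range(10)])
        t = Tree.from_newick("((A,B),(C,D),(E,F));")
        collapsed = collapse_zero_length_branches(t, bm)
        assert len(collapsed.bipartitions()) == 0
        assert sorted(collapsed.taxa()) == taxa


class TestLikelihood:
    def test_two_taxon_two_state_closed_form(self):
        t = Tree()
        a = t.new_node("A")
        b = t.new_node("B")
        total = 0.37
        t.add_edge(a, b, total)
        cm_codes = np.array([[0], [0]], dtype=np.int16)
        from corephylo.treeinfer.encode import CharMatrix
        cm = CharMatrix(["A", "B"], cm_codes, "binary")
        spec = ModelSpec("binary", alpha=1.0, n_cat=1)
        lnl = log_likelihood(t, cm, spec).total
        expect = math.log(0.5 * 0.5 * (1.0 + math.exp(-2.0 * total)))
        assert lnl == pytest.approx(expect, abs=1e-9)

    def test_large_alpha_matches_rate_homogeneous_limit(self, small_supermatrix):
        tree = Tree.from_newick(
            "((G01:0.1,G02:0.1):0.05,(G03:0.1,G04:0.1):0.05,"
            "(G05:0.1,G06:0.1):0.05);")
        homo = log_likelihood(tree, small_supermatrix,
                              ModelSpec("lg", alpha=1.0, n_cat=1,
                                        empirical_freqs=True)).total
        limit = log_likelihood(tree, small_supermatrix,
                               ModelSpec("lg", alpha=1e6, n_cat=4,
                                         empirical_freqs=True)).total
        assert limit == pytest.approx(homo, abs=1e-3)

    def test_all_missing_column_contributes_zero(self):
        from corephylo.treeinfer.encode import CharMatrix
        codes = np.array([[0, -1], [1, -1], [0, -1], [1, -1]], dtype=np.int16)
        cm = CharMatrix(list("ABCD"), codes, "binary")
        t = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        vals = log_likelihood(t, cm, ModelSpec("binary")).values
        assert vals[1] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_rerooting_pulley_principle(self):
        rng = np.random.default_rng(5)
        t = Tree.random_topology([f"T{i}" for i in range(6)], rng)
        for u, v in t.edges():
            t.set_length(u, v, float(rng.uniform(0.05, 0.4)))
        data = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        bm = BinaryMatrix(sorted(t.taxa()), data, [f"c{i}" for i in range(40)])
        spec = ModelSpec("binary", alpha=0.7)
        ref = log_likelihood(t, bm, spec).total
        for _ in range(3):
            t = Tree.from_newick(t.to_newick())
            assert log_likelihood(t, bm, spec).total == pytest.approx(ref, abs=1e-6)

    def test_alphabet_model_mismatch_rejected(self):
        bm = BinaryMatrix(list("ABCD"), np.zeros((4, 3), np.int8),
                          ["a", "b", "c"])
        t = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        with pytest.raises(ValueError):
            log_likelihood(t, bm, ModelSpec("lg"))


class TestMlSearch:
    def test_four_taxon_equals_exhaustive_maximum(self):
        true = simulate_species_tree(4, seed=8)
        bm = evolve_binary_characters(true, 400, 1.0, 1.0, seed=3)
        spec = ModelSpec("binary", alpha=1.0, empirical_freqs=True)
        res = ml_search(bm, spec, SearchParams(addition_rounds=3, seed=5))
        # exhaustive: optimize each of the 3 topologies fully
        from corephylo.treeinfer.likelihood import (_PruningEngine,
                                                    _fitch_init_lengths,
                                                    _optimize_all_branches,
                                                    _optimize_alpha, _resolve)
        from corephylo.treeinfer.encode import as_char_matrix
        cm = as_char_matrix(bm)
        model = _resolve(cm, spec)
        best = -np.inf
        best_topo = None
        for t in Tree.enumerate_topologies(sorted(true.taxa())):
            _fitch_init_lengths(t, cm)
            engine = _PruningEngine(cm, model, discrete_gamma_rates(1.0, 4))
            _optimize_all_branches(t, engine, 2)
            _, lnl = _optimize_alpha(t, cm, spec, model)
            if lnl > best:
                best, best_topo = lnl, t
        assert res.tree.same_topology(best_topo)
        # the search may optimize a little deeper than the oracle's two
        # passes, but can never do worse than the exhaustive optimum
        assert res.lnl >= best - 0.05

    def test_monotone_improvement_over_start(self, small_supermatrix):
        spec = ModelSpec("lg", alpha=1.0, empirical_freqs=True)
        start, _ = mp_search(small_supermatrix,
                             SearchParams(addition_rounds=1, seed=3))
        tree = start[0].copy()
        for u, v in tree.edges():
            tree.set_length(u, v, 0.1)
        start_lnl = log_likelihood(tree, small_supermatrix, spec).total
        res = ml_search(small_supermatrix, spec,
                        SearchParams(addition_rounds=1, seed=3))
        assert res.lnl >= start_lnl

    def test_recovers_known_topology(self, small_dataset, small_supermatrix):
        res = ml_search(small_supermatrix,
                        ModelSpec("lg", empirical_freqs=True),
                        SearchParams(addition_rounds=2, seed=7))
        assert res.tree.same_topology(small_dataset.species_tree)

    def test_parameter_recovery_within_twenty_percent(self):
        """Gamma shape and total tree length re-estimated on the true
        topology from 2000-site alignments (median over 3 seeds)."""
        from corephylo.treeinfer.likelihood import (_PruningEngine,
                                                    _optimize_all_branches,
                                                    _optimize_alpha, _resolve)
        from corephylo.treeinfer.encode import as_char_matrix
        from corephylo.alignfilter import Msa
        from corephylo.matrices import GeneSet, concatenate_supermatrix
        alpha_errs, len_errs = [], []
        for seed in (1, 2, 3):
            params = SimulationParams(n_taxa=8, n_families=1, seed=seed,
                                      duplication_rate=0.0, loss_rate=0.0,
                                      mean_length=2000, gamma_shape=1.0)
            ds = simulate_dataset(params)
            fam = ds.families[0]
            aln = ds.true_alignments[fam.family_id]
            ids = [fam.seq_genome[s] for s in sorted(aln)]
            msa = Msa(ids, [aln[s] for s in sorted(aln)])
            sm = concatenate_supermatrix({"g": msa},
                                         GeneSet(["g"], "preselected"),
                                         ds.species_tree.taxa())
            cm = as_char_matrix(sm)
            spec = ModelSpec("lg", alpha=1.0, empirical_freqs=True)
            model = _resolve(cm, spec)
            tree = ds.species_tree.copy()
            engine = _PruningEngine(cm, model, discrete_gamma_rates(1.0, 4))
            _optimize_all_branches(tree, engine, 2)
            alpha, _ = _optimize_alpha(tree, cm, spec, model)
            true_len = ds.species_tree.total_length()
            alpha_errs.append(abs(alpha - 1.0))
            len_errs.append(abs(tree.total_length() - true_len) / true_len)
        assert np.median(alpha_errs) < 0.2
        assert np.median(len_errs) < 0.2


class TestChooseModel:
    def test_single_candidate_returned(self, small_supermatrix):
        start, _ = mp_search(small_supermatrix,
                             SearchParams(addition_rounds=1, seed=1))
        spec = ModelSpec("lg", empirical_freqs=True)
        chosen = choose_model(small_supermatrix, [spec], start[0])
        assert chosen.family == "lg"

    def test_ranking_invariant_to_candidate_order(self, small_supermatrix):
        start, _ = mp_search(small_supermatrix,
                             SearchParams(addition_rounds=1, seed=1))
        cands = [ModelSpec("lg", empirical_freqs=True),
                 ModelSpec("wag", empirical_freqs=True)]
        a = choose_model(small_supermatrix, cands, start[0])
        b = choose_model(small_supermatrix, cands[::-1], start[0])
        assert a.family == b.family

    def test_generating_family_selected(self, small_supermatrix):
        """Data simulated under the LG model should prefer LG over WAG."""
        start, _ = mp_search(small_supermatrix,
                             SearchParams(addition_rounds=1, seed=1))
        chosen, scores = choose_model(
            small_supermatrix,
            [ModelSpec("wag", empirical_freqs=True),
             ModelSpec("lg", empirical_freqs=True)],
            start[0], return_scores=True)
        assert chosen.family == "lg"
        assert scores["lg+F"] > scores["wag+F"]


class TestBootstrap:
    def _clean_matrix(self, seed=31, n_chars=600):
        true = simulate_species_tree(6, seed)
        for u, v in true.edges():
            true.set_length(u, v, 0.3)
        return true, evolve_binary_characters(true, n_chars, 1.0, 1.0, seed)

    def test_overwhelming_signal_stops_at_first_checkpoint(self):
        """Perfect-signal fixture: 60 clean synapomorphies per internal
        edge of ((A,B),(C,D),(E,F)) and no conflict — every replicate
        recovers the same topology, so the half-split consensus distance
        is 0 at the first checkpoint."""
        taxa = list("ABCDEF")
        cols = []
        for side in (("A", "B"), ("C", "D"), ("E", "F")):
            col = [1 if t in side else 0 for t in taxa]
            cols.extend([col] * 60)
        bm = BinaryMatrix(taxa, np.array(cols, np.int8).T,
                          [f"c{i}" for i in range(180)])
        res = bootstrap_autoMRE(bm, "mp", params=SearchParams(seed=5))
        assert res.stopped_at == 50
        assert res.converged

    def test_replicate_count_never_exceeds_maximum(self):
        rng = np.random.default_rng(0)
        taxa = [f"T{i}" for i in range(6)]
        bm = BinaryMatrix(taxa, rng.integers(0, 2, (6, 40)).astype(np.int8),
                          [f"c{i}" for i in range(40)])
        res = bootstrap_autoMRE(bm, "mp",
                                params=SearchParams(seed=2, max_bootstrap=100))
        assert res.stopped_at <= 100

    def test_seed_fixes_replicate_tree_multiset(self):
        _, bm = self._clean_matrix()
        p = SearchParams(seed=9, max_bootstrap=60)
        a = bootstrap_autoMRE(bm, "mp", params=p)
        b = bootstrap_autoMRE(bm, "mp", params=p)
        na = sorted(t.to_newick(lengths=False) for t in a.replicates)
        nb = sorted(t.to_newick(lengths=False) for t in b.replicates)
        assert na == nb

    def test_ml_bootstrap_runs_and_stops(self):
        _, bm = self._clean_matrix(n_chars=400)
        spec = ModelSpec("binary", alpha=1.0, empirical_freqs=True)
        res = bootstrap_autoMRE(bm, "ml", spec=spec,
                                params=SearchParams(seed=3, max_bootstrap=50))
        assert res.stopped_at == 50


class TestMapSupport:
    def test_identical_replicates_give_full_support(self):
        t = Tree.from_newick("((A,B),(C,D),(E,F));")
        out = map_support(t, [t.copy() for _ in range(10)])
        assert set(out.support.values()) == {100.0}

    def test_absent_bipartition_scores_zero(self):
        best = Tree.from_newick("((A,B),(C,D),(E,F));")
        reps = [Tree.from_newick("((A,C),(B,D),(E,F));") for _ in range(5)]
        out = map_support(best, reps)
        assert out.support[frozenset(["C", "D"])] == 0.0

    def test_manual_tally_fixture(self):
        best = Tree.from_newick("((A,B),(C,D),(E,F));")
        reps = [Tree.from_newick(n) for n in [
            "((A,B),(C,D),(E,F));",
            "((A,B),(C,D),(E,F));",
            "((A,B),(C,E),(D,F));",
            "((A,C),(B,D),(E,F));",
            "((A,B),(C,D),(E,F));",
        ]]
        out = map_support(best, reps)
        # bipartitions are keyed by the side not containing taxon A
        assert out.support[frozenset(["C", "D", "E", "F"])] == 80.0  # A,B: 4/5
        assert out.support[frozenset(["C", "D"])] == 60.0            # 3 of 5
        assert out.support[frozenset(["E", "F"])] == 80.0            # 4 of 5

    def test_frequencies_match_independent_dendropy_oracle(self):
        import dendropy
        rng = np.random.default_rng(12)
        taxa = [f"T{i}" for i in range(6)]
        best = Tree.random_topology(taxa, rng)
        reps = [Tree.random_topology(taxa, rng) for _ in range(40)]
        out = map_support(best, reps)
        tns = dendropy.TaxonNamespace()
        dreps = [dendropy.Tree.get(data=r.to_newick(lengths=False),
                                   schema="newick", taxon_namespace=tns)
                 for r in reps]
        dbest = dendropy.Tree.get(data=best.to_newick(lengths=False),
                                  schema="newick", taxon_namespace=tns)
        for t in dreps + [dbest]:
            t.encode_bipartitions()
        counts = {}
        for t in dreps:
            for b in t.bipartition_encoding:
                counts[b.split_bitmask] = counts.get(b.split_bitmask, 0) + 1
        for edge in dbest.preorder_edge_iter():
            b = edge.bipartition
            if b is None or b.is_trivial():
                continue
            leafset = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter())
            if len(leafset) < 2 or len(leafset) > 4:
                continue
            if "T0" in leafset:
                leafset = frozenset(taxa) - leafset
            expect = 100.0 * counts.get(b.split_bitmask, 0) / len(dreps)
            assert out.support[leafset] == pytest.approx(expect)

    def test_leafset_mismatch_rejected(self):
        best = Tree.from_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            map_support(best, [Tree.from_newick("((A,B),(C,E));")])
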