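"""Backbone constraints, constrained searches, KH/SH tests, LBE."""

import numpy as np
import pytest

from corephylo.consttest import (ConstraintTree, check_compatibility,
                                 constrained_search, extract_backbone,
                                 kh_test_mp, lbe_experiment, sh_test_rell)
from corephylo.matrices import BinaryMatrix
from corephylo.models import ModelSpec
from corephylo.synthdata import (SimulationParams, evolve_binary_characters,
                                 simulate_dataset, simulate_species_tree)
from corephylo.treeinfer import (SearchParams, SiteScoreVector,
                                 log_likelihood, mp_search, parsimony_length)
from corephylo.trees import Tree


def supported_tree(newick, support_value=100.0):
    t = Tree.from_newick(newick)
    t.support = {bip: support_value for bip in t.bipartitions()}
    return t


class TestExtractBackbone:
    def test_full_support_preserves_topology(self):
        t = supported_tree("(((A,B),C),((D,E),F));")
        c = extract_backbone(t, threshold=100.0)
        assert c.tree.rf_distance(t) == 0

    def test_unreachable_threshold_gives_star(self):
        t = supported_tree("(((A,B),C),((D,E),F));")
        c = extract_backbone(t, threshold=101.0)
        assert len(c.tree.bipartitions()) == 0
        assert sorted(c.taxa) == list("ABCDEF")

    def test_mixed_support_keeps_only_maximal_groups(self):
        """Five internal branches, three at 100 and two at 90: exactly the
        three fully supported bipartitions survive."""
        t = Tree.from_newick("((((A,B),(C,D)),(E,F)),(G,H));")
        bips = t.bipartitions()
        hundred = [frozenset(["C", "D"]), frozenset(["E", "F"]),
                   frozenset(["G", "H"])]
        t.support = {b: (100.0 if b in hundred else 90.0) for b in bips}
        assert len(t.support) == 5
        c = extract_backbone(t, threshold=100.0)
        kept = set(c.tree.bipartitions())
        assert kept == set(hundred)

    def test_restriction_to_target_taxa(self):
        t = supported_tree("(((A,B),C),((D,E),F));")
        c = extract_backbone(t, threshold=100.0,
                             target_taxa=["A", "B", "D", "E"])
        assert sorted(c.taxa) == ["A", "B", "D", "E"]
        assert frozenset(["D", "E"]) in c.tree.bipartitions()


class TestCompatibility:
    def test_tree_displays_its_own_backbone(self):
        t = supported_tree("(((A,B),C),((D,E),F));")
        c = extract_backbone(t, threshold=100.0)
        assert check_compatibility(t, c)

    def test_leaf_swap_across_constrained_split_fails(self):
        t = supported_tree("(((A,B),C),((D,E),F));")
        c = extract_backbone(t, threshold=100.0)
        swapped = Tree.from_newick("(((A,D),C),((B,E),F));")
        assert not check_compatibility(swapped, c)

    def test_missing_constraint_taxon_rejected(self):
        c = ConstraintTree(Tree.from_newick("((A,B),(C,Z));"))
        with pytest.raises(ValueError):
            check_compatibility(Tree.from_newick("((A,B),(C,D));"), c)

    def test_agrees_with_bipartition_containment_oracle(self):
        """Random tree/constraint pairs versus a brute-force oracle that
        restricts the tree and compares bipartition sets directly."""
        rng = np.random.default_rng(23)
        taxa = [f"T{i}" for i in range(8)]
        agree = 0
        for trial in range(200):
            tree = Tree.random_topology(taxa, rng)
            sub = sorted(rng.choice(taxa, size=6, replace=False))
            cons_tree = Tree.random_topology(sub, rng)
            # randomly collapse some constraint edges into polytomies
            for bip, (u, v) in list(cons_tree.bipartitions().items()):
                if rng.random() < 0.5:
                    try:
                        cons_tree.collapse_edge(u, v)
                    except (KeyError, ValueError):
                        pass
            c = ConstraintTree(cons_tree)
            got = check_compatibility(tree, c)
            induced = tree.restrict(sub)
            expect = set(cons_tree.bipartitions()) <= set(induced.bipartitions())
            assert got == expect
            agree += 1
        assert agree == 200


class TestConstrainedSearch:
    def _matrix(self, seed=17):
        true = simulate_species_tree(6, seed)
        return true, evolve_binary_characters(true, 400, 1.0, 1.0, seed)

    def test_own_backbone_reaches_unconstrained_score(self):
        true, bm = self._matrix()
        params = SearchParams(addition_rounds=6, seed=3)
        trees, best = mp_search(bm, params)
        backbone = trees[0].copy()
        backbone.support = {b: 100.0 for b in backbone.bipartitions()}
        c = extract_backbone(backbone, threshold=100.0)
        _, constrained = constrained_search(bm, c, "mp", params)
        assert constrained == best

    def test_conflicting_constraint_strictly_worse(self):
        true, bm = self._matrix()
        params = SearchParams(addition_rounds=6, seed=3)
        _, best = mp_search(bm, params)
        # constrain against the data's strongest split: pair the two taxa
        # that the optimal tree separates
        trees, _ = mp_search(bm, params)
        some_bip = min(trees[0].bipartitions(), key=sorted)
        inside = sorted(some_bip)[0]
        outside = sorted(set(trees[0].taxa()) - some_bip)[0]
        others = [t for t in trees[0].taxa() if t not in (inside, outside)]
        cons = Tree.star(others)
        hub = next(n for n in cons.adj if n not in cons.labels)
        mid = cons.new_node()
        cons.add_edge(hub, mid)
        for lab in (inside, outside):
            cons.add_edge(mid, cons.new_node(lab))
        c = ConstraintTree(cons)
        _, constrained = constrained_search(bm, c, "mp", params)
        assert constrained > best

    def test_constrained_optimum_equals_enumeration_minimum(self):
        true, bm = self._matrix(seed=29)
        taxa = sorted(true.taxa())
        cons_tree = Tree.star(taxa[2:])
        hub = next(n for n in cons_tree.adj if n not in cons_tree.labels)
        mid = cons_tree.new_node()
        cons_tree.add_edge(hub, mid)
        for lab in taxa[:2]:
            cons_tree.add_edge(mid, cons_tree.new_node(lab))
        c = ConstraintTree(cons_tree)
        compat_best = min(
            parsimony_length(t, bm).total
            for t in Tree.enumerate_topologies(taxa)
            if check_compatibility(t, c))
        _, constrained = constrained_search(
            bm, c, "mp", SearchParams(addition_rounds=8, seed=5))
        assert constrained == compat_best


class TestKh:
    def _vec(self, values, tree_id, matrix_id="m1"):
        return SiteScoreVector(np.asarray(values, float), tree_id, matrix_id,
                               "steps")

    def test_identical_trees_give_p_one(self):
        a = self._vec([1, 2, 0, 1], "tA")
        res = kh_test_mp(a, self._vec([1, 2, 0, 1], "tB"))
        assert res.p_value == 1.0
        assert res.score_difference == 0.0
        assert not res.reject

    def test_uniformly_better_tree_significant(self):
        """Unit difference at all 30 sites: degenerate, maximally
        significant."""
        n = 30
        a = self._vec([1.0] * n, "tA")
        b = self._vec([2.0] * n, "tB")
        res = kh_test_mp(a, b, alpha=0.01)
        assert res.p_value < 0.01
        assert res.reject

    def test_mostly_better_tree_significant(self):
        rng = np.random.default_rng(4)
        n = 100
        d = rng.choice([0, 1], size=n, p=[0.3, 0.7])
        a = self._vec(np.ones(n), "tA")
        b = self._vec(np.ones(n) + d, "tB")
        res = kh_test_mp(a, b, alpha=0.01)
        assert res.p_value < 0.01
        assert res.score_difference < 0

    def test_symmetry_negates_statistic(self):
        rng = np.random.default_rng(9)
        a = self._vec(rng.integers(0, 4, 50), "tA")
        b = self._vec(rng.integers(0, 4, 50), "tB")
        fwd = kh_test_mp(a, b)
        rev = kh_test_mp(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_rell_variant_agrees_on_clear_cases(self):
        rng = np.random.default_rng(6)
        n = 120
        d = rng.choice([0, 1], size=n, p=[0.2, 0.8])
        a = self._vec(np.ones(n), "tA")
        b = self._vec(np.ones(n) + d, "tB")
        normal = kh_test_mp(a, b, alpha=0.01)
        rell = kh_test_mp(a, b, alpha=0.01, method="rell", seed=3)
        assert normal.reject and rell.reject
        same = kh_test_mp(a, a, method="rell")
        assert same.p_value == 1.0

    def test_matrix_provenance_mismatch_rejected(self):
        a = self._vec([1, 2], "tA", "m1")
        b = self._vec([1, 2], "tB", "m2")
        with pytest.raises(ValueError):
            kh_test_mp(a, b)


class TestSh:
    def _vecs(self, rows, matrix_id="m1"):
        return [SiteScoreVector(np.asarray(r, float), f"t{i}", matrix_id, "lnl")
                for i, r in enumerate(rows)]

    def test_best_candidate_has_p_one(self):
        rng = np.random.default_rng(7)
        base = -np.abs(rng.normal(2, 0.5, 200))
        rows = [base, base - 0.02, base - 0.05]
        res = sh_test_rell(self._vecs(rows), seed=1)
        assert res[0].p_value == 1.0

    def test_duplicate_of_best_not_significant(self):
        rng = np.random.default_rng(3)
        base = -np.abs(rng.normal(2, 0.5, 150))
        rows = [base, base.copy(), base - 0.3]
        res = sh_test_rell(self._vecs(rows), seed=2)
        assert res[1].p_value >= 0.5

    def test_matches_bruteforce_resampling_oracle(self):
        """Three-candidate fixture checked against an independently coded
        RELL loop at the same seed."""
        rng = np.random.default_rng(11)
        n = 60
        rows = [-np.abs(rng.normal(1.5, 0.4, n)) for _ in range(3)]
        vecs = self._vecs(rows)
        res = sh_test_rell(vecs, replicates=500, seed=5)

        from corephylo._seeds import stream
        S = np.vstack(rows)
        totals = S.sum(axis=1)
        best = int(np.argmax(totals))
        d_obs = totals[best] - totals
        r2 = stream(5, "sh-rell")
        idx = r2.integers(0, n, size=(500, n))
        ps = []
        for k in range(3):
            count = 0
            R = np.array([[S[j, idx[b]].sum() for j in range(3)]
                          for b in range(500)])
            Rc = R - R.mean(axis=0, keepdims=True)
            for b in range(500):
                if Rc[b].max() - Rc[b, k] >= d_obs[k]:
                    count += 1
            ps.append(count / 500)
        for r, p in zip(res, ps):
            assert r.p_value == pytest.approx(p)

    def test_fewer_than_two_candidates_rejected(self):
        with pytest.raises(ValueError):
            sh_test_rell(self._vecs([[1.0, 2.0]]))


class TestLbe:
    def test_dropping_leaf_from_clean_data_preserves_topology(self):
        true = simulate_species_tree(7, seed=2)
        bm = evolve_binary_characters(true, 800, 1.0, 1.0, seed=3)
        report = lbe_experiment(bm, ["G07"], "mp",
                                SearchParams(addition_rounds=5, seed=1))
        assert report.rf_distance == 0
        assert report.topology_unchanged

    def test_unknown_taxon_rejected(self):
        true = simulate_species_tree(5, seed=2)
        bm = evolve_binary_characters(true, 100, 1.0, 1.0, seed=3)
        with pytest.raises(ValueError):
            lbe_experiment(bm, ["G99"], "mp")

    def test_report_contains_both_topologies_and_rf(self):
        true = simulate_species_tree(6, seed=4)
        bm = evolve_binary_characters(true, 500, 1.0, 1.0, seed=5)
        report = lbe_experiment(bm, ["G01"], "mp",
                                SearchParams(addition_rounds=4, seed=2))
        text = report.summary()
        assert "RF=" in text
        assert report.reduced_tree.n_leaves == 5
        assert report.induced_subtree.n_leaves == 5
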