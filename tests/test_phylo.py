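import dendropy
import numpy as np
import pytest
from scipy.optimize import minimize

import thermoniche as tn
from thermoniche.errors import DegenerateDistributionError, FormatError, ParameterError


def squared_change_oracle(tree, traits, weighted):
    """Numeric minimization of the squared-change objective, independent of
    the linear-system solver: optimize internal values directly."""
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {id(nd): i for i, nd in enumerate(internal)}

    def value(nd, x):
        if nd.is_leaf():
            return traits[nd.taxon.label]
        return x[idx[id(nd)]]

    def objective(x):
        total = 0.0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            w = float(nd.edge.length) if weighted else 1.0
            total += (value(nd, x) - value(nd.parent_node, x)) ** 2 / w
        return total

    x0 = np.full(len(internal), np.mean(list(traits.values())))
    res = minimize(objective, x0, method="BFGS", options={"gtol": 1e-12})
    return {internal[i]: res.x[i] for i in range(len(internal))}, res.fun


class TestReadNewick:
    def test_parses_topology_and_lengths(self):
        tree = tn.read_newick("((A:1,B:1):1,C:2);")
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert sorted(tips) == ["A", "B", "C"]
        assert sum(1 for nd in tree.preorder_node_iter() if not nd.is_leaf()) == 2

    def test_round_trip_preserves_tree(self, tmp_path, tree8):
        path = tmp_path / "t.nwk"
        tn.write_newick(tree8, path)
        back = tn.read_newick(path)
        ns = dendropy.TaxonNamespace()
        t1, t2 = tree8.clone(1), back.clone(1)
        t1.migrate_taxon_namespace(ns)
        t2.migrate_taxon_namespace(ns)
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0
        lengths = sorted(
            e.length for e in back.preorder_edge_iter() if e.length is not None
        )
        orig = sorted(e.length for e in tree8.preorder_edge_iter() if e.length is not None)
        np.testing.assert_allclose(lengths, orig)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(FormatError):
            tn.read_newick("((A,B),A);")

    def test_malformed_string_rejected(self):
        with pytest.raises(FormatError):
            tn.read_newick("((A,B;")


class TestAncestralStates:
    def test_two_tip_symmetry(self):
        tree = tn.read_newick("(A:1,B:1);")
        states = tn.ancestral_states(tree, {"A": 10.0, "B": 20.0})
        assert states.root_value == pytest.approx(15.0)

    def test_three_tip_worked_example(self):
        tree = tn.read_newick("((A:1,B:1):1,C:2);")
        states = tn.ancestral_states(tree, {"A": 0.0, "B": 2.0, "C": 4.0}, weighted=True)
        vals = sorted(states.states.values())
        assert vals[0] == pytest.approx(10 / 7, abs=1e-12)  # internal node
        assert states.root_value == pytest.approx(16 / 7, abs=1e-12)

    def test_matches_numeric_minimization_oracle(self, tree8, rng):
        traits = {f"{c}": float(v) for c, v in zip("ABCDEFGH", rng.uniform(0, 30, 8))}
        for weighted in (True, False):
            states = tn.ancestral_states(tree8, traits, weighted=weighted)
            oracle, _ = squared_change_oracle(tree8, traits, weighted)
            ours = sorted(states.states.values())
            theirs = sorted(oracle.values())
            np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_constant_traits_propagate(self, tree8):
        states = tn.ancestral_states(tree8, {t: 7.7 for t in "ABCDEFGH"})
        assert all(v == pytest.approx(7.7) for v in states.states.values())

    def test_values_bounded_by_tip_range(self, rng):
        for seed in range(10):
            tree = tn.gen_random_tree(int(rng.integers(5, 12)), seed=seed)
            tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
            traits = {t: float(v) for t, v in zip(tips, rng.uniform(-10, 40, len(tips)))}
            states = tn.ancestral_states(tree, traits)
            lo, hi = min(traits.values()), max(traits.values())
            assert all(lo - 1e-9 <= v <= hi + 1e-9 for v in states.states.values())

    def test_weighted_root_equals_gls_mean(self, rng):
        # closed-form equivalence of the weighted optimum with the Brownian
        # GLS phylogenetic mean computed from the tip covariance
        for seed in range(25):
            n = int(rng.integers(6, 13))
            tree = tn.gen_random_tree(n, seed=1000 + seed)
            tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
            traits = {t: float(v) for t, v in zip(tips, rng.normal(15, 5, n))}
            states = tn.ancestral_states(tree, traits, weighted=True)
            C, labels = tn.brownian_covariance(tree)
            y = np.array([traits[t] for t in labels])
            Cinv = np.linalg.inv(C)
            ones = np.ones(n)
            gls_mean = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
            assert states.root_value == pytest.approx(gls_mean, abs=1e-8)

    def test_missing_tip_traits_pruned_with_warning(self, tree8):
        traits = {t: 1.0 * i for i, t in enumerate("ABCDEFG")}  # H missing
        with pytest.warns(UserWarning, match="pruning"):
            states = tn.ancestral_states(tree8, traits)
        assert states.root_value == pytest.approx(
            tn.ancestral_states(tn.read_newick(
                "(((A:0.5,B:1.2):0.8,(C:0.3,D:0.9):1.1):0.4,((E:0.7,F:0.2):0.6,G:2.4):1.3);"
            ), traits).root_value, abs=1e-9)

    def test_zero_length_internal_branch_modes(self):
        tree = tn.read_newick("((A:1,B:1):0,C:2);")
        traits = {"A": 0.0, "B": 2.0, "C": 4.0}
        collapsed = tn.ancestral_states(tree, traits, weighted=True, zero_length="collapse")
        assert np.isfinite(collapsed.root_value)
        with pytest.raises(ParameterError):
            tn.ancestral_states(tree, traits, weighted=True, zero_length="error")


def blomberg_oracle(tree, traits):
    """Direct dense-matrix evaluation of K with C built from patristic
    distances and root depths — independent of the implementation's
    path-walking covariance construction."""
    pdm = tree.phylogenetic_distance_matrix()
    tips = [lf.taxon for lf in tree.leaf_node_iter()]
    depth = {}
    for lf in tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length
            nd = nd.parent_node
        depth[lf.taxon] = d
    n = len(tips)
    C = np.zeros((n, n))
    for i, ti in enumerate(tips):
        for j, tj in enumerate(tips):
            if i == j:
                C[i, j] = depth[ti]
            else:
                C[i, j] = (depth[ti] + depth[tj] - pdm.patristic_distance(ti, tj)) / 2.0
    y = np.array([traits[t.label] for t in tips])
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
    r = y - a
    ratio = (r @ r) / (r @ Cinv @ r)
    expected = (np.trace(C) - n / Cinv.sum()) / (n - 1)
    return ratio / expected


class TestBlombergK:
    def test_star_tree_gives_exactly_one(self):
        tree = tn.read_newick("(A:2,B:2,C:2,D:2,E:2);")
        res = tn.blomberg_k(tree, {"A": 1, "B": 3, "C": 0, "D": 7, "E": 2}, n_perm=19, seed=0)
        assert res.K == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, tree8, rng):
        tips = list("ABCDEFGH")
        y = rng.normal(20, 4, 8)
        base = tn.blomberg_k(tree8, dict(zip(tips, y)), n_perm=9, seed=1).K
        trans = tn.blomberg_k(tree8, dict(zip(tips, -2.5 * y + 40)), n_perm=9, seed=1).K
        assert trans == pytest.approx(base, rel=1e-12)

    def test_matches_dense_matrix_oracle(self, tree8, rng):
        traits = dict(zip("ABCDEFGH", rng.normal(10, 5, 8)))
        res = tn.blomberg_k(tree8, traits, n_perm=9, seed=0)
        assert res.K == pytest.approx(blomberg_oracle(tree8, traits), abs=1e-10)

    def test_permutation_p_floor_and_determinism(self, tree8, rng):
        traits = dict(zip("ABCDEFGH", rng.normal(0, 1, 8)))
        a = tn.blomberg_k(tree8, traits, n_perm=99, seed=12)
        b = tn.blomberg_k(tree8, traits, n_perm=99, seed=12)
        assert a.p == b.p
        assert a.p >= 1.0 / (99 + 1)
        assert a.p <= 1.0

    def test_constant_trait_rejected(self, tree8):
        with pytest.raises(DegenerateDistributionError):
            tn.blomberg_k(tree8, {t: 5.0 for t in "ABCDEFGH"})

    def test_strong_signal_detected_on_clustered_traits(self, tree8):
        # the two basal clades carry well-separated values -> small p
        traits = {"A": 1.0, "B": 1.2, "C": 0.9, "D": 1.1, "E": 9.0, "F": 9.2, "G": 8.8, "H": 9.1}
        res = tn.blomberg_k(tree8, traits, n_perm=199, seed=3)
        assert res.p <= 0.05


class TestDeltaVsAncestor:
    def test_signs_follow_root_comparison(self):
        tree = tn.read_newick("((A:1,B:1):1,C:2);")
        traits = {"A": 0.0, "B": 2.0, "C": 4.0}
        states = tn.ancestral_states(tree, traits)  # root = 16/7
        signs = tn.delta_vs_ancestor(states, traits)
        assert signs == {"A": "-", "B": "-", "C": "+"}

    def test_higher_tip_is_positive(self):
        tree = tn.read_newick("(A:1,B:1);")
        states = tn.ancestral_states(tree, {"A": 31.7, "B": 31.7})
        assert tn.delta_vs_ancestor(states, {"A": 34.6, "B": 31.7}) == {"A": "+", "B": "0"}

    def test_infinite_tolerance_yields_all_zero(self):
        tree = tn.read_newick("(A:1,B:1);")
        states = tn.ancestral_states(tree, {"A": 0.0, "B": 50.0})
        signs = tn.delta_vs_ancestor(states, {"A": 0.0, "B": 50.0}, tol=np.inf)
        assert set(signs.values()) == {"0"}
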