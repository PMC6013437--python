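import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mkhet
from mkhet import MkModel, FLAT_PRIOR, transition_probability
from mkhet.trees import TreeIndex
from conftest import make_tree
from oracles import enum_log_likelihood, random_tree

rates = st.floats(min_value=1e-6, max_value=5.0)
times = st.floats(min_value=0.0, max_value=50.0)


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        P = transition_probability(MkModel.mk2(0.3, 0.01), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_closed_form_value(self):
        # P01 = 0.5 * (1 - exp(-2 q t)) for Mk1
        P = transition_probability(MkModel.mk1(0.01), 10.0)
        assert P[0, 1] == pytest.approx(0.5 * (1 - math.exp(-0.2)), abs=1e-12)
        assert P[0, 1] == pytest.approx(0.090635, abs=1e-6)

    def test_absorbing_state(self):
        P = transition_probability(MkModel.mk2(0.0, 0.7), 12.0)
        assert P[0, 0] == 1.0 and P[0, 1] == 0.0

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            transition_probability(MkModel.mk1(0.1), -1.0)

    @settings(deadline=None, derandomize=True)
    @given(q01=rates, q10=rates, t=times)
    def test_rows_are_distributions(self, q01, q10, t):
        P = transition_probability(MkModel.mk2(q01, q10), t)
        assert np.all(P >= 0) and np.all(P <= 1)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(q01=rates, q10=rates, t1=times, t2=times)
    def test_chapman_kolmogorov(self, q01, q10, t1, t2):
        m = MkModel.mk2(q01, q10)
        lhs = transition_probability(m, t1) @ transition_probability(m, t2)
        rhs = transition_probability(m, t1 + t2)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestPruningLikelihood:
    def test_star_tree_zero_lengths_forced_by_prior(self):
        tree = make_tree("(a:0,b:0,c:0);")
        lnl = mkhet.pruning_log_likelihood(
            tree, {"a": 0, "b": 0, "c": 0}, MkModel.mk1(0.1)
        )
        assert lnl == pytest.approx(math.log(0.5), abs=1e-12)

    def test_all_missing_gives_likelihood_one(self, four_tip_tree):
        lnl = mkhet.pruning_log_likelihood(
            four_tip_tree, {t: 2 for t in "ABCD"}, MkModel.mk2(0.03, 0.3)
        )
        assert lnl == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_on_random_trees(self):
        rng = random.Random(1234)
        for _ in range(30):
            tree = random_tree(rng, rng.randint(2, 6))
            idx = TreeIndex(tree)
            col = {lab: rng.choice([0, 1, 0, 1, 2, 3]) for lab in idx.tip_index}
            codes = idx.tip_codes(col)
            model = MkModel.mk2(rng.uniform(0.001, 0.3), rng.uniform(0.001, 0.3))
            got = mkhet.pruning_log_likelihood(idx, col, model)
            want = enum_log_likelihood(idx, codes, model, FLAT_PRIOR)
            assert got == pytest.approx(want, abs=1e-9)

    def test_mk1_flat_prior_invariant_to_rerooting(self):
        rng = random.Random(7)
        tree = random_tree(rng, 8, polytomies=False)
        idx = TreeIndex(tree)
        col = {lab: rng.choice([0, 1]) for lab in idx.tip_index}
        model = MkModel.mk1(0.05)
        ref = mkhet.pruning_log_likelihood(idx, col, model)
        # reroot along a few internal edges
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()][2:]
        for nd in internals[:3]:
            t2 = tree.clone(depth=1)
            # find the matching node in the clone by leaf set, reroot on its edge
            leaves = {lf.taxon.label for lf in nd.leaf_iter()}
            cand = [
                x
                for x in t2.preorder_node_iter()
                if {lf.taxon.label for lf in x.leaf_iter()} == leaves
            ][0]
            t2.reroot_at_edge(cand.edge, length1=cand.edge.length / 2, length2=cand.edge.length / 2)
            got = mkhet.pruning_log_likelihood(t2, col, model)
            assert got == pytest.approx(ref, abs=1e-8)

    def test_tip_without_cell_raises(self, four_tip_tree):
        with pytest.raises(KeyError):
            mkhet.pruning_log_likelihood(four_tip_tree, {"A": 0}, MkModel.mk1(0.1))


class TestFitting:
    def test_mk1_recovers_simulated_rate(self):
        cfg = mkhet.SimulationConfig(
            seed=5, partition_sizes={"P1": 250, "P2": 250, "P3": 250, "P4": 250, "P5": 250}
        )
        tree = mkhet.simulate_tree(cfg)
        idx = TreeIndex(tree)
        models = {f"P{i}": MkModel.mk1(0.01) for i in range(1, 6)}
        col, _, _ = mkhet.simulate_character(idx, models, seed=5)
        fit = mkhet.fit_mk1(idx, col)
        assert 0.005 <= fit.model.q01 <= 0.02
        assert fit.k == 1 and not fit.bound_hit

    def test_constant_character_hits_lower_bound(self, four_tip_tree):
        fit = mkhet.fit_mk1(four_tip_tree, {t: 0 for t in "ABCD"})
        assert fit.bound_hit
        assert fit.model.q01 <= 1e-6

    def test_mk2_nests_mk1(self, study_bundle):
        col = study_bundle.matrix.column("symmetry")
        f1 = mkhet.fit_mk1(study_bundle.index, col)
        f2 = mkhet.fit_mk2(study_bundle.index, col)
        assert f2.log_likelihood >= f1.log_likelihood - 1e-6
        assert f2.k == 2

    def test_aic_identity(self, study_bundle):
        col = study_bundle.matrix.column("fusion")
        f = mkhet.fit_mk1(study_bundle.index, col)
        assert f.aic == pytest.approx(2 * f.k - 2 * f.log_likelihood, abs=1e-9)

    def test_no_determinate_tip_raises(self, four_tip_tree):
        with pytest.raises(ValueError):
            mkhet.fit_mk1(four_tip_tree, {t: 2 for t in "ABCD"})


class TestAicCompare:
    def test_identical_fits_tie(self, study_bundle):
        col = study_bundle.matrix.column("merism")
        f = mkhet.fit_mk1(study_bundle.index, col)
        table = mkhet.aic_compare([f, f])
        assert table["dAIC"].tolist() == [0.0, 0.0]

    def test_mk1_preferred_on_mk1_data(self):
        # symmetric-rate data: the extra Mk2 parameter is AIC-penalized
        cfg = mkhet.SimulationConfig(
            seed=9, partition_sizes={"P1": 150, "P2": 150, "P3": 150, "P4": 150, "P5": 150}
        )
        tree = mkhet.simulate_tree(cfg)
        idx = TreeIndex(tree)
        models = {f"P{i}": MkModel.mk1(0.008) for i in range(1, 6)}
        col, _, _ = mkhet.simulate_character(idx, models, seed=9)
        f1 = mkhet.fit_mk1(idx, col, label="Mk1")
        f2 = mkhet.fit_mk2(idx, col, label="Mk2")
        table = mkhet.aic_compare([f1, f2])
        assert table.iloc[0]["label"] == "Mk1"
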