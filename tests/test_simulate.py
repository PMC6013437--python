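import math

import dendropy
import numpy as np
import pytest

import mkhet
from mkhet import MkModel, SimulationConfig
from mkhet.characters import MISSING, POLYMORPHIC
from mkhet.trees import TreeIndex, is_ultrametric, node_ages


SMALL_SIZES = {"P1": 20, "P2": 25, "P3": 15, "P4": 30, "P5": 20}


class TestTreeSimulation:
    def test_same_seed_reproduces_newick_exactly(self):
        cfg = SimulationConfig(seed=42, partition_sizes=SMALL_SIZES)
        t1 = mkhet.simulate_tree(cfg).as_string(schema="newick")
        t2 = mkhet.simulate_tree(cfg).as_string(schema="newick")
        assert t1 == t2

    def test_structure_tip_count_clades_and_depth(self):
        cfg = SimulationConfig(seed=1, partition_sizes=SMALL_SIZES, depth=140.0)
        tree = mkhet.simulate_tree(cfg)
        assert len(tree.leaf_nodes()) == sum(SMALL_SIZES.values())
        labels = {nd.label for nd in tree.preorder_node_iter() if nd.label}
        assert set(SMALL_SIZES) <= labels
        assert is_ultrametric(tree, tol=1e-6)
        assert max(node_ages(tree).values()) == pytest.approx(140.0, abs=1e-6)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, partition_sizes={"P1": 1, "P2": 5})


class TestCharacterSimulation:
    def test_zero_rates_freeze_root_state(self):
        cfg = SimulationConfig(seed=3, partition_sizes=SMALL_SIZES)
        tree = mkhet.simulate_tree(cfg)
        models = {n: MkModel.mk1(0.0) for n in SMALL_SIZES}
        col, states, idx = mkhet.simulate_character(tree, models, seed=3)
        root_state = states[idx.root]
        assert set(col.values()) == {root_state}

    def test_stationary_frequency_on_long_branch_star_tree(self):
        # tips on effectively infinite branches sample the stationary law
        n = 400
        tree = dendropy.Tree()
        for i in range(n):
            leaf = dendropy.Node()
            tree.seed_node.add_child(leaf)
            leaf.edge.length = 1e5
            leaf.taxon = tree.taxon_namespace.new_taxon(label=f"t{i}")
        tree.is_rooted = True
        tree.seed_node.label = "all"
        model = MkModel.mk2(0.002, 0.02)
        col, _, _ = mkhet.simulate_character(tree, {"all": model}, seed=11)
        pi1 = model.stationary[1]
        freq = np.mean(list(col.values()))
        se = math.sqrt(pi1 * (1 - pi1) / n)
        assert abs(freq - pi1) <= 3 * se

    def test_partition_rate_contrast_recovered_in_direction(self):
        cfg = SimulationConfig(seed=6, partition_sizes={"P1": 150, "P2": 150})
        tree = mkhet.simulate_tree(cfg)
        models = {"P1": MkModel.mk1(0.0005), "P2": MkModel.mk1(0.05)}
        col, _, _ = mkhet.simulate_character(tree, models, seed=6)
        sub1 = mkhet.prune_to_taxa(tree, [t for t in col if t.startswith("P1")])
        sub2 = mkhet.prune_to_taxa(tree, [t for t in col if t.startswith("P2")])
        f1 = mkhet.fit_mk1(sub1, {t: c for t, c in col.items() if t.startswith("P1")})
        f2 = mkhet.fit_mk1(sub2, {t: c for t, c in col.items() if t.startswith("P2")})
        assert f2.model.q01 > f1.model.q01

    def test_asr_accuracy_beats_chance_and_improves_at_lower_rate(self):
        cfg = SimulationConfig(seed=13, partition_sizes=SMALL_SIZES)
        tree = mkhet.simulate_tree(cfg)
        idx = TreeIndex(tree)
        accs = {}
        for q, counter in [(0.002, 21), (0.02, 22)]:
            models = {n: MkModel.mk1(q) for n in SMALL_SIZES}
            hits = total = 0
            for rep in range(10):
                col, states, _ = mkhet.simulate_character(
                    idx, models, seed=13, counter=counter + 100 * rep
                )
                if len(set(col.values())) < 2:
                    continue
                res = mkhet.marginal_asr(idx, col, MkModel.mk1(q))
                for i in range(idx.n):
                    if idx.is_tip[i]:
                        continue
                    p0, p1 = res.probabilities[i]
                    guess = 0 if p0 > p1 else 1
                    hits += guess == states[i]
                    total += 1
            accs[q] = hits / total
        assert accs[0.002] > 0.5 and accs[0.02] > 0.5
        assert accs[0.002] >= accs[0.02]


class TestDegradation:
    def test_zero_fractions_identity(self, study_bundle):
        out = mkhet.degrade_matrix(study_bundle.clean_matrix, 0.0, 0.0, seed=1)
        assert out == study_bundle.clean_matrix

    def test_exact_cell_counts(self, study_bundle):
        clean = study_bundle.clean_matrix
        out = mkhet.degrade_matrix(clean, 0.0, 0.1, seed=5)
        arr = out.data.to_numpy()
        assert (arr == POLYMORPHIC).sum() == round(0.1 * arr.size)

    def test_all_missing_gives_zero_log_likelihood(self, study_bundle):
        out = mkhet.degrade_matrix(study_bundle.clean_matrix, 1.0, 0.0, seed=2)
        col = out.column("symmetry")
        lnl = mkhet.pruning_log_likelihood(study_bundle.index, col, MkModel.mk1(0.01))
        assert lnl == pytest.approx(0.0, abs=1e-12)

    def test_overfull_fractions_rejected(self, study_bundle):
        with pytest.raises(ValueError):
            mkhet.degrade_matrix(study_bundle.clean_matrix, 0.7, 0.5, seed=1)
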