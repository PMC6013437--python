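import numpy as np
import pytest

import mkhet
from mkhet import MkModel, FitResult, PartitionScheme
from mkhet.partitions import (
    fit_partitioned,
    select_best_composite,
    split_tree,
    symmetry_ratio,
)
from mkhet.trees import TreeIndex, leaf_labels, normalize_label
from conftest import make_tree


@pytest.fixture
def three_clade_tree():
    return make_tree(
        "(((a1:1,a2:1)A:2,(b1:1,b2:1)B:2)AB:1,(c1:2,c2:2)C:2)root;"
    )


class TestSplitTree:
    def test_tip_conservation_and_disjointness(self, study_bundle, study_scheme):
        subtrees, _ = split_tree(study_bundle.tree, study_scheme)
        all_tips = [normalize_label(l) for t in subtrees.values() for l in leaf_labels(t)]
        assert len(all_tips) == len(set(all_tips))
        assert set(all_tips) == {normalize_label(l) for l in leaf_labels(study_bundle.tree)}

    def test_named_node_spanning_clades_is_lost(self, three_clade_tree):
        scheme = PartitionScheme.from_tip_sets(
            {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1", "c2"]}
        )
        subtrees, lost = split_tree(three_clade_tree, scheme)
        assert set(lost) == {"AB", "root"}
        assert set(subtrees) == {"A", "B", "C"}

    def test_single_partition_scheme_loses_nothing(self, three_clade_tree):
        scheme = PartitionScheme.from_tip_sets(
            {"all": ["a1", "a2", "b1", "b2", "c1", "c2"]}
        )
        subtrees, lost = split_tree(three_clade_tree, scheme)
        assert lost == []
        assert len(leaf_labels(subtrees["all"])) == 6

    def test_overlapping_partitions_rejected(self, three_clade_tree):
        scheme = PartitionScheme.from_tip_sets(
            {"X": ["a1", "a2", "b1"], "Y": ["b1", "b2", "c1", "c2"]}
        )
        with pytest.raises(ValueError, match="b1"):
            split_tree(three_clade_tree, scheme)

    def test_uncovered_tips_rejected(self, three_clade_tree):
        scheme = PartitionScheme.from_tip_sets({"X": ["a1", "a2"]})
        with pytest.raises(ValueError, match="not covered"):
            split_tree(three_clade_tree, scheme)


class TestCompositeFit:
    def test_single_partition_reduces_to_full_tree_fit(self, study_bundle):
        col = study_bundle.matrix.column("fusion")
        tips = list(study_bundle.index.tip_index)
        scheme = PartitionScheme.from_tip_sets({"all": tips})
        subtrees, _ = split_tree(study_bundle.tree, scheme)
        comp = fit_partitioned(subtrees, col, "mk1")
        full = mkhet.fit_mk1(study_bundle.index, col)
        assert comp.log_likelihood == pytest.approx(full.log_likelihood, abs=1e-6)
        assert comp.k == full.k

    def test_aic_arithmetic_identity(self, study_bundle, study_scheme):
        col = study_bundle.matrix.column("symmetry")
        subtrees, _ = split_tree(study_bundle.tree, study_scheme)
        comp = fit_partitioned(subtrees, col, "mk1")
        assert comp.aic == 2 * comp.k - 2 * comp.log_likelihood
        assert comp.k == 5

    def test_degenerate_partition_flagged(self, three_clade_tree):
        scheme = PartitionScheme.from_tip_sets(
            {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1", "c2"]}
        )
        subtrees, _ = split_tree(three_clade_tree, scheme)
        col = {"a1": 0, "a2": 1, "b1": 0, "b2": 1, "c1": 2, "c2": 2}
        comp = fit_partitioned(subtrees, col, "mk1")
        assert comp.degenerate == ["C"]
        assert comp.partition_fits["C"].log_likelihood == 0.0
        assert comp.partition_fits["C"].k == 0

    def test_censored_additivity(self, study_bundle, study_scheme):
        """Per-partition optima fit at least as well as a shared rate on the
        same (censored) edges."""
        col = study_bundle.matrix.column("differentiation")
        subtrees, _ = split_tree(study_bundle.tree, study_scheme)
        sub_idx = {n: TreeIndex(t) for n, t in subtrees.items()}
        comp = fit_partitioned(sub_idx, col, "mk1")
        shared = mkhet.fit_mk1(study_bundle.index, col)
        shared_on_subtrees = sum(
            mkhet.pruning_log_likelihood(
                si, {t: c for t, c in col.items() if normalize_label(t) in si.tip_index},
                shared.model,
            )
            for si in sub_idx.values()
        )
        assert comp.log_likelihood >= shared_on_subtrees - 1e-9


class TestSymmetryRatioAndSelection:
    def test_ratio_arithmetic(self):
        f = FitResult(MkModel.mk2(0.001, 0.05), -10.0, 2)
        assert symmetry_ratio(f) == pytest.approx(0.02)
        f_eq = FitResult(MkModel.mk2(0.01, 0.01), -10.0, 2)
        assert symmetry_ratio(f_eq) == 1.0

    def test_ratio_zero_and_undefined(self):
        assert symmetry_ratio(FitResult(MkModel.mk2(0.0, 0.01), -1.0, 2)) == 0.0
        with pytest.raises(ValueError):
            symmetry_ratio(FitResult(MkModel.mk2(0.0, 0.0), -1.0, 2))

    def test_tie_goes_to_mk1(self):
        mk1 = {"P": FitResult(MkModel.mk1(0.01), -100.0, 1)}
        mk2 = {"P": FitResult(MkModel.mk2(0.01, 0.02), -100.0, 2)}  # dAIC = 2 worse
        choices, comp = select_best_composite(mk1, mk2)
        assert choices == {"P": "Mk1"}
        assert comp.aic == mk1["P"].aic

    def test_clear_mk2_advantage_selected(self):
        mk1 = {"P": FitResult(MkModel.mk1(0.01), -110.0, 1)}
        mk2 = {"P": FitResult(MkModel.mk2(0.001, 0.05), -100.0, 2)}
        choices, comp = select_best_composite(mk1, mk2)
        assert choices == {"P": "Mk2"}

    def test_composite_never_worse_than_uniform_choices(self):
        mk1 = {
            "P1": FitResult(MkModel.mk1(0.01), -110.0, 1),
            "P2": FitResult(MkModel.mk1(0.01), -50.0, 1),
        }
        mk2 = {
            "P1": FitResult(MkModel.mk2(0.001, 0.05), -100.0, 2),
            "P2": FitResult(MkModel.mk2(0.01, 0.012), -49.9, 2),
        }
        choices, comp = select_best_composite(mk1, mk2)
        assert choices == {"P1": "Mk2", "P2": "Mk1"}
        uniform1 = sum(f.aic for f in mk1.values())
        uniform2 = sum(f.aic for f in mk2.values())
        assert comp.aic <= min(uniform1, uniform2)
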