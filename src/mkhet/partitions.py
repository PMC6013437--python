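"""Censored partitioned-rate models and AIC heterogeneity tests.

The tree is split into named partitions (clades or grades given as explicit
tip sets), each partition is pruned to its own MRCA-rooted subtree, and an
independent Mk model is fitted per subtree.  Because the subtrees drop the
backbone edges connecting partitions (the "censored" approach), the combined
log-likelihood is simply the sum over partitions; the composite is compared
with the single full-tree model by AIC.  Note the caveat that full-tree and
composite likelihoods are not computed on identical edge sets — the censored
comparison is deliberate and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .mk import FLAT_PRIOR, FitResult, MkModel, RootPrior, fit_mk1, fit_mk2
from .trees import TreeIndex, leaf_labels, normalize_label, node_by_label, prune_to_taxa


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered named partitions defined by explicit tip sets.

    Grades (non-monophyletic partitions) are supported because membership is
    by tip list, not by clade anchor.
    """

    partitions: tuple[tuple[str, frozenset[str]], ...]

    @classmethod
    def from_tip_sets(cls, sets: Mapping[str, Sequence[str]]) -> "PartitionScheme":
        return cls(
            tuple(
                (name, frozenset(normalize_label(t) for t in tips))
                for name, tips in sets.items()
            )
        )

    @classmethod
    def from_clades(cls, tree: dendropy.Tree, clade_labels: Sequence[str]) -> "PartitionScheme":
        """Build a scheme from labelled monophyletic clade anchors."""
        sets = {}
        for label in clade_labels:
            node = node_by_label(tree, label)
            sets[label] = [lf.taxon.label for lf in node.leaf_iter()]
        return cls.from_tip_sets(sets)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.partitions]

    def tip_set(self, name: str) -> frozenset[str]:
        for n, s in self.partitions:
            if n == name:
                return s
        raise KeyError(name)

    def partition_of(self, tip_label: str) -> str | None:
        t = normalize_label(tip_label)
        for name, tips in self.partitions:
            if t in tips:
                return name
        return None

    def validate(self, tree: dendropy.Tree) -> None:
        seen: dict[str, str] = {}
        for name, tips in self.partitions:
            for t in tips:
                if t in seen:
                    raise ValueError(f"tip {t!r} in partitions {seen[t]!r} and {name!r}")
                seen[t] = name
        tree_tips = {normalize_label(l) for l in leaf_labels(tree)}
        uncovered = tree_tips - set(seen)
        if uncovered:
            raise ValueError(f"tips not covered by any partition: {sorted(uncovered)[:10]}")
        unknown = set(seen) - tree_tips
        if unknown:
            raise ValueError(f"partition tips absent from tree: {sorted(unknown)[:10]}")


def split_tree(
    tree: dendropy.Tree, scheme: PartitionScheme
) -> tuple[dict[str, dendropy.Tree], list[str]]:
    """Prune one MRCA-rooted subtree per partition; report lost named nodes.

    A labelled internal node whose descendant tips span more than one
    partition cannot be reconstructed on any subtree and is returned in the
    lost list.
    """
    scheme.validate(tree)
    subtrees = {name: prune_to_taxa(tree, tips) for name, tips in scheme.partitions}
    lost = []
    idx = TreeIndex(tree, require_lengths=False)
    tipsets = idx.descendant_tip_labels()
    for i, nd in enumerate(idx.nodes):
        if idx.is_tip[i] or not nd.label:
            continue
        parts = {scheme.partition_of(t) for t in tipsets[i]}
        if len(parts) > 1:
            lost.append(nd.label)
    return subtrees, lost


@dataclass
class CompositeFit:
    """Independent per-partition fits combined by summing lnL and k."""

    partition_fits: dict[str, FitResult]
    degenerate: list[str] = field(default_factory=list)

    @property
    def log_likelihood(self) -> float:
        return sum(f.log_likelihood for f in self.partition_fits.values())

    @property
    def k(self) -> int:
        return sum(f.k for f in self.partition_fits.values())

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_likelihood

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, f in self.partition_fits.items():
            rows.append(
                {
                    "partition": name,
                    "model": "Mk1" if f.model.is_mk1 else ("none" if f.k == 0 else "Mk2"),
                    "q01": f.model.q01,
                    "q10": f.model.q10,
                    "lnL": f.log_likelihood,
                    "k": f.k,
                    "AIC": f.aic,
                    "degenerate": name in self.degenerate,
                }
            )
        return pd.DataFrame(rows)


def _restrict_column(column: dict[str, int], tree) -> dict[str, int]:
    if isinstance(tree, TreeIndex):
        tips = set(tree.tip_index)
    else:
        tips = {normalize_label(l) for l in leaf_labels(tree)}
    return {t: c for t, c in column.items() if normalize_label(t) in tips}


def fit_partitioned(
    subtrees: Mapping[str, dendropy.Tree],
    column: dict[str, int],
    model_kind: str | Mapping[str, str] = "mk1",
    prior: RootPrior = FLAT_PRIOR,
) -> CompositeFit:
    """Fit an independent Mk model on every partition subtree.

    ``model_kind`` is "mk1", "mk2", or a per-partition mapping.  A partition
    with no determinate tip cannot inform a rate; its fit is flagged
    degenerate and contributes lnL = 0 with k = 0 (its tip pattern has
    probability 1 under any model).
    """
    fits: dict[str, FitResult] = {}
    degenerate: list[str] = []
    for name, sub in subtrees.items():
        kind = model_kind if isinstance(model_kind, str) else model_kind[name]
        col = _restrict_column(column, sub)
        fitter = fit_mk1 if kind.lower() == "mk1" else fit_mk2
        try:
            fits[name] = fitter(sub, col, prior, label=name)
        except ValueError:
            degenerate.append(name)
            fits[name] = FitResult(
                model=MkModel.mk1(0.0),
                log_likelihood=0.0,
                k=0,
                converged=True,
                prior=prior,
                label=name,
            )
    return CompositeFit(partition_fits=fits, degenerate=degenerate)


def symmetry_ratio(fit: FitResult) -> float:
    """min(q01, q10) / max(q01, q10) of an Mk2 fit: 1 = effectively Mk1."""
    hi = max(fit.model.q01, fit.model.q10)
    lo = min(fit.model.q01, fit.model.q10)
    if hi == 0:
        raise ValueError("both rates are zero; symmetry ratio undefined")
    return lo / hi


def select_best_composite(
    mk1_fits: Mapping[str, FitResult],
    mk2_fits: Mapping[str, FitResult],
    tie_margin: float = 2.0,
) -> tuple[dict[str, str], CompositeFit]:
    """Choose the lower-AIC model per partition; ties go to Mk1.

    Mk2 must beat Mk1 by at least ``tie_margin`` AIC units to be selected
    (parameter parsimony on |dAIC| < 2 ties).
    """
    if set(mk1_fits) != set(mk2_fits):
        raise ValueError("Mk1 and Mk2 fits cover different partitions")
    choices: dict[str, str] = {}
    chosen: dict[str, FitResult] = {}
    for name in mk1_fits:
        if mk1_fits[name].aic - mk2_fits[name].aic >= tie_margin:
            choices[name] = "Mk2"
            chosen[name] = mk2_fits[name]
        else:
            choices[name] = "Mk1"
            chosen[name] = mk1_fits[name]
    return choices, CompositeFit(partition_fits=chosen)
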