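"""Marginal ancestral state reconstruction and support categories.

For every node the marginal probability of each state given *all* tip data
("proportional relative likelihood") is computed by combining the postorder
conditional likelihoods with a preorder outside pass — equivalent to
re-rooting the tree at each node — and normalizing per node.

Support categories follow the usual reporting convention for these
probabilities: >= 0.90 strong, 0.61–0.89 moderate, <= 0.60 weak, and
"equivocal" reserved for probabilities of exactly 0.5 (within a small
tolerance).  Because published tables print two decimals, the gaps between
the printed category limits are resolved by half-open intervals at 0.605 and
0.895.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import dendropy
import numpy as np
import pandas as pd

from .mk import FLAT_PRIOR, MkModel, RootPrior, _down_pass, _edge_probabilities
from .trees import TreeIndex, mrca, normalize_label

#: |p - 0.5| below this is reported as equivocal ("hr"-style entries).
EQUIVOCAL_TOL = 1e-3


class SupportCategory(str, Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"
    EQUIVOCAL = "equivocal"


def classify_support(p: float, tol: float = EQUIVOCAL_TOL) -> SupportCategory:
    """Category of the probability of the most-likely state at a node."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if abs(p - 0.5) <= tol:
        return SupportCategory.EQUIVOCAL
    if p < 0.5:
        raise ValueError(f"{p} is not the larger of the two state probabilities")
    if p >= 0.895:
        return SupportCategory.STRONG
    if p >= 0.605:
        return SupportCategory.MODERATE
    return SupportCategory.WEAK


@dataclass
class AsrResult:
    """Per-node marginal state probabilities for one character and model."""

    index: TreeIndex
    probabilities: np.ndarray  # (n_nodes, 2), rows sum to 1
    model: MkModel
    prior: RootPrior

    def node_probability(self, i: int) -> tuple[float, float]:
        return float(self.probabilities[i, 0]), float(self.probabilities[i, 1])

    def at_label(self, label: str) -> tuple[float, float]:
        for i, nd in enumerate(self.index.nodes):
            if nd.label == label:
                return self.node_probability(i)
        raise KeyError(f"no node labelled {label!r} in tree")

    def at_mrca(self, tip_labels) -> tuple[float, float]:
        node = mrca(self.index.tree, tip_labels)
        for i, nd in enumerate(self.index.nodes):
            if nd is node:
                return self.node_probability(i)
        raise KeyError("MRCA not indexed")  # pragma: no cover

    def most_likely(self, i: int) -> str:
        p0, p1 = self.node_probability(i)
        if abs(p0 - 0.5) <= EQUIVOCAL_TOL:
            return "equivocal"
        return "0" if p0 > p1 else "1"

    def support(self, i: int) -> SupportCategory:
        p0, p1 = self.node_probability(i)
        return classify_support(max(p0, p1))

    def labelled_nodes(self) -> dict[str, int]:
        return {
            nd.label: i
            for i, nd in enumerate(self.index.nodes)
            if nd.label and not self.index.is_tip[i]
        }

    def to_frame(self, labels=None) -> pd.DataFrame:
        """Long table (node, P0, P1, state, category) for labelled nodes."""
        lab = self.labelled_nodes()
        if labels is not None:
            lab = {l: lab[l] for l in labels if l in lab}
        rows = []
        for l, i in lab.items():
            p0, p1 = self.node_probability(i)
            rows.append(
                {
                    "node": l,
                    "P0": p0,
                    "P1": p1,
                    "state": self.most_likely(i),
                    "category": self.support(i).value,
                }
            )
        return pd.DataFrame(rows)


def marginal_asr(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    model: MkModel,
    prior: RootPrior = FLAT_PRIOR,
) -> AsrResult:
    """Marginal state probabilities at every node of the tree.

    The outside ("up") partial of a node conditions on everything that is not
    in its subtree, including the root prior; the product of inside and
    outside partials, normalized, is the node's marginal.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    codes = idx.tip_codes(column)
    L0, L1, _ = _down_pass(idx, codes, model)
    p00, p01, p10, p11 = _edge_probabilities(model, idx.edge_length)
    n = idx.n
    U0 = [0.0] * n
    U1 = [0.0] * n
    pr = prior.vector(model)
    U0[idx.root], U1[idx.root] = float(pr[0]), float(pr[1])
    # Preorder = reversed postorder: parents before children.
    for u in range(n - 1, -1, -1):
        if idx.is_tip[u]:
            continue
        kids = idx.children[u]
        down0 = [p00[c] * L0[c] + p01[c] * L1[c] for c in kids]
        down1 = [p10[c] * L0[c] + p11[c] * L1[c] for c in kids]
        for j, c in enumerate(kids):
            sib0, sib1 = U0[u], U1[u]
            for jj in range(len(kids)):
                if jj != j:
                    sib0 *= down0[jj]
                    sib1 *= down1[jj]
            u0 = sib0 * p00[c] + sib1 * p10[c]
            u1 = sib0 * p01[c] + sib1 * p11[c]
            m = u0 if u0 >= u1 else u1
            if m > 0:
                u0, u1 = u0 / m, u1 / m
            U0[c], U1[c] = u0, u1
    probs = np.empty((n, 2))
    for i in range(n):
        a = L0[i] * U0[i]
        b = L1[i] * U1[i]
        tot = a + b
        if tot > 0:
            probs[i] = (a / tot, b / tot)
        else:
            probs[i] = (math.nan, math.nan)
    return AsrResult(index=idx, probabilities=probs, model=model, prior=prior)


def _node_state_map(result) -> dict[str, str]:
    """Most-likely state per labelled node, from an AsrResult or a mapping
    {label: (p0, p1)}."""
    if isinstance(result, AsrResult):
        return {name: result.most_likely(i) for name, i in result.labelled_nodes().items()}
    out = {}
    for name, (p0, p1) in result.items():
        if abs(p0 - 0.5) <= EQUIVOCAL_TOL:
            out[name] = "equivocal"
        else:
            out[name] = "0" if p0 > p1 else "1"
    return out


def compare_asr(
    result_a,
    result_b,
    nodes: list[str],
    count_equivocal: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Count nodes whose most-likely state differs between two reconstructions.

    Each argument is an :class:`AsrResult` or a mapping {node label:
    (p0, p1)} (the latter is how a reconstruction stitched together from
    partition subtrees is passed in).  Nodes absent from either
    reconstruction (e.g. lost by partitioning) are listed in the table with
    state "lost" and never counted.  By default the comparison is argmax vs
    argmax with equivocal nodes excluded; with ``count_equivocal=True`` an
    equivocal node differs from any determinate state.
    """
    states_a = _node_state_map(result_a)
    states_b = _node_state_map(result_b)
    rows = []
    changed = 0
    for name in nodes:
        if name not in states_a or name not in states_b:
            rows.append({"node": name, "state_a": "lost", "state_b": "lost", "differs": False})
            continue
        sa = states_a[name]
        sb = states_b[name]
        if "equivocal" in (sa, sb):
            differs = count_equivocal and sa != sb
        else:
            differs = sa != sb
        changed += int(differs)
        rows.append({"node": name, "state_a": sa, "state_b": sb, "differs": differs})
    return changed, pd.DataFrame(rows)
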