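"""Fitch parsimony counting of state changes, origins and reversals.

Change counting uses equal-cost Sankoff dynamic programming, which is the
generalization of Fitch parsimony that handles polytomies (hard, structural)
and tips carrying state sets (missing or polymorphic cells license {0, 1}).
Branch lengths are ignored.

The number of *origins* of the derived state (changes ancestral -> derived)
versus *reversals* is not unique across the most-parsimonious
reconstructions (MPRs).  Bounds are obtained by resolving every equivocal
node — one whose MPR state set is {0, 1} — uniformly to the derived state,
and uniformly to the ancestral state; each resolution realizes exactly the
Fitch length, so the two (origins, reversals) pairs satisfy the additive
identity min_origins + max_reversals = max_origins + min_reversals = length.
An exact DP over all MPRs computes the same bounds independently and is used
to cross-check the resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import math
import pandas as pd

from .characters import ALLOWED_STATES
from .trees import TreeIndex, normalize_label

_INF = 10**9


def _sankoff_down(idx: TreeIndex, codes) -> list[tuple[int, int]]:
    """Minimal subtree change counts per node and state (equal costs)."""
    cost: list[tuple[int, int]] = [(0, 0)] * idx.n
    for i in range(idx.n):
        if idx.is_tip[i]:
            allowed = ALLOWED_STATES[int(codes[i])]
            cost[i] = (0 if 0 in allowed else _INF, 0 if 1 in allowed else _INF)
        else:
            c0 = c1 = 0
            for ch in idx.children[i]:
                a, b = cost[ch]
                c0 += min(a, b + 1)
                c1 += min(a + 1, b)
            cost[i] = (c0, c1)
    return cost


def _mpr_sets(idx: TreeIndex, cost: list[tuple[int, int]]) -> tuple[int, list[frozenset[int]]]:
    """Fitch length and, per node, the set of states realized in some MPR."""
    root = idx.root
    length = min(cost[root])
    # m[child][s_parent] = child's best contribution given the parent state
    m = [None] * idx.n
    tot = [None] * idx.n
    for i in range(idx.n):
        if not idx.is_tip[i]:
            t0 = t1 = 0
            for ch in idx.children[i]:
                a, b = cost[ch]
                m0, m1 = min(a, b + 1), min(a + 1, b)
                m[ch] = (m0, m1)
                t0 += m0
                t1 += m1
            tot[i] = (t0, t1)
    up: list[tuple[int, int]] = [(0, 0)] * idx.n
    for p in range(idx.n - 1, -1, -1):
        if idx.is_tip[p]:
            continue
        base0 = up[p][0] + tot[p][0]
        base1 = up[p][1] + tot[p][1]
        for ch in idx.children[p]:
            o0 = min(base0 - m[ch][0], base1 - m[ch][1] + 1)
            o1 = min(base0 - m[ch][0] + 1, base1 - m[ch][1])
            up[ch] = (o0, o1)
    sets = []
    for i in range(idx.n):
        s = frozenset(
            st for st in (0, 1) if cost[i][st] + up[i][st] == length
        )
        sets.append(s)
    return length, sets


def fitch_counts(
    tree: dendropy.Tree | TreeIndex, column: dict[str, int]
) -> tuple[int, list[frozenset[int]]]:
    """Fitch length and per-node MPR state sets.

    The state sets are aligned with ``TreeIndex(tree).nodes`` (postorder);
    a set of {0, 1} marks an equivocal node.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, require_lengths=False)
    codes = idx.tip_codes(column)
    cost = _sankoff_down(idx, codes)
    return _mpr_sets(idx, cost)


def _resolve(sets: list[frozenset[int]], favoured: int) -> list[int]:
    """Resolve every equivocal node (and tip) to ``favoured`` where allowed."""
    out = []
    for s in sets:
        if favoured in s:
            out.append(favoured)
        else:
            (only,) = s
            out.append(only)
    return out


def _count_changes(idx: TreeIndex, states: list[int], derived: int) -> tuple[int, int, int]:
    """(total changes, origins, reversals) of a full labeling."""
    total = origins = reversals = 0
    for i in range(idx.n - 1):  # root has no edge
        p = idx.parent[i]
        if states[i] != states[p]:
            total += 1
            if states[i] == derived:
                origins += 1
            else:
                reversals += 1
    return total, origins, reversals


def _extreme_origins(idx: TreeIndex, codes, derived: int, maximize: bool) -> tuple[int, int]:
    """(Fitch length, min or max origins over all MPRs) by lexicographic DP."""
    sign = -1 if maximize else 1
    # f[i][s] = (cost, sign*origins) lexicographic minimum for subtree of i
    f: list[tuple[tuple[int, int], tuple[int, int]]] = [None] * idx.n
    for i in range(idx.n):
        if idx.is_tip[i]:
            allowed = ALLOWED_STATES[int(codes[i])]
            f[i] = tuple(
                (0, 0) if s in allowed else (_INF, 0) for s in (0, 1)
            )
        else:
            acc = [[0, 0], [0, 0]]
            for ch in idx.children[i]:
                for s in (0, 1):
                    best = None
                    for s2 in (0, 1):
                        c = f[ch][s2][0] + (1 if s != s2 else 0)
                        o = f[ch][s2][1] + (sign if (s != s2 and s2 == derived) else 0)
                        if best is None or (c, o) < best:
                            best = (c, o)
                    acc[s][0] += best[0]
                    acc[s][1] += best[1]
            f[i] = (tuple(acc[0]), tuple(acc[1]))
    root = idx.root
    length = min(f[root][0][0], f[root][1][0])
    o = min(f[root][s][1] for s in (0, 1) if f[root][s][0] == length)
    return length, sign * o


@dataclass
class ParsimonyResult:
    """Fitch length with origin/reversal ranges for one character."""

    length: int
    derived_state: int
    min_origins: int
    max_origins: int
    min_reversals: int
    max_reversals: int
    state_sets: list[frozenset[int]]
    #: resolution name -> (origins, reversals) realized by resolving all
    #: equivocal nodes to that state
    resolution_counts: dict[str, tuple[int, int]]
    index: TreeIndex
    labelings: dict[str, list[int]]

    def __post_init__(self):
        assert self.min_origins + self.max_reversals == self.length
        assert self.max_origins + self.min_reversals == self.length

    def most_parsimonious_state(self, label: str) -> str:
        """"0", "1" or "equivocal" at the named internal node."""
        for i, nd in enumerate(self.index.nodes):
            if nd.label == label and not self.index.is_tip[i]:
                s = self.state_sets[i]
                return "equivocal" if len(s) == 2 else str(next(iter(s)))
        raise KeyError(f"no node labelled {label!r} in tree")


def minmax_origins_reversals(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    derived_state: int,
) -> ParsimonyResult:
    """Origin and reversal ranges over all most-parsimonious reconstructions.

    Both equivocal-branch resolutions (all-derived, all-ancestral) are
    computed and labelled; the reported min/max are additionally verified
    against an exact DP over all MPRs.  Because every resolution realizes
    the Fitch length, min_origins + max_reversals = max_origins +
    min_reversals = length.
    """
    if derived_state not in (0, 1):
        raise ValueError("derived_state must be 0 or 1")
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, require_lengths=False)
    codes = idx.tip_codes(column)
    cost = _sankoff_down(idx, codes)
    length, sets = _mpr_sets(idx, cost)
    ancestral = 1 - derived_state

    labelings = {
        "derived": _resolve(sets, derived_state),
        "ancestral": _resolve(sets, ancestral),
    }
    resolution_counts = {}
    for name, states in labelings.items():
        total, o, r = _count_changes(idx, states, derived_state)
        if total != length:
            raise RuntimeError(
                f"{name} resolution realizes {total} changes, Fitch length is {length}"
            )
        resolution_counts[name] = (o, r)

    _, min_o = _extreme_origins(idx, codes, derived_state, maximize=False)
    _, max_o = _extreme_origins(idx, codes, derived_state, maximize=True)
    for name, (o, _) in resolution_counts.items():
        if not min_o <= o <= max_o:
            raise RuntimeError(
                f"{name} resolution yields {o} origins, outside MPR bounds [{min_o}, {max_o}]"
            )
    return ParsimonyResult(
        length=length,
        derived_state=derived_state,
        min_origins=min_o,
        max_origins=max_o,
        min_reversals=length - max_o,
        max_reversals=length - min_o,
        state_sets=sets,
        resolution_counts=resolution_counts,
        index=idx,
        labelings=labelings,
    )


def origin_reversal_ratio_range(result: ParsimonyResult) -> tuple[float, float]:
    """(min_origins/max_reversals, max_origins/min_reversals), 1 decimal.

    With no reversals in some MPR the upper bound is infinite; with no
    reversals in *any* MPR both bounds are infinite (unless there are no
    origins either, in which case the ratio is undefined).
    """
    if result.max_reversals == 0:
        if result.min_origins == 0:
            raise ValueError("no origins and no reversals; ratio undefined")
        low = math.inf
    else:
        low = round(result.min_origins / result.max_reversals, 1)
    if result.min_reversals == 0:
        high = math.inf
    else:
        high = round(result.max_origins / result.min_reversals, 1)
    return low, high


def partition_breakdown(
    result: ParsimonyResult, scheme, resolution: str = "derived"
) -> pd.DataFrame:
    """Assign each change to the partition of the child node of its edge.

    A change on an edge whose child node spans several partitions (a
    backbone edge) is reported in a separate "backbone" row, so partition
    totals plus backbone equal the whole-tree counts of that resolution.
    """
    idx = result.index
    states = result.labelings[resolution]
    tipsets = idx.descendant_tip_labels()
    node_part: list[str] = []
    for i in range(idx.n):
        parts = {scheme.partition_of(t) for t in tipsets[i]}
        node_part.append(parts.pop() if len(parts) == 1 else "backbone")
    counts = {name: [0, 0] for name in scheme.names}
    counts["backbone"] = [0, 0]
    for i in range(idx.n - 1):
        p = idx.parent[i]
        if states[i] != states[p]:
            key = node_part[i] if node_part[i] is not None else "backbone"
            if states[i] == result.derived_state:
                counts[key][0] += 1
            else:
                counts[key][1] += 1
    rows = [
        {"partition": name, "origins": o, "reversals": r, "changes": o + r}
        for name, (o, r) in counts.items()
    ]
    return pd.DataFrame(rows)
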