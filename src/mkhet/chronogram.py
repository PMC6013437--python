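"""bladj-style ultrametric calibration by even age interpolation.

Given a topology (input branch lengths are ignored) and ages in Ma for a set
of named internal nodes — the root must be among them; tips are implicitly at
age 0 — every constrained node is fixed at exactly its age and each maximal
chain of unconstrained nodes between two fixed ages is spaced evenly:
with ancestor age A, descendant age D and m unconstrained nodes in between,
node i (from the ancestor) gets age A - i * (A - D) / (m + 1).  Edge lengths
are parent age minus child age, which makes the tree ultrametric.

Fixed nodes are processed oldest-first and, within the region below a fixed
node, paths to older fixed descendants are spaced before paths to younger
ones; nodes shared between paths keep their first-assigned age and later
paths interpolate inside the remaining segments.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import dendropy

from .trees import describe_node


class CalibrationError(ValueError):
    pass


def _node_name(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def bladj_calibrate(
    tree: dendropy.Tree,
    constraints: Mapping[str, float],
    epsilon: float = 1e-6,
) -> dendropy.Tree:
    """Return an ultrametric copy of ``tree`` honouring the age constraints.

    Raises :class:`CalibrationError` if the root is unconstrained, a
    constrained name is absent from the tree, or a constrained descendant is
    older than its nearest constrained ancestor.  Equal ancestor/descendant
    ages would create zero-length edges; these are perturbed by ``epsilon``
    Ma with a warning.
    """
    out = tree.clone(depth=1)
    nodes = list(out.preorder_node_iter())
    named = {}
    for nd in nodes:
        name = _node_name(nd)
        if name is not None:
            named.setdefault(name, nd)
    missing = [n for n in constraints if n not in named]
    if missing:
        raise CalibrationError(f"constrained nodes absent from tree: {sorted(missing)}")
    for name, age in constraints.items():
        if age < 0:
            raise CalibrationError(f"negative age {age} for {name!r}")

    fixed: dict[int, float] = {}  # id(node) -> age
    for name, age in constraints.items():
        fixed[id(named[name])] = float(age)
    root = out.seed_node
    if id(root) not in fixed:
        raise CalibrationError("the root node must carry an age constraint")

    # Monotonicity of the constraints along every root-to-tip path.
    anc_age: dict[int, tuple[float, str]] = {id(root): (fixed[id(root)], _node_name(root) or "root")}
    for nd in nodes:
        if nd is root:
            continue
        a_age, a_name = anc_age[id(nd.parent_node)]
        if id(nd) in fixed:
            if fixed[id(nd)] > a_age:
                raise CalibrationError(
                    f"constraint conflict: {_node_name(nd)!r} ({fixed[id(nd)]} Ma) is older "
                    f"than its constrained ancestor {a_name!r} ({a_age} Ma)"
                )
            anc_age[id(nd)] = (fixed[id(nd)], _node_name(nd))
        else:
            anc_age[id(nd)] = (a_age, a_name)

    ages: dict[int, float] = dict(fixed)
    for nd in nodes:
        if nd.is_leaf():
            ages.setdefault(id(nd), 0.0)

    def endpoints_below(start: dendropy.Node):
        """(endpoint, path of intermediate nodes) for the region under start."""
        found = []
        stack = [(c, []) for c in start.child_nodes()]
        while stack:
            nd, path = stack.pop()
            if id(nd) in fixed or nd.is_leaf():
                found.append((nd, path))
            else:
                for c in nd.child_nodes():
                    stack.append((c, path + [nd]))
        return found

    for fnode_id, fage in sorted(fixed.items(), key=lambda kv: -kv[1]):
        fnode = next(nd for nd in nodes if id(nd) == fnode_id)
        eps = endpoints_below(fnode)
        # older fixed descendants first, then nearer ones, then by name, so
        # shared chain prefixes are spaced against the nearest fixed
        # descendant deterministically
        eps.sort(key=lambda e: (-ages[id(e[0])], len(e[1]), _node_name(e[0]) or ""))
        for endpoint, path in eps:
            if not path:
                continue
            # interpolate each run of still-unassigned nodes between anchors
            chain = [fnode] + path + [endpoint]
            anchor_pos = [i for i, nd in enumerate(chain) if id(nd) in ages]
            for a, b in zip(anchor_pos, anchor_pos[1:]):
                m = b - a - 1
                if m == 0:
                    continue
                hi, lo = ages[id(chain[a])], ages[id(chain[b])]
                for i in range(1, m + 1):
                    ages[id(chain[a + i])] = hi - i * (hi - lo) / (m + 1)

    # Ages -> edge lengths; perturb zero-length edges to keep durations > 0.
    for nd in nodes:
        if nd is root:
            nd.edge.length = None
            continue
        page = ages[id(nd.parent_node)]
        if not nd.is_leaf() and ages[id(nd)] >= page:
            warnings.warn(
                f"zero-length edge above {describe_node(nd)!r} perturbed by {epsilon} Ma",
                stacklevel=2,
            )
            ages[id(nd)] = page - epsilon
        nd.edge.length = page - ages[id(nd)]
    return out
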