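"""Independent brute-force oracles used by the test suite.

These enumerate over all internal-node state assignments (and all states
allowed by missing/polymorphic tips), so they are exponential in tree size
and only usable on tiny trees — which is the point: they share no code with
the pruning/Sankoff implementations they check.
"""

import itertools
import math
import random

import dendropy

from mkhet import transition_probability
from mkhet.characters import ALLOWED_STATES
from mkhet.trees import TreeIndex


def random_tree(rng: random.Random, n_tips: int, polytomies: bool = True) -> dendropy.Tree:
    """Random rooted topology (possibly multifurcating) with random lengths."""
    nodes = [dendropy.Node() for _ in range(n_tips)]
    while len(nodes) > 1:
        k = rng.choice([2, 2, 2, 3]) if polytomies and len(nodes) >= 3 else 2
        k = min(k, len(nodes))
        parent = dendropy.Node()
        for _ in range(k):
            child = nodes.pop(rng.randrange(len(nodes)))
            parent.add_child(child)
            child.edge.length = round(rng.uniform(0.1, 20.0), 3)
        nodes.append(parent)
    tree = dendropy.Tree()
    tree.seed_node = nodes[0]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=f"t{i}")
    tree.is_rooted = True
    return tree


def _full_assignments(idx: TreeIndex, codes):
    """Yield every state assignment consistent with the tip cells."""
    internal = [i for i in range(idx.n) if not idx.is_tip[i]]
    tips = [i for i in range(idx.n) if idx.is_tip[i]]
    tip_choices = [ALLOWED_STATES[int(codes[i])] for i in tips]
    for assign in itertools.product((0, 1), repeat=len(internal)):
        base = dict(zip(internal, assign))
        for states in itertools.product(*tip_choices):
            full = dict(base)
            full.update(zip(tips, states))
            yield full


def _assignment_probability(idx: TreeIndex, full, model, prior_vec) -> float:
    p = prior_vec[full[idx.root]]
    for i in range(idx.n - 1):
        P = transition_probability(model, float(idx.edge_length[i]))
        p *= P[full[idx.parent[i]], full[i]]
    return p


def enum_log_likelihood(idx: TreeIndex, codes, model, prior) -> float:
    pr = prior.vector(model)
    total = sum(
        _assignment_probability(idx, full, model, pr)
        for full in _full_assignments(idx, codes)
    )
    return math.log(total) if total > 0 else -math.inf


def enum_marginal(idx: TreeIndex, codes, model, prior, node: int):
    pr = prior.vector(model)
    out = [0.0, 0.0]
    for full in _full_assignments(idx, codes):
        out[full[node]] += _assignment_probability(idx, full, model, pr)
    s = sum(out)
    return [out[0] / s, out[1] / s]


def enum_parsimony(idx: TreeIndex, codes, derived: int):
    """(Fitch length, min origins, max origins) over all minimum assignments."""
    best_len = 10**9
    origins = set()
    for full in _full_assignments(idx, codes):
        length = o = 0
        for i in range(idx.n - 1):
            if full[i] != full[idx.parent[i]]:
                length += 1
                if full[i] == derived:
                    o += 1
        if length < best_len:
            best_len, origins = length, {o}
        elif length == best_len:
            origins.add(o)
    return best_len, min(origins), max(origins)
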