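"""Fixed-rate Mk1 sensitivity sweeps.

Instead of estimating the transition rate, a grid of imposed rates is swept
and the marginal reconstruction recomputed at each one.  As the rate grows
every node's probabilities converge to the 0.5/0.5 "high transition rate
equilibrium"; on the way there a node either converges monotonically or
switches its most-likely state (a probability curve that dips through 0.5).
Each imposed rate is also scored by AIC with k = 0, since nothing is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import dendropy
import numpy as np
import pandas as pd

from .asr import EQUIVOCAL_TOL, AsrResult, classify_support, marginal_asr
from .mk import FLAT_PRIOR, MkModel, RootPrior, pruning_log_likelihood
from .trees import TreeIndex

#: The sparse default grid (per-Ma rates) used for sensitivity tables.
DEFAULT_GRID = (0.0001, 0.001, 0.01, 0.1)


class CurveClass(str, Enum):
    MONOTONE_CONVERGENCE = "monotone_convergence"
    STATE_SWITCH_DIP = "state_switch_dip"


def dense_grid(lo: float = 1e-4, hi: float = 1e-1, per_decade: int = 40) -> np.ndarray:
    """Log-spaced grid for smooth probability-vs-rate curves."""
    decades = np.log10(hi) - np.log10(lo)
    return np.logspace(np.log10(lo), np.log10(hi), int(round(decades * per_decade)) + 1)


@dataclass
class RateSweepResult:
    """Marginal probabilities of tracked nodes across a rate grid."""

    grid: np.ndarray
    node_probabilities: dict[str, np.ndarray]  # label -> (n_rates, 2)
    aic_table: pd.DataFrame  # q, lnL, AIC (k = 0)
    results: list[AsrResult]

    def states(self, node: str) -> list[str]:
        """Most-likely state of one node at each grid rate."""
        out = []
        for p0, p1 in self.node_probabilities[node]:
            if abs(p0 - 0.5) <= EQUIVOCAL_TOL:
                out.append("equivocal")
            else:
                out.append("0" if p0 > p1 else "1")
        return out

    def curve_class(self, node: str) -> CurveClass:
        return classify_curve(self.states(node))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node, probs in self.node_probabilities.items():
            states = self.states(node)
            for q, (p0, p1), st in zip(self.grid, probs, states):
                rows.append(
                    {
                        "node": node,
                        "q": q,
                        "P0": p0,
                        "P1": p1,
                        "state": st,
                        "category": classify_support(max(p0, p1)).value,
                    }
                )
        return pd.DataFrame(rows)


def sweep_fixed_rates(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    grid=DEFAULT_GRID,
    nodes: list[str] | None = None,
    prior: RootPrior = FLAT_PRIOR,
) -> RateSweepResult:
    """Marginal ASR at each imposed Mk1 rate in ``grid`` (no fitting).

    ``nodes`` restricts tracking to the named internal nodes; by default all
    labelled internal nodes are tracked.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty rate grid")
    if np.any(grid <= 0):
        raise ValueError("grid rates must be > 0")
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    results = []
    aic_rows = []
    for q in grid:
        model = MkModel.mk1(float(q))
        res = marginal_asr(idx, column, model, prior)
        results.append(res)
        lnl = pruning_log_likelihood(idx, column, model, prior)
        aic_rows.append({"q": float(q), "lnL": lnl, "AIC": -2 * lnl})
    labelled = results[0].labelled_nodes()
    if nodes is not None:
        missing = [n for n in nodes if n not in labelled]
        if missing:
            raise KeyError(f"nodes not in tree: {missing}")
        labelled = {n: labelled[n] for n in nodes}
    node_probs = {
        name: np.array([res.probabilities[i] for res in results])
        for name, i in labelled.items()
    }
    return RateSweepResult(
        grid=grid,
        node_probabilities=node_probs,
        aic_table=pd.DataFrame(aic_rows),
        results=results,
    )


def detect_equilibrium(probabilities: np.ndarray, tol: float = EQUIVOCAL_TOL) -> bool:
    """True iff every node probability is within ``tol`` of 0.5."""
    p = np.asarray(probabilities, dtype=float)
    return bool(np.nanmax(np.abs(p - 0.5)) <= tol)


def classify_curve(states: list[str]) -> CurveClass:
    """Curve type from the per-rate most-likely states of one node.

    A node whose determinate most-likely state differs between grid points
    (before sinking into the equilibrium) has a probability curve that dips
    through 0.5; otherwise the curve converges monotonically.
    """
    if len(states) < 3:
        raise ValueError("need at least 3 grid points to classify a curve")
    determinate = [s for s in states if s != "equivocal"]
    if len(set(determinate)) > 1:
        return CurveClass.STATE_SWITCH_DIP
    return CurveClass.MONOTONE_CONVERGENCE


def best_fixed_rate(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    grid=DEFAULT_GRID,
    prior: RootPrior = FLAT_PRIOR,
) -> tuple[float, pd.DataFrame]:
    """The imposed rate with minimum AIC (k = 0) and the full table."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid rates must be > 0 and non-empty")
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rows = []
    for q in grid:
        lnl = pruning_log_likelihood(idx, column, MkModel.mk1(float(q)), prior)
        rows.append({"q": float(q), "lnL": lnl, "AIC": -2 * lnl})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["AIC"].idxmin(), "q"])
    return best, table
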