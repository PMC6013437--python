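"""Two-state continuous-time Markov (Mk) models: likelihood and ML fitting.

The model has instantaneous rates ``q01`` (gain of the derived state, per Ma)
and ``q10`` (reversal).  Mk1 constrains the two rates to be equal; Mk2 lets
them differ.  Transition probabilities have the closed form

    P01(t) = pi1 * (1 - exp(-(q01 + q10) * t)),   pi1 = q01 / (q01 + q10)

and the likelihood of a tip pattern on a rooted tree with branch lengths is
computed by Felsenstein's pruning algorithm with per-node rescaling, so that
matrices of >1000 taxa do not underflow.  Missing and polymorphic tips enter
the pruning with partial likelihood 1 for every state they allow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .characters import ALLOWED_STATES
from .trees import TreeIndex

RATE_BOUNDS = (1e-10, 100.0)
_LOG_BOUNDS = (math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1]))


@dataclass(frozen=True)
class MkModel:
    """Instantaneous rates of a binary-character Markov model (per Ma)."""

    q01: float
    q10: float
    is_mk1: bool = False

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        if self.is_mk1 and self.q01 != self.q10:
            raise ValueError("Mk1 requires q01 == q10")

    @classmethod
    def mk1(cls, q: float) -> "MkModel":
        return cls(q, q, is_mk1=True)

    @classmethod
    def mk2(cls, q01: float, q10: float) -> "MkModel":
        return cls(q01, q10, is_mk1=False)

    @property
    def stationary(self) -> np.ndarray:
        s = self.q01 + self.q10
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / s, self.q01 / s])


@dataclass(frozen=True)
class RootPrior:
    """Distribution over the root state used to weight the root partials.

    ``flat`` (0.5/0.5) is the default; under Mk1 it coincides with the
    stationary distribution, so Mk1 results do not depend on this choice.
    """

    kind: str = "flat"  # flat | stationary | fixed
    probabilities: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("flat", "stationary", "fixed"):
            raise ValueError(f"unknown root prior kind {self.kind!r}")
        if self.kind == "fixed":
            if self.probabilities is None:
                raise ValueError("fixed prior requires probabilities")
            if abs(sum(self.probabilities) - 1.0) > 1e-9:
                raise ValueError("fixed prior probabilities must sum to 1")

    def vector(self, model: MkModel) -> np.ndarray:
        if self.kind == "flat":
            return np.array([0.5, 0.5])
        if self.kind == "stationary":
            return model.stationary
        return np.asarray(self.probabilities, dtype=float)


FLAT_PRIOR = RootPrior("flat")


def transition_probability(model: MkModel, t: float) -> np.ndarray:
    """Closed-form 2x2 transition matrix P(t); rows are the source state."""
    if t < 0:
        raise ValueError(f"negative time {t}")
    s = model.q01 + model.q10
    if s == 0.0:
        return np.eye(2)
    pi0, pi1 = model.q10 / s, model.q01 / s
    e = math.exp(-s * t)
    return np.array(
        [
            [pi0 + pi1 * e, pi1 * (1 - e)],
            [pi0 * (1 - e), pi0 * e + pi1],
        ]
    )


def _edge_probabilities(model: MkModel, lengths: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized P(t) entries for every edge; nan lengths yield identity."""
    t = np.where(np.isnan(lengths), 0.0, lengths)
    s = model.q01 + model.q10
    if s == 0.0:
        e = np.ones_like(t)
        pi0 = pi1 = 0.5  # unused when e == 1
    else:
        e = np.exp(-s * t)
        pi0, pi1 = model.q10 / s, model.q01 / s
    p01 = pi1 * (1 - e)
    p10 = pi0 * (1 - e)
    return 1.0 - p01, p01, p10, 1.0 - p10


_TIP_PARTIALS = {code: tuple(1.0 if s in allowed else 0.0 for s in (0, 1))
                 for code, allowed in ALLOWED_STATES.items()}


def _down_pass(
    idx: TreeIndex, codes: np.ndarray, model: MkModel
) -> tuple[list[float], list[float], list[float]]:
    """Postorder conditional likelihoods with per-node rescaling.

    Returns per-node rescaled partials (L0, L1) and per-node log scale
    factors; the likelihood of the data below node i given its state s is
    ``L_s[i] * exp(sum of logf over i's subtree)``.
    """
    p00, p01, p10, p11 = _edge_probabilities(model, idx.edge_length)
    n = idx.n
    L0 = [0.0] * n
    L1 = [0.0] * n
    logf = [0.0] * n
    for i in range(n):
        if idx.is_tip[i]:
            L0[i], L1[i] = _TIP_PARTIALS[int(codes[i])]
            continue
        a, b = 1.0, 1.0
        for c in idx.children[i]:
            a *= p00[c] * L0[c] + p01[c] * L1[c]
            b *= p10[c] * L0[c] + p11[c] * L1[c]
        m = a if a >= b else b
        if m <= 0.0:
            L0[i] = L1[i] = 0.0
            continue
        L0[i], L1[i] = a / m, b / m
        logf[i] = math.log(m)
    return L0, L1, logf


def pruning_log_likelihood(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    model: MkModel,
    prior: RootPrior = FLAT_PRIOR,
) -> float:
    """Log-likelihood (nats) of one character column under ``model``.

    Sums the probability of the tip pattern over all internal-node state
    assignments (Felsenstein pruning).  Every tip must have a cell; missing
    and polymorphic cells contribute 1 for each allowed state.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    codes = idx.tip_codes(column)
    return _log_likelihood_from_codes(idx, codes, model, prior)


def _log_likelihood_from_codes(
    idx: TreeIndex, codes: np.ndarray, model: MkModel, prior: RootPrior
) -> float:
    L0, L1, logf = _down_pass(idx, codes, model)
    pr = prior.vector(model)
    r = idx.root
    lik = pr[0] * L0[r] + pr[1] * L1[r]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + math.fsum(logf)


@dataclass(frozen=True)
class FitResult:
    """Outcome of an Mk model fit (or a fixed-rate evaluation, k = 0)."""

    model: MkModel
    log_likelihood: float
    k: int
    converged: bool = True
    bound_hit: bool = False
    prior: RootPrior = FLAT_PRIOR
    label: str | None = None

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_likelihood


def _has_determinate_tip(codes: np.ndarray, idx: TreeIndex) -> bool:
    tip_codes = codes[idx.is_tip]
    return bool(np.any(tip_codes == 0) or np.any(tip_codes == 1))


def fit_mk1(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    prior: RootPrior = FLAT_PRIOR,
    label: str | None = None,
) -> FitResult:
    """ML estimate of the single Mk1 rate by bounded search on log q.

    A coarse log-spaced scan brackets the optimum before Brent refinement,
    which is robust to the flat likelihood ridges of near-invariant
    characters.  An optimum at the rate bounds is flagged, not raised.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    codes = idx.tip_codes(column)
    if not _has_determinate_tip(codes, idx):
        raise ValueError("character has no determinate tip state")

    def neg_lnl(logq: float) -> float:
        return -_log_likelihood_from_codes(idx, codes, MkModel.mk1(math.exp(logq)), prior)

    lo, hi = _LOG_BOUNDS
    grid = np.linspace(lo, hi, 31)
    vals = [neg_lnl(g) for g in grid]
    j = int(np.argmin(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(neg_lnl, bounds=(a, b), method="bounded", options={"xatol": 1e-10})
    best_logq, best_neg = (res.x, res.fun) if res.fun <= vals[j] else (grid[j], vals[j])
    q = math.exp(best_logq)
    bound_hit = best_logq - lo < 1e-3 or hi - best_logq < 1e-3
    return FitResult(
        model=MkModel.mk1(q),
        log_likelihood=-best_neg,
        k=1,
        converged=bool(res.success),
        bound_hit=bound_hit,
        prior=prior,
        label=label,
    )


# Deterministic multi-start grid for the 2-D optimization (log10 rates);
# chosen to straddle the rate magnitudes seen in morphological data and the
# asymmetric ridges that arise when one state is rare.
_MK2_STARTS = [
    (1e-3, 1e-3),
    (1e-2, 1e-2),
    (1e-4, 1e-4),
    (1e-2, 1e-4),
    (1e-4, 1e-2),
]


def fit_mk2(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    prior: RootPrior = FLAT_PRIOR,
    label: str | None = None,
) -> FitResult:
    """ML estimate of (q01, q10) by bounded quasi-Newton with multi-starts.

    When a state is rare and reversals are unobserved the surface has a flat
    ridge along which the reversal rate can grow enormously; the fit reports
    whatever optimum it finds and flags bound hits rather than suppressing
    them.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    codes = idx.tip_codes(column)
    if not _has_determinate_tip(codes, idx):
        raise ValueError("character has no determinate tip state")

    def neg_lnl(logq: np.ndarray) -> float:
        m = MkModel.mk2(math.exp(logq[0]), math.exp(logq[1]))
        return -_log_likelihood_from_codes(idx, codes, m, prior)

    starts = [np.log(s) for s in _MK2_STARTS]
    mk1_fit = fit_mk1(idx, column, prior)
    starts.append(np.log([mk1_fit.model.q01, mk1_fit.model.q10]))
    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            neg_lnl,
            x0,
            method="L-BFGS-B",
            bounds=[_LOG_BOUNDS, _LOG_BOUNDS],
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    lo, hi = _LOG_BOUNDS
    bound_hit = bool(
        np.any(best.x - lo < 1e-3) or np.any(hi - best.x < 1e-3)
    )
    q01, q10 = np.exp(best.x)
    return FitResult(
        model=MkModel.mk2(float(q01), float(q10)),
        log_likelihood=-float(best.fun),
        k=2,
        converged=any_success,
        bound_hit=bound_hit,
        prior=prior,
        label=label,
    )


def evaluate_fixed(
    tree: dendropy.Tree | TreeIndex,
    column: dict[str, int],
    model: MkModel,
    prior: RootPrior = FLAT_PRIOR,
    label: str | None = None,
) -> FitResult:
    """Likelihood of the data under an imposed model (k = 0, nothing fitted)."""
    lnl = pruning_log_likelihood(tree, column, model, prior)
    return FitResult(model=model, log_likelihood=lnl, k=0, prior=prior, label=label)


def aic_compare(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of the same data by AIC.

    Verdict relative to the best model: ``"no difference in fit"`` when
    dAIC < 2, ``"better fit"`` for the minimum, ``"worse"`` for 2 <= dAIC < 10
    and ``"very different"`` for dAIC >= 10.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    aics = [f.aic for f in fits]
    best = min(aics)
    for f, a in zip(fits, aics):
        d = a - best
        if d == 0:
            verdict = "best"
        elif d < 2:
            verdict = "no difference in fit"
        elif d < 10:
            verdict = "worse"
        else:
            verdict = "very different"
        rows.append(
            {
                "label": f.label or ("Mk1" if f.model.is_mk1 else "Mk2"),
                "q01": f.model.q01,
                "q10": f.model.q10,
                "lnL": f.log_likelihood,
                "k": f.k,
                "AIC": a,
                "dAIC": d,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
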