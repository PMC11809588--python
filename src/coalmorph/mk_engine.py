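"""Discrete-character (Mk) likelihood and parsimony machinery.

The Mk model is the symmetric k-state continuous-time Markov chain with all
exchange rates equal, scaled so that branch lengths are expected changes per
character.  Its transition probabilities have the closed form::

    P(same)   = 1/k + (k-1)/k * exp(-k*t/(k-1))
    P(differ) = 1/k * (1 - exp(-k*t/(k-1)))   (for each of the k-1 others)

Rate heterogeneity uses discrete gamma categories (equal-probability bins,
category-mean rates, overall mean 1).  The Lewis "variable" ascertainment
correction conditions the likelihood on the character being variable:
``L_v = L / (1 - sum_s L_const(s))`` with the constant-pattern likelihoods
averaged over categories first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .tree import PhyloTree, TreeError

__all__ = [
    "MkModel",
    "mk_transition_matrix",
    "mk_character_loglik",
    "mk_loglik_matrix",
    "parsimony_steps",
    "optimize_scalar",
    "discrete_gamma_rates",
]


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability discrete gamma categories (mean 1)."""
    if alpha <= 0 or n_categories < 1:
        raise ValueError("alpha and n_categories must be positive")
    if n_categories == 1:
        return np.ones(1)
    edges = stats.gamma.ppf(
        np.linspace(0, 1, n_categories + 1), a=alpha, scale=1.0 / alpha
    )
    # mean within [a,b] of Gamma(alpha, 1/alpha) equals the shape+1 CDF mass
    upper = stats.gamma.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = stats.gamma.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = n_categories * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class MkModel:
    """Symmetric k-state model with optional gamma rates and Mkv correction."""

    k: int
    rate: float = 1.0
    gamma_categories: int | None = None
    gamma_alpha: float = 1.0
    ascertainment: str = "none"  # 'none' | 'lewis_variable'

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("Mk model needs k >= 2 states")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.ascertainment not in ("none", "lewis_variable"):
            raise ValueError(f"unknown ascertainment {self.ascertainment!r}")

    def category_rates(self) -> np.ndarray:
        if self.gamma_categories is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_alpha, self.gamma_categories)


def mk_transition_matrix(k: int, t: float) -> np.ndarray:
    """P(t) for the symmetric k-state chain, t in expected changes."""
    if t < 0:
        raise ValueError("negative branch length")
    e = np.exp(-k * t / (k - 1))
    off = (1.0 - e) / k
    mat = np.full((k, k), off)
    np.fill_diagonal(mat, 1.0 / k + (k - 1) / k * e)
    return mat


def _tip_partials(
    tree: PhyloTree, columns: np.ndarray, k: int
) -> np.ndarray:
    """(n_leaves, n_chars, k) indicator partials; negatives -> all ones."""
    n_chars = columns.shape[1]
    leaves = tree.leaves()
    tp = np.zeros((len(leaves), n_chars, k))
    for li in range(len(leaves)):
        col = columns[li]
        miss = col < 0
        tp[li, miss, :] = 1.0
        scored = ~miss
        tp[li, scored, col[scored]] = 1.0
    return tp


def _prune(
    tree: PhyloTree,
    tips: np.ndarray,
    k: int,
    branch_scale: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Felsenstein pruning for all characters at one rate.

    ``tips``: (n_leaves, n_chars, k) partials aligned to ``tree.leaves()``.
    ``branch_scale``: scalar rate, or per-node multiplier array.
    Returns (root partials (n_chars, k), per-char log scaling factors).
    """
    lengths = tree._require_lengths()
    if not np.all(np.isfinite(lengths[tree.parent >= 0])):
        raise TreeError("tree has missing branch lengths")
    scale = np.broadcast_to(np.asarray(branch_scale, dtype=float), (tree.n_nodes,))
    n_chars = tips.shape[1]
    leaves = tree.leaves()
    leaf_pos = {int(l): i for i, l in enumerate(leaves)}
    partial = np.empty((tree.n_nodes, n_chars, k))
    logscale = np.zeros(n_chars)
    children = tree.children()
    for node in tree.postorder():
        node = int(node)
        if not children[node]:
            partial[node] = tips[leaf_pos[node]]
            continue
        acc = np.ones((n_chars, k))
        for c in children[node]:
            P = mk_transition_matrix(k, float(lengths[c]) * float(scale[c]))
            acc *= partial[c] @ P  # P symmetric
        m = acc.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        partial[node] = acc / safe[:, None]
        logscale += np.where(m > 0, np.log(safe), -np.inf)
    return partial[tree.root], logscale


def _constant_pattern_likelihoods(
    tree: PhyloTree, k: int, rates: np.ndarray, branch_scale
) -> np.ndarray:
    """Category-averaged likelihood of each all-s constant pattern."""
    n_leaves = tree.n_leaves
    cols = np.tile(np.arange(k, dtype=np.int64), (n_leaves, 1))  # char s = state s
    tips = _tip_partials(tree, cols, k)
    liks = np.zeros(k)
    for r in rates:
        root, logscale = _prune(tree, tips, k, r * np.asarray(branch_scale))
        liks += np.exp(np.log(root.mean(axis=1)) + logscale) / len(rates)
    return liks


def mk_loglik_matrix(
    tree: PhyloTree,
    columns: np.ndarray,
    model: MkModel,
    branch_scale: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Log-likelihood of each character column under the Mk model.

    ``columns`` is ``(n_leaves, n_chars)`` of states aligned to
    ``tree.leaves()``; negative entries are missing/inapplicable (all-ones
    tip vectors).  ``branch_scale`` optionally multiplies branch lengths
    (scalar or per-node), on top of ``model.rate``.
    """
    columns = np.asarray(columns)
    if columns.ndim != 2 or columns.shape[0] != tree.n_leaves:
        raise ValueError("columns must be (n_leaves, n_chars)")
    if columns.max(initial=-1) >= model.k:
        raise ValueError("state index outside the model's k states")
    k = model.k
    rates = model.category_rates() * model.rate
    scale = np.asarray(branch_scale, dtype=float)
    tips = _tip_partials(tree, columns, k)
    n_chars = columns.shape[1]
    lik = np.zeros(n_chars)
    for r in rates:
        root, logscale = _prune(tree, tips, k, r * scale)
        lik += np.exp(np.log(root.mean(axis=1)) + logscale) / len(rates)
    loglik = np.log(lik)
    if model.ascertainment == "lewis_variable":
        const = _constant_pattern_likelihoods(tree, k, rates, scale)
        total_const = const.sum()
        if total_const >= 1.0:
            raise FloatingPointError(
                "constant-pattern likelihoods sum to >= 1; branch lengths "
                "are degenerate"
            )
        loglik = loglik - np.log1p(-total_const)
    return loglik


def mk_character_loglik(
    tree: PhyloTree,
    column: Mapping[str, int] | Sequence[int],
    model: MkModel,
) -> float:
    """Log-likelihood of a single character.

    ``column`` maps taxon label -> state (missing taxa, or states < 0, are
    treated as unobserved), or is an array aligned to ``tree.leaves()``.
    """
    if isinstance(column, Mapping):
        col = np.full(tree.n_leaves, -1, dtype=np.int64)
        labels = [tree.labels[i] for i in tree.leaves()]
        for i, lab in enumerate(labels):
            if lab in column:
                col[i] = int(column[lab])
    else:
        col = np.asarray(column, dtype=np.int64)
    return float(mk_loglik_matrix(tree, col[:, None], model)[0])


# ----------------------------------------------------------------------
# parsimony
# ----------------------------------------------------------------------

def parsimony_steps(
    tree: PhyloTree,
    column: Mapping[str, int] | Sequence[int],
    ordered: bool = False,
) -> int:
    """Minimum number of changes for one character on the tree.

    Unordered characters use unit costs (Fitch count); ordered characters
    use the linear ladder ``|i - j|`` (Sankoff).  Missing/inapplicable tips
    (negative states) are unconstrained.
    """
    if isinstance(column, Mapping):
        col = np.full(tree.n_leaves, -1, dtype=np.int64)
        labels = [tree.labels[i] for i in tree.leaves()]
        for i, lab in enumerate(labels):
            if lab in column:
                col[i] = int(column[lab])
    else:
        col = np.asarray(column, dtype=np.int64)
    scored = col[col >= 0]
    if scored.size == 0:
        raise ValueError("all tips missing")
    if scored.size == 1:
        return 0
    k = int(scored.max()) + 1
    if ordered:
        cost = np.abs(np.subtract.outer(np.arange(k), np.arange(k))).astype(float)
    else:
        cost = 1.0 - np.eye(k)
    INF = np.inf
    leaves = tree.leaves()
    leaf_pos = {int(l): i for i, l in enumerate(leaves)}
    children = tree.children()
    node_cost = np.zeros((tree.n_nodes, k))
    for node in tree.postorder():
        node = int(node)
        if not children[node]:
            s = col[leaf_pos[node]]
            if s < 0:
                node_cost[node] = 0.0
            else:
                node_cost[node] = INF
                node_cost[node, s] = 0.0
            continue
        acc = np.zeros(k)
        for c in children[node]:
            acc += (cost + node_cost[c][None, :]).min(axis=1)
        node_cost[node] = acc
    best = node_cost[tree.root].min()
    return int(round(best))


# ----------------------------------------------------------------------
# scalar optimization
# ----------------------------------------------------------------------

def optimize_scalar(
    objective: Callable[[float], float],
    bounds: tuple[float, float],
    rel_tol: float = 1e-6,
) -> tuple[float, float]:
    """Maximise a (contractually unimodal) objective on an interval.

    Returns ``(argmax, value)``; a bound is returned when the optimum sits
    on the boundary.
    """
    lo, hi = bounds
    f_lo, f_hi = objective(lo), objective(hi)
    if not (np.isfinite(f_lo) or np.isfinite(f_hi)):
        raise ValueError("objective non-finite at both bounds")
    res = optimize.minimize_scalar(
        lambda x: -objective(x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": rel_tol * max(abs(hi), 1.0)},
    )
    candidates = [(lo, f_lo), (hi, f_hi)]
    if np.isfinite(res.fun):
        candidates.append((float(res.x), float(-res.fun)))
    x, v = max(candidates, key=lambda t: t[1] if np.isfinite(t[1]) else -np.inf)
    return x, v
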