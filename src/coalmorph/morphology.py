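"""Morphological distances, character weighting, placement and rate tests.

The toolkit around a discrete morphological matrix and a reference
phylogeny: MORD distances, implied-weighting homoplasy scores and k-means
character partitioning, weight-calibrated maximum-likelihood placement of
query taxa (Mk + gamma + Lewis correction), marginal ancestral states,
rate-shift model selection by AIC weights, and morphology-vs-molecule
distance comparison (Poisson or LG amino-acid ML distances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io_formats import (
    MultipleAlignment,
    MorphMatrix,
    MISSING,
    INAPPLICABLE,
)
from .tree import PhyloTree, TreeError
from .mk_engine import (
    MkModel,
    mk_loglik_matrix,
    mk_transition_matrix,
    parsimony_steps,
    optimize_scalar,
)
from .gene_properties import occupancy as _occupancy

logger = logging.getLogger(__name__)

__all__ = [
    "CharacterWeightSet",
    "PlacementResult",
    "AncestralStateTable",
    "RateScheme",
    "mord_distances",
    "implied_weights",
    "calibrate_weights",
    "partition_characters_kmeans",
    "place_query",
    "summarize_placements",
    "ancestral_states",
    "test_rates",
    "aic_weights",
    "pairwise_ml_distances",
    "morpho_molecular_comparison",
]


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def mord_distances(
    matrix: MorphMatrix, inapplicable: str = "missing"
) -> pd.DataFrame:
    """Maximum Observable Rescaled Distance between all taxon pairs.

    A Gower-style coefficient rescaled to [0, 1]: per comparable character
    the dissimilarity is ``|a-b| / observed range`` for ordered characters
    and an inequality indicator for unordered ones; the pairwise distance is
    the mean over comparable characters.  Pairs with no comparable
    characters are NaN.

    ``inapplicable``: ``"missing"`` excludes inapplicable cells from
    comparability (the default); ``"match"`` additionally scores two
    inapplicable cells as a comparable match (dissimilarity 0).
    """
    if matrix.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if inapplicable not in ("missing", "match"):
        raise ValueError(f"unknown inapplicable policy {inapplicable!r}")
    cells = matrix.cells
    n, m = cells.shape
    ranges = np.ones(m)
    for j, ch in enumerate(matrix.characters):
        col = cells[:, j]
        scored = col[col >= 0]
        if ch.ordered and scored.size:
            ranges[j] = max(int(scored.max()) - int(scored.min()), 1)
    ordered_mask = np.array([c.ordered for c in matrix.characters])
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = cells[a], cells[b]
            comp = (ra >= 0) & (rb >= 0)
            diff = np.zeros(m)
            diff[ordered_mask] = np.abs(
                ra[ordered_mask].astype(float) - rb[ordered_mask]
            ) / ranges[ordered_mask]
            diff[~ordered_mask] = (ra[~ordered_mask] != rb[~ordered_mask]).astype(float)
            if inapplicable == "match":
                both_inap = (ra == INAPPLICABLE) & (rb == INAPPLICABLE)
                diff = np.where(both_inap, 0.0, diff)
                comp = comp | both_inap
            k = int(comp.sum())
            out[a, b] = out[b, a] = diff[comp].mean() if k else np.nan
    return pd.DataFrame(out, index=matrix.taxa, columns=matrix.taxa)


# ----------------------------------------------------------------------
# implied weighting
# ----------------------------------------------------------------------

@dataclass
class CharacterWeightSet:
    """Implied-weighting fits ``f = k / (k + es)`` per character.

    ``es`` is the number of extra (homoplastic) parsimony steps beyond the
    minimum conceivable for the observed states; ``k`` is the concavity
    constant.  Characters scored for fewer than two taxa have NaN fit.
    """

    fits: np.ndarray
    extra_steps: np.ndarray
    concavity: float

    def rescaled(self) -> "CharacterWeightSet":
        """Same fits divided by their (nan-)mean, so the mean weight is 1."""
        mean = np.nanmean(self.fits)
        return CharacterWeightSet(self.fits / mean, self.extra_steps, self.concavity)


def implied_weights(
    matrix: MorphMatrix, tree: PhyloTree, concavity: float = 3.0
) -> CharacterWeightSet:
    """Per-character homoplasy fits measured on a given tree."""
    if concavity <= 0:
        raise ValueError("concavity must be positive")
    tree_taxa = set(tree.leaf_labels())
    missing = set(matrix.taxa) - tree_taxa
    if missing:
        raise ValueError(f"tree lacks matrix taxa: {sorted(missing)}")
    fits = np.full(matrix.n_characters, np.nan)
    es = np.full(matrix.n_characters, np.nan)
    for j, ch in enumerate(matrix.characters):
        col = matrix.cells[:, j]
        scored = col >= 0
        if scored.sum() < 2:
            continue
        column = {
            t: int(s) for t, s in zip(matrix.taxa, col) if s >= 0
        }
        steps = parsimony_steps(tree, column, ordered=ch.ordered)
        n_states = len(np.unique(col[scored]))
        extra = steps - (n_states - 1)
        es[j] = extra
        fits[j] = concavity / (concavity + extra)
    return CharacterWeightSet(fits, es, concavity)


def calibrate_weights(
    matrix: MorphMatrix, guide_tree: PhyloTree, concavity: float = 3.0
) -> CharacterWeightSet:
    """Implied weights on a guide tree, rescaled to mean weight 1."""
    return implied_weights(matrix, guide_tree, concavity).rescaled()


def partition_characters_kmeans(
    scores: Sequence[float],
    k_max: int = 10,
    seed: int = 0,
    k_override: int | None = None,
) -> tuple[int, np.ndarray, dict[int, float]]:
    """Cluster per-character scores (1-D k-means) into rate partitions.

    Runs k-means for k = 1..k_max (best of 25 restarts), recording the
    total within-cluster sum of squares.  The chosen k is the smallest one
    achieving SS = 0 if any does, otherwise the k with the largest second
    difference of the SS curve (the elbow); ``k_override`` forces a k.
    Returns (chosen k, per-character cluster labels with -1 for characters
    whose score is not finite, SS per k).
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if finite.sum() < 2:
        raise ValueError("need at least 2 characters with finite scores")
    x = scores[finite].reshape(-1, 1)
    n_distinct = len(np.unique(x))
    ss: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k > n_distinct:
            continue  # fewer distinct scores than clusters
        km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(x)
        ss[k] = float(km.inertia_)
        labelings[k] = km.labels_
    ks = sorted(ss)
    zero = [k for k in ks if ss[k] <= 1e-12]
    if k_override is not None:
        if k_override not in ss:
            raise ValueError(f"k={k_override} was not fitted")
        chosen = k_override
    elif zero:
        chosen = zero[0]
    elif len(ks) >= 3:
        second_diff = {
            k: (ss[km1] - ss[k]) - (ss[k] - ss[kp1])
            for km1, k, kp1 in zip(ks, ks[1:], ks[2:])
        }
        chosen = max(second_diff, key=lambda k: (second_diff[k], -k))
    else:
        chosen = min(ks, key=lambda k: (ss[k], k))
    labels = np.full(scores.shape[0], -1, dtype=np.int64)
    labels[finite] = labelings[chosen]
    return chosen, labels, ss


# ----------------------------------------------------------------------
# grouped Mk likelihood (characters may differ in state count)
# ----------------------------------------------------------------------

def _char_state_counts(matrix: MorphMatrix, extra_rows: np.ndarray | None = None) -> np.ndarray:
    ks = np.empty(matrix.n_characters, dtype=np.int64)
    for j, ch in enumerate(matrix.characters):
        mx = max(ch.states) if ch.states else 1
        if extra_rows is not None:
            q = extra_rows[..., j]
            qmax = q.max(initial=-1)
            mx = max(mx, int(qmax))
        ks[j] = max(2, mx + 1)
    return ks


def _grouped_logliks(
    tree: PhyloTree,
    columns: np.ndarray,
    ks: np.ndarray,
    model: MkModel,
    branch_scale: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Per-character log-likelihoods, grouping characters by state count.

    ``model`` supplies rate, gamma and ascertainment settings; each group
    uses its own state count k.
    """
    out = np.empty(columns.shape[1])
    for k in np.unique(ks):
        sel = np.flatnonzero(ks == k)
        sub_model = MkModel(
            k=int(k),
            rate=model.rate,
            gamma_categories=model.gamma_categories,
            gamma_alpha=model.gamma_alpha,
            ascertainment=model.ascertainment,
        )
        out[sel] = mk_loglik_matrix(tree, columns[:, sel], sub_model, branch_scale)
    return out


def _columns_for_tree(
    tree: PhyloTree, matrix: MorphMatrix, extra: Mapping[str, np.ndarray] | None = None
) -> np.ndarray:
    """(n_tree_leaves, n_chars) state columns aligned to ``tree.leaves()``.

    Taxa absent from the matrix get all-missing rows; ``extra`` supplies
    rows for taxa outside the matrix (e.g. a query).
    """
    leaves = tree.leaves()
    cols = np.full((len(leaves), matrix.n_characters), MISSING, dtype=np.int64)
    for i, node in enumerate(leaves):
        lab = tree.labels[node]
        if extra and lab in extra:
            cols[i] = extra[lab]
        elif lab in matrix.taxa:
            cols[i] = matrix.row(lab)
    return cols


# ----------------------------------------------------------------------
# placement
# ----------------------------------------------------------------------

@dataclass
class PlacementResult:
    query: str
    ranked: list[tuple[int, float, float]]  # (edge child id, score, pendant)
    best_edge: int
    pendant_length: float
    assigned_group: str | None


def _clade_group(
    tree: PhyloTree, edge_child: int, groups: Mapping[str, str]
) -> str | None:
    """Unique group label of the leaves under ``edge_child``, else None."""
    stack = [edge_child]
    found: set[str] = set()
    while stack:
        node = stack.pop()
        if tree.is_leaf(node):
            g = groups.get(tree.labels[node])
            if g is not None:
                found.add(g)
        else:
            stack.extend(tree.children()[node])
    return found.pop() if len(found) == 1 else None


def place_query(
    reference_tree: PhyloTree,
    matrix: MorphMatrix,
    weights: CharacterWeightSet | np.ndarray | None,
    query: np.ndarray,
    model: MkModel,
    query_id: str = "query",
    groups: Mapping[str, str] | None = None,
    pendant_bounds: tuple[float, float] = (1e-8, 10.0),
) -> PlacementResult:
    """Maximum-likelihood placement of a query row on every reference edge.

    The query is attached at the midpoint of each edge in turn; its pendant
    branch length is optimised, and the edge score is the weighted sum of
    per-character Mk log-likelihoods.  Edges are ranked by score; the
    assigned group is the unique group label of the clade below the best
    edge (None when that clade mixes groups).
    """
    query = np.asarray(query, dtype=np.int64)
    if query.shape != (matrix.n_characters,):
        raise ValueError("query length must equal the number of characters")
    if not np.any(query >= 0):
        raise ValueError("query has no scored characters")
    if query_id in reference_tree.leaf_labels():
        raise ValueError(f"query id {query_id!r} already in the reference tree")
    tree = reference_tree
    if not tree.has_lengths:
        logger.info("reference tree has no branch lengths; using unit lengths")
        tree = tree.with_lengths(np.ones(tree.n_nodes), "none")
    if isinstance(weights, CharacterWeightSet):
        w = weights.fits
    elif weights is None:
        w = np.ones(matrix.n_characters)
    else:
        w = np.asarray(weights, dtype=float)
    w = np.where(np.isfinite(w), w, 0.0)
    ks = _char_state_counts(matrix, extra_rows=query[None, :])
    results: list[tuple[int, float, float]] = []
    for edge in tree.edges():
        attached = tree.attach_leaf(edge, query_id, pendant_length=1.0)
        cols = _columns_for_tree(attached, matrix, extra={query_id: query})
        scale = np.ones(attached.n_nodes)
        leaf_node = attached.leaf_index(query_id)

        def score(p: float) -> float:
            scale[leaf_node] = p
            ll = _grouped_logliks(attached, cols, ks, model, scale)
            return float(np.sum(w * ll))

        p_hat, s_hat = optimize_scalar(score, pendant_bounds, rel_tol=1e-4)
        results.append((edge, s_hat, p_hat))
    results.sort(key=lambda t: -t[1])
    best_edge, _, best_pendant = results[0]
    assigned = (
        _clade_group(tree, best_edge, groups) if groups is not None else None
    )
    return PlacementResult(
        query=query_id,
        ranked=results,
        best_edge=best_edge,
        pendant_length=best_pendant,
        assigned_group=assigned,
    )


def summarize_placements(
    placements: Sequence[tuple[str, str | None, str]],
    reference_groups: Sequence[str],
) -> pd.DataFrame:
    """Per-group placement accuracy table.

    ``placements`` holds ``(query id, assigned group or None, truth group)``
    records; ``reference_groups`` lists the groups represented in the
    reference tree.  Rows: one per truth group (alphabetical), then
    ``In the reference tree``, ``Not in the reference tree`` and ``Total``;
    columns: number of species, number correct, percentage (2 decimals).
    """
    ref = set(reference_groups)
    per_group: dict[str, list[int]] = {}
    for _, assigned, truth in placements:
        n, c = per_group.setdefault(truth, [0, 0])
        per_group[truth][0] = n + 1
        per_group[truth][1] = c + int(assigned == truth)
    rows = []

    def add_row(name: str, n: int, c: int) -> None:
        pct = round(100.0 * c / n, 2) if n else 0.0
        rows.append({"group": name, "n_species": n, "n_correct": c, "percentage": pct})

    in_ref = [g for g in sorted(per_group) if g in ref]
    out_ref = [g for g in sorted(per_group) if g not in ref]
    for g in sorted(per_group):
        add_row(g, *per_group[g])
    add_row(
        "In the reference tree",
        sum(per_group[g][0] for g in in_ref),
        sum(per_group[g][1] for g in in_ref),
    )
    add_row(
        "Not in the reference tree",
        sum(per_group[g][0] for g in out_ref),
        sum(per_group[g][1] for g in out_ref),
    )
    add_row(
        "Total",
        sum(v[0] for v in per_group.values()),
        sum(v[1] for v in per_group.values()),
    )
    return pd.DataFrame(rows).set_index("group")


# ----------------------------------------------------------------------
# ancestral states
# ----------------------------------------------------------------------

@dataclass
class AncestralStateTable:
    """Marginal state probabilities for internal nodes.

    ``probabilities[j]`` is an ``(n_internal_nodes, k_j)`` array for
    character ``j`` (rows follow ``nodes``).  ``resolved`` holds the state
    with marginal probability above the threshold, else NA.
    """

    nodes: list[int]
    probabilities: dict[int, np.ndarray]
    threshold: float
    resolved: pd.DataFrame = field(init=False)

    def __post_init__(self):
        data = {}
        for j, probs in self.probabilities.items():
            best = probs.argmax(axis=1)
            ok = probs.max(axis=1) > self.threshold
            data[j] = [int(s) if o else pd.NA for s, o in zip(best, ok)]
        self.resolved = pd.DataFrame(data, index=self.nodes)


def _marginals_one_group(
    tree: PhyloTree, columns: np.ndarray, k: int, model: MkModel
) -> np.ndarray:
    """(n_internal, n_chars, k) marginal probabilities (up/down passes)."""
    from .mk_engine import _tip_partials  # shared tip encoding

    lengths = tree._require_lengths()
    rates = model.category_rates() * model.rate
    n_chars = columns.shape[1]
    children = tree.children()
    leaves = tree.leaves()
    leaf_pos = {int(l): i for i, l in enumerate(leaves)}
    internal = [i for i in range(tree.n_nodes) if children[i]]
    tips = _tip_partials(tree, columns, k)
    log_marg = np.full((len(rates), len(internal), n_chars, k), -np.inf)
    for ci, r in enumerate(rates):
        P = {
            int(c): mk_transition_matrix(k, float(lengths[c]) * r)
            for c in range(tree.n_nodes)
            if tree.parent[c] >= 0
        }
        up = np.empty((tree.n_nodes, n_chars, k))
        upls = np.zeros((tree.n_nodes, n_chars))
        for node in tree.postorder():
            node = int(node)
            if not children[node]:
                up[node] = tips[leaf_pos[node]]
                continue
            acc = np.ones((n_chars, k))
            ls = np.zeros(n_chars)
            for c in children[node]:
                acc *= up[c] @ P[c]
                ls += upls[c]
            m = acc.max(axis=1)
            safe = np.where(m > 0, m, 1.0)
            up[node] = acc / safe[:, None]
            upls[node] = ls + np.log(safe)
        down = np.empty((tree.n_nodes, n_chars, k))
        downls = np.zeros((tree.n_nodes, n_chars))
        down[tree.root] = 1.0 / k
        for node in tree.preorder():
            node = int(node)
            for c in children[node]:
                msg = down[node].copy()
                ls = downls[node].copy()
                for b in children[node]:
                    if b == c:
                        continue
                    msg *= up[b] @ P[b]
                    ls += upls[b]
                msg = msg @ P[c]
                m = msg.max(axis=1)
                safe = np.where(m > 0, m, 1.0)
                down[c] = msg / safe[:, None]
                downls[c] = ls + np.log(safe)
        for ni, node in enumerate(internal):
            joint = up[node] * down[node]
            with np.errstate(divide="ignore"):
                log_marg[ci, ni] = (
                    np.log(joint)
                    + (upls[node] + downls[node])[:, None]
                )
    weighted = logsumexp(log_marg, axis=0, b=1.0 / len(rates))
    norm = logsumexp(weighted, axis=2, keepdims=True)
    return np.exp(weighted - norm)


def ancestral_states(
    tree: PhyloTree,
    matrix: MorphMatrix,
    model: MkModel,
    threshold: float = 0.69,
) -> AncestralStateTable:
    """Marginal ancestral-state reconstruction at every internal node.

    Missing and inapplicable cells contribute flat tip vectors.  A node's
    state is reported as resolved only where its marginal probability
    exceeds ``threshold`` (an intentionally conservative default).
    """
    cols = _columns_for_tree(tree, matrix)
    ks = _char_state_counts(matrix)
    children = tree.children()
    internal = [i for i in range(tree.n_nodes) if children[i]]
    probabilities: dict[int, np.ndarray] = {}
    for k in np.unique(ks):
        sel = np.flatnonzero(ks == k)
        sub_model = MkModel(
            k=int(k),
            rate=model.rate,
            gamma_categories=model.gamma_categories,
            gamma_alpha=model.gamma_alpha,
        )
        marg = _marginals_one_group(tree, cols[:, sel], int(k), sub_model)
        for idx, j in enumerate(sel):
            probabilities[int(j)] = marg[:, idx, :]
    return AncestralStateTable(internal, probabilities, threshold)


# ----------------------------------------------------------------------
# rate-shift model selection
# ----------------------------------------------------------------------

@dataclass
class RateScheme:
    """One candidate rate model: branch blocks and/or character blocks.

    ``branch_blocks`` maps each non-root node (its parent edge) to a block
    id; ``char_blocks`` maps characters to blocks.  ``None`` means a single
    shared block.  Every block gets one free rate multiplier.
    """

    name: str
    branch_blocks: np.ndarray | None = None
    char_blocks: np.ndarray | None = None


def aic_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights: ``exp(-delta_i/2)`` normalised to sum 1."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _scheme_loglik(
    tree: PhyloTree,
    cols: np.ndarray,
    ks: np.ndarray,
    model: MkModel,
    scheme: RateScheme,
) -> tuple[float, int]:
    """Maximised log-likelihood and parameter count for one scheme."""
    n_nodes = tree.n_nodes
    if scheme.branch_blocks is not None:
        bb = np.asarray(scheme.branch_blocks, dtype=np.int64)
        if bb.shape[0] != n_nodes:
            raise ValueError("branch_blocks must have one entry per node")
        blocks = np.unique(bb[tree.parent >= 0])
        if any((bb[tree.parent >= 0] == b).sum() == 0 for b in blocks):
            raise ValueError("empty branch block")
    else:
        bb = np.zeros(n_nodes, dtype=np.int64)
        blocks = np.array([0])
    if scheme.char_blocks is not None:
        cb = np.asarray(scheme.char_blocks, dtype=np.int64)
        if cb.shape[0] != cols.shape[1]:
            raise ValueError("char_blocks must have one entry per character")
        cblocks = np.unique(cb)
        for b in cblocks:
            if not np.any(cols[:, cb == b] >= 0):
                raise ValueError(f"character block {b} has no data")
    else:
        cb = None
        cblocks = None

    if cb is not None and scheme.branch_blocks is None:
        # per-character-block rates are separable: one scalar fit per block
        total = 0.0
        for b in cblocks:
            sel = np.flatnonzero(cb == b)

            def obj(log_r: float, sel=sel) -> float:
                return float(
                    _grouped_logliks(
                        tree, cols[:, sel], ks[sel], model, np.exp(log_r)
                    ).sum()
                )

            _, val = optimize_scalar(obj, (np.log(1e-4), np.log(1e3)), rel_tol=1e-6)
            total += val
        return total, len(cblocks)

    if cb is not None:
        raise NotImplementedError(
            "schemes combining branch and character blocks are not supported"
        )
    block_index = {int(b): i for i, b in enumerate(blocks)}
    # the root carries no edge; give it any valid slot
    mapped = np.array([block_index.get(int(b), 0) for b in bb])

    def negll(log_rates: np.ndarray) -> float:
        scale = np.exp(log_rates)[mapped]
        return -float(_grouped_logliks(tree, cols, ks, model, scale).sum())

    # start from the shared-rate optimum so a partitioned scheme can never
    # score below its nested single-rate special case
    log_r0, ll0 = optimize_scalar(
        lambda u: -negll(np.full(len(blocks), u)),
        (np.log(1e-4), np.log(1e3)),
        rel_tol=1e-6,
    )
    x0 = np.full(len(blocks), log_r0)
    best = ll0
    for method in ("L-BFGS-B", "Nelder-Mead"):
        res = optimize.minimize(
            negll,
            x0=x0,
            method=method,
            bounds=[(np.log(1e-4), np.log(1e3))] * len(blocks),
        )
        if np.isfinite(res.fun):
            best = max(best, -float(res.fun))
    return best, len(blocks)


def test_rates(
    chronogram: PhyloTree,
    matrix: MorphMatrix,
    schemes: Sequence[RateScheme],
    model: MkModel | None = None,
) -> pd.DataFrame:
    """Compare rate-shift schemes on a time tree by AIC weight.

    Each scheme fits one Mk rate multiplier per block (branch length =
    time x block rate); AIC = 2p - 2 lnL and Akaike weights are reported.
    Missing cells are uncertainty over all states; inapplicable cells are
    treated as missing.
    """
    if model is None:
        model = MkModel(k=2)
    cols = _columns_for_tree(chronogram, matrix)
    ks = _char_state_counts(matrix)
    rows = []
    for scheme in schemes:
        lnl, p = _scheme_loglik(chronogram, cols, ks, model, scheme)
        rows.append(
            dict(scheme=scheme.name, lnL=lnl, n_params=p, aic=2 * p - 2 * lnl)
        )
    df = pd.DataFrame(rows).set_index("scheme")
    df["aic_weight"] = aic_weights(df["aic"].to_numpy())
    return df


# ----------------------------------------------------------------------
# molecular distances
# ----------------------------------------------------------------------

# LG amino-acid model (Le & Gascuel 2008): exchangeabilities as the
# lower-triangular rows of the rate matrix in PAML order, plus equilibrium
# frequencies.
_PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
_LG_LOWER = np.array([
    0.425093,
    0.276818, 0.751878,
    0.395144, 0.123954, 5.076149,
    2.489084, 0.534551, 0.528768, 0.062556,
    0.969894, 2.807908, 1.695752, 0.523386, 0.084808,
    1.038545, 0.363970, 0.541712, 5.243870, 0.003499, 4.128591,
    2.066040, 0.390192, 1.437645, 0.844926, 0.569265, 0.267959, 0.348847,
    0.358858, 2.426601, 4.509238, 0.927114, 0.640543, 4.813505, 0.423881,
    0.311484,
    0.149830, 0.126991, 0.191503, 0.010690, 0.320627, 0.072854, 0.044265,
    0.008705, 0.108882,
    0.395337, 0.301848, 0.068427, 0.015076, 0.594007, 0.582457, 0.069673,
    0.044261, 0.366317, 4.145067,
    0.536518, 6.326067, 2.145078, 0.282959, 0.013266, 3.234294, 1.807177,
    0.296636, 0.697264, 0.159069, 0.137500,
    1.124035, 0.484133, 0.371004, 0.025548, 0.893680, 1.672569, 0.173735,
    0.139538, 0.442472, 4.273607, 6.312358, 0.656604,
    0.253701, 0.052722, 0.089525, 0.017416, 1.105251, 0.035855, 0.018811,
    0.089586, 0.682139, 1.112727, 2.592692, 0.023918, 1.798853,
    1.177651, 0.332533, 0.161787, 0.394456, 0.075382, 0.624294, 0.419409,
    0.196961, 0.508851, 0.078281, 0.249060, 0.390322, 0.099849, 0.094464,
    4.727182, 0.858151, 4.008358, 1.240275, 2.784478, 1.223828, 0.611973,
    1.739990, 0.990012, 0.064105, 0.182287, 0.748683, 0.346960, 0.361819,
    1.338132,
    2.139501, 0.578987, 2.000679, 0.425860, 1.143480, 1.080136, 0.604545,
    0.129836, 0.584262, 1.033739, 0.302936, 1.136863, 2.020366, 0.165001,
    0.571468, 6.472279,
    0.180717, 0.593607, 0.045376, 0.029890, 0.670128, 0.236199, 0.077852,
    0.268491, 0.597054, 0.111660, 0.619632, 0.049906, 0.696175, 2.457121,
    0.095131, 0.248862, 0.140825,
    0.218959, 0.314440, 0.612025, 0.135107, 1.165532, 0.257336, 0.120037,
    0.054679, 5.306834, 0.232523, 0.299648, 0.131932, 0.481306, 7.803902,
    0.089613, 0.400547, 0.245841, 3.151815,
    2.547870, 0.170887, 0.083688, 0.037967, 1.959291, 0.210332, 0.245034,
    0.076701, 0.119013, 10.649107, 1.702745, 0.185202, 1.898718, 0.654683,
    0.296501, 0.098369, 2.188158, 0.189510, 0.249313,
])
_LG_FREQS = np.array([
    0.079066, 0.055941, 0.041977, 0.053052, 0.012937, 0.040767, 0.071586,
    0.057337, 0.022355, 0.062157, 0.099081, 0.064600, 0.022951, 0.042302,
    0.044040, 0.061197, 0.053287, 0.012066, 0.034155, 0.069147,
])


def _aa_model(name: str, alphabet_order: str) -> tuple[np.ndarray, np.ndarray]:
    """(pi, Q) in the given residue order, Q scaled to 1 change/unit time."""
    k = len(alphabet_order)
    if name == "poisson":
        pi = np.full(k, 1.0 / k)
        S = np.ones((k, k)) - np.eye(k)
    elif name == "lg":
        S_paml = np.zeros((20, 20))
        idx = 0
        for i in range(1, 20):
            for j in range(i):
                S_paml[i, j] = S_paml[j, i] = _LG_LOWER[idx]
                idx += 1
        perm = [_PAML_ORDER.index(ch) for ch in alphabet_order]
        S = S_paml[np.ix_(perm, perm)]
        pi = _LG_FREQS[perm]
    else:
        raise ValueError(f"unknown substitution model {name!r}")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.sum(pi * np.diag(Q)))
    return pi, Q / mu


def _ml_distance(
    counts: np.ndarray, pi: np.ndarray, Q: np.ndarray, t_max: float = 20.0
) -> float:
    """ML evolutionary distance from a pairwise substitution-count matrix."""
    # symmetric eigen-decomposition of pi^{1/2} Q pi^{-1/2}
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = 0.5 * (B + B.T)
    evals, evecs = np.linalg.eigh(B)
    left = evecs / sq[:, None]
    right = evecs * sq[:, None]

    def loglik(t: float) -> float:
        P = right @ (np.exp(evals * t)[:, None] * left.T)
        P = np.clip(P, 1e-300, None)
        return float(np.sum(counts * np.log(pi[:, None] * P)))

    if counts.sum() == 0:
        return np.nan
    off = counts.sum() - np.trace(counts)
    if off == 0:
        return 0.0
    t_hat, _ = optimize_scalar(loglik, (1e-9, t_max), rel_tol=1e-7)
    return float(t_hat)


def pairwise_ml_distances(
    alignments: Sequence[MultipleAlignment],
    model: str = "lg",
    top_k: int | None = None,
    full_taxon_set: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise and per-taxon-average ML distances from concatenated genes.

    With ``top_k`` the most occupancy-complete genes are selected first
    (ties broken by gene name).  For each taxon pair the ML distance
    maximises the likelihood over the sites shared by both sequences under
    the chosen amino-acid model (``"poisson"`` or ``"lg"``); pairs sharing
    no scored sites are NaN.  The per-taxon value is the mean distance to
    all other taxa.
    """
    if not alignments:
        raise ValueError("empty gene set")
    taxa: list[str] = []
    for a in alignments:
        for t in a.taxa:
            if t not in taxa:
                taxa.append(t)
    if full_taxon_set is not None:
        taxa = list(full_taxon_set)
    if top_k is not None:
        ranked = sorted(
            alignments,
            key=lambda a: (-_occupancy(a, taxa), a.name),
        )
        alignments = ranked[:top_k]
    alphabet = alignments[0].alphabet
    order = "ACDEFGHIKLMNPQRSTVWY" if alphabet == "AA" else "ACGT"
    if model == "lg" and alphabet != "AA":
        raise ValueError("the LG model applies to amino-acid data")
    pi, Q = _aa_model(model, order)
    k = len(order)
    n = len(taxa)
    counts = np.zeros((n, n, k, k), dtype=np.int64)
    for a in alignments:
        codes = a.codes()
        present = [i for i, t in enumerate(taxa) if t in a.taxa]
        rows = {i: codes[a.taxa.index(taxa[i])] for i in present}
        for xi in range(len(present)):
            i = present[xi]
            for yj in range(xi + 1, len(present)):
                j = present[yj]
                ri, rj = rows[i], rows[j]
                both = (ri >= 0) & (rj >= 0)
                if not both.any():
                    continue
                np.add.at(counts[i, j], (ri[both], rj[both]), 1)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = counts[i, j] + counts[j, i].T
            c = 0.5 * (c + c.T)  # symmetrise: unrooted pair direction
            d = _ml_distance(c, pi, Q) if c.sum() else np.nan
            dist[i, j] = dist[j, i] = d
    df = pd.DataFrame(dist, index=taxa, columns=taxa)
    per_taxon = df.where(~np.eye(n, dtype=bool)).mean(axis=1)
    return df, per_taxon


def morpho_molecular_comparison(
    morph_distances: pd.DataFrame, molecular_distances: pd.DataFrame
) -> pd.DataFrame:
    """Per-taxon mean morphological vs mean molecular distance.

    Both inputs are square taxon-labelled distance tables; means are taken
    over the other taxa shared by both.
    """
    shared = [t for t in morph_distances.index if t in molecular_distances.index]
    if not shared:
        raise ValueError("no shared taxa between the two distance tables")
    rows = []
    for t in shared:
        others = [u for u in shared if u != t]
        rows.append(
            dict(
                taxon=t,
                morphological=float(morph_distances.loc[t, others].mean()),
                molecular=float(molecular_distances.loc[t, others].mean()),
            )
        )
    return pd.DataFrame(rows).set_index("taxon")
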