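"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/vectorised code paths:
likelihoods are computed by exhaustive summation over ancestral state
assignments, parsimony by exhaustive minimisation, distances by explicit
path walking, and site patterns by per-column Python classification.
"""

from __future__ import annotations

import itertools

import numpy as np

from coalmorph.tree import PhyloTree
from coalmorph.mk_engine import mk_transition_matrix


def enumerate_internal_assignments(tree: PhyloTree, k: int):
    children = tree.children()
    internal = [i for i in range(tree.n_nodes) if children[i]]
    for assign in itertools.product(range(k), repeat=len(internal)):
        yield dict(zip(internal, assign))


def brute_likelihood(
    tree: PhyloTree, column: dict[str, int], k: int, rate: float = 1.0
) -> float:
    """Sum over all ancestral assignments of prior x transition products.

    Tips missing from ``column`` (or scored negative) are summed over.
    """
    leaves = list(tree.leaves())
    tip_state = {}
    free_tips = []
    for l in leaves:
        s = column.get(tree.labels[l], -1)
        if s >= 0:
            tip_state[l] = s
        else:
            free_tips.append(l)
    total = 0.0
    L = tree.lengths
    P = {
        int(c): mk_transition_matrix(k, float(L[c]) * rate)
        for c in range(tree.n_nodes)
        if tree.parent[c] >= 0
    }
    for anc in enumerate_internal_assignments(tree, k):
        for free in itertools.product(range(k), repeat=len(free_tips)):
            st = dict(anc)
            st.update(tip_state)
            st.update(dict(zip(free_tips, free)))
            p = 1.0 / k
            for node in range(tree.n_nodes):
                if tree.parent[node] < 0:
                    continue
                p *= P[node][st[int(tree.parent[node])], st[node]]
            total += p
    return total


def brute_loglik_gamma_lewis(
    tree: PhyloTree,
    column: dict[str, int],
    k: int,
    rates: np.ndarray,
    lewis: bool = False,
) -> float:
    lik = float(np.mean([brute_likelihood(tree, column, k, r) for r in rates]))
    if lewis:
        const = 0.0
        labels = [tree.labels[i] for i in tree.leaves()]
        for s in range(k):
            cc = {lab: s for lab in labels}
            const += float(
                np.mean([brute_likelihood(tree, cc, k, r) for r in rates])
            )
        lik = lik / (1.0 - const)
    return float(np.log(lik))


def brute_marginals(
    tree: PhyloTree, column: dict[str, int], k: int, rates: np.ndarray
) -> dict[int, np.ndarray]:
    """Marginal posterior state probabilities for every internal node."""
    children = tree.children()
    internal = [i for i in range(tree.n_nodes) if children[i]]
    out = {i: np.zeros(k) for i in internal}
    L = tree.lengths
    leaves = list(tree.leaves())
    tip_state = {
        l: column.get(tree.labels[l], -1) for l in leaves
    }
    free_tips = [l for l in leaves if tip_state[l] < 0]
    for r in rates:
        P = {
            int(c): mk_transition_matrix(k, float(L[c]) * r)
            for c in range(tree.n_nodes)
            if tree.parent[c] >= 0
        }
        for anc in enumerate_internal_assignments(tree, k):
            for free in itertools.product(range(k), repeat=len(free_tips)):
                st = dict(anc)
                st.update({l: s for l, s in tip_state.items() if s >= 0})
                st.update(dict(zip(free_tips, free)))
                p = 1.0 / k / len(rates)
                for node in range(tree.n_nodes):
                    if tree.parent[node] < 0:
                        continue
                    p *= P[node][st[int(tree.parent[node])], st[node]]
                for i in internal:
                    out[i][anc[i]] += p
    for i in internal:
        out[i] /= out[i].sum()
    return out


def brute_parsimony(
    tree: PhyloTree, column: dict[str, int], ordered: bool
) -> int:
    """Exhaustive minimisation over internal (and missing-tip) states."""
    scored = [s for s in column.values() if s >= 0]
    k = max(scored) + 1
    leaves = list(tree.leaves())
    tip_state = {l: column.get(tree.labels[l], -1) for l in leaves}
    free_tips = [l for l in leaves if tip_state[l] < 0]
    best = np.inf
    for anc in enumerate_internal_assignments(tree, k):
        for free in itertools.product(range(k), repeat=len(free_tips)):
            st = dict(anc)
            st.update({l: s for l, s in tip_state.items() if s >= 0})
            st.update(dict(zip(free_tips, free)))
            cost = 0
            for node in range(tree.n_nodes):
                p = int(tree.parent[node])
                if p < 0:
                    continue
                a, b = st[p], st[node]
                cost += abs(a - b) if ordered else int(a != b)
            best = min(best, cost)
    return int(best)


def brute_patristic(tree: PhyloTree, a: str, b: str) -> float:
    """Path length via explicit root-path walking."""
    def path(label):
        node = tree.leaf_index(label)
        nodes = []
        while node >= 0:
            nodes.append(node)
            node = int(tree.parent[node])
        return nodes

    pa, pb = path(a), path(b)
    common = set(pa) & set(pb)
    dist = 0.0
    for n in pa:
        if n in common:
            break
        dist += float(tree.lengths[n])
    for n in pb:
        if n in common:
            break
        dist += float(tree.lengths[n])
    return dist


def classify_quartet_column(p1: str, p2: str, p3: str, o: str) -> str:
    """'abba' / 'baba' / 'informative' / 'other' for one residue column."""
    states = [p1, p2, p3, o]
    if any(s in "-?XNxn" for s in states):
        return "other"
    if len(set(states)) != 2:
        return "other"
    if p1 == o and p2 == p3 and p2 != o:
        return "abba"
    if p2 == o and p1 == p3 and p1 != o:
        return "baba"
    return "informative"


def best_1d_partition_ss(values: np.ndarray, k: int) -> float:
    """Exhaustive optimal 1-D clustering: contiguous partitions of the
    sorted values minimise within-cluster SS."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = len(xs)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        ss = 0.0
        for a, b in zip(edges, edges[1:]):
            seg = xs[a:b]
            ss += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, ss)
    return best
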