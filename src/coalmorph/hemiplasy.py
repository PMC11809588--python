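"""Hemiplasy Risk Factor (HRF) for internal species-tree branches.

A binary trait that conflicts with a species-tree clade can arise in two
ways: a single mutation on the internal branch of a *discordant* gene
genealogy (hemiplasy), or two or more mutations on any genealogy
(homoplasy).  The HRF of a branch is the hemiplastic fraction of expected
conflicting trait patterns, so HRF near 1 means observed incongruence is
cheap to produce without convergent evolution.

The model is the rooted-triplet multispecies coalescent around the focal
internal branch (length ``t`` in coalescent units): the two descendant
lineages coalesce within the branch with probability ``1 - e^(-t)``,
otherwise the three lineages (including the sister/outgroup lineage) join
uniformly at random above it.  Mutations are Poisson with rate ``mu`` per
coalescent unit on each genealogy branch; multiple hits toggle the binary
state.  A conflicting pattern is one where the derived state is shared by a
tip pair that crosses the focal clade boundary.

Genealogies are always sampled by Monte Carlo.  For the default estimator
the mutation layer is integrated out exactly (per-genealogy conditional
probabilities via parity enumeration over branches), which keeps HRF
estimates stable even at the tiny mutation rates where actual conflicting
draws would be vanishingly rare; ``method="scatter"`` instead draws Poisson
mutation counts explicitly and classifies realised patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np
import pandas as pd

from .tree import PhyloTree, TreeError

logger = logging.getLogger(__name__)

__all__ = ["HRFEstimate", "hrf_branch", "hrf_profile"]

DEFAULT_MU_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1)


@dataclass
class HRFEstimate:
    branch: int  # child-node id of the focal branch
    mu: float
    hrf: float  # nan when undefined (no conflicting replicates)
    n_replicates: int
    hemiplastic: float
    homoplastic: float
    se: float
    defined: bool


# genealogy classes
_WITHIN = 0  # coalescence inside the focal branch (concordant)
_DEEP_AB = 1  # deep coalescence, concordant topology
_DEEP_AC = 2  # discordant: outer lineage pairs with A
_DEEP_BC = 3  # discordant: outer lineage pairs with B


def _sample_genealogies(
    t: float, pendant: float, n: int, rng: np.random.Generator
):
    """Sample triplet genealogies around a focal branch.

    Returns (class, Lx, Ly, Li, Lz) where (x, y) is the cherry, ``Li`` the
    internal branch above it and ``z`` the outer lineage.
    """
    cls = np.empty(n, dtype=np.int8)
    Lx = np.empty(n)
    Ly = np.empty(n)
    Li = np.empty(n)
    Lz = np.empty(n)
    u_all = rng.random(n)
    within = u_all < 1.0 - np.exp(-t)
    nw = int(within.sum())
    # coalescence time inside the branch: truncated Exp(1) on [0, t]
    u = -np.log1p(-rng.random(nw) * (1.0 - np.exp(-t)))
    w = rng.exponential(1.0, size=nw)
    cls[within] = _WITHIN
    Lx[within] = Ly[within] = pendant + u
    Li[within] = (t - u) + w
    Lz[within] = pendant + t + w
    nd = n - nw
    deep = ~within
    w1 = rng.exponential(1.0 / 3.0, size=nd)
    w2 = rng.exponential(1.0, size=nd)
    pair = rng.integers(0, 3, size=nd)  # 0: (a,b), 1: (a,c), 2: (b,c)
    cls[deep] = np.choose(pair, [_DEEP_AB, _DEEP_AC, _DEEP_BC])
    Lx[deep] = Ly[deep] = pendant + t + w1
    Li[deep] = w2
    Lz[deep] = pendant + t + w1 + w2
    return cls, Lx, Ly, Li, Lz


def _conflict_probability(cls, Lx, Ly, Li, Lz, mu: float) -> np.ndarray:
    """P(conflicting tip pattern) per genealogy, exact in the mutations.

    Tip states are parities of Poisson counts along root-to-tip paths;
    enumerate the 2^4 branch-parity combinations.
    """
    q = lambda L: 0.5 * (1.0 - np.exp(-2.0 * mu * L))
    qx, qy, qi, qz = q(Lx), q(Ly), q(Li), q(Lz)
    p_conf = np.zeros_like(qx)
    for bx, by, bi, bz in _iterproduct((0, 1), repeat=4):
        prob = (
            (qx if bx else 1 - qx)
            * (qy if by else 1 - qy)
            * (qi if bi else 1 - qi)
            * (qz if bz else 1 - qz)
        )
        x = bx ^ bi
        y = by ^ bi
        z = bz
        # map cherry tips (x, y) and outer z onto species (a, b, c)
        for c_id, (a, b, c) in (
            (_WITHIN, (x, y, z)),
            (_DEEP_AB, (x, y, z)),
            (_DEEP_AC, (x, z, y)),
            (_DEEP_BC, (z, x, y)),
        ):
            if (a, b, c) in ((1, 0, 1), (0, 1, 1)):
                sel = cls == c_id
                if np.any(sel):
                    p_conf[sel] += prob[sel] if np.ndim(prob) else prob
    return p_conf


def _hrf_components(cls, Lx, Ly, Li, Lz, mu: float):
    """Per-replicate (hemiplastic prob, conflicting prob)."""
    p_conf = _conflict_probability(cls, Lx, Ly, Li, Lz, mu)
    Ltot = Lx + Ly + Li + Lz
    discordant = (cls == _DEEP_AC) | (cls == _DEEP_BC)
    p_hemi = np.where(discordant, mu * Li * np.exp(-mu * Ltot), 0.0)
    return p_hemi, p_conf


def _hrf_scatter(cls, Lx, Ly, Li, Lz, mu, rng):
    """Explicit Poisson mutation draws; integer hemiplasy/homoplasy counts."""
    nx = rng.poisson(mu * Lx)
    ny = rng.poisson(mu * Ly)
    ni = rng.poisson(mu * Li)
    nz = rng.poisson(mu * Lz)
    x = (nx + ni) % 2
    y = (ny + ni) % 2
    z = nz % 2
    a = np.where(cls == _DEEP_AC, x, np.where(cls == _DEEP_BC, z, x))
    b = np.where(cls == _DEEP_AC, z, np.where(cls == _DEEP_BC, x, y))
    c = np.where(cls == _DEEP_AC, y, np.where(cls == _DEEP_BC, y, z))
    conflict = ((a == 1) & (b == 0) & (c == 1)) | ((a == 0) & (b == 1) & (c == 1))
    total = nx + ny + ni + nz
    discordant = (cls == _DEEP_AC) | (cls == _DEEP_BC)
    hemi = conflict & (total == 1) & (ni == 1) & discordant
    homo = conflict & (total >= 2)
    return int(hemi.sum()), int(homo.sum())


def hrf_branch(
    species_tree: PhyloTree,
    branch: int,
    mu: float,
    n_replicates: int = 100_000,
    seed: int = 1,
    pendant_length: float = 1.0,
    method: str = "conditional",
) -> HRFEstimate:
    """Estimate the HRF of one internal branch at mutation rate ``mu``.

    ``branch`` is the child-node id of a non-terminal, non-root edge whose
    length is in coalescent units.  ``pendant_length`` sets the tip branch
    lengths of the surrogate triplet (summary-coalescent species trees carry
    no terminal lengths in coalescent units).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if species_tree.is_leaf(branch):
        raise ValueError("HRF is defined for internal branches only")
    if species_tree.parent[branch] < 0:
        raise ValueError("the root has no branch")
    lengths = species_tree._require_lengths()
    t = float(lengths[branch])
    if not np.isfinite(t):
        raise ValueError(f"branch {branch} has no length")
    rng = np.random.default_rng(seed)
    gene = _sample_genealogies(t, pendant_length, n_replicates, rng)
    if method == "conditional":
        p_hemi, p_conf = _hrf_components(*gene, mu)
        hemi = float(p_hemi.sum())
        conf = float(p_conf.sum())
        homo = conf - hemi
        if conf <= 0:
            return HRFEstimate(
                branch, mu, np.nan, n_replicates, hemi, homo, np.nan, False
            )
        hrf = hemi / conf
        # delta-method SE of the ratio-of-means estimator
        n = n_replicates
        hbar, cbar = hemi / n, conf / n
        var = (
            np.var(p_hemi)
            - 2 * hrf * np.cov(p_hemi, p_conf)[0, 1]
            + hrf**2 * np.var(p_conf)
        )
        se = float(np.sqrt(max(var, 0.0) / n) / cbar)
        return HRFEstimate(branch, mu, float(hrf), n_replicates, hemi, homo, se, True)
    elif method == "scatter":
        hemi, homo = _hrf_scatter(*gene, mu, rng)
        conf = hemi + homo
        if conf == 0:
            return HRFEstimate(
                branch, mu, np.nan, n_replicates, hemi, homo, np.nan, False
            )
        hrf = hemi / conf
        se = float(np.sqrt(hrf * (1 - hrf) / conf))
        return HRFEstimate(branch, mu, hrf, n_replicates, hemi, homo, se, True)
    raise ValueError(f"unknown method {method!r}")


def hrf_profile(
    species_tree: PhyloTree,
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID,
    n_replicates: int = 100_000,
    seed: int = 1,
    pendant_length: float = 1.0,
) -> pd.DataFrame:
    """HRF for every measured internal branch across a mutation-rate grid.

    For each branch one set of genealogies is sampled and reused across the
    grid, so the profile in ``mu`` is smooth at fixed seed.  Branches
    without lengths are skipped with a warning.
    """
    lengths = species_tree._require_lengths()
    rows = []
    rng = np.random.default_rng(seed)
    candidates = species_tree.internal_edges()
    measured = [b for b in candidates if np.isfinite(lengths[b])]
    for b in set(candidates) - set(measured):
        logger.warning("branch %d has no length; skipped", b)
    if not measured:
        raise TreeError("no internal branch with a length")
    for b in measured:
        branch_seed = int(rng.integers(2**31))
        brng = np.random.default_rng(branch_seed)
        gene = _sample_genealogies(
            float(lengths[b]), pendant_length, n_replicates, brng
        )
        for mu in mu_grid:
            p_hemi, p_conf = _hrf_components(*gene, mu)
            hemi = float(p_hemi.sum())
            conf = float(p_conf.sum())
            defined = conf > 0
            hrf = hemi / conf if defined else np.nan
            rows.append(
                dict(
                    branch=b,
                    branch_length=float(lengths[b]),
                    mu=mu,
                    hrf=hrf,
                    hemiplastic=hemi,
                    homoplastic=conf - hemi,
                    n_replicates=n_replicates,
                    defined=defined,
                )
            )
    return pd.DataFrame(rows)
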