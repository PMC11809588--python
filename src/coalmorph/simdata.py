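"""Synthetic data generation for every pipeline stage.

The generator emulates the structure of a transcriptome-derived phylogenomic
dataset: a species tree in coalescent units, multispecies-coalescent (MSC)
gene trees with optional introgression pulses, per-gene sequence alignments,
Mk-evolved morphological matrices, and highly skewed per-taxon occupancy.

Gene trees come from msprime: every species-tree branch is a population of
(haploid) size 1, so time is measured in coalescent units and a pair of
lineages entering a branch of length ``t`` fails to coalesce within it with
probability ``e^(-t)`` — the classic source of incomplete lineage sorting.
An introgression pulse is an instantaneous mass migration: at the pulse time
each lineage currently in the recipient population is reassigned to the
donor population with probability gamma (viewed backwards in time).

Sequences evolve under the symmetric k-state model (Jukes–Cantor for DNA,
the 20-state Poisson model for amino acids): on a branch of length ``l`` the
probability that a site's state changes is ``(k-1)/k * (1 - e^(-k*mu*l/(k-1)))``
with ``mu*l`` expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import msprime

from .tree import PhyloTree, TreeError
from .io_formats import (
    ALPHABETS,
    GAP,
    MultipleAlignment,
    MorphMatrix,
    CharacterDef,
    PartitionScheme,
    MISSING,
    build_supermatrix,
)

__all__ = [
    "IntrogressionPulse",
    "SimConfig",
    "SimulatedDataset",
    "simulate_species_tree",
    "simulate_msc_gene_trees",
    "simulate_alignment",
    "simulate_concatenated_loci",
    "simulate_morph_matrix",
    "inject_missingness",
    "simulate_dataset",
]


@dataclass(frozen=True)
class IntrogressionPulse:
    """A single instantaneous gene-flow event between two lineages.

    ``donor`` and ``recipient`` are taxon labels; the populations used are
    the species-tree branches containing those taxa at ``time`` (coalescent
    units before present).  ``proportion`` is the probability gamma with
    which a recipient lineage is reassigned to the donor population.
    """

    donor: str
    recipient: str
    time: float
    proportion: float

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("introgression proportion must be in [0, 1]")
        if self.time < 0:
            raise ValueError("pulse time must be non-negative")


@dataclass
class SimConfig:
    """Study-condition bundle for :func:`simulate_dataset`.

    Defaults mirror a transcriptome-scale study: tens of taxa, a few
    thousand genes of a few hundred aligned sites, and per-gene trees whose
    branch lengths are coalescent units scaled to substitutions by ``mu``.
    """

    seed: int = 1
    n_taxa: int = 40
    n_genes: int = 200
    sites_per_gene: int = 200
    mu: float = 0.05
    alphabet: str = "AA"
    pulses: tuple[IntrogressionPulse, ...] = ()
    occupancy_profile: dict[str, int] | None = None

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")


@dataclass
class SimulatedDataset:
    species_tree: PhyloTree
    gene_trees: list[PhyloTree]
    alignments: list[MultipleAlignment]


# ----------------------------------------------------------------------
# species trees
# ----------------------------------------------------------------------

def simulate_species_tree(
    n_taxa: int, seed: int, birth_rate: float = 1.0
) -> PhyloTree:
    """Rooted ultrametric Yule tree with branch lengths in coalescent units.

    The reconstructed-process construction is used: the period during which
    the tree has ``k`` lineages lasts ``Exp(k * birth_rate)``, so the
    expected root height is ``sum_{k=2..n} 1/(k*birth_rate)``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]  # depth at which each lineage starts
    depth_of = [0.0, np.nan, np.nan]
    active = [1, 2]
    now = 0.0
    for k in range(2, n_taxa + 1):
        now += rng.exponential(1.0 / (k * birth_rate))
        if k < n_taxa:
            split = active.pop(int(rng.integers(len(active))))
            depth_of[split] = now
            for _ in range(2):
                parent.append(split)
                birth.append(now)
                depth_of.append(np.nan)
                active.append(len(parent) - 1)
    lengths = np.zeros(len(parent))
    labels: list[str | None] = [None] * len(parent)
    leaf_no = 0
    for i in range(1, len(parent)):
        end = depth_of[i] if np.isfinite(depth_of[i]) else now
        lengths[i] = end - birth[i]
    for i in range(len(parent)):
        if i in active:
            leaf_no += 1
            labels[i] = f"T{leaf_no}"
    return PhyloTree(parent, lengths, labels, length_unit="coalescent_units")


# ----------------------------------------------------------------------
# MSC gene trees
# ----------------------------------------------------------------------

def _demography_for(
    species_tree: PhyloTree, pulses: Sequence[IntrogressionPulse]
) -> tuple[msprime.Demography, list[str]]:
    if species_tree.lengths is None:
        raise TreeError("species tree needs branch lengths in coalescent units")
    heights = species_tree.node_heights()
    depths = species_tree.depths()
    # ultrametricity check: all leaves at the same depth
    leaf_depths = depths[species_tree.leaves()]
    if np.ptp(leaf_depths) > 1e-6 * max(1.0, float(leaf_depths.max())):
        raise TreeError("species tree must be ultrametric for MSC simulation")
    names = [
        species_tree.labels[i] if species_tree.is_leaf(i) else f"anc{i}"
        for i in range(species_tree.n_nodes)
    ]
    dem = msprime.Demography()
    for name in names:
        dem.add_population(name=name, initial_size=1.0)
    internal = sorted(
        (i for i in range(species_tree.n_nodes) if not species_tree.is_leaf(i)),
        key=lambda i: heights[i],
    )
    for i in internal:
        dem.add_population_split(
            time=float(heights[i]),
            derived=[names[c] for c in species_tree.children()[i]],
            ancestral=names[i],
        )
    root_height = float(heights[species_tree.root])

    def population_at(taxon: str, time: float) -> str:
        # branch above `node` spans heights [h(node), h(parent)); climb until
        # that interval contains `time`
        node = species_tree.leaf_index(taxon)
        while (
            int(species_tree.parent[node]) >= 0
            and heights[int(species_tree.parent[node])] <= time
        ):
            node = int(species_tree.parent[node])
        return names[node]

    for pulse in pulses:
        if pulse.time >= root_height:
            raise ValueError(
                f"pulse time {pulse.time} is above the species-tree root "
                f"({root_height:g})"
            )
        src = population_at(pulse.recipient, pulse.time)
        dst = population_at(pulse.donor, pulse.time)
        if src == dst:
            raise ValueError(
                "pulse at time "
                f"{pulse.time}: donor and recipient are already the same "
                "population (time is above their common ancestor)"
            )
        dem.add_mass_migration(
            time=float(pulse.time), source=src, dest=dst,
            proportion=float(pulse.proportion),
        )
    dem.sort_events()
    leaf_labels = species_tree.leaf_labels()
    return dem, leaf_labels


def _msc_replicates(species_tree, n_genes, pulses, seed):
    dem, leaf_labels = _demography_for(species_tree, pulses)
    samples = [
        msprime.SampleSet(1, population=lab, ploidy=1) for lab in leaf_labels
    ]
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        num_replicates=n_genes,
        random_seed=(int(seed) % (2**31 - 1)) + 1,
    )
    return reps, leaf_labels


def simulate_msc_gene_trees(
    species_tree: PhyloTree,
    n_genes: int,
    pulses: Sequence[IntrogressionPulse] = (),
    seed: int = 1,
) -> list[PhyloTree]:
    """Simulate one labelled MSC gene tree per gene (one lineage/species)."""
    reps, leaf_labels = _msc_replicates(species_tree, n_genes, pulses, seed)
    out = []
    for ts in reps:
        out.append(PhyloTree.from_tskit(ts.first(), leaf_labels))
    return out


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------

def _p_change(mu_lengths: np.ndarray, k: int) -> np.ndarray:
    return (k - 1) / k * (1.0 - np.exp(-k * mu_lengths / (k - 1)))


def _evolve_states(
    parent: np.ndarray,
    mu_lengths: np.ndarray,
    order: np.ndarray,
    k: int,
    n_sites: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve i.i.d. sites down one tree; returns (n_nodes, n_sites) states."""
    n_nodes = parent.shape[0]
    states = np.empty((n_nodes, n_sites), dtype=np.int8)
    p = _p_change(mu_lengths, k)
    for node in order:
        par = parent[node]
        if par < 0:
            states[node] = rng.integers(0, k, size=n_sites, dtype=np.int8)
            continue
        s = states[par].copy()
        hit = rng.random(n_sites) < p[node]
        n_hit = int(hit.sum())
        if n_hit:
            s[hit] = (
                s[hit] + 1 + rng.integers(0, k - 1, size=n_hit, dtype=np.int8)
            ) % k
        states[node] = s
    return states


def simulate_alignment(
    gene_tree: PhyloTree,
    n_sites: int,
    mu: float,
    alphabet: str = "DNA",
    seed: int = 1,
    name: str | None = None,
) -> MultipleAlignment:
    """Evolve an i.i.d.-site alignment along a gene tree.

    Substitutions follow the symmetric k-state model with ``mu * length``
    expected substitutions per site on each branch.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    lengths = gene_tree._require_lengths()
    if not np.all(np.isfinite(lengths[gene_tree.parent >= 0])):
        raise TreeError("gene tree has missing branch lengths")
    k = len(ALPHABETS[alphabet])
    rng = np.random.default_rng(seed)
    states = _evolve_states(
        gene_tree.parent,
        mu * np.nan_to_num(lengths),
        gene_tree.preorder(),
        k,
        n_sites,
        rng,
    )
    symbols = np.frombuffer(ALPHABETS[alphabet].encode(), dtype=np.uint8)
    leaves = gene_tree.leaves()
    return MultipleAlignment(
        name or "sim_gene",
        [gene_tree.labels[i] for i in leaves],
        symbols[states[leaves]],
        alphabet=alphabet,
    )


def simulate_concatenated_loci(
    species_tree: PhyloTree,
    n_loci: int,
    sites_per_locus: int,
    mu: float,
    pulses: Sequence[IntrogressionPulse] = (),
    alphabet: str = "DNA",
    seed: int = 1,
) -> tuple[MultipleAlignment, PartitionScheme]:
    """MSC loci evolved and concatenated in one vectorised pass.

    Equivalent to simulating each gene tree, evolving an alignment on it and
    concatenating, but batched across loci (all loci share the sample count,
    so the tskit node tables stack into rectangular arrays).  This is the
    fast path used for D-statistic calibration, where ~10^5 loci are needed.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    reps, leaf_labels = _msc_replicates(species_tree, n_loci, pulses, seed)
    n = len(leaf_labels)
    n_nodes = 2 * n - 1
    parents = np.empty((n_loci, n_nodes), dtype=np.int64)
    blens = np.empty((n_loci, n_nodes))
    for g, ts in enumerate(reps):
        t = ts.first()
        pa = t.parent_array[:n_nodes]
        parents[g] = pa
        times = ts.nodes_time[:n_nodes]
        blens[g] = np.where(pa >= 0, times[np.clip(pa, 0, None)] - times, 0.0)
    # tskit assigns internal node ids in coalescence order, so ascending id
    # is a valid parents-after-children order; evolve root -> tips.
    k = len(ALPHABETS[alphabet])
    rng = np.random.default_rng(seed)
    p = _p_change(mu * blens, k)
    states = np.empty((n_nodes, n_loci, sites_per_locus), dtype=np.int8)
    states[n_nodes - 1] = rng.integers(
        0, k, size=(n_loci, sites_per_locus), dtype=np.int8
    )
    for node in range(n_nodes - 2, -1, -1):
        par_states = np.take_along_axis(
            states, parents[:, node][None, :, None], axis=0
        )[0]
        hit = rng.random((n_loci, sites_per_locus)) < p[:, node][:, None]
        s = par_states.copy()
        n_hit = int(hit.sum())
        if n_hit:
            s[hit] = (
                s[hit] + 1 + rng.integers(0, k - 1, size=n_hit, dtype=np.int8)
            ) % k
        states[node] = s
    symbols = np.frombuffer(ALPHABETS[alphabet].encode(), dtype=np.uint8)
    mat = symbols[states[:n].reshape(n, n_loci * sites_per_locus)]
    blocks = [
        (f"locus{g + 1}", g * sites_per_locus + 1, (g + 1) * sites_per_locus)
        for g in range(n_loci)
    ]
    aln = MultipleAlignment("msc_loci", leaf_labels, mat, alphabet=alphabet)
    return aln, PartitionScheme(blocks)


# ----------------------------------------------------------------------
# morphology
# ----------------------------------------------------------------------

def simulate_morph_matrix(
    tree: PhyloTree,
    n_chars: int,
    states_per_char: int = 2,
    rate_distribution: float | Sequence[float] = 1.0,
    seed: int = 1,
) -> tuple[MorphMatrix, np.ndarray]:
    """Evolve discrete characters under the symmetric Mk model.

    Each character gets a rate multiplier from ``rate_distribution`` (a
    scalar applied to all characters, or one value per character).  Returns
    the tip matrix and the full ``(n_nodes, n_chars)`` array of true states
    (indexed by tree node), so ancestral-state recovery can be scored.
    """
    if not 2 <= states_per_char <= 10:
        raise ValueError("states_per_char must be in 2..10")
    lengths = tree._require_lengths()
    rates = np.broadcast_to(
        np.asarray(rate_distribution, dtype=float), (n_chars,)
    )
    if np.any(rates < 0):
        raise ValueError("negative character rate")
    rng = np.random.default_rng(seed)
    k = states_per_char
    n_nodes = tree.n_nodes
    states = np.empty((n_nodes, n_chars), dtype=np.int8)
    bl = np.nan_to_num(lengths)
    for node in tree.preorder():
        par = tree.parent[node]
        if par < 0:
            states[node] = rng.integers(0, k, size=n_chars, dtype=np.int8)
            continue
        p = _p_change(rates * bl[node], k)
        s = states[par].copy()
        hit = rng.random(n_chars) < p
        n_hit = int(hit.sum())
        if n_hit:
            s[hit] = (
                s[hit] + 1 + rng.integers(0, k - 1, size=n_hit, dtype=np.int8)
            ) % k
        states[node] = s
    leaves = tree.leaves()
    chars = [
        CharacterDef(id=f"char{j + 1}", ordered=False, states=frozenset(range(k)))
        for j in range(n_chars)
    ]
    matrix = MorphMatrix(
        [tree.labels[i] for i in leaves], chars, states[leaves]
    )
    return matrix, states


# ----------------------------------------------------------------------
# occupancy
# ----------------------------------------------------------------------

def inject_missingness(
    data: Sequence[MultipleAlignment] | MorphMatrix,
    occupancy_profile: dict[str, int],
    seed: int = 1,
):
    """Thin taxa until each one's presence count matches the profile.

    For a list of gene alignments, each taxon is removed from randomly
    chosen genes until it is present in exactly ``occupancy_profile[taxon]``
    of them.  For a morphological matrix, scored cells are replaced by
    missing ``?`` until the taxon has the target number of scored cells.
    """
    rng = np.random.default_rng(seed)
    if isinstance(data, MorphMatrix):
        cells = data.cells.copy()
        for i, taxon in enumerate(data.taxa):
            if taxon not in occupancy_profile:
                continue
            target = int(occupancy_profile[taxon])
            scored = np.flatnonzero(cells[i] != MISSING)
            if target > len(scored):
                raise ValueError(
                    f"taxon {taxon!r}: target {target} exceeds its "
                    f"{len(scored)} scored cells"
                )
            drop = rng.choice(scored, size=len(scored) - target, replace=False)
            cells[i, drop] = MISSING
        return MorphMatrix(data.taxa, data.characters, cells)

    genes = list(data)
    n_genes = len(genes)
    keep_masks = [np.ones(len(g.taxa), dtype=bool) for g in genes]
    for taxon, target in occupancy_profile.items():
        present = [gi for gi, g in enumerate(genes) if taxon in g]
        if int(target) > len(present):
            raise ValueError(
                f"taxon {taxon!r}: target {target} exceeds the {len(present)} "
                "genes containing it"
            )
        drop = rng.choice(
            len(present), size=len(present) - int(target), replace=False
        )
        for d in drop:
            gi = present[int(d)]
            keep_masks[gi][genes[gi].taxa.index(taxon)] = False
    out = []
    for g, mask in zip(genes, keep_masks):
        if mask.all():
            out.append(g)
        else:
            kept = [t for t, m in zip(g.taxa, mask) if m]
            out.append(g.subset(kept, name=g.name))
    return out


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Species tree -> MSC gene trees -> alignments -> occupancy thinning."""
    rng = np.random.default_rng(config.seed)
    species_tree = simulate_species_tree(config.n_taxa, seed=int(rng.integers(2**31)))
    gene_trees = simulate_msc_gene_trees(
        species_tree, config.n_genes, config.pulses,
        seed=int(rng.integers(2**31)),
    )
    alignments = [
        simulate_alignment(
            gt,
            config.sites_per_gene,
            config.mu,
            alphabet=config.alphabet,
            seed=int(rng.integers(2**31)),
            name=f"OG{g + 1:05d}",
        )
        for g, gt in enumerate(gene_trees)
    ]
    if config.occupancy_profile:
        alignments = inject_missingness(
            alignments, config.occupancy_profile, seed=int(rng.integers(2**31))
        )
    return SimulatedDataset(species_tree, gene_trees, alignments)
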