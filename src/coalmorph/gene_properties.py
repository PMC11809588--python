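"""Per-orthogroup filtering properties and gene ranking.

Five properties drive matrix filtering in transcriptome-scale phylogenomics:
occupancy (fraction of study taxa present), total gene-tree length (a proxy
for substitution rate), saturation (erosion of the linear relation between
observed and patristic distances), compositional heterogeneity (RCFV), and
mean patristic distance (an indicator of long-branch attraction potential).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MultipleAlignment
from .tree import PhyloTree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "GenePropertyRecord",
    "occupancy",
    "tree_length",
    "saturation",
    "rcfv",
    "mean_patristic",
    "proportion_variable_sites",
    "rank_and_subset",
    "compute_gene_properties",
    "RANK_DIRECTIONS",
]


@dataclass
class GenePropertyRecord:
    gene: str
    occupancy: float
    tree_length: float
    saturation: float
    rcfv: float
    mean_patristic: float


def occupancy(alignment: MultipleAlignment, full_taxon_set: Sequence[str]) -> float:
    """Fraction of the full taxon set present in the alignment."""
    full = set(full_taxon_set)
    if not full:
        raise ValueError("empty full taxon set")
    present = set(alignment.taxa)
    extra = present - full
    if extra:
        raise ValueError(f"alignment taxa outside the full set: {sorted(extra)}")
    return len(present) / len(full)


def tree_length(gene_tree: PhyloTree) -> float:
    """Sum of all branch lengths (substitutions/site summed over edges)."""
    return gene_tree.total_length()


def _p_distance_matrix(alignment: MultipleAlignment) -> np.ndarray:
    """Pairwise uncorrected p-distances; columns with gap/unknown in either
    sequence are ignored.  nan where no comparable columns exist."""
    codes = alignment.codes()
    n = alignment.n_taxa
    valid = codes >= 0
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                continue
            diff = int((codes[i][both] != codes[j][both]).sum())
            out[i, j] = out[j, i] = diff / m
    return out


def saturation(alignment: MultipleAlignment, gene_tree: PhyloTree) -> float:
    """``1 - b`` where ``b`` is the through-origin least-squares slope of
    pairwise p-distances on pairwise patristic distances.

    Unsaturated genes have observed distances tracking patristic distances
    (slope near 1, saturation near 0); saturated genes plateau (slope well
    below 1, saturation approaching 1).
    """
    labels, pat = gene_tree.patristic_matrix()
    shared = [t for t in alignment.taxa if t in labels]
    if len(shared) < 3:
        raise ValueError("need at least 3 taxa shared between alignment and tree")
    skipped = (alignment.n_taxa - len(shared)) + (len(labels) - len(shared))
    if skipped:
        logger.info("saturation: %d unshared taxa skipped", skipped)
    pdist = _p_distance_matrix(alignment)
    ai = [alignment.taxa.index(t) for t in shared]
    ti = [labels.index(t) for t in shared]
    xs, ys = [], []
    for a in range(len(shared)):
        for b in range(a + 1, len(shared)):
            x = pat[ti[a], ti[b]]
            y = pdist[ai[a], ai[b]]
            if np.isfinite(x) and np.isfinite(y):
                xs.append(x)
                ys.append(y)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    sxx = float(np.sum(xs * xs))
    if sxx == 0:
        raise ValueError("all patristic distances are zero")
    slope = float(np.sum(xs * ys)) / sxx
    return 1.0 - slope


def rcfv(alignment: MultipleAlignment) -> float:
    """Relative Composition Frequency Variability.

    Mean absolute deviation of per-taxon state frequencies from the grand
    mean frequency, summed over states and averaged over taxa; computed on
    scored residues only (gaps/unknowns excluded).
    """
    if alignment.n_taxa < 2:
        raise ValueError("RCFV needs at least 2 taxa")
    codes = alignment.codes()
    k = alignment.k
    freqs = np.empty((alignment.n_taxa, k))
    for i in range(alignment.n_taxa):
        scored = codes[i][codes[i] >= 0]
        if scored.size == 0:
            raise ValueError(
                f"taxon {alignment.taxa[i]!r} has no scored residues"
            )
        freqs[i] = np.bincount(scored, minlength=k) / scored.size
    mean = freqs.mean(axis=0)
    return float(np.abs(freqs - mean).sum() / alignment.n_taxa)


def mean_patristic(gene_tree: PhyloTree) -> float:
    """Mean path-length distance over all unordered leaf pairs."""
    labels, pat = gene_tree.patristic_matrix()
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    iu = np.triu_indices(n, k=1)
    return float(pat[iu].mean())


def proportion_variable_sites(supermatrix: MultipleAlignment) -> float:
    """Fraction of columns showing >= 2 distinct scored states."""
    codes = supermatrix.codes()
    if codes.size == 0:
        raise ValueError("empty matrix")
    masked = np.where(codes >= 0, codes, -1)
    col_max = masked.max(axis=0)
    # smallest scored state per column (ignore negatives)
    big = np.where(codes >= 0, codes, np.iinfo(np.int16).max).astype(np.int16)
    col_min = big.min(axis=0)
    variable = (col_max >= 0) & (col_min < np.iinfo(np.int16).max) & (col_max != col_min)
    return float(variable.sum() / codes.shape[1])


RANK_DIRECTIONS = {
    "occupancy": "high",
    "tree_length": "low",
    "saturation": "low",
    "rcfv": "low",
    "mean_patristic": "low",
}


def rank_and_subset(
    records: Iterable[GenePropertyRecord],
    property: str,
    K: int,
    direction: str | None = None,
) -> list[str]:
    """The ``K`` best gene ids by one property (deterministic tie-break).

    High occupancy is best; low rate/saturation/RCFV/patristic is best.
    Ties are broken by gene id, lexicographically.
    """
    if property not in RANK_DIRECTIONS:
        raise ValueError(f"unknown property {property!r}")
    direction = direction or RANK_DIRECTIONS[property]
    records = list(records)
    if K > len(records):
        raise ValueError(f"K={K} exceeds the {len(records)} records")
    sign = -1.0 if direction == "high" else 1.0
    ordered = sorted(records, key=lambda r: (sign * getattr(r, property), r.gene))
    return [r.gene for r in ordered[:K]]


def compute_gene_properties(
    alignments: Sequence[MultipleAlignment],
    gene_trees: Mapping[str, PhyloTree],
    full_taxon_set: Sequence[str],
) -> pd.DataFrame:
    """All five properties per gene, as a DataFrame indexed by gene id.

    Tree-based properties are nan for genes without a tree.
    """
    rows = []
    for aln in alignments:
        tree = gene_trees.get(aln.name)
        tl = sat = mp = np.nan
        if tree is not None:
            tl = tree_length(tree)
            mp = mean_patristic(tree)
            try:
                sat = saturation(aln, tree)
            except ValueError:
                sat = np.nan
        rows.append(
            dict(
                gene=aln.name,
                occupancy=occupancy(aln, full_taxon_set),
                tree_length=tl,
                saturation=sat,
                rcfv=rcfv(aln),
                mean_patristic=mp,
            )
        )
    return pd.DataFrame(rows).set_index("gene")
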