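"""Patterson's D (ABBA–BABA) and the five-taxon D_FOIL statistics.

Both tests compare counts of biallelic site patterns that are equally
probable under incomplete lineage sorting alone, so a significant asymmetry
indicates introgression.  Patterson's D works on a four-taxon asymmetric
topology ``(((P1,P2),P3),O)``: with the outgroup state taken as ancestral
(``A``) and the alternative as derived (``B``), ``D = (ABBA - BABA) /
(ABBA + BABA)`` with a z-score from a delete-one block jackknife over
contiguous alignment columns.

D_FOIL generalises to the symmetric five-taxon topology
``((P1,P2),(P3,P4),O)`` (the ``(P1,P2)`` split being the younger) and forms
four statistics from the 16 biallelic patterns; the signature of their
signs identifies donor and recipient:

* ``DFO``: does P1 match P3 or P4 more often, over sites where P3 != P4?
* ``DIL``: the same for P2;
* ``DFI``: does P3 match P1 or P2 more often, over sites where P1 != P2?
* ``DOL``: the same for P4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .io_formats import MultipleAlignment, build_supermatrix, FormatError

__all__ = [
    "QuartetSpec",
    "QuintetSpec",
    "SitePatternCounts",
    "DStatResult",
    "DfoilResult",
    "enumerate_combination_matrices",
    "count_quartet_patterns",
    "patterson_d",
    "dfoil",
    "DFOIL_PATTERN_SETS",
    "DFOIL_SIGNATURES",
]


@dataclass(frozen=True)
class QuartetSpec:
    """Four taxa with assumed topology (((P1,P2),P3),O)."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self):
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise ValueError("quartet taxa must be distinct")

    @property
    def taxa(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)


@dataclass(frozen=True)
class QuintetSpec:
    """Five taxa with assumed symmetric topology ((P1,P2),(P3,P4),O).

    The (P1,P2) split is assumed younger than the (P3,P4) split.
    """

    p1: str
    p2: str
    p3: str
    p4: str
    outgroup: str

    def __post_init__(self):
        if len({self.p1, self.p2, self.p3, self.p4, self.outgroup}) != 5:
            raise ValueError("quintet taxa must be distinct")

    @property
    def taxa(self) -> tuple[str, ...]:
        return (self.p1, self.p2, self.p3, self.p4, self.outgroup)


@dataclass
class SitePatternCounts:
    n_abba: int = 0
    n_baba: int = 0
    n_informative: int = 0
    n_sites_scanned: int = 0
    pattern_counts: dict[str, int] | None = None  # quintets: 'ABBA' etc. -> n


@dataclass
class DStatResult:
    d: float
    z: float
    se: float
    n_blocks: int
    counts: SitePatternCounts
    significant: bool
    z_threshold: float = 3.0


@dataclass
class DfoilResult:
    stats: dict[str, float]  # DFO, DIL, DFI, DOL
    p_values: dict[str, float]
    signature: tuple[str, str, str, str]  # '+', '-', '0' per statistic
    introgression_class: str
    counts: SitePatternCounts
    sufficient_data: bool = True


# ----------------------------------------------------------------------
# combination matrices
# ----------------------------------------------------------------------

def _empty_like(taxa: Sequence[str], alphabet: str) -> MultipleAlignment:
    mat = np.empty((len(taxa), 0), dtype=np.uint8)
    return MultipleAlignment("combination", taxa, mat, alphabet)


def enumerate_combination_matrices(
    genes: Sequence[MultipleAlignment],
    groups: Sequence[Sequence[str]],
    outgroup: str,
) -> list[tuple[QuartetSpec, MultipleAlignment]]:
    """One concatenated four-taxon matrix per cross-group species triple.

    ``groups`` is three disjoint taxon lists (P1, P2 and P3 candidates).
    For every combination, only genes containing all four taxa survive, and
    only those four rows are kept.
    """
    if len(groups) != 3:
        raise ValueError("exactly three groups are required")
    if any(not g for g in groups):
        raise ValueError("empty group")
    sets = [set(g) for g in groups]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError("groups must be disjoint")
        if outgroup in sets[i]:
            raise ValueError("outgroup must not belong to any group")
    out = []
    for a, b, c in product(*groups):
        spec = QuartetSpec(a, b, c, outgroup)
        selected = [
            g.subset(list(spec.taxa), name=g.name)
            for g in genes
            if all(t in g for t in spec.taxa)
        ]
        if selected:
            matrix, _ = build_supermatrix(selected, full_taxon_set=list(spec.taxa))
        else:
            matrix = _empty_like(list(spec.taxa), genes[0].alphabet)
        out.append((spec, matrix))
    return out


# ----------------------------------------------------------------------
# quartet patterns / Patterson's D
# ----------------------------------------------------------------------

def _rows_for(matrix: MultipleAlignment, taxa: Sequence[str]) -> np.ndarray:
    missing = [t for t in taxa if t not in matrix.taxa]
    if missing:
        raise ValueError(f"taxa absent from matrix: {missing}")
    idx = [matrix.taxa.index(t) for t in taxa]
    return matrix.codes()[idx]


def _quartet_site_classes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean site masks (informative, abba, baba) for 4 x L codes."""
    valid = (codes >= 0).all(axis=0)
    p1, p2, p3, o = codes
    # biallelic: exactly two distinct states among the four rows
    mx = codes.max(axis=0)
    mn = codes.min(axis=0)
    two = mx != mn
    mid = ((codes != mx[None, :]) & (codes != mn[None, :])).any(axis=0)
    informative = valid & two & ~mid
    abba = informative & (p1 == o) & (p2 == p3) & (p2 != o)
    baba = informative & (p2 == o) & (p1 == p3) & (p1 != o)
    return informative, abba, baba


def count_quartet_patterns(
    matrix: MultipleAlignment, spec: QuartetSpec
) -> SitePatternCounts:
    """ABBA/BABA tallies over fully scored biallelic columns."""
    codes = _rows_for(matrix, spec.taxa)
    informative, abba, baba = _quartet_site_classes(codes)
    return SitePatternCounts(
        n_abba=int(abba.sum()),
        n_baba=int(baba.sum()),
        n_informative=int(informative.sum()),
        n_sites_scanned=codes.shape[1],
    )


def patterson_d(
    matrix: MultipleAlignment,
    spec: QuartetSpec,
    block_size: int = 1000,
    z_threshold: float = 3.0,
) -> DStatResult:
    """Patterson's D with a delete-one block-jackknife z-score.

    Columns are cut into contiguous blocks of ``block_size`` (the trailing
    remainder is merged into the last block); the SE is the standard
    delete-one jackknife estimate over blocks.
    """
    codes = _rows_for(matrix, spec.taxa)
    L = codes.shape[1]
    informative, abba, baba = _quartet_site_classes(codes)
    n_abba, n_baba = int(abba.sum()), int(baba.sum())
    counts = SitePatternCounts(
        n_abba=n_abba,
        n_baba=n_baba,
        n_informative=int(informative.sum()),
        n_sites_scanned=L,
    )
    if n_abba + n_baba == 0:
        raise ValueError("no ABBA/BABA-informative sites")
    d = (n_abba - n_baba) / (n_abba + n_baba)
    n_blocks = L // block_size
    if n_blocks < 2:
        raise ValueError(
            "need at least two jackknife blocks; reduce block_size or add sites"
        )
    starts = np.arange(n_blocks) * block_size  # last block absorbs remainder
    abba_b = np.add.reduceat(abba.astype(np.int64), starts)
    baba_b = np.add.reduceat(baba.astype(np.int64), starts)
    rem_a = n_abba - abba_b
    rem_b = n_baba - baba_b
    denom = rem_a + rem_b
    d_i = np.where(denom > 0, (rem_a - rem_b) / np.where(denom > 0, denom, 1), d)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((d_i - d_i.mean()) ** 2)))
    z = d / se if se > 0 else np.inf * np.sign(d) if d != 0 else 0.0
    return DStatResult(
        d=float(d),
        z=float(z),
        se=se,
        n_blocks=int(n_blocks),
        counts=counts,
        significant=bool(abs(z) >= z_threshold),
        z_threshold=z_threshold,
    )


# ----------------------------------------------------------------------
# D_FOIL
# ----------------------------------------------------------------------

# Left/right site-pattern sets of the four statistics.  A pattern string
# gives the states of (P1, P2, P3, P4) with the outgroup ancestral ('A');
# e.g. 'ABBA' = P2 and P3 carry the derived state.
DFOIL_PATTERN_SETS: dict[str, tuple[frozenset, frozenset]] = {
    "DFO": (
        frozenset({"BABA", "BBBA", "ABAB", "AAAB"}),
        frozenset({"BAAB", "BBAB", "ABBA", "AABA"}),
    ),
    "DIL": (
        frozenset({"ABBA", "BBBA", "BAAB", "AAAB"}),
        frozenset({"ABAB", "BBAB", "BABA", "AABA"}),
    ),
    "DFI": (
        frozenset({"BABA", "BABB", "ABAB", "ABAA"}),
        frozenset({"ABBA", "ABBB", "BAAB", "BAAA"}),
    ),
    "DOL": (
        frozenset({"BAAB", "BABB", "ABBA", "ABAA"}),
        frozenset({"BABA", "BAAA", "ABAB", "ABBB"}),
    ),
}

# Sign signature (DFO, DIL, DFI, DOL) -> introgression class.  DFO and DIL
# respond whenever the first pair (or its ancestor) exchanges with the outer
# pair; DFI/DOL polarise which taxa are involved; ancestral exchange leaves
# DFI and DOL at zero.
DFOIL_SIGNATURES: dict[tuple[str, str, str, str], str] = {
    ("0", "0", "0", "0"): "none",
    ("+", "+", "+", "0"): "P1=>P3",
    ("+", "0", "+", "+"): "P3=>P1",
    ("+", "+", "-", "0"): "P2=>P3",
    ("0", "+", "-", "-"): "P3=>P2",
    ("-", "-", "0", "+"): "P1=>P4",
    ("-", "0", "+", "+"): "P4=>P1",
    ("-", "-", "0", "-"): "P2=>P4",
    ("0", "-", "-", "-"): "P4=>P2",
    ("+", "+", "0", "0"): "P1P2-ancestor<=>P3",
    ("-", "-", "0", "0"): "P1P2-ancestor<=>P4",
}


def _quintet_pattern_counts(codes: np.ndarray) -> dict[str, int]:
    """Counts of the 16 derived/ancestral patterns for 5 x L codes."""
    valid = (codes >= 0).all(axis=0)
    mx = codes.max(axis=0)
    mn = codes.min(axis=0)
    two = mx != mn
    mid = ((codes != mx[None, :]) & (codes != mn[None, :])).any(axis=0)
    informative = valid & two & ~mid
    o = codes[4]
    derived = (codes[:4] != o[None, :]) & informative[None, :]
    idx = (
        derived[0].astype(np.int64) * 8
        + derived[1] * 4
        + derived[2] * 2
        + derived[3]
    )
    idx = idx[informative]
    tally = np.bincount(idx, minlength=16)
    out = {}
    for i in range(16):
        pat = "".join("B" if i & (8 >> b) else "A" for b in range(4))
        out[pat] = int(tally[i])
    return out


def dfoil(
    matrix: MultipleAlignment,
    spec: QuintetSpec,
    min_informative: int = 100,
    alpha: float = 0.01,
) -> DfoilResult:
    """The four D_FOIL statistics with binomial significance per statistic.

    Each statistic is (left - right) / (left + right) over its two pattern
    sets; its sign is called significant when a two-sided binomial test of
    left vs right counts rejects symmetry at ``alpha``.  The sign signature
    is mapped to a donor/recipient class; insufficiently informative
    matrices yield a result flagged ``sufficient_data=False``.
    """
    codes = _rows_for(matrix, spec.taxa)
    pattern_counts = _quintet_pattern_counts(codes)
    n_informative = sum(
        n for pat, n in pattern_counts.items() if pat != "AAAA"
    )
    counts = SitePatternCounts(
        n_informative=n_informative,
        n_sites_scanned=codes.shape[1],
        pattern_counts=pattern_counts,
    )
    stats: dict[str, float] = {}
    p_values: dict[str, float] = {}
    signature: list[str] = []
    for name, (left_set, right_set) in DFOIL_PATTERN_SETS.items():
        left = sum(pattern_counts[p] for p in left_set)
        right = sum(pattern_counts[p] for p in right_set)
        total = left + right
        stat = (left - right) / total if total else 0.0
        pval = binomtest(left, total, 0.5).pvalue if total else 1.0
        stats[name] = stat
        p_values[name] = pval
        if pval < alpha and stat > 0:
            signature.append("+")
        elif pval < alpha and stat < 0:
            signature.append("-")
        else:
            signature.append("0")
    sig = tuple(signature)
    if n_informative < min_informative:
        return DfoilResult(
            stats=stats,
            p_values=p_values,
            signature=sig,
            introgression_class="insufficient data",
            counts=counts,
            sufficient_data=False,
        )
    cls = DFOIL_SIGNATURES.get(sig, "unresolved")
    return DfoilResult(
        stats=stats,
        p_values=p_values,
        signature=sig,
        introgression_class=cls,
        counts=counts,
    )
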