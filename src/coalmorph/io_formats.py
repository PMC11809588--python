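"""Readers/writers for the formats the pipeline consumes.

Alignments (FASTA, relaxed PHYLIP), trees (Newick, via :mod:`dendropy`),
discrete morphological matrices (NEXUS ``DATA``/``CHARACTERS`` blocks with an
optional ``ASSUMPTIONS`` ``TYPESET`` marking ordered characters), RAxML-style
partition files, and TSV taxon→group maps.  Also builds concatenated
supermatrices with partition definitions.

Conventions
-----------
* taxon ids are normalised at read time: internal whitespace becomes ``_``;
* residues outside the declared alphabet (other than gap/unknown) are
  remapped to the unknown symbol with a logged warning, since
  transcriptome-derived protein data routinely contain ambiguity codes;
* morphological cells distinguish missing ``?`` from inapplicable ``-``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import dendropy
from Bio import SeqIO, AlignIO

from .tree import PhyloTree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "MultipleAlignment",
    "MorphMatrix",
    "CharacterDef",
    "PartitionScheme",
    "MISSING",
    "INAPPLICABLE",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "read_morph_nexus",
    "write_morph_nexus",
    "build_supermatrix",
    "read_group_map",
    "write_group_map",
]


class FormatError(ValueError):
    """Raised for malformed input files or invalid containers."""


ALPHABETS = {"AA": "ACDEFGHIKLMNPQRSTVWY", "DNA": "ACGT"}
UNKNOWN = {"AA": "X", "DNA": "N"}
GAP = "-"

# residue -> small int codes used throughout: 0..k-1 states, -1 gap, -2 unknown
GAP_CODE = -1
UNKNOWN_CODE = -2


def _code_table(alphabet: str) -> np.ndarray:
    """256-entry lookup: byte -> state code; unexpected bytes -> -3."""
    tab = np.full(256, -3, dtype=np.int8)
    for i, ch in enumerate(ALPHABETS[alphabet]):
        tab[ord(ch)] = i
        tab[ord(ch.lower())] = i
    tab[ord(GAP)] = GAP_CODE
    tab[ord(UNKNOWN[alphabet])] = UNKNOWN_CODE
    tab[ord(UNKNOWN[alphabet].lower())] = UNKNOWN_CODE
    tab[ord("?")] = UNKNOWN_CODE
    return tab


_CODE_TABLES = {a: _code_table(a) for a in ALPHABETS}


class MultipleAlignment:
    """Taxon-labelled aligned residue rows over a declared alphabet.

    Rows are stored as an ``(n_taxa, length)`` byte matrix; ``codes()``
    exposes the integer view (states ``0..k-1``, gap ``-1``, unknown ``-2``)
    that the numerical modules work on.
    """

    def __init__(
        self,
        name: str,
        taxa: Sequence[str],
        rows: Sequence[str] | np.ndarray,
        alphabet: str = "AA",
    ):
        if alphabet not in ALPHABETS:
            raise FormatError(f"unknown alphabet {alphabet!r}")
        self.name = name
        self.alphabet = alphabet
        self.taxa = [t.strip().replace(" ", "_") for t in taxa]
        if len(set(self.taxa)) != len(self.taxa):
            dup = next(t for t in self.taxa if self.taxa.count(t) > 1)
            raise FormatError(f"duplicate taxon id {dup!r} in alignment {name!r}")
        if isinstance(rows, np.ndarray):
            mat = rows.astype(np.uint8, copy=True)
        else:
            lens = {len(r) for r in rows}
            if len(rows) != len(self.taxa):
                raise FormatError("row count does not match taxon count")
            if len(lens) > 1:
                raise FormatError(
                    f"ragged alignment {name!r}: row lengths {sorted(lens)}"
                )
            joined = "".join(r.upper() for r in rows).encode("ascii")
            mat = np.frombuffer(joined, dtype=np.uint8).reshape(
                len(self.taxa), -1 if rows else 0
            ).copy()
        if mat.ndim != 2 or mat.shape[0] != len(self.taxa):
            raise FormatError("row matrix shape does not match taxa")
        codes = _CODE_TABLES[alphabet][mat]
        bad = codes == -3
        if bad.any():
            n_bad = int(bad.sum())
            offending = {chr(b) for b in np.unique(mat[bad])}
            logger.warning(
                "alignment %s: %d residues outside the %s alphabet (%s) "
                "remapped to %s",
                name, n_bad, alphabet, "".join(sorted(offending)),
                UNKNOWN[alphabet],
            )
            mat = mat.copy()
            mat[bad] = ord(UNKNOWN[alphabet])
            codes = codes.copy()
            codes[bad] = UNKNOWN_CODE
        self._matrix = mat
        self._codes = codes

    # -- basic views ----------------------------------------------------
    @property
    def length(self) -> int:
        return self._matrix.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def k(self) -> int:
        return len(ALPHABETS[self.alphabet])

    def row(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return self._matrix[i].tobytes().decode("ascii")

    @property
    def rows(self) -> list[str]:
        return [self._matrix[i].tobytes().decode("ascii") for i in range(self.n_taxa)]

    def matrix(self) -> np.ndarray:
        """Byte matrix view (do not mutate)."""
        return self._matrix

    def codes(self) -> np.ndarray:
        """Integer codes: ``0..k-1`` states, ``-1`` gap, ``-2`` unknown."""
        return self._codes

    def subset(self, taxa: Sequence[str], name: str | None = None) -> "MultipleAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return MultipleAlignment(
            name or self.name, list(taxa), self._matrix[idx], self.alphabet
        )

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.taxa

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MultipleAlignment)
            and self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and np.array_equal(self._matrix, other._matrix)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MultipleAlignment({self.name!r}, {self.n_taxa} taxa x "
            f"{self.length} {self.alphabet} columns)"
        )


# ----------------------------------------------------------------------
# alignment I/O
# ----------------------------------------------------------------------

def read_alignment(path: str | Path, alphabet: str = "AA") -> MultipleAlignment:
    """Read a FASTA or relaxed-PHYLIP alignment (sniffed from content)."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1024)
    first = head.lstrip()[:1]
    name = path.stem
    if first == ">":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise FormatError(f"{path}: empty FASTA")
        ids = [r.id for r in records]
        rows = [str(r.seq) for r in records]
    else:
        try:
            aln = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as e:
            raise FormatError(f"{path}: cannot parse as FASTA or PHYLIP: {e}") from e
        ids = [r.id for r in aln]
        rows = [str(r.seq) for r in aln]
    return MultipleAlignment(name, ids, rows, alphabet=alphabet)


def write_alignment(
    aln: MultipleAlignment, path: str | Path, schema: str = "fasta"
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if schema == "fasta":
            for t, r in zip(aln.taxa, aln.rows):
                fh.write(f">{t}\n{r}\n")
        elif schema == "phylip":
            fh.write(f" {aln.n_taxa} {aln.length}\n")
            for t, r in zip(aln.taxa, aln.rows):
                fh.write(f"{t}  {r}\n")
        else:
            raise FormatError(f"unknown alignment schema {schema!r}")


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def read_tree(path: str | Path, length_unit: str = "none") -> PhyloTree:
    """Read a Newick tree; branch lengths are optional but must be >= 0."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as e:  # dendropy raises several error types
        raise FormatError(f"{path}: Newick parse error: {e}") from e
    try:
        return PhyloTree.from_dendropy(dtree, length_unit=length_unit)
    except TreeError as e:
        raise FormatError(f"{path}: {e}") from e


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


# ----------------------------------------------------------------------
# morphology (NEXUS)
# ----------------------------------------------------------------------

MISSING = -1
INAPPLICABLE = -2


@dataclass
class CharacterDef:
    """One discrete character: id, ordered flag, state set, weight."""

    id: str
    ordered: bool = False
    states: frozenset = frozenset()
    weight: float = 1.0


class MorphMatrix:
    """Taxa x discrete characters with missing (``?``) and inapplicable (``-``).

    Cells hold the integer state (``0..9``), :data:`MISSING` or
    :data:`INAPPLICABLE`.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[CharacterDef],
        cells: np.ndarray,
    ):
        self.taxa = [t.strip().replace(" ", "_") for t in taxa]
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon id in morphological matrix")
        self.characters = list(characters)
        cells = np.asarray(cells, dtype=np.int8)
        if cells.shape != (len(self.taxa), len(self.characters)):
            raise FormatError(
                f"cell matrix shape {cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        self.cells = cells
        for j, ch in enumerate(self.characters):
            observed = {int(s) for s in cells[:, j] if s >= 0}
            if not ch.states:
                self.characters[j] = CharacterDef(
                    ch.id, ch.ordered, frozenset(observed), ch.weight
                )
            elif not observed <= set(ch.states):
                raise FormatError(
                    f"character {ch.id!r}: scored state outside its state set"
                )
            if not np.isfinite(ch.weight) or ch.weight < 0:
                raise FormatError(f"character {ch.id!r}: invalid weight")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, j: int) -> np.ndarray:
        return self.cells[:, j]

    def row(self, taxon: str) -> np.ndarray:
        return self.cells[self.taxa.index(taxon)]

    def subset_taxa(self, taxa: Sequence[str]) -> "MorphMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return MorphMatrix(list(taxa), self.characters, self.cells[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MorphMatrix)
            and self.taxa == other.taxa
            and np.array_equal(self.cells, other.cells)
            and [(c.id, c.ordered) for c in self.characters]
            == [(c.id, c.ordered) for c in other.characters]
            and np.allclose(
                [c.weight for c in self.characters],
                [c.weight for c in other.characters],
            )
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"MorphMatrix({self.n_taxa} taxa x {self.n_characters} characters)"


_TYPESET_RE = re.compile(
    r"TYPESET[^=;]*=\s*([^;]*);", re.IGNORECASE | re.DOTALL
)
_WTSET_RE = re.compile(r"WTSET[^=;]*=\s*([^;]*);", re.IGNORECASE | re.DOTALL)


def _parse_index_list(spec: str, n: int) -> list[int]:
    """Parse NEXUS 1-based character index lists like ``1-3 5 7-8``."""
    out: list[int] = []
    for tok in spec.replace(",", " ").split():
        if "-" in tok:
            a, b = tok.split("-", 1)
            out.extend(range(int(a) - 1, int(b)))
        else:
            out.append(int(tok) - 1)
    bad = [i for i in out if i < 0 or i >= n]
    if bad:
        raise FormatError(f"character index {bad[0] + 1} out of range 1..{n}")
    return out


def read_morph_nexus(path: str | Path) -> MorphMatrix:
    """Read a NEXUS standard-data matrix.

    ``?`` is stored as missing, ``-`` (the NEXUS gap) as inapplicable.
    Ordered characters are taken from an ``ASSUMPTIONS`` ``TYPESET`` with
    ``ord``/``unord`` groups (default: unordered); weights from a ``WTSET``.
    """
    path = Path(path)
    text = path.read_text()
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as e:
        raise FormatError(f"{path}: NEXUS parse error: {e}") from e
    taxa = [t.label for t in dm.taxon_namespace]
    ncols = max(len(dm[t]) for t in dm.taxon_namespace)
    cells = np.full((len(taxa), ncols), MISSING, dtype=np.int8)
    for i, t in enumerate(dm.taxon_namespace):
        for j, cell in enumerate(dm[t]):
            sym = str(cell)
            if sym == "?":
                cells[i, j] = MISSING
            elif sym == "-":
                cells[i, j] = INAPPLICABLE
            else:
                if not sym.isdigit():
                    raise FormatError(
                        f"{path}: unexpected state symbol {sym!r} "
                        f"(taxon {taxa[i]!r}, character {j + 1})"
                    )
                cells[i, j] = int(sym)
    ordered = np.zeros(ncols, dtype=bool)
    m = _TYPESET_RE.search(text)
    if m:
        for group in m.group(1).split(","):
            if ":" not in group:
                continue
            kind, idxs = group.split(":", 1)
            if kind.strip().lower() in ("ord", "ordered"):
                for j in _parse_index_list(idxs, ncols):
                    ordered[j] = True
    weights = np.ones(ncols)
    m = _WTSET_RE.search(text)
    if m:
        for group in m.group(1).split(","):
            if ":" not in group:
                continue
            w, idxs = group.split(":", 1)
            for j in _parse_index_list(idxs, ncols):
                weights[j] = float(w)
    chars = [
        CharacterDef(id=f"char{j + 1}", ordered=bool(ordered[j]), weight=float(weights[j]))
        for j in range(ncols)
    ]
    return MorphMatrix(taxa, chars, cells)


def write_morph_nexus(matrix: MorphMatrix, path: str | Path) -> None:
    symbols = sorted(
        {str(int(s)) for s in np.unique(matrix.cells) if s >= 0}
    ) or ["0", "1"]
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f"FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(symbols)}\" MISSING=? GAP=-;",
        "MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, t in enumerate(matrix.taxa):
        row = "".join(
            "?" if c == MISSING else "-" if c == INAPPLICABLE else str(int(c))
            for c in matrix.cells[i]
        )
        lines.append(f"{t:<{width}}{row}")
    lines += [";", "END;"]
    ordered = [j + 1 for j, c in enumerate(matrix.characters) if c.ordered]
    unordered = [j + 1 for j, c in enumerate(matrix.characters) if not c.ordered]
    assumption_lines = []
    if ordered:
        parts = []
        if ordered:
            parts.append("ord: " + " ".join(map(str, ordered)))
        if unordered:
            parts.append("unord: " + " ".join(map(str, unordered)))
        assumption_lines.append("TYPESET * default = " + ", ".join(parts) + ";")
    wts = [c.weight for c in matrix.characters]
    if any(w != 1.0 for w in wts):
        groups: dict[float, list[int]] = {}
        for j, w in enumerate(wts):
            groups.setdefault(w, []).append(j + 1)
        spec = ", ".join(
            f"{w:g}: " + " ".join(map(str, idxs)) for w, idxs in groups.items()
        )
        assumption_lines.append(f"WTSET * default = {spec};")
    if assumption_lines:
        lines += ["BEGIN ASSUMPTIONS;", *assumption_lines, "END;"]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# supermatrix
# ----------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """Named 1-based inclusive column blocks of a supermatrix."""

    blocks: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self, total_length: int | None = None) -> None:
        covered: list[tuple[int, int]] = []
        for name, start, end in self.blocks:
            if start < 1 or end < start:
                raise FormatError(f"partition {name!r}: bad range {start}-{end}")
            covered.append((start, end))
        covered.sort()
        for (a0, a1), (b0, b1) in zip(covered, covered[1:]):
            if b0 <= a1:
                raise FormatError("partition ranges overlap")
        if total_length is not None:
            span = sum(e - s + 1 for s, e in covered)
            if span != total_length or (covered and covered[-1][1] != total_length):
                raise FormatError("partition ranges do not cover the matrix")

    def write_raxml(self, path: str | Path, model: str = "LG") -> None:
        with open(path, "w") as fh:
            for name, start, end in self.blocks:
                fh.write(f"{model}, {name} = {start}-{end}\n")


def build_supermatrix(
    alignments: Sequence[MultipleAlignment],
    full_taxon_set: Sequence[str] | None = None,
) -> tuple[MultipleAlignment, PartitionScheme]:
    """Concatenate gene alignments, gap-filling absent taxa per block.

    Returns the supermatrix (taxon order = ``full_taxon_set`` order, or first
    occurrence across genes) and the 1-based inclusive partition scheme in
    input gene order.
    """
    if not alignments:
        raise FormatError("no alignments to concatenate")
    names = [a.name for a in alignments]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise FormatError(f"duplicate gene name {dup!r}")
    alphabet = alignments[0].alphabet
    if any(a.alphabet != alphabet for a in alignments):
        raise FormatError("alignments mix alphabets")
    if full_taxon_set is None:
        taxa: list[str] = []
        for a in alignments:
            for t in a.taxa:
                if t not in taxa:
                    taxa.append(t)
    else:
        taxa = [t.strip().replace(" ", "_") for t in full_taxon_set]
        for a in alignments:
            extra = set(a.taxa) - set(taxa)
            if extra:
                raise FormatError(
                    f"gene {a.name!r} contains taxa outside the full set: "
                    f"{sorted(extra)}"
                )
    total = sum(a.length for a in alignments)
    out = np.full((len(taxa), total), ord(GAP), dtype=np.uint8)
    blocks = []
    pos = 0
    tindex = {t: i for i, t in enumerate(taxa)}
    for a in alignments:
        idx = [tindex[t] for t in a.taxa]
        out[idx, pos : pos + a.length] = a.matrix()
        blocks.append((a.name, pos + 1, pos + a.length))
        pos += a.length
    scheme = PartitionScheme(blocks)
    scheme.validate(total_length=total)
    return MultipleAlignment("supermatrix", taxa, out, alphabet), scheme


# ----------------------------------------------------------------------
# taxon group maps
# ----------------------------------------------------------------------

def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``taxon<TAB>group``; each taxon mapped once."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 'taxon<TAB>group'")
            taxon = parts[0].strip().replace(" ", "_")
            if taxon in out:
                raise FormatError(f"{path}:{ln}: taxon {taxon!r} mapped twice")
            out[taxon] = parts[1].strip()
    return out


def write_group_map(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, group in mapping.items():
            fh.write(f"{taxon}\t{group}\n")
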