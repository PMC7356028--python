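"""Alignment I/O, validation, species matching, concatenation and encoding.

Alignments are aligned-FASTA files whose headers carry a species token.
Two alignments for an interacting protein pair are matched on that token,
intersected, and concatenated column-wise (protein A columns first) so that
downstream co-evolution statistics can relate columns of A to columns of B.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: The 20 standard residues in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical gap symbol; '.' is normalized to this on input.
GAP = "-"

#: Number of encoded symbols (gap + 20 residues).
N_SYMBOLS = 21

#: Fixed numeric code table: gap -> 0, residues -> 1..20 alphabetically.
CODE_TABLE: dict[str, int] = {GAP: 0, **{aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}}

#: Inverse of :data:`CODE_TABLE`.
LETTER_TABLE: dict[int, str] = {v: k for k, v in CODE_TABLE.items()}

#: Default regex extracting a species token from a FASTA header: the first
#: whitespace/underscore-free token after an optional accession prefix, e.g.
#: ``>sp|P12345|NAME_HUMAN`` -> ``HUMAN``; plain ``>homo_sapiens`` is kept whole.
DEFAULT_SPECIES_REGEX = r"(?:_|\|)?([^|\s_]+)\s*$"


class AlignmentFormatError(ValueError):
    """Raised for ragged rows, illegal characters or malformed FASTA."""


@dataclass(frozen=True)
class Alignment:
    """A validated multiple sequence alignment.

    Parameters
    ----------
    rows
        ``(species_id, sequence)`` pairs. Sequences are uppercase over the
        20 standard residues plus the gap symbol and share one width.
    name
        Free-text label used in error messages.
    """

    rows: tuple[tuple[str, str], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError(f"alignment {self.name!r} has no rows")
        width = len(self.rows[0][1])
        seen: set[str] = set()
        allowed = set(AMINO_ACIDS) | {GAP}
        for species, seq in self.rows:
            if len(seq) != width:
                raise AlignmentFormatError(
                    f"alignment {self.name!r}: row {species!r} has length "
                    f"{len(seq)}, expected {width} (ragged alignment)"
                )
            bad = set(seq) - allowed
            if bad:
                raise AlignmentFormatError(
                    f"alignment {self.name!r}: row {species!r} contains "
                    f"illegal character(s) {sorted(bad)}"
                )
            if species in seen:
                raise AlignmentFormatError(
                    f"alignment {self.name!r}: duplicate species id {species!r}"
                )
            seen.add(species)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.rows)

    def row(self, species_id: str) -> str:
        for s, seq in self.rows:
            if s == species_id:
                return seq
        raise KeyError(species_id)


@dataclass(frozen=True)
class ConcatenatedAlignment:
    """Species-matched column concatenation of two alignments (A then B)."""

    rows: tuple[tuple[str, str], ...]
    lenA: int
    lenB: int
    name: str = ""

    def __post_init__(self) -> None:
        width = self.lenA + self.lenB
        for species, seq in self.rows:
            if len(seq) != width:
                raise AlignmentFormatError(
                    f"concatenated alignment {self.name!r}: row {species!r} "
                    f"has width {len(seq)}, expected {width}"
                )

    @property
    def boundary(self) -> int:
        """Index of the first protein-B column (equals ``lenA``)."""
        return self.lenA

    @property
    def width(self) -> int:
        return self.lenA + self.lenB

    def as_alignment(self) -> Alignment:
        return Alignment(rows=self.rows, name=self.name)


@dataclass(frozen=True)
class EncodedAlignment:
    """Integer-coded alignment: gap -> 0, residues -> 1..20 alphabetically."""

    matrix: np.ndarray
    code_table: dict[str, int] = field(default_factory=lambda: dict(CODE_TABLE))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("encoded alignment must be 2-D")
        if m.size and (m.min() < 0 or m.max() >= N_SYMBOLS):
            raise ValueError("codes must lie in 0..20")
        object.__setattr__(self, "matrix", m.astype(np.int8))

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def _parse_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks)))
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise AlignmentFormatError("sequence data before first FASTA header")
            chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def read_alignment(
    path: str | Path,
    name: str | None = None,
    species_regex: str | None = None,
) -> Alignment:
    """Read an aligned FASTA file into a validated :class:`Alignment`.

    Gap characters ``-`` and ``.`` are normalized to ``-`` and letters are
    uppercased. When ``species_regex`` is given, each header is reduced to
    the first capture group of the regex; otherwise the full header is the
    species id.
    """
    path = Path(path)
    records = _parse_fasta(path.read_text())
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    rows = []
    for header, seq in records:
        species = header
        if species_regex is not None:
            m = re.search(species_regex, header)
            if not m:
                raise AlignmentFormatError(
                    f"{path}: header {header!r} does not match species regex"
                )
            species = m.group(1)
        rows.append((species, seq.upper().replace(".", GAP)))
    # keep-first policy for duplicate species ids
    deduped: dict[str, str] = {}
    for species, seq in rows:
        if species in deduped:
            warnings.warn(
                f"{path}: duplicate species {species!r}; keeping first occurrence",
                stacklevel=2,
            )
            continue
        deduped[species] = seq
    return Alignment(rows=tuple(deduped.items()), name=name or path.stem)


def write_alignment(aln: Alignment | ConcatenatedAlignment, path: str | Path) -> None:
    """Write rows as aligned FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for species, seq in aln.rows:
            fh.write(f">{species}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def pairwise_identity(reference: str, other: str) -> float:
    """Fraction of non-gap reference columns where the two rows agree."""
    cols = [(r, o) for r, o in zip(reference, other) if r != GAP]
    if not cols:
        return 0.0
    return sum(r == o for r, o in cols) / len(cols)


def filter_low_identity(
    aln: Alignment, reference_row: int = 0, min_identity: float = 0.25
) -> Alignment:
    """Drop rows with pairwise identity to the reference below ``min_identity``.

    Identity is counted over non-gap reference columns only. The reference
    row itself is always retained and the input row order is preserved.
    """
    if not 0 <= reference_row < aln.n_rows:
        raise IndexError(f"reference_row {reference_row} out of range")
    ref_seq = aln.rows[reference_row][1]
    kept = []
    for idx, (species, seq) in enumerate(aln.rows):
        if idx == reference_row or pairwise_identity(ref_seq, seq) >= min_identity:
            kept.append((species, seq))
    if len(kept) == 1:
        warnings.warn(
            f"alignment {aln.name!r}: no rows besides the reference pass "
            f"min_identity={min_identity}",
            stacklevel=2,
        )
    return Alignment(rows=tuple(kept), name=aln.name)


def concatenate_by_species(
    alnA: Alignment, alnB: Alignment, name: str = ""
) -> ConcatenatedAlignment:
    """Concatenate two alignments row-wise on their shared species.

    Only species present in both alignments are kept; each output row is
    the A-row followed by the B-row for that species. Row order follows
    ``alnA``.
    """
    speciesB = {s: seq for s, seq in alnB.rows}
    rows = tuple(
        (s, seqA + speciesB[s]) for s, seqA in alnA.rows if s in speciesB
    )
    if not rows:
        raise ValueError(
            f"no shared species between {alnA.name!r} and {alnB.name!r}"
        )
    return ConcatenatedAlignment(
        rows=rows, lenA=alnA.width, lenB=alnB.width, name=name or f"{alnA.name}+{alnB.name}"
    )


def encode(aln: Alignment | ConcatenatedAlignment) -> EncodedAlignment:
    """Encode letters to integer codes (gap 0, residues 1..20)."""
    rows = aln.rows
    mat = np.empty((len(rows), len(rows[0][1])), dtype=np.int8)
    for i, (_, seq) in enumerate(rows):
        mat[i] = [CODE_TABLE[c] for c in seq]
    return EncodedAlignment(matrix=mat)


def decode(enc: EncodedAlignment, species: Sequence[str] | None = None) -> Alignment:
    """Invert :func:`encode`; synthesizes ``seq{i}`` ids when none given."""
    n = enc.n_sequences
    ids: Iterable[str] = species if species is not None else (f"seq{i}" for i in range(n))
    rows = tuple(
        (sid, "".join(LETTER_TABLE[int(c)] for c in row))
        for sid, row in zip(ids, enc.matrix)
    )
    return Alignment(rows=rows)
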