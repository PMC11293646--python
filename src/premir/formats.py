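"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions used throughout the package:

* genomic intervals are BED-style 0-based half-open (:class:`Interval`);
* positions on a folded sequence are 1-based inclusive, the native CT
  convention (:class:`SecondaryStructure.pairs`).

DNA and RNA are compared with T and U equal; folded structures always
store U.  Ambiguity codes other than N are rejected.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FormatError",
    "StructureError",
    "SeqRecord",
    "Interval",
    "SecondaryStructure",
    "read_fasta",
    "write_fasta",
    "parse_ct",
    "write_ct",
    "dot_bracket",
    "from_dot_bracket",
    "write_bed6",
    "reverse_complement",
    "to_rna",
    "to_dna",
]

_VALID_CHARS = set("ACGUTN")
MIN_LOOP = 3  # minimum hairpin loop size: partners must satisfy j - i >= 4


class FormatError(ValueError):
    """Malformed input text (FASTA/CT/dot-bracket/BED)."""


class StructureError(ValueError):
    """A pair table violating the secondary-structure invariants."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over the alphabet {A,C,G,U,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"empty sequence under record {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise FormatError(
                f"record {self.id!r}: unsupported characters {sorted(bad)}; "
                "only A,C,G,U,T,N are accepted"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """BED-style 0-based half-open genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def _check_pairs(seq: str, pairs: np.ndarray) -> None:
    L = len(seq)
    if len(pairs) != L:
        raise StructureError(f"pair table length {len(pairs)} != sequence length {L}")
    for i1 in range(1, L + 1):
        j1 = int(pairs[i1 - 1])
        if j1 == 0:
            continue
        if not (1 <= j1 <= L):
            raise StructureError(f"position {i1} pairs with out-of-range {j1}")
        if j1 == i1:
            raise StructureError(f"position {i1} pairs with itself")
        if int(pairs[j1 - 1]) != i1:
            raise StructureError(
                f"asymmetric pair: {i1}->{j1} but {j1}->{int(pairs[j1 - 1])}"
            )
        if abs(j1 - i1) < MIN_LOOP + 1:
            raise StructureError(
                f"pair ({i1},{j1}) closes a loop shorter than {MIN_LOOP} nt"
            )
    # nestedness (pseudoknot-free)
    stack: list[int] = []
    for i1 in range(1, L + 1):
        j1 = int(pairs[i1 - 1])
        if j1 > i1:
            stack.append(j1)
        elif 0 < j1 < i1:
            if not stack or stack[-1] != i1:
                raise StructureError("pair table contains a pseudoknot")
            stack.pop()


@dataclass
class SecondaryStructure:
    """An RNA sequence with its 1-based base-pair table and free energy.

    ``pairs[i-1]`` is the 1-based partner of position ``i`` (0 when
    unpaired).  The table must be symmetric, self-pair free, honour the
    minimum hairpin loop of 3 nt, and be pseudoknot-free.
    """

    seq: str
    pairs: np.ndarray
    energy: float | None = None

    def __post_init__(self):
        self.seq = to_rna(self.seq)
        bad = set(self.seq) - {"A", "C", "G", "U", "N"}
        if bad:
            raise StructureError(f"non-RNA characters in structure: {sorted(bad)}")
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        _check_pairs(self.seq, self.pairs)

    def __len__(self) -> int:
        return len(self.seq)

    def partner(self, i1: int) -> int:
        """1-based partner of 1-based position ``i1`` (0 when unpaired)."""
        return int(self.pairs[i1 - 1])

    @property
    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.pairs)) // 2

    def paired_positions(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, 1-based, in 5' order."""
        return [
            (i + 1, int(j))
            for i, j in enumerate(self.pairs)
            if j > i + 1
        ]

    def substructure(self, start1: int, end1: int) -> "SecondaryStructure":
        """Restrict to 1-based inclusive span; pairs leaving the span open up."""
        sub = self.pairs[start1 - 1 : end1].copy()
        for k in range(len(sub)):
            j = int(sub[k])
            if j and not (start1 <= j <= end1):
                sub[k] = 0
            elif j:
                sub[k] = j - start1 + 1
        return SecondaryStructure(self.seq[start1 - 1 : end1], sub)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(text: str) -> list[SeqRecord]:
    """Parse (multi-)FASTA text into records.

    Multi-line sequences are concatenated; sequences are upper-cased.
    Raises :class:`FormatError` on a missing header or an empty record.
    """
    stripped = text.lstrip()
    if not stripped:
        raise FormatError("empty FASTA input")
    if not stripped.startswith(">"):
        raise FormatError("FASTA input does not start with a '>' header")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise FormatError("no records in FASTA input")
    for rec in records:
        if not rec.seq:
            raise FormatError(f"empty sequence under header {rec.id!r}")
    return records


def write_fasta(records: list[SeqRecord], width: int = 70) -> str:
    out = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        out.append(header)
        for i in range(0, len(rec.seq), width):
            out.append(rec.seq[i : i + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# CT

_CT_ENERGY_RE = re.compile(r"(?:dG|ENERGY)\s*=\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE)


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a 6-column CT file into a :class:`SecondaryStructure`.

    The header line carries the length and, optionally, the energy as
    ``dG = x`` or ``ENERGY = x``.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT input")
    header = lines[0].split()
    try:
        length = int(header[0])
    except (ValueError, IndexError):
        raise FormatError(f"CT header does not start with a length: {lines[0]!r}")
    m = _CT_ENERGY_RE.search(lines[0])
    energy = float(m.group(1)) if m else None
    body = lines[1:]
    if len(body) != length:
        raise FormatError(f"CT header claims {length} rows, found {len(body)}")
    seq_chars = []
    pairs = np.zeros(length, dtype=np.int64)
    for row in body:
        cols = row.split()
        if len(cols) < 6:
            raise FormatError(f"CT row with fewer than 6 columns: {row!r}")
        i1 = int(cols[0])
        if not (1 <= i1 <= length):
            raise FormatError(f"CT row index {i1} out of range")
        seq_chars.append(cols[1])
        pairs[i1 - 1] = int(cols[4])
    seq = "".join(seq_chars)
    try:
        return SecondaryStructure(seq=seq, pairs=pairs, energy=energy)
    except StructureError:
        raise
    except ValueError as exc:  # pragma: no cover - defensive
        raise FormatError(str(exc)) from exc


def write_ct(structure: SecondaryStructure, name: str = "structure") -> str:
    L = len(structure)
    head = f"{L}"
    if structure.energy is not None:
        head += f" dG = {structure.energy:.2f}"
    head += f" {name}"
    rows = [head]
    for i1 in range(1, L + 1):
        rows.append(
            f"{i1} {structure.seq[i1 - 1]} {i1 - 1} "
            f"{i1 + 1 if i1 < L else 0} {structure.partner(i1)} {i1}"
        )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# dot-bracket


def dot_bracket(structure: SecondaryStructure) -> str:
    """Nested pairs to dot-bracket: '(' at the 5' partner, ')' at the 3'."""
    chars = []
    for i1 in range(1, len(structure) + 1):
        j1 = structure.partner(i1)
        chars.append("." if j1 == 0 else ("(" if j1 > i1 else ")"))
    return "".join(chars)


def from_dot_bracket(
    seq: str, db: str, energy: float | None = None
) -> SecondaryStructure:
    if len(seq) != len(db):
        raise FormatError("sequence and dot-bracket lengths differ")
    pairs = np.zeros(len(db), dtype=np.int64)
    stack: list[int] = []
    for i1, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(i1)
        elif ch == ")":
            if not stack:
                raise FormatError("unbalanced ')' in dot-bracket")
            j1 = stack.pop()
            pairs[j1 - 1] = i1
            pairs[i1 - 1] = j1
        elif ch != ".":
            raise FormatError(f"unsupported dot-bracket character {ch!r}")
    if stack:
        raise FormatError("unbalanced '(' in dot-bracket")
    return SecondaryStructure(seq=seq, pairs=pairs, energy=energy)


# ---------------------------------------------------------------------------
# BED


def write_bed6(intervals: list[tuple[Interval, str, float]]) -> str:
    """BED6 lines from (interval, name, score) triples."""
    lines = []
    for iv, name, score in intervals:
        lines.append(
            f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# alphabet helpers


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving the input alphabet (DNA in, DNA out)."""
    is_rna = "U" in seq.upper() and "T" not in seq.upper()
    s = Seq(to_dna(seq))
    rc = str(s.reverse_complement())
    return to_rna(rc) if is_rna else rc
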