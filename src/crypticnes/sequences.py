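"""Protein sequences, point mutations, and FASTA I/O.

Sequences carry a ``numbering_offset`` so that a peptide excised from a
larger protein keeps the parent's residue numbering (e.g. the SOD1
fragment spanning residues 33-51 is stored with offset 33, and position
42 of the fragment is the same Leu42 that mutant nomenclature refers
to).  All reported positions are 1-based, inclusive, in that "mature"
numbering.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Hydrophobic residues eligible as NES anchor (Phi) positions.
HYDROPHOBIC_ANCHORS = frozenset("LIVFM")

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationFormatError(ValueError):
    """Raised when a mutation code does not parse as <wt><pos><mut>."""


class MutationMismatchError(ValueError):
    """Raised when the sequence residue disagrees with a mutation's wild type.

    This guards against numbering-convention mistakes (mature vs. precursor
    numbering differ by one residue for proteins whose initiator Met is
    cleaved).
    """


@dataclass(frozen=True)
class PointMutation:
    """A single amino-acid substitution in mature numbering, e.g. L42Q."""

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in STANDARD_AA or self.mut_aa not in STANDARD_AA:
            raise MutationFormatError(
                f"non-standard residue in mutation {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise MutationFormatError(
                f"mutation {self.wt_aa}{self.position}{self.mut_aa} is silent"
            )
        if self.position < 1:
            raise MutationFormatError(f"position must be >= 1, got {self.position}")

    @property
    def code(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def inverse(self) -> "PointMutation":
        return PointMutation(self.mut_aa, self.position, self.wt_aa)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with an explicit numbering offset.

    Parameters
    ----------
    id : str
        Sequence identifier.
    residues : str
        One-letter codes, upper-cased on ingest; only the 20 standard
        residues are accepted.
    numbering_offset : int
        Mature-numbering position of the first residue (>= 1).
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue code(s) {sorted(bad)} in {self.id!r}")
        if self.numbering_offset < 1:
            raise ValueError(f"numbering_offset must be >= 1, got {self.numbering_offset}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        return self.numbering_offset

    @property
    def end(self) -> int:
        """Mature-numbering position of the last residue (inclusive)."""
        return self.numbering_offset + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """Residue at a mature-numbering position."""
        if not self.start <= position <= self.end:
            raise IndexError(
                f"position {position} outside {self.id!r} span {self.start}-{self.end}"
            )
        return self.residues[position - self.numbering_offset]

    def subsequence(self, start: int, end: int) -> str:
        """Residues spanning [start, end] inclusive, mature numbering."""
        if start > end:
            raise ValueError(f"span start {start} > end {end}")
        if start < self.start or end > self.end:
            raise IndexError(
                f"span {start}-{end} outside {self.id!r} span {self.start}-{self.end}"
            )
        i = start - self.numbering_offset
        return self.residues[i : i + (end - start + 1)]


def parse_mutation_code(code: str) -> PointMutation:
    """Parse a mutant name like ``"L42Q"`` into a :class:`PointMutation`."""
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise MutationFormatError(f"malformed mutation code {code!r}")
    wt, pos, mut = m.groups()
    return PointMutation(wt.upper(), int(pos), mut.upper())


def parse_mutation_list(codes: str) -> list[PointMutation]:
    """Parse a comma-separated list of mutation codes ("L42Q,G85R")."""
    return [parse_mutation_code(c) for c in codes.split(",") if c.strip()]


def apply_mutations(
    seq: ProteinSequence, mutations: Iterable[PointMutation]
) -> ProteinSequence:
    """Return a copy of *seq* with the given substitutions applied.

    Each mutation's wild-type residue is checked against the sequence;
    a mismatch raises :class:`MutationMismatchError` rather than silently
    mutating the wrong site.
    """
    residues = list(seq.residues)
    for mut in mutations:
        if not seq.start <= mut.position <= seq.end:
            raise IndexError(
                f"mutation {mut.code} outside {seq.id!r} span {seq.start}-{seq.end}"
            )
        idx = mut.position - seq.numbering_offset
        if residues[idx] != mut.wt_aa:
            raise MutationMismatchError(
                f"{mut.code}: residue {mut.position} of {seq.id!r} is "
                f"{residues[idx]}, not {mut.wt_aa}"
            )
        residues[idx] = mut.mut_aa
    return ProteinSequence(seq.id, "".join(residues), seq.numbering_offset)


def hydrophobic_positions(
    seq: ProteinSequence,
    span: tuple[int, int] | None = None,
    alphabet: frozenset[str] | set[str] = HYDROPHOBIC_ANCHORS,
) -> list[int]:
    """Mature-numbering positions within *span* whose residue is in *alphabet*."""
    if span is None:
        span = (seq.start, seq.end)
    start, end = span
    if start < seq.start or end > seq.end:
        raise IndexError(f"span {start}-{end} outside {seq.id!r} span {seq.start}-{seq.end}")
    return [p for p in range(start, end + 1) if seq.residue_at(p) in alphabet]


# ---------------------------------------------------------------------------
# FASTA I/O.  The description line may carry the numbering offset as a
# whitespace-separated "offset=<n>" key (default 1).

_OFFSET_RE = re.compile(r"\boffset=(\d+)\b")


def _record_to_sequence(rec: SeqRecord) -> ProteinSequence:
    m = _OFFSET_RE.search(rec.description or "")
    offset = int(m.group(1)) if m else 1
    return ProteinSequence(rec.id, str(rec.seq), offset)


def read_fasta(source) -> list[ProteinSequence]:
    """Read one or more records from a FASTA path or text handle."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return [_record_to_sequence(rec) for rec in SeqIO.parse(source, "fasta")]


def write_fasta(seqs: Iterable[ProteinSequence], handle) -> None:
    """Write records, carrying each sequence's offset on the description line."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"offset={s.numbering_offset}")
        for s in seqs
    ]
    SeqIO.write(records, handle, "fasta")


def read_alignment(source) -> dict[str, str]:
    """Read an aligned FASTA (gap character '-') as an id -> row mapping."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(source, "fasta"):
        rows[rec.id] = str(rec.seq).upper()
    lengths = {len(v) for v in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
    return rows
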