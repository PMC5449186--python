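"""NES consensus classes, exhaustive motif scanning, and region merging.

A nuclear export signal (NES) class is an anchor/spacer pattern: a set of
hydrophobic anchor residues (Phi) separated by runs of arbitrary residues
(X) whose lengths are constrained per inter-anchor gap.  The default
class is the PKI spacing Phi0-X2-Phi1-X3-Phi2-X(2-3)-Phi3-X-Phi4; a
looser "relaxed" class with uniform X(1-3) spacers is provided for
candidate discovery, where the precise spacing of a functional signal is
not known in advance.

Scanning is exhaustive over start positions and over every admissible
choice of each variable gap, so distinct anchor placements on the same
span are all reported; overlapping placements are merged into regions
for region-level reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .sequences import HYDROPHOBIC_ANCHORS, ProteinSequence


class AlignmentError(ValueError):
    """Raised when an anchor cannot be mapped to an alignment column."""


@dataclass(frozen=True)
class NESConsensusClass:
    """An anchor/spacer NES pattern.

    ``gaps[k]`` is the inclusive (min, max) number of X residues allowed
    between anchor k and anchor k+1, so a class with ``n`` anchors has
    ``n - 1`` gap ranges.
    """

    name: str
    anchor_alphabet: frozenset[str] = HYDROPHOBIC_ANCHORS
    gaps: tuple[tuple[int, int], ...] = ((2, 2), (3, 3), (2, 3), (1, 1))

    def __post_init__(self) -> None:
        if len(self.gaps) < 1:
            raise ValueError("a consensus class needs at least two anchors")
        for lo, hi in self.gaps:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid gap range ({lo}, {hi})")
        if not self.anchor_alphabet:
            raise ValueError("anchor alphabet is empty")
        object.__setattr__(self, "anchor_alphabet", frozenset(self.anchor_alphabet))

    @property
    def n_anchors(self) -> int:
        return len(self.gaps) + 1

    @property
    def min_span(self) -> int:
        """Shortest possible match length, anchors included."""
        return self.n_anchors + sum(lo for lo, _ in self.gaps)

    @property
    def max_span(self) -> int:
        return self.n_anchors + sum(hi for _, hi in self.gaps)


#: PKI-class spacing: Phi0-X2-Phi1-X3-Phi2-X(2-3)-Phi3-X-Phi4.
PKI_CLASS = NESConsensusClass("pki")

#: Uniform X(1-3) spacers between five anchors; used for candidate
#: discovery where the functional spacing is unknown.
RELAXED_CLASS = NESConsensusClass("relaxed", gaps=((1, 3), (1, 3), (1, 3), (1, 3)))

CONSENSUS_CLASSES: dict[str, NESConsensusClass] = {
    PKI_CLASS.name: PKI_CLASS,
    RELAXED_CLASS.name: RELAXED_CLASS,
}


@dataclass(frozen=True)
class NESMatch:
    """One concrete placement of a consensus class on a sequence.

    Anchors are mature-numbering positions of the Phi residues, in order;
    the span runs from the first to the last anchor, inclusive.
    """

    sequence_id: str
    class_name: str
    anchors: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.anchors[0], self.anchors[-1])

    def matched_subsequence(self, seq: ProteinSequence) -> str:
        return seq.subsequence(*self.span)


@dataclass(frozen=True)
class NESRegion:
    """A maximal run of transitively overlapping matches."""

    span: tuple[int, int]
    member_matches: tuple[NESMatch, ...]


@dataclass(frozen=True)
class AnchorConservation:
    """Per-anchor cross-species conservation at one alignment column."""

    anchor_index: int
    position: int
    column_residues: Mapping[str, str]
    conserved: bool


def scan_nes(seq: ProteinSequence, cls: NESConsensusClass = PKI_CLASS) -> list[NESMatch]:
    """Enumerate every placement of *cls* on *seq*.

    All start positions and all admissible choices of each variable gap
    are tried, so the output is the complete set of placements whose
    anchors lie in the class alphabet and whose gaps are within range.
    Matches are sorted by span start, then by anchor tuple, and the
    result is deterministic.
    """
    residues = seq.residues
    n = len(residues)
    alphabet = cls.anchor_alphabet
    gaps = cls.gaps
    matches: list[NESMatch] = []

    def extend(placed: list[int]) -> None:
        k = len(placed) - 1  # index of the gap after the last placed anchor
        if k == len(gaps):
            matches.append(
                NESMatch(
                    seq.id,
                    cls.name,
                    tuple(p + seq.numbering_offset for p in placed),
                )
            )
            return
        lo, hi = gaps[k]
        last = placed[-1]
        for g in range(lo, hi + 1):
            nxt = last + g + 1
            if nxt >= n:
                break
            if residues[nxt] in alphabet:
                placed.append(nxt)
                extend(placed)
                placed.pop()

    for i in range(n):
        if residues[i] in alphabet:
            extend([i])
    matches.sort(key=lambda m: (m.span[0], m.anchors))
    return matches


def merge_matches(matches: Sequence[NESMatch]) -> list[NESRegion]:
    """Merge matches into pairwise non-overlapping regions.

    Regions are the transitive closure of span overlap: two matches whose
    spans intersect belong to one region, and the region span runs from
    the minimum member start to the maximum member end.
    """
    if not matches:
        return []
    ordered = sorted(matches, key=lambda m: (m.span[0], m.anchors))
    regions: list[NESRegion] = []
    members: list[NESMatch] = [ordered[0]]
    start, end = ordered[0].span
    for m in ordered[1:]:
        s, e = m.span
        if s <= end:  # inclusive spans: touching at the same residue overlaps
            members.append(m)
            end = max(end, e)
        else:
            regions.append(NESRegion((start, end), tuple(members)))
            members = [m]
            start, end = s, e
    regions.append(NESRegion((start, end), tuple(members)))
    return regions


def anchor_conservation(
    alignment: Mapping[str, str],
    match: NESMatch,
    reference_id: str,
    alphabet: frozenset[str] | set[str] = HYDROPHOBIC_ANCHORS,
    reference_offset: int = 1,
    gap_char: str = "-",
) -> list[AnchorConservation]:
    """Evaluate conservation of each anchor column across orthologs.

    The reference (e.g. human) row maps each anchor's mature-numbering
    position to an alignment column; the anchor is conserved iff every
    ortholog residue in that column is in the anchor alphabet.  Gap
    characters in orthologs count as non-conserving.
    """
    if reference_id not in alignment:
        raise AlignmentError(f"reference {reference_id!r} not in alignment")
    ref_row = alignment[reference_id]
    # column index for each reference ungapped position
    col_of_pos: dict[int, int] = {}
    pos = reference_offset - 1
    for col, ch in enumerate(ref_row):
        if ch != gap_char:
            pos += 1
            col_of_pos[pos] = col

    records: list[AnchorConservation] = []
    for k, anchor_pos in enumerate(match.anchors):
        col = col_of_pos.get(anchor_pos)
        if col is None:
            raise AlignmentError(
                f"anchor position {anchor_pos} not mappable through {reference_id!r}"
            )
        column = {oid: row[col] for oid, row in alignment.items()}
        if all(ch == gap_char for ch in column.values()):
            raise AlignmentError(f"anchor {k} maps to a gap-only column {col}")
        conserved = all(ch in alphabet for ch in column.values())
        records.append(AnchorConservation(k, anchor_pos, column, conserved))
    return records


def match_table(matches: Sequence[NESMatch], seq: ProteinSequence | None = None) -> pd.DataFrame:
    """Tabulate matches (one row each) for TSV output."""
    rows = []
    for m in matches:
        row = {
            "sequence_id": m.sequence_id,
            "class": m.class_name,
            **{f"phi{k}": p for k, p in enumerate(m.anchors)},
            "span_start": m.span[0],
            "span_end": m.span[1],
        }
        if seq is not None:
            row["subsequence"] = m.matched_subsequence(seq)
        rows.append(row)
    columns = ["sequence_id", "class"]
    if matches:
        columns += [f"phi{k}" for k in range(len(matches[0].anchors))]
    columns += ["span_start", "span_end"] + (["subsequence"] if seq is not None else [])
    return pd.DataFrame(rows, columns=columns)
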