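"""Calling consensus matches cryptic (buried) versus surface-accessible.

A consensus match whose hydrophobic anchors are buried in the native
fold cannot engage the CRM1 export receptor until misfolding exposes
them; such a match is called *cryptic*.  A match whose anchors sit on
the protein surface is a canonical *surface* NES candidate.  The default
rule calls cryptic at >= 4 of 5 anchors buried and surface at <= 1
buried, with everything between ambiguous; both cutoffs are
configurable and echoed in the report header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

from .motifs import NESMatch
from .structure import ResidueAccessibility


class CoverageError(ValueError):
    """Raised when accessibility records do not cover all anchors."""


@dataclass(frozen=True)
class CrypticRule:
    """Verdict thresholds on the number of buried anchors."""

    min_buried_cryptic: int = 4
    max_buried_surface: int = 1

    def __post_init__(self) -> None:
        if self.max_buried_surface >= self.min_buried_cryptic:
            raise ValueError("surface cutoff must be below cryptic cutoff")

    def verdict(self, n_buried: int) -> str:
        if n_buried >= self.min_buried_cryptic:
            return "cryptic"
        if n_buried <= self.max_buried_surface:
            return "surface"
        return "ambiguous"


DEFAULT_RULE = CrypticRule()


@dataclass(frozen=True)
class CrypticNESCall:
    """A consensus match annotated with per-anchor burial and a verdict."""

    match: NESMatch
    anchor_rsa: tuple[tuple[int, float, bool], ...]  # (position, rsa, exposed)
    n_buried_anchors: int
    verdict: str


def call_cryptic(
    match: NESMatch,
    access: Sequence[ResidueAccessibility],
    rule: CrypticRule = DEFAULT_RULE,
) -> CrypticNESCall:
    """Classify one match as cryptic, surface, or ambiguous.

    Every anchor position must be covered by an accessibility record
    (matching ``res_seq``); a gap in coverage raises
    :class:`CoverageError` rather than guessing.
    """
    by_pos = {r.res_seq: r for r in access}
    anchor_rsa: list[tuple[int, float, bool]] = []
    for pos in match.anchors:
        rec = by_pos.get(pos)
        if rec is None:
            raise CoverageError(f"no accessibility record for anchor position {pos}")
        anchor_rsa.append((pos, rec.rsa, rec.exposed))
    n_buried = sum(1 for _, _, exposed in anchor_rsa if not exposed)
    return CrypticNESCall(match, tuple(anchor_rsa), n_buried, rule.verdict(n_buried))


def report(
    calls: Sequence[CrypticNESCall],
    rule: CrypticRule = DEFAULT_RULE,
    rsa_threshold: float = 0.20,
) -> str:
    """Tab-separated report, one row per call, with a ``#config:`` header.

    Rows are ordered by sequence id then span, so identical inputs yield
    byte-identical reports.
    """
    buf = io.StringIO()
    buf.write(
        "#config:\trsa_threshold={:.2f}\tcryptic_if_buried>={}\tsurface_if_buried<={}\n".format(
            rsa_threshold, rule.min_buried_cryptic, rule.max_buried_surface
        )
    )
    header = [
        "sequence_id",
        "class",
        "span_start",
        "span_end",
        "anchor_positions",
        "anchor_rsa",
        "n_buried_anchors",
        "verdict",
    ]
    buf.write("\t".join(header) + "\n")
    ordered = sorted(calls, key=lambda c: (c.match.sequence_id, c.match.span, c.match.anchors))
    for c in ordered:
        buf.write(
            "\t".join(
                [
                    c.match.sequence_id,
                    c.match.class_name,
                    str(c.match.span[0]),
                    str(c.match.span[1]),
                    ",".join(str(p) for p, _, _ in c.anchor_rsa),
                    ",".join(f"{rsa:.4f}" for _, rsa, _ in c.anchor_rsa),
                    str(c.n_buried_anchors),
                    c.verdict,
                ]
            )
            + "\n"
        )
    return buf.getvalue()
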