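"""Bundled reference sequences for the SOD1 worked example.

The mature human SOD1 chain (UniProt P00441 minus the initiator Met,
153 residues) is shipped with the package; the 19-residue NES-like
peptide (NLP) spanning residues 33-51 is sliced from it.  Mature
numbering is the convention of SOD1 mutant nomenclature (A4V, G85R,
G93A).
"""

from __future__ import annotations

from importlib import resources

from .sequences import ProteinSequence, read_fasta

#: Span of the NES-like peptide used for immunization, mature numbering.
NLP_SPAN = (33, 51)

#: Span of the P1 candidate peptide cloned for export assays.
P1_SPAN = (24, 55)

#: The five essential hydrophobic anchors of the NES-like consensus.
NES_ANCHORS = (35, 38, 42, 45, 47)


def sod1_mature() -> ProteinSequence:
    """The mature human SOD1 sequence (153 residues, offset 1)."""
    path = resources.files("crypticnes.data") / "sod1_human_mature.fasta"
    (seq,) = read_fasta(str(path))
    return seq


def nlp_peptide() -> ProteinSequence:
    """The NES-like peptide, residues 33-51 of mature SOD1 (offset 33).

    The immunization construct carried an extra C-terminal Cys as a
    carrier-conjugation linker; that linker is not part of the
    biological peptide and is not included here.
    """
    sod1 = sod1_mature()
    return ProteinSequence(
        "SOD1_NLP_33_51", sod1.subsequence(*NLP_SPAN), numbering_offset=NLP_SPAN[0]
    )
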