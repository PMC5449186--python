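"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from crypticnes.motifs import NESConsensusClass, NESMatch, PKI_CLASS
from crypticnes.reference import nlp_peptide, sod1_mature
from crypticnes.sequences import ProteinSequence


@pytest.fixture(scope="session")
def sod1() -> ProteinSequence:
    return sod1_mature()


@pytest.fixture(scope="session")
def nlp() -> ProteinSequence:
    return nlp_peptide()


@pytest.fixture(scope="session")
def pki() -> NESConsensusClass:
    return PKI_CLASS


def brute_force_scan(seq: ProteinSequence, cls: NESConsensusClass) -> set[tuple[int, ...]]:
    """Independent scanner oracle: test every k-tuple of anchor-eligible
    positions against the class definition directly."""
    eligible = [
        i + seq.numbering_offset
        for i, ch in enumerate(seq.residues)
        if ch in cls.anchor_alphabet
    ]
    found: set[tuple[int, ...]] = set()
    for combo in itertools.combinations(eligible, cls.n_anchors):
        ok = all(
            lo <= combo[k + 1] - combo[k] - 1 <= hi
            for k, (lo, hi) in enumerate(cls.gaps)
        )
        if ok:
            found.add(combo)
    return found


def random_sequence(rng: np.random.Generator, length: int, sid: str) -> ProteinSequence:
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return ProteinSequence(sid, "".join(rng.choice(letters, size=length)))


def anchors_of(matches: list[NESMatch]) -> set[tuple[int, ...]]:
    return {m.anchors for m in matches}
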