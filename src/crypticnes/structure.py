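"""Atomic structures, Shrake-Rupley SASA, and burial classification.

Solvent-accessible surface area (SASA) is computed by the Shrake-Rupley
method: around each atom a sphere of radius (vdW + probe) carries a
fixed set of quasi-uniform test points, and the atom's SASA is the
sphere area times the fraction of points not inside any other atom's
expanded sphere.  The point set is a deterministic golden-spiral
construction, so results are reproducible without a seed.

Per-residue relative solvent accessibility (RSA) divides a residue's
summed atomic SASA by a per-amino-acid reference maximum (theoretical
Gly-X-Gly extended-tripeptide values); residues at or above an RSA
threshold (default 0.20) are classified as exposed, the rest as buried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class StructureParseError(ValueError):
    """Raised for malformed structure input."""


class EmptyStructureError(StructureParseError):
    """Raised when no atoms survive parsing and filtering."""


class RadiusLookupError(KeyError):
    """Raised when an element has no van der Waals radius entry."""


class MaxASALookupError(KeyError):
    """Raised when a residue name has no reference maximum ASA."""


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0


@dataclass
class Structure:
    """A flat list of atoms, optionally restricted to one chain."""

    atoms: list[Atom]
    selected_chain: str | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def select_chain(self, chain: str) -> "Structure":
        atoms = [a for a in self.atoms if a.chain == chain]
        if not atoms:
            raise EmptyStructureError(f"no atoms in chain {chain!r}")
        return Structure(atoms, selected_chain=chain)

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain, res_seq, res_name) triples in first-appearance order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.res_seq, a.res_name), None)
        return list(seen)


#: Default van der Waals radii (Angstrom) by element.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}


@dataclass(frozen=True)
class RadiusTable:
    """Van der Waals radii plus the solvent probe radius (water: 1.4 A)."""

    radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("van der Waals radii must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")

    def radius_of(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise RadiusLookupError(
                f"no van der Waals radius for element {element!r}"
            ) from None


DEFAULT_RADIUS_TABLE = RadiusTable()

#: Theoretical maximum ASA (A^2) per residue, Gly-X-Gly extended
#: tripeptide convention (Tien et al. 2013, theoretical column).
MAX_ASA_TIEN_2013: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueAccessibility:
    """Per-residue SASA, reference maximum, RSA, and exposure flag."""

    chain: str
    res_seq: int
    res_name: str
    sasa: float
    max_asa: float
    rsa: float
    exposed: bool


def read_structure(
    source: str,
    chain: str | None = None,
    include_hetatm: bool = False,
    include_hydrogens: bool = False,
) -> Structure:
    """Parse PDB fixed-column text (or a path to it) into a :class:`Structure`.

    HETATM records (waters, the Cu/Zn ions of SOD1, ligands) and
    hydrogens are excluded by default; alternate locations are resolved
    by keeping the highest-occupancy conformer of each atom.
    """
    if "\n" in source:
        try:
            st = gemmi.read_pdb_string(source)
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(str(exc)) from exc
    else:
        try:
            st = gemmi.read_structure(source, format=gemmi.CoorFormat.Pdb)
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(str(exc)) from exc
    if len(st) == 0:
        raise EmptyStructureError("structure contains no models")

    best: dict[tuple[str, int, str, str], Atom] = {}
    order: list[tuple[str, int, str, str]] = []
    for ch in st[0]:
        for res in ch:
            is_het = res.het_flag == "H"
            if is_het and not include_hetatm:
                continue
            for at in res:
                element = at.element.name.upper()
                if element == "H" and not include_hydrogens:
                    continue
                key = (ch.name, res.seqid.num, res.name, at.name)
                atom = Atom(
                    chain=ch.name,
                    res_seq=res.seqid.num,
                    res_name=res.name,
                    atom_name=at.name,
                    element=element,
                    x=at.pos.x,
                    y=at.pos.y,
                    z=at.pos.z,
                    occupancy=at.occ,
                )
                if key not in best:
                    best[key] = atom
                    order.append(key)
                elif atom.occupancy > best[key].occupancy:
                    best[key] = atom
    atoms = [best[k] for k in order]
    if not atoms:
        raise EmptyStructureError("no atoms after filtering")
    structure = Structure(atoms)
    if chain is not None:
        structure = structure.select_chain(chain)
    return structure


def golden_spiral_points(n: int) -> np.ndarray:
    """*n* deterministic quasi-uniform unit vectors (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one test point")
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    structure: Structure,
    radii: RadiusTable = DEFAULT_RADIUS_TABLE,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (A^2) by the Shrake-Rupley method.

    Deterministic for a fixed ``n_points``: the test-point set is the
    golden-spiral lattice, not a random sample.
    """
    if n_points < 60:
        raise ValueError(f"n_points must be >= 60, got {n_points}")
    coords = structure.coords
    if not np.all(np.isfinite(coords)):
        raise StructureParseError("non-finite coordinates")
    expanded = np.array(
        [radii.radius_of(a.element) + radii.probe_radius for a in structure.atoms]
    )
    n_atoms = len(structure.atoms)
    unit = golden_spiral_points(n_points)
    sasa = np.empty(n_atoms)
    if n_atoms == 1:
        sasa[0] = 4.0 * math.pi * expanded[0] ** 2
        return sasa
    tree = cKDTree(coords)
    r_max = expanded.max()
    for i in range(n_atoms):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        # any atom whose expanded sphere can reach a test point of atom i
        neighbors = tree.query_ball_point(coords[i], ri + r_max)
        free = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            free &= d2 >= expanded[j] ** 2
        sasa[i] = 4.0 * math.pi * ri**2 * (np.count_nonzero(free) / n_points)
    return sasa


def classify_exposure(rsa: float, threshold: float = 0.20) -> bool:
    """True iff *rsa* >= *threshold* (inclusive boundary)."""
    if rsa < 0:
        raise ValueError(f"rsa must be >= 0, got {rsa}")
    return rsa >= threshold


def residue_rsa(
    per_atom_sasa: np.ndarray,
    structure: Structure,
    max_asa: Mapping[str, float] | None = None,
    threshold: float = 0.20,
) -> list[ResidueAccessibility]:
    """Aggregate atomic SASA per residue and classify burial.

    RSA = residue SASA / reference maximum ASA; values slightly above 1
    are possible for residues in extended or terminal conformations.
    """
    if max_asa is None:
        max_asa = MAX_ASA_TIEN_2013
    if len(per_atom_sasa) != len(structure.atoms):
        raise ValueError("per-atom SASA length does not match structure")
    totals: dict[tuple[str, int, str], float] = {}
    order: list[tuple[str, int, str]] = []
    for a, s in zip(structure.atoms, per_atom_sasa):
        key = (a.chain, a.res_seq, a.res_name)
        if key not in totals:
            totals[key] = 0.0
            order.append(key)
        totals[key] += float(s)
    out: list[ResidueAccessibility] = []
    for chain, res_seq, res_name in order:
        try:
            ref = max_asa[res_name]
        except KeyError:
            raise MaxASALookupError(
                f"no reference maximum ASA for residue {res_name!r}"
            ) from None
        sasa = totals[(chain, res_seq, res_name)]
        rsa = sasa / ref
        out.append(
            ResidueAccessibility(
                chain, res_seq, res_name, sasa, ref, rsa, classify_exposure(rsa, threshold)
            )
        )
    return out


def accessibility_table(records: Sequence[ResidueAccessibility]) -> pd.DataFrame:
    """Per-residue accessibility as a table (chain, resi, resn, sasa, ...)."""
    return pd.DataFrame(
        [
            {
                "chain": r.chain,
                "resi": r.res_seq,
                "resn": r.res_name,
                "sasa": round(r.sasa, 3),
                "max_asa": r.max_asa,
                "rsa": round(r.rsa, 4),
                "exposed": r.exposed,
            }
            for r in records
        ],
        columns=["chain", "resi", "resn", "sasa", "max_asa", "rsa", "exposed"],
    )
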