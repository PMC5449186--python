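"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emits both the input artifact (FASTA, PDB text, image
pair, animal table) and a machine-readable truth record, so downstream
stages can be tested by parameter recovery rather than against
irreproducible laboratory data.  All generators are deterministic under
a fixed seed.

Defaults emulate the study conditions of the SOD1 experiments this
package quantifies: 30-cell imaging groups, n = 20 body-bend cohorts,
n = 50 survival cohorts, and the four transgenic lines (WT, L42Q,
G85R, G85R/L42Q) with their printed bagging denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import NESConsensusClass, PKI_CLASS
from .sequences import STANDARD_AA, ProteinSequence
from .stats import AnimalRecord


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


# ---------------------------------------------------------------------------
# Peptides with planted NES motifs


@dataclass(frozen=True)
class PeptideSimConfig:
    """Random peptides with PKI-class motifs planted at known anchors.

    Background residues down-weight the anchor alphabet (frequency
    ``phi_weight`` each) so negative controls have low accidental match
    rates while staying sequence-like.
    """

    n_sequences: int = 100
    length: int = 60
    n_planted: int = 1
    consensus: NESConsensusClass = PKI_CLASS
    phi_weight: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < self.consensus.max_span and self.n_planted > 0:
            raise ConfigError(
                f"length {self.length} cannot hold a motif of up to "
                f"{self.consensus.max_span} residues"
            )
        if not 0 < self.phi_weight * len(self.consensus.anchor_alphabet) < 1:
            raise ConfigError("phi_weight must leave probability for background letters")


def _background_letters(cfg: PeptideSimConfig) -> tuple[list[str], np.ndarray]:
    phi = sorted(cfg.consensus.anchor_alphabet)
    other = sorted(STANDARD_AA - cfg.consensus.anchor_alphabet)
    letters = phi + other
    p_other = (1.0 - cfg.phi_weight * len(phi)) / len(other)
    weights = np.array([cfg.phi_weight] * len(phi) + [p_other] * len(other))
    return letters, weights


def gen_planted_peptides(
    cfg: PeptideSimConfig,
) -> tuple[list[ProteinSequence], pd.DataFrame]:
    """Generate peptides and the truth table of planted anchor tuples.

    Spacer residues inside a planted motif are drawn from the non-anchor
    alphabet, so the planted anchor tuple is guaranteed to be a valid
    match of the configured class.
    """
    rng = np.random.default_rng(cfg.seed)
    letters, weights = _background_letters(cfg)
    phi = sorted(cfg.consensus.anchor_alphabet)
    non_phi = sorted(STANDARD_AA - cfg.consensus.anchor_alphabet)
    truth_rows = []
    seqs: list[ProteinSequence] = []
    for i in range(cfg.n_sequences):
        residues = list(rng.choice(letters, size=cfg.length, p=weights))
        for _ in range(cfg.n_planted):
            gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in cfg.consensus.gaps]
            span = cfg.consensus.n_anchors + sum(gaps)
            start = int(rng.integers(0, cfg.length - span + 1))
            pos = start
            anchors = []
            for k in range(cfg.consensus.n_anchors):
                residues[pos] = str(rng.choice(phi))
                anchors.append(pos + 1)  # 1-based
                if k < len(gaps):
                    for j in range(gaps[k]):
                        residues[pos + 1 + j] = str(rng.choice(non_phi))
                    pos += gaps[k] + 1
            truth_rows.append(
                {
                    "sequence_id": f"sim_{i:04d}",
                    **{f"phi{k}": a for k, a in enumerate(anchors)},
                }
            )
        seqs.append(ProteinSequence(f"sim_{i:04d}", "".join(residues)))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sequence_id"] + [f"phi{k}" for k in range(cfg.consensus.n_anchors)],
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# Toy structures with analytic SASA truth


def isolated_sphere_sasa(radius: float, probe: float) -> float:
    """Closed-form SASA of one isolated atom: 4*pi*(r + probe)^2."""
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_sasa(radius: float, probe: float, distance: float) -> float:
    """Closed-form per-atom SASA of two identical intersecting atoms.

    The buried patch on each expanded sphere (radius R = r + probe) is a
    spherical cap of height R - d/2, with area 2*pi*R*h.
    """
    if distance <= 0:
        raise ConfigError("distance must be > 0")
    R = radius + probe
    if distance >= 2 * R:
        return isolated_sphere_sasa(radius, probe)
    h = R - distance / 2.0
    return 4.0 * math.pi * R**2 - 2.0 * math.pi * R * h


def _pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    x: float,
    y: float,
    z: float,
    element: str,
) -> str:
    # PDB fixed columns: name in 13-16 (single-letter elements indented), occ/B 55-66
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {padded}{'':1s}{res_name:>3s} {chain:1s}{res_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@dataclass(frozen=True)
class ToyStructureConfig:
    """A toy structure kind with analytically known SASA where defined."""

    kind: str = "isolated-atom"  # isolated-atom | pair | cage | helix
    distance: float = 2.0  # pair separation, Angstrom
    n_shell: int = 60  # cage shell atoms
    n_residues: int = 10  # helix length
    radius: float = 1.70  # carbon vdW
    probe: float = 1.4


def gen_toy_structure(cfg: ToyStructureConfig) -> tuple[str, dict[int, float]]:
    """PDB text plus {res_seq: analytic SASA} truth (empty where undefined).

    Kinds: ``isolated-atom`` (closed-form sphere), ``pair`` (two-sphere
    spherical-cap truth), ``cage`` (central atom fully enclosed, truth
    0), ``helix`` (CA trace along an alpha-helical spiral, no analytic
    truth; for cross-implementation comparison only).
    """
    lines: list[str] = []
    truth: dict[int, float] = {}
    if cfg.kind == "isolated-atom":
        lines.append(_pdb_atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"))
        truth[1] = isolated_sphere_sasa(cfg.radius, cfg.probe)
    elif cfg.kind == "pair":
        lines.append(_pdb_atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"))
        lines.append(_pdb_atom_line(2, "CA", "GLY", "A", 2, cfg.distance, 0.0, 0.0, "C"))
        per_atom = two_sphere_sasa(cfg.radius, cfg.probe, cfg.distance)
        truth[1] = per_atom
        truth[2] = per_atom
    elif cfg.kind == "cage":
        # Shell atoms at 3.0 A: every test point of the central expanded
        # sphere (R = 3.1) lies inside some shell atom's expanded sphere
        # provided the angular spacing is < ~60 deg, easily met by n >= 30.
        if cfg.n_shell < 30:
            raise ConfigError("cage needs at least 30 shell atoms to enclose")
        lines.append(_pdb_atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"))
        truth[1] = 0.0
        k = np.arange(cfg.n_shell, dtype=float)
        zc = 1.0 - 2.0 * (k + 0.5) / cfg.n_shell
        rc = np.sqrt(1.0 - zc**2)
        phi = k * math.pi * (3.0 - math.sqrt(5.0))
        shell = 3.0 * np.column_stack([rc * np.cos(phi), rc * np.sin(phi), zc])
        for j, (x, y, z) in enumerate(shell, start=2):
            lines.append(_pdb_atom_line(j, "CA", "GLY", "A", j, x, y, z, "C"))
    elif cfg.kind == "helix":
        # CA trace with alpha-helix geometry: radius 2.3 A, rise 1.5 A,
        # 100 degrees per residue
        for i in range(cfg.n_residues):
            theta = math.radians(100.0 * i)
            lines.append(
                _pdb_atom_line(
                    i + 1,
                    "CA",
                    "ALA",
                    "A",
                    i + 1,
                    2.3 * math.cos(theta),
                    2.3 * math.sin(theta),
                    1.5 * i,
                    "C",
                )
            )
    else:
        raise ConfigError(f"unknown toy structure kind {cfg.kind!r}")
    return "\n".join(lines) + "\nEND\n", truth


# ---------------------------------------------------------------------------
# Two-compartment cell images


@dataclass(frozen=True)
class ImageSimConfig:
    """Disk cells with inner nuclear disks and a known true N/T ratio.

    Intensities follow the standard microscopy noise model: Poisson shot
    noise at the configured photon budget plus Gaussian read noise.
    ``photons_at_cyto`` is the expected photon count of one cytoplasm
    pixel, so the per-pixel SNR there is roughly its square root.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 30
    n_border: int = 0  # cells deliberately clipped by the image border
    cell_radius: float = 12.0
    nucleus_radius: float = 6.5
    nuclear_fraction: float = 0.5  # true N/T
    cyto_intensity: float = 100.0
    background: float = 5.0
    photons_at_cyto: float = 100.0  # per-pixel SNR ~ 10
    read_noise_sd: float = 1.0
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.nuclear_fraction < 1.0:
            raise ConfigError("nuclear_fraction must be in (0, 1)")
        if self.nucleus_radius >= self.cell_radius:
            raise ConfigError("nucleus must fit inside the cell")


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def gen_cell_images(
    cfg: ImageSimConfig,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """(signal, nuclear marker, truth table) for one synthetic field.

    Each cell's nuclear intensity is solved from the pixel-counted
    nucleus and cytoplasm areas so that its noise-free N/T equals the
    configured nuclear fraction exactly, up to pixelation of the masks.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    r = cfg.cell_radius
    centers: list[tuple[float, float, bool]] = []
    attempts = 0
    # interior cells: fully inside with a 2 px margin
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > cfg.max_attempts:
            raise ConfigError("could not place all cells without overlap")
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * r + 2) ** 2 for y, x, _ in centers):
            centers.append((cy, cx, False))
    # border cells: centers on the border so the disk is clipped
    while len(centers) < cfg.n_cells + cfg.n_border:
        attempts += 1
        if attempts > cfg.max_attempts:
            raise ConfigError("could not place border cells without overlap")
        edge = rng.integers(0, 4)
        cy, cx = {
            0: (0.0, float(rng.uniform(r, w - r))),
            1: (float(h - 1), float(rng.uniform(r, w - r))),
            2: (float(rng.uniform(r, h - r)), 0.0),
            3: (float(rng.uniform(r, h - r)), float(w - 1)),
        }[int(edge)]
        if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * r + 2) ** 2 for y, x, _ in centers):
            centers.append((cy, cx, True))

    signal = np.full(cfg.shape, cfg.background, dtype=float)
    nuclei = np.full(cfg.shape, cfg.background, dtype=float)
    f = cfg.nuclear_fraction
    rows = []
    for i, (cy, cx, border) in enumerate(centers, start=1):
        cell = _disk_mask(cfg.shape, cy, cx, r)
        nuc = _disk_mask(cfg.shape, cy, cx, cfg.nucleus_radius) & cell
        a_cell = int(cell.sum())
        a_nuc = int(nuc.sum())
        a_cyto = a_cell - a_nuc
        if a_nuc == 0 or a_cyto == 0:
            continue
        # N/T = I_nuc*A_nuc / (I_nuc*A_nuc + I_cyto*A_cyto) = f
        i_nuc = (f / (1.0 - f)) * cfg.cyto_intensity * a_cyto / a_nuc
        signal[cell & ~nuc] += cfg.cyto_intensity
        signal[nuc] += i_nuc
        nuclei[nuc] += cfg.cyto_intensity
        rows.append(
            {
                "cell_id": i,
                "cy": cy,
                "cx": cx,
                "cell_radius": r,
                "nucleus_radius": cfg.nucleus_radius,
                "true_ratio": f,
                "border": border,
            }
        )
    # Poisson shot noise at the photon budget, plus Gaussian read noise
    gain = cfg.photons_at_cyto / cfg.cyto_intensity
    signal = rng.poisson(signal * gain) / gain + rng.normal(0, cfg.read_noise_sd, cfg.shape)
    nuclei = rng.poisson(nuclei * gain) / gain + rng.normal(0, cfg.read_noise_sd, cfg.shape)
    truth = pd.DataFrame(
        rows,
        columns=["cell_id", "cy", "cx", "cell_radius", "nucleus_radius", "true_ratio", "border"],
    )
    return np.clip(signal, 0, None), np.clip(nuclei, 0, None), truth


# ---------------------------------------------------------------------------
# Phenotype tables


@dataclass(frozen=True)
class LineConfig:
    """Per-line phenotype parameters.

    Body bends are rounded normal draws; death days are geometric (the
    discrete memoryless lifetime, parameterized by the per-day hazard);
    bagging is Bernoulli; hatched eggs are Poisson truncated at >= 1 for
    bagged animals; eggs laid in 48 h are Poisson.
    """

    name: str
    n_bends: int = 20
    bends_mean: float = 60.0
    bends_sd: float = 12.0
    n_survival: int = 50
    death_hazard: float = 1.0 / 10.0  # per-day geometric hazard
    n_bagging: int = 40
    p_bag: float = 0.0
    hatched_mean: float = 2.0
    n_eggs: int = 12
    eggs_mean: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bag <= 1.0:
            raise ConfigError("p_bag must be in [0, 1]")
        if not 0.0 < self.death_hazard <= 1.0:
            raise ConfigError("death_hazard must be in (0, 1]")
        for v in (self.bends_mean, self.bends_sd, self.hatched_mean, self.eggs_mean):
            if v < 0:
                raise ConfigError("negative phenotype parameter")


#: Study-condition defaults: the four transgenic lines with their printed
#: bagging denominators (46/45/41/47) and probabilities matching the
#: observed counts (0, 0, 7/41, 33/47); the double mutant's per-day death
#: hazard is set so ~80% of animals die by day 3.
DEFAULT_LINES: tuple[LineConfig, ...] = (
    LineConfig("WT", bends_mean=95.0, bends_sd=10.0, death_hazard=1 / 12,
               n_bagging=46, p_bag=0.0, eggs_mean=100.0),
    LineConfig("L42Q", bends_mean=95.0, bends_sd=10.0, death_hazard=1 / 12,
               n_bagging=45, p_bag=0.0, eggs_mean=100.0),
    LineConfig("G85R", bends_mean=60.0, bends_sd=12.0, death_hazard=1 / 8,
               n_bagging=41, p_bag=7 / 41, hatched_mean=2.4, eggs_mean=80.0),
    LineConfig("G85R/L42Q", bends_mean=35.0, bends_sd=12.0, death_hazard=0.415,
               n_bagging=47, p_bag=33 / 47, hatched_mean=4.2, eggs_mean=30.0),
)


def _truncated_poisson_ge1(rng: np.random.Generator, mean: float) -> int:
    """Poisson draw conditioned on >= 1 (a bagged animal hatched something)."""
    for _ in range(1000):
        v = int(rng.poisson(mean))
        if v >= 1:
            return v
    return 1


def gen_phenotype_table(
    lines: tuple[LineConfig, ...] = DEFAULT_LINES, seed: int = 0
) -> list[AnimalRecord]:
    """Per-animal records for separate bends/survival/bagging/egg cohorts.

    Mirrors the study design: each assay uses its own cohort, so each
    record carries exactly one measured field.
    """
    rng = np.random.default_rng(seed)
    records: list[AnimalRecord] = []
    for line in lines:
        for _ in range(line.n_bends):
            bends = max(0, int(round(rng.normal(line.bends_mean, line.bends_sd))))
            records.append(AnimalRecord(line.name, bends_per_min=bends))
        for _ in range(line.n_survival):
            records.append(
                AnimalRecord(line.name, death_day=int(rng.geometric(line.death_hazard)))
            )
        for _ in range(line.n_bagging):
            bagged = bool(rng.random() < line.p_bag)
            hatched = _truncated_poisson_ge1(rng, line.hatched_mean) if bagged else None
            records.append(AnimalRecord(line.name, bagged=bagged, hatched_eggs=hatched))
        for _ in range(line.n_eggs):
            records.append(AnimalRecord(line.name, eggs_48h=int(rng.poisson(line.eggs_mean))))
    return records
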