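"""Shrake-Rupley SASA: closed-form oracles, invariances, and burial calls."""

import io
import math

import numpy as np
import pytest

from crypticnes.structure import (
    Atom,
    EmptyStructureError,
    MaxASALookupError,
    RadiusLookupError,
    Structure,
    classify_exposure,
    golden_spiral_points,
    read_structure,
    residue_rsa,
    shrake_rupley,
)
from crypticnes.synthetic import (
    ToyStructureConfig,
    gen_toy_structure,
    isolated_sphere_sasa,
    two_sphere_sasa,
)


def carbon(res_seq, x, y, z, chain="A", res_name="GLY"):
    return Atom(chain, res_seq, res_name, "CA", "C", x, y, z)


class TestReadStructure:
    def test_single_atom_record(self):
        pdb, _ = gen_toy_structure(ToyStructureConfig(kind="isolated-atom"))
        st = read_structure(pdb)
        assert len(st) == 1
        assert st.atoms[0].element == "C"

    def test_chain_selection(self):
        lines = [
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  CA  GLY B   1       5.000   0.000   0.000  1.00  0.00           C",
        ]
        st = read_structure("\n".join(lines) + "\nEND\n", chain="A")
        assert st.chains() == ["A"]
        assert len(st) == 1

    def test_hetatm_excluded_by_default(self):
        lines = [
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    2  O   HOH A 201       9.000   0.000   0.000  1.00  0.00           O",
        ]
        text = "\n".join(lines) + "\nEND\n"
        assert len(read_structure(text)) == 1
        assert len(read_structure(text, include_hetatm=True)) == 2

    def test_altloc_keeps_highest_occupancy(self):
        lines = [
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.30  0.00           C",
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.70  0.00           C",
        ]
        st = read_structure("\n".join(lines) + "\nEND\n")
        assert len(st) == 1
        assert st.atoms[0].x == pytest.approx(9.0)

    def test_no_atoms_raises(self):
        with pytest.raises(EmptyStructureError):
            read_structure("END\n")


class TestShrakeRupley:
    def test_isolated_sphere_matches_closed_form_at_every_n(self):
        st = Structure([carbon(1, 0, 0, 0)])
        expected = isolated_sphere_sasa(1.70, 1.4)
        for n in (60, 120, 240, 480, 960):
            assert shrake_rupley(st, n_points=n)[0] == pytest.approx(expected)

    def test_distant_pair_additive(self):
        st = Structure([carbon(1, 0, 0, 0), carbon(2, 100, 0, 0)])
        expected = isolated_sphere_sasa(1.70, 1.4)
        assert shrake_rupley(st) == pytest.approx([expected, expected])

    def test_two_sphere_cap_oracle_within_2_percent(self):
        st = Structure([carbon(1, 0, 0, 0), carbon(2, 2.0, 0, 0)])
        expected = two_sphere_sasa(1.70, 1.4, 2.0)
        sasa = shrake_rupley(st, n_points=960)
        assert np.max(np.abs(sasa - expected) / expected) < 0.02

    def test_quadrature_error_shrinks_with_point_count(self):
        st = Structure([carbon(1, 0, 0, 0), carbon(2, 2.0, 0, 0)])
        expected = two_sphere_sasa(1.70, 1.4, 2.0)
        errors = [
            np.max(np.abs(shrake_rupley(st, n_points=n) - expected) / expected)
            for n in (60, 960)
        ]
        assert errors[1] < errors[0]

    def test_sasa_non_increasing_as_neighbor_approaches(self):
        prev = math.inf
        for d in (10.0, 6.5, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0):
            st = Structure([carbon(1, 0, 0, 0), carbon(2, d, 0, 0)])
            s = shrake_rupley(st)[0]
            assert s <= prev + 1e-9
            prev = s

    def test_translation_invariance_exact(self):
        pdb, _ = gen_toy_structure(ToyStructureConfig(kind="helix"))
        st = read_structure(pdb)
        base = shrake_rupley(st)
        shifted = Structure(
            [
                Atom(a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                     a.x + 123.0, a.y - 45.0, a.z + 7.0)
                for a in st.atoms
            ]
        )
        assert shrake_rupley(shifted) == pytest.approx(base, rel=1e-9)

    def test_rotation_invariance_within_2_percent(self):
        pdb, _ = gen_toy_structure(ToyStructureConfig(kind="helix"))
        st = read_structure(pdb)
        base = shrake_rupley(st)
        theta = 0.7
        c, s = math.cos(theta), math.sin(theta)
        rotated = Structure(
            [
                Atom(a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                     c * a.x - s * a.y, s * a.x + c * a.y, a.z)
                for a in st.atoms
            ]
        )
        rot = shrake_rupley(rotated)
        assert np.max(np.abs(rot - base) / np.maximum(base, 1.0)) < 0.02

    def test_total_sasa_invariant_to_atom_order(self):
        pdb, _ = gen_toy_structure(ToyStructureConfig(kind="helix"))
        st = read_structure(pdb)
        total = shrake_rupley(st).sum()
        reversed_st = Structure(list(reversed(st.atoms)))
        assert shrake_rupley(reversed_st).sum() == pytest.approx(total, rel=1e-9)

    def test_caged_atom_has_zero_sasa(self):
        pdb, truth = gen_toy_structure(ToyStructureConfig(kind="cage"))
        st = read_structure(pdb)
        sasa = shrake_rupley(st)
        assert sasa[0] == truth[1] == 0.0

    def test_unknown_element_raises(self):
        st = Structure([Atom("A", 1, "HEM", "FE", "FE", 0, 0, 0)])
        with pytest.raises(RadiusLookupError):
            shrake_rupley(st)

    def test_too_few_points_rejected(self):
        st = Structure([carbon(1, 0, 0, 0)])
        with pytest.raises(ValueError):
            shrake_rupley(st, n_points=30)


class TestAgainstIndependentImplementation:
    def test_per_residue_agreement_within_5_percent(self):
        """Cross-check against biotite's Shrake-Rupley on a 10-residue
        synthetic peptide trace, using the same element radii."""
        bstruc = pytest.importorskip("biotite.structure")
        import biotite.structure.io.pdb as bpdb

        pdb, _ = gen_toy_structure(ToyStructureConfig(kind="helix", n_residues=10))
        arr = bpdb.get_structure(bpdb.PDBFile.read(io.StringIO(pdb)), model=1)
        theirs = bstruc.apply_residue_wise(
            arr, bstruc.sasa(arr, probe_radius=1.4, point_number=1000, vdw_radii="Single"),
            np.sum,
        )
        st = read_structure(pdb)
        mine = [r.sasa for r in residue_rsa(shrake_rupley(st), st)]
        assert np.max(np.abs(np.array(mine) - theirs) / theirs) < 0.05


class TestResidueRSA:
    def test_enclosed_residue_is_buried(self):
        pdb, _ = gen_toy_structure(ToyStructureConfig(kind="cage"))
        st = read_structure(pdb)
        records = residue_rsa(shrake_rupley(st), st)
        central = next(r for r in records if r.res_seq == 1)
        assert central.sasa == 0.0 and central.rsa == 0.0 and not central.exposed

    def test_isolated_glycine_is_exposed(self):
        st = Structure([carbon(1, 0, 0, 0)])
        (rec,) = residue_rsa(shrake_rupley(st), st)
        assert rec.rsa > 0.20 and rec.exposed

    def test_missing_reference_entry_raises(self):
        st = Structure([Atom("A", 1, "UNK", "CA", "C", 0, 0, 0)])
        with pytest.raises(MaxASALookupError):
            residue_rsa(shrake_rupley(st), st)

    def test_ordering_follows_residue_index(self):
        pdb, _ = gen_toy_structure(ToyStructureConfig(kind="helix"))
        st = read_structure(pdb)
        records = residue_rsa(shrake_rupley(st), st)
        assert [r.res_seq for r in records] == sorted(r.res_seq for r in records)


class TestClassifyExposure:
    @pytest.mark.parametrize(
        "rsa, threshold, expected",
        [(0.0, 0.20, False), (0.19, 0.20, False), (0.20, 0.20, True), (0.55, 0.20, True)],
    )
    def test_threshold_inclusive(self, rsa, threshold, expected):
        assert classify_exposure(rsa, threshold) is expected

    def test_negative_rsa_rejected(self):
        with pytest.raises(ValueError):
            classify_exposure(-0.1)


def test_golden_spiral_points_are_unit_and_deterministic():
    pts = golden_spiral_points(960)
    assert pts.shape == (960, 3)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.array_equal(pts, golden_spiral_points(960))
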