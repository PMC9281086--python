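"""Angle primitives, PDB parsing, the +/-10% criterion and contact maps."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mimicryscan import (
    AngleDescriptor,
    compare_angles,
    contact_map,
    dihedral_angle,
    parse_pdb,
    planar_angle,
    tcr_facing_positions,
    write_pdb,
)
from mimicryscan.structure_geom import (
    angles_identical,
    circular_difference_deg,
    default_descriptors,
    measure_angle,
)
from mimicryscan.synthetic_data import generate_ideal_peptide


# ---------------------------------------------------------------------------
# angle primitives
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p1,p2,p3,expected",
    [
        ((0, 0, 0), (1, 0, 0), (1, 1, 0), 90.0),
        ((0, 0, 0), (1, 0, 0), (2, 0, 0), 180.0),  # collinear in order
        ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
    ],
)
def test_planar_angle_examples(p1, p2, p3, expected):
    assert planar_angle(p1, p2, p3) == pytest.approx(expected)


def test_planar_angle_coincident_points_error():
    with pytest.raises(ValueError, match="coincident"):
        planar_angle((0, 0, 0), (0, 0, 0), (1, 1, 1))


@pytest.mark.parametrize(
    "p4,expected",
    [
        ((2, 1, 0), 180.0),  # planar trans zig-zag
        ((0, 1, 0), 0.0),    # planar cis
        ((1, 1, 1), -90.0),  # out-of-plane, IUPAC sign
    ],
)
def test_dihedral_angle_examples(p4, expected):
    assert dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), p4) == pytest.approx(expected)


def test_dihedral_degenerate_geometry_error():
    with pytest.raises(ValueError, match="degenerate"):
        dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def test_angles_invariant_under_rigid_body_transforms():
    """100 random rotation+translation transforms change neither angle by
    more than 1e-6 degrees."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(4, 3)) * 5
    ref_planar = planar_angle(*pts[:3])
    ref_dihedral = dihedral_angle(*pts)
    for _ in range(100):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 10
        moved = pts @ rot.T + shift
        assert abs(planar_angle(*moved[:3]) - ref_planar) < 1e-6
        assert abs(dihedral_angle(*moved) - ref_dihedral) < 1e-6


def test_mirror_flips_dihedral_sign_not_planar():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(4, 3)) * 5
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    assert dihedral_angle(*mirrored) == pytest.approx(-dihedral_angle(*pts), abs=1e-9)
    assert planar_angle(*mirrored[:3]) == pytest.approx(planar_angle(*pts[:3]), abs=1e-9)


# ---------------------------------------------------------------------------
# the +/-10% identity criterion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        (100.0, 109.0, True),   # 9 <= 10% of 100
        (100.0, 115.0, False),  # 15 > 10
        (40.0, 44.5, True),     # 4.5 within the 5 deg floor for small angles
        (40.0, 46.0, False),    # 6 beyond both the 4 deg band and the floor
        (-170.0, 175.0, True),  # circular wrap: difference is 15 <= 17
        (2.0, 6.5, True),       # near-zero reference saved by the floor
    ],
)
def test_angle_identity_band(ref, alt, expected):
    assert angles_identical(ref, alt) is expected


def test_circular_difference():
    assert circular_difference_deg(179.0, -179.0) == pytest.approx(2.0)
    assert circular_difference_deg(0.0, 360.0) == pytest.approx(0.0)


def test_compare_angles_self_is_100_percent():
    s = generate_ideal_peptide("KVAELVHFL", [(-120.0, 130.0)] * 9)
    descs = default_descriptors(s)
    comps, pct = compare_angles(s, s, descs)
    assert pct == 100.0
    assert all(c.identical for c in comps)


def test_compare_angles_detects_conformational_change():
    extended = generate_ideal_peptide("KVAELVHFL", [(-120.0, 130.0)] * 9)
    helical = generate_ideal_peptide("KVAELVHFL", [(-57.0, -47.0)] * 9)
    descs = [d for d in default_descriptors(extended) if d.kind == "planar"]
    _, pct = compare_angles(extended, helical, descs)
    assert pct < 100.0


def test_unresolvable_atom_ref_errors():
    s = generate_ideal_peptide("GGGGGGGGG", [(-120.0, 130.0)] * 9)  # glycines: no CB
    bad = AngleDescriptor("dihedral", ((4, "N"), (4, "CA"), (4, "CB"), (4, "CG")))
    with pytest.raises(ValueError, match="CB"):
        measure_angle(s, bad)


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def test_pdb_write_parse_roundtrip(tmp_path):
    s = generate_ideal_peptide("KVAELVHFL", [(-120.0, 130.0)] * 9)
    path = tmp_path / "ideal.pdb"
    write_pdb(s, path)
    parsed = parse_pdb(path, {"P": "peptide"})
    assert parsed.peptide_sequence_length() == 9
    for res_a, res_b in zip(s.peptide_chain, parsed.peptide_chain):
        assert res_a.name == res_b.name
        for name, atom in res_a.atoms.items():
            np.testing.assert_allclose(res_b.atoms[name].xyz, atom.xyz, atol=1e-3)


def test_parse_pdb_error_cases(tmp_path):
    no_atoms = tmp_path / "empty.pdb"
    no_atoms.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(ValueError, match="no ATOM"):
        parse_pdb(no_atoms, {"P": "peptide"})

    malformed = tmp_path / "bad.pdb"
    malformed.write_text("ATOM      1  CA  ALA P   1    not_a_number\n")
    with pytest.raises(ValueError, match="line 1"):
        parse_pdb(malformed, {"P": "peptide"})

    with pytest.raises(ValueError, match="role"):
        parse_pdb(no_atoms, {"P": "nonsense"})


def test_parse_pdb_missing_chain_and_length(tmp_path):
    s = generate_ideal_peptide("KVAELVHFL", [(-120.0, 130.0)] * 9)
    path = tmp_path / "s.pdb"
    write_pdb(s, path)
    with pytest.raises(ValueError, match="'Q'"):
        parse_pdb(path, {"P": "peptide", "Q": "hla"})

    short = generate_ideal_peptide("KVAELVH", [(-120.0, 130.0)] * 7)
    short_path = tmp_path / "short.pdb"
    write_pdb(short, short_path)
    with pytest.raises(ValueError, match="8-11"):
        parse_pdb(short_path, {"P": "peptide"})


def test_parse_pdb_altloc_rule(tmp_path):
    lines = []
    for i in range(1, 10):
        x = 3.8 * i
        lines.append(
            f"ATOM  {i:5d}  CA AALA P{i:4d}    {x:8.3f}{0.0:8.3f}{0.0:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}           C"
        )
        lines.append(
            f"ATOM  {i:5d}  CA BALA P{i:4d}    {x + 9:8.3f}{0.0:8.3f}{0.0:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}           C"
        )
    parsed = parse_pdb(lines, {"P": "peptide"}, structure_id="ALT")
    chain = parsed.peptide_chain
    assert len(chain) == 9
    # altloc A retained, B dropped
    assert chain[0].atoms["CA"].xyz[0] == pytest.approx(3.8)
    assert len(chain[0].atoms) == 1


# ---------------------------------------------------------------------------
# contacts and TCR-facing positions
# ---------------------------------------------------------------------------

def test_contact_map_planted_contacts(contact_fixture_structure):
    cmap = contact_map(contact_fixture_structure, cutoff_A=4.0)
    assert cmap.contacts[3] == {"HLA"}
    assert cmap.contacts[5] == {"TCR_alpha"}
    assert cmap.contacts[8] == {"TCR_beta"}
    for pos in (1, 2, 4, 6, 7, 9):
        assert cmap.contacts[pos] == frozenset()


def test_contact_map_cutoff_zero_and_peptide_only(contact_fixture_structure):
    cmap = contact_map(contact_fixture_structure, cutoff_A=0.0)
    assert all(not cats for cats in cmap.contacts.values())

    peptide_only = generate_ideal_peptide("KVAELVHFL", [(-120.0, 130.0)] * 9)
    cmap = contact_map(peptide_only)
    assert all(not cats for cats in cmap.contacts.values())


def test_tcr_facing_positions(contact_fixture_structure):
    cmap = contact_map(contact_fixture_structure, cutoff_A=4.0)
    assert tcr_facing_positions(cmap) == {5, 8}
    # structure without TCR contacts -> static central-position fallback
    peptide_only = generate_ideal_peptide("KVAELVHFL", [(-120.0, 130.0)] * 9)
    assert tcr_facing_positions(contact_map(peptide_only)) == {4, 5, 6, 7, 8}
    assert tcr_facing_positions("HLA-A*02:01") == {4, 5, 6, 7, 8}
    assert tcr_facing_positions() == {4, 5, 6, 7, 8}
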