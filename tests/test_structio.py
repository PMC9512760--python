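"""Structure I/O and geometry kernel tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem

from covflex.structio import (Atom, GeometryError, Ligand, PDBParseError,
                              ProteinStructure, Residue, StructIOError,
                              dihedral, kabsch, place_atom, read_ligand_sdf,
                              read_pdb, rotation_about_axis, superpose,
                              write_ligand_sdf, write_pdb)


# ---------------------------------------------------------------------------
# PDB round trips

def test_pdb_roundtrip_preserves_model(easy_system, tmp_path):
    path = tmp_path / "rt.pdb"
    write_pdb(easy_system.receptor, path)
    back = read_pdb(path)
    assert len(back) == len(easy_system.receptor)
    for orig, rt in zip(easy_system.receptor.residues, back.residues):
        assert (rt.chain_id, rt.resnum, rt.name) == (orig.chain_id, orig.resnum, orig.name)
        assert [a.name for a in rt.atoms] == [a.name for a in orig.atoms]
        for a, b in zip(orig.atoms, rt.atoms):
            assert np.allclose(a.coords, b.coords, atol=1.5e-3)


def test_altloc_keeps_highest_occupancy(tmp_path, caplog):
    text = "\n".join([
        "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C",
        "ATOM      4  O   SER A   1       1.500   2.500   0.000  1.00  0.00           O",
        "ATOM      5  CB  SER A   1       2.000  -0.900   1.100  1.00  0.00           C",
        "ATOM      6  OG ASER A   1       1.500  -2.200   1.100  0.30  0.00           O",
        "ATOM      7  OG BSER A   1       3.400  -1.000   1.200  0.70  0.00           O",
        "END", ""])
    path = tmp_path / "altloc.pdb"
    path.write_text(text)
    st = read_pdb(path)
    ser = st.get("A", 1)
    ogs = [a for a in ser.atoms if a.name == "OG"]
    assert len(ogs) == 1
    assert np.allclose(ogs[0].coords, [3.4, -1.0, 1.2], atol=1e-3)  # occ 0.70 wins


def test_read_pdb_errors(tmp_path):
    with pytest.raises(PDBParseError):
        read_pdb(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("")
    with pytest.raises(PDBParseError):
        read_pdb(empty)


def test_serial_wrap_warns(tmp_path, caplog, easy_system):
    import logging
    with caplog.at_level(logging.WARNING, logger="covflex.structio"):
        write_pdb(easy_system.receptor, tmp_path / "wrap.pdb", start_serial=99998)
    assert any("wrap" in rec.message for rec in caplog.records)


def test_hetatm_records_follow_atom_records(tmp_path):
    res = Residue("A", 1, "GLY", [
        Atom("N", "N", [0, 0, 0]), Atom("CA", "C", [1.46, 0, 0]),
        Atom("C", "C", [2.0, 1.4, 0]), Atom("O", "O", [1.5, 2.5, 0])])
    het = Residue("A", 90, "MG", [Atom("MG", "MG", [5, 5, 5])], role="het")
    st = ProteinStructure([res], "toy", [het])
    path = tmp_path / "het.pdb"
    write_pdb(st, path)
    lines = [ln[:6].strip() for ln in path.read_text().splitlines()]
    assert lines.index("HETATM") > max(i for i, tag in enumerate(lines) if tag == "ATOM")
    back = read_pdb(path)
    assert len(back.heteroatoms) == 1 and back.heteroatoms[0].name == "MG"


# ---------------------------------------------------------------------------
# Ligand SDF

def _sdf_from_smiles(smiles: str, path, three_d: bool = True):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if three_d:
        AllChem.EmbedMolecule(mol, randomSeed=11)
    else:
        AllChem.Compute2DCoords(mol)
    mol = Chem.RemoveHs(mol)
    writer = Chem.SDWriter(str(path))
    writer.write(mol)
    writer.close()
    return path


@pytest.mark.parametrize("smiles,n_rotatable", [
    ("CC", 0),            # ethane: terminal bond
    ("CCCC", 1),          # butane: C2-C3 only
    ("C1CCCCC1", 0),      # cyclohexane: ring bonds excluded
])
def test_rotatable_torsion_detection(tmp_path, smiles, n_rotatable):
    path = _sdf_from_smiles(smiles, tmp_path / "m.sdf")
    lig = read_ligand_sdf(path)
    assert len(lig.rotatable_torsions) == n_rotatable


def test_sdf_rejects_2d(tmp_path):
    path = _sdf_from_smiles("CCCC", tmp_path / "flat.sdf", three_d=False)
    with pytest.raises(StructIOError):
        read_ligand_sdf(path)


def test_ligand_sdf_roundtrip(tmp_path, easy_system):
    path = tmp_path / "lig.sdf"
    write_ligand_sdf(easy_system.ligand, path)
    back = read_ligand_sdf(path)
    assert len(back.atoms) == len(easy_system.ligand.atoms)
    assert sorted((min(i, j), max(i, j), o) for i, j, o in back.bonds) == \
        sorted((min(i, j), max(i, j), o) for i, j, o in easy_system.ligand.bonds)
    assert np.allclose(back.coords(), easy_system.ligand.coords(), atol=1e-3)


def test_disconnected_ligand_rejected():
    atoms = [Atom("C1", "C", [0, 0, 0]), Atom("C2", "C", [2, 0, 0]),
             Atom("C3", "C", [10, 0, 0])]
    with pytest.raises(StructIOError):
        Ligand(atoms, [(0, 1, 1)])


# ---------------------------------------------------------------------------
# Dihedrals

def _dihedral_oracle(p1, p2, p3, p4):
    """Independent formulation: signed angle between plane projections."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b /= np.linalg.norm(b)
    u = (p1 - p2) - np.dot(p1 - p2, b) * b
    v = (p4 - p3) - np.dot(p4 - p3, b) * b
    ang = math.degrees(math.atan2(np.dot(np.cross(u, v), b), np.dot(u, v)))
    return ang if ang > -180.0 else ang + 360.0


def test_dihedral_planar_cases():
    assert dihedral([0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]) == pytest.approx(0.0, abs=1e-12)
    assert abs(dihedral([0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0])) == pytest.approx(180.0, abs=1e-12)


def test_dihedral_matches_independent_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        pts = rng.normal(scale=3.0, size=(4, 3))
        try:
            ours = dihedral(*pts)
        except GeometryError:
            continue
        assert ours == pytest.approx(_dihedral_oracle(*pts), abs=1e-6)


def test_dihedral_reversal_identity():
    rng = np.random.default_rng(1)
    for _ in range(25):
        p = rng.normal(size=(4, 3))
        assert dihedral(*p) == pytest.approx(dihedral(*p[::-1]), abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-8.0, 8.0, allow_nan=False), min_size=12, max_size=12),
       st.floats(-179.0, 179.0), st.lists(st.floats(-5.0, 5.0), min_size=3, max_size=3))
def test_dihedral_invariant_under_rigid_motion(vals, angle, shift):
    pts = np.array(vals).reshape(4, 3)
    try:
        base = dihedral(*pts)
    except GeometryError:
        return
    R = rotation_about_axis(np.array([0.3, -0.5, 0.81]), angle)
    moved = (R @ pts.T).T + np.array(shift)
    assert dihedral(*moved) == pytest.approx(base, abs=1e-6)


def test_dihedral_collinear_raises():
    with pytest.raises(GeometryError):
        dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


def test_place_atom_inverts_dihedral():
    a, b, c = np.zeros(3), np.array([1.5, 0, 0]), np.array([1.5, 1.5, 0])
    for phi in (-155.0, -60.0, 0.0, 77.5, 180.0):
        d = place_atom(a, b, c, 1.5, 109.5, phi)
        assert dihedral(a, b, c, d) == pytest.approx(phi, abs=1e-9)
        assert np.linalg.norm(d - c) == pytest.approx(1.5, abs=1e-12)


# ---------------------------------------------------------------------------
# Superposition

def _random_structure(rng, n=12):
    residues = []
    for i in range(n):
        xyz = rng.normal(scale=5.0, size=3)
        residues.append(Residue("A", i + 1, "GLY", [
            Atom("N", "N", xyz), Atom("CA", "C", xyz + [1.4, 0, 0]),
            Atom("C", "C", xyz + [2.0, 1.2, 0]), Atom("O", "O", xyz + [1.6, 2.3, 0])]))
    return ProteinStructure(residues, "rand")


def test_superpose_self_is_identity(easy_system):
    sup = superpose(easy_system.receptor, easy_system.receptor, "CA")
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(sup.translation, 0.0, atol=1e-9)


def test_superpose_recovers_rigid_motion():
    rng = np.random.default_rng(7)
    ref = _random_structure(rng)
    mob = ref.copy()
    R = rotation_about_axis([0, 0, 1.0], 90.0)
    mob.transform(R, np.array([1.0, 2.0, 3.0]))
    sup = superpose(mob, ref, "CA")
    assert sup.rmsd < 1e-6
    _, ref_ca = ref.ca_coords()
    _, mob_ca = mob.ca_coords()
    assert np.allclose(sup.apply(mob_ca), ref_ca, atol=1e-6)


def test_superpose_noisy_rmsd_bounds():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        ref = _random_structure(rng)
        mob = ref.copy()
        for _, a in mob.iter_atoms():
            a.coords = a.coords + rng.normal(scale=0.1, size=3)
        sup = superpose(mob, ref, "CA")
        assert 0.05 <= sup.rmsd <= 0.35


def test_superpose_invariant_to_premotion():
    rng = np.random.default_rng(3)
    ref = _random_structure(rng)
    mob = ref.copy()
    for _, a in mob.iter_atoms():
        a.coords = a.coords + rng.normal(scale=0.2, size=3)
    base = superpose(mob, ref, "CA").rmsd
    moved = mob.copy()
    moved.transform(rotation_about_axis([1.0, 1.0, 0.0], 35.0), np.array([4.0, -2.0, 9.0]))
    assert superpose(moved, ref, "CA").rmsd == pytest.approx(base, abs=1e-9)


def test_superpose_matches_scipy_oracle():
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(5)
    for _ in range(100):
        P = rng.normal(scale=4.0, size=(10, 3))
        Q = rng.normal(scale=4.0, size=(10, 3))
        R, t, rmsd = kabsch(P, Q)
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        oracle_rmsd = float(np.sqrt(np.mean(np.sum(
            (rot.apply(P - P.mean(0)) - (Q - Q.mean(0))) ** 2, axis=1))))
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)


def test_superpose_degenerate_inputs():
    with pytest.raises(GeometryError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    with pytest.raises(GeometryError):
        kabsch(line, line + 1.0)
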