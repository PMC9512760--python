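"""Protein/ligand structure I/O and geometric primitives.

This module owns the atomic data model used everywhere else: a lightweight
chain/residue/atom hierarchy for receptors (heavy-atom, single-conformer),
a small-molecule graph for ligands, and the geometry kernel (dihedrals,
internal-coordinate atom placement, Kabsch superposition).

Conventions
-----------
* Coordinates are in Angstrom, right-handed frame, no re-centering on read.
* Receptor hydrogens are dropped on read; the model is heavy-atom only.
* Ligand hydrogens are kept if present but excluded from scoring and RMSD.
* Alternate locations: the highest-occupancy conformer is kept (ties break
  to altloc 'A'), so the in-memory model is always single-conformer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
from rdkit import Chem

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "Ligand",
    "WarheadSpec",
    "StructIOError",
    "PDBParseError",
    "GeometryError",
    "VDW_RADII",
    "BACKBONE_ATOMS",
    "read_pdb",
    "write_pdb",
    "read_ligand_sdf",
    "write_ligand_sdf",
    "dihedral",
    "bond_angle",
    "place_atom",
    "rotation_about_axis",
    "rotation_between",
    "kabsch",
    "superpose",
    "Superposition",
]


class StructIOError(Exception):
    """Base error for structure I/O and geometry."""


class PDBParseError(StructIOError):
    pass


class GeometryError(StructIOError):
    pass


# Bondi-style van der Waals radii (Angstrom), element-keyed.  Metals get
# effective radii adequate for clash detection of rigid cofactors.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "ZN": 1.39, "MN": 1.61, "FE": 1.52, "NA": 2.27, "K": 2.75,
    "CA": 2.31, "CU": 1.40, "NI": 1.63, "CO": 1.53, "SI": 2.10,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass
class Atom:
    """One heavy atom (PDB naming convention for receptors)."""

    name: str
    element: str
    coords: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructIOError(f"atom {self.name}: coords must be a finite 3-vector")
        el = self.element.upper()
        if el not in VDW_RADII:
            raise StructIOError(f"atom {self.name}: unknown element {self.element!r}")
        self.element = el

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII[self.element]

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.serial)


@dataclass
class Residue:
    """One residue: author numbering, ordered atom list, and a role tag.

    role is one of {"normal", "flexible", "blocking", "reactive", "het"};
    the docking pipeline uses roles only as annotations — the authoritative
    residue classification lives in BindingSiteSpec.
    """

    chain_id: str
    resnum: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    role: str = "normal"

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.resnum)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def require(self, name: str) -> Atom:
        a = self.atom(name)
        if a is None:
            raise StructIOError(f"residue {self.chain_id}:{self.resnum} {self.name} lacks atom {name}")
        return a

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_backbone and a.element != "H"]

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.resnum, self.name,
                       [a.copy() for a in self.atoms], self.icode, self.role)


class ProteinStructure:
    """Ordered residues + rigid heteroatom groups, indexed by (chain, resnum)."""

    def __init__(self, residues: list[Residue], source_id: str = "",
                 heteroatoms: list[Residue] | None = None):
        self.residues = residues
        self.source_id = source_id
        self.heteroatoms = heteroatoms or []
        self._reindex()

    def _reindex(self) -> None:
        self._index: dict[tuple[str, int, str], Residue] = {}
        for r in self.residues:
            k = (r.chain_id, r.resnum, r.icode)
            if k in self._index:
                raise StructIOError(f"duplicate residue key {k}")
            self._index[k] = r

    def get(self, chain_id: str, resnum: int, icode: str = "") -> Residue:
        try:
            return self._index[(chain_id, resnum, icode)]
        except KeyError:
            raise KeyError(f"no residue {chain_id}:{resnum}{icode} in {self.source_id or 'structure'}") from None

    def has(self, chain_id: str, resnum: int, icode: str = "") -> bool:
        return (chain_id, resnum, icode) in self._index

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def iter_atoms(self, include_het: bool = True):
        for r in self.residues:
            for a in r.atoms:
                yield r, a
        if include_het:
            for r in self.heteroatoms:
                for a in r.atoms:
                    yield r, a

    def ca_coords(self) -> tuple[list[tuple[str, int]], np.ndarray]:
        keys, xyz = [], []
        for r in self.residues:
            ca = r.atom("CA")
            if ca is not None:
                keys.append(r.key)
                xyz.append(ca.coords)
        return keys, np.array(xyz)

    def copy(self) -> "ProteinStructure":
        return ProteinStructure([r.copy() for r in self.residues], self.source_id,
                                [r.copy() for r in self.heteroatoms])

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply x -> R x + t in place to every atom (polymer and het)."""
        for _, a in self.iter_atoms():
            a.coords = rotation @ a.coords + translation


# ---------------------------------------------------------------------------
# PDB I/O

def read_pdb(path: str | Path) -> ProteinStructure:
    """Read a PDB file into the heavy-atom single-conformer data model.

    Altloc policy: keep the highest-occupancy alternate (ties -> altloc 'A').
    HETATM groups (ions, nucleotides, waters) are routed to ``heteroatoms``.
    Hydrogens are dropped.  Raises :class:`PDBParseError` for a missing file,
    a file with no ATOM records, or text gemmi cannot parse.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    residues: list[Residue] = []
    het: list[Residue] = []
    n_polymer_atoms = 0
    if len(st) > 0:
        for chain in st[0]:
            for gres in chain:
                picked = _pick_altlocs(gres, f"{chain.name}:{gres.seqid.num}")
                atoms = []
                for ga in picked:
                    el = ga.element.name.upper()
                    if el == "H" or el == "D":
                        continue
                    if el not in VDW_RADII:
                        log.warning("skipping atom %s with unknown element %r", ga.name, el)
                        continue
                    atoms.append(Atom(ga.name, el, np.array([ga.pos.x, ga.pos.y, ga.pos.z]), ga.serial))
                if not atoms:
                    continue
                res = Residue(chain.name, gres.seqid.num, gres.name, atoms,
                              gres.seqid.icode.strip(), "normal")
                if gres.het_flag == "H" or gres.name in _WATER_NAMES:
                    res.role = "het"
                    het.append(res)
                else:
                    n_polymer_atoms += len(atoms)
                    if res.atom("O") is None and res.name not in ("HOH",):
                        log.warning("residue %s:%d %s missing backbone O", res.chain_id, res.resnum, res.name)
                    residues.append(res)
    if n_polymer_atoms == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    return ProteinStructure(residues, source_id=path.stem, heteroatoms=het)


def _pick_altlocs(gres, label: str):
    """Collapse alternate locations to the highest-occupancy one per atom name."""
    by_name: dict[str, list] = {}
    for ga in gres:
        by_name.setdefault(ga.name, []).append(ga)
    picked = []
    warned = False
    for name, alts in by_name.items():
        if len(alts) == 1:
            picked.append(alts[0])
            continue
        if not warned:
            log.warning("residue %s: %d altlocs for some atoms; keeping highest occupancy", label, len(alts))
            warned = True
        # highest occupancy wins; ties break to altloc 'A' then lexical order
        best = sorted(alts, key=lambda a: (-a.occ, a.altloc or "A"))[0]
        picked.append(best)
    picked.sort(key=lambda a: a.serial)
    return picked


def _pdb_atom_line(record: str, serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    return (f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{res.name:>3s} "
            f"{res.chain_id:1s}{res.resnum:>4d}{res.icode or '':1s}   "
            f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}")


def write_pdb(structure: ProteinStructure, path: str | Path, start_serial: int = 1) -> None:
    """Write PDB v3.3 fixed-column ATOM/HETATM/TER records.

    Within each chain, polymer ATOM records come first, then that chain's
    HETATM groups.  Serials above 99999 wrap with a warning (column width).
    """
    if len(structure) == 0:
        raise StructIOError("refusing to write an empty structure")
    lines: list[str] = []
    serial = start_serial
    wrapped = False

    def next_serial() -> int:
        nonlocal serial, wrapped
        s = serial
        if s > 99999:
            if not wrapped:
                log.warning("atom serial exceeded 99999; wrapping (PDB column width)")
                wrapped = True
            s = ((s - 1) % 99999) + 1
        serial += 1
        return s

    het_by_chain: dict[str, list[Residue]] = {}
    for hr in structure.heteroatoms:
        het_by_chain.setdefault(hr.chain_id, []).append(hr)

    for chain_id in structure.chains:
        last_res = None
        for res in structure.residues:
            if res.chain_id != chain_id:
                continue
            for a in res.atoms:
                lines.append(_pdb_atom_line("ATOM", next_serial(), a, res))
            last_res = res
        if last_res is not None:
            lines.append(f"{'TER':<6s}{next_serial():>5d}      {last_res.name:>3s} "
                         f"{last_res.chain_id:1s}{last_res.resnum:>4d}{last_res.icode or '':1s}")
        for hres in het_by_chain.pop(chain_id, []):
            for a in hres.atoms:
                lines.append(_pdb_atom_line("HETATM", next_serial(), a, hres))
    # het groups on chains with no polymer residues
    for hlist in het_by_chain.values():
        for hres in hlist:
            for a in hres.atoms:
                lines.append(_pdb_atom_line("HETATM", next_serial(), a, hres))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ligands

@dataclass
class WarheadSpec:
    """Covalent attachment contract for a Michael-acceptor warhead.

    ``reactive_ligand_atom`` is the ligand carbon that bonds to the cysteine
    SG after addition (the olefin beta-carbon for acrylamides).  Geometry
    targets describe the nascent thioether: S-C bond length and the CB-SG-C
    angle at sulfur.  ``modified_bonds`` lists bond-order changes on adduct
    formation, e.g. the acrylamide C=C reducing to a single bond.
    """

    reactive_ligand_atom: int
    bond_length_target: float = 1.81
    bond_length_tol: float = 0.30
    bond_angle_target: float = 100.0
    bond_angle_tol: float = 20.0
    modified_bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reactive_ligand_atom < 0:
            raise StructIOError("reactive_ligand_atom must be a valid atom index")
        if min(self.bond_length_tol, self.bond_angle_tol) <= 0:
            raise StructIOError("warhead tolerances must be strictly positive")


@dataclass
class Ligand:
    """Small-molecule graph with 3D coordinates and rotatable torsions."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]
    rotatable_torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    name: str = "LIG"
    props: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.atoms:
            g = self.graph()
            if not nx.is_connected(g):
                raise StructIOError(f"ligand {self.name}: bond graph is not connected")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        for a, p in zip(self.atoms, np.asarray(xyz, dtype=float)):
            a.coords = p.copy()

    def copy(self) -> "Ligand":
        return Ligand([a.copy() for a in self.atoms], list(self.bonds),
                      list(self.rotatable_torsions), self.name, dict(self.props))

    # -- RDKit bridges ------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str | None = None) -> "Ligand":
        conf = mol.GetConformer()
        atoms = []
        for at in mol.GetAtoms():
            p = conf.GetAtomPosition(at.GetIdx())
            atoms.append(Atom(f"{at.GetSymbol().upper()}{at.GetIdx() + 1}",
                              at.GetSymbol().upper(), np.array([p.x, p.y, p.z])))
        bonds = []
        for b in mol.GetBonds():
            if b.GetBondType() == Chem.BondType.AROMATIC:
                order = 4  # V2000 aromatic bond code
            else:
                order = int(round(b.GetBondTypeAsDouble())) or 1
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        lig = cls(atoms, bonds, [], name or (mol.GetProp("_Name") if mol.HasProp("_Name") else "LIG"),
                  dict(mol.GetPropsAsDict()))
        lig.rotatable_torsions = _detect_rotatable_torsions(lig)
        return lig

    def to_rdkit(self) -> Chem.Mol:
        em = Chem.RWMol()
        for a in self.atoms:
            em.AddAtom(Chem.Atom(a.element.capitalize()))
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}
        for i, j, order in self.bonds:
            em.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
            if order == 4:
                em.GetAtomWithIdx(i).SetIsAromatic(True)
                em.GetAtomWithIdx(j).SetIsAromatic(True)
                em.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
        mol = em.GetMol()
        conf = Chem.Conformer(len(self.atoms))
        for i, a in enumerate(self.atoms):
            conf.SetAtomPosition(i, tuple(float(x) for x in a.coords))
        mol.AddConformer(conf)
        mol.SetProp("_Name", self.name)
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # valence quirks in adduct forms are tolerable
            Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
        return mol


def _detect_rotatable_torsions(lig: Ligand) -> list[tuple[int, int, int, int]]:
    """Rotatable = single, acyclic bond with heavy-atom degree >= 2 on both ends."""
    g = lig.graph()
    heavy = set(lig.heavy_indices())
    hg = g.subgraph(heavy)
    ring_edges = set()
    for cycle in nx.cycle_basis(hg):
        for i in range(len(cycle)):
            e = frozenset((cycle[i], cycle[(i + 1) % len(cycle)]))
            ring_edges.add(e)
    torsions = []
    for i, j, order in lig.bonds:
        if order != 1 or i not in heavy or j not in heavy:
            continue
        if frozenset((i, j)) in ring_edges:
            continue
        ni = [n for n in hg.neighbors(i) if n != j]
        nj = [n for n in hg.neighbors(j) if n != i]
        if not ni or not nj:
            continue  # terminal bond
        torsions.append((min(ni), i, j, min(nj)))
    return torsions


def read_ligand_sdf(path: str | Path) -> Ligand:
    """Read the first record of a V2000 SDF/MOL file with 3D coordinates."""
    path = Path(path)
    if not path.exists():
        raise StructIOError(f"no such file: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise StructIOError(f"{path}: no parsable molecule")
    if mol.GetNumConformers() == 0:
        raise StructIOError(f"{path}: molecule has no coordinates")
    conf = mol.GetConformer()
    zs = [conf.GetAtomPosition(i).z for i in range(mol.GetNumAtoms())]
    if not conf.Is3D() and all(abs(z) < 1e-9 for z in zs):
        raise StructIOError(f"{path}: 2D-only coordinates; provide a 3D conformer")
    return Ligand.from_rdkit(mol, name=path.stem if not mol.HasProp("_Name") or not mol.GetProp("_Name") else None)


def write_ligand_sdf(ligands: Ligand | list[Ligand], path: str | Path,
                     props: list[dict] | None = None) -> None:
    """Write one or more ligands (poses) as a multi-record V2000 SDF."""
    if isinstance(ligands, Ligand):
        ligands = [ligands]
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for k, lig in enumerate(ligands):
            mol = lig.to_rdkit()
            tags = dict(lig.props)
            if props is not None:
                tags.update(props[k])
            for key, val in tags.items():
                mol.SetProp(str(key), str(val))
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Geometry kernel

def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, range (-180, 180].

    Raises :class:`GeometryError` when three consecutive points are collinear
    (the torsion is undefined).  Scalar math on purpose — this sits in the
    inner loop of side-chain construction and refinement.
    """
    a1, a2, a3 = float(p1[0]), float(p1[1]), float(p1[2])
    b1x, b1y, b1z = float(p2[0]) - a1, float(p2[1]) - a2, float(p2[2]) - a3
    c1, c2, c3 = float(p3[0]), float(p3[1]), float(p3[2])
    b2x, b2y, b2z = c1 - float(p2[0]), c2 - float(p2[1]), c3 - float(p2[2])
    b3x, b3y, b3z = float(p4[0]) - c1, float(p4[1]) - c2, float(p4[2]) - c3
    # n1 = b1 x b2 ; n2 = b2 x b3
    n1x, n1y, n1z = (b1y * b2z - b1z * b2y, b1z * b2x - b1x * b2z, b1x * b2y - b1y * b2x)
    n2x, n2y, n2z = (b2y * b3z - b2z * b3y, b2z * b3x - b2x * b3z, b2x * b3y - b2y * b3x)
    l1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    l2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    l3 = math.sqrt(b3x * b3x + b3y * b3y + b3z * b3z)
    nn1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    nn2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    if nn1 < 1e-8 * max(l1 * l2, 1e-12) or nn2 < 1e-8 * max(l2 * l3, 1e-12):
        raise GeometryError("undefined dihedral: collinear points")
    ib2 = 1.0 / l2
    m1x, m1y, m1z = (n1y * b2z - n1z * b2y, n1z * b2x - n1x * b2z, n1x * b2y - n1y * b2x)
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = -(m1x * n2x + m1y * n2y + m1z * n2z) * ib2
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1x, v1y, v1z = float(a[0]) - float(b[0]), float(a[1]) - float(b[1]), float(a[2]) - float(b[2])
    v2x, v2y, v2z = float(c[0]) - float(b[0]), float(c[1]) - float(b[1]), float(c[2]) - float(b[2])
    n1 = math.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
    n2 = math.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
    cosang = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def place_atom(a, b, c, r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom D from internal coordinates (NeRF construction).

    D is at distance ``r`` from c, with angle(b, c, D) = ``theta`` degrees and
    dihedral(a, b, c, D) = ``phi`` degrees.
    """
    th = math.radians(theta)
    ph = math.radians(phi)
    bcx, bcy, bcz = float(c[0]) - float(b[0]), float(c[1]) - float(b[1]), float(c[2]) - float(b[2])
    lbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / lbc, bcy / lbc, bcz / lbc
    abx, aby, abz = float(b[0]) - float(a[0]), float(b[1]) - float(a[1]), float(b[2]) - float(a[2])
    nx, ny, nz = (aby * bcz - abz * bcy, abz * bcx - abx * bcz, abx * bcy - aby * bcx)
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        raise GeometryError("cannot place atom: reference points collinear")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx, my, mz = (ny * bcz - nz * bcy, nz * bcx - nx * bcz, nx * bcy - ny * bcx)
    d0 = -r * math.cos(th)
    d1 = r * math.sin(th) * math.cos(ph)
    d2 = r * math.sin(th) * math.sin(ph)
    return np.array([float(c[0]) + d0 * bcx + d1 * mx + d2 * nx,
                     float(c[1]) + d0 * bcy + d1 * my + d2 * ny,
                     float(c[2]) + d0 * bcz + d1 * mz + d2 * nz])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    t = math.radians(angle_deg)
    ct, st = math.cos(t), math.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return ct * np.eye(3) + st * K + (1 - ct) * np.outer(u, u)


def rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction v_from to direction v_to."""
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1.0 / (1.0 + c))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (rotation, translation, fit RMSD).

    Returns (R, t) such that ``R @ x + t`` maps mobile points onto the
    reference in the least-squares sense.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("superposition needs matched Nx3 coordinate arrays")
    if len(P) < 3:
        raise GeometryError("superposition needs at least 3 paired atoms")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise GeometryError("superposition undefined: all paired atoms collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (self.rotation @ np.asarray(coords, dtype=float).T).T + self.translation


def superpose(mobile: ProteinStructure, reference: ProteinStructure,
              atom_selector: str = "CA") -> Superposition:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    ``atom_selector`` is an atom name (paired on shared (chain, resnum)
    residues that carry it) or a list of ((chain, resnum), atom_name) pairs.
    """
    if isinstance(atom_selector, str):
        name = atom_selector
        pairs = []
        for r in mobile.residues:
            if reference.has(r.chain_id, r.resnum, r.icode):
                rr = reference.get(r.chain_id, r.resnum, r.icode)
                am, ar = r.atom(name), rr.atom(name)
                if am is not None and ar is not None:
                    pairs.append((am.coords, ar.coords))
    else:
        pairs = []
        for (key, name) in atom_selector:
            am = mobile.get(*key).require(name)
            ar = reference.get(*key).require(name)
            pairs.append((am.coords, ar.coords))
    if len(pairs) < 3:
        raise GeometryError(f"superposition needs >=3 paired atoms, found {len(pairs)}")
    P = np.array([p for p, _ in pairs])
    Q = np.array([q for _, q in pairs])
    R, t, rmsd = kabsch(P, Q)
    return Superposition(R, t, rmsd)
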