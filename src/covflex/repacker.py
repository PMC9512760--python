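"""Side-chain construction, rotamer library, and binding-site repacking.

After covalent pose generation the flexible binding-site residues are
re-packed around each candidate pose: a combinatorial search over discrete
rotamers (weight-biased multi-start greedy with Metropolis sweeps over
precomputed pair-energy tables) followed by a continuous torsional
refinement (cyclic golden-section line search over each flexible chi and
each ligand rotatable torsion).  The reactive cysteine chi1 is pinned by
the covalent bond and backbone atoms never move.

The shipped rotamer library is a compact backbone-independent set built
from canonical staggered chi combinations (3-9 rotamers per residue type,
mildly non-uniform priors); a richer user library can be loaded from a
plain tab-separated file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._energy import (AtomTable, ScoreParams, combine, ligand_atom_table,
                      pair_terms, protein_atom_table, torsion_penalty)
from .flexprofile import BindingSiteSpec
from .structio import (Atom, GeometryError, Ligand, ProteinStructure, Residue,
                       dihedral, place_atom, rotation_about_axis)

log = logging.getLogger(__name__)

__all__ = [
    "SIDECHAIN_TEMPLATES",
    "NUM_CHI",
    "RotamerLibrary",
    "RepackResult",
    "build_sidechain",
    "measure_chis",
    "repack_site",
    "refine_continuous",
    "default_library",
]


@dataclass(frozen=True)
class _SideAtom:
    name: str
    element: str
    refs: tuple[str, str, str]   # (a, b, c): placed bonded to c
    r: float                     # bond length to c, A
    theta: float                 # angle b-c-new, deg
    chi: int | None              # 1-based chi index, or None for a constant
    offset: float                # deg added to the chi (or the constant itself)


def _sa(name, element, refs, r, theta, chi=None, offset=0.0):
    return _SideAtom(name, element, tuple(refs), r, theta, chi, offset)


# Ideal internal-coordinate templates for side-chain heavy atoms beyond CB.
# Bond lengths/angles are standard ideal values; ring closures are placed by
# planarity (constant dihedrals), adequate for a clash/contact energy model.
SIDECHAIN_TEMPLATES: dict[str, list[_SideAtom]] = {
    "CYS": [_sa("SG", "S", ("N", "CA", "CB"), 1.808, 114.4, 1)],
    "SER": [_sa("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, 1)],
    "THR": [_sa("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, 1),
            _sa("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, 1, -120.0)],
    "VAL": [_sa("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, 1),
            _sa("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, 1, 120.0)],
    "LEU": [_sa("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, 1),
            _sa("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, 2),
            _sa("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, 2, 120.0)],
    "ILE": [_sa("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, 1),
            _sa("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, 1, -120.0),
            _sa("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, 2)],
    "MET": [_sa("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 1),
            _sa("SD", "S", ("CA", "CB", "CG"), 1.807, 112.7, 2),
            _sa("CE", "C", ("CB", "CG", "SD"), 1.789, 100.9, 3)],
    "ASP": [_sa("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 1),
            _sa("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, 2),
            _sa("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, 2, 180.0)],
    "ASN": [_sa("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 1),
            _sa("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, 2),
            _sa("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, 2, 180.0)],
    "GLU": [_sa("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 1),
            _sa("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 2),
            _sa("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, 3),
            _sa("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 3, 180.0)],
    "GLN": [_sa("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 1),
            _sa("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 2),
            _sa("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, 3),
            _sa("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 3, 180.0)],
    "LYS": [_sa("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 1),
            _sa("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 2),
            _sa("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, 3),
            _sa("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, 4)],
    "ARG": [_sa("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 1),
            _sa("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 2),
            _sa("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, 3),
            _sa("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, 4),
            _sa("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, None, 0.0),
            _sa("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, None, 180.0)],
    "HIS": [_sa("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, 1),
            _sa("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, 2),
            _sa("CD2", "C", ("CA", "CB", "CG"), 1.354, 131.0, 2, 180.0),
            _sa("CE1", "C", ("CB", "CG", "ND1"), 1.320, 109.2, None, 180.0),
            _sa("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, None, 180.0)],
    "PHE": [_sa("CG", "C", ("N", "CA", "CB"), 1.500, 113.8, 1),
            _sa("CD1", "C", ("CA", "CB", "CG"), 1.390, 120.7, 2),
            _sa("CD2", "C", ("CA", "CB", "CG"), 1.390, 120.7, 2, 180.0),
            _sa("CE1", "C", ("CB", "CG", "CD1"), 1.390, 120.7, None, 180.0),
            _sa("CE2", "C", ("CB", "CG", "CD2"), 1.390, 120.7, None, 180.0),
            _sa("CZ", "C", ("CG", "CD1", "CE1"), 1.390, 120.0, None, 0.0)],
    "TYR": [_sa("CG", "C", ("N", "CA", "CB"), 1.500, 113.8, 1),
            _sa("CD1", "C", ("CA", "CB", "CG"), 1.390, 120.7, 2),
            _sa("CD2", "C", ("CA", "CB", "CG"), 1.390, 120.7, 2, 180.0),
            _sa("CE1", "C", ("CB", "CG", "CD1"), 1.390, 120.7, None, 180.0),
            _sa("CE2", "C", ("CB", "CG", "CD2"), 1.390, 120.7, None, 180.0),
            _sa("CZ", "C", ("CG", "CD1", "CE1"), 1.390, 120.0, None, 0.0),
            _sa("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, None, 180.0)],
    "TRP": [_sa("CG", "C", ("N", "CA", "CB"), 1.500, 113.8, 1),
            _sa("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, 2),
            _sa("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.7, 2, 180.0),
            _sa("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, None, 180.0),
            _sa("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, None, 180.0),
            _sa("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, None, 0.0),
            _sa("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, None, 180.0),
            _sa("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, None, 180.0),
            _sa("CH2", "C", ("CD2", "CE3", "CZ3"), 1.400, 121.1, None, 0.0)],
    "PRO": [_sa("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, 1),
            _sa("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, 2)],
}

NUM_CHI: dict[str, int] = {
    name: max([sa.chi for sa in atoms if sa.chi is not None], default=0)
    for name, atoms in SIDECHAIN_TEMPLATES.items()
}
NUM_CHI.update({"ALA": 0, "GLY": 0})

# chi-defining quadruples by type, derived from the templates so that
# construction and measurement are exact inverses.
CHI_QUADRUPLES: dict[str, list[tuple[str, str, str, str]]] = {}
for _name, _atoms in SIDECHAIN_TEMPLATES.items():
    quads = []
    for _a in _atoms:
        if _a.chi is not None and abs(_a.offset) < 1e-9:
            quads.append((_a.refs[0], _a.refs[1], _a.refs[2], _a.name))
    CHI_QUADRUPLES[_name] = quads

_CB_LENGTH, _CB_ANGLE, _CB_DIHEDRAL = 1.530, 110.5, 122.7  # C-N-CA-CB improper


def _place_cb(res: Residue) -> np.ndarray:
    n = res.require("N").coords
    ca = res.require("CA").coords
    c = res.require("C").coords
    return place_atom(c, n, ca, _CB_LENGTH, _CB_ANGLE, _CB_DIHEDRAL)


def build_sidechain(residue: Residue, chis: tuple[float, ...]) -> Residue:
    """Rebuild side-chain heavy atoms from ideal internal coordinates.

    The backbone (and CB, if present) is reused as-is; missing CB is placed
    from ideal geometry.  ``chis`` must match the residue type's chi count.
    ALA and GLY are returned unchanged (no chi torsions).
    """
    if not residue.has_backbone:
        raise GeometryError(f"residue {residue.chain_id}:{residue.resnum} lacks backbone")
    n_chi = NUM_CHI.get(residue.name)
    if n_chi is None:
        raise GeometryError(f"no side-chain template for residue type {residue.name!r}")
    if len(chis) != n_chi:
        raise GeometryError(f"{residue.name} takes {n_chi} chi angles, got {len(chis)}")
    out = residue.copy()
    if residue.name in ("ALA", "GLY"):
        return out
    positions: dict[str, np.ndarray] = {a.name: a.coords for a in out.atoms
                                        if a.is_backbone or a.name == "CB"}
    if "CB" not in positions:
        positions["CB"] = _place_cb(out)
    new_atoms = [a for a in out.atoms if a.is_backbone]
    cb = out.atom("CB")
    new_atoms.append(cb if cb is not None else Atom("CB", "C", positions["CB"]))
    for sa in SIDECHAIN_TEMPLATES[residue.name]:
        phi = sa.offset if sa.chi is None else chis[sa.chi - 1] + sa.offset
        try:
            a, b, c = (positions[r] for r in sa.refs)
        except KeyError as exc:
            raise GeometryError(f"missing reference atom {exc} for {sa.name}") from exc
        pos = place_atom(a, b, c, sa.r, sa.theta, phi)
        positions[sa.name] = pos
        new_atoms.append(Atom(sa.name, sa.element, pos))
    out.atoms = new_atoms
    return out


def measure_chis(residue: Residue) -> tuple[float, ...] | None:
    """Measured chi tuple for a residue, or None if atoms are missing."""
    quads = CHI_QUADRUPLES.get(residue.name)
    if quads is None:
        return () if residue.name in ("ALA", "GLY") else None
    chis = []
    for quad in quads:
        atoms = [residue.atom(n) for n in quad]
        if any(a is None for a in atoms):
            return None
        try:
            chis.append(dihedral(*(a.coords for a in atoms)))
        except GeometryError:
            return None
    return tuple(chis)


# ---------------------------------------------------------------------------
# Rotamer library

@dataclass
class RotamerLibrary:
    """Per-type list of (chi tuple, prior weight); weights normalized per type."""

    rotamers: dict[str, list[tuple[tuple[float, ...], float]]]

    def __post_init__(self) -> None:
        for name, entries in self.rotamers.items():
            if not entries:
                raise ValueError(f"rotamer library entry for {name} is empty")
            total = sum(w for _, w in entries)
            self.rotamers[name] = [(tuple(c), w / total) for c, w in entries]

    def for_type(self, resname: str) -> list[tuple[tuple[float, ...], float]]:
        return self.rotamers.get(resname, [])

    def to_file(self, path: str | Path) -> None:
        lines = ["residue_type\tchi1\tchi2\tchi3\tchi4\tweight"]
        for name, entries in sorted(self.rotamers.items()):
            for chis, w in entries:
                padded = list(chis) + [""] * (4 - len(chis))
                lines.append(name + "\t" + "\t".join(str(c) for c in padded) + f"\t{w:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RotamerLibrary":
        rot: dict[str, list[tuple[tuple[float, ...], float]]] = {}
        lines = Path(path).read_text().strip().splitlines()
        for line in lines[1:]:
            parts = line.split("\t")
            name = parts[0]
            chis = tuple(float(p) for p in parts[1:5] if p not in ("", "NA"))
            weight = float(parts[5])
            rot.setdefault(name, []).append((chis, weight))
        return cls(rot)


_CHI1_SET = [(-60.0, 0.40), (180.0, 0.35), (60.0, 0.25)]
_CHI2_SP3 = [(180.0, 0.40), (-60.0, 0.30), (60.0, 0.30)]
_CHI2_AROMATIC = [(90.0, 0.5), (-90.0, 0.5)]
_CHI2_AMIDE = [(-30.0, 0.5), (60.0, 0.5)]


def default_library() -> RotamerLibrary:
    """Compact backbone-independent library from staggered chi combinations."""
    rot: dict[str, list[tuple[tuple[float, ...], float]]] = {}
    for name, n_chi in NUM_CHI.items():
        if n_chi == 0 or name == "PRO":
            continue
        if n_chi == 1:
            rot[name] = [((c,), w) for c, w in _CHI1_SET]
            continue
        if name in ("HIS", "PHE", "TYR", "TRP"):
            chi2_set = _CHI2_AROMATIC
        elif name in ("ASP", "ASN"):
            chi2_set = _CHI2_AMIDE
        else:
            chi2_set = _CHI2_SP3
        extras = {"MET": (180.0,), "GLU": (0.0,), "GLN": (0.0,),
                  "LYS": (180.0, 180.0), "ARG": (180.0, 180.0)}.get(name, ())
        entries = []
        for c1, w1 in _CHI1_SET:
            for c2, w2 in chi2_set:
                chis = (c1, c2) + extras
                entries.append((chis[:n_chi], w1 * w2))
        rot[name] = entries
    return RotamerLibrary(rot)


# ---------------------------------------------------------------------------
# Repacking

@dataclass
class RepackResult:
    structure: ProteinStructure
    energy_before: float
    energy_after: float
    moved_residues: list[dict]
    n_sweeps: int
    ligand: Ligand | None = None


def _sidechain_table(residue: Residue) -> AtomTable:
    """AtomTable over side-chain atoms beyond CB.

    When the side chain matches its template, each atom's hydrogen-bond base
    is its template parent — much cheaper than the generic nearest-neighbour
    search and identical in effect for template-built side chains.
    """
    side = [a for a in residue.sidechain_atoms() if a.name != "CB"]
    if not side:
        return AtomTable.empty()
    tmpl = SIDECHAIN_TEMPLATES.get(residue.name)
    pos = {a.name: a.coords for a in residue.atoms}
    if tmpl is None or "CB" not in pos or not all(sa.name in pos for sa in tmpl):
        return protein_atom_table([(residue, a) for a in side])
    from ._energy import _PROTEIN_ACCEPTORS_SIDE, _PROTEIN_DONORS_SIDE
    parent = {sa.name: sa.refs[2] for sa in tmpl}
    coords = np.empty((len(side), 3))
    radii = np.empty(len(side))
    donor = np.zeros(len(side), bool)
    acceptor = np.zeros(len(side), bool)
    base = np.empty((len(side), 3))
    labels = []
    for i, a in enumerate(side):
        coords[i] = a.coords
        radii[i] = a.vdw_radius
        donor[i] = (residue.name, a.name) in _PROTEIN_DONORS_SIDE
        acceptor[i] = (residue.name, a.name) in _PROTEIN_ACCEPTORS_SIDE
        base[i] = pos[parent[a.name]]
        labels.append((residue.key, a.name))
    return AtomTable(coords, radii, donor, acceptor, base, labels)


def _repackable_keys(receptor: ProteinStructure, site: BindingSiteSpec) -> list[tuple[str, int]]:
    keys = []
    for key in site.flexible_residues:
        if key == site.reactive_residue or not receptor.has(*key):
            continue
        res = receptor.get(*key)
        if res.name in ("ALA", "GLY", "PRO") or res.name not in SIDECHAIN_TEMPLATES:
            continue
        if not res.has_backbone:
            log.warning("flexible residue %s:%s lacks backbone; skipped", *key)
            continue
        keys.append(key)
    return keys


def _rigid_context_table(receptor: ProteinStructure, flex_keys: list[tuple[str, int]],
                         center: np.ndarray | None, cutoff: float) -> AtomTable:
    """Receptor atoms that do not move during repacking.

    Flexible side chains beyond CB are excluded; backbones, CBs, non-site
    residues, and non-water heteroatom groups are all rigid context.
    """
    flex = set(flex_keys)
    pairs = []
    for res in receptor.residues:
        movable = res.key in flex
        for a in res.heavy_atoms():
            if movable and not a.is_backbone and a.name != "CB":
                continue
            if center is not None and np.linalg.norm(a.coords - center) > cutoff:
                continue
            pairs.append((res, a))
    for het in receptor.heteroatoms:
        if het.name in ("HOH", "WAT", "DOD"):
            continue
        for a in het.heavy_atoms():
            if center is not None and np.linalg.norm(a.coords - center) > cutoff:
                continue
            pairs.append((het, a))
    return protein_atom_table(pairs)


def _system_energy(flex_tables: list[AtomTable], lig_table: AtomTable,
                   rigid: AtomTable, lig_tors: list[float], params: ScoreParams,
                   lig_rigid_exclude: np.ndarray | None = None) -> float:
    e = 0.0
    rep, attr, hb = pair_terms(lig_table, rigid, params, exclude=lig_rigid_exclude)
    e += combine(rep, attr, hb, torsion_penalty(lig_tors), params)
    for i, ft in enumerate(flex_tables):
        rep, attr, hb = pair_terms(ft, rigid, params)
        e += combine(rep, attr, hb, 0.0, params)
        rep, attr, hb = pair_terms(ft, lig_table, params)
        e += combine(rep, attr, hb, 0.0, params)
        for jt in flex_tables[i + 1:]:
            rep, attr, hb = pair_terms(ft, jt, params)
            e += combine(rep, attr, hb, 0.0, params)
    return e


@dataclass
class RepackCache:
    """Pose-independent tables shared by every repack of one docking job.

    Rotamer side-chain coordinates, rotamer-rotamer pair energies, and
    rotamer-vs-rigid-context energies depend only on the receptor backbone
    and the non-flexible atoms, so they are computed once per job.  The
    reactive cysteine SG (which changes rotamer per pose) and the ligand
    are the only per-pose contributions.
    """

    flex_keys: list[tuple[str, int]]
    cand_tables: list[list[AtomTable]]
    cand_chis: list[list[tuple[float, ...] | None]]
    cand_weights: list[np.ndarray]
    e_pair: dict[tuple[int, int], list[list[float]]]
    e_rigid_base: list[list[float]]
    rigid_nocys: AtomTable
    center: np.ndarray
    cutoff: float


def build_repack_cache(receptor: ProteinStructure, site: BindingSiteSpec,
                       library: RotamerLibrary, params: ScoreParams,
                       center: np.ndarray, cutoff: float) -> RepackCache:
    flex_keys = _repackable_keys(receptor, site)
    # exclude the reactive side chain beyond CB from the shared context; the
    # per-pose SG is appended later
    rigid_nocys = _rigid_context_table(
        receptor, flex_keys + [site.reactive_residue], center, cutoff)
    cand_tables: list[list[AtomTable]] = []
    cand_chis: list[list[tuple[float, ...] | None]] = []
    cand_weights: list[np.ndarray] = []
    for key in flex_keys:
        res = receptor.get(*key)
        tables, chis_list, weights = [], [], []
        current = measure_chis(res)
        if current is not None and len(res.sidechain_atoms()) > 1:
            tables.append(_sidechain_table(res))
            chis_list.append(None)  # marker: keep existing atoms
            weights.append(0.1)
        for chis, w in library.for_type(res.name):
            built = build_sidechain(res, chis)
            tables.append(_sidechain_table(built))
            chis_list.append(chis)
            weights.append(w)
        cand_tables.append(tables)
        cand_chis.append(chis_list)
        cand_weights.append(np.array(weights) / sum(weights))
    e_rigid_base = []
    for tables in cand_tables:
        row = []
        for t in tables:
            rep, attr, hb = pair_terms(t, rigid_nocys, params)
            row.append(combine(rep, attr, hb, 0.0, params))
        e_rigid_base.append(row)
    e_pair: dict[tuple[int, int], list[list[float]]] = {}
    n_res = len(flex_keys)
    for i in range(n_res):
        for j in range(i + 1, n_res):
            mat = []
            for ti in cand_tables[i]:
                rowv = []
                for tj in cand_tables[j]:
                    rep, attr, hb = pair_terms(ti, tj, params)
                    rowv.append(combine(rep, attr, hb, 0.0, params))
                mat.append(rowv)
            e_pair[(i, j)] = mat
    return RepackCache(flex_keys, cand_tables, cand_chis, cand_weights,
                       e_pair, e_rigid_base, rigid_nocys, center, cutoff)


def _reactive_sg_table(receptor: ProteinStructure, site: BindingSiteSpec) -> AtomTable:
    if not receptor.has(*site.reactive_residue):
        return AtomTable.empty()
    res = receptor.get(*site.reactive_residue)
    pairs = [(res, a) for a in res.heavy_atoms()
             if not a.is_backbone and a.name != "CB"]
    return protein_atom_table(pairs)


def repack_site(receptor: ProteinStructure, pose, site: BindingSiteSpec,
                library: RotamerLibrary | None = None,
                params: ScoreParams | None = None,
                seed: int = 0,
                refine: bool = True,
                n_starts: int = 5,
                n_sweeps: int = 200,
                temperature: float = 1.0,
                context_cutoff: float = 18.0,
                cache: RepackCache | None = None,
                copy_receptor: bool = True) -> RepackResult:
    """Re-pack flexible side chains around a covalent pose and refine.

    ``pose`` is any object with ``ligand`` (a :class:`Ligand` positioned in
    the receptor frame) and optional ``torsion_values``/``spin_axis``
    attributes (see dockcore).  The search is a weight-biased multi-start
    greedy pass followed by Metropolis sweeps over precomputed pair-energy
    tables; the current side-chain conformation is always a member of the
    search space, so ``energy_after <= energy_before`` holds on every call.
    Deterministic given ``seed``.
    """
    library = library or default_library()
    params = params or ScoreParams()
    rng = np.random.default_rng(seed)
    work = receptor.copy() if copy_receptor else receptor
    ligand = pose.ligand.copy()
    lig_table = ligand_atom_table(ligand)
    center = lig_table.coords.mean(axis=0)

    if cache is None:
        cache = build_repack_cache(work, site, library, params, center, context_cutoff)
    flex_keys = cache.flex_keys
    n_res = len(flex_keys)

    sg_table = _reactive_sg_table(work, site)
    rigid_full = AtomTable.concatenate([cache.rigid_nocys, sg_table])
    lig_excl = _covalent_exclusion_mask(ligand, work, site, rigid_full)

    lig_tors_values = list(getattr(pose, "torsion_values", ()) or ())
    rep, attr, hb = pair_terms(lig_table, rigid_full, params, exclude=lig_excl)
    e_const = combine(rep, attr, hb, torsion_penalty(lig_tors_values), params)

    # per-pose single-body energies: shared rigid part + SG + ligand
    e_single: list[list[float]] = []
    for i, tables in enumerate(cache.cand_tables):
        row = []
        for r, t in enumerate(tables):
            e = cache.e_rigid_base[i][r]
            if len(sg_table):
                r1, a1, h1 = pair_terms(t, sg_table, params)
                e += combine(r1, a1, h1, 0.0, params)
            r2, a2, h2 = pair_terms(t, lig_table, params)
            e += combine(r2, a2, h2, 0.0, params)
            row.append(e)
        e_single.append(row)
    e_pair = cache.e_pair
    cand_weights = cache.cand_weights

    def assignment_energy(assign: list[int]) -> float:
        e = e_const
        for i in range(n_res):
            e += e_single[i][assign[i]]
            for j in range(i + 1, n_res):
                e += e_pair[(i, j)][assign[i]][assign[j]]
        return e

    current_assign = [0] * n_res  # index 0 = input conformation when available
    energy_before = assignment_energy(current_assign)

    def greedy(assign: list[int]) -> list[int]:
        assign = list(assign)
        for _ in range(10):
            changed = False
            for i in range(n_res):
                best_r, best_e = assign[i], None
                for r in range(len(e_single[i])):
                    e = e_single[i][r]
                    for j in range(n_res):
                        if j == i:
                            continue
                        a, b = (i, j) if i < j else (j, i)
                        m = e_pair[(a, b)]
                        e += m[r][assign[j]] if i < j else m[assign[j]][r]
                    if best_e is None or e < best_e - 1e-12:
                        best_e, best_r = e, r
                if best_r != assign[i]:
                    assign[i] = best_r
                    changed = True
            if not changed:
                break
        return assign

    best_assign = list(current_assign)
    best_energy = energy_before
    total_sweeps = 0
    import bisect
    cumw = [list(np.cumsum(w)) for w in cand_weights]
    uniform = rng.random

    def sample(i: int) -> int:
        return min(bisect.bisect_left(cumw[i], uniform()), len(cumw[i]) - 1)

    if n_res > 0:
        for start in range(n_starts):
            if start == 0:
                assign = list(current_assign)
            else:
                assign = [sample(i) for i in range(n_res)]
            assign = greedy(assign)
            e_cur = assignment_energy(assign)
            if e_cur < best_energy:
                best_energy, best_assign = e_cur, list(assign)
            for _ in range(n_sweeps):
                total_sweeps += 1
                for i in range(n_res):
                    r_new = sample(i)
                    r_old = assign[i]
                    if r_new == r_old:
                        continue
                    de = e_single[i][r_new] - e_single[i][r_old]
                    for j in range(n_res):
                        if j == i:
                            continue
                        a, b = (i, j) if i < j else (j, i)
                        m = e_pair[(a, b)]
                        if i < j:
                            de += m[r_new][assign[j]] - m[r_old][assign[j]]
                        else:
                            de += m[assign[j]][r_new] - m[assign[j]][r_old]
                    if de <= 0 or rng.random() < math.exp(-de / temperature):
                        assign[i] = r_new
                        e_cur += de
                        if e_cur < best_energy - 1e-12:
                            best_energy, best_assign = e_cur, list(assign)

    # apply the winning rotamers
    moved = []
    for i, key in enumerate(flex_keys):
        res = work.get(*key)
        chis = cache.cand_chis[i][best_assign[i]]
        old_chis = measure_chis(res)
        if chis is not None:
            rebuilt = build_sidechain(res, chis)
            res.atoms = rebuilt.atoms
        new_chis = measure_chis(res)
        if old_chis is not None and new_chis is not None and old_chis != new_chis:
            moved.append({"residue": f"{key[0]}:{key[1]}", "name": res.name,
                          "chi_before": [round(c, 1) for c in old_chis],
                          "chi_after": [round(c, 1) for c in new_chis]})

    energy_after = best_energy
    if refine:
        work, ligand, energy_after = refine_continuous(
            work, pose, site, params, structure=work, ligand=ligand,
            context_cutoff=context_cutoff)
        energy_after = min(energy_after, best_energy)

    return RepackResult(work, energy_before, energy_after, moved, total_sweeps, ligand)


def _covalent_exclusion_mask(ligand: Ligand, receptor: ProteinStructure,
                             site: BindingSiteSpec, rigid: AtomTable) -> np.ndarray | None:
    """Mask ligand/receptor pairs across the covalent attachment (1-2/1-3)."""
    reactive_idx = ligand.props.get("reactive_atom")
    if reactive_idx is None or not receptor.has(*site.reactive_residue):
        return None
    reactive_idx = int(reactive_idx)
    import networkx as nx
    g = ligand.graph()
    dist = nx.single_source_shortest_path_length(g, reactive_idx, cutoff=2)
    heavy = ligand.heavy_indices()
    lig_near1 = np.array([dist.get(i, 99) <= 1 for i in heavy])
    lig_near2 = np.array([dist.get(i, 99) <= 2 for i in heavy])
    mask = np.zeros((len(heavy), len(rigid)), bool)
    key = site.reactive_residue
    for col, (rkey, aname) in enumerate(rigid.labels):
        if rkey == key and aname == "SG":
            mask[lig_near2, col] = True
        elif rkey == key and aname == "CB":
            mask[lig_near1, col] = True
    return mask if mask.any() else None


def set_ligand_torsion(lig: Ligand, tq: tuple[int, int, int, int],
                       moving: list[int], target_deg: float) -> None:
    """Rotate ``moving`` atoms about the b-c bond so dihedral(tq) == target."""
    b, c = tq[1], tq[2]
    axis = lig.atoms[c].coords - lig.atoms[b].coords
    pivot = lig.atoms[b].coords.copy()

    def apply(delta: float) -> None:
        R = rotation_about_axis(axis, delta)
        for m in moving:
            lig.atoms[m].coords = pivot + R @ (lig.atoms[m].coords - pivot)

    cur = dihedral(*(lig.atoms[i].coords for i in tq))
    delta = ((target_deg - cur + 180.0) % 360.0) - 180.0
    apply(delta)
    new = dihedral(*(lig.atoms[i].coords for i in tq))
    err = ((target_deg - new + 180.0) % 360.0) - 180.0
    if abs(err) > 1e-6:  # rotation sense depends on which side moves
        apply(-2.0 * delta)


def refine_continuous(receptor: ProteinStructure, pose, site: BindingSiteSpec,
                      params: ScoreParams | None = None,
                      window: float = 15.0, cycles: int = 2,
                      structure: ProteinStructure | None = None,
                      ligand: Ligand | None = None,
                      context_cutoff: float = 18.0,
                      ) -> tuple[ProteinStructure, Ligand, float]:
    """Cyclic golden-section torsional refinement; energy never increases.

    Degrees of freedom: every chi of every flexible residue (the reactive
    cysteine is pinned by the covalent bond), every ligand rotatable
    torsion (rotating the side of the bond away from the warhead, so the
    covalent geometry is preserved), and the rigid spin of the whole ligand
    about the nascent S-C bond when the pose carries a spin axis.  Energies
    are maintained per interacting component so one degree-of-freedom move
    only recomputes the terms it touches.
    """
    params = params or ScoreParams()
    work = structure if structure is not None else receptor.copy()
    lig = (ligand if ligand is not None else pose.ligand).copy()
    center = ligand_atom_table(lig).coords.mean(axis=0)
    flex_keys = _repackable_keys(work, site)
    rigid = _rigid_context_table(work, flex_keys, center, context_cutoff)
    lig_excl = _covalent_exclusion_mask(lig, work, site, rigid)
    residues = [work.get(*k) for k in flex_keys]
    n_res = len(residues)

    g = lig.graph()
    reactive_idx = lig.props.get("reactive_atom")
    spin_axis = getattr(pose, "spin_axis", None)

    def lig_torsion_moving_side(tors):
        b, c = tors[1], tors[2]
        g2 = g.copy()
        g2.remove_edge(b, c)
        import networkx as nx
        comp_c = nx.node_connected_component(g2, c)
        if reactive_idx is not None and int(reactive_idx) in comp_c:
            return [i for i in g2.nodes if i not in comp_c]
        return sorted(comp_c)

    # --- incremental energy bookkeeping -----------------------------------
    tabs = [_sidechain_table(r) for r in residues]
    lt = ligand_atom_table(lig)

    def _combine2(t1, t2, excl=None):
        rep, attr, hb = pair_terms(t1, t2, params, exclude=excl)
        return combine(rep, attr, hb, 0.0, params)

    def _tors_term():
        vals = []
        for tq in lig.rotatable_torsions:
            try:
                vals.append(dihedral(*(lig.atoms[i].coords for i in tq)))
            except GeometryError:
                pass
        return params.w_tors * torsion_penalty(vals)

    e_rr = [_combine2(t, rigid) for t in tabs]
    e_pair = {(i, j): _combine2(tabs[i], tabs[j])
              for i in range(n_res) for j in range(i + 1, n_res)}
    e_lig_res = [_combine2(t, lt) for t in tabs]
    e_lig_rigid = _combine2(lt, rigid, lig_excl)
    e_tors = _tors_term()

    def total() -> float:
        return (sum(e_rr) + sum(e_pair.values()) + sum(e_lig_res)
                + e_lig_rigid + e_tors)

    def update_residue(k: int) -> float:
        tabs[k] = _sidechain_table(residues[k])
        e_rr[k] = _combine2(tabs[k], rigid)
        for j in range(n_res):
            if j < k:
                e_pair[(j, k)] = _combine2(tabs[j], tabs[k])
            elif j > k:
                e_pair[(k, j)] = _combine2(tabs[k], tabs[j])
        e_lig_res[k] = _combine2(tabs[k], lt)
        return total()

    def update_ligand() -> float:
        nonlocal lt, e_lig_rigid, e_tors
        lt = ligand_atom_table(lig)
        e_lig_rigid = _combine2(lt, rigid, lig_excl)
        for k in range(n_res):
            e_lig_res[k] = _combine2(tabs[k], lt)
        e_tors = _tors_term()
        return total()

    def golden_min(set_fn, update_fn, cur: float, e_cur: float) -> float:
        gr = (math.sqrt(5.0) - 1.0) / 2.0
        lo, hi = cur - window, cur + window
        x1 = hi - gr * (hi - lo)
        x2 = lo + gr * (hi - lo)
        set_fn(x1)
        f1 = update_fn()
        set_fn(x2)
        f2 = update_fn()
        for _ in range(6):
            if f1 < f2:
                hi, x2, f2 = x2, x1, f1
                x1 = hi - gr * (hi - lo)
                set_fn(x1)
                f1 = update_fn()
            else:
                lo, x1, f1 = x1, x2, f2
                x2 = lo + gr * (hi - lo)
                set_fn(x2)
                f2 = update_fn()
        x_best, f_best = (x1, f1) if f1 < f2 else (x2, f2)
        if f_best < e_cur - 1e-12:
            set_fn(x_best)
            return update_fn()
        set_fn(cur)
        update_fn()
        return e_cur

    e_cur = total()
    for _ in range(cycles):
        for k, res in enumerate(residues):
            chis = measure_chis(res)
            if chis is None:
                continue
            for ci in range(len(chis)):

                def set_chi(val, res=res, ci=ci):
                    cur = list(measure_chis(res))
                    cur[ci] = val
                    rebuilt = build_sidechain(res, tuple(cur))
                    res.atoms = rebuilt.atoms

                def upd(k=k):
                    return update_residue(k)

                cur_val = measure_chis(res)[ci]
                e_cur = golden_min(set_chi, upd, cur_val, e_cur)
        for tq in lig.rotatable_torsions:
            moving = lig_torsion_moving_side(tq)
            if not moving:
                continue

            def set_tors(val, tq=tq, moving=moving):
                set_ligand_torsion(lig, tq, moving, val)

            cur_val = dihedral(*(lig.atoms[i].coords for i in tq))
            e_cur = golden_min(set_tors, update_ligand, cur_val, e_cur)
        if spin_axis is not None:
            anchor, axis = spin_axis
            state = {"cur": 0.0}

            def set_spin(val, state=state, anchor=anchor, axis=axis):
                delta = val - state["cur"]
                R = rotation_about_axis(axis, delta)
                for i in range(len(lig.atoms)):
                    lig.atoms[i].coords = anchor + R @ (lig.atoms[i].coords - anchor)
                state["cur"] = val

            e_cur = golden_min(set_spin, update_ligand, 0.0, e_cur)
    return work, lig, e_cur
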