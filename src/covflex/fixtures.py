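"""Synthetic mini-pocket systems with known ground truth.

Every stage of the docking pipeline is testable offline against generated
miniature systems: a ~42-residue receptor (one beta-strand carrying the
reactive cysteine, one loop, one alpha-helix framing a concave site),
an acrylamide-warhead ligand built from a small fragment grammar, and a
geometry-valid, clash-free reference covalent pose.

The fixtures emulate the scenario that motivates flexible-receptor
covalent docking: "blocking" residues are planted with two library
rotamers, an *open* state compatible with the reference pose and a
*closed* state that hard-clashes it.  The shipped receptor carries the
closed state, so a rigid-receptor protocol is blind to the true pose
while the mutate-dock-restore-repack pipeline can recover it.

Generation is deterministic in the seed and validates its own invariants
(reference pose passes the covalent geometry filter with zero repulsion
against the open-state receptor; each closed blocker hard-clashes the
reference pose), retrying with perturbed internal choices a bounded
number of times and failing loudly rather than easing the fixture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._energy import ScoreParams, ligand_atom_table, pair_terms
from .dockcore import (DockJobConfig, CovalentPose, _adduct_ligand,
                       _covalent_mask, _scoring_context, enumerate_poses)
from .flexprofile import BindingSiteSpec, format_residue_key
from .repacker import NUM_CHI, build_sidechain
from .structio import (Atom, Ligand, ProteinStructure, Residue, WarheadSpec,
                       place_atom, rotation_about_axis, rotation_between,
                       write_ligand_sdf, write_pdb)

log = logging.getLogger(__name__)

__all__ = [
    "FixtureError",
    "MiniPocketSystem",
    "make_minipocket",
    "make_ensemble",
    "DIFFICULTIES",
]

DIFFICULTIES = ("easy", "blocking", "multiblocking")

_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8

# acrylamide warhead + R-group grammar; atom 0 is always the olefin
# beta-carbon that bonds to SG (SMILES atom order is preserved by RDKit)
_WARHEAD_SMILES = "C=CC(=O)N"
_R_GROUPS = ["C", "CC", "C(C)C", "CCC", "CCO", "Cc1ccccc1"]

_CHI1_STATES = (-60.0, 180.0, 60.0)


class FixtureError(RuntimeError):
    pass


def _build_backbone(phipsi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry backbone (N, CA, C, O per residue) from phi/psi."""
    out: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - _ANG_N_CA_C)
    c = ca + _CA_C * np.array([np.cos(np.pi - th), np.sin(np.pi - th), 0.0])
    for i, (phi, psi) in enumerate(phipsi):
        if i > 0:
            n_new = place_atom(out[-1]["N"], out[-1]["CA"], out[-1]["C"],
                               _C_N, _ANG_CA_C_N, phipsi[i - 1][1])
            ca = place_atom(out[-1]["CA"], out[-1]["C"], n_new,
                            _N_CA, _ANG_C_N_CA, 180.0)
            c = place_atom(out[-1]["C"], n_new, ca, _CA_C, _ANG_N_CA_C, phi)
            n = n_new
        o = place_atom(n, ca, c, _C_O, _ANG_CA_C_O, psi + 180.0)
        out.append({"N": n.copy(), "CA": ca.copy(), "C": c.copy(), "O": o.copy()})
    return out


def _segment_to_residues(backbone: list[dict], names: list[str], chain: str,
                         start_resnum: int) -> list[Residue]:
    residues = []
    for i, (bb, name) in enumerate(zip(backbone, names)):
        atoms = [Atom("N", "N", bb["N"]), Atom("CA", "C", bb["CA"]),
                 Atom("C", "C", bb["C"]), Atom("O", "O", bb["O"])]
        residues.append(Residue(chain, start_resnum + i, name, atoms))
    return residues


def _transform_residues(residues: list[Residue], R: np.ndarray, t: np.ndarray) -> None:
    for res in residues:
        for a in res.atoms:
            a.coords = R @ a.coords + t


def _axis_to_x(residues: list[Residue]) -> None:
    """Rotate a segment so its CA principal axis lies along +x, centered at 0."""
    cas = np.array([r.require("CA").coords for r in residues])
    center = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    R = rotation_between(axis, np.array([1.0, 0.0, 0.0]))
    _transform_residues(residues, R, -R @ center)


def _cb_direction(res: Residue) -> np.ndarray:
    """Unit CA->CB direction from ideal geometry (no CB atom needed)."""
    from .repacker import _place_cb
    cb = _place_cb(res)
    v = cb - res.require("CA").coords
    return v / np.linalg.norm(v)


def _roll_about_x(residues: list[Residue], anchor: Residue, target: np.ndarray) -> None:
    """Rotate about the x axis so the anchor's CB direction points to target (in yz)."""
    d = _cb_direction(anchor)
    cur = np.array([d[1], d[2]])
    tgt = np.array([target[1], target[2]])
    if np.linalg.norm(cur) < 1e-8 or np.linalg.norm(tgt) < 1e-8:
        return
    ang = np.degrees(np.arctan2(tgt[1], tgt[0]) - np.arctan2(cur[1], cur[0]))
    R = rotation_about_axis(np.array([1.0, 0.0, 0.0]), ang)
    _transform_residues(residues, R, np.zeros(3))


@dataclass
class MiniPocketSystem:
    """A generated receptor/ligand/reference-pose triple with planted truth."""

    receptor: ProteinStructure
    ligand: Ligand                       # input conformer, pre-adduct bond orders
    reference_pose: CovalentPose         # ground-truth covalent pose (adduct form)
    site: BindingSiteSpec
    warhead: WarheadSpec
    seed: int
    difficulty: str
    truth: dict = field(default_factory=dict)

    @property
    def system_id(self) -> str:
        return f"mini_{self.difficulty}_{self.seed}"

    def open_receptor(self) -> ProteinStructure:
        """Receptor copy with every planted blocker in its open rotamer."""
        rec = self.receptor.copy()
        for key_s, states in self.truth.get("blocking_states", {}).items():
            chain, num = key_s.split(":")
            res = rec.get(chain, int(num))
            rebuilt = build_sidechain(res, tuple(states["open"]))
            res.atoms = rebuilt.atoms
        return rec

    def write_files(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "receptor": outdir / "receptor.pdb",
            "ligand": outdir / "ligand.sdf",
            "reference": outdir / "reference.sdf",
            "site": outdir / "site.yaml",
            "truth": outdir / "truth.json",
            "manifest": outdir / "manifest.csv",
        }
        write_pdb(self.receptor, paths["receptor"])
        lig = self.ligand.copy()
        lig.props["REACTIVE_ATOM_INDEX"] = int(self.warhead.reactive_ligand_atom)
        write_ligand_sdf(lig, paths["ligand"])
        ref = self.reference_pose.ligand.copy()
        ref.props["REACTIVE_ATOM_INDEX"] = int(self.warhead.reactive_ligand_atom)
        write_ligand_sdf(ref, paths["reference"])
        self.site.to_yaml(paths["site"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        paths["manifest"].write_text(
            "system_id,receptor,ligand,reference,cognate\n"
            f"{self.system_id},{paths['receptor'].name},{paths['ligand'].name},"
            f"{paths['reference'].name},1\n")
        return paths


def _make_ligand(rng: np.random.Generator, seed: int) -> tuple[Ligand, WarheadSpec, str]:
    smiles = _WARHEAD_SMILES + str(rng.choice(_R_GROUPS))
    mol = Chem.MolFromSmiles(smiles)
    molh = Chem.AddHs(mol)
    ok = AllChem.EmbedMolecule(molh, randomSeed=int(seed % (2 ** 31 - 1)) or 1)
    if ok != 0:
        raise FixtureError(f"conformer embedding failed for {smiles}")
    mol3d = Chem.RemoveHs(molh)
    lig = Ligand.from_rdkit(mol3d, name=f"lig{seed}")
    warhead = WarheadSpec(reactive_ligand_atom=0, modified_bonds=[(0, 1, 1)])
    return lig, warhead, smiles


def _sidechain_reach(res: Residue, chis: tuple[float, ...],
                     toward: np.ndarray) -> float:
    """Signed reach of the rebuilt side chain toward a target point."""
    built = build_sidechain(res, chis)
    ca = res.require("CA").coords
    u = toward - ca
    u /= np.linalg.norm(u)
    return max(float(np.dot(a.coords - ca, u)) for a in built.sidechain_atoms())


def _hard_clash(res: Residue, lig_xyz: np.ndarray, lig_r: np.ndarray,
                overlap_fraction: float = 0.70, min_atoms: int = 2) -> bool:
    """The blocking criterion: one side-chain atom overlapping >=2 ligand atoms."""
    side = res.sidechain_atoms()
    if not side:
        return False
    sxyz = np.array([a.coords for a in side])
    sr = np.array([a.vdw_radius for a in side])
    d = np.sqrt(((sxyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(-1))
    cut = overlap_fraction * (sr[:, None] + lig_r[None, :])
    return bool(((d < cut).sum(axis=1) >= min_atoms).any())


def _assemble_receptor(rng: np.random.Generator, seed: int, n_block: int):
    """Build the mini-pocket scaffold and plant flexible/blocking residues."""
    chain = "A"
    jit = lambda lo, hi, n: rng.uniform(lo, hi, n)

    # beta-strand (residues 1-14), CYS at 7
    n_strand = 14
    pp = [(-120.0 + j, 120.0 + k) for j, k in zip(jit(-5, 5, n_strand), jit(-5, 5, n_strand))]
    strand = _segment_to_residues(_build_backbone(pp), ["ALA"] * n_strand, chain, 1)
    _axis_to_x(strand)
    cys = strand[6]
    _roll_about_x(strand, cys, np.array([0.0, 1.0, 0.0]))
    cys.name = "CYS"

    # alpha-helix (residues 23-42) above the strand
    n_helix = 20
    pp = [(-57.0 + j, -47.0 + k) for j, k in zip(jit(-3, 3, n_helix), jit(-3, 3, n_helix))]
    helix = _segment_to_residues(_build_backbone(pp), ["ALA"] * n_helix, chain, 23)
    _axis_to_x(helix)
    gap = float(rng.uniform(11.5, 13.0))
    # roll so a mid-helix residue faces the strand (-y)
    _roll_about_x(helix, helix[n_helix // 2], np.array([0.0, -1.0, 0.0]))
    _transform_residues(helix, np.eye(3), np.array([cys.require("CA").coords[0], gap, 0.0]))

    # loop (residues 15-22) capping one end of the site
    n_loop = 8
    pp = [(float(rng.uniform(-100, -60)), float(rng.uniform(-60, 160))) for _ in range(n_loop)]
    loop = _segment_to_residues(_build_backbone(pp),
                                [str(rng.choice(["GLY", "SER", "ASN", "ASP"])) for _ in range(n_loop)],
                                chain, 15)
    _axis_to_x(loop)
    x_end = max(r.require("CA").coords[0] for r in strand) + 5.0
    _transform_residues(loop, rotation_about_axis(np.array([0, 0, 1.0]), 90.0),
                        np.array([x_end, gap / 2.0, 0.0]))

    residues = strand + loop + helix
    receptor = ProteinStructure(residues, source_id=f"mini{seed}")

    # pocket-facing helix positions (CB pointing toward the strand)
    cys_x = cys.require("CA").coords[0]
    facing = []
    for res in helix:
        d = _cb_direction(res)
        if d[1] < -0.5:
            facing.append((abs(res.require("CA").coords[0] - cys_x), res))
    facing.sort(key=lambda t: t[0])
    if len(facing) < n_block + 2:
        raise FixtureError("helix roll produced too few pocket-facing residues")

    blockers = [res for _, res in facing[:n_block]]
    flex_pool = [res for _, res in facing[n_block:n_block + 3]]
    for res in blockers:
        res.name = str(rng.choice(["MET", "GLN"]))
    flex_extra = []
    for res in flex_pool[:int(rng.integers(2, 4))]:
        res.name = str(rng.choice(["LEU", "GLN", "MET", "VAL", "SER"]))
        flex_extra.append(res)

    # strand neighbours of the cysteine on the pocket face
    for pos in (4, 8):
        strand[pos].name = str(rng.choice(["SER", "VAL", "THR"]))

    # everything else gets small rigid types and a side chain
    for res in residues:
        if res.name == "ALA":
            res.name = str(rng.choice(["ALA", "ALA", "SER", "VAL", "THR"]))
    for res in residues:
        n_chi = NUM_CHI.get(res.name, 0)
        if res.name == "GLY":
            continue
        chis = tuple([-60.0, 180.0, 180.0, 180.0][:n_chi])
        rebuilt = build_sidechain(res, chis)
        res.atoms = rebuilt.atoms

    cys.role = "reactive"
    return receptor, cys, blockers, flex_extra, gap


def make_minipocket(seed: int, difficulty: str = "easy",
                    max_retries: int = 24) -> MiniPocketSystem:
    """Deterministic synthetic docking system with planted ground truth.

    ``difficulty`` sets the number of planted blocking residues: easy 0,
    blocking 1, multiblocking 2.  Raises :class:`FixtureError` when no
    internally consistent system is found within the retry budget.
    """
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"difficulty must be one of {DIFFICULTIES}")
    n_block = DIFFICULTIES.index(difficulty)
    last_err = "?"
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed * 1000 + attempt * 13 + 1) % (2 ** 31))
        try:
            return _try_build(rng, seed, difficulty, n_block)
        except FixtureError as exc:
            last_err = str(exc)
            continue
    raise FixtureError(f"seed {seed} ({difficulty}): no valid fixture in "
                       f"{max_retries} attempts; last failure: {last_err}")


def _try_build(rng: np.random.Generator, seed: int, difficulty: str,
               n_block: int) -> MiniPocketSystem:
    receptor, cys, blockers, flex_extra, gap = _assemble_receptor(rng, seed, n_block)
    ligand, warhead, smiles = _make_ligand(rng, seed)

    site = BindingSiteSpec(
        reactive_residue=cys.key,
        flexible_residues=[cys.key] + [r.key for r in blockers] + [r.key for r in flex_extra],
        blocking_residues=[r.key for r in blockers],
    )
    params = ScoreParams()
    config = DockJobConfig(site=site, warhead=warhead, score=params, seed=seed)

    # Open/closed rotamer states for each blocker: the open state points away
    # from the pocket; the closed state is chosen later, per candidate, from
    # a pool of pocket-facing rotamer variants so it occludes the whole
    # success basin.  Flexible extras get two planted states.
    from .dockcore import pocket_center
    center = pocket_center(receptor, site)
    blocking_states: dict[str, dict] = {}
    variant_pool: dict[tuple[str, int], list[tuple[float, ...]]] = {}
    for res in blockers:
        n_chi = NUM_CHI[res.name]
        tail = tuple([180.0] * (n_chi - 1))
        scored = sorted(_CHI1_STATES,
                        key=lambda c1: -_sidechain_reach(res, (c1,) + tail, center))
        open_ = (scored[-1],) + tail
        variants = []
        for c1 in scored[:2]:  # the two most pocket-facing chi1 states
            if n_chi >= 2:
                for t2 in (180.0, -60.0, 60.0):
                    variants.append((c1, t2) + tuple([180.0] * (n_chi - 2)))
            else:
                variants.append((c1,))
        variant_pool[res.key] = list(dict.fromkeys(variants))
        blocking_states[format_residue_key(res.key)] = {
            "closed": None, "open": list(open_)}
        rebuilt = build_sidechain(res, open_)  # closed is committed later
        res.atoms = rebuilt.atoms
        res.role = "blocking"

    flexible_states: dict[str, dict] = {}
    for res in flex_extra:
        n_chi = NUM_CHI[res.name]
        tail = tuple([180.0] * (n_chi - 1))
        scored = sorted(_CHI1_STATES,
                        key=lambda c1: -_sidechain_reach(res, (c1,) + tail, center))
        # the two most pocket-averse chi1 states, so neither blocks the pose
        a_state, b_state = (scored[-1],) + tail, (scored[-2],) + tail
        flexible_states[format_residue_key(res.key)] = {
            "A": list(a_state), "B": list(b_state)}
        rebuilt = build_sidechain(res, a_state)
        res.atoms = rebuilt.atoms
        res.role = "flexible"

    open_receptor = receptor.copy()
    for key_s, states in blocking_states.items():
        chain, num = key_s.split(":")
        res = open_receptor.get(chain, int(num))
        rebuilt = build_sidechain(res, tuple(states["open"]))
        res.atoms = rebuilt.atoms

    # enumerate candidates against the fully open receptor in rigid mode:
    # survivors are clash-free against every open-state atom
    candidates, _ = enumerate_poses(open_receptor, ligand, config, mode="rigid")
    if not candidates:
        raise FixtureError("no clash-free candidate against the open receptor")

    lig_proto = _adduct_ligand(ligand, warhead)
    heavy = lig_proto.heavy_indices()
    lt_proto = ligand_atom_table(lig_proto)
    ctx = _scoring_context(open_receptor, site, center, config.context_cutoff,
                           exclude_flex_sides=False)
    mask = _covalent_mask(lig_proto, ctx, site.reactive_residue)
    lig_r = lt_proto.radii

    scored_cands = []
    for cand in candidates:
        lt = lt_proto.with_coords(cand.coords[heavy])
        rep, attr, hb = pair_terms(lt, ctx, params, exclude=mask)
        if rep > 1e-9:
            continue
        scored_cands.append((attr, cand))
    if not scored_cands:
        raise FixtureError("no zero-repulsion candidate pose")
    scored_cands.sort(key=lambda t: (t[0], t[1].index))

    # Occlusion search: one rigid-mode enumeration against the receptor with
    # blockers truncated gives the blocker-independent reachable set; per
    # candidate, closed-rotamer variants are then tested vectorially so the
    # chosen closed state occludes the candidate's whole 2.0 A success basin.
    rest_grid = None
    variant_tables: dict[tuple[str, int], list[tuple[tuple[float, ...], np.ndarray, np.ndarray]]] = {}
    if blockers:
        from .mutator import mutate_to
        rest = receptor.copy()
        rest, _ = mutate_to(rest, [r.key for r in blockers], "ALA")
        rest_cands, _ = enumerate_poses(rest, ligand, config, mode="rigid")
        if rest_cands:
            rest_grid = np.stack([c.coords[heavy] for c in rest_cands])
        for res in blockers:
            tables = []
            for v in variant_pool[res.key]:
                built = build_sidechain(receptor.get(*res.key), v)
                side = [a for a in built.sidechain_atoms() if a.name != "CB"]
                tables.append((v, np.array([a.coords for a in side]),
                               np.array([a.vdw_radius for a in side])))
            variant_tables[res.key] = tables

    def _overlap_counts(lig_xyz, sxyz, sr):
        d = np.sqrt(((sxyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(-1))
        cut = 0.7 * (sr[:, None] + lig_r[None, :])
        return (d < cut).sum(axis=1)

    def _grid_clashes(variant_xyz, variant_r):
        # any-overlap of each rest-grid candidate with the variant side chain
        d2 = ((rest_grid[:, :, None, :] - variant_xyz[None, None, :, :]) ** 2).sum(-1)
        cut = (0.7 * (lig_r[None, :, None] + variant_r[None, None, :])) ** 2
        return (d2 < cut).any(axis=(1, 2))

    from itertools import product as _iproduct
    eligible = []
    for attr, cand in scored_cands:
        lig_xyz = cand.coords[heavy]
        closed_choice = None
        if blockers:
            if rest_grid is None:
                break
            per_blocker = []
            for res in blockers:
                vs = [(v, sxyz, sr) for (v, sxyz, sr) in variant_tables[res.key]
                      if (_overlap_counts(lig_xyz, sxyz, sr) >= 2).any()]
                per_blocker.append(vs)
            if any(not vs for vs in per_blocker):
                continue  # some blocker cannot reach this candidate
            for combo in _iproduct(*per_blocker):
                blocked = np.zeros(len(rest_grid), bool)
                for (_, sxyz, sr) in combo:
                    blocked |= _grid_clashes(sxyz, sr)
                reachable = rest_grid[~blocked]
                if len(reachable) == 0:
                    closed_choice = combo
                    break
                rmsds = np.sqrt(((reachable - lig_xyz[None]) ** 2).sum(-1).mean(-1))
                if rmsds.min() > 2.0:
                    closed_choice = combo
                    break
            if closed_choice is None:
                continue
        # flexible extras must not clash the pose in either planted state
        bad = False
        for res in flex_extra:
            for state in flexible_states[format_residue_key(res.key)].values():
                test = build_sidechain(receptor.get(*res.key), tuple(state))
                if _hard_clash(test, lig_xyz, lig_r, min_atoms=1):
                    bad = True
                    break
            if bad:
                break
        if not bad:
            eligible.append((cand, closed_choice))
        if len(eligible) >= 4:
            break
    if not eligible:
        raise FixtureError("no candidate separates open and closed blocker states")

    import copy
    last_err = "?"
    for chosen, closed_choice in eligible:
        bs = copy.deepcopy(blocking_states)
        if closed_choice is not None:
            for res, (v, _, _) in zip(blockers, closed_choice):
                bs[format_residue_key(res.key)]["closed"] = list(v)
        try:
            outcome = _finalize_reference(
                receptor, chosen, site, params, config, lig_proto, lt_proto,
                heavy, lig_r, center, seed,
                bs, copy.deepcopy(flexible_states),
                blockers, flex_extra)
            break
        except FixtureError as exc:
            last_err = str(exc)
    else:
        raise FixtureError(f"no candidate yields a stable reference: {last_err}")
    ref_pose, blocking_states, flexible_states, plant_used = outcome

    # commit the shipped state to the receptor: CYS at the docking rotamer,
    # flexible extras at the planted states, blockers closed
    rebuilt = build_sidechain(cys, (chosen.chi1,))
    cys.atoms = rebuilt.atoms
    for res in flex_extra:
        rebuilt = build_sidechain(res, plant_used[res.key])
        res.atoms = rebuilt.atoms
    for res in blockers:
        key_s = format_residue_key(res.key)
        rebuilt = build_sidechain(res, tuple(blocking_states[key_s]["closed"]))
        res.atoms = rebuilt.atoms

    truth = {
        "difficulty": difficulty,
        "seed": seed,
        "smiles": smiles,
        "cys_chi1": chosen.chi1,
        "spin": chosen.spin,
        "torsions": list(chosen.torsion_values),
        "flexible": sorted(flexible_states) + sorted(blocking_states),
        "flexible_states": flexible_states,
        "blocking_states": blocking_states,
        "reference_coords": [[round(float(x), 4) for x in p]
                             for p in ref_pose.ligand.coords()],
    }
    return MiniPocketSystem(receptor, ligand, ref_pose, site, warhead,
                            seed, difficulty, truth)


def _finalize_reference(receptor, chosen, site, params, config, lig_proto,
                        lt_proto, heavy, lig_r, center, seed,
                        blocking_states, flexible_states, blockers, flex_extra):
    """Fixed-point reference construction for one grid candidate.

    Builds the receptor exactly as it will be shipped (blockers closed,
    flexible extras at the planted states), restarts the ligand from the
    grid candidate, and runs repack+refine — precisely what a docking job
    does.  Iterating the planted states makes the reference reproducible in
    a single pipeline pass; candidates whose reference drifts, clashes, or
    loses its blocker separation are rejected.
    """
    from .repacker import measure_chis, repack_site

    axis = chosen.anchor - chosen.sg
    axis = axis / np.linalg.norm(axis)
    ref_pose = CovalentPose(
        lig_proto.copy(), chosen.chi1, chosen.spin, chosen.torsion_values,
        bond_length=float(np.linalg.norm(chosen.sg - chosen.coords[int(lig_proto.props["reactive_atom"])])),
        bond_angle=config.warhead.bond_angle_target, index=chosen.index,
        spin_axis=(chosen.anchor.copy(), axis))

    plant: dict[tuple[str, int], tuple[float, ...]] = {
        res.key: tuple(flexible_states[format_residue_key(res.key)]["A"])
        for res in flex_extra}
    lig_ref = None
    rr = None
    plant_used = dict(plant)
    for round_ in range(4):
        plant_used = dict(plant)
        base = receptor.copy()
        for key, chis in plant.items():
            resb = base.get(*key)
            rebuilt = build_sidechain(resb, chis)
            resb.atoms = rebuilt.atoms
        for res in blockers:  # shipped state: closed
            key_s = format_residue_key(res.key)
            resb = base.get(*res.key)
            rebuilt = build_sidechain(resb, tuple(blocking_states[key_s]["closed"]))
            resb.atoms = rebuilt.atoms
        _set_sg(base, site, chosen.chi1)
        grid_lig = lig_proto.copy()
        grid_lig.set_coords(chosen.coords)
        ref_pose.ligand = grid_lig
        rp = repack_site(base, ref_pose, site, params=params,
                         seed=(seed * 37 + 11) % (2 ** 31), refine=True)
        new_plant = {}
        for key in plant:
            chis = measure_chis(rp.structure.get(*key))
            if chis is None:
                raise FixtureError("lost side chain during fixed-point iteration")
            new_plant[key] = tuple(round(float(c), 3) for c in chis)
        delta = (np.inf if lig_ref is None else float(np.sqrt(np.mean(
            ((rp.ligand.coords()[heavy] - lig_ref.coords()[heavy]) ** 2).sum(1)))))
        rr, lig_ref = rp.structure, rp.ligand
        if delta < 0.03:
            break
        plant = new_plant

    # keep the reference recoverable by grid sampling: if refinement walked
    # the pose far from its grid candidate, this pocket/candidate pairing is
    # too loosely confined to serve as ground truth
    grid_disp = float(np.sqrt(np.mean(
        ((lig_ref.coords()[heavy] - chosen.coords[heavy]) ** 2).sum(1))))
    if grid_disp > 0.8:
        raise FixtureError(f"reference drifted {grid_disp:.2f} A from its grid candidate")

    lig_xyz_ref = lig_ref.coords()[heavy]
    ctx_ref = _scoring_context(rr, site, center, config.context_cutoff,
                               exclude_flex_sides=False)
    mask_ref = _covalent_mask(lig_proto, ctx_ref, site.reactive_residue)
    rep_ref, _, _ = pair_terms(lt_proto.with_coords(lig_xyz_ref), ctx_ref,
                               params, exclude=mask_ref)
    if rep_ref > 1e-2:
        raise FixtureError("refined reference pose is not clash-free")
    for key_s, states in blocking_states.items():
        chis = measure_chis(rr.get(key_s.split(":")[0], int(key_s.split(":")[1])))
        if chis is not None:  # repacked-open state, for the ensemble truth
            states["open"] = [round(float(c), 3) for c in chis]
        # the two planted states must be chi1-separated, or the ensemble
        # heterogeneity they encode is invisible to torsion profiling
        sep = abs(((states["open"][0] - states["closed"][0] + 180.0) % 360.0) - 180.0)
        if sep < 90.0:
            raise FixtureError(f"blocker {key_s} open/closed chi1 separated by only {sep:.0f} deg")
        if not _hard_clash(_closed_copy(receptor, key_s, states), lig_xyz_ref, lig_r):
            raise FixtureError("closed blocker no longer clashes the refined pose")
    if blocking_states:
        # "severely blocking" means the closed rotamer occludes the whole
        # success basin, not just the reference point: no candidate a rigid
        # job can emit may lie within 2.0 A of the reference
        from .mutator import mutate_to
        shipped = base.copy()
        shipped, _ = mutate_to(shipped, [site.reactive_residue], "ALA")
        rigid_cands, _ = enumerate_poses(shipped, lig_proto, config, mode="rigid")
        for cand2 in rigid_cands:
            r = float(np.sqrt(np.mean(
                ((cand2.coords[heavy] - lig_xyz_ref) ** 2).sum(1))))
            if r <= 2.0:
                raise FixtureError("closed blocker leaves part of the success basin open")

    for res in flex_extra:
        key_s = format_residue_key(res.key)
        chis = plant_used[res.key]
        flexible_states[key_s]["A"] = [round(float(c), 3) for c in chis]
        # re-derive the alternate (B) state: the library chi1 farthest from
        # the planted A chi1 that stays clash-free against the reference
        n_chi = NUM_CHI[res.name]
        tail = tuple([180.0] * (n_chi - 1))
        alts = sorted(_CHI1_STATES,
                      key=lambda c1: -abs(((c1 - chis[0] + 180.0) % 360.0) - 180.0))
        for c1 in alts:
            cand_state = (c1,) + tail
            sep = abs(((c1 - chis[0] + 180.0) % 360.0) - 180.0)
            test = build_sidechain(rr.get(*res.key), cand_state)
            if sep >= 90.0 and not _hard_clash(test, lig_xyz_ref, lig_r, min_atoms=1):
                flexible_states[key_s]["B"] = list(cand_state)
                break
        else:
            raise FixtureError(f"no clash-free alternate rotamer for {key_s}")

    ref_pose.ligand = lig_ref
    c_ref = lig_ref.atoms[int(lig_proto.props["reactive_atom"])].coords
    ref_pose.bond_length = float(np.linalg.norm(chosen.sg - c_ref))
    return ref_pose, blocking_states, flexible_states, plant_used


def _set_sg(receptor: ProteinStructure, site: BindingSiteSpec, chi1: float) -> None:
    res = receptor.get(*site.reactive_residue)
    rebuilt = build_sidechain(res, (chi1,))
    res.atoms = rebuilt.atoms


def _closed_copy(receptor: ProteinStructure, key_s: str, states: dict) -> Residue:
    chain, num = key_s.split(":")
    res = receptor.get(chain, int(num))
    return build_sidechain(res, tuple(states["closed"]))


def make_ensemble(seed: int, n_structures: int, difficulty: str = "blocking",
                  jitter: float = 0.1, chi_jitter: float = 4.0,
                  system: MiniPocketSystem | None = None,
                  ) -> tuple[list[ProteinStructure], MiniPocketSystem]:
    """Ensemble of one mini-pocket with planted side-chain heterogeneity.

    Planted flexible residues (including blockers) alternate between their
    two rotamer states across members; every atom receives positional
    jitter of at most ``jitter`` Angstrom.  Returns the ensemble and the
    generating system (whose truth lists the planted flexible residues).
    """
    if n_structures < 2:
        raise ValueError("an ensemble needs at least 2 members")
    if system is None:
        system = make_minipocket(seed, difficulty)
    rng = np.random.default_rng((seed * 7919 + 17) % (2 ** 31))
    two_state: dict[tuple[str, int], list[tuple[float, ...]]] = {}
    for key_s, states in system.truth["flexible_states"].items():
        chain, num = key_s.split(":")
        two_state[(chain, int(num))] = [tuple(states["A"]), tuple(states["B"])]
    for key_s, states in system.truth["blocking_states"].items():
        chain, num = key_s.split(":")
        two_state[(chain, int(num))] = [tuple(states["open"]), tuple(states["closed"])]
    offsets = {k: int(rng.integers(0, 2)) for k in two_state}

    members = []
    for i in range(n_structures):
        st = system.receptor.copy()
        st.source_id = f"{system.receptor.source_id}_m{i}"
        for res in st.residues:
            for a in res.atoms:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                a.coords = a.coords + direction * rng.uniform(0.0, jitter)
        for key, states in two_state.items():
            res = st.get(*key)
            chis = states[(i + offsets[key]) % 2]
            chis = tuple(c + float(rng.uniform(-chi_jitter, chi_jitter)) for c in chis)
            rebuilt = build_sidechain(res, chis)
            res.atoms = rebuilt.atoms
        members.append(st)
    return members, system
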