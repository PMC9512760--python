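"""Covalent pose generation, scoring, clustering, and ranking.

The pipeline mirrors a two-stage covalent docking protocol with an
induced-fit twist: the reactive cysteine and any blocking residues are
mutated to alanine to open the pocket, candidate adducts are enumerated
anchor-first (cysteine chi1 rotamers x ligand torsion grid x spin about
the nascent S-C bond), the mutated residues are restored, poses that fail
the covalent-geometry filter are rejected, flexible side chains are
re-packed around each surviving pose, and the refined ensemble is
clustered and ranked by the pairwise surrogate score.

Anchor-first sampling replaces grid-based non-covalent docking of the
classic first stage: the covalent constraint pins the warhead carbon at
thioether geometry from the start, which makes exhaustive enumeration
tractable without a full docking engine.  This is the package's largest
declared deviation from the protocol it emulates and is documented in the
methods note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._energy import (AtomTable, ScoreParams, combine, ligand_atom_table,
                      pair_terms, protein_atom_table, torsion_penalty)
from .flexprofile import BindingSiteSpec
from .mutator import mutate_to, restore
from .repacker import (RotamerLibrary, build_sidechain, default_library,
                       repack_site, set_ligand_torsion)
from .structio import (Ligand, ProteinStructure, WarheadSpec, bond_angle,
                       place_atom, rotation_about_axis, rotation_between)

log = logging.getLogger(__name__)

__all__ = [
    "ScoreParams",
    "DockJobConfig",
    "CovalentPose",
    "DockResult",
    "CANONICAL_CHI1",
    "dock_covalent",
    "enumerate_poses",
    "check_adduct_geometry",
    "score_pose",
    "cluster_poses",
]

CANONICAL_CHI1 = (-60.0, 180.0, 60.0)
_SG_BOND, _SG_ANGLE = 1.808, 114.4  # CB-SG geometry of cysteine


@dataclass
class DockJobConfig:
    """Everything a docking job needs besides the structures themselves."""

    site: BindingSiteSpec
    warhead: WarheadSpec
    score: ScoreParams = field(default_factory=ScoreParams)
    n_cys_rotamers: int = 3
    torsion_grid_degrees: float = 120.0
    spin_grid_degrees: float = 30.0
    max_poses_out: int = 20
    cluster_rmsd_cutoff: float = 1.0
    n_repack: int = 64          # candidates carried into side-chain repacking
    n_refine: int = 8           # top poses given continuous torsional refinement
    context_cutoff: float = 16.0  # A around the pocket considered in scoring
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_poses_out < 1:
            raise ValueError("max_poses_out must be >= 1")
        for grid in (self.torsion_grid_degrees, self.spin_grid_degrees):
            if abs(360.0 / grid - round(360.0 / grid)) > 1e-9:
                raise ValueError(f"grid of {grid} deg must divide 360")
        if not 1 <= self.n_cys_rotamers <= len(CANONICAL_CHI1):
            raise ValueError("n_cys_rotamers must be 1..3")


@dataclass
class CovalentPose:
    """One candidate ligand placement covalently bonded to the cysteine."""

    ligand: Ligand
    cys_chi1: float
    spin: float
    torsion_values: tuple[float, ...]
    bond_length: float
    bond_angle: float
    score_total: float | None = None
    score_terms: dict = field(default_factory=dict)
    cluster_id: int = -1
    rank: int = 0
    index: int = 0
    spin_axis: tuple[np.ndarray, np.ndarray] | None = None
    receptor: ProteinStructure | None = None

    @property
    def ligand_coords(self) -> np.ndarray:
        return self.ligand.coords()

    def heavy_coords(self) -> np.ndarray:
        return np.array([self.ligand.atoms[i].coords for i in self.ligand.heavy_indices()])


@dataclass
class DockResult:
    poses: list[CovalentPose]
    counts: dict
    reason: str = ""

    def __iter__(self):
        return iter(self.poses)

    def __len__(self):
        return len(self.poses)


def _grid_values(grid: float, anchor: float) -> list[float]:
    n = int(round(360.0 / grid))
    return [((anchor + k * grid + 180.0) % 360.0) - 180.0 for k in range(n)]


def pocket_center(receptor: ProteinStructure, site: BindingSiteSpec) -> np.ndarray:
    keys = list(dict.fromkeys([site.reactive_residue] + site.flexible_residues
                              + site.blocking_residues))
    cas = [receptor.get(*k).atom("CA").coords for k in keys
           if receptor.has(*k) and receptor.get(*k).atom("CA") is not None]
    if not cas:
        raise ValueError("no site residues with CA found in receptor")
    return np.mean(cas, axis=0)


def _adduct_ligand(ligand: Ligand, warhead: WarheadSpec) -> Ligand:
    """Ligand copy in adduct form (bond orders updated, reactive atom tagged)."""
    lig = ligand.copy()
    for (i, j, order) in warhead.modified_bonds:
        for k, (a, b, o) in enumerate(lig.bonds):
            if {a, b} == {i, j}:
                lig.bonds[k] = (a, b, order)
    if warhead.reactive_ligand_atom >= len(lig.atoms):
        raise ValueError("warhead reactive atom index out of range")
    lig.props["reactive_atom"] = int(warhead.reactive_ligand_atom)
    return lig


@dataclass
class _Candidate:
    coords: np.ndarray
    chi1: float
    spin: float
    torsion_values: tuple[float, ...]
    index: int
    sg: np.ndarray
    anchor: np.ndarray


def _anchor_direction(sg: np.ndarray, cb: np.ndarray, center: np.ndarray,
                      angle_deg: float) -> np.ndarray:
    """Unit direction from SG to the warhead carbon.

    The direction makes the target CB-SG-C angle with the SG->CB vector; the
    remaining azimuthal freedom is fixed deterministically by steering the
    carbon toward the pocket center.
    """
    w = cb - sg
    w /= np.linalg.norm(w)
    t = center - sg
    t_perp = t - np.dot(t, w) * w
    if np.linalg.norm(t_perp) < 1e-8:  # center on the CB axis: arbitrary normal
        t_perp = np.cross(w, [1.0, 0.0, 0.0])
        if np.linalg.norm(t_perp) < 1e-6:
            t_perp = np.cross(w, [0.0, 1.0, 0.0])
    e1 = t_perp / np.linalg.norm(t_perp)
    th = math.radians(angle_deg)
    return math.cos(th) * w + math.sin(th) * e1


def enumerate_poses(receptor: ProteinStructure, ligand: Ligand,
                    config: DockJobConfig, mode: str = "flex",
                    ) -> tuple[list[_Candidate], dict]:
    """Anchor-first candidate enumeration with a hard clash pre-filter.

    ``receptor`` is the (possibly alanine-mutated) docking receptor.  For
    each cysteine chi1 rotamer the SG is placed from backbone geometry, the
    warhead carbon is anchored at thioether bond geometry, and the ligand is
    swept over its internal torsion grid and the spin about the nascent S-C
    bond.  Candidates clashing with non-flexible receptor atoms are
    discarded (flexible side chains are exempt — repacking may move them;
    in rigid mode every side chain participates in the filter).
    """
    site, warhead = config.site, config.warhead
    lig = _adduct_ligand(ligand, warhead)
    ridx = int(warhead.reactive_ligand_atom)
    g = lig.graph()
    heavy_nbrs = [n for n in g.neighbors(ridx) if lig.atoms[n].element != "H"]
    counts = {"n_enumerated": 0, "n_clash_pass": 0}
    if not heavy_nbrs:
        return [], counts

    cys = receptor.get(*site.reactive_residue)
    n = cys.require("N").coords
    ca = cys.require("CA").coords
    cb_atom = cys.atom("CB")
    cb = cb_atom.coords if cb_atom is not None else _rebuild_cb(cys)
    center = pocket_center(receptor, site)

    # torsion moving sides (away from the warhead)
    import networkx as nx
    moving_sides = []
    for tq in lig.rotatable_torsions:
        b, c = tq[1], tq[2]
        g2 = g.copy()
        g2.remove_edge(b, c)
        comp_c = nx.node_connected_component(g2, c)
        moving_sides.append([i for i in g2.nodes if i not in comp_c]
                            if ridx in comp_c else sorted(comp_c))

    tors_grid = _grid_values(config.torsion_grid_degrees, 60.0)
    spin_grid = _grid_values(config.spin_grid_degrees, 0.0)
    chi1s = CANONICAL_CHI1[:config.n_cys_rotamers]

    # conformers: all torsion-grid combinations applied to the input geometry
    from itertools import product
    conformers: list[tuple[tuple[float, ...], np.ndarray]] = []
    if lig.rotatable_torsions:
        for combo in product(tors_grid, repeat=len(lig.rotatable_torsions)):
            work = lig.copy()
            for tq, moving, val in zip(work.rotatable_torsions, moving_sides, combo):
                set_ligand_torsion(work, tq, moving, val)
            conformers.append((tuple(combo), work.coords()))
    else:
        conformers.append(((), lig.coords()))

    candidates: list[_Candidate] = []
    idx = 0
    for chi1 in chi1s:
        sg = place_atom(n, ca, cb, _SG_BOND, _SG_ANGLE, chi1)
        direction = _anchor_direction(sg, cb, center, warhead.bond_angle_target)
        anchor = sg + warhead.bond_length_target * direction
        axis = direction  # S->C bond axis
        for combo, conf in conformers:
            # orient substituents of the reactive carbon away from sulfur
            nbr_mean = np.mean([conf[j] for j in heavy_nbrs], axis=0)
            v_lig = nbr_mean - conf[ridx]
            R0 = rotation_between(v_lig, axis)
            placed0 = (R0 @ (conf - conf[ridx]).T).T + anchor
            for spin in spin_grid:
                Rs = rotation_about_axis(axis, spin)
                placed = (Rs @ (placed0 - anchor).T).T + anchor
                candidates.append(_Candidate(placed, chi1, spin, combo, idx, sg, anchor))
                idx += 1
    counts["n_enumerated"] = len(candidates)

    ctx = _prefilter_table(receptor, site, center, config, mode)
    if len(ctx) == 0 or not candidates:
        counts["n_clash_pass"] = len(candidates)
        return candidates, counts
    heavy = lig.heavy_indices()
    lig_r = np.array([lig.atoms[i].vdw_radius for i in heavy])
    onset = config.score.clash_onset_fraction * (lig_r[:, None] + ctx.radii[None, :])
    survivors = []
    chunk = 256
    for k0 in range(0, len(candidates), chunk):
        block = candidates[k0:k0 + chunk]
        coords = np.stack([c.coords[heavy] for c in block])  # (B, L, 3)
        d2 = ((coords[:, :, None, :] - ctx.coords[None, None, :, :]) ** 2).sum(-1)
        clash = (d2 < (onset[None, :, :] ** 2)).any(axis=(1, 2))
        survivors.extend(c for c, bad in zip(block, clash) if not bad)
    counts["n_clash_pass"] = len(survivors)
    return survivors, counts


def _rebuild_cb(res) -> np.ndarray:
    from .repacker import _place_cb
    return _place_cb(res)


def _prefilter_table(receptor: ProteinStructure, site: BindingSiteSpec,
                     center: np.ndarray, config: DockJobConfig, mode: str) -> AtomTable:
    flex = set(site.flexible_residues) | set(site.blocking_residues)
    pairs = []
    for res in receptor.residues:
        exempt_side = mode == "flex" and res.key in flex
        for a in res.heavy_atoms():
            if res.key == site.reactive_residue and not a.is_backbone:
                continue  # the cysteine side chain is rebuilt per rotamer
            if exempt_side and not a.is_backbone and a.name != "CB":
                continue
            if np.linalg.norm(a.coords - center) > config.context_cutoff:
                continue
            pairs.append((res, a))
    for het in receptor.heteroatoms:
        if het.name in ("HOH", "WAT", "DOD"):
            continue
        for a in het.heavy_atoms():
            if np.linalg.norm(a.coords - center) <= config.context_cutoff:
                pairs.append((het, a))
    return protein_atom_table(pairs)


def check_adduct_geometry(pose, warhead: WarheadSpec, cys) -> tuple[bool, float, float]:
    """Measure the covalent bond geometry and test it against the tolerances.

    Accepts a :class:`CovalentPose` or a raw candidate; ``cys`` must carry
    SG (position of the bonded sulfur).  Returns (passed, length, angle).
    """
    sg = cys.require("SG").coords if hasattr(cys, "require") else np.asarray(cys)
    cb = cys.atom("CB").coords if hasattr(cys, "atom") and cys.atom("CB") is not None else None
    if hasattr(pose, "ligand"):
        c = pose.ligand.atoms[int(pose.ligand.props["reactive_atom"])].coords
    else:
        c = pose.coords[int(pose.index_reactive)]
    length = float(np.linalg.norm(sg - c))
    angle = bond_angle(cb, sg, c) if cb is not None else warhead.bond_angle_target
    ok = (abs(length - warhead.bond_length_target) <= warhead.bond_length_tol
          and abs(angle - warhead.bond_angle_target) <= warhead.bond_angle_tol)
    return ok, length, angle


def _scoring_context(receptor: ProteinStructure, site: BindingSiteSpec,
                     center: np.ndarray, cutoff: float,
                     exclude_flex_sides: bool) -> AtomTable:
    flex = set(site.flexible_residues) | set(site.blocking_residues)
    pairs = []
    for res in receptor.residues:
        for a in res.heavy_atoms():
            if exclude_flex_sides and res.key in flex and not a.is_backbone and a.name != "CB":
                continue
            if np.linalg.norm(a.coords - center) > cutoff:
                continue
            pairs.append((res, a))
    for het in receptor.heteroatoms:
        if het.name in ("HOH", "WAT", "DOD"):
            continue
        for a in het.heavy_atoms():
            if np.linalg.norm(a.coords - center) <= cutoff:
                pairs.append((het, a))
    return protein_atom_table(pairs)


def _covalent_mask(lig: Ligand, ctx: AtomTable, reactive_key) -> np.ndarray | None:
    import networkx as nx
    ridx = int(lig.props["reactive_atom"])
    dist = nx.single_source_shortest_path_length(lig.graph(), ridx, cutoff=2)
    heavy = lig.heavy_indices()
    near1 = np.array([dist.get(i, 99) <= 1 for i in heavy])
    near2 = np.array([dist.get(i, 99) <= 2 for i in heavy])
    mask = np.zeros((len(heavy), len(ctx)), bool)
    for col, (rkey, aname) in enumerate(ctx.labels):
        if rkey == reactive_key and aname == "SG":
            mask[near2, col] = True
        elif rkey == reactive_key and aname == "CB":
            mask[near1, col] = True
    return mask if mask.any() else None


def score_pose(pose: CovalentPose, receptor: ProteinStructure, params: ScoreParams,
               site: BindingSiteSpec, context: AtomTable | None = None,
               ) -> tuple[float, dict]:
    """Pairwise surrogate score of a pose against a receptor; lower is better.

    score = w_rep * repulsion + w_attr * attraction + w_hb * hbond
    + w_tors * torsion strain; the breakdown is returned alongside the
    total and sums to it exactly.  Atom pairs across the covalent
    attachment (1-2 and 1-3) are excluded.
    """
    lig = pose.ligand
    lt = ligand_atom_table(lig)
    if context is None:
        center = lt.coords.mean(axis=0)
        context = _scoring_context(receptor, site, center, 16.0, exclude_flex_sides=False)
    mask = _covalent_mask(lig, context, site.reactive_residue)
    rep, attr, hb = pair_terms(lt, context, params, exclude=mask)
    tors = torsion_penalty(pose.torsion_values)
    terms = {"repulsion": params.w_rep * rep, "attraction": params.w_attr * attr,
             "hbond": params.w_hb * hb, "torsion": params.w_tors * tors}
    total = combine(rep, attr, hb, tors, params)
    return total, terms


def cluster_poses(poses: list[CovalentPose], cutoff: float) -> list[list[CovalentPose]]:
    """Greedy leader clustering on in-frame heavy-atom ligand RMSD.

    Poses are visited by ascending score (ties by construction index); a
    pose joins the first cluster whose leader is within ``cutoff``,
    otherwise it founds a new cluster.  Because visiting order is by score,
    each leader is also its cluster's lowest-score member (the
    representative).
    """
    if not poses:
        return []
    ordered = sorted(poses, key=lambda p: (p.score_total if p.score_total is not None else 0.0,
                                           p.index))
    clusters: list[list[CovalentPose]] = []
    leaders: list[np.ndarray] = []
    for p in ordered:
        xyz = p.heavy_coords()
        placed = False
        for ci, lead in enumerate(leaders):
            rmsd = float(np.sqrt(np.mean(((xyz - lead) ** 2).sum(axis=1))))
            if rmsd <= cutoff:
                clusters[ci].append(p)
                p.cluster_id = ci
                placed = True
                break
        if not placed:
            p.cluster_id = len(clusters)
            clusters.append([p])
            leaders.append(xyz)
    return clusters


def dock_covalent(receptor: ProteinStructure, ligand: Ligand,
                  config: DockJobConfig, mode: str = "flex",
                  library: RotamerLibrary | None = None) -> DockResult:
    """Run one covalent docking job; deterministic given ``config.seed``.

    ``mode='flex'``: blocking residues are mutated to alanine before
    enumeration and restored before repacking; flexible side chains are
    re-packed around each surviving candidate.  ``mode='rigid'``: no
    blocking mutation, no repacking — the classic rigid-receptor baseline.
    """
    if mode not in ("flex", "rigid"):
        raise ValueError("mode must be 'flex' or 'rigid'")
    site, warhead = config.site, config.warhead
    params = config.score
    library = library or default_library()
    counts: dict = {}

    cys = receptor.get(*site.reactive_residue)
    if cys.name not in ("CYS", "ALA"):
        raise ValueError(f"reactive residue {site.reactive_residue} is {cys.name}, expected CYS")

    work = receptor.copy()
    to_ala = []
    if mode == "flex":
        to_ala = [k for k in site.blocking_residues
                  if work.has(*k) and work.get(*k).name not in ("ALA", "GLY")]
    if work.get(*site.reactive_residue).name != "ALA":
        to_ala = to_ala + [site.reactive_residue]
    work, records = mutate_to(work, to_ala, "ALA")

    candidates, enum_counts = enumerate_poses(work, ligand, config, mode)
    counts.update(enum_counts)
    restore(work, records)

    if counts["n_enumerated"] == 0:
        return DockResult([], counts, "geometry infeasible")
    if not candidates:
        return DockResult([], counts, "pocket blocked")

    lig_proto = _adduct_ligand(ligand, warhead)
    center = pocket_center(receptor, site)

    # geometry filter (anchor construction satisfies it; still enforced)
    geo_pass = []
    ridx = int(warhead.reactive_ligand_atom)
    for cand in candidates:
        length = float(np.linalg.norm(cand.sg - cand.coords[ridx]))
        cb = work.get(*site.reactive_residue).atom("CB")
        ang = bond_angle(cb.coords, cand.sg, cand.coords[ridx]) if cb is not None else warhead.bond_angle_target
        if (abs(length - warhead.bond_length_target) <= warhead.bond_length_tol
                and abs(ang - warhead.bond_angle_target) <= warhead.bond_angle_tol):
            geo_pass.append((cand, length, ang))
    counts["n_geometry_pass"] = len(geo_pass)
    if not geo_pass:
        return DockResult([], counts, "geometry infeasible")

    # pre-score against the restored receptor (flexible side chains exempt
    # in flex mode, since repacking may move them)
    pre_ctx = _scoring_context(work, site, center, config.context_cutoff,
                               exclude_flex_sides=(mode == "flex"))
    lt_proto = ligand_atom_table(lig_proto)
    mask = _covalent_mask(lig_proto, pre_ctx, site.reactive_residue)
    heavy = lig_proto.heavy_indices()
    pre_energies = _batch_prescore([c.coords[heavy] for c, _, _ in geo_pass],
                                   lt_proto, pre_ctx, params, mask)
    prescored = [(e + params.w_tors * torsion_penalty(cand.torsion_values), cand, length, ang)
                 for e, (cand, length, ang) in zip(pre_energies, geo_pass)]
    prescored.sort(key=lambda t: (t[0], t[1].index))

    n_keep = config.n_repack if mode == "flex" else max(40, 2 * config.max_poses_out)
    keep = prescored[:n_keep]
    poses: list[CovalentPose] = []
    for e, cand, length, ang in keep:
        lig = lig_proto.copy()
        lig.set_coords(cand.coords)
        axis = cand.anchor - cand.sg
        pose = CovalentPose(lig, cand.chi1, cand.spin, cand.torsion_values,
                            length, ang, index=cand.index,
                            spin_axis=(cand.anchor.copy(), axis / np.linalg.norm(axis)))
        poses.append(pose)

    final: list[CovalentPose] = []
    score_cache = _ScoreCache(work, site, center, config, lig_proto)
    if mode == "flex":
        from .repacker import build_repack_cache
        cache = build_repack_cache(work, site, library, params, center,
                                   config.context_cutoff + 2)
        for k, pose in enumerate(poses):
            rr = work.copy()
            _set_cys_rotamer(rr, site.reactive_residue, pose.cys_chi1)
            pose_seed = (config.seed * 1000003 + 7919 * pose.index) % (2 ** 31)
            result = repack_site(rr, pose, site, library, params, seed=pose_seed,
                                 refine=False, context_cutoff=config.context_cutoff + 2,
                                 cache=cache, copy_receptor=False)
            pose.receptor = result.structure
            _final_score(pose, score_cache, params)
            final.append(pose)
        counts["n_repacked"] = len(final)
        final.sort(key=lambda p: (p.score_total, p.index))
        # continuous refinement of the leading poses
        from .repacker import refine_continuous
        for pose in final[:config.n_refine]:
            rr, lig_ref, _ = refine_continuous(pose.receptor, pose, site, params,
                                               structure=pose.receptor,
                                               context_cutoff=config.context_cutoff + 2)
            pose.receptor = rr
            pose.ligand = lig_ref
            _remeasure_geometry(pose, site)
            _final_score(pose, score_cache, params)
        final.sort(key=lambda p: (p.score_total, p.index))
    else:
        for pose in poses:
            rr = work.copy()
            _set_cys_rotamer(rr, site.reactive_residue, pose.cys_chi1)
            pose.receptor = rr
            _final_score(pose, score_cache, params)
            final.append(pose)

    # geometry invariant: every emitted pose satisfies the warhead contract
    emitted_pool = []
    for pose in final:
        cys_res = pose.receptor.get(*site.reactive_residue) if pose.receptor is not None else None
        if cys_res is not None and cys_res.atom("SG") is not None:
            ok, length, ang = check_adduct_geometry(pose, warhead, cys_res)
            pose.bond_length, pose.bond_angle = length, ang
            if not ok:
                continue
        emitted_pool.append(pose)
    if not emitted_pool:
        return DockResult([], counts, "geometry infeasible")

    clusters = cluster_poses(emitted_pool, config.cluster_rmsd_cutoff)
    counts["n_clusters"] = len(clusters)
    reps = [cl[0] for cl in clusters]
    rest = [p for cl in clusters for p in cl[1:]]
    rest.sort(key=lambda p: (p.score_total, p.index))
    ranked = (reps + rest)[:config.max_poses_out]
    for r, pose in enumerate(ranked, start=1):
        pose.rank = r
    counts["n_emitted"] = len(ranked)
    return DockResult(ranked, counts, "")


def _batch_prescore(coord_list: list[np.ndarray], lt_proto, ctx: AtomTable,
                    params: ScoreParams, mask: np.ndarray | None) -> list[float]:
    """Vectorized repulsion+attraction pre-score over many candidates.

    The pre-score only ranks candidates for the repacking stage, so the
    (expensive, angle-dependent) hydrogen-bond term is left out here; the
    full score is applied after repacking.
    """
    if not coord_list:
        return []
    from ._energy import ATTR_CUTOFF
    radii_l = lt_proto.radii
    onset = params.clash_onset_fraction * (radii_l[:, None] + ctx.radii[None, :])
    contact = np.minimum(radii_l[:, None] + ctx.radii[None, :], ATTR_CUTOFF - 0.1)
    valid = np.ones_like(onset, bool) if mask is None else ~mask
    out = []
    chunk = 128
    for k0 in range(0, len(coord_list), chunk):
        block = np.stack(coord_list[k0:k0 + chunk])          # (B, L, 3)
        d = np.sqrt(((block[:, :, None, :] - ctx.coords[None, None, :, :]) ** 2).sum(-1))
        over = np.where((d < onset) & valid, onset - d, 0.0)
        rep = (over ** 2).sum(axis=(1, 2))
        rise = (d - onset) / np.maximum(contact - onset, 1e-9)
        fall = (ATTR_CUTOFF - d) / np.maximum(ATTR_CUTOFF - contact, 1e-9)
        well = np.clip(np.minimum(rise, fall), 0.0, 1.0)
        in_well = (d >= onset) & (d <= ATTR_CUTOFF) & valid
        attr = -np.where(in_well, well, 0.0).sum(axis=(1, 2))
        out.extend((params.w_rep * rep + params.w_attr * attr).tolist())
    return out


class _ScoreCache:
    """Per-job cached rigid context for pose scoring.

    Only the reactive SG and the flexible side chains change between poses;
    everything else (the rigid context and the covalent-exclusion pattern)
    is computed once.
    """

    def __init__(self, work: ProteinStructure, site: BindingSiteSpec,
                 center: np.ndarray, config: DockJobConfig, lig_proto: Ligand):
        from .repacker import _repackable_keys, _rigid_context_table
        self.site = site
        self.keys = _repackable_keys(work, site)
        self.ctx_rigid = _rigid_context_table(
            work, self.keys + [site.reactive_residue], center, config.context_cutoff)
        import networkx as nx
        ridx = int(lig_proto.props["reactive_atom"])
        dist = nx.single_source_shortest_path_length(lig_proto.graph(), ridx, cutoff=2)
        heavy = lig_proto.heavy_indices()
        self.near1 = np.array([dist.get(i, 99) <= 1 for i in heavy])
        self.near2 = np.array([dist.get(i, 99) <= 2 for i in heavy])
        self.mask_rigid = np.zeros((len(heavy), len(self.ctx_rigid)), bool)
        for col, (rkey, aname) in enumerate(self.ctx_rigid.labels):
            if rkey == site.reactive_residue and aname == "CB":
                self.mask_rigid[self.near1, col] = True


def _final_score(pose: CovalentPose, cache: _ScoreCache,
                 params: ScoreParams) -> None:
    """Ligand-centric score plus side-chain strain; terms sum to the total."""
    from .repacker import _reactive_sg_table, _sidechain_table
    rr = pose.receptor
    sg_table = _reactive_sg_table(rr, cache.site)
    flex_tables = [_sidechain_table(rr.get(*k)) for k in cache.keys]
    full_ctx = AtomTable.concatenate([cache.ctx_rigid, sg_table] + flex_tables)
    n_lig = cache.mask_rigid.shape[0]
    mask = np.zeros((n_lig, len(full_ctx)), bool)
    mask[:, :len(cache.ctx_rigid)] = cache.mask_rigid
    if len(sg_table):
        mask[cache.near2, len(cache.ctx_rigid):len(cache.ctx_rigid) + len(sg_table)] = True

    lt = ligand_atom_table(pose.ligand)
    rep, attr, hb = pair_terms(lt, full_ctx, params, exclude=mask)
    tors = torsion_penalty(pose.torsion_values)
    terms = {"repulsion": params.w_rep * rep, "attraction": params.w_attr * attr,
             "hbond": params.w_hb * hb, "torsion": params.w_tors * tors}

    # repulsive side-chain strain: flexible vs (rigid + SG) and flexible pairs
    rigid_plus_sg = AtomTable.concatenate([cache.ctx_rigid, sg_table])
    strain_rep = 0.0
    for i, t in enumerate(flex_tables):
        r, _, _ = pair_terms(t, rigid_plus_sg, params)
        strain_rep += r
        for u in flex_tables[i + 1:]:
            r, _, _ = pair_terms(t, u, params)
            strain_rep += r
    terms["sidechain"] = params.w_rep * strain_rep
    pose.score_terms = terms
    pose.score_total = float(sum(terms.values()))


def _set_cys_rotamer(receptor: ProteinStructure, key, chi1: float) -> None:
    res = receptor.get(*key)
    if res.name == "ALA":
        res.name = "CYS"
    rebuilt = build_sidechain(res, (chi1,))
    res.atoms = rebuilt.atoms


def _remeasure_geometry(pose: CovalentPose, site: BindingSiteSpec) -> None:
    if pose.receptor is None:
        return
    cys = pose.receptor.get(*site.reactive_residue)
    sg = cys.atom("SG")
    cb = cys.atom("CB")
    if sg is None:
        return
    c = pose.ligand.atoms[int(pose.ligand.props["reactive_atom"])].coords
    pose.bond_length = float(np.linalg.norm(sg.coords - c))
    if cb is not None:
        pose.bond_angle = bond_angle(cb.coords, sg.coords, c)
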