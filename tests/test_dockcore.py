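"""Covalent pose enumeration, scoring, clustering, and pipeline tests."""

from __future__ import annotations

import numpy as np
import pytest

from covflex._energy import ScoreParams
from covflex.dockcore import (CovalentPose, DockJobConfig, check_adduct_geometry,
                              cluster_poses, dock_covalent, enumerate_poses,
                              score_pose)
from covflex.flexprofile import BindingSiteSpec
from covflex.mutator import mutate_to, restore
from covflex.repacker import build_sidechain
from covflex.structio import Atom, Ligand, ProteinStructure, Residue, WarheadSpec

from conftest import best_rmsd_topn


def _cys_only_receptor():
    res = Residue("A", 1, "CYS", [
        Atom("N", "N", [0.0, 0.0, 0.0]), Atom("CA", "C", [1.458, 0.0, 0.0]),
        Atom("C", "C", [2.0, 1.42, 0.0]), Atom("O", "O", [1.4, 2.44, 0.0])])
    return ProteinStructure([build_sidechain(res, (-60.0,))], "cysonly")


def _rigid_ligand():
    """Three heavy atoms, no rotatable torsions (both inner atoms terminal-ish)."""
    atoms = [Atom("C1", "C", [0.0, 0.0, 0.0]), Atom("C2", "C", [1.5, 0.0, 0.0]),
             Atom("O1", "O", [2.1, 1.1, 0.0])]
    return Ligand(atoms, [(0, 1, 2), (1, 2, 1)], [], "acryl")


def _minimal_config(seed=0, **kw):
    site = BindingSiteSpec(("A", 1), [("A", 1)])
    warhead = WarheadSpec(reactive_ligand_atom=0, modified_bonds=[(0, 1, 1)])
    return DockJobConfig(site=site, warhead=warhead, seed=seed, **kw)


def test_enumeration_count_rigid_ligand():
    """3 rotamers x 12 spin steps, no torsions -> exactly 36 candidates."""
    receptor = _cys_only_receptor()
    config = _minimal_config()
    cands, counts = enumerate_poses(receptor, _rigid_ligand(), config, "flex")
    assert counts["n_enumerated"] == 3 * 12
    # nothing to clash against beyond the cysteine backbone
    assert counts["n_clash_pass"] >= 30


def test_enumeration_count_with_torsion_grid(easy_system):
    config = DockJobConfig(site=easy_system.site, warhead=easy_system.warhead)
    work = easy_system.receptor.copy()
    work, recs = mutate_to(work, [easy_system.site.reactive_residue], "ALA")
    cands, counts = enumerate_poses(work, easy_system.ligand, config, "flex")
    t = len(easy_system.ligand.rotatable_torsions)
    assert counts["n_enumerated"] == 3 * 12 * 3 ** t
    assert 0 < counts["n_clash_pass"] <= counts["n_enumerated"]


def test_fully_occluded_pocket_reports_blocked():
    receptor = _cys_only_receptor()
    # a dense shell of carbon atoms around the anchor region
    rng = np.random.default_rng(0)
    blob = []
    sg = receptor.get("A", 1).require("SG").coords
    for i in range(400):
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * rng.uniform(0.0, 7.0)
        blob.append(Atom("C", "C", sg + v))
    receptor.heteroatoms.append(Residue("A", 900, "BLB", blob, role="het"))
    result = dock_covalent(receptor, _rigid_ligand(), _minimal_config(), mode="flex")
    assert len(result) == 0
    assert result.reason == "pocket blocked"
    assert result.counts["n_clash_pass"] == 0


def test_unanchorable_ligand_reports_geometry_infeasible():
    atoms = [Atom("C1", "C", [0.0, 0.0, 0.0])]
    lonely = Ligand(atoms, [], [], "atom")
    result = dock_covalent(_cys_only_receptor(), lonely,
                           _minimal_config(), mode="flex")
    assert len(result) == 0
    assert result.reason == "geometry infeasible"


# ---------------------------------------------------------------------------
# Geometry filter

def _pose_at(sg, cb, length, angle_deg):
    """Ligand whose reactive carbon sits at given thioether geometry."""
    from covflex.structio import place_atom
    c = place_atom(np.array([0.0, 0.0, 1.0]), cb, sg, length, angle_deg, 45.0)
    atoms = [Atom("C1", "C", c), Atom("C2", "C", c + [1.5, 0.0, 0.0])]
    lig = Ligand(atoms, [(0, 1, 1)], [], "probe")
    lig.props["reactive_atom"] = 0
    return CovalentPose(lig, -60.0, 0.0, (), length, angle_deg)


def test_adduct_geometry_filter():
    warhead = WarheadSpec(reactive_ligand_atom=0)
    cys = build_sidechain(Residue("A", 1, "CYS", [
        Atom("N", "N", [0.0, 0.0, 0.0]), Atom("CA", "C", [1.458, 0.0, 0.0]),
        Atom("C", "C", [2.0, 1.42, 0.0]), Atom("O", "O", [1.4, 2.44, 0.0])]), (-60.0,))
    sg = cys.require("SG").coords
    cb = cys.require("CB").coords
    ok, length, angle = check_adduct_geometry(_pose_at(sg, cb, 1.81, 100.0), warhead, cys)
    assert ok and length == pytest.approx(1.81, abs=1e-6) and angle == pytest.approx(100.0, abs=1e-6)
    ok, length, _ = check_adduct_geometry(_pose_at(sg, cb, 3.0, 100.0), warhead, cys)
    assert not ok and length == pytest.approx(3.0, abs=1e-6)
    ok, _, angle = check_adduct_geometry(_pose_at(sg, cb, 1.81, 140.0), warhead, cys)
    assert not ok and angle == pytest.approx(140.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Scoring

def test_isolated_ligand_scores_torsion_only(easy_system):
    params = ScoreParams()
    lig = easy_system.reference_pose.ligand.copy()
    lig.set_coords(lig.coords() + 500.0)
    pose = CovalentPose(lig, -60.0, 0.0, (17.0,), 1.81, 100.0)
    total, terms = score_pose(pose, easy_system.receptor, params, easy_system.site)
    assert terms["repulsion"] == 0.0
    assert terms["attraction"] == 0.0
    assert terms["hbond"] == 0.0
    assert total == pytest.approx(terms["torsion"])
    assert terms["torsion"] > 0.0


def test_repulsion_zero_at_clash_onset():
    from covflex._energy import AtomTable, pair_terms
    params = ScoreParams()
    onset = params.clash_onset_fraction * (1.70 + 1.70)

    def table(x):
        return AtomTable(np.array([[x, 0.0, 0.0]]), np.array([1.70]),
                         np.zeros(1, bool), np.zeros(1, bool),
                         np.full((1, 3), np.nan))

    rep, _, _ = pair_terms(table(0.0), table(onset), params)
    assert rep == 0.0
    rep_in, _, _ = pair_terms(table(0.0), table(onset - 0.1), params)
    assert rep_in == pytest.approx(0.1 ** 2)


def _score_oracle(pose, receptor, params, site):
    """Slow double-loop reimplementation of the pose score."""
    import math
    from covflex._energy import (_PROTEIN_ACCEPTORS_BACKBONE,
                                 _PROTEIN_ACCEPTORS_SIDE,
                                 _PROTEIN_DONORS_BACKBONE,
                                 _PROTEIN_DONORS_SIDE, _STAGGERED, ATTR_CUTOFF)
    import networkx as nx
    lig = pose.ligand
    ridx = int(lig.props["reactive_atom"])
    dist = nx.single_source_shortest_path_length(lig.graph(), ridx, cutoff=2)
    heavy = lig.heavy_indices()
    center = np.mean([lig.atoms[i].coords for i in heavy], axis=0)

    rec_atoms = []
    for res in receptor.residues:
        for a in res.heavy_atoms():
            if np.linalg.norm(a.coords - center) <= 16.0:
                rec_atoms.append((res, a))
    for het in receptor.heteroatoms:
        if het.name in ("HOH", "WAT", "DOD"):
            continue
        for a in het.heavy_atoms():
            if np.linalg.norm(a.coords - center) <= 16.0:
                rec_atoms.append((het, a))

    nbrs = {i: [] for i in heavy}
    for i, j, _ in lig.bonds:
        if i in nbrs and j in nbrs:
            nbrs[i].append(j)
            nbrs[j].append(i)

    def angle(base, centre, partner):
        v1, v2 = base - centre, partner - centre
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    rep = attr = hb = 0.0
    for li in heavy:
        la = lig.atoms[li]
        excluded_names = []
        if dist.get(li, 99) <= 2:
            excluded_names.append("SG")
        if dist.get(li, 99) <= 1:
            excluded_names.append("CB")
        for res, ra in rec_atoms:
            if res.key == site.reactive_residue and ra.name in excluded_names:
                continue
            d = float(np.linalg.norm(la.coords - ra.coords))
            onset = params.clash_onset_fraction * (la.vdw_radius + ra.vdw_radius)
            contact = min(la.vdw_radius + ra.vdw_radius, ATTR_CUTOFF - 0.1)
            if d < onset:
                rep += (onset - d) ** 2
            elif d <= ATTR_CUTOFF:
                rise = (d - onset) / max(contact - onset, 1e-9)
                fall = (ATTR_CUTOFF - d) / max(ATTR_CUTOFF - contact, 1e-9)
                attr -= max(0.0, min(1.0, rise, fall))
            lig_polar = la.element in ("N", "O")
            rec_donor = (ra.name in _PROTEIN_DONORS_BACKBONE
                         or (res.name, ra.name) in _PROTEIN_DONORS_SIDE)
            rec_acceptor = (ra.name in _PROTEIN_ACCEPTORS_BACKBONE
                            or (res.name, ra.name) in _PROTEIN_ACCEPTORS_SIDE)
            lo, hi = params.hb_distance_range
            if lig_polar and (rec_donor or rec_acceptor) and lo <= d <= hi:
                ok = True
                if nbrs[li]:
                    if angle(lig.atoms[nbrs[li][0]].coords, la.coords, ra.coords) <= params.hb_min_angle:
                        ok = False
                base = None
                best = 1.9
                for other in res.heavy_atoms():
                    if other is ra:
                        continue
                    dd = float(np.linalg.norm(other.coords - ra.coords))
                    if dd < best:
                        base, best = other, dd
                if ok and base is not None:
                    if angle(base.coords, ra.coords, la.coords) <= params.hb_min_angle:
                        ok = False
                if ok:
                    hb -= 1.0
    tors = 0.0
    for t in pose.torsion_values:
        dev = np.abs((((t - _STAGGERED) + 180.0) % 360.0) - 180.0).min()
        tors += float((dev / 60.0) ** 2)
    return (params.w_rep * rep + params.w_attr * attr + params.w_hb * hb
            + params.w_tors * tors)


def test_score_matches_double_loop_oracle(easy_system):
    params = ScoreParams()
    rng = np.random.default_rng(12)
    base = easy_system.reference_pose.ligand
    for k in range(20):
        lig = base.copy()
        R_jitter = rng.normal(scale=0.7, size=(len(lig.atoms), 3))
        lig.set_coords(lig.coords() + R_jitter + rng.normal(scale=2.0, size=3))
        pose = CovalentPose(lig, -60.0, 0.0, tuple(rng.uniform(-180, 180, 2)), 1.81, 100.0)
        ours, terms = score_pose(pose, easy_system.receptor, params, easy_system.site)
        oracle = _score_oracle(pose, easy_system.receptor, params, easy_system.site)
        assert ours == pytest.approx(oracle, abs=1e-9), f"pose {k}"
        assert sum(terms.values()) == pytest.approx(ours, abs=1e-12)


def test_repulsion_monotone_on_core_translation():
    """Pushing the ligand into a solid receptor core never lowers repulsion."""
    params = ScoreParams()
    receptor = _cys_only_receptor()
    rng = np.random.default_rng(5)
    core_center = np.array([20.0, 0.0, 0.0])
    blob = [Atom("C", "C", core_center + rng.normal(scale=2.0, size=3))
            for _ in range(300)]
    receptor.heteroatoms.append(Residue("A", 900, "BLB", blob, role="het"))
    lig0 = _rigid_ligand()
    start = core_center + np.array([12.0, 0.0, 0.0])
    site = BindingSiteSpec(("A", 1), [("A", 1)])
    last = -1.0
    for step in np.linspace(0.0, 12.0, 25):
        lig = lig0.copy()
        lig.props["reactive_atom"] = 0
        lig.set_coords(lig.coords() + start - np.array([step, 0.0, 0.0]))
        pose = CovalentPose(lig, -60.0, 0.0, (), 1.81, 100.0)
        _, terms = score_pose(pose, receptor, params, site)
        assert terms["repulsion"] >= last - 1e-9
        last = terms["repulsion"]
    assert last > 0.0


# ---------------------------------------------------------------------------
# Clustering

def _poses_from_coords(coord_sets, scores):
    poses = []
    for k, (xyz, s) in enumerate(zip(coord_sets, scores)):
        atoms = [Atom(f"C{i+1}", "C", p) for i, p in enumerate(xyz)]
        bonds = [(i, i + 1, 1) for i in range(len(atoms) - 1)]
        lig = Ligand(atoms, bonds, [], f"p{k}")
        poses.append(CovalentPose(lig, -60.0, 0.0, (), 1.81, 100.0,
                                  score_total=s, index=k))
    return poses


def test_cluster_trivial_cases():
    base = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
    single = _poses_from_coords([base], [0.0])
    assert len(cluster_poses(single, 1.0)) == 1
    pair = _poses_from_coords([base, base], [1.0, 0.0])
    clusters = cluster_poses(pair, 1.0)
    assert len(clusters) == 1 and len(clusters[0]) == 2
    assert clusters[0][0].score_total == 0.0  # representative = lowest score


def _leader_oracle(poses, cutoff):
    ordered = sorted(poses, key=lambda p: (p.score_total, p.index))
    leaders, assign = [], {}
    for p in ordered:
        xyz = p.heavy_coords()
        for ci, lead in enumerate(leaders):
            if np.sqrt(np.mean(((xyz - lead) ** 2).sum(axis=1))) <= cutoff:
                assign[p.index] = ci
                break
        else:
            assign[p.index] = len(leaders)
            leaders.append(xyz)
    return assign


def test_cluster_matches_leader_oracle():
    rng = np.random.default_rng(8)
    base = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])
    coords = [base + rng.normal(scale=1.2, size=3) for _ in range(50)]
    scores = list(rng.normal(size=50))
    poses = _poses_from_coords(coords, scores)
    clusters = cluster_poses(poses, 1.5)
    oracle = _leader_oracle(poses, 1.5)
    for cl in clusters:
        for p in cl:
            assert p.cluster_id == oracle[p.index]
    reps = [cl[0].heavy_coords() for cl in clusters]
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            rmsd = np.sqrt(np.mean(((reps[i] - reps[j]) ** 2).sum(axis=1)))
            assert rmsd > 1.5


# ---------------------------------------------------------------------------
# Full pipeline properties

def test_dock_deterministic(blocking_system):
    config = DockJobConfig(site=blocking_system.site, warhead=blocking_system.warhead, seed=11)
    a = dock_covalent(blocking_system.receptor, blocking_system.ligand, config, mode="flex")
    b = dock_covalent(blocking_system.receptor, blocking_system.ligand, config, mode="flex")
    assert len(a) == len(b)
    for pa, pb in zip(a.poses, b.poses):
        assert pa.score_total == pb.score_total
        assert np.array_equal(pa.ligand.coords(), pb.ligand.coords())


def test_emitted_poses_satisfy_geometry_and_ranking(blocking_system, dock_cache):
    result = dock_cache(3, "blocking", 3, "flex")
    warhead = blocking_system.warhead
    assert [p.rank for p in result.poses] == list(range(1, len(result) + 1))
    assert result.poses[0].score_total == min(p.score_total for p in result.poses)
    for pose in result.poses:
        assert abs(pose.bond_length - warhead.bond_length_target) <= warhead.bond_length_tol
        assert abs(pose.bond_angle - warhead.bond_angle_target) <= warhead.bond_angle_tol
        assert sum(pose.score_terms.values()) == pytest.approx(pose.score_total, abs=1e-9)


def test_blocking_mutation_never_reduces_candidates(blocking_system):
    config = DockJobConfig(site=blocking_system.site, warhead=blocking_system.warhead)
    plain = blocking_system.receptor.copy()
    plain, recs = mutate_to(plain, [blocking_system.site.reactive_residue], "ALA")
    _, counts_plain = enumerate_poses(plain, blocking_system.ligand, config, "rigid")
    opened = blocking_system.receptor.copy()
    opened, _ = mutate_to(opened, blocking_system.site.blocking_residues
                          + [blocking_system.site.reactive_residue], "ALA")
    _, counts_open = enumerate_poses(opened, blocking_system.ligand, config, "rigid")
    assert counts_open["n_clash_pass"] >= counts_plain["n_clash_pass"]


def test_flex_recovers_blocked_pose_better_than_rigid(blocking_system, dock_cache):
    flex = dock_cache(3, "blocking", 3, "flex")
    rigid = dock_cache(3, "blocking", 3, "rigid")
    best_flex = best_rmsd_topn(flex, blocking_system.reference_pose, 20)
    best_rigid = best_rmsd_topn(rigid, blocking_system.reference_pose, 20)
    assert best_flex <= best_rigid + 1e-9
    assert best_flex <= 1.0
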