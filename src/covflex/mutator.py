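"""Residue mutation/restoration and a coarse-grained loop-transition toy.

Two jobs live here.  First, the reversible side-chain truncation used by
the docking pipeline: blocking residues (and the reactive cysteine) are
mutated to alanine to open the pocket before pose enumeration and restored
afterwards.  Restoration re-anchors the archived side chain on the local
backbone frame (N, CA, C), so it stays well defined even if the backbone
drifted between mutation and restoration; when the backbone is untouched
the original coordinates are reproduced exactly.

Second, a glycine-mutant receptor preparation for downstream free-energy
engines, together with a minimal Metropolis Monte-Carlo simulator that
demonstrates why glycine substitutions accelerate backbone conformational
transitions: per-torsion periodic potentials with residue-type-dependent
barrier heights yield first-passage times that grow steeply with the
barrier.  The simulator is a didactic kinetic model, not an MD surrogate.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import numpy as np

from .structio import Atom, ProteinStructure, Residue, StructIOError

log = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "MutationError",
    "mutate_to",
    "restore",
    "prepare_loop_mutant",
    "ToyLoopModel",
    "FirstPassage",
    "simulate_loop_transition",
    "compare_barriers",
]

_BACKBONE_KEEP = ("N", "CA", "C", "O", "OXT")


class MutationError(StructIOError):
    pass


def backbone_frame(residue: Residue) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal local frame (origin at CA) from N, CA, C."""
    n = residue.require("N").coords
    ca = residue.require("CA").coords
    c = residue.require("C").coords
    x = n - ca
    x = x / np.linalg.norm(x)
    z = np.cross(x, c - ca)
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise MutationError(f"degenerate backbone frame at {residue.chain_id}:{residue.resnum}")
    z /= nz
    y = np.cross(z, x)
    return ca, np.column_stack([x, y, z])


@dataclass
class MutationRecord:
    """Everything needed to restore a truncated residue exactly."""

    residue_key: tuple[str, int]
    original_name: str
    mutant_name: str
    removed_atoms: list[Atom]
    local_coords: np.ndarray            # removed-atom coords in the backbone frame
    backbone_snapshot: np.ndarray       # N, CA, C coords at mutation time


def mutate_to(structure: ProteinStructure, residues: list[tuple[str, int]],
              target: str) -> tuple[ProteinStructure, list[MutationRecord]]:
    """Truncate the given residues to ALA or GLY, archiving removed atoms.

    ALA keeps the backbone plus CB; GLY keeps the backbone only.  Backbone
    and retained-atom coordinates are untouched.  Mutating GLY to ALA is an
    error (there is no CB to keep); mutating a residue to its own identity
    is a no-op with an empty record.
    """
    target = target.upper()
    if target not in ("ALA", "GLY"):
        raise MutationError(f"mutation target must be ALA or GLY, got {target!r}")
    keep = set(_BACKBONE_KEEP) | ({"CB"} if target == "ALA" else set())
    records = []
    for key in residues:
        res = structure.get(*key)
        if res.name == "GLY" and target == "ALA":
            raise MutationError(f"cannot mutate GLY {key[0]}:{key[1]} to ALA (no CB)")
        if not res.has_backbone:
            raise MutationError(f"residue {key[0]}:{key[1]} lacks backbone atoms")
        removed = [a for a in res.atoms if a.name not in keep]
        origin, R = backbone_frame(res)
        local = np.array([(R.T @ (a.coords - origin)) for a in removed]).reshape(-1, 3)
        snapshot = np.array([res.require(n).coords for n in ("N", "CA", "C")])
        records.append(MutationRecord(key, res.name, target,
                                      [a.copy() for a in removed], local, snapshot))
        res.atoms = [a for a in res.atoms if a.name in keep]
        res.name = target
    return structure, records


def restore(structure: ProteinStructure,
            records: list[MutationRecord]) -> ProteinStructure:
    """Reinstate archived side chains, re-anchored on the local backbone frame.

    If the backbone has not moved since mutation the original coordinates
    are reproduced exactly; otherwise the side chain co-rotates rigidly with
    the (N, CA, C) frame.
    """
    for rec in reversed(records):
        try:
            res = structure.get(*rec.residue_key)
        except KeyError as exc:
            raise MutationError(f"cannot restore: {exc}") from exc
        if res.name != rec.mutant_name:
            raise MutationError(
                f"record/residue mismatch at {rec.residue_key}: residue is "
                f"{res.name}, record expects {rec.mutant_name}")
        snapshot = np.array([res.require(n).coords for n in ("N", "CA", "C")])
        if np.allclose(snapshot, rec.backbone_snapshot, atol=1e-9):
            restored = [a.copy() for a in rec.removed_atoms]
        else:
            origin, R = backbone_frame(res)
            restored = []
            for a, local in zip(rec.removed_atoms, rec.local_coords):
                b = a.copy()
                b.coords = origin + R @ local
                restored.append(b)
        res.atoms.extend(restored)
        res.name = rec.original_name
    return structure


def prepare_loop_mutant(structure: ProteinStructure,
                        mutations: list[tuple[str, int]],
                        ligand=None,
                        reactive_residue: tuple[str, int] | None = None,
                        contact_cutoff: float = 4.0,
                        ) -> tuple[ProteinStructure, list[MutationRecord], dict]:
    """Glycine-mutant receptor preparation for external free-energy engines.

    Mutates the requested loop residues to glycine and reports two safety
    checks: runs of >=3 consecutive glycines created by the mutations (a
    deliberate mobility enhancer, but worth flagging), and any mutated
    residue whose original side chain lay within ``contact_cutoff`` of
    ligand heavy atoms — the strategy assumes mutated side chains do not
    contact the ligand, so such contacts void its premise.
    """
    if reactive_residue is not None and reactive_residue in mutations:
        raise MutationError("refusing to mutate the reactive cysteine")
    for key in mutations:
        res = structure.get(*key)
        if res.name == "CYS" and res.role == "reactive":
            raise MutationError("refusing to mutate the reactive cysteine")

    contacts = []
    if ligand is not None:
        lig_xyz = np.array([ligand.atoms[i].coords for i in ligand.heavy_indices()])
        for key in mutations:
            side = structure.get(*key).sidechain_atoms()
            for a in side:
                d = np.linalg.norm(lig_xyz - a.coords, axis=1).min() if len(lig_xyz) else np.inf
                if d < contact_cutoff:
                    contacts.append({"residue": f"{key[0]}:{key[1]}", "atom": a.name,
                                     "min_distance": round(float(d), 3)})
                    log.warning("mutation residue %s:%s side chain within %.1f A of ligand",
                                key[0], key[1], contact_cutoff)
                    break

    mutant, records = mutate_to(structure, mutations, "GLY")

    gly_runs = []
    for chain_id in mutant.chains:
        chain_res = [r for r in mutant.residues if r.chain_id == chain_id]
        run: list[Residue] = []
        for r in chain_res + [None]:
            if r is not None and r.name == "GLY" and (not run or r.resnum == run[-1].resnum + 1):
                run.append(r)
                continue
            if len(run) >= 3 and any((g.chain_id, g.resnum) in mutations for g in run):
                gly_runs.append({
                    "chain": chain_id,
                    "resnums": [g.resnum for g in run],
                    "note": f"{len(run)} consecutive glycines",
                })
                log.warning("mutations created %d consecutive glycines in chain %s", len(run), chain_id)
            run = [r] if (r is not None and r.name == "GLY") else []
    report = {
        "mutations": [{"residue": f"{rec.residue_key[0]}:{rec.residue_key[1]}",
                       "from": rec.original_name, "to": rec.mutant_name}
                      for rec in records],
        "consecutive_glycine_runs": gly_runs,
        "ligand_contacts": contacts,
    }
    return mutant, records, report


# ---------------------------------------------------------------------------
# Coarse-grained loop-transition kinetics

@dataclass
class ToyLoopModel:
    """Per-residue (phi, psi) torsions on a periodic multi-well potential.

    Each torsion feels U(d) = h*(1 - cos(3d))/2 + tilt*(1 - cos(d))/2 where
    d is the deviation from the start well; adjacent minima sit 120 deg
    apart and the start well is destabilized by the tilt so trajectories
    drain toward the +/-120 deg target basin.  The barrier height h is set
    per residue by type: glycine backbones cross far lower barriers than
    side-chain-bearing residues, which is the entire point of the
    loop-to-glycine receptor preparation.
    """

    n_residues: int
    residue_types: list[str] = field(default_factory=list)  # "GLY" | "nonGLY"
    barrier_height_gly: float = 2.0       # kT
    barrier_height_nongly: float = 6.0    # kT
    tilt: float = 1.0                     # kT; destabilizes the start well
    move_sigma: float = 15.0              # deg; Gaussian torsion perturbation
    target_basin: list[tuple[float, float]] = field(
        default_factory=lambda: [(120.0, 30.0), (-120.0, 30.0)])
    start_torsions: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("empty loop model")
        if not self.residue_types:
            self.residue_types = ["nonGLY"] * self.n_residues
        if len(self.residue_types) != self.n_residues:
            raise ValueError("residue_types length must match n_residues")
        if not self.barrier_height_gly < self.barrier_height_nongly:
            raise ValueError("glycine barrier must be below the non-glycine barrier")

    def barrier(self, i: int) -> float:
        return (self.barrier_height_gly if self.residue_types[i] == "GLY"
                else self.barrier_height_nongly)


@dataclass
class FirstPassage:
    steps: int
    censored: bool


def _in_basin(angle: float, basin: list[tuple[float, float]]) -> bool:
    for center, half in basin:
        d = abs((angle - center + 180.0) % 360.0 - 180.0)
        if d <= half:
            return True
    return False


def simulate_loop_transition(model: ToyLoopModel, n_steps: int, seed: int) -> FirstPassage:
    """Metropolis MC first-passage time into the target basin (all torsions).

    One step perturbs one randomly chosen torsion by a Gaussian move and
    accepts by the Metropolis criterion at kT = 1.  Returns the first step
    at which every torsion lies in the target basin, or a censored result
    at ``n_steps``.  Deterministic given the seed.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = random.Random(seed)
    n = model.n_residues
    torsions = [list(t) for t in (model.start_torsions or [(0.0, 0.0)] * n)]
    if len(torsions) != n:
        raise ValueError("start_torsions length must match n_residues")
    barriers = [model.barrier(i) for i in range(n)]
    tilt = model.tilt
    basin = model.target_basin
    rad = math.pi / 180.0

    def u(angle: float, h: float) -> float:
        d = angle * rad
        return 0.5 * h * (1.0 - math.cos(3.0 * d)) + 0.5 * tilt * (1.0 - math.cos(d))

    in_target = [[_in_basin(a, basin) for a in pair] for pair in torsions]
    n_out = sum(1 for pair in in_target for v in pair if not v)
    if n_out == 0:
        return FirstPassage(0, False)

    gauss = rng.gauss
    uniform = rng.random
    randint = rng.randrange
    exp = math.exp
    for step in range(1, n_steps + 1):
        k = randint(2 * n)
        i, j = divmod(k, 2)
        old = torsions[i][j]
        new = (old + gauss(0.0, model.move_sigma) + 180.0) % 360.0 - 180.0
        du = u(new, barriers[i]) - u(old, barriers[i])
        if du <= 0.0 or uniform() < exp(-du):
            torsions[i][j] = new
            was = in_target[i][j]
            now = _in_basin(new, basin)
            if now != was:
                in_target[i][j] = now
                n_out += -1 if now else 1
                if n_out == 0:
                    return FirstPassage(step, False)
    return FirstPassage(n_steps, True)


def compare_barriers(n_pairs: int, n_steps: int, seed: int,
                     n_residues: int = 3,
                     barrier_gly: float = 2.0,
                     barrier_nongly: float = 6.0) -> dict:
    """Paired all-GLY vs all-nonGLY first-passage comparison.

    For each paired seed, runs one all-glycine and one all-non-glycine loop
    from the same stream seed and records which finished first (censored
    runs count at the cap).  Returns summary statistics used by the CLI and
    the acceptance battery.
    """
    gly_fpts, non_fpts, wins, ties = [], [], 0, 0
    for k in range(n_pairs):
        pair_seed = (seed * 1000003 + k) % (2 ** 31)
        mg = ToyLoopModel(n_residues, ["GLY"] * n_residues,
                          barrier_height_gly=barrier_gly, barrier_height_nongly=barrier_nongly)
        mn = ToyLoopModel(n_residues, ["nonGLY"] * n_residues,
                          barrier_height_gly=barrier_gly, barrier_height_nongly=barrier_nongly)
        fg = simulate_loop_transition(mg, n_steps, pair_seed)
        fn = simulate_loop_transition(mn, n_steps, pair_seed + 1)
        gly_fpts.append(fg.steps)
        non_fpts.append(fn.steps)
        if fg.steps < fn.steps:
            wins += 1
        elif fg.steps == fn.steps:
            ties += 1
    return {
        "n_pairs": n_pairs,
        "gly_median_fpt": float(np.median(gly_fpts)),
        "nongly_median_fpt": float(np.median(non_fpts)),
        "gly_faster_fraction": wins / n_pairs,
        "ties": ties,
        "barrier_gly": barrier_gly,
        "barrier_nongly": barrier_nongly,
        "n_steps_cap": n_steps,
    }
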