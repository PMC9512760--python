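"""Cross-docking evaluation: RMSD metrics, docking matrices, success curves.

The benchmark protocol docks every ligand of a manifest into every
receptor (the diagonal being self-docking), measures symmetry-corrected
heavy-atom RMSD of each emitted pose against the crystal/reference pose
transformed into the docking receptor's frame, and tabulates top-N success
fractions over RMSD cutoffs.

Pose accuracy is measured in a common frame established by superposing the
reference complex's receptor onto the docking receptor on all shared CA
atoms; the ligand itself is never re-superposed.  Chemically equivalent
atom mappings (graph automorphisms preserving element and bond order) are
enumerated so that, e.g., a para-phenyl flip does not inflate the RMSD.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from itertools import islice
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dockcore import DockJobConfig, dock_covalent
from .structio import Ligand, WarheadSpec, read_ligand_sdf, read_pdb, superpose

log = logging.getLogger(__name__)

__all__ = [
    "BenchmarkManifest",
    "ManifestEntry",
    "JobResult",
    "BenchmarkResult",
    "ligand_rmsd",
    "identity_rmsd",
    "run_matrix",
    "success_curves",
    "plot_success_bars",
]

DEFAULT_CUTOFFS = (2.0, 2.5)
DEFAULT_TOPNS = (1, 5, 20)
_MAX_AUTOMORPHISMS = 10000


@dataclass
class ManifestEntry:
    system_id: str
    receptor: Path
    ligand: Path
    reference: Path
    cognate: bool = True


@dataclass
class BenchmarkManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.system_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest system_ids must be unique")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BenchmarkManifest":
        path = Path(path)
        df = pd.read_csv(path)
        required = {"system_id", "receptor", "ligand", "reference", "cognate"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        entries = []
        for _, row in df.iterrows():
            entries.append(ManifestEntry(
                str(row["system_id"]),
                path.parent / str(row["receptor"]),
                path.parent / str(row["ligand"]),
                path.parent / str(row["reference"]),
                bool(int(row["cognate"]))))
        return cls(entries)


# ---------------------------------------------------------------------------
# Symmetry-corrected RMSD

def _element_bond_graph(lig: Ligand) -> nx.Graph:
    g = nx.Graph()
    heavy = set(lig.heavy_indices())
    for i in heavy:
        g.add_node(i, element=lig.atoms[i].element)
    for i, j, order in lig.bonds:
        if i in heavy and j in heavy:
            g.add_edge(i, j, order=order)
    return g


def _automorphisms(lig: Ligand, limit: int = _MAX_AUTOMORPHISMS):
    """Element- and bond-order-preserving graph automorphisms (capped)."""
    g = _element_bond_graph(lig)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"])
    return islice(gm.isomorphisms_iter(), limit)


def identity_rmsd(pose_coords: np.ndarray, ref_coords: np.ndarray) -> float:
    d = np.asarray(pose_coords, float) - np.asarray(ref_coords, float)
    return float(np.sqrt(np.mean((d ** 2).sum(axis=1))))


def ligand_rmsd(pose, reference: Ligand, symmetry: bool = True) -> float:
    """Heavy-atom RMSD minimized over chemically equivalent atom mappings.

    ``pose`` is a CovalentPose or a Ligand; both molecules must be the same
    chemical species in a common coordinate frame (no re-superposition).
    Hydrogens are stripped before comparison.
    """
    pose_lig: Ligand = pose.ligand if hasattr(pose, "ligand") else pose
    heavy_p = pose_lig.heavy_indices()
    heavy_r = reference.heavy_indices()
    if len(heavy_p) != len(heavy_r):
        raise ValueError(
            f"heavy-atom count mismatch: pose has {len(heavy_p)}, reference {len(heavy_r)}")
    formula_p = sorted(pose_lig.atoms[i].element for i in heavy_p)
    formula_r = sorted(reference.atoms[i].element for i in heavy_r)
    if formula_p != formula_r:
        raise ValueError(f"formula mismatch after hydrogen stripping: "
                         f"{formula_p} vs {formula_r}")
    pose_xyz = {i: pose_lig.atoms[i].coords for i in heavy_p}
    ref_xyz = {i: reference.atoms[i].coords for i in heavy_r}
    base = identity_rmsd(np.array([pose_xyz[i] for i in heavy_p]),
                         np.array([ref_xyz[i] for i in heavy_r]))
    if not symmetry:
        return base
    best = base
    for mapping in _automorphisms(reference):
        # mapping permutes reference atom indices among equivalent positions
        ref_perm = np.array([ref_xyz[mapping[i]] for i in heavy_r])
        pose_arr = np.array([pose_xyz[i] for i in heavy_p])
        best = min(best, identity_rmsd(pose_arr, ref_perm))
    return best


# ---------------------------------------------------------------------------
# Matrix protocol

@dataclass
class JobResult:
    receptor_id: str
    ligand_id: str
    is_self_docking: bool
    pose_rmsds: list[float]            # symmetry-corrected, rank order
    pose_rmsds_identity: list[float]   # without symmetry correction
    n_poses: int
    reason: str = ""

    def best_rmsd_topn(self, n: int) -> float:
        vals = self.pose_rmsds[:n]
        return min(vals) if vals else float("inf")

    @property
    def best_rmsd_top1(self) -> float:
        return self.best_rmsd_topn(1)


@dataclass
class BenchmarkResult:
    jobs: list[JobResult]
    mode: str
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j in self.jobs:
            rows.append({
                "receptor_id": j.receptor_id, "ligand_id": j.ligand_id,
                "self_docking": j.is_self_docking, "n_poses": j.n_poses,
                "best_rmsd_top1": j.best_rmsd_topn(1),
                "best_rmsd_top5": j.best_rmsd_topn(5),
                "best_rmsd_top20": j.best_rmsd_topn(20),
                "reason": j.reason,
            })
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "jobs.tsv", sep="\t", index=False,
                                   float_format="%.4f")
        payload = {
            "mode": self.mode, "seed": self.seed, "n_jobs": len(self.jobs),
            "jobs": [{
                "receptor_id": j.receptor_id, "ligand_id": j.ligand_id,
                "self_docking": j.is_self_docking,
                "pose_rmsds": [round(v, 4) for v in j.pose_rmsds],
                "pose_rmsds_identity": [round(v, 4) for v in j.pose_rmsds_identity],
                "reason": j.reason,
            } for j in self.jobs],
        }
        (outdir / "results.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read(cls, outdir: str | Path) -> "BenchmarkResult":
        payload = json.loads((Path(outdir) / "results.json").read_text())
        jobs = [JobResult(j["receptor_id"], j["ligand_id"], j["self_docking"],
                          j["pose_rmsds"], j.get("pose_rmsds_identity", []),
                          len(j["pose_rmsds"]), j.get("reason", ""))
                for j in payload["jobs"]]
        return cls(jobs, payload["mode"], payload["seed"])


def _job_seed(global_seed: int, receptor_id: str, ligand_id: str) -> int:
    tag = f"{receptor_id}|{ligand_id}".encode()
    return (global_seed * 1000003 + zlib.crc32(tag)) % (2 ** 31)


def _warhead_for(ligand: Ligand, template: WarheadSpec | None) -> WarheadSpec:
    """Resolve the warhead: SDF tag, template, or acrylamide SMARTS match."""
    if "REACTIVE_ATOM_INDEX" in ligand.props:
        idx = int(ligand.props["REACTIVE_ATOM_INDEX"])
        base = template or WarheadSpec(reactive_ligand_atom=idx)
        return WarheadSpec(idx, base.bond_length_target, base.bond_length_tol,
                           base.bond_angle_target, base.bond_angle_tol,
                           _acrylamide_bond_changes(ligand, idx))
    if template is not None:
        return template
    from rdkit import Chem
    mol = ligand.to_rdkit()
    patt = Chem.MolFromSmarts("[CH2]=[CH]C(=O)N")
    matches = mol.GetSubstructMatches(patt)
    if not matches:
        raise ValueError(f"ligand {ligand.name}: no declared warhead and no acrylamide found")
    idx = matches[0][0]
    return WarheadSpec(idx, modified_bonds=_acrylamide_bond_changes(ligand, idx))


def _acrylamide_bond_changes(ligand: Ligand, reactive_idx: int) -> list[tuple[int, int, int]]:
    for i, j, order in ligand.bonds:
        if order == 2 and reactive_idx in (i, j):
            return [(i, j, 1)]
    return []


def run_matrix(manifest: BenchmarkManifest, config_factory, mode: str = "flex",
               seed: int = 0, self_only: bool = False,
               progress: bool = False) -> BenchmarkResult:
    """All-against-all (or diagonal-only) covalent docking over a manifest.

    ``config_factory(receptor_entry, ligand, job_seed)`` must return the
    DockJobConfig for one job — the caller owns site/score configuration
    (see :func:`_warhead_for` for warhead resolution from SDF tags).
    Reference poses are transformed into each docking receptor's frame by
    whole-CA superposition of their cognate receptor.  Failed jobs (no
    emitted poses) are recorded with empty RMSD lists, never dropped.
    """
    receptors, ligands, references = {}, {}, {}
    for e in manifest.entries:
        receptors[e.system_id] = read_pdb(e.receptor)
        ligands[e.system_id] = read_ligand_sdf(e.ligand)
        references[e.system_id] = read_ligand_sdf(e.reference)

    jobs: list[JobResult] = []
    for er in manifest.entries:
        for el in manifest.entries:
            if self_only and er.system_id != el.system_id:
                continue
            rec = receptors[er.system_id]
            lig = ligands[el.system_id]
            ref = references[el.system_id].copy()
            if er.system_id != el.system_id:
                sup = superpose(receptors[el.system_id], rec, "CA")
                ref.set_coords(sup.apply(ref.coords()))
            job_seed = _job_seed(seed, er.system_id, el.system_id)
            config = config_factory(er, lig, job_seed)
            try:
                result = dock_covalent(rec, lig, config, mode=mode)
                rmsds = [ligand_rmsd(p, ref) for p in result.poses]
                rmsds_id = [ligand_rmsd(p, ref, symmetry=False) for p in result.poses]
                jobs.append(JobResult(er.system_id, el.system_id,
                                      er.system_id == el.system_id,
                                      rmsds, rmsds_id, len(result.poses),
                                      result.reason))
            except Exception as exc:  # a failed job must not abort the matrix
                log.warning("job %s x %s failed: %s", er.system_id, el.system_id, exc)
                jobs.append(JobResult(er.system_id, el.system_id,
                                      er.system_id == el.system_id,
                                      [], [], 0, f"error: {exc}"))
            if progress:
                log.info("done %s x %s", er.system_id, el.system_id)
    jobs.sort(key=lambda j: (j.receptor_id, j.ligand_id))
    return BenchmarkResult(jobs, mode, seed)


def success_curves(results: BenchmarkResult,
                   cutoffs=DEFAULT_CUTOFFS,
                   topns=DEFAULT_TOPNS) -> pd.DataFrame:
    """Success fraction per (RMSD cutoff, top-N); jobs with no poses fail."""
    if not results.jobs:
        raise ValueError("empty result set")
    rows = []
    for cutoff in cutoffs:
        for n in topns:
            wins = sum(1 for j in results.jobs if j.best_rmsd_topn(n) <= cutoff)
            rows.append({"cutoff": cutoff, "top_n": n,
                         "success": wins / len(results.jobs),
                         "n_jobs": len(results.jobs)})
    return pd.DataFrame(rows)


def plot_success_bars(curves: pd.DataFrame, path: str | Path,
                      label: str = "") -> None:
    """Bar chart of success fractions by cutoff and top-N."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cutoffs = sorted(curves["cutoff"].unique())
    topns = sorted(curves["top_n"].unique())
    width = 0.8 / len(topns)
    fig, ax = plt.subplots(figsize=(1.8 * len(cutoffs) + 2, 3.4))
    for k, n in enumerate(topns):
        sub = curves[curves["top_n"] == n].sort_values("cutoff")
        xs = np.arange(len(cutoffs)) + k * width
        ax.bar(xs, sub["success"], width=width, label=f"top-{n}")
    ax.set_xticks(np.arange(len(cutoffs)) + 0.4 - width / 2)
    ax.set_xticklabels([f"{c:g} " + "Å" for c in cutoffs])
    ax.set_ylabel("success fraction")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    if label:
        ax.set_title(label, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
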