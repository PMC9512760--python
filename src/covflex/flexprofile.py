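"""Side-chain torsion profiling and binding-site residue classification.

Given a superposed ensemble of receptor structures, this module computes
chi1/chi2 distributions per binding-site residue, classifies residues as
rigid or flexible (circular spread, multimodality, or backbone movement),
and identifies the subset of flexible residues that sterically block the
cross-docking of non-cognate ligand poses.  The resulting residue lists are
the inputs that drive the flexible-receptor docking pipeline.

Classification is threshold-based and every threshold is config-exposed via
:class:`ProfileParams`; the defaults (30 deg circular std, two or more chi1
modes, 1.0 A backbone displacement) are deliberately conservative so that
crystallographic noise does not inflate the flexible set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import circstd

from .structio import GeometryError, Ligand, ProteinStructure, Residue, dihedral

log = logging.getLogger(__name__)

__all__ = [
    "CHI1_GAMMA_ATOM",
    "CHI2_DELTA_ATOM",
    "TorsionRecord",
    "ResidueFlexibility",
    "FlexibilityProfile",
    "ProfileParams",
    "BindingSiteSpec",
    "chi_angles",
    "ensemble_torsions",
    "profile_ensemble",
    "detect_blocking",
    "parse_residue_key",
    "format_residue_key",
    "plot_chi_scatter",
]

# chi1 = dihedral(N, CA, CB, Xg); the gamma atom name depends on residue type.
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

# chi2 = dihedral(CA, CB, Xg, Xd).
CHI2_DELTA_ATOM: dict[str, str] = {
    "ARG": "CD", "ASN": "OD1", "ASP": "OD1", "GLN": "CD", "GLU": "CD",
    "HIS": "ND1", "ILE": "CD1", "LEU": "CD1", "LYS": "CD", "MET": "SD",
    "PHE": "CD1", "PRO": "CD", "TRP": "CD1", "TYR": "CD1",
}


def parse_residue_key(text: str) -> tuple[str, int]:
    """Parse 'A:95' into ('A', 95)."""
    chain, _, num = text.partition(":")
    if not chain or not num:
        raise ValueError(f"bad residue key {text!r}; expected 'CHAIN:RESNUM'")
    return chain, int(num)


def format_residue_key(key: tuple[str, int]) -> str:
    return f"{key[0]}:{key[1]}"


def chi_angles(residue: Residue) -> tuple[float | None, float | None]:
    """(chi1, chi2) in degrees; None where the defining atoms are absent.

    GLY and ALA have no chi torsions by definition; truncated side chains
    yield None rather than an error (absence is a value).
    """
    gamma_name = CHI1_GAMMA_ATOM.get(residue.name)
    if gamma_name is None:
        return None, None
    n, ca, cb, g = (residue.atom(a) for a in ("N", "CA", "CB", gamma_name))
    if any(a is None for a in (n, ca, cb, g)):
        return None, None
    try:
        chi1 = dihedral(n.coords, ca.coords, cb.coords, g.coords)
    except GeometryError:
        return None, None
    delta_name = CHI2_DELTA_ATOM.get(residue.name)
    chi2 = None
    if delta_name is not None:
        d = residue.atom(delta_name)
        if d is not None:
            try:
                chi2 = dihedral(ca.coords, cb.coords, g.coords, d.coords)
            except GeometryError:
                chi2 = None
    return chi1, chi2


@dataclass
class TorsionRecord:
    residue_key: tuple[str, int, str]  # (chain, resnum, residue name)
    chi1: float | None
    chi2: float | None
    source_id: str


def ensemble_torsions(structures: list[ProteinStructure],
                      site_residues: list[tuple[str, int]]) -> list[TorsionRecord]:
    """Collect chi1/chi2 observations for the given residues across an ensemble."""
    records = []
    for st in structures:
        for key in site_residues:
            if not st.has(*key):
                continue
            res = st.get(*key)
            chi1, chi2 = chi_angles(res)
            records.append(TorsionRecord((key[0], key[1], res.name), chi1, chi2, st.source_id))
    return records


@dataclass
class ProfileParams:
    """Thresholds for flexibility classification and blocking detection."""

    circ_std_threshold: float = 30.0      # deg; chi1 spread above this -> flexible
    backbone_threshold: float = 1.0       # A; max CA excursion above this -> flexible
    bin_width: float = 30.0               # deg; circular histogram bin for mode finding
    mode_min_occupancy: float = 0.10      # fraction of observations a mode needs
    overlap_fraction: float = 0.70        # of summed vdW radii; hard-core overlap
    min_clash_atoms: int = 2              # ligand atoms one side-chain atom must hit


@dataclass
class ResidueFlexibility:
    key: tuple[str, int]
    name: str
    circular_std_chi1: float | None
    circular_std_chi2: float | None
    n_modes_chi1: int
    n_modes_chi2: int
    occupancy: float
    backbone_disp: float
    classification: str | None  # "rigid" | "flexible" | None (never resolved)
    blocking: bool = False


@dataclass
class FlexibilityProfile:
    residues: dict[tuple[str, int], ResidueFlexibility]
    params: ProfileParams = field(default_factory=ProfileParams)

    def flexible_keys(self) -> list[tuple[str, int]]:
        return [k for k, r in self.residues.items() if r.classification == "flexible"]

    def mark_blocking(self, keys: list[tuple[str, int]]) -> None:
        """Set the blocking flag; only flexible residues can block."""
        flexible = set(self.flexible_keys())
        bad = [k for k in keys if k not in flexible]
        if bad:
            raise ValueError(f"blocking residues must be classified flexible: {bad}")
        for k in keys:
            self.residues[k].blocking = True

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, r in self.residues.items():
            rows.append({
                "residue": format_residue_key(k), "name": r.name,
                "circ_std_chi1": r.circular_std_chi1, "circ_std_chi2": r.circular_std_chi2,
                "n_modes_chi1": r.n_modes_chi1, "n_modes_chi2": r.n_modes_chi2,
                "occupancy": r.occupancy, "backbone_disp": r.backbone_disp,
                "classification": r.classification, "blocking": r.blocking,
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.4f")


def _circular_modes(angles: np.ndarray, bin_width: float, min_frac: float) -> int:
    """Number of circular runs of occupied histogram bins.

    A bin is occupied when it holds at least ``min_frac`` of the observations
    (never fewer than one); contiguous occupied bins (circularly) collapse to
    a single mode, so jitter that straddles a bin edge is not double-counted.
    """
    if angles.size == 0:
        return 0
    nbins = int(round(360.0 / bin_width))
    idx = np.floor((angles + 180.0) / bin_width).astype(int) % nbins
    counts = np.bincount(idx, minlength=nbins)
    thresh = max(1, int(np.ceil(min_frac * angles.size)))
    occ = counts >= thresh
    if not occ.any():
        return 0
    if occ.all():
        return 1
    # count circular runs of True
    runs = 0
    prev = occ[-1]
    for o in occ:
        if o and not prev:
            runs += 1
        prev = o
    return max(runs, 1)


def _circ_std(angles: np.ndarray) -> float | None:
    if angles.size < 2:
        return 0.0 if angles.size == 1 else None
    return float(circstd(angles, high=180.0, low=-180.0))


def profile_ensemble(structures: list[ProteinStructure],
                     site_residues: list[tuple[str, int]],
                     params: ProfileParams | None = None) -> FlexibilityProfile:
    """Classify binding-site residues as rigid or flexible across an ensemble.

    A residue is flexible when its chi1 circular standard deviation exceeds
    the threshold, its chi1 distribution has two or more modes, or its CA
    wanders more than the backbone threshold across the (superposed)
    ensemble — the last clause captures loop residues without chi angles.
    """
    params = params or ProfileParams()
    if len(structures) < 2:
        raise ValueError("profiling needs an ensemble of at least 2 structures")
    out: dict[tuple[str, int], ResidueFlexibility] = {}
    for key in site_residues:
        chi1s, chi2s, cas = [], [], []
        name = "?"
        n_resolved = 0
        for st in structures:
            if not st.has(*key):
                continue
            res = st.get(*key)
            name = res.name
            chi1, chi2 = chi_angles(res)
            side_complete = (CHI1_GAMMA_ATOM.get(res.name) is None) or (chi1 is not None)
            if side_complete:
                n_resolved += 1
            if chi1 is not None:
                chi1s.append(chi1)
            if chi2 is not None:
                chi2s.append(chi2)
            ca = res.atom("CA")
            if ca is not None:
                cas.append(ca.coords)
        occupancy = n_resolved / len(structures)
        if n_resolved == 0 and not cas:
            log.warning("residue %s never resolved in ensemble", format_residue_key(key))
            out[key] = ResidueFlexibility(key, name, None, None, 0, 0, 0.0, 0.0, None)
            continue
        chi1a = np.array(chi1s, dtype=float)
        chi2a = np.array(chi2s, dtype=float)
        std1 = _circ_std(chi1a)
        std2 = _circ_std(chi2a)
        modes1 = _circular_modes(chi1a, params.bin_width, params.mode_min_occupancy)
        modes2 = _circular_modes(chi2a, params.bin_width, params.mode_min_occupancy)
        bdisp = 0.0
        if len(cas) >= 2:
            P = np.array(cas)
            diff = P[:, None, :] - P[None, :, :]
            bdisp = float(np.sqrt((diff ** 2).sum(-1)).max())
        flexible = ((std1 is not None and std1 > params.circ_std_threshold)
                    or modes1 >= 2
                    or bdisp > params.backbone_threshold)
        out[key] = ResidueFlexibility(key, name, std1, std2, modes1, modes2,
                                      occupancy, bdisp,
                                      "flexible" if flexible else "rigid")
    return FlexibilityProfile(out, params)


def detect_blocking(structures: list[ProteinStructure],
                    ligand_poses: list[Ligand],
                    flexible: list[tuple[str, int]],
                    params: ProfileParams | None = None,
                    cognate_of: dict[str, str] | None = None) -> list[tuple[str, int]]:
    """Flexible residues whose side chains hard-clash non-cognate ligand poses.

    A residue blocks a ligand when, in at least one ensemble structure, one
    of its side-chain heavy atoms overlaps (distance below
    ``overlap_fraction`` x summed vdW radii) at least ``min_clash_atoms``
    heavy atoms of the pose.  ``cognate_of`` maps ligand name -> structure
    source_id to skip cognate pairs.  Output is sorted by the number of
    ligands blocked (descending), and is always a subset of ``flexible``.
    """
    params = params or ProfileParams()
    if not ligand_poses:
        raise ValueError("detect_blocking needs at least one ligand pose")
    cognate_of = cognate_of or {}
    blocked_count: dict[tuple[str, int], int] = {}
    for key in flexible:
        hit_ligands = set()
        for lig in ligand_poses:
            lig_xyz = np.array([lig.atoms[i].coords for i in lig.heavy_indices()])
            lig_r = np.array([lig.atoms[i].vdw_radius for i in lig.heavy_indices()])
            for st in structures:
                if cognate_of.get(lig.name) == st.source_id:
                    continue
                if not st.has(*key):
                    continue
                side = st.get(*key).sidechain_atoms()
                if not side:
                    continue
                sxyz = np.array([a.coords for a in side])
                sr = np.array([a.vdw_radius for a in side])
                d = np.sqrt(((sxyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(-1))
                cutoff = params.overlap_fraction * (sr[:, None] + lig_r[None, :])
                overlaps_per_side_atom = (d < cutoff).sum(axis=1)
                if (overlaps_per_side_atom >= params.min_clash_atoms).any():
                    hit_ligands.add(lig.name)
                    break
        if hit_ligands:
            blocked_count[key] = len(hit_ligands)
    return sorted(blocked_count, key=lambda k: (-blocked_count[k], k))


@dataclass
class BindingSiteSpec:
    """Residue lists driving the flexible covalent docking pipeline."""

    reactive_residue: tuple[str, int]
    flexible_residues: list[tuple[str, int]] = field(default_factory=list)
    blocking_residues: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.blocking_residues) - set(self.flexible_residues)
        if missing:
            raise ValueError(f"blocking residues must be a subset of flexible: {missing}")
        if self.reactive_residue in self.blocking_residues:
            raise ValueError("the reactive residue cannot be a blocking residue")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "reactive_residue": format_residue_key(self.reactive_residue),
            "flexible_residues": [format_residue_key(k) for k in self.flexible_residues],
            "blocking_residues": [format_residue_key(k) for k in self.blocking_residues],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BindingSiteSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            reactive_residue=parse_residue_key(data["reactive_residue"]),
            flexible_residues=[parse_residue_key(k) for k in data.get("flexible_residues", [])],
            blocking_residues=[parse_residue_key(k) for k in data.get("blocking_residues", [])],
        )


def plot_chi_scatter(records: list[TorsionRecord], path: str | Path) -> None:
    """chi1/chi2 scatter per residue, one panel each (survey-style plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = sorted({r.residue_key for r in records})
    ncols = min(4, max(1, len(keys)))
    nrows = (len(keys) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for i, key in enumerate(keys):
        ax = axes[i // ncols][i % ncols]
        ax.set_visible(True)
        xs = [r.chi1 for r in records if r.residue_key == key and r.chi1 is not None]
        ys = [r.chi2 if r.chi2 is not None else 0.0
              for r in records if r.residue_key == key and r.chi1 is not None]
        ax.scatter(xs, ys, s=12, alpha=0.7)
        ax.set_xlim(-180, 180)
        ax.set_ylim(-180, 180)
        ax.set_title(f"{key[2]} {key[0]}:{key[1]}", fontsize=9)
        ax.set_xlabel("chi1 (deg)", fontsize=8)
        ax.set_ylabel("chi2 (deg)", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
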