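"""Pairwise scoring kernel shared by the docking scorer and the repacker.

The energy model is a deliberately simple, fully pairwise surrogate for a
physics-based refinement function: softened-core repulsion beyond a vdW
clash onset, a capped short-range attractive well, a distance+angle
hydrogen-bond bonus, and a ligand torsion-strain penalty.  Lower is better.
All terms are deterministic and invariant to rigid motions of the whole
system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ATTR_CUTOFF = 4.5  # A; outer edge of the attractive well

# Hydrogen-bond capable protein atoms (heavy-atom model, PDB names).
_PROTEIN_DONORS_BACKBONE = {"N"}
_PROTEIN_ACCEPTORS_BACKBONE = {"O", "OXT"}
_PROTEIN_DONORS_SIDE = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("TRP", "NE1"),
}
_PROTEIN_ACCEPTORS_SIDE = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}


@dataclass
class ScoreParams:
    """Weights and geometric parameters of the pose score.

    All quantities are dimensionless weights except where noted.  The clash
    onset is a fraction of the summed vdW radii: repulsion turns on once two
    atoms approach closer than that fraction (piecewise-quadratic in the
    overlap), which matches the hard pre-filter used during enumeration.
    """

    w_rep: float = 3.0
    w_attr: float = 0.25
    w_hb: float = 1.0
    w_tors: float = 0.3
    clash_onset_fraction: float = 0.70
    hb_distance_range: tuple[float, float] = (2.6, 3.5)
    hb_min_angle: float = 120.0  # deg at donor and acceptor

    def __post_init__(self) -> None:
        if min(self.w_rep, self.w_attr, self.w_hb, self.w_tors) < 0:
            raise ValueError("score weights must be non-negative")
        if not (0.0 < self.clash_onset_fraction <= 1.0):
            raise ValueError("clash_onset_fraction must lie in (0, 1]")


@dataclass
class AtomTable:
    """Flat arrays describing one interacting atom set."""

    coords: np.ndarray                  # (N, 3)
    radii: np.ndarray                   # (N,)
    donor: np.ndarray                   # (N,) bool
    acceptor: np.ndarray                # (N,) bool
    base: np.ndarray                    # (N, 3); NaN rows = no bonded base atom
    labels: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def empty(cls) -> "AtomTable":
        return cls(np.zeros((0, 3)), np.zeros(0), np.zeros(0, bool),
                   np.zeros(0, bool), np.zeros((0, 3)))

    @classmethod
    def concatenate(cls, tables: list["AtomTable"]) -> "AtomTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return cls.empty()
        return cls(
            np.concatenate([t.coords for t in tables]),
            np.concatenate([t.radii for t in tables]),
            np.concatenate([t.donor for t in tables]),
            np.concatenate([t.acceptor for t in tables]),
            np.concatenate([t.base for t in tables]),
            sum((t.labels for t in tables), []),
        )

    def with_coords(self, coords: np.ndarray, base: np.ndarray | None = None) -> "AtomTable":
        return AtomTable(np.asarray(coords, float), self.radii, self.donor,
                         self.acceptor, self.base if base is None else base, self.labels)


def protein_atom_table(residue_atom_pairs) -> AtomTable:
    """Build an AtomTable from (residue, atom) pairs of a receptor.

    The hydrogen-bond base of each atom is its nearest intra-residue heavy
    atom within covalent range (used for the H-bond angle test).
    """
    coords, radii, donor, acceptor, base, labels = [], [], [], [], [], []
    by_res: dict[int, list] = {}
    pairs = list(residue_atom_pairs)
    for res, atom in pairs:
        by_res.setdefault(id(res), []).append(atom)
    for res, atom in pairs:
        coords.append(atom.coords)
        radii.append(atom.vdw_radius)
        donor.append(atom.name in _PROTEIN_DONORS_BACKBONE
                     or (res.name, atom.name) in _PROTEIN_DONORS_SIDE)
        acceptor.append(atom.name in _PROTEIN_ACCEPTORS_BACKBONE
                        or (res.name, atom.name) in _PROTEIN_ACCEPTORS_SIDE)
        best, best_d = None, 1.9
        for other in by_res[id(res)]:
            if other is atom:
                continue
            d = float(np.linalg.norm(other.coords - atom.coords))
            if d < best_d:
                best, best_d = other, d
        base.append(best.coords if best is not None else np.full(3, np.nan))
        labels.append((res.key, atom.name))
    if not coords:
        return AtomTable.empty()
    return AtomTable(np.array(coords), np.array(radii), np.array(donor, bool),
                     np.array(acceptor, bool), np.array(base), labels)


def ligand_atom_table(ligand, indices: list[int] | None = None) -> AtomTable:
    """AtomTable over a ligand's heavy atoms (N/O are donor+acceptor)."""
    idx = indices if indices is not None else ligand.heavy_indices()
    nbrs: dict[int, list[int]] = {i: [] for i in idx}
    heavy = set(ligand.heavy_indices())
    for i, j, _ in ligand.bonds:
        if i in heavy and j in heavy:
            if i in nbrs:
                nbrs[i].append(j)
            if j in nbrs:
                nbrs[j].append(i)
    coords, radii, donor, acceptor, base, labels = [], [], [], [], [], []
    for i in idx:
        a = ligand.atoms[i]
        coords.append(a.coords)
        radii.append(a.vdw_radius)
        is_polar = a.element in ("N", "O")
        donor.append(is_polar)
        acceptor.append(is_polar)
        nb = nbrs.get(i, [])
        base.append(ligand.atoms[nb[0]].coords if nb else np.full(3, np.nan))
        labels.append(("LIG", i))
    return AtomTable(np.array(coords), np.array(radii), np.array(donor, bool),
                     np.array(acceptor, bool), np.array(base), labels)


def _angles_deg(base: np.ndarray, center: np.ndarray, partner: np.ndarray) -> np.ndarray:
    v1 = base - center
    v2 = partner - center
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = (v1 * v2).sum(-1) / np.maximum(n1 * n2, 1e-12)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def pair_terms(a: AtomTable, b: AtomTable, params: ScoreParams,
               exclude: np.ndarray | None = None) -> tuple[float, float, float]:
    """(repulsion, attraction, hbond_count_negative) between two atom sets.

    ``exclude`` is an optional (len(a), len(b)) boolean mask of pairs to
    ignore (e.g. atoms across the covalent attachment).
    Repulsion is unweighted sum of (onset - d)^2 over overlapping pairs;
    attraction is the unweighted sum of a capped linear well on
    [onset, 4.5 A]; hbond is -1 per satisfied donor-acceptor contact.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0.0, 0.0
    # bounding-sphere early exit: most side-chain/side-chain pairs are far apart
    ca = a.coords.mean(axis=0)
    cb = b.coords.mean(axis=0)
    ra = float(np.sqrt(((a.coords - ca) ** 2).sum(-1).max()))
    rb = float(np.sqrt(((b.coords - cb) ** 2).sum(-1).max()))
    gap = float(np.sqrt(((ca - cb) ** 2).sum())) - ra - rb
    if gap > ATTR_CUTOFF:
        return 0.0, 0.0, 0.0
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    onset = params.clash_onset_fraction * (a.radii[:, None] + b.radii[None, :])
    valid = np.ones_like(d, bool) if exclude is None else ~exclude

    overlap = np.where((d < onset) & valid, onset - d, 0.0)
    rep = float((overlap ** 2).sum())

    # capped triangular well peaking at the vdW contact distance: compressed
    # pairs gain little, ideal contacts gain -1, the well closes at 4.5 A
    contact = np.minimum(a.radii[:, None] + b.radii[None, :], ATTR_CUTOFF - 0.1)
    in_well = (d >= onset) & (d <= ATTR_CUTOFF) & valid
    rise = (d - onset) / np.maximum(contact - onset, 1e-9)
    fall = (ATTR_CUTOFF - d) / np.maximum(ATTR_CUTOFF - contact, 1e-9)
    well = np.clip(np.minimum(rise, fall), 0.0, 1.0)
    attr = float(-np.where(in_well, well, 0.0).sum())

    lo, hi = params.hb_distance_range
    compat = (a.donor[:, None] & b.acceptor[None, :]) | (a.acceptor[:, None] & b.donor[None, :])
    cand = compat & (d >= lo) & (d <= hi) & valid
    hb = 0.0
    if cand.any():
        ia, ib = np.where(cand)
        ok = np.ones(len(ia), bool)
        base_a = a.base[ia]
        has_base_a = ~np.isnan(base_a[:, 0])
        if has_base_a.any():
            ang = _angles_deg(base_a[has_base_a], a.coords[ia[has_base_a]], b.coords[ib[has_base_a]])
            sub = ok[has_base_a]
            sub &= ang > params.hb_min_angle
            ok[has_base_a] = sub
        base_b = b.base[ib]
        has_base_b = ~np.isnan(base_b[:, 0])
        if has_base_b.any():
            ang = _angles_deg(base_b[has_base_b], b.coords[ib[has_base_b]], a.coords[ia[has_base_b]])
            sub = ok[has_base_b]
            sub &= ang > params.hb_min_angle
            ok[has_base_b] = sub
        hb = -float(ok.sum())
    return rep, attr, hb


_STAGGERED = np.array([-60.0, 60.0, 180.0])


def torsion_penalty(torsion_values_deg) -> float:
    """Sum of squared (scaled) deviations from the nearest staggered value."""
    total = 0.0
    for t in torsion_values_deg:
        dev = np.abs((((t - _STAGGERED) + 180.0) % 360.0) - 180.0).min()
        total += float((dev / 60.0) ** 2)
    return total


def combine(rep: float, attr: float, hb: float, tors: float,
            params: ScoreParams) -> float:
    return (params.w_rep * rep + params.w_attr * attr
            + params.w_hb * hb + params.w_tors * tors)
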