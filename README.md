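# covflex

Flexible-receptor covalent docking at desk scale.

Covalent inhibitors that alkylate a cysteine at the rim of a plastic
binding site — the canonical example being acrylamide warheads attacking
an oncogenic-GTPase switch-II pocket — defeat rigid-receptor docking:
side chains frozen in a crystal structure solved with one ligand occlude
the volume the next ligand needs.  covflex implements an open,
deterministic workflow for this problem:

* **Profile** an ensemble of receptor structures: chi1/chi2 circular
  statistics and backbone excursions classify binding-site residues as
  rigid or *flexible*, and hard-clash analysis against non-cognate ligand
  poses identifies the *blocking* subset.
* **Dock** covalently with induced fit: blocking residues (and the
  reactive cysteine) are mutated to alanine, covalent adducts are
  enumerated anchor-first at thioether geometry (cysteine chi1 rotamers ×
  ligand torsion grid × spin about the nascent S–C bond), the original
  side chains are restored, flexible side chains are re-packed around each
  candidate (multi-start greedy + Metropolis over rotamer pair-energy
  tables, then torsional refinement), and poses are geometry-filtered,
  clustered, and ranked.  A `rigid` mode provides the classical baseline.
* **Benchmark** with all-against-all cross-docking matrices,
  symmetry-corrected heavy-atom ligand RMSD (graph-automorphism
  minimisation in a common receptor frame), and top-N success curves.
* **Prepare** glycine loop mutants for external free-energy engines, with
  a Metropolis toy model demonstrating why glycine substitutions
  accelerate backbone transitions (barrier-limited first-passage times).
* **Generate** synthetic mini-pocket systems with planted ground truth —
  a reactive cysteine, flexible residues with two planted rotamer states,
  and blocking residues whose closed rotamer provably occludes the true
  pose — so the whole pipeline is testable offline.

The pose score is a simple pairwise surrogate (softened-core repulsion,
capped contact well, geometric hydrogen bonds, torsion strain, repulsive
side-chain strain); it ranks poses, it does not predict affinities.
See `docs/methods.md` for the model, parameters, and limitations.

## Worked example

Generate a synthetic system with one planted blocking residue, then dock
its ligand back into the shipped receptor — whose blocker is in the
*closed* state — in both modes:

```bash
covflex fixtures --seed 9 --difficulty blocking --out fx/
covflex dock --receptor fx/receptor.pdb --ligand fx/ligand.sdf \
             --site fx/site.yaml --out dock_flex/ --seed 9 --mode flex
covflex dock --receptor fx/receptor.pdb --ligand fx/ligand.sdf \
             --site fx/site.yaml --out dock_rigid/ --seed 9 --mode rigid
python - <<'PY'
import json
import numpy as np
from covflex import read_ligand_sdf
ref = read_ligand_sdf("fx/reference.sdf")
heavy = ref.heavy_indices()
refc = np.array([ref.atoms[i].coords for i in heavy])
for tag in ("dock_flex", "dock_rigid"):
    counts = json.load(open(f"{tag}/report.json"))["outcome"]["counts"]
    top = read_ligand_sdf(f"{tag}/poses.sdf")  # rank-1 pose is record 1
    xyz = np.array([top.atoms[i].coords for i in heavy])
    rmsd = float(np.sqrt(np.mean(((xyz - refc) ** 2).sum(1))))
    print(f"{tag}: counts={counts}  top-1 RMSD = {rmsd:.2f} A")
PY
```

Output from this exact sequence:

```
dock_flex: counts={'n_clash_pass': 260, 'n_clusters': 30, 'n_emitted': 20,
 'n_enumerated': 324, 'n_geometry_pass': 260, 'n_repacked': 64}
 top-1 RMSD = 0.82 A
dock_rigid: counts={'n_clash_pass': 74, 'n_clusters': 14, 'n_emitted': 20,
 'n_enumerated': 324, 'n_geometry_pass': 74}  top-1 RMSD = 2.94 A
```

324 candidates are enumerated (3 cysteine rotamers × 12 spin steps × 9
torsion combinations).  In flexible mode the clash pre-filter exempts the
blocking side chain (260 survivors), repacking swings it open, and the
top-ranked pose lands 0.8 Å from the planted reference; the rigid run
keeps the closed side chain in the filter (74 survivors, none in the true
basin) and its best-ranked pose sits 2.9 Å away.

The per-residue flexibility table, the mutation report, and the benchmark
success curves are all plain TSV/JSON; every run writes a
schema-versioned `report.json`, and identical invocations with the same
`--seed` are byte-identical.

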