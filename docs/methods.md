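# Methods

covflex models the pose-prediction problem posed by covalent inhibitors of
conformationally plastic pockets — the motivating case being acrylamide
warheads attacking an engineered cysteine at the rim of an allosteric site
whose walls (a loop, two helices, and several long side chains) rearrange
from ligand to ligand.  A rigid-receptor docking run against a structure
solved with a different ligand routinely fails there, because side chains
frozen in the crystal conformation occlude the volume the new ligand needs.

## The docking model

The receptor is a heavy-atom, single-conformer model.  Site residues are
partitioned into three classes supplied in a `BindingSiteSpec`:

* the **reactive residue** — a cysteine whose SG forms the covalent bond;
* **flexible residues** — side chains re-packed around each candidate pose;
* **blocking residues** — the subset of flexible residues whose side
  chains, in some receptor conformations, sterically bar non-cognate
  ligands from the site.

One docking job runs:

1. **Open the pocket.** Blocking residues and the reactive cysteine are
   truncated to alanine (side-chain atoms archived for exact restoration).
2. **Anchor-first enumeration.** For each canonical cysteine chi1 rotamer
   (−60°, 180°, +60°) the SG position is rebuilt from backbone geometry.
   The warhead carbon is placed at thioether geometry — S–C bond 1.81 Å,
   CB–SG–C angle 100° — with the remaining azimuth fixed deterministically
   toward the pocket centre (mean CA of the site residues).  The ligand is
   then swept over a staggered grid on each rotatable torsion (120° default)
   and over the spin about the nascent S–C bond (30° default).  Candidates
   whose heavy atoms approach non-flexible receptor atoms closer than
   0.7 × the summed vdW radii are discarded; flexible side chains are
   exempt from this pre-filter because repacking may move them.
3. **Restore and filter.** Mutated residues are restored; every candidate
   must satisfy the warhead geometry contract (|ΔS–C| ≤ 0.3 Å,
   |Δangle| ≤ 20°).  Anchor-first construction satisfies it by design, and
   later refinement steps are torsional, so the filter holds by invariant —
   it is still enforced on every emitted pose.
4. **Pre-score and repack.** Candidates are ranked by a vectorised
   repulsion+attraction pre-score (flexible side chains excluded) and the
   top `n_repack` (64) proceed to side-chain repacking (below).
5. **Score, refine, cluster, rank.** Each repacked pose is scored by the
   pairwise surrogate function; the best `n_refine` (10) also receive
   continuous torsional refinement.  Poses are leader-clustered on
   in-frame heavy-atom ligand RMSD; representatives (each cluster's
   lowest-scoring member) are emitted first, then remaining poses by
   score, truncated to `max_poses_out` (20).

In **rigid mode** the same job runs with no blocking mutation and no
repacking — every side chain participates in the clash pre-filter — giving
the classic rigid-receptor baseline for paired comparisons.

Anchor-first enumeration is this package's largest deviation from the
engine-based protocols it emulates: those dock non-covalently first and
form the bond afterwards.  The covalent constraint makes anchor-and-grow
exhaustive and deterministic at desk scale, which we value more than
fidelity to the staging of proprietary pipelines.

### Scoring function

The score is deliberately simple, fully pairwise, and deterministic;
lower is better:

    score = w_rep · Σ (onset − d)²           d < onset, onset = 0.7 (r_i+r_j)
          + w_attr · Σ well(d)               capped triangular well peaking
                                             at vdW contact, closing at 4.5 Å
          + w_hb · (−1 per satisfied donor–acceptor pair, 2.6–3.5 Å,
                    >120° at donor and acceptor)
          + w_tors · Σ (Δstaggered/60°)²     ligand torsion strain
          + w_rep · (side-chain strain)      repulsive part only

Defaults: `w_rep` 3.0, `w_attr` 0.25, `w_hb` 1.0, `w_tors` 0.3.  The heavy
repulsion weight reflects that hard-core overlap should dominate any
contact reward; the attraction well peaks at the vdW contact distance so
compressed ("jammed") placements gain little.  The side-chain strain term
charges a pose for any clashes its induced side-chain arrangement carries,
but deliberately not for favourable side-chain packing — cosy wrap-around
of a mispose must not subsidise it.  Atom pairs across the covalent
attachment (1–2, 1–3) are excluded.  Pairwise vdW radii come from a
Bondi-style element table.  This function is a stand-in for a refinement
energy, not a binding-affinity estimate; affinity prediction is out of
scope.

### Side-chain repacking

Flexible side chains are rebuilt from ideal internal-coordinate templates
(standard bond lengths/angles; ring closures by planarity).  The shipped
rotamer library is backbone-independent: staggered chi1 (−60°/180°/+60°,
weights 0.40/0.35/0.25) crossed with staggered or ±90° (aromatic) chi2,
3–9 rotamers per type, distal chis fixed at canonical values; a richer
library can be loaded from TSV.  The current side-chain conformation is
always included as a candidate, which guarantees
`energy_after ≤ energy_before` on every call.

Optimisation is weight-biased multi-start greedy (5 starts) with 200
Metropolis sweeps at kT = 1 over precomputed single-body and pair energy
tables, followed by cyclic golden-section line search over each flexible
chi, each ligand rotatable torsion (rotating the side away from the
warhead so the covalent bond is untouched), and the rigid spin about the
S–C axis — ±15° window, two cycles.  On instances small enough to
enumerate exhaustively the search recovers the global rotamer optimum in
≥94 % of cases (validated in the test battery).  Backbone atoms never
move; backbone flexibility is explicitly out of scope, which is the known
fidelity gap of this refinement stage.

### Flexibility profiling

Given a superposed ensemble, chi1/chi2 are measured per site residue
(standard defining-atom tables).  A residue is *flexible* when its chi1
circular standard deviation exceeds 30°, its chi1 histogram (30° bins,
modes = circular runs of bins holding ≥10 % of observations) has ≥2
modes, or its CA wanders more than 1.0 Å across the ensemble (capturing
loop residues with no chi).  A flexible residue is *blocking* when, in at
least one ensemble member, one side-chain heavy atom overlaps (d < 0.7 ×
summed vdW radii) at least two heavy atoms of at least one non-cognate
ligand pose.  All thresholds are config-exposed; they are deliberately
conservative defaults chosen so positional noise at crystallographic
magnitude (~0.1 Å) never inflates the flexible set.

### Loop-to-glycine preparation and the kinetic toy

For downstream free-energy work the package writes glycine-mutant
receptors (side chains archived, backbone untouched) and reports two
hazards: runs of ≥3 consecutive glycines created by the mutation
(intended — they mobilise the backbone — but worth flagging) and mutated
side chains within 4 Å of ligand heavy atoms, which void the strategy's
assumption that the mutations do not perturb ligand contacts.

The accompanying simulator is a didactic kinetic model, not an MD
surrogate: each backbone torsion feels U(θ) = h·(1−cos 3θ)/2 +
t·(1−cos θ)/2 — a periodic potential whose adjacent minima are 120° apart,
with the start well destabilised by the tilt t = 1 kT — and evolves by
Metropolis Monte Carlo with Gaussian 15° moves.  Barrier heights are set
by residue type (glycine 2 kT, non-glycine 6 kT by default).  The
first-passage time into the ±120° target basin is the readout; because
the dynamics are barrier-limited, glycine loops transition first in the
overwhelming majority of paired runs, which is the mechanistic rationale
for the mutation strategy in miniature.

## The synthetic mini-pocket generator

All offline validation runs on generated systems, so what they demonstrate
must be stated precisely.  A mini-pocket is a ~42-residue single chain —
a beta-strand carrying the reactive cysteine, a capping loop, and an
alpha-helix ~12 Å above the strand — built from ideal backbone templates
(helix φ/ψ −57°/−47°, strand −120°/+120°, small random perturbations) with
template side chains.  Ligands come from a small fragment grammar
(acrylamide warhead + alkyl/phenyl R-groups, 8–16 heavy atoms, ≤4
rotatable torsions) embedded with RDKit.

Planting ground truth proceeds in three steps.  (1) Candidate poses are
enumerated against the fully open receptor; only zero-repulsion
candidates qualify.  (2) For blocking fixtures, a closed rotamer variant
is selected per blocker such that it both hard-clashes the candidate and
occludes the candidate's whole 2.0 Å success basin — verified against the
rigid-mode reachable set, so a rigid-receptor job genuinely cannot
succeed, which is what "severely blocking" means here.  (3) The reference
pose is made a fixed point of the pipeline's own machinery: the shipped
receptor (blockers closed, flexible extras at planted states) plus the
grid candidate are run through repack+refine, the resulting side-chain
states are re-planted, and the cycle repeats until the pose is stable;
candidates whose refined pose drifts more than 0.8 Å from the grid
candidate are rejected as under-constrained.  The generator validates all
invariants and retries boundedly, failing loudly rather than easing the
fixture.

Consequences worth keeping in mind: passing self-docking tests shows the
pipeline recovers poses that are *consistent with its own energy model and
sampling grid* in pockets of this geometry; it does not show accuracy
against experimental structures, real pocket chemistry (waters,
electrostatics, protonation), or backbone rearrangement.  The ensembles
emulate side-chain rotamer heterogeneity plus 0.1 Å positional jitter and
nothing else — no occupancy gaps, correlated motions, or backbone
excursions beyond jitter.

## Benchmark protocol

The cross-docking matrix docks every manifest ligand into every manifest
receptor (the diagonal is self-docking).  Reference poses travel into each
docking receptor's frame by Kabsch superposition of their cognate
receptor on all shared CA atoms; the ligand itself is never re-fit.  Pose
error is heavy-atom RMSD minimised over element- and bond-order-preserving
graph automorphisms (networkx VF2, capped at 10⁴ mappings), with the
uncorrected value reported alongside.  Success tables report the fraction
of jobs whose best pose among the top N is within a cutoff, by default
N ∈ {1, 5, 20} and cutoffs {2.0, 2.5} Å; jobs that emit no poses count as
failures at every operating point rather than being dropped.  Per-job
seeds derive deterministically from (global seed, receptor id, ligand id),
so matrices are reproducible and independent of manifest row order.

## Numerical choices

* Coordinates in Å throughout; no re-centring on read; altlocs collapse to
  the highest-occupancy conformer (ties → 'A').
* Cluster radius 1.0 Å: clustering granularity matches the pose-accuracy
  scale, so a near-native pose cannot be absorbed into a cluster whose
  representative lies outside the accuracy tolerance.
* Ranking ties break by pose construction index (stable, deterministic).
* Golden-section line searches use 8 bracketing iterations (final interval
  ≈0.6° on a ±15° window) and only ever accept energy-decreasing moves.
* Degenerate inputs fail loudly: collinear dihedrals, <3 superposition
  pairs, mutating glycine to alanine, formula mismatches in RMSD.
* All stochastic stages (repacking restarts, Metropolis sweeps, toy
  kinetics) are driven by explicit integer seeds; identical inputs and
  seeds reproduce results bit-for-bit.

## Problem sizes used in the shipped validation

The test battery and the validation script generate their own data:
100 mini-pocket systems (40 easy / 40 single-blocker / 20 double-blocker)
for the geometry-contract battery (the standalone script samples 90,
reusing jobs shared with the other sections); 20 easy systems for
self-docking;
20 blocking systems × 10 repacking seeds for the paired flexible-vs-rigid
comparison (the rigid stage has no stochastic step, so its result is
computed once per system; the standalone validation script reports the
same comparison over 5 replicates); 50 easy systems for exhaustive repacker
enumeration; 50 ensembles of 10 members for profiling recovery; 200
paired trajectories for the kinetic toy.  These sizes were chosen as the
smallest at which the stochastic comparisons are decisive (sign test
p < 0.05 with margin) while a full validation pass stays comfortable on a
single CPU.

## Known limitations

* No backbone motion anywhere in docking or repacking.
* The energy model has no electrostatics, solvation, or waters; hydrogen
  bonds are geometric counts on heavy atoms.
* One protomer/tautomer per ligand; warhead chemistry ships only the
  acrylamide Michael-addition template (others can be declared via
  `WarheadSpec`).
* The mmCIF format is not read; assemblies and symmetry mates are not
  expanded.
* Binding-affinity prediction (docking scores as affinities, MM-GB
  rescoring, free-energy methods) is intentionally absent; the glycine
  loop preparation only writes receptors for external engines.
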