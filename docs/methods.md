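# Methods

## Search model

A docking problem is a box-constrained global minimization over the pose
vector x = (p, q, φ): the ligand root-center position p ∈ R³ (clamped to
the docking box), a unit quaternion q for the rigid orientation, and one
dihedral offset φ_k ∈ (−π, π] per rotatable bond, giving D = 7 + N_rot
dimensions. Coordinates are produced from the reference (file) geometry by
applying branch rotations ancestors-first about each parent→child bond
axis (right-hand rule), then rotating about the root center and
translating. The torsion tree is taken verbatim from the PDBQT
ROOT/BRANCH nesting; the branch child atom lies on its own rotation axis,
so including it in the moved set is a no-op.

### Particle swarm

The swarm holds N particles with velocity clamping (half a box length per
translational component, 1 per quaternion component, π per torsion).
After each position update the vector is projected back into the feasible
set: position clamped, quaternion renormalized (a zero quaternion maps to
identity), torsions wrapped. In chaos-embedded mode the inertia weight and
the acceleration randomness are two independent chaotic streams per
particle, drawn once per particle per generation and shared across all D
components; the cognitive and social weights are coupled as r_cm and
1 − r_cm, so a draw that emphasizes the particle's own memory
de-emphasizes the swarm's, and vice versa. With chaos disabled the engine
falls back to scalar uniform r1, r2 per particle per generation.

Defaults follow the docking parameterization this engine is built
around: N = 8 (16 for screening), w = 0.36, c1 = c2 = 0.99, R = 0.1,
C_r = 18. Termination: the swarm stops when the best score has not
improved by more than 10⁻⁴ for C_r consecutive generations, or at
`max_generations` (default 200). The initialization sweep counts as
generation 1.

### Two-stage local search

Each position update is refined by BFGS with Armijo backtracking,
operating in a 6 + N_rot local chart: translation, a world-frame
axis-angle increment about the current orientation (with the exact SO(3)
left-Jacobian transform applied to the torque gradient, so analytic and
finite-difference derivatives agree anywhere in the chart, not only at
its origin), and the torsions. Proposed steps are capped at norm 2
(trust-region style) because gradients near steric walls are enormous and
would otherwise exhaust the backtracking budget.

The full step budget is 10·D + 30 (configurable); stage 1 probes with
⌈R · budget⌉ steps, and only if the probe already beats the particle's
stored personal best does stage 2 *continue the same search* with the
remaining budget. Continuing (rather than restarting) keeps the total
evaluation cost of 2LS at or below a single full-budget search and makes
the R = 1 limit exactly equal to the one-stage variant. The gate compares
against the stored pbest score. The interpretation of R as a step-budget
ratio and C_r as a stall-generation count is a design choice; both are
plain config fields.

### Chaotic streams

The five maps run at their chaotic-regime parameters (logistic α = 4,
Singer μ = 1.07, sinusoidal α = 2.3, tent in its 0.7-kink form,
Zaslavskii v = 400, r = 3, a = 12; for the Zaslavskii map the auxiliary
state is advanced first, y' = cos(2πx) + e^{−r}·y, then
x' = (x + v + a·y') mod 1). Streams are initialized uniformly from each
map's admissible start set (logistic (0,1) minus {0.25, 0.5, 0.75},
sinusoidal [0.45, 0.92], Singer/tent (0,1), Zaslavskii x₀ ∈ [0,1) with
y₀ = 0) using a seedable RNG. In floating point an orbit that lands
exactly on a fixed point (or leaves (0,1)) dies, so the stream re-seeds
transparently and re-steps; every value returned is strictly inside
(0, 1). Two properties worth noting: the sinusoidal map's chaotic values
stay above 0.4, so as an acceleration weight it never produces very small
cognitive coefficients (used as-is, not rescaled); and the Singer
attractor at μ = 1.07 spans roughly [0.02, 0.996] — it never visits the
lowest two percentiles of (0, 1), while the logistic orbit at α = 4 is
ergodic on the whole interval.

## Scoring

The published Vina functional forms and weights are the shipped defaults
(gauss1 e^{−(d/0.5)²} × −0.035579; gauss2 e^{−((d−3)/2)²} × −0.005156;
repulsion d²·[d<0] × 0.840245; hydrophobic ramp 1→0 over d ∈ [0.5, 1.5] ×
−0.035069; h-bond ramp 1→0 over d ∈ [−0.7, 0] × −0.587439; torsion
penalty weight 0.05846; 8 Å interatomic cutoff), every field overridable
from YAML. d is the surface distance r − R_i − R_j over heavy atoms, with
Vina-style vdW radii per AD4 type. There is no electrostatic term; PDBQT
charges are parsed but unused by the default scoring. Hydrophobicity is
assigned from the AD4 type alone (C/A/halogens); acceptors are OA/NA/SA;
donors are polar heavy atoms with a polar hydrogen (HD) within 1.3 Å.
Intramolecular energy sums heavy-atom pairs in different rigid bodies
more than three bonds apart, with ligand bonds inferred from reference
distances (< 1.75 Å) plus the declared branch bonds.

The search objective is (inter + intra)/(1 + 0.05846·N_rot); the reported
affinity is inter/(1 + 0.05846·N_rot). The divisor is constant per
ligand, so search and reporting rank poses identically; including intra
in the search keeps flexible ligands from self-clashing.

Three evaluation paths exist — a compiled (numba) flat-loop kernel, a
vectorized full-matrix path, and a KD-tree neighbor-list path — agreeing
to ~10⁻¹²; tests cross-check them. The hard 8 Å cutoff introduces a
discontinuity of order 10⁻⁵ kcal/mol per pair (the largest surviving term
there is gauss2), which is below every tolerance used.

## Docking protocol

`dock` runs n_runs (default 10) independent swarm searches with sub-seeds
fanned out from the master seed via numpy `SeedSequence.spawn`, so run
count and chaos-map choice never perturb unrelated draws. Poses are
sorted by affinity, de-duplicated at 1.0 Å heavy-atom RMSD (keeping the
lower affinity), and capped at 9 reported modes; the lowest-affinity pose
is the docking solution. Boxes come either from pocket atoms (center =
their geometric mean, lengths = per-axis extents, degenerate axes padded
to 1 Å with a warning) or from a bound ligand (geometric center, cubic
edge 22.5 Å by default). RMSD is the standard receptor-frame,
index-matched, heavy-atom RMSD without symmetry correction; 2 Å or less
(inclusive) counts as success.

## Synthetic fixtures

The generator builds miniature complexes so every layer is testable
offline. The ligand is a rigid core with two N–H donor arms of unequal
length (1.5 and 2.3 Å) plus a nested branch chain, one two-atom branch
per torsion, each ending in its own N–H donor. The receptor is a concave
shell *cast around the planted ligand geometry*: ~26 carbons along
cap-removed sphere directions placed where they just graze the ligand
envelope (nearest C–C contact 3.9 Å), plus OA acceptor anchors — a
bidentate pair straddling each root donor's N–H axis at ±20°, one anchor
per branch donor — at the 3.0 Å h-bond optimum. Unequal arms break the
arm-swap symmetry, branch anchors pin the torsions, and the snug cast
penalizes rigid displacement.

The planted pose is polished to the nearest scoring minimum and then
*certified* at generation time: 40 full-budget local searches from random
poses plus 3 independent swarm searches must find nothing more than
1 Å away that scores within 0.05 of the crystal (closer-and-deeper
solutions replace the crystal; a deeper distant solution rejects the
geometry and the generator retries, erroring after 100 attempts). Every
shipped complex also satisfies the planted-funnel property: the crystal
scores below at least 95% of 1000 random poses in its box. Certification
reliability drops as torsion count grows (more near-degenerate packings);
the recovery experiments therefore use 0–2 torsions per complex, while
the generator accepts up to 10.

The screening generator emulates an actives/decoys library over one
shared pocket: actives are jittered copies of a three-armed template
matched to the pocket's anchors; decoys have identical composition but
arm lengths detuned by ±0.6–0.8 Å × `separation`, so their donors either
miss the h-bond ramp or clash. At separation 0 the classes are
indistinguishable (AUC ≈ 0.5); at separation 1 the engine separates them
essentially perfectly.

What the toys do *not* emulate: real pockets are not rigid casts of one
conformer; real ligands have correlated torsions, rings, and symmetric
substructures (which would need symmetry-aware RMSD); affinity magnitudes
are milder than drug-like values; and decoys in curated benchmarks are
property-matched by chemistry, not by construction against a known
answer. Passing the recovery and enrichment tests shows the search finds
certified global minima and the ranking separates geometrically encoded
signal — not that the scoring function is predictive for real chemistry.

## Problem sizes and numerical choices

The test suite runs the redocking protocol on 20 generated complexes
(26-atom shells, 0–2 torsions, best of 10 runs each) and the screening
experiment on 8 actives + 8 decoys with one run per compound at N = 16 —
sizes chosen so the whole suite completes in minutes on one core while
still exercising every code path. Chaotic-map bounds are measured over
100 trajectories × 10⁵ iterates. BFGS stops at gradient norm 10⁻⁶;
stall tolerance is 10⁻⁴; quaternions are renormalized after every
update; torsion ties and bin-boundary ties in the enrichment factor are
broken deterministically (by ligand id). The top-x% bin is ⌊x%·n⌋ with a
minimum of 1; AUC is the rank-sum statistic with ties counted one half,
identical to the trapezoidal ROC area over all thresholds.

## Known limitations

Rigid receptor only; no symmetry-corrected RMSD by default; no
electrostatics or desolvation; no precomputed grid maps (direct pairwise
evaluation is fast enough at toy scale, and a cell list covers larger
receptors); single-threaded (runs are independent and could be
parallelized without changing results). A classic-PSO comparison mode
(uniform randomness, constant inertia, one-stage local search) is exposed
via `SwarmConfig.baseline()` for A/B experiments.
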