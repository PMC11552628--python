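# Methods

## Pose model and kinematics

A ligand is a tree of rigid frames connected by rotatable bonds, parsed from
PDBQT torsion-tree records (ROOT/BRANCH/TORSDOF). Its state is the
(6+k)-vector (translation, axis-angle orientation, k torsions); flexible
receptor side-chains append up to four chi angles per residue. Cartesian
expansion applies torsions root-outward (BRANCH file order; each rotation is
Rodrigues' formula about the current bond axis), then rotates the whole
molecule about the root reference point and translates it. The rotation
center is the centroid of the root frame's heavy atoms — the format does not
prescribe one, and the centroid keeps translation and orientation degrees of
freedom approximately decoupled. Bond lengths and angles inside each frame
are invariant by construction; the tests assert preservation to 1e-9 Å.

Orientation is stored as a single axis-angle 3-vector so the ligand DOF count
is exactly 6+k. Monte Carlo orientation moves compose a random small rotation
with the current one through quaternions (scipy rotations) to avoid gimbal
artefacts; gradients with respect to the axis-angle parameters are obtained
by computing the world-frame torque and pulling it back through the
transposed left Jacobian of SO(3) (closed form, with the usual series
expansion below 1e-6 rad).

Docking RMSD is heavy-atom, identity-correspondence, without superposition
(both poses live in the receptor frame). No graph-symmetry correction is
applied; for ligands with topological symmetry this can overestimate the
RMSD, which is a known caveat when comparing success rates.

## Scoring

The empirical scorer uses the five classic terms (two Gaussians, quadratic
overlap repulsion, hydrophobic ramp, hydrogen-bond ramp) of the surface
distance s = d − Ri − Rj, the published term weights, per-type van der Waals
radii, and an 8 Å interatomic cutoff. Typing: OA/NA/SA accept; a heavy atom
bonded to an HD hydrogen donates; carbons are hydrophobic unless bonded to a
heteroatom; halogens are hydrophobic. Bonds are inferred from covalent radii
(1.3 × sum) since PDBQT carries no connectivity. Hydrogens are parsed (HD
drives donor typing) but only heavy atoms enter the pair sums.

The intramolecular sum runs over heavy-atom pairs in different rigid frames
at least four bonds apart (1-2, 1-3, 1-4 exclusions). The sampling score
includes this intra term by default (configurable); the reported binding
free energy is the intermolecular part divided by 1 + w_rot·N_rot with N_rot
from the TORSDOF record. Pair evaluation is direct and vectorized with a
cutoff mask — at the system sizes this package targets (tens to a few
hundred atoms) that is faster and simpler than neighbour lists or
precomputed grids, and keeps the function differentiable everywhere except
the term boundaries (ramp corners and the cutoff itself, which is a genuine
discontinuity of the classic functional form).

Two implementations of the fused score+gradient and of the kinematic
expansion exist: a reference numpy path and a numba-compiled path with
identical arithmetic (no fastmath). The compiled path is used when numba
imports; tests assert the two routes agree to 1e-10.

Scoring functions compose: a hybrid scorer is a weighted linear combination
(gradients combine linearly when all components provide them), and arbitrary
external scorers — including trained machine-learning models — can be wrapped
via `register_external_sf`, with an optional gradient callable; without one
they are usable by the gradient-free samplers and for re-ranking only.

## Restraints

Harmonic (k(d−d0)²), one-sided walls (k·max(0, d−upper)² / k·max(0,
lower−d)²), a two-sided wall, and the native distance-matrix penalty
Σij (dij − dij*)². All are C1, non-negative and zero on their feasible sets;
selectors resolve to exactly one atom at construction time so typos fail
fast. The default force constant is 1.0 score-units/Å². The usual protocol
mixes the restraint score with the empirical score at equal 0.5/0.5 weights.
Note the scale asymmetry: a full distance-matrix penalty over hundreds of
pairs dwarfs the empirical score away from the native pose, so at equal
weights the matrix term dominates early sampling and the empirical term
decides among near-feasible poses. The weights are exposed verbatim rather
than normalized; users combining matrix restraints with other terms should
set the matrix `weight` field accordingly.

## Global samplers

All samplers run `exhaustiveness` independent replicas (default 8, validated
to ≤ 32 unless overridden), with replica seeds = master seed + replica index
so results are independent of execution order and bit-reproducible.

* **Monte Carlo.** Metropolis acceptance with a geometric temperature
  schedule T_i = T0 · 0.97^i; T0 is auto-calibrated per replica so a typical
  initial uphill move is accepted with probability about one half (an
  explicit `t0` disables annealing calibration; `decay=1` gives constant-T
  sampling). Local proposals perturb the translation (Gaussian, σ = 1 Å),
  the orientation (random axis, Gaussian angle, σ = 0.5 rad) and one
  uniformly chosen torsion/chi (σ = 1 rad); with probability 0.3 the proposal
  is instead a fresh uniform pose in the box. Every proposal is locally
  refined before the acceptance test (basin hopping); the independence moves
  are what lets a replica keep probing new orientation basins after the
  temperature has dropped.
* **Genetic algorithm.** Chromosome = full DOF vector; tournament selection
  (size 3), one-point crossover (rate 0.8), per-gene Gaussian mutation (rate
  1/dim, σ per gene type), elitism 1. Each generation the fittest
  individuals are locally refined and written back (Lamarckian memetic
  search) and two locally refined random immigrants are injected, which
  prevents premature convergence on a competitor basin.
* **Particle swarm.** Constriction form (inertia 0.729, cognitive = social =
  1.49445), angular DOFs wrapped when differencing, translations clamped to
  the box. The worst particles are re-seeded at refined random positions
  each iteration and the frontrunners are refined into their personal bests;
  the global best is monotone by bookkeeping.

Poses whose root reference point leaves the box are clamped back; scoring is
unchanged. The per-move refinement uses L-BFGS for a configurable number of
iterations (sampler default 30; tolerance defaults are scipy's, so refinement
stops early in converged basins).

## Local refinement

`local_minimize` treats the score as a loss over the pose vector and runs a
fixed number of optimizer iterations (default 5 at learning rate 0.1;
methods: L-BFGS with strong-Wolfe line search and history 10, Adam, SGD).
Because Adam and SGD are not monotone, the best pose *visited* is returned,
so refinement can never return something worse than its input; "5 steps"
counts optimizer iterations, not function evaluations. Angles are left
unwrapped during optimization (the score is 2π-periodic) and re-wrapped on
return. Non-finite gradients abort the loop and return the best-so-far with
a warning.

## Clustering, re-ranking, success metrics

Greedy leader clustering in ascending score order at a 1.0 Å heavy-atom RMSD
cutoff, comparing to cluster representatives; ties in score break by
(replica, step), which is stable and seed-reproducible. Chosen for
determinism and O(N·M) cost; tests compare it against an exhaustive oracle.
Representatives can be re-scored by any scoring function (gradient not
required) with a stable ascending sort; a pose whose re-scorer raises is
dropped with a logged warning. Top-N success is the percentage of targets
whose best pose among ranks 1..N lies below 2 Å RMSD to the reference.

## Synthetic study systems

The generator builds everything the tests and the acceptance script consume:

* **Toy ligands** — zigzag heavy-atom chains (bond lengths 1.45–1.55 Å,
  tetrahedral-like angles) with a valid nested torsion tree (k branches), an
  HD-bearing amine donor at the head, carbonyl-like OA acceptors at the tail
  (and mid-chain from 7 heavy atoms up), apolar carbons elsewhere.
* **Toy pockets** — a complementary shell around a chosen ligand pose: each
  apolar ligand atom gets up to three carbon partners at surface distance
  +0.15 Å (hydrophobic-ramp plateau, no overlap), each donor/acceptor gets
  two polar partners at −0.35 Å (mid hydrogen-bond ramp), plus an outer
  carbon cage on a Fibonacci sphere that blocks trivially equivalent
  placements. By construction the planted pose is the funnel minimum: a
  coarse rigid 6-DOF grid scan finds nothing clearly better, and the only
  negative surface distances are the hydrogen-bond geometries, so the soft
  overlap penalty at the planted pose stays a small fraction of the
  attraction (it cannot be exactly zero while hydrogen-bond contacts are
  rewarded, since that ramp lives at negative surface distance).
* **Funnel benchmark** — independent toy complexes (6–8 heavy atoms,
  k ∈ {1,2}) with stored planted coordinates and native ligand–receptor
  distance matrices, plus a perturbation utility adding i.i.d. Gaussian
  noise whose absolute value has a stated mean (σ = mean·√(π/2), entries
  clipped positive).

What this emulates: funnel-shaped landscapes with a unique, type-discriminated
optimum at redocking scale. What it does not: real protein chemistry
(rotamers, waters, electrostatics), ligand-conformer strain, symmetric
ligands, large pockets with decoy sub-pockets. Passing the recovery battery
therefore demonstrates that sampling, scoring plumbing, gradients and
post-processing work as specified — not that the empirical score is accurate
on real complexes.

## Problem sizes and determinism of the checks

The recovery battery uses 20 funnel targets per sampler with exhaustiveness
8 (plus Monte Carlo at 32), 60 MC steps or 30 GA/PSO generations per
replica, and populations of 24 — sizes chosen so the whole battery completes
in minutes on one CPU while leaving the 2 Å success criterion demanding.
The constrained-redocking comparison uses 10 targets at exhaustiveness 4.
Gradient checks use central differences (h = 1e-4) at 50 poses per scorer,
drawn away from the scoring function's non-smooth set (ramp corners and the
8 Å cutoff), where a finite-difference oracle is valid. All randomness in
tests and the acceptance script is seeded.

## Known limitations

* The classic cutoff truncation is discontinuous; gradients are exact for
  the implemented function but the function itself has a small jump at 8 Å.
* No symmetry-corrected RMSD; no ring-conformer sampling; frames are rigid.
* Receptor flexibility scores ligand–side-chain interactions but not
  side-chain–side-chain strain.
* PDBQT preparation (protonation, charges, atom typing from raw PDB/SDF) is
  out of scope; inputs are assumed prepared by standard tools.
* The equal-weight hybrid of empirical score and matrix restraint is scale
  sensitive (see Restraints).
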