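# Methods

## The estimator

`mrcgbsa` scores protein–ligand binding by a multiple-random-conformation
(MRC) variant of MM-GBSA. Instead of pulling the ligand out of its site in a
steered simulation, the method builds an ensemble of rigid-body ligand
placements on shells of increasing protein–ligand distance r and aggregates
their minimized potential energies with the Jarzynski identity,

    exp(-ΔG / kT) = ⟨ exp(-W / kT) ⟩ .

In the quasi-static limit the work of moving between adjacent shells reduces
to the potential-energy difference of the two states, so for the transition
between shells i and i+1 the per-replicate work sample is

    W_j = U[j, i] - U[j, i+1]        (binding direction, far → near)

and the shell score is the exponential average

    score_i = -kT ln (1/N) Σ_j exp(-W_j / kT),

evaluated through a max-shifted log-sum-exp (`scipy.special.logsumexp`), so
|W|/kT of many hundreds stays finite. The total score is Σ_i score_i; more
negative totals mean stronger predicted binding. kT = 0.0019872041 × 300 ≈
0.5961 kcal/mol, the temperature of the bound-state sampler.

Two pairing conventions are implemented because the estimator's sample
pairing is genuinely open:

* `replicate` (default): shell conformations inherit the lineage of the
  bound-state snapshot they were generated from, giving N work samples per
  transition. This is the faithful reading of "shells generated from the
  r = 0 samples".
* `ensemble`: the ratio of per-shell Boltzmann averages,
  `-kT [ln ⟨e^(-U_near/kT)⟩ - ln ⟨e^(-U_far/kT)⟩]`, normalized per shell so
  unequal shell sizes remain well defined. With exhaustive enumeration this
  is exactly `-kT ln(Z_near/Z_far)`, which is what the brute-force oracle
  computes independently.

The two coincide on zero-variance grids, where the total telescopes exactly
to U(r=0) − U(r_max).

**Direction and sign.** Work is accumulated in the binding direction so that
binders score negative; this matches the positive fitted slopes relating
scores to experimental ΔG. `direction="unbinding"` exposes the reverse sum
(the exact negation only in the zero-variance limit — the exponential average
is not antisymmetric).

**Uncertainty.** Per-transition standard errors are leave-one-replicate-out
jackknife estimates of the Jarzynski value. The SE of a total is taken as the
root sum of squares of transition SEs; adjacent transitions share a shell, so
this is an approximation, used only for consistency checks.

## Protocol

The default protocol follows the published configuration of the method:

| parameter | default | meaning |
|---|---|---|
| N_conf | 100 | replicates per shell |
| N_min | 100 | minimization steps per conformation |
| schedule r1 | 0, 0.5, 1, 2, …, 10 Å (12 points) | shells; 100 × 12 = 1200 conformations |
| schedule r2 | 0, 0.1, 0.25, 0.5, 1, …, 15 Å (19 points) | fine preset for convergence checks |
| bound-state sampling | 10 ps Langevin, 300 K, γ = 2 ps⁻¹, 1 fs | snapshot every 0.1 ps → 100 snapshots |
| template minimization | SD→CG switch at step 100, grad RMS < 0.1 kcal/mol/Å | reference complex before sampling |
| conformation minimization | SD→CG switch at step 10, exactly N_min steps | U sampled at the final step |
| ε_in | 4 | interior dielectric (sweep {1, 2, 4} supported) |
| ε_w | 78.5 | solvent dielectric |
| optimal-pose cutoff | 2.0 Å (strict `<`) | receptor-fit heavy-atom ligand RMSD |
| α (generalized) | 0.20 | ΔΔG = α·(score_X − score_ref) |

Placements draw six numbers: a displacement direction uniform on the sphere
scaled to magnitude exactly r, and an orientation drawn as a uniform random
unit quaternion (default). A literal `euler` mode with three independent
uniform angles is available; it is not uniform over orientations, but the
method's statistics are insensitive to the choice and both are offered.
RNG substreams are derived per (replicate, shell) from a single seed
(`numpy` `SeedSequence` spawn keys), so grids are bitwise reproducible and
embarrassingly parallel in principle.

Flexible receptors use two conformations: the closed (holo) receptor for the
bound shell r = 0 and the open (apo) receptor for every r > 0, because closed
receptors sterically exclude placements at small nonzero r.

**Clash handling.** A placement that brings any receptor–ligand pair closer
than the clash threshold is redrawn (up to 50 times), then accepted as-is.
The default threshold is 0.9 of the smallest receptor–ligand LJ σ — just
inside contact. A threshold much smaller than σ admits placements wedged deep
into the repulsive wall; the displacement-capped minimizer (below) cannot
rescue those within N_min steps, and a single extreme far-shell energy then
dominates the binding-direction exponential average. A numeric threshold can
still be passed explicitly.

## The built-in energy model

The toy force field is a conventional MM + generalized-Born + surface-area
model over explicit per-atom parameters (charge, LJ σ/ε with
Lorentz–Berthelot combining, fixed Born radius, mass), with Coulomb constant
332.0636 kcal·mol⁻¹·Å·e⁻². The polar solvation term is the Still pairwise
form with fixed input Born radii (no descreening recomputation — the scoring
layer only needs a consistent U, and fixed radii keep the engine
deterministic and desk-scale). ε_in enters both the Coulomb denominator and
the GB prefactor. The GB sum runs over all atom pairs including self terms;
LJ/Coulomb run over inter-molecular pairs and intramolecular pairs at least
three bonds apart. An optional cutoff applies potential-shift truncation
(V(d) − V(r_c) inside, 0 outside) to LJ and Coulomb; forces are untouched
inside and zero outside.

The nonpolar term is γ·SASA with γ = 0.005 kcal/mol/Å², where SASA is a
sphere-point (Shrake–Rupley) accessibility area with a 1.4 Å probe and van
der Waals radii 2^{1/6}σ/2. Two numerical choices matter:

* **Canonical frame.** Sphere points are fixed directions, so the raw
  point-count area is not rotation invariant at finite point counts. SASA is
  therefore evaluated in a canonical principal-axes frame (axis signs fixed
  by coordinate skewness, handedness by a cross product), making the total
  energy exactly invariant under global rigid motions (< 1e-8 kcal/mol).
* **Piecewise constancy.** The point-count area is piecewise constant in the
  coordinates, so its exact gradient is zero almost everywhere. The analytic
  gradient treats it accordingly, which is what central finite differences
  see away from flip boundaries; line searches compare the smooth part of
  the energy (`minimization_energy`) because the area staircase would
  otherwise stall backtracking, while reported/sampled energies always
  include the area term. 32 sphere points per atom are the default — for
  these toy systems the resulting area error is a few percent of a term that
  contributes ~10⁻² kcal/mol differences, and the count is configurable.

**Minimizer.** Steepest descent switching to Polak–Ribière conjugate
gradient (restarting on non-descent directions), with a backtracking line
search that halves from a trial step scaled so the largest atomic
displacement is 0.01 Å; the trial recovers after accepted steps but never
exceeds the 0.01 Å cap. The cap is load-bearing: an N-step minimization then
moves no atom more than N × 0.01 Å, so N_min-step relaxations stay local to
their shell instead of sliding placed ligands back down the attraction
gradient into the pocket. Template minimization (convergence mode) stops at
gradient RMS < 0.1 kcal/mol/Å (read as per-Å; the printed tolerance omits
the unit).

**Integrator.** BAOAB Langevin with Maxwell–Boltzmann initial velocities;
γ given in ps⁻¹ (the printed "2.0 ps" collision frequency is read as ps⁻¹).
The timestep must satisfy ω_max·dt ≤ 0.3 for the stiffest bond; engines
expose `max_stable_dt_fs` and the integrator refuses larger steps. There are
no constraints — at 1 fs with the toy bond stiffness none are needed. At
T = 0 the noise vanishes and the integrator performs damped descent.

**Rigid receptor.** Toy workflows freeze receptor atoms in minimization and
dynamics (masks apply to updates, not to the gradient, preserving
gradient/finite-difference consistency) and exclude receptor-internal
nonbonded pairs (constant for a rigid body). Frozen-receptor terms cancel in
work differences and in the comparator's complex − receptor difference.

## S-MMGBSA comparator and affinity maps

The single-structure comparator is G_complex − G_receptor − G_ligand, each
term the final energy of an independent minimization of that species
(complex: ligand mobile against the rigid receptor; isolated ligand: fully
mobile; rigid receptor: evaluated as-is).

Scores map to affinities linearly, ΔG_calc = α·score + β. The intercept β is
system dependent and no generalized value exists, so relative affinities are
the supported output: ΔΔG_calc = α·(score_X − score_ref) with the
generalized α = 0.20, referenced to the ligand with the highest experimental
ΔG (ties broken by label order, with a warning). Ranking quality is reported
as the Pearson correlation (the linear-response assumption makes linear, not
rank, correlation the relevant statistic).

## Docking-pose rescoring

A pose is *optimal* when its heavy-atom ligand RMSD to the reference complex,
after superposing the receptors (Kabsch, proper rotation only; receptor
atoms corresponded by residue number and atom name, ligand atoms by order),
is strictly below 2.0 Å. Poses are ranked ascending by score with
deterministic tie-break by pose index; failed poses are logged and excluded
rather than assigned sentinel scores. A two-stage workflow (single-structure
scoring to pick each ligand's pose, ensemble scoring to rank ligands) is
provided.

Pose scoring relaxes each pose *locally* — 150 displacement-capped steps,
i.e. at most ~1.5 Å of motion — rather than minimizing to convergence. On
the smooth toy landscape an unrestricted minimization walks any pose within
several Å back into the binding site and erases pose identity; real, rugged
landscapes enforce this locality by themselves, the toy engine needs the cap.
The RMSD reported for a pose is always computed on the docked (unrelaxed)
coordinates.

## Synthetic systems

`make_toy_complex` builds a rigid bowl-shaped cage of LJ sites (a spherical
cap of radius 2.8 Å, opening along +z, 32 sites by default) around a small
star-shaped bonded ligand (4 atoms, 0.8 Å arms, k = 300 kcal/mol/Å²) seated
at the center of curvature. `pocket_depth` sets the receptor–ligand pair
well depth in kcal/mol *exactly*: the ligand ε is chosen so the
Lorentz–Berthelot combination with the fixed cage ε equals the requested
depth, which makes single-structure interaction energies linear in the depth
parameter across a ligand series — the property behind the noise-free
ranking tests. The apo variant dilates the cage radially (×1.25), emulating
an open state. `geometry_scale` shrinks all lengths for studies that need
the full interaction range (including the probe-inflated SASA occlusion
range, ≈ 2·(2^{1/6}σ/2 + 1.4)) to end well inside the sampled window.

`make_ligand_series` assigns pseudo-experimental affinities
ΔG_exp = −2.0 − 1.8·depth + N(0, σ) (σ = 0 by default) — an affine map of
depth, so a correct scorer recovers |R| ≈ 1 on noise-free series.
`make_pose_set` builds decoys by rigid rotation about the ligand centroid
plus translation; rotations about the centroid have zero mean displacement,
so rmsd² = rmsd_rot² + |t|² holds in closed form and targets are met to
0.01 Å without search (even-indexed targets use pure translation).

What the toy systems do **not** emulate: ligand internal flexibility beyond
harmonic arms, receptor thermal motion, rugged energy landscapes, realistic
charge distributions (series default to neutral ligands, so the GB term is
exercised by dedicated unit tests rather than the pipeline), and solvent
structure. Passing tests therefore demonstrate the estimator's statistical
and numerical properties under controlled conditions, not chemical accuracy
on real targets; for real systems the engine contract accepts external
energy models.

## Problem sizes used in tests and the acceptance script

The statistical checks run complete pipelines at N_conf = 50 (the regime
where results stabilize), N_min = 100, full 10 ps bound-state sampling, on
the 36-atom toy complex: the decay and schedule-robustness studies on the
scale-0.8 system with a 4 Å truncated potential (interaction range < 8 Å,
shells at 9–10 Å strictly interaction-free); the ranking study on a
five-ligand noise-free series (depths 1.0–4.0); pose recovery on three
ligands × five poses with decoys at 4–8.5 Å (outside the basin the local
relaxation can re-seat). The enumeration-oracle check uses 6 directions × 8
orientations per shell with no minimization, where estimator and oracle must
agree to 1e-6 kcal/mol. These sizes are the package's chosen study
conditions and are fixed in `tests/test_acceptance.py` and
`scripts/acceptance.py`.

## Known limitations

* The binding-direction exponential average is dominated by its largest
  work samples; with few replicates the estimator is biased (Jensen bound:
  the estimate never exceeds the mean work). Jackknife SEs quantify
  stability, not bias.
* Born radii are inputs, not recomputed from geometry; GB quality on real
  molecules depends entirely on the supplied radii.
* The SASA term has zero gradient a.e., so minimization and dynamics ignore
  area forces; with γ = 0.005 and toy-scale areas this is a ≲0.05 kcal/mol
  effect on sampled energies.
* Pose RMSD uses all ligand heavy atoms (the choice of substructure is not
  specified in the source protocol; supplementary tables are titled
  heavy-atom RMSD).
* `ensemble` pairing with unequal shell sizes normalizes per shell; the
  replicate mode requires complete rectangular grids.
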