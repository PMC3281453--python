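# Methods

This note documents the models the package implements, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a user should know before trusting a number.

## Units and constants

Internal units are Å, amu, kcal/mol and fs.  A single conversion constant
(1 amu·Å²/fs² = 2390.0574 kcal/mol, `stericds.constants`) relates gradients
over masses to accelerations; k_B = 1.987204×10⁻³ kcal/mol/K and the Coulomb
prefactor 332.0637 kcal·Å/(mol·e²) live in the same module.  Nothing else in
the package defines a conversion factor — unit bugs are the dominant failure
mode in this kind of code, so there is one source of truth.

Atom indices are 0-based internally; XYZ/SDF/PDB keep their native 1-based
conventions at the file boundary.

## Force field

The steric energy is a deliberately minimal molecular-mechanics form with an
element-typed, pinned parameter set (`data/params_minimal.yaml`, UFF-like
magnitudes):

| term | form | notes |
|---|---|---|
| stretch | k_b (r−r₀)² | per bond |
| bend | k_θ (θ−θ₀)² | per angle triple |
| torsion | V/2 (1+cos(nφ−γ)) | per proper dihedral |
| van der Waals | LJ 12-6, Lorentz–Berthelot | 1-2/1-3 excluded, 1-4 × 0.5 |
| electrostatic | q_i q_j /(ε_r r), ε_r = 1.5 | same exclusions/scaling |
| hydrogen bond | ε(5(r₀/r)¹²−6(r₀/r)¹⁰) | donor-H···acceptor, r₀ = 1.9 Å, ε = 2 kcal/mol, 5 Å cutoff |

Nonbonded interactions truncate sharply at 12 Å with no switching function.
Atom typing is by element only: a carbonyl carbon bends like an sp³ carbon.
That is a known limitation accepted for totality — every structure over the
supported elements either parameterizes fully or raises a named
`UnparameterizedPatternError`; parameters are never silently zeroed.
Donors are hydrogens bonded to N/O/F; acceptors are N/O/F atoms.  Absolute
energies are therefore not comparable to any commercial force field; only
differences under this parameter set are meaningful, and reproducing
published absolute steric energies is a non-goal.

Gradients are fully analytic (including the cross-product forms for bends
and dihedrals) and are validated against central finite differences on 100
randomized systems per test run.  Finite-difference checks are performed at
relaxed-then-jittered geometries: on the r⁻¹² wall of a clashed construction
geometry the central-difference truncation error itself exceeds the
tolerance, which says nothing about the analytic gradient.

The minimizer is gradient descent with backtracking (step shrinks ×0.5 on
rejection, grows ×1.2 on acceptance, capped at 0.1 Å); energy never
increases across accepted steps and convergence is declared at a max-norm
gradient tolerance (default 0.05 kcal/mol/Å) or an iteration cap.  It finds
nearby local minima only — that is intentional, since the complexation
protocol (below) relies on annealing, not the minimizer, for basin hopping.

## Dynamics

The integrator is the classical Beeman scheme,

x(t+Δt) = x + vΔt + (2/3 a − 1/6 a_old)Δt²,
v(t+Δt) = v + (1/3 a_new + 5/6 a − 1/6 a_old)Δt,

bootstrapped with a_old := a at the first step (making step one
velocity-Verlet-equivalent).  Velocities initialize from a Maxwell–Boltzmann
draw with net momentum removed and an exact rescale to the target
temperature; temperature control during a run is plain velocity rescaling
every 50 steps (deterministic, minimal).  Instantaneous temperature uses
N_dof = 3N−3 (3 for a single atom); frozen atoms are excluded from both the
kinetic energy and N_dof.

Step-size guidance baked into the tests: the 2.0 fs protocol default is fine
for thermostatted annealing, but NVE conservation checks run at 0.5 fs
(rigid-free diatomic) and 0.1 fs (H-bearing molecules), because unconstrained
X–H stretches have ~9–11 fs periods and Beeman is not symplectic — at 2 fs
the drift bound of 0.1% per 10⁴ steps is unreachable for any unconstrained
integrator of this order.  Constraint algorithms are out of scope.

Hydrogen bonds are recorded geometrically along trajectories
(H···acceptor ≤ 2.5 Å and donor–H···acceptor angle ≥ 120°), restricted to
inter-molecular pairs when a host/guest partition exists.

## Complexation and the stability index

`run_complexation` computes Ds = 100 (E_Chit + E_Insectic − E_k)/|E_Chit +
E_Insectic| with classification stable (> 50) / unstable (< 35) / medium
(boundaries inclusive of neither, so 35 and 50 are medium).  The denominator
carries an absolute value so the sign convention survives parameter sets
that give negative totals.  Decisions worth knowing:

* **One relaxation protocol for everything.**  Host, guest, and every pose
  get the same anneal-then-minimize treatment (short pre-relaxation, 10 ps
  thermostatted dynamics by default, then minimization), so all three
  energies sit in comparable basins.
* **Rigid host during pose refinement.**  The host is annealed and
  minimized once, poses are built from the relaxed structures, and the host
  stays frozen while each pose anneals.  The oligosaccharide host has a
  glassy torsional landscape: repeated 300 K anneals scatter its minimized
  energy over several kcal/mol, which would both bias E_k (a minimum over
  poses selects the deepest host relaxation) and drown the ~1–10 kcal/mol
  interaction signal.  With a rigid host its internal energy cancels
  exactly in Ds, which then isolates host–guest interaction plus guest
  strain.  Flexible-receptor refinement is an explicit non-goal.
* **E_k is the minimized end-state of the best pose**, not a trajectory
  average: a single-configuration steric energy is reproducible and matches
  the quantity's usual meaning.
* **Pose sampling** applies a uniform random rotation and places the guest
  at a 3–6 Å surface clearance along a random direction, rejecting contacts
  under 1.5 Å; the pose stream is prefix-stable in n_poses, so increasing
  n_poses can only lower E_k.  The default is 20 poses: the polar-guest
  advantage comes from hydrogen-bonding sites that sparse sampling (≈10
  poses) can miss, and the measured polar/apolar contrast only stabilizes
  near the default pose count.
* Determinism: everything derives from the config seed (pose k anneals with
  seed + k + 1).

The acceptance run compares a polar diol probe and an equal-heavy-atom
alkane against a two-unit host at 5 ps × 20 poses — chosen to keep the
contrast measurement at the default pose depth within a desk-scale run
time; at these settings the contrast held with a 6–29 point margin on every
seed probed during development.

## The chitin-model host

The host is assembled from a shipped N-acetylglucosamine-like monomer
template (30 atoms, synthetic geometry: chair-like pyranose ring with
hydroxyl, N-acetyl and hydroxymethyl substituents, relaxed under the builtin
parameter set; it is not an experimental structure).  β(1→4)-style linking
eliminates the anomeric O–H of one unit and the C4-hydroxyl hydrogen of the
next (3 atoms per linkage, so n units have 30n−3(n−1) atoms), bonds C1 to
O4 at the vacated oxygen position, and flips alternate units 180° about the
chain axis as in the two-fold screw of crystalline chitin.  Partial charges
are template-fixed and re-neutralized exactly after linkage.  No published
coordinates exist for the original model, so this template is a pinned,
versioned stand-in: deterministic, clash-free up to the supported 8 units,
and polar where chitin is polar (the hydroxyl/amide surface).

## Ecological statistics

* **Summaries.**  An assessment is one (site, date, phase, insecticide)
  combination of ten traps; abundance is its total count, richness its
  number of distinct species with positive counts; summaries are means per
  requested group.
* **One-way ANOVA** uses the classical between/within decomposition (p from
  the F distribution); the all-constant corner returns F = 0, p = 1 rather
  than NaN.  Two groups reduce exactly to the squared pooled t.
* **Two-way ANOVA** uses sequential (Type I) sums of squares computed by
  nested least-squares projections with the factor order fixed as phase,
  then treatment, then interaction.  In unbalanced designs that order is
  part of the contract (the alternative conventions are equally defensible;
  determinism was the criterion).  The implementation is plain numpy for
  speed and is pinned against statsmodels' `anova_lm(typ=1)` in the test
  suite; single-level factors degenerate to one-way with a warning.
* **Regression** is OLS of N on [1, Ds, logP, Pe, S, logKoc] through
  statsmodels, with R = +√R², overall F = (R²/k)/((1−R²)/(n−k−1)), and
  exact p-values (never "P < x" bounds).  The response is raw abundance by
  default with a log10 switch; neither transform is privileged by the
  module, but the synthetic generator's mean model is log-linear, so
  recovery studies regress log10(N).
* **Partial correlations** control each predictor for the other four by the
  residual method; a precision-matrix identity and pingouin serve as
  independent oracles in the tests.  Designs with correlation-matrix
  condition number above 10¹⁰ raise a `CollinearityError` naming the
  offending columns.

## Synthetic data

The trap generator simulates total counts per assessment as negative
binomial (dispersion 2.0 — pitfall counts are overdispersed, and the
parameter is visible and testable) around

log μ = baseline + site effect + [after] · β·(d − d_ref),

with defaults: 12 sites, 5 years, 10 spray events/year cycling through the
insecticide table in a balanced rotation, site-effect SD 0.3, baseline
ln(5.2) (sized so a default run yields ≈6×10³ individuals over ≈1200
assessments, the scale of a multi-year orchard study).  β is standardized:
each default coefficient moves the log-mean by 0.4 per SD of its descriptor
(Ds −0.03 %⁻¹, logP +0.23, Pe −7×10⁻⁴ h⁻¹, S +0.014 L/mg, logKoc −0.46),
signs matching the field observation that abundance falls with stability,
persistence and soil adsorption and rises with lipo- and water solubility.
Descriptor tables draw from ranges typical of registered contact
insecticides (Ds 15–60%, logP 1–7, Pe 24–2000 h, S log-uniform
0.001–150 mg/L, logKoc 2–5), centred at d_ref so the baseline stays
interpretable.  Individuals are assigned to a 238-species pool with
log-series weights (x = 0.9999), which reproduces the dominance structure
of real staphylinid assemblages — the nine most abundant species carry
≈47% of individuals.

What the generator does **not** emulate: real species identities and
phenology, weather, spatial trap layout, between-year trends, or
species-specific insecticide responses.  Passing recovery tests therefore
demonstrates that the statistical chain is consistent and calibrated — not
that the field effect sizes are correct, which unpublished raw data make
untestable here.

A lighter generator (`gen_abundance_response`) draws N directly from the
linear model N = 5.2 + β·(d−d_ref) + Normal(0,1) for estimator-property
studies (coefficient bias, partial-correlation sign recovery at n = 60),
where OLS is exactly specified.

Every generator is a pure function of its seed.

## Problem sizes in the shipped checks

The test suite and acceptance script size their simulations for a
single-CPU desk run: 10⁴-step NVE checks, 100-system gradient sweeps,
10⁴-replicate ANOVA calibrations, 10³-replicate bias studies,
500-dataset sign-recovery studies, and one 5 ps × 20-pose complexation
contrast — a few minutes end to end.  All bounds asserted by the tests
(0.1% drift, 1×10⁻⁴ kcal/mol/Å gradient agreement, the 0.045–0.055
calibration band, 5% bias, 95% sign recovery) are stated in the tests
themselves at those sizes.

## Known limitations

* Element-only atom typing; no aromaticity, stereochemistry, or protonation
  handling; no cutoff smoothing (tiny energy discontinuities at 12 Å).
* Beeman + velocity rescaling is not a canonical-ensemble sampler; it is a
  deterministic annealing device here, not a thermodynamics engine.
* Ds magnitudes depend on the parameter set and the |E_host + E_guest|
  denominator; when that reference is small the index is ill-conditioned
  (the package raises rather than reporting a number when it is numerically
  zero).
* The SDF dialect (V2000) carries 4 decimal places of coordinate precision;
  round-trips are exact only to 10⁻⁴ Å.  Partial charges persist through a
  `partial_charges` data field, which other software will ignore.
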