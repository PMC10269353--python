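# Methods

`smirkfit` reimplements, at desk scale, the production loop of a
SMIRNOFF-style small-molecule force field: direct chemical perception,
a gas-phase MM engine, regularized least-squares fitting of Lennard-Jones
and valence parameters, training-data curation, and benchmark statistics.
Everything runs on synthetic inputs with known ground truth, so every stage
is testable end to end without quantum chemistry, molecular dynamics, or
external databases.

## Direct chemical perception

A force field is a set of ordered parameter lists per interaction class
(bonds, angles, proper and improper torsions, vdW), each parameter keyed by
a SMIRKS pattern whose tagged atoms identify the tuple that receives it.
Assignment enumerates every bonded tuple of a molecule and applies the
*last* matching parameter in list order, so generic patterns come first and
specific chemistry later in the list overrides them.  Substructure matching
is delegated to RDKit; ordering, tuple canonicalization (a tuple and its
reverse collapse to one key; impropers are keyed by central atom plus
sorted neighbors) and the last-match-wins rule live in `chem_model`.
Symmetric matches count once.  Impropers apply one term per matched
(center, sorted-neighbor) tuple — no trefoil averaging, a deliberate
simplification documented here because impropers are never optimized in
this protocol.

Units are fixed: Å, degrees in files, kcal/mol, with harmonic terms in the
SMIRNOFF convention E = (k/2)(x − x0)² (angle k per rad²).  Note AMBER
parameter files use k(x − x0)²; values are not interchangeable.

## MM engine

Gas phase, no cutoffs, Lorentz–Berthelot combining, 1-2/1-3 exclusions and
AMBER-family 1-4 scaling (vdW 0.5, electrostatics 1/1.2, configurable).
Analytic gradients for every term are tested against central finite
differences at 1e-6 relative; a numba-compiled scalar-loop kernel carries
the hot path (systems of tens of atoms are too small for vectorized numpy
to amortize its call overhead), with the numpy implementation retained as
the reference path and cross-checked in tests.

Minimization is L-BFGS-B over free coordinates; frozen atoms are excluded
from the optimization vector.  Torsion scans follow a two-stage restrained
protocol per grid point: (1) drive the dihedral to the grid angle with a
stiff harmonic dihedral restraint (1000 kcal/mol/rad²) while all atoms
outside the torsion carry 1 kcal/mol/Å² positional restraints to their
seed coordinates, (2) snap the residual driving error to zero by rigidly
rotating the far-side subtree about the central bond, then freeze the four
torsion atoms Cartesian and relax the rest.  Whether the reference
protocol Cartesian-freezes or dihedral-constrains the four atoms is
ambiguous; both stages exist here and freezing-after-driving is the
default.  Reported profiles exclude all restraint energy exactly and are
referenced to the grid minimum.  Grid points above an energy cutoff
(0.05 hartree ≈ 31.4 kcal/mol, the in-ring scan convention) can be
dropped.  Scans store their per-point seed coordinates; re-running a scan
with those seeds pinned evaluates a fixed objective reproducibly, which is
what makes the fitting loss a deterministic function of the parameters.

## Fitting targets

*opt-geo*: internal coordinates (bond lengths, angles, improper dihedrals
of the canonical improper tuple; proper torsions excluded) of an
MM-minimized geometry versus the reference minimum, each deviation divided
by 0.05 Å, 8°, or 20° respectively, squared, summed, and normalized by the
coordinate count.  The MM geometry is re-minimized from the reference
geometry at every objective evaluation.  Improper deviations use the
improper dihedral rather than an out-of-plane angle; the two differ only
in parameterization of the same planarity measure.

*torsion-profile*: both MM and reference profiles re-referenced to their
own grid minima, squared differences divided by d_E = 1 kcal/mol, weighted
by w(E): 1 below 1 kcal/mol, 1/√(1 + (E−1)²) between 1 and 5, exactly 0 at
and above 5 kcal/mol — matching near the minima matters for Boltzmann-
weighted observables, barrier tops do not.  Normalized per grid point.
The per-target normalization constants are configuration values
(`weight`, divisors, grid) rather than hard-coded.

## Objectives and optimization

Valence objective: Σᵢ wᵢ·Lᵢ + w_reg·Σₚ(Δθₚ/σₚ)², with weights 0.1
(opt-geo) and 1 (torsion-profile), and Gaussian-prior scales σₚ: bond k
100 kcal/mol/Å², bond length 0.1 Å, angle k 100 kcal/mol·rad², angle
equilibrium 20°, torsion k 1 kcal/mol.  LJ objective: pooled pure and
mixture densities averaged over N_ρ with divisor d_ρ = 0.05 g/mL, plus
enthalpies of mixing averaged over N_ΔHmix with d_ΔHmix = 1.6 kJ/mol, plus
the prior with σ = 0.1 kcal/mol (ε) and 1 Å (R_min/2).

Eligibility: only parameters applied to at least 5 molecules enter the
parameter vector; linear angles (θ0 = 180°) contribute only their force
constant; torsion periodicities and phases are frozen; impropers are never
optimized.  A vdW type is refit-eligible only with ≥5 density and ≥5
enthalpy points touching it.

The LJ stage iterates L-BFGS-B (analytic surrogate gradients) in
σₚ-rescaled coordinates — the prior scales double as natural parameter
units, keeping quasi-Newton updates well conditioned across attribute
kinds that differ by four orders of magnitude — with box constraints
ε ≥ 0, R_min/2 > 0.  Convergence is declared when two of three criteria
hold: objective ≤ 0.1, gradient norm ≤ 0.1, step ≤ 0.01 (thresholds are
configuration).

The valence stage defaults to a trust-region least-squares (Gauss–Newton)
fit on the per-coordinate residual vector: opt-geo targets contribute
√(w/N)·Δx/d per internal coordinate, torsion targets √(w·w(E)/N)·ΔE/d_E
per grid point, and the prior √(w_reg)·Δθₚ/σₚ per parameter.  Residual
Jacobians are 3-point finite differences with per-kind steps
(0.1 kcal/mol/Å² for force constants, 1e-3 Å, 1e-2°, 1e-3 kcal/mol).
The Gauss–Newton model is what lets the weakly-curved force-constant
directions converge in tens of iterations where a scalar quasi-Newton
loop crawls; a scalar L-BFGS-B route with central-difference gradients
and the two-of-three rule remains available (`method="lbfgs"`).  The
least-squares solve runs unbounded: its bounded reflective variant stalls
in the sloppy directions, and a trial step into unphysical territory
(negative force constant) produces divergent target minimizations, huge
residuals, and a rejected step, so iterates stay physical without boxes.
Scans inside the objective always restart from their stored seeds rather
than from the previous iterate's frames: warm-starting leaves a small
hysteresis floor once a line search has visited a neighboring rotamer
well, which both biases the optimum and corrupts trust-region
actual-versus-predicted reduction ratios.

## Synthetic ground truth

Toy molecules (ethane through butane, ethanol/propanol, ethylamine,
acetamide-like and methanesulfonamide-like templates) are built from
explicit internal-coordinate templates via natural-extension placement —
no conformer embedder, so geometries are bit-reproducible.  Partial
charges are fixed small rule-based values summing to zero.  The
ground-truth force field covers H/C/N/O/S with one specific and one
generic parameter layer per class so last-match-wins is always exercised.

Synthetic "QM" targets are minimizations and torsion scans under the
ground truth plus optional Gaussian noise; with zero noise the valence
data term at the generating parameters is zero to solver precision.
Property data come from an analytic surrogate: molar volume
V = v_scale·Σ n_t R_t³, cohesion e = Σ n_t ε_t, density
ρ = (Σx M)/(Σx V)·(1 + α ē/n̄) (decreasing in every R_min/2, increasing in
every ε), and a regular-solution mixing enthalpy
ΔH = (x₁V₁x₂V₂/(x₁V₁+x₂V₂))·(δ₁−δ₂)² with cohesive-energy-density
contrast δ = c·e/V.  Surrogate gradients are analytic and FD-verified.
The surrogate reproduces none of the physics of liquid simulation beyond
these declared monotonicities — passing tests demonstrate the fitting
machinery, not transferability to real liquids.

Free-energy benchmark tables are paired draws around common experimental
values with stated biases and Gaussian noise; the expected mean shift has
a closed folded-normal form used as the test oracle.

## Parameter-recovery protocol

The strongest end-to-end check: perturb a refit subset of parameters by
10%, regenerate nothing, and fit back on noiseless targets.  Two design
choices matter and are deliberate:

* **Regularization off (w_reg = 0) during recovery.**  Recovery is an
  identifiability statement about the data terms.  At desk-scale data
  volumes the Gaussian prior dominates the weakly-determined directions
  and would pin parameters near the perturbed start (a bias of order
  0.1 Å on a bond length under the production σₚ).  Production-style fits
  keep w_reg = 1.
* **Tight convergence thresholds during recovery.**  The production
  two-of-three thresholds (0.1/0.1/0.01) are calibrated to noisy,
  large-scale objectives; on a noiseless desk-scale objective they stop
  the optimizer long before the flat directions resolve.  Recovery runs
  with thresholds of 1e-8/1e-6/1e-7 and a larger iteration budget.

Identifiability itself is instructive and finite: geometry and profile
targets pin bond lengths (recovered to ≪1%), equilibrium angles, and
torsion force constants (≪1%) strongly, but bond/angle force constants
only through second-order relaxation effects — the curvature information
that vibrational-frequency targets would carry, and this protocol
deliberately has none.  Those directions converge orders of magnitude more
slowly, which is why the recovery budget is hundreds of quasi-Newton
iterations rather than tens.  Problem sizes used: eligibility counted
over five molecules, targets from the butane and ethanol templates with a
60° scan grid; the LJ stage refits three vdW types against 65 surrogate
points over five substances.  These sizes were chosen so a full two-stage
recovery runs in minutes on one core while every moving part of the
production loop is exercised.

## Curation

Conformer capping is greedy max-min selection on optimal-superposition
RMSD (heavy atoms by default), seeded at the lowest-energy conformer,
equal to brute-force stepwise max-min on every small instance tested.
Connectivity change is perceived from distances (bonded iff
d < 1.2 × sum of covalent radii, RDKit radii) and any change between
initial and final geometry rejects the pair — the proton-transfer filter.
Intramolecular hydrogen bonds use a single-structure geometric criterion
(D, A ∈ {N, O}, H···A ≤ 2.5 Å, ∠D–H···A ≥ 120°), cross-checked against the
reference trajectory-analysis implementation in tests; thresholds are
configuration because the cited criterion is defined on trajectories, not
single structures.  Torsion-scan selection prefers candidates exercising a
parameter with zero overlapping parameters on the central bond, escalating
the allowed overlap one at a time; ties break on identifier order.

Property curation order: element whitelist {H, C, N, O, Cl, Br}; ambient
window 99.9–101.4 kPa and 288.15–318.15 K (boundaries inclusive);
mole-fraction floor 0.05 (inclusive — a "minimum of 0.05" admits 0.05);
optional named substructure exclusions; per binary system and data type up
to three points nearest x₁ ∈ {0.25, 0.5, 0.75}; finally drop functional
groups with fewer than five surviving measurements per data type.  The
≥5-per-group rule is applied last; applying it before the concentration
selection is also defensible and the ordering is stated here because the
source protocol leaves it open.  Widening a window retains a superset of
the windowed survivors; the concentration selection can displace
previously chosen points, so strict monotonicity holds stage-wise, not
end-to-end.

## Benchmarks

RMSD is Kabsch superposition (SVD with determinant correction), tested
against the closed-form quaternion solution.  TFD uses the reference
implementation of the torsion-fingerprint method (RDKit); molecules with
no nonterminal rotatable bonds return an explicit undefined flag, never a
silent zero, and the single-torsion closed form |Δφ|/180 is the test
oracle.  ΔΔE references both energy scales to the reference minimum-energy
conformer, which is excluded from summaries.  The mean shift is the paired
difference in unsigned errors between a refit and a reference force field;
CIs are percentile bootstrap (2000 resamples, seed mandatory).  Transfer
free energies compose as ΔG_trans(aq→nonaq) = ΔG_solv(nonaq) −
ΔG_solv(aq), asserted by the additivity identity.  Shift-variance
deconvolution assumes zero-mean Gaussian simulation noise with σ equal to
the mean propagated uncertainty: fraction = max(0, s² − σ²)/s².
Parameter enrichment among high-TFD molecules defaults to the normalized
form [n(param ∧ TFD>0.1)/n(TFD>0.1)] / [n(param)/n]; the literal ratio
n(param ∧ high)/n(param) is bounded by 1 and available behind a flag —
reported over-representation values above 2 are only consistent with the
normalized form.

## Known limitations

* The surrogate property model is smooth and low-dimensional; realistic
  liquid-state response surfaces are noisy and the LJ loop's
  fluctuation-based stopping rule for stochastic backends is not exercised
  by it.
* Chemically realistic compositions make C- and H-type parameters nearly
  collinear (H counts track C counts), so recovering all vdW types at once
  is ill-conditioned; the recovery protocol refits a well-conditioned
  subset and leaves the rest frozen, as production refits do.
* Toy molecules are acyclic; ring torsions, puckering, and aromaticity are
  untested territory.
* Improper handling (single term, canonical tuple) differs from trefoil-
  averaged conventions; comparing improper energies across packages
  requires accounting for this.
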