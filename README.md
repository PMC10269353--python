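# smirkfit

A desk-scale reimplementation of the production pipeline behind
SMIRNOFF-style small-molecule force fields, for people who want to study,
test, or teach how such force fields are built without a cluster: direct
chemical perception from ordered SMIRKS parameter lists, a gas-phase MM
engine with analytic gradients, the regularized least-squares objectives
used to refit Lennard-Jones parameters against liquid densities and
enthalpies of mixing and valence parameters against optimized geometries
and torsion profiles, the training-data curation filters, and the
benchmark statistics used to judge the result (RMSD, TFD, ΔΔE, paired mean
shift with bootstrap CIs, variance deconvolution).

Everything runs against synthetic inputs with known ground truth — toy
molecules built from internal-coordinate templates, "QM" targets generated
by minimizing and scanning under a ground-truth parameter set, and an
analytic surrogate mapping LJ parameters to liquid properties — so the
whole loop is verifiable end to end on one core in minutes.

## The model in brief

Parameters are keyed by SMIRKS patterns in ordered lists; for every bonded
tuple the last matching pattern wins.  The potential is AMBER-family:
harmonic bonds and angles in the (k/2)(x−x0)² convention, cosine torsion
series Σₙ kₙ(1+cos(nφ−γₙ)), 12-6 LJ from (R_min/2, ε) with
Lorentz–Berthelot combining, Coulomb with 1-2/1-3 exclusions and scaled
1-4 interactions.  Fitting minimizes

    L(θ) = Σᵢ wᵢ·Lᵢ(θ) + w_reg·Σₚ (Δθₚ/σₚ)²

with per-target losses normalized by their size: opt-geo targets penalize
internal-coordinate deviations scaled by 0.05 Å / 8° / 20°, torsion-profile
targets penalize energy-profile deviations (d_E = 1 kcal/mol) weighted by
w(E) = 1 below 1 kcal/mol, 1/√(1+(E−1)²) to 5 kcal/mol, 0 above; the LJ
objective block-averages pooled densities (d_ρ = 0.05 g/mL) and mixing
enthalpies (d_ΔH = 1.6 kJ/mol).  The Gaussian-prior scales σₚ and the
two-of-three convergence rule (objective ≤ 0.1, gradient ≤ 0.1,
step ≤ 0.01) follow the production protocol.  See `docs/methods.md` for
the full account, including which parameters the available target types
can and cannot identify.

## Worked example

Generate a synthetic training world, perturb a refit subset of parameters
by 10%, and recover them with the two-stage protocol (LJ first, then
valence):

```python
from smirkfit.protocols import lj_recovery, valence_recovery

lj = lj_recovery(seed=0)
for name, err in lj.errors.items():
    print(f"{name:22s} {100 * err:8.4f}%")

valence = valence_recovery(seed=0)
for name, err in valence.errors.items():
    print(f"{name:22s} {100 * err:8.4f}%")
```

prints (seed 0):

```
n-c4.epsilon             0.0000%
n-c4.rmin_half           0.0000%
n-o.epsilon              0.0000%
n-o.rmin_half            0.0000%
n-n.epsilon              0.0000%
n-n.rmin_half            0.0000%
b-cc.k                   3.3644%
b-cc.length              0.0019%
a-c4.k                   0.3989%
a-c4.angle               0.0808%
t-cc.k1                  0.0013%
```

Each number is the relative error of a refit parameter against the ground
truth it was perturbed away from.  The LJ stage recovers the eligible vdW
types exactly on noiseless surrogate data; the valence stage pins the bond
length, equilibrium angle, and torsion barrier to well under 1%, while the
bond-stretch force constant — whose information would come from the
vibrational targets this protocol deliberately omits — is recovered only
through second-order relaxation effects and converges far more slowly.

The same machinery is scriptable from the shell:

```bash
smirkfit make-synthetic --seed 3 --out world/
smirkfit curate properties --in world/properties.csv --out kept.csv --report report.json
smirkfit fit-lj --forcefield world/forcefield.json --data kept.csv --out lj_fit.json
smirkfit benchmark fe --new world/fe_new.csv --ref world/fe_ref.csv --out fe_stats.json
```

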