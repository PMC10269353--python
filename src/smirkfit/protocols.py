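"""End-to-end refit protocols on synthetic ground truth.

These drive the full machinery the way a production refit would: generate
training inputs under a known parameter set θ*, perturb a refit subset of
parameters by a fixed fraction, and optimize back.  They exist both as the
package's self-validation (parameter recovery on noiseless data is the
strongest end-to-end check the synthetic setup admits) and as worked
examples of the two-stage protocol: LJ parameters are fit first against
condensed-phase property data with valence terms frozen, then valence
parameters against geometry and torsion-profile targets with LJ frozen.

The recovery experiments run with the regularization weight at zero: they
are identifiability checks of the data terms, and at desk-scale data
volumes the Gaussian prior would otherwise dominate the sloppy directions
and pin parameters near the perturbed start.  Production-style fits keep
w_reg = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from smirkfit.chem_model import ForceField, applied_parameter_counts
from smirkfit.curation import eligible_lj_types
from smirkfit.fit_driver import (
    FitConfig,
    FitReport,
    RegularizationScheme,
    fit_lj,
    fit_valence,
)
from smirkfit.synthetic_data import (
    SurrogateModel,
    SurrogatePropertyBackend,
    make_property_dataset,
    make_qm_targets,
    make_toy_molecules,
    toy_forcefield,
)

# refit subsets: parameters perturbed and re-optimized in the recovery runs
VALENCE_REFIT = {"b-cc": ("k", "length"), "a-c4": ("k", "angle"),
                 "t-cc": ("k1",)}
LJ_REFIT = ("n-c4", "n-o", "n-n")
PERTURBATION = 0.10

# tight convergence for noiseless identifiability runs; production fits use
# the FitConfig defaults (0.1 / 0.1 / 0.01, two of three)
TIGHT = dict(objective_threshold=1e-8, gradient_threshold=1e-6,
             step_threshold=1e-7)


@dataclass
class RecoveryResult:
    report: FitReport
    truth: ForceField
    fitted: ForceField
    errors: dict[str, float]  # "pid.attr" -> relative error (fraction)

    def worst(self, attr_kinds: tuple[str, ...] = ()) -> float:
        pool = {
            key: err for key, err in self.errors.items()
            if not attr_kinds or key.split(".")[1].rstrip("0123456789")
            in attr_kinds
        }
        return max(pool.values()) if pool else 0.0


def _perturbed_start(truth: ForceField, refit: dict[str, tuple[str, ...]],
                     fraction: float) -> ForceField:
    start = truth.copy()
    for params in start.parameters.values():
        for p in params:
            p.optimize = refit.get(p.id, ())
            for attr in p.optimize:
                p.attributes[attr] *= 1.0 + fraction
    return start


def _errors(truth, entries, theta):
    out = {}
    for (cls, pid, attr), v in zip(entries, theta):
        ref = truth.get_parameter(pid).attributes[attr]
        out[f"{pid}.{attr}"] = abs(v - ref) / abs(ref)
    return out


def valence_recovery(
    seed: int = 0,
    grid_spacing: float = 60.0,
    max_iterations: int = 25,
    perturbation: float = PERTURBATION,
) -> RecoveryResult:
    """Refit perturbed valence parameters against noiseless synthetic QM
    targets (optimized geometries + torsion profiles) generated at θ*.

    Problem size: five toy molecules define parameter eligibility; targets
    come from the butane and ethanol templates with a coarse torsion grid,
    which keeps a full refit within minutes on one core.
    """
    truth = toy_forcefield()
    mols = make_toy_molecules(
        [{"template": "alkane", "n": 2}, {"template": "alkane", "n": 3},
         {"template": "alkane", "n": 4}, {"template": "alcohol", "n": 2},
         {"template": "amine", "n": 2}],
        seed=seed,
    )
    counts = applied_parameter_counts(mols, truth)
    optgeo, torsions, _ = make_qm_targets(
        mols[2:4], truth, seed=seed, grid_spacing=grid_spacing
    )
    start = _perturbed_start(truth, VALENCE_REFIT, perturbation)
    config = FitConfig(max_iterations=max_iterations, seed=seed, **TIGHT)
    scheme = RegularizationScheme(w_reg=0.0)
    fitted, report, vec = fit_valence(
        optgeo + torsions, start, counts, scheme, config
    )
    return RecoveryResult(report, truth, fitted,
                          _errors(truth, vec.entries, report.final_theta))


def lj_recovery(
    seed: int = 0,
    max_iterations: int = 150,
    perturbation: float = PERTURBATION,
) -> RecoveryResult:
    """Refit perturbed LJ parameters of the eligible types against noiseless
    surrogate property data generated at θ*."""
    truth = toy_forcefield()
    model = SurrogateModel()
    points = make_property_dataset(truth, [], seed=seed, model=model)
    substance_types = {
        name: list(s.type_counts) for name, s in model.substances.items()
    }
    eligible = eligible_lj_types(points, substance_types=substance_types)
    refit = {pid: ("epsilon", "rmin_half")
             for pid in LJ_REFIT if pid in eligible}
    start = _perturbed_start(truth, refit, perturbation)
    entries = [("vdw", p.id, attr)
               for p in start.parameters["vdw"] if p.id in refit
               for attr in p.optimize]
    backend = SurrogatePropertyBackend(start, entries, model)
    config = FitConfig(max_iterations_lj=max_iterations, seed=seed, **TIGHT)
    scheme = RegularizationScheme(w_reg=0.0)
    fitted, report, vec = fit_lj(points, backend, start, list(refit),
                                 scheme, config)
    return RecoveryResult(report, truth, fitted,
                          _errors(truth, vec.entries, report.final_theta))


def two_stage_refit(seed: int = 0, grid_spacing: float = 60.0):
    """LJ stage first (valence frozen), then valence stage (LJ frozen)."""
    lj = lj_recovery(seed=seed)
    valence = valence_recovery(seed=seed, grid_spacing=grid_spacing)
    return lj, valence
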