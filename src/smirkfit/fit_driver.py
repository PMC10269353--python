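"""Regularized fitting objectives and optimization loops.

Two refits are supported, mirroring a two-stage force-field production
protocol: an LJ stage driven by condensed-phase property data through a
pluggable :class:`PropertyBackend` (a weighted least-squares objective with
blocks for pooled densities and enthalpies of mixing), and a valence stage
driven by opt-geo and torsion-profile targets.  Both carry a Gaussian-prior
regularization penalty Σ(Δθ_p/σ_p)² with per-attribute scales (bond k
100 kcal/mol/Å², r0 0.1 Å, angle k 100 kcal/mol·rad², θ0 20°, torsion k
1 kcal/mol, ε 0.1 kcal/mol, R_min/2 1 Å).

Parameter eligibility: only parameters applied to at least five molecules in
the training set are vectorized; linear-angle equilibrium values are held at
180°, torsion periodicities and phases are frozen, and improper parameters
are never optimized.

Convergence is declared when at least two of three criteria hold: total
objective ≤ 0.1, parameter-gradient norm ≤ 0.1, step size ≤ 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.optimize import least_squares as _scipy_least_squares
from scipy.optimize import minimize as _scipy_minimize

from smirkfit.chem_model import ForceField, assign_parameters
from smirkfit.fit_targets import (
    OptGeoTarget,
    TorsionProfileTarget,
    optgeo_loss,
    torsion_profile_loss,
)
from smirkfit.mm_engine import compile_system, minimize as mm_minimize, torsion_scan

# σ_p per (parameter class, attribute kind)
DEFAULT_SIGMAS = {
    ("bond", "k"): 100.0,
    ("bond", "length"): 0.1,
    ("angle", "k"): 100.0,
    ("angle", "angle"): 20.0,
    ("proper_torsion", "k"): 1.0,
    ("vdw", "epsilon"): 0.1,
    ("vdw", "rmin_half"): 1.0,
}

# central finite-difference steps per attribute kind
DEFAULT_FD_STEPS = {
    ("bond", "k"): 1e-1,
    ("bond", "length"): 1e-3,
    ("angle", "k"): 1e-1,
    ("angle", "angle"): 1e-2,
    ("proper_torsion", "k"): 1e-3,
    ("vdw", "epsilon"): 1e-3,
    ("vdw", "rmin_half"): 1e-3,
}


def _attribute_kind(attr: str) -> str:
    """'k3' -> 'k' etc.; maps a stored attribute name to its kind."""
    return attr.rstrip("0123456789")


@dataclass
class RegularizationScheme:
    sigmas: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SIGMAS)
    )
    w_reg: float = 1.0

    def __post_init__(self):
        if any(s <= 0 for s in self.sigmas.values()):
            raise ValueError("all regularization scales must be > 0")

    def sigma_for(self, parameter_class: str, attr: str) -> float:
        return self.sigmas[(parameter_class, _attribute_kind(attr))]


@dataclass
class FitConfig:
    weight_optgeo: float = 0.1
    weight_torsion: float = 1.0
    objective_threshold: float = 0.1
    gradient_threshold: float = 0.1
    step_threshold: float = 0.01
    fd_steps: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FD_STEPS)
    )
    max_iterations: int = 50
    max_iterations_lj: int = 15
    eligibility_threshold: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("objective_threshold", "gradient_threshold",
                     "step_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.weight_optgeo < 0 or self.weight_torsion < 0:
            raise ValueError("target weights must be >= 0")


@dataclass
class PropertyDataPoint:
    """One experimental measurement: pure/mixture density or ΔH_mix."""

    kind: str  # "density" | "density_mix" | "hmix"
    components: list[str]
    mole_fractions: list[float]
    temperature_k: float
    pressure_kpa: float
    value: float  # g/mL for densities, kJ/mol for hmix
    uncertainty: float = 0.0
    elements: tuple[str, ...] = ()
    functional_groups: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("density", "density_mix", "hmix"):
            raise ValueError(f"unknown data kind {self.kind!r}")
        if abs(sum(self.mole_fractions) - 1.0) > 1e-6:
            raise ValueError("mole fractions must sum to 1")


class PropertyBackend(Protocol):
    """Contract for a property estimator (simulation or surrogate)."""

    def estimate(
        self, theta: np.ndarray, datapoints: Sequence[PropertyDataPoint]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (values, gradient d value/d θ with shape (n, dim), stderr)."""
        ...


# ---------------------------------------------------------------------------
# Parameter vectorization
# ---------------------------------------------------------------------------

_NEVER_OPTIMIZED_CLASSES = ("improper_torsion",)
_FROZEN_TORSION_KINDS = ("periodicity", "phase")


@dataclass
class ParameterVectorization:
    entries: list[tuple[str, str, str]]  # (class, parameter id, attribute)
    theta: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.entries)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        """Physical box constraints: nonnegative force constants and well
        depths, positive sizes, equilibrium angles within [0°, 180°]."""
        out = []
        for cls, _, attr in self.entries:
            kind = _attribute_kind(attr)
            if kind in ("k", "epsilon"):
                out.append((0.0, None))
            elif kind == "rmin_half":
                out.append((1e-3, None))
            elif kind == "angle":
                out.append((0.0, 180.0))
            elif kind == "length":
                out.append((0.05, None))
            else:
                out.append((None, None))
        return out

    def fd_steps(self, config: FitConfig) -> np.ndarray:
        return np.array(
            [config.fd_steps[(cls, _attribute_kind(attr))]
             for cls, _, attr in self.entries]
        )

    def apply(self, ff: ForceField, theta: np.ndarray) -> ForceField:
        """Inverse map: write θ back into a copy of the force field."""
        new = ff.copy()
        for (cls, pid, attr), val in zip(self.entries, theta):
            for p in new.parameters[cls]:
                if p.id == pid:
                    p.attributes[attr] = float(val)
                    break
        return new


def vectorize_parameters(
    ff: ForceField,
    eligibility_counts: dict[str, int],
    config: FitConfig | None = None,
    parameter_classes: Sequence[str] | None = None,
) -> ParameterVectorization:
    """Build θ from eligible, optimizable attributes.

    Includes attributes flagged ``optimize`` on parameters applied to at
    least ``eligibility_threshold`` molecules; excludes linear-angle θ0
    (equilibrium held at 180°), torsion periodicities/phases, and all
    improper-torsion attributes.
    """
    config = config or FitConfig()
    entries: list[tuple[str, str, str]] = []
    values: list[float] = []
    for cls, params in ff.parameters.items():
        if cls in _NEVER_OPTIMIZED_CLASSES:
            continue
        if parameter_classes is not None and cls not in parameter_classes:
            continue
        for p in params:
            if eligibility_counts.get(p.id, 0) < config.eligibility_threshold:
                continue
            linear_angle = (
                cls == "angle" and abs(p.attributes.get("angle", 0) - 180.0) < 1e-9
            )
            for attr in p.optimize:
                kind = _attribute_kind(attr)
                if cls == "proper_torsion" and kind in _FROZEN_TORSION_KINDS:
                    continue
                if linear_angle and kind == "angle":
                    continue
                entries.append((cls, p.id, attr))
                values.append(p.attributes[attr])
    if not entries:
        raise ValueError("nothing to optimize: empty parameter vector")
    return ParameterVectorization(entries, np.asarray(values, dtype=float))


def regularization_penalty(
    theta: np.ndarray,
    theta_start: np.ndarray,
    scheme: RegularizationScheme,
    entries: Sequence[tuple[str, str, str]],
) -> float:
    """w_reg · Σ_p (Δθ_p / σ_p)²."""
    theta = np.asarray(theta, dtype=float)
    theta_start = np.asarray(theta_start, dtype=float)
    if theta.shape != theta_start.shape or len(theta) != len(entries):
        raise ValueError("parameter vectors and entries must be aligned")
    sig = np.array([scheme.sigma_for(cls, attr) for cls, _, attr in entries])
    return float(scheme.w_reg * np.sum(((theta - theta_start) / sig) ** 2))


def _penalty_gradient(theta, theta_start, scheme, entries):
    sig = np.array([scheme.sigma_for(cls, attr) for cls, _, attr in entries])
    return scheme.w_reg * 2.0 * (theta - theta_start) / sig**2


# ---------------------------------------------------------------------------
# Valence objective
# ---------------------------------------------------------------------------


class TargetEvaluationError(RuntimeError):
    def __init__(self, target_name: str, cause: Exception):
        self.target_name = target_name
        super().__init__(f"target {target_name!r} failed: {cause}")


def evaluate_valence_data_term(
    targets: Sequence,
    ff: ForceField,
    config: FitConfig,
    scan_cache: dict | None = None,
) -> tuple[float, dict[str, float]]:
    """Σ_i w_i·L_i over opt-geo and torsion-profile targets.

    For each opt-geo target the molecule is re-minimized from the reference
    geometry under the current parameters; for each torsion-profile target a
    restrained scan re-runs with restraint references pinned to the stored
    per-point seeds.  ``scan_cache`` (keyed by target) carries the previous
    evaluation's optimized frames as warm starts — the minimized objective
    is unchanged, only the solver path shortens.
    """
    total = 0.0
    per_target: dict[str, float] = {}
    for idx, target in enumerate(targets):
        name = target.name or f"target-{idx}"
        try:
            assignment = assign_parameters(target.molecule, ff)
            if isinstance(target, OptGeoTarget):
                system = compile_system(target.molecule, ff, assignment)
                res = mm_minimize(system, target.reference_coords)
                loss, _ = optgeo_loss(target, res.coordinates)
                w = config.weight_optgeo if target.weight is None else target.weight
            elif isinstance(target, TorsionProfileTarget):
                warm = scan_cache.get(name) if scan_cache is not None else None
                scan = torsion_scan(
                    target.molecule, ff, assignment, target.dihedral,
                    grid_deg=target.grid_deg,
                    starting_conformers=target.starting_conformers,
                    warm_starts=warm,
                )
                if scan_cache is not None:
                    scan_cache[name] = list(scan.conformers)
                loss, _ = torsion_profile_loss(target, scan.energies)
                w = config.weight_torsion if target.weight is None else target.weight
            else:
                raise TypeError(f"unknown target type {type(target)!r}")
        except TargetEvaluationError:
            raise
        except Exception as exc:  # identify the failing target
            raise TargetEvaluationError(name, exc) from exc
        per_target[name] = w * loss
        total += w * loss
    return total, per_target


def total_valence_objective(
    targets: Sequence,
    ff: ForceField,
    theta: np.ndarray,
    theta_start: np.ndarray,
    vectorization: ParameterVectorization,
    scheme: RegularizationScheme,
    config: FitConfig,
    scan_cache: dict | None = None,
) -> dict:
    """One objective-decomposition row: data term, penalty, total."""
    ff_theta = vectorization.apply(ff, theta)
    data_term, per_target = evaluate_valence_data_term(
        targets, ff_theta, config, scan_cache=scan_cache)
    penalty = regularization_penalty(theta, theta_start, scheme,
                                     vectorization.entries)
    return {
        "data_term": data_term,
        "penalty": penalty,
        "total": data_term + penalty,
        "per_target": per_target,
    }


def make_valence_objective(
    targets: Sequence,
    ff: ForceField,
    vectorization: ParameterVectorization,
    scheme: RegularizationScheme,
    config: FitConfig,
) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """(value, gradient) callable; gradient by central finite differences
    with per-attribute-kind steps; evaluations memoized."""
    theta_start = vectorization.theta.copy()
    steps = vectorization.fd_steps(config)
    cache: dict[bytes, float] = {}

    def value(theta: np.ndarray) -> float:
        # scans run cold from their stored seeds: warm-starting from a
        # previous iterate's frames leaves a small hysteresis floor in the
        # objective once a line search has visited a different rotamer well
        key = np.asarray(theta, dtype=float).tobytes()
        if key not in cache:
            row = total_valence_objective(
                targets, ff, theta, theta_start, vectorization, scheme,
                config,
            )
            cache[key] = row["total"]
        return cache[key]

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        f0 = value(theta)
        grad = np.zeros_like(theta)
        for p in range(len(theta)):
            tp = theta.copy()
            tp[p] += steps[p]
            tm = theta.copy()
            tm[p] -= steps[p]
            grad[p] = (value(tp) - value(tm)) / (2.0 * steps[p])
        return f0, grad

    return fun


def evaluate_valence_residuals(
    targets: Sequence,
    ff: ForceField,
    config: FitConfig,
    scan_cache: dict | None = None,
) -> np.ndarray:
    """Residual vector whose sum of squares is the weighted data term.

    Opt-geo targets contribute sqrt(w/N)·Δx/d per internal coordinate,
    torsion-profile targets sqrt(w·w(E)/N)·ΔE/d_E per grid point — the same
    decomposition as :func:`evaluate_valence_data_term`, exposed per term so
    a least-squares trust-region optimizer can exploit the structure.
    """
    from smirkfit.fit_targets import torsion_weight

    residuals: list[np.ndarray] = []
    for idx, target in enumerate(targets):
        name = target.name or f"target-{idx}"
        try:
            assignment = assign_parameters(target.molecule, ff)
            if isinstance(target, OptGeoTarget):
                system = compile_system(target.molecule, ff, assignment)
                res = mm_minimize(system, target.reference_coords)
                _, contribs = optgeo_loss(target, res.coordinates)
                w = config.weight_optgeo if target.weight is None else target.weight
                n = len(contribs)
                vals = np.array([np.sqrt(c) for c in contribs.values()])
                residuals.append(np.sqrt(w / n) * vals)
            elif isinstance(target, TorsionProfileTarget):
                warm = scan_cache.get(name) if scan_cache is not None else None
                scan = torsion_scan(
                    target.molecule, ff, assignment, target.dihedral,
                    grid_deg=target.grid_deg,
                    starting_conformers=target.starting_conformers,
                    warm_starts=warm,
                )
                if scan_cache is not None:
                    scan_cache[name] = list(scan.conformers)
                mm_rel = scan.energies - scan.energies.min()
                qm_rel = target.qm_energies - target.qm_energies.min()
                wts = torsion_weight(qm_rel, target.weight_low,
                                     target.weight_high)
                w = config.weight_torsion if target.weight is None else target.weight
                n = len(qm_rel)
                residuals.append(
                    np.sqrt(w * wts / n) * (mm_rel - qm_rel) / target.d_e
                )
            else:
                raise TypeError(f"unknown target type {type(target)!r}")
        except TargetEvaluationError:
            raise
        except Exception as exc:
            raise TargetEvaluationError(name, exc) from exc
    return np.concatenate(residuals) if residuals else np.zeros(0)


def fit_valence_least_squares(
    targets: Sequence,
    ff: ForceField,
    vectorization: ParameterVectorization,
    scheme: RegularizationScheme,
    config: FitConfig,
    max_nfev: int | None = None,
) -> FitReport:
    """Trust-region least-squares valence refit on the residual vector.

    Unlike the generic quasi-Newton loop, the Gauss-Newton approximation
    resolves the weakly-curved (sloppy) parameter directions of geometry
    and profile data in few iterations.  Regularization enters as extra
    residuals sqrt(w_reg)·Δθ_p/σ_p.
    """
    theta_start = vectorization.theta.copy()
    sig = np.array([scheme.sigma_for(c, a)
                    for c, _, a in vectorization.entries])
    steps = vectorization.fd_steps(config)

    # scans run cold (from the stored seeds) on every evaluation: warm
    # starts introduce tiny path dependence that corrupts the trust-region
    # actual-vs-predicted reduction ratios
    def residuals(theta):
        ff_theta = vectorization.apply(ff, theta)
        data = evaluate_valence_residuals(targets, ff_theta, config)
        reg = np.sqrt(scheme.w_reg) * (theta - theta_start) / sig \
            if scheme.w_reg > 0 else np.zeros(0)
        return np.concatenate([data, reg])

    # unbounded: the reflective bounded variant of the trust-region solver
    # stalls in the sloppy directions of this problem.  A trial step into
    # unphysical territory (e.g. negative force constant) produces divergent
    # target minimizations, huge residuals, and a rejected step, so the
    # iterates stay physical without explicit boxes.
    theta0 = vectorization.theta.copy()
    result = _scipy_least_squares(
        residuals,
        theta0,
        jac="3-point",
        diff_step=steps / np.maximum(np.abs(theta0), 1e-8),
        max_nfev=max_nfev or config.max_iterations * (2 * len(theta0) + 2),
        xtol=1e-13, ftol=1e-13, gtol=1e-14,
    )
    total = float(2.0 * result.cost)  # scipy's cost is (1/2)Σr²
    grad_norm = float(np.linalg.norm(2.0 * result.jac.T @ result.fun))
    row = {
        "iteration": int(result.nfev),
        "total": total,
        "gradient_norm": grad_norm,
        "step_norm": 0.0 if result.status in (2, 3) else np.inf,
        "theta": np.asarray(result.x, dtype=float),
    }
    report = FitReport(seed=config.seed)
    report.iterations.append(row)
    report.final_theta = np.asarray(result.x, dtype=float)
    report.converged, report.criteria = check_convergence(row, config)
    report.converged = bool(report.converged or result.status > 0)
    return report


# ---------------------------------------------------------------------------
# LJ objective
# ---------------------------------------------------------------------------

D_RHO = 0.05  # g/mL
D_HMIX = 1.6  # kJ/mol


def lj_objective(
    datapoints: Sequence[PropertyDataPoint],
    backend: PropertyBackend,
    theta: np.ndarray,
    theta_start: np.ndarray,
    scheme: RegularizationScheme,
    entries: Sequence[tuple[str, str, str]],
    d_rho: float = D_RHO,
    d_hmix: float = D_HMIX,
) -> tuple[float, dict]:
    """Weighted least-squares LJ objective with analytic gradient.

    Pure and mixture densities are pooled into one block averaged over N_ρ
    with divisor d_ρ; enthalpies of mixing form a second block averaged over
    N_ΔHmix with divisor d_ΔHmix; plus the Gaussian-prior penalty.
    """
    theta = np.asarray(theta, dtype=float)
    values, grads, _ = backend.estimate(theta, datapoints)
    if len(values) != len(datapoints):
        missing = [dp.kind for dp in datapoints[len(values):]]
        raise ValueError(f"backend returned no estimate for points: {missing}")

    is_rho = np.array([dp.kind in ("density", "density_mix") for dp in datapoints])
    exp = np.array([dp.value for dp in datapoints])
    resid = values - exp

    decomposition = {"density": 0.0, "hmix": 0.0}
    grad = np.zeros_like(theta)
    n_rho = int(is_rho.sum())
    n_h = int((~is_rho).sum())
    if n_rho:
        r = resid[is_rho] / d_rho
        decomposition["density"] = float(np.sum(r**2) / n_rho)
        grad += 2.0 / n_rho * (r / d_rho) @ grads[is_rho]
    if n_h:
        r = resid[~is_rho] / d_hmix
        decomposition["hmix"] = float(np.sum(r**2) / n_h)
        grad += 2.0 / n_h * (r / d_hmix) @ grads[~is_rho]

    penalty = regularization_penalty(theta, theta_start, scheme, entries)
    grad += _penalty_gradient(theta, np.asarray(theta_start, float), scheme,
                              entries)
    total = decomposition["density"] + decomposition["hmix"] + penalty
    decomposition["penalty"] = penalty
    decomposition["total"] = total
    decomposition["gradient"] = grad
    return total, decomposition


# ---------------------------------------------------------------------------
# Optimization loop and convergence
# ---------------------------------------------------------------------------


def check_convergence(row: dict, config: FitConfig) -> tuple[bool, dict]:
    """Two-of-three rule on objective value, gradient norm, step size."""
    criteria = {
        "objective": row["total"] <= config.objective_threshold,
        "gradient": row["gradient_norm"] <= config.gradient_threshold,
        "step": row["step_norm"] <= config.step_threshold,
    }
    return sum(criteria.values()) >= 2, criteria


@dataclass
class FitReport:
    iterations: list[dict] = field(default_factory=list)
    final_theta: np.ndarray = None
    converged: bool = False
    criteria: dict = field(default_factory=dict)
    seed: int = 0
    aborted: bool = False
    abort_reason: str = ""

    def to_json(self) -> str:
        doc = {
            "converged": self.converged,
            "criteria": self.criteria,
            "seed": self.seed,
            "aborted": self.aborted,
            "abort_reason": self.abort_reason,
            "final_theta": [float(x) for x in np.atleast_1d(self.final_theta)],
            "iterations": [
                {
                    k: (v if not isinstance(v, np.ndarray) else v.tolist())
                    for k, v in row.items()
                }
                for row in self.iterations
            ],
        }
        return json.dumps(doc, indent=2)


def optimize(
    objective: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    config: FitConfig,
    bounds: Sequence[tuple] | None = None,
    max_iterations: int | None = None,
    scales: np.ndarray | None = None,
) -> FitReport:
    """Iterate L-BFGS-B until the two-of-three convergence test passes or the
    iteration budget is exhausted; records the full trajectory.

    The search runs in rescaled coordinates θ/σ_p when ``scales`` is given
    (the regularization scales double as natural parameter units, which
    keeps the quasi-Newton updates well conditioned across attribute kinds);
    recorded gradient and step norms refer to the rescaled coordinates.
    Each recorded iteration holds the objective value, parameter vector,
    gradient norm and step norm at the accepted iterate.
    """
    theta0 = np.asarray(theta0, dtype=float)
    if scales is None:
        scales = np.ones_like(theta0)
    scales = np.asarray(scales, dtype=float)
    max_iter = max_iterations or config.max_iterations
    report = FitReport(seed=config.seed)

    cache: dict[bytes, tuple[float, np.ndarray]] = {}

    def fun(scaled):
        key = scaled.tobytes()
        if key not in cache:
            try:
                f, g = objective(np.asarray(scaled, dtype=float) * scales)
                cache[key] = (f, np.asarray(g, dtype=float) * scales)
            except TargetEvaluationError as exc:
                report.aborted = True
                report.abort_reason = str(exc)
                raise StopIteration from exc
        return cache[key]

    if bounds is not None:
        bounds = [
            (lo / s if lo is not None else None,
             hi / s if hi is not None else None)
            for (lo, hi), s in zip(bounds, scales)
        ]
    theta0 = theta0 / scales
    prev = {"theta": theta0.copy()}

    f0, g0 = fun(theta0)
    report.iterations.append(
        {
            "iteration": 0,
            "total": f0,
            "gradient_norm": float(np.linalg.norm(g0)),
            "step_norm": np.inf,
            "theta": theta0 * scales,
        }
    )
    converged, criteria = check_convergence(
        {**report.iterations[-1], "step_norm": np.inf}, config
    )
    # the step criterion is meaningless before the first step; require the
    # other two both to pass for an immediate fixed-point exit
    if criteria["objective"] and criteria["gradient"]:
        report.final_theta = theta0 * scales
        report.converged = True
        report.criteria = criteria
        return report

    def callback(xk):
        theta = np.asarray(xk, dtype=float)
        f, g = fun(theta)
        step = float(np.linalg.norm(theta - prev["theta"]))
        prev["theta"] = theta.copy()
        row = {
            "iteration": len(report.iterations),
            "total": f,
            "gradient_norm": float(np.linalg.norm(g)),
            "step_norm": step,
            "theta": theta * scales,
        }
        report.iterations.append(row)
        done, crit = check_convergence(row, config)
        if done:
            report.converged = True
            report.criteria = crit
            raise StopIteration

    try:
        res = _scipy_minimize(
            lambda t: fun(t),
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            callback=callback,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12},
        )
        final = np.asarray(res.x, dtype=float) * scales
    except StopIteration:
        final = prev["theta"] * scales

    if report.aborted:
        report.final_theta = prev["theta"] * scales
        return report
    report.final_theta = report.iterations[-1]["theta"] \
        if report.converged else final
    if not report.converged and report.iterations:
        _, report.criteria = check_convergence(report.iterations[-1], config)
    return report


def fit_valence(
    targets: Sequence,
    ff: ForceField,
    eligibility_counts: dict[str, int],
    scheme: RegularizationScheme | None = None,
    config: FitConfig | None = None,
    method: str = "trust-region",
) -> tuple[ForceField, FitReport, ParameterVectorization]:
    """Full valence refit: vectorize, optimize, write parameters back.

    ``method`` selects the optimizer: "trust-region" (Gauss-Newton on the
    residual vector, the default — it resolves the sloppy force-constant
    directions of geometry/profile data) or "lbfgs" (the generic scalar
    quasi-Newton loop with the two-of-three convergence rule).
    """
    scheme = scheme or RegularizationScheme()
    config = config or FitConfig()
    vec = vectorize_parameters(
        ff, eligibility_counts, config,
        parameter_classes=("bond", "angle", "proper_torsion"),
    )
    if method == "trust-region":
        report = fit_valence_least_squares(targets, ff, vec, scheme, config)
    elif method == "lbfgs":
        objective = make_valence_objective(targets, ff, vec, scheme, config)
        scales = np.array([scheme.sigma_for(c, a)
                           for c, _, a in vec.entries])
        report = optimize(objective, vec.theta, config, bounds=vec.bounds(),
                          scales=scales)
    else:
        raise ValueError(f"unknown method {method!r}")
    fitted = vec.apply(ff, report.final_theta)
    return fitted, report, vec


def fit_lj(
    datapoints: Sequence[PropertyDataPoint],
    backend: PropertyBackend,
    ff: ForceField,
    eligible_type_ids: Sequence[str],
    scheme: RegularizationScheme | None = None,
    config: FitConfig | None = None,
) -> tuple[ForceField, FitReport, ParameterVectorization]:
    """LJ refit of the eligible vdW types against property data."""
    scheme = scheme or RegularizationScheme()
    config = config or FitConfig()
    counts = {pid: config.eligibility_threshold for pid in eligible_type_ids}
    vec = vectorize_parameters(ff, counts, config, parameter_classes=("vdw",))
    theta_start = vec.theta.copy()

    def objective(theta):
        total, dec = lj_objective(
            datapoints, backend, theta, theta_start, scheme, vec.entries
        )
        return total, dec["gradient"]

    scales = np.array([scheme.sigma_for(c, a) for c, _, a in vec.entries])
    report = optimize(
        objective, vec.theta, config, bounds=vec.bounds(),
        max_iterations=config.max_iterations_lj, scales=scales,
    )
    fitted = vec.apply(ff, report.final_theta)
    return fitted, report, vec
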