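"""Gas-phase classical potential energy, analytic gradients, minimization,
and restrained torsion scans.

Functional form (AMBER-family, SMIRNOFF harmonic convention):

* bond        (k/2)(r - r0)^2                      k in kcal/mol/Å², r0 Å
* angle       (k/2)(θ - θ0)^2                      k in kcal/mol/rad², θ0 deg
* torsion     Σ_n k_n (1 + cos(nφ - γ_n))          k in kcal/mol, γ deg
* improper    same form, one term per (center, sorted-neighbor) match
* vdW         12-6 from (R_min/2, ε), Lorentz–Berthelot combining
* Coulomb     all pairs with 1-2/1-3 exclusions and configurable 1-4 scaling

No cutoffs, no periodicity: every target in this package is gas phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from smirkfit import _kernels
from smirkfit.chem_model import (
    ForceField,
    Molecule,
    ParameterAssignment,
)
from smirkfit.constants import COULOMB_CONSTANT


@dataclass
class EnergyBreakdown:
    """Per-term potential energy in kcal/mol."""

    bond: float = 0.0
    angle: float = 0.0
    proper_torsion: float = 0.0
    improper_torsion: float = 0.0
    vdw: float = 0.0
    electrostatic: float = 0.0
    restraint: float = 0.0

    @property
    def total_without_restraint(self) -> float:
        return (
            self.bond
            + self.angle
            + self.proper_torsion
            + self.improper_torsion
            + self.vdw
            + self.electrostatic
        )

    @property
    def total(self) -> float:
        return self.total_without_restraint + self.restraint


@dataclass
class PositionRestraint:
    """Harmonic positional restraint (k/2)|x - x_ref|² on selected atoms."""

    atom_indices: Sequence[int]
    reference: np.ndarray  # (n_sel, 3)
    k: float = 1.0  # kcal/mol/Å²


@dataclass
class DihedralRestraint:
    """Stiff harmonic dihedral restraint (k/2)Δφ² driving a torsion angle."""

    atoms: tuple[int, int, int, int]
    target_deg: float
    k: float = 1000.0  # kcal/mol/rad²


@dataclass
class ScanResult:
    """Restrained torsion-scan profile, restraint-excluded, min-referenced."""

    grid_deg: np.ndarray
    energies: np.ndarray  # kcal/mol, min exactly 0
    conformers: list[np.ndarray]
    converged: np.ndarray  # bool per point
    dihedral: tuple[int, int, int, int] = (0, 1, 2, 3)
    seeds: list[np.ndarray] | None = None  # per-point starting coordinates

    def to_json(self) -> str:
        return json.dumps(
            {
                "dihedral": list(self.dihedral),
                "grid_deg": [float(x) for x in self.grid_deg],
                "energies": [float(x) for x in self.energies],
                "converged": [bool(x) for x in self.converged],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Compiled system
# ---------------------------------------------------------------------------


@dataclass
class CompiledSystem:
    """Parameter arrays gathered from a (molecule, force field, assignment)."""

    n_atoms: int
    bond_idx: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angle_idx: np.ndarray
    angle_k: np.ndarray
    angle_theta0: np.ndarray  # radians
    torsion_idx: np.ndarray  # one row per Fourier term
    torsion_k: np.ndarray
    torsion_n: np.ndarray
    torsion_phase: np.ndarray  # radians
    improper_idx: np.ndarray
    improper_k: np.ndarray
    improper_n: np.ndarray
    improper_phase: np.ndarray
    pair_idx: np.ndarray  # nonbonded pairs (i, j)
    pair_rmin: np.ndarray
    pair_eps: np.ndarray
    pair_qq: np.ndarray  # scaled q_i q_j * COULOMB (0 if no charges)
    has_charges: bool = True


def _exclusion_maps(mol: Molecule):
    nbrs = mol.neighbors()
    set12 = {(min(i, j), max(i, j)) for i, j, _ in mol.bonds}
    set13 = set()
    for j in range(mol.n_atoms):
        ns = nbrs[j]
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                i, k = sorted((ns[a], ns[b]))
                set13.add((i, k))
    set14 = set()
    for t in mol.proper_torsion_tuples():
        i, l = sorted((t[0], t[3]))
        set14.add((i, l))
    set13 -= set12
    set14 -= set12 | set13
    return set12, set13, set14


def compile_system(
    mol: Molecule,
    ff: ForceField,
    assignment: ParameterAssignment,
    include_electrostatics: bool | None = None,
) -> CompiledSystem:
    """Gather per-tuple parameters into flat arrays once per (mol, ff)."""
    param = {p.id: p for cls in ff.parameters.values() for p in cls}

    b_idx, b_k, b_r0 = [], [], []
    for key, pid in sorted(assignment.bond.items()):
        p = param[pid]
        b_idx.append(key)
        b_k.append(p.attributes["k"])
        b_r0.append(p.attributes["length"])

    a_idx, a_k, a_t0 = [], [], []
    for key, pid in sorted(assignment.angle.items()):
        p = param[pid]
        a_idx.append(key)
        a_k.append(p.attributes["k"])
        a_t0.append(np.deg2rad(p.attributes["angle"]))

    t_idx, t_k, t_n, t_ph = [], [], [], []
    for key, pid in sorted(assignment.proper_torsion.items()):
        for k_val, n_val, phase in param[pid].torsion_terms():
            t_idx.append(key)
            t_k.append(k_val)
            t_n.append(n_val)
            t_ph.append(np.deg2rad(phase))

    i_idx, i_k, i_n, i_ph = [], [], [], []
    for key, pid in sorted(assignment.improper_torsion.items()):
        for k_val, n_val, phase in param[pid].torsion_terms():
            i_idx.append(key)  # (n1, center, n2, n3) — dihedral on that order
            i_k.append(k_val)
            i_n.append(n_val)
            i_ph.append(np.deg2rad(phase))

    rmin_half = np.zeros(mol.n_atoms)
    eps = np.zeros(mol.n_atoms)
    for (i,), pid in assignment.vdw.items():
        p = param[pid]
        rmin_half[i] = p.attributes["rmin_half"]
        eps[i] = p.attributes["epsilon"]

    if include_electrostatics is None:
        include_electrostatics = mol.partial_charges is not None
    if include_electrostatics and mol.partial_charges is None:
        raise ValueError("electrostatics requested but molecule has no charges")
    charges = (
        mol.partial_charges if include_electrostatics else np.zeros(mol.n_atoms)
    )

    set12, set13, set14 = _exclusion_maps(mol)
    p_idx, p_rmin, p_eps, p_qq = [], [], [], []
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            key = (i, j)
            if key in set12 or key in set13:
                continue
            s_vdw = ff.scale_vdw_14 if key in set14 else 1.0
            s_ele = ff.scale_elec_14 if key in set14 else 1.0
            p_idx.append(key)
            p_rmin.append(rmin_half[i] + rmin_half[j])  # Lorentz
            p_eps.append(s_vdw * np.sqrt(eps[i] * eps[j]))  # Berthelot
            p_qq.append(s_ele * COULOMB_CONSTANT * charges[i] * charges[j])

    return CompiledSystem(
        n_atoms=mol.n_atoms,
        bond_idx=np.asarray(b_idx, dtype=int).reshape(-1, 2),
        bond_k=np.asarray(b_k, dtype=float),
        bond_r0=np.asarray(b_r0, dtype=float),
        angle_idx=np.asarray(a_idx, dtype=int).reshape(-1, 3),
        angle_k=np.asarray(a_k, dtype=float),
        angle_theta0=np.asarray(a_t0, dtype=float),
        torsion_idx=np.asarray(t_idx, dtype=int).reshape(-1, 4),
        torsion_k=np.asarray(t_k, dtype=float),
        torsion_n=np.asarray(t_n, dtype=int),
        torsion_phase=np.asarray(t_ph, dtype=float),
        improper_idx=np.asarray(i_idx, dtype=int).reshape(-1, 4),
        improper_k=np.asarray(i_k, dtype=float),
        improper_n=np.asarray(i_n, dtype=int),
        improper_phase=np.asarray(i_ph, dtype=float),
        pair_idx=np.asarray(p_idx, dtype=int).reshape(-1, 2),
        pair_rmin=np.asarray(p_rmin, dtype=float),
        pair_eps=np.asarray(p_eps, dtype=float),
        pair_qq=np.asarray(p_qq, dtype=float),
        has_charges=bool(include_electrostatics),
    )


# ---------------------------------------------------------------------------
# Geometry kernels (value + per-atom derivative of the coordinate)
# ---------------------------------------------------------------------------


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-handling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def dihedral_angle(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed dihedral angles (radians) for rows of 4-atom indices."""
    idx = np.atleast_2d(idx)
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", _cross(n1, n2), b2) / np.where(b2n > 0, b2n, 1.0)
    return np.arctan2(y, x)


def _dihedral_gradients(coords, idx):
    """dφ/dr for each of the four atoms; shapes (M, 3) each."""
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    safe1 = np.where(n1sq > 1e-18, n1sq, 1.0)
    safe2 = np.where(n2sq > 1e-18, n2sq, 1.0)
    g1 = -(b2n / safe1)[:, None] * n1
    g4 = (b2n / safe2)[:, None] * n2
    d12 = np.einsum("ij,ij->i", b1, b2) / np.where(b2n > 0, b2n**2, 1.0)
    d32 = np.einsum("ij,ij->i", b3, b2) / np.where(b2n > 0, b2n**2, 1.0)
    g2 = -(1.0 + d12)[:, None] * g1 + d32[:, None] * g4
    g3 = d12[:, None] * g1 - (1.0 + d32)[:, None] * g4
    return g1, g2, g3, g4


def _accumulate_torsion(coords, grad, idx, k, n, phase):
    """Energy Σ k(1 + cos(nφ - γ)) and its gradient accumulation."""
    if len(idx) == 0:
        return 0.0
    phi = dihedral_angle(coords, idx)
    energy = float(np.sum(k * (1.0 + np.cos(n * phi - phase))))
    if grad is not None:
        dE = -k * n * np.sin(n * phi - phase)
        g1, g2, g3, g4 = _dihedral_gradients(coords, idx)
        for col, g in zip(range(4), (g1, g2, g3, g4)):
            np.add.at(grad, idx[:, col], dE[:, None] * g)
    return energy


def energy_and_gradient(
    coords: np.ndarray,
    system: CompiledSystem,
    restraints: Sequence | None = None,
    with_gradient: bool = True,
):
    """Return (EnergyBreakdown, gradient (N,3) or None).

    Dispatches to the compiled scalar-loop kernel when available (the
    systems are far too small for vectorized numpy to amortize its
    overhead); the numpy implementation below is the reference path and
    handles any restraint combination."""
    coords = np.asarray(coords, dtype=float).reshape(system.n_atoms, 3)
    if _kernels.HAVE_NUMBA:
        packed = _pack_restraints(system, restraints)
        if packed is not None:
            grad = np.zeros_like(coords)
            terms = _kernels.energy_gradient_core(
                coords,
                system.bond_idx, system.bond_k, system.bond_r0,
                system.angle_idx, system.angle_k, system.angle_theta0,
                system.torsion_idx, system.torsion_k,
                system.torsion_n.astype(np.float64), system.torsion_phase,
                system.improper_idx, system.improper_k,
                system.improper_n.astype(np.float64), system.improper_phase,
                system.pair_idx, system.pair_rmin, system.pair_eps,
                system.pair_qq,
                *packed,
                grad,
            )
            br = EnergyBreakdown(*[float(t) for t in terms])
            return br, (grad if with_gradient else None)
    grad = np.zeros_like(coords) if with_gradient else None
    br = EnergyBreakdown()

    # bonds
    if len(system.bond_idx):
        vec = coords[system.bond_idx[:, 1]] - coords[system.bond_idx[:, 0]]
        r = np.linalg.norm(vec, axis=1)
        dr = r - system.bond_r0
        br.bond = float(np.sum(0.5 * system.bond_k * dr**2))
        if with_gradient:
            with np.errstate(invalid="ignore"):
                unit = vec / np.where(r > 0, r, 1.0)[:, None]
            f = (system.bond_k * dr)[:, None] * unit
            np.add.at(grad, system.bond_idx[:, 1], f)
            np.add.at(grad, system.bond_idx[:, 0], -f)

    # angles
    if len(system.angle_idx):
        i, j, k = (system.angle_idx[:, c] for c in range(3))
        rij = coords[i] - coords[j]
        rkj = coords[k] - coords[j]
        nij = np.linalg.norm(rij, axis=1)
        nkj = np.linalg.norm(rkj, axis=1)
        cos_t = np.einsum("ij,ij->i", rij, rkj) / (nij * nkj)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        theta = np.arccos(cos_t)
        dt = theta - system.angle_theta0
        br.angle = float(np.sum(0.5 * system.angle_k * dt**2))
        if with_gradient:
            sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-16))
            uij = rij / nij[:, None]
            ukj = rkj / nkj[:, None]
            dti = (cos_t[:, None] * uij - ukj) / (nij * sin_t)[:, None]
            dtk = (cos_t[:, None] * ukj - uij) / (nkj * sin_t)[:, None]
            dE = (system.angle_k * dt)[:, None]
            np.add.at(grad, i, dE * dti)
            np.add.at(grad, k, dE * dtk)
            np.add.at(grad, j, -dE * (dti + dtk))

    br.proper_torsion = _accumulate_torsion(
        coords, grad, system.torsion_idx, system.torsion_k,
        system.torsion_n, system.torsion_phase,
    )
    br.improper_torsion = _accumulate_torsion(
        coords, grad, system.improper_idx, system.improper_k,
        system.improper_n, system.improper_phase,
    )

    # nonbonded
    if len(system.pair_idx):
        i, j = system.pair_idx[:, 0], system.pair_idx[:, 1]
        vec = coords[j] - coords[i]
        r = np.linalg.norm(vec, axis=1)
        inv_r = 1.0 / r
        x6 = (system.pair_rmin * inv_r) ** 6
        br.vdw = float(np.sum(system.pair_eps * (x6**2 - 2.0 * x6)))
        br.electrostatic = float(np.sum(system.pair_qq * inv_r))
        if with_gradient:
            # dE/dr for LJ: eps * (-12 x^12 + 12 x^6)/r ; Coulomb: -qq/r^2
            dE_dr = (
                system.pair_eps * (-12.0 * x6**2 + 12.0 * x6) * inv_r
                - system.pair_qq * inv_r**2
            )
            f = (dE_dr * inv_r)[:, None] * vec
            np.add.at(grad, j, f)
            np.add.at(grad, i, -f)

    # restraints
    if restraints:
        for res in restraints:
            if isinstance(res, PositionRestraint):
                sel = np.asarray(res.atom_indices, dtype=int)
                disp = coords[sel] - res.reference
                br.restraint += float(0.5 * res.k * np.sum(disp**2))
                if with_gradient:
                    np.add.at(grad, sel, res.k * disp)
            elif isinstance(res, DihedralRestraint):
                idx = np.asarray([res.atoms], dtype=int)
                phi = dihedral_angle(coords, idx)[0]
                dphi = _wrap_angle(phi - np.deg2rad(res.target_deg))
                br.restraint += float(0.5 * res.k * dphi**2)
                if with_gradient:
                    g1, g2, g3, g4 = _dihedral_gradients(coords, idx)
                    dE = res.k * dphi
                    for col, g in zip(res.atoms, (g1, g2, g3, g4)):
                        grad[col] += dE * g[0]
            else:
                raise TypeError(f"unknown restraint {type(res)!r}")

    return br, grad


def _wrap_angle(x: float | np.ndarray):
    """Wrap radians to (-π, π]."""
    return -((-np.asarray(x) + np.pi) % (2 * np.pi) - np.pi)


_NO_DIHEDRAL = np.array([-1, -1, -1, -1], dtype=np.int64)


def _pack_restraints(system: CompiledSystem, restraints: Sequence | None):
    """Flatten restraints for the compiled kernel; None if unsupported."""
    pos_idx: list[int] = []
    pos_ref: list[np.ndarray] = []
    pos_k: list[float] = []
    dih = None
    for res in restraints or ():
        if isinstance(res, PositionRestraint):
            sel = np.asarray(res.atom_indices, dtype=np.int64)
            pos_idx.extend(sel.tolist())
            pos_ref.extend(np.asarray(res.reference, dtype=float))
            pos_k.extend([float(res.k)] * len(sel))
        elif isinstance(res, DihedralRestraint):
            if dih is not None:
                return None  # kernel supports a single driven dihedral
            dih = (
                np.asarray(res.atoms, dtype=np.int64),
                float(np.deg2rad(res.target_deg)),
                float(res.k),
            )
        else:
            return None
    if dih is None:
        dih = (_NO_DIHEDRAL, 0.0, 0.0)
    return (
        np.asarray(pos_idx, dtype=np.int64),
        np.asarray(pos_ref, dtype=float).reshape(len(pos_idx), 3),
        np.asarray(pos_k, dtype=float),
        dih[0], dih[1], dih[2],
    )


# ---------------------------------------------------------------------------
# Public energy / gradient on molecules
# ---------------------------------------------------------------------------


def potential_energy(
    mol: Molecule,
    conformer_index: int,
    ff: ForceField,
    assignment: ParameterAssignment,
    include_electrostatics: bool | None = None,
) -> EnergyBreakdown:
    system = compile_system(mol, ff, assignment, include_electrostatics)
    br, _ = energy_and_gradient(
        mol.conformers[conformer_index], system, with_gradient=False
    )
    return br


def gradient(
    mol: Molecule,
    conformer_index: int,
    ff: ForceField,
    assignment: ParameterAssignment,
    include_electrostatics: bool | None = None,
) -> np.ndarray:
    system = compile_system(mol, ff, assignment, include_electrostatics)
    _, g = energy_and_gradient(mol.conformers[conformer_index], system)
    return g


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------


@dataclass
class MinimizationResult:
    coordinates: np.ndarray
    breakdown: EnergyBreakdown  # restraint term separated
    converged: bool
    n_iterations: int
    gradient_rms: float


def minimize(
    mol_or_system,
    conformer,
    ff: ForceField | None = None,
    assignment: ParameterAssignment | None = None,
    frozen_atoms: Sequence[int] = (),
    restraints: Sequence | None = None,
    gtol_rms: float = 1e-6,
    max_steps: int = 2000,
    ftol: float = 1e-12,
) -> MinimizationResult:
    """L-BFGS minimization of the potential (plus restraints).

    Accepts either a Molecule (with ff + assignment) or a pre-compiled
    :class:`CompiledSystem`; ``conformer`` is a conformer index for the former
    and an (N, 3) array for the latter.  Frozen atoms do not move.  Returns a
    flagged (never raised) non-convergence.
    """
    if isinstance(mol_or_system, CompiledSystem):
        system = mol_or_system
        x0 = np.asarray(conformer, dtype=float).copy()
    else:
        system = compile_system(mol_or_system, ff, assignment)
        x0 = np.asarray(mol_or_system.conformers[conformer], dtype=float).copy()

    frozen = np.zeros(system.n_atoms, dtype=bool)
    if len(frozen_atoms):
        frozen[np.asarray(list(frozen_atoms), dtype=int)] = True
    free = ~frozen
    n_free = int(free.sum())

    if n_free == 0:
        br, _ = energy_and_gradient(x0, system, restraints)
        return MinimizationResult(x0, br, True, 0, 0.0)

    coords = x0.copy()

    def fun(x_free):
        coords[free] = x_free.reshape(n_free, 3)
        br, g = energy_and_gradient(coords, system, restraints)
        return br.total, g[free].ravel()

    res = _scipy_minimize(
        fun,
        x0[free].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "ftol": ftol, "gtol": 1e-10},
    )
    coords[free] = res.x.reshape(n_free, 3)
    br, g = energy_and_gradient(coords, system, restraints)
    grms = float(np.sqrt(np.mean(g[free] ** 2)))
    return MinimizationResult(
        coords.copy(), br, bool(res.success or grms <= gtol_rms),
        int(res.nit), grms,
    )


# ---------------------------------------------------------------------------
# Torsion grids and scans
# ---------------------------------------------------------------------------


def make_torsion_grid(
    spacing_deg: float = 15.0, range_deg: tuple[float, float] = (-180.0, 180.0)
) -> np.ndarray:
    """Half-open grid [lo, hi) at the given spacing; default 15° → 24 points."""
    lo, hi = range_deg
    width = hi - lo
    n, rem = divmod(width, spacing_deg)
    if abs(rem) > 1e-9 and abs(rem - spacing_deg) > 1e-9:
        raise ValueError(
            f"spacing {spacing_deg}° does not divide range width {width}°"
        )
    return lo + spacing_deg * np.arange(int(round(width / spacing_deg)))


def torsion_scan(
    mol: Molecule,
    ff: ForceField,
    assignment: ParameterAssignment,
    dihedral: tuple[int, int, int, int],
    grid_deg: np.ndarray | None = None,
    restraint_k: float = 1.0,
    drive_k: float = 1000.0,
    energy_cutoff: float | None = None,
    conformer_index: int = 0,
    starting_conformers: Sequence[np.ndarray] | None = None,
    warm_starts: Sequence[np.ndarray] | None = None,
) -> ScanResult:
    """Restrained torsion scan.

    At each grid angle the dihedral is driven there with a stiff harmonic
    dihedral restraint, all atoms outside the torsion carry harmonic
    positional restraints (default k = 1 kcal/mol/Å²), and after driving the
    four torsion atoms are frozen in place for a final relaxation.  Reported
    energies exclude all restraint contributions and are referenced to the
    grid minimum.  Points above ``energy_cutoff`` (kcal/mol, relative) are
    dropped — the in-ring scan convention uses 0.05 hartree ≈ 31.4 kcal/mol.

    ``starting_conformers`` pins the per-point seeds (and hence the
    positional-restraint reference geometries), making repeated scans under
    changing parameters evaluate a fixed, reproducible objective;
    ``warm_starts`` optionally supplies better initial coordinates for the
    driven minimization without touching the restraint references.
    """
    i, j, k, l = dihedral
    bonded = {(min(a, b), max(a, b)) for a, b, _ in mol.bonds}
    for a, b in ((i, j), (j, k), (k, l)):
        if (min(a, b), max(a, b)) not in bonded:
            raise ValueError(f"dihedral atoms {dihedral} are not bonded i–j–k–l")
    if grid_deg is None:
        grid_deg = make_torsion_grid()
    grid_deg = np.asarray(grid_deg, dtype=float)

    system = compile_system(mol, ff, assignment)
    torsion_atoms = list(dihedral)
    other_atoms = [a for a in range(mol.n_atoms) if a not in torsion_atoms]

    start = np.asarray(mol.conformers[conformer_index], dtype=float)
    # scan order: start from the grid point nearest the input dihedral and
    # sweep outward, seeding each point from its optimized neighbor
    phi0 = np.rad2deg(dihedral_angle(start, np.asarray([dihedral]))[0])
    nearest = int(np.argmin(np.abs(_wrap_deg(grid_deg - phi0))))
    order = sorted(range(len(grid_deg)),
                   key=lambda idx: (abs(idx - nearest), idx))

    coords_out: list[np.ndarray | None] = [None] * len(grid_deg)
    seeds_out: list[np.ndarray | None] = [None] * len(grid_deg)
    energies = np.full(len(grid_deg), np.nan)
    converged = np.zeros(len(grid_deg), dtype=bool)

    for pos, idx in enumerate(order):
        target = float(grid_deg[idx])
        if starting_conformers is not None:
            seed = np.asarray(starting_conformers[idx], dtype=float)
        elif pos == 0:
            seed = start
        else:
            # nearest already-optimized neighbor
            done = [x for x in order[:pos] if coords_out[x] is not None]
            seed = coords_out[min(done, key=lambda x: abs(x - idx))]

        seeds_out[idx] = seed.copy()
        restraints = [
            DihedralRestraint(tuple(dihedral), target, k=drive_k),
        ]
        if other_atoms:
            restraints.append(
                PositionRestraint(other_atoms, seed[other_atoms], k=restraint_k)
            )
        start_coords = (
            np.asarray(warm_starts[idx], dtype=float)
            if warm_starts is not None and warm_starts[idx] is not None
            else seed
        )
        stage1 = minimize(system, start_coords, restraints=restraints)

        # snap the residual driving error to zero: rigidly rotate the
        # l-side subtree about the j-k axis onto the exact grid angle
        driven = stage1.coordinates.copy()
        phi1 = np.rad2deg(dihedral_angle(driven, np.asarray([dihedral]))[0])
        residual = float(_wrap_deg(phi1 - target))
        if abs(residual) > 1e-12:
            subtree = _side_subtree(mol, j, k)
            axis = driven[k] - driven[j]
            driven[subtree] = _rotate_points(
                driven[subtree], driven[k], axis, -np.deg2rad(residual)
            )
        stage1.coordinates = driven

        # stage 2: Cartesian-freeze the four torsion atoms after driving
        res2_restraints = []
        if other_atoms:
            res2_restraints.append(
                PositionRestraint(
                    other_atoms, stage1.coordinates[other_atoms], k=restraint_k
                )
            )
        stage2 = minimize(
            system,
            stage1.coordinates,
            frozen_atoms=torsion_atoms,
            restraints=res2_restraints,
        )
        final = stage2.coordinates
        phi = np.rad2deg(dihedral_angle(final, np.asarray([dihedral]))[0])
        ok = abs(float(_wrap_deg(phi - target))) < 0.1
        br, _ = energy_and_gradient(final, system, with_gradient=False)
        coords_out[idx] = final
        energies[idx] = br.total_without_restraint  # restraint-excluded
        converged[idx] = ok and stage1.converged and stage2.converged

    energies = energies - np.nanmin(energies)
    keep = np.ones(len(grid_deg), dtype=bool)
    if energy_cutoff is not None:
        keep = energies <= energy_cutoff
    grid_kept = grid_deg[keep]
    e_kept = energies[keep]
    e_kept = e_kept - e_kept.min()
    return ScanResult(
        grid_deg=grid_kept,
        energies=e_kept,
        conformers=[coords_out[idx] for idx in np.where(keep)[0]],
        converged=converged[keep],
        dihedral=tuple(dihedral),
        seeds=[seeds_out[idx] for idx in np.where(keep)[0]],
    )


def _wrap_deg(x):
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


def _side_subtree(mol: Molecule, j: int, k: int) -> list[int]:
    """Atoms reachable from k without passing through j (k excluded)."""
    nbrs = mol.neighbors()
    seen = {j, k}
    stack = [x for x in nbrs[k] if x != j]
    out = []
    while stack:
        a = stack.pop()
        if a in seen:
            continue
        seen.add(a)
        out.append(a)
        stack.extend(x for x in nbrs[a] if x not in seen)
    return sorted(out)


def _rotate_points(points, origin, axis, angle_rad):
    """Rodrigues rotation of points about an axis through origin."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    p = np.asarray(points, dtype=float) - origin
    cos_a, sin_a = np.cos(angle_rad), np.sin(angle_rad)
    rotated = (
        p * cos_a
        + np.cross(u, p) * sin_a
        + np.outer(p @ u, u) * (1.0 - cos_a)
    )
    return rotated + origin
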