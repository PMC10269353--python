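"""Numba-compiled energy/gradient kernel.

The gas-phase systems here are tiny (tens of atoms), so the numpy
vectorized path is dominated by per-call overhead; minimizations and
restrained scans call the potential tens of thousands of times during a
fit.  This module provides a fused scalar-loop kernel for the same
functional form.  ``HAVE_NUMBA`` gates dispatch; the numpy implementation
in :mod:`smirkfit.mm_engine` remains the reference and the fallback.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def energy_gradient_core(
    coords,
    bond_idx, bond_k, bond_r0,
    angle_idx, angle_k, angle_theta0,
    torsion_idx, torsion_k, torsion_n, torsion_phase,
    improper_idx, improper_k, improper_n, improper_phase,
    pair_idx, pair_rmin, pair_eps, pair_qq,
    pos_idx, pos_ref, pos_k,
    dih_atoms, dih_target, dih_k,
    grad,
):
    """Return (bond, angle, proper, improper, vdw, elec, restraint) energies
    and accumulate the gradient in-place."""
    e_bond = 0.0
    for m in range(bond_idx.shape[0]):
        i, j = bond_idx[m, 0], bond_idx[m, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[m]
        e_bond += 0.5 * bond_k[m] * dr * dr
        if r > 0.0:
            f = bond_k[m] * dr / r
            grad[j, 0] += f * dx
            grad[j, 1] += f * dy
            grad[j, 2] += f * dz
            grad[i, 0] -= f * dx
            grad[i, 1] -= f * dy
            grad[i, 2] -= f * dz

    e_angle = 0.0
    for m in range(angle_idx.shape[0]):
        i, j, k = angle_idx[m, 0], angle_idx[m, 1], angle_idx[m, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cos_t = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
        theta = np.arccos(cos_t)
        dt = theta - angle_theta0[m]
        e_angle += 0.5 * angle_k[m] * dt * dt
        sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-16))
        dE = angle_k[m] * dt
        cu = 1.0 / (nu * sin_t)
        cv = 1.0 / (nv * sin_t)
        gix = cu * (cos_t * ux / nu - vx / nv)
        giy = cu * (cos_t * uy / nu - vy / nv)
        giz = cu * (cos_t * uz / nu - vz / nv)
        gkx = cv * (cos_t * vx / nv - ux / nu)
        gky = cv * (cos_t * vy / nv - uy / nu)
        gkz = cv * (cos_t * vz / nv - uz / nu)
        grad[i, 0] += dE * gix
        grad[i, 1] += dE * giy
        grad[i, 2] += dE * giz
        grad[k, 0] += dE * gkx
        grad[k, 1] += dE * gky
        grad[k, 2] += dE * gkz
        grad[j, 0] -= dE * (gix + gkx)
        grad[j, 1] -= dE * (giy + gky)
        grad[j, 2] -= dE * (giz + gkz)

    e_proper = _torsion_block(coords, torsion_idx, torsion_k, torsion_n,
                              torsion_phase, grad)
    e_improper = _torsion_block(coords, improper_idx, improper_k,
                                improper_n, improper_phase, grad)

    e_vdw = 0.0
    e_elec = 0.0
    for m in range(pair_idx.shape[0]):
        i, j = pair_idx[m, 0], pair_idx[m, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        x2 = pair_rmin[m] * pair_rmin[m] / r2
        x6 = x2 * x2 * x2
        e_vdw += pair_eps[m] * (x6 * x6 - 2.0 * x6)
        e_elec += pair_qq[m] * inv_r
        dE_dr = (pair_eps[m] * (-12.0 * x6 * x6 + 12.0 * x6) * inv_r
                 - pair_qq[m] * inv_r * inv_r)
        f = dE_dr * inv_r
        grad[j, 0] += f * dx
        grad[j, 1] += f * dy
        grad[j, 2] += f * dz
        grad[i, 0] -= f * dx
        grad[i, 1] -= f * dy
        grad[i, 2] -= f * dz

    e_res = 0.0
    for m in range(pos_idx.shape[0]):
        i = pos_idx[m]
        km = pos_k[m]
        dx = coords[i, 0] - pos_ref[m, 0]
        dy = coords[i, 1] - pos_ref[m, 1]
        dz = coords[i, 2] - pos_ref[m, 2]
        e_res += 0.5 * km * (dx * dx + dy * dy + dz * dz)
        grad[i, 0] += km * dx
        grad[i, 1] += km * dy
        grad[i, 2] += km * dz

    if dih_atoms[0] >= 0:
        e_res += _dihedral_restraint(coords, dih_atoms, dih_target, dih_k,
                                     grad)

    return e_bond, e_angle, e_proper, e_improper, e_vdw, e_elec, e_res


@njit(cache=True)
def _dihedral_terms(coords, i, j, k, l):
    """phi plus dphi/dr for the four atoms (flattened 12-vector)."""
    b1x = coords[j, 0] - coords[i, 0]
    b1y = coords[j, 1] - coords[i, 1]
    b1z = coords[j, 2] - coords[i, 2]
    b2x = coords[k, 0] - coords[j, 0]
    b2y = coords[k, 1] - coords[j, 1]
    b2z = coords[k, 2] - coords[j, 2]
    b3x = coords[l, 0] - coords[k, 0]
    b3y = coords[l, 1] - coords[k, 1]
    b3z = coords[l, 2] - coords[k, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    cx = n1y * n2z - n1z * n2y
    cy = n1z * n2x - n1x * n2z
    cz = n1x * n2y - n1y * n2x
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = (cx * b2x + cy * b2y + cz * b2z) / (b2n if b2n > 0 else 1.0)
    phi = np.arctan2(y, x)
    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z
    if n1sq < 1e-18:
        n1sq = 1.0
    if n2sq < 1e-18:
        n2sq = 1.0
    g1x = -b2n / n1sq * n1x
    g1y = -b2n / n1sq * n1y
    g1z = -b2n / n1sq * n1z
    g4x = b2n / n2sq * n2x
    g4y = b2n / n2sq * n2y
    g4z = b2n / n2sq * n2z
    b2sq = b2n * b2n if b2n > 0 else 1.0
    d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
    d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
    g2x = -(1.0 + d12) * g1x + d32 * g4x
    g2y = -(1.0 + d12) * g1y + d32 * g4y
    g2z = -(1.0 + d12) * g1z + d32 * g4z
    g3x = d12 * g1x - (1.0 + d32) * g4x
    g3y = d12 * g1y - (1.0 + d32) * g4y
    g3z = d12 * g1z - (1.0 + d32) * g4z
    out = np.empty(13)
    out[0] = phi
    out[1] = g1x; out[2] = g1y; out[3] = g1z
    out[4] = g2x; out[5] = g2y; out[6] = g2z
    out[7] = g3x; out[8] = g3y; out[9] = g3z
    out[10] = g4x; out[11] = g4y; out[12] = g4z
    return out


@njit(cache=True)
def _torsion_block(coords, idx, ks, ns, phases, grad):
    energy = 0.0
    for m in range(idx.shape[0]):
        i, j, k, l = idx[m, 0], idx[m, 1], idx[m, 2], idx[m, 3]
        t = _dihedral_terms(coords, i, j, k, l)
        phi = t[0]
        arg = ns[m] * phi - phases[m]
        energy += ks[m] * (1.0 + np.cos(arg))
        dE = -ks[m] * ns[m] * np.sin(arg)
        grad[i, 0] += dE * t[1]
        grad[i, 1] += dE * t[2]
        grad[i, 2] += dE * t[3]
        grad[j, 0] += dE * t[4]
        grad[j, 1] += dE * t[5]
        grad[j, 2] += dE * t[6]
        grad[k, 0] += dE * t[7]
        grad[k, 1] += dE * t[8]
        grad[k, 2] += dE * t[9]
        grad[l, 0] += dE * t[10]
        grad[l, 1] += dE * t[11]
        grad[l, 2] += dE * t[12]
    return energy


@njit(cache=True)
def _dihedral_restraint(coords, atoms, target, k_res, grad):
    t = _dihedral_terms(coords, atoms[0], atoms[1], atoms[2], atoms[3])
    dphi = t[0] - target
    # wrap to (-pi, pi]
    while dphi <= -np.pi:
        dphi += 2 * np.pi
    while dphi > np.pi:
        dphi -= 2 * np.pi
    dE = k_res * dphi
    for a in range(4):
        grad[atoms[a], 0] += dE * t[1 + 3 * a]
        grad[atoms[a], 1] += dE * t[2 + 3 * a]
        grad[atoms[a], 2] += dE * t[3 + 3 * a]
    return 0.5 * k_res * dphi * dphi
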