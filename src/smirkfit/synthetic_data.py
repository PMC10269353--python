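"""Synthetic inputs with known ground truth.

Everything the fitting and benchmarking machinery consumes can be generated
here with no external data: toy molecules built from explicit
internal-coordinate templates (no conformer-embedder randomness), a
ground-truth toy force field θ*, "QM" targets produced by minimizing and
scanning under θ* plus optional Gaussian noise, physical-property data from
an analytic surrogate mapping LJ parameters to densities and enthalpies of
mixing, and paired free-energy benchmark tables with controlled biases.

The generators are seed-deterministic: the same seed reproduces outputs
bit-for-bit at the data-model level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from smirkfit.benchmarks import FreeEnergyRecord
from smirkfit.chem_model import (
    ForceField,
    Molecule,
    SmirksParameter,
    assign_parameters,
)
from smirkfit.fit_driver import PropertyDataPoint
from smirkfit.fit_targets import OptGeoTarget, TorsionProfileTarget
from smirkfit.mm_engine import make_torsion_grid, minimize, torsion_scan


# ---------------------------------------------------------------------------
# Internal-coordinate (z-matrix) geometry construction
# ---------------------------------------------------------------------------


class ZMatrixBuilder:
    """Place atoms one at a time from bond length / angle / dihedral refs."""

    def __init__(self):
        self.coords: list[np.ndarray] = []

    def add(self, b=None, r=None, a=None, theta=None, d=None, phi=None) -> int:
        """Add an atom; returns its index.  theta/phi in degrees."""
        n = len(self.coords)
        if n == 0:
            pos = np.zeros(3)
        elif n == 1:
            pos = self.coords[b] + np.array([r, 0.0, 0.0])
        elif d is None:
            # place in the xy-plane at the requested angle
            c = self.coords[b]
            u = self.coords[a] - c
            u = u / np.linalg.norm(u)
            w = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(w) < 1e-8:
                w = np.array([0.0, 1.0, 0.0])
            w = w / np.linalg.norm(w)
            t = np.deg2rad(theta)
            pos = c + r * (np.cos(t) * u + np.sin(t) * w)
        else:
            pos = _nerf(
                self.coords[d], self.coords[a], self.coords[b],
                r, np.deg2rad(theta), np.deg2rad(phi),
            )
        self.coords.append(pos)
        return n

    def array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


def _nerf(a, b, c, r, theta, phi):
    """Natural-extension placement: new atom D bonded to c with |Dc| = r,
    angle D-c-b = theta, dihedral D-c-b-a = phi."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # colinear reference frame; pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-8:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi),
         r * np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Ground-truth toy force field
# ---------------------------------------------------------------------------


def toy_forcefield() -> ForceField:
    """Ground-truth force field covering the toy molecule templates.

    Every class is represented; generic parameters come first so that the
    more specific entries later in each list exercise last-match-wins.
    Optimize flags follow the production protocol: bond k and length, angle
    k and equilibrium (force constant only for linear angles), torsion
    force constants only, nothing on impropers.
    """

    def bond(pid, smirks, k, length):
        return SmirksParameter(pid, smirks, "bond",
                               {"k": k, "length": length}, ("k", "length"))

    def angle(pid, smirks, k, theta0):
        return SmirksParameter(pid, smirks, "angle",
                               {"k": k, "angle": theta0}, ("k", "angle"))

    def torsion(pid, smirks, k, per, phase):
        return SmirksParameter(
            pid, smirks, "proper_torsion",
            {"k1": k, "periodicity1": per, "phase1": phase},
            ("k1",),
        )

    def improper(pid, smirks, k, per, phase):
        return SmirksParameter(
            pid, smirks, "improper_torsion",
            {"k1": k, "periodicity1": per, "phase1": phase},
            (),
        )

    def vdw(pid, smirks, eps, rmin_half):
        return SmirksParameter(pid, smirks, "vdw",
                               {"epsilon": eps, "rmin_half": rmin_half},
                               ("epsilon", "rmin_half"))

    params = {
        "bond": [
            bond("b-cc-gen", "[#6:1]~[#6:2]", 600.0, 1.50),
            bond("b-cc", "[#6X4:1]-[#6X4:2]", 530.0, 1.526),
            bond("b-ch", "[#6:1]-[#1:2]", 680.0, 1.092),
            bond("b-co", "[#6X4:1]-[#8X2:2]", 660.0, 1.42),
            bond("b-oh", "[#8:1]-[#1:2]", 1120.0, 0.97),
            bond("b-cn", "[#6X4:1]-[#7:2]", 700.0, 1.47),
            bond("b-nh", "[#7:1]-[#1:2]", 1010.0, 1.01),
            bond("b-c=o", "[#6X3:1]=[#8X1:2]", 1200.0, 1.22),
            bond("b-camn", "[#6X3:1]-[#7:2]", 770.0, 1.35),
            bond("b-s=o", "[#16:1]=[#8X1:2]", 1100.0, 1.46),
            bond("b-sn", "[#16:1]-[#7:2]", 600.0, 1.70),
            bond("b-cs", "[#6:1]-[#16:2]", 470.0, 1.81),
        ],
        "angle": [
            angle("a-gen", "[*:1]~[*:2]~[*:3]", 80.0, 112.0),
            angle("a-c4", "[*:1]~[#6X4:2]~[*:3]", 100.0, 109.5),
            angle("a-c3", "[*:1]~[#6X3:2]~[*:3]", 120.0, 120.0),
            angle("a-o", "[*:1]~[#8X2:2]~[*:3]", 110.0, 104.5),
            angle("a-n", "[*:1]~[#7:2]~[*:3]", 105.0, 109.0),
            angle("a-s", "[*:1]~[#16:2]~[*:3]", 120.0, 105.0),
            # linear-bond angle: equilibrium held at 180°, only k free
            angle("a-linear", "[*:1]~[#6X2:2]~[*:3]", 90.0, 180.0),
        ],
        "proper_torsion": [
            torsion("t-gen", "[*:1]~[*:2]~[*:3]~[*:4]", 0.15, 3, 0.0),
            torsion("t-cc", "[*:1]~[#6X4:2]-[#6X4:3]~[*:4]", 0.20, 3, 0.0),
            torsion("t-co", "[*:1]~[#6X4:2]-[#8X2:3]~[*:4]", 0.25, 3, 0.0),
            torsion("t-cn", "[*:1]~[#6X4:2]-[#7X3:3]~[*:4]", 0.18, 3, 0.0),
            torsion("t-amide", "[*:1]~[#6X3:2]-[#7X3:3]~[*:4]", 2.5, 2, 180.0),
            torsion("t-cs", "[*:1]~[#6X4:2]-[#16:3]~[*:4]", 0.30, 3, 0.0),
        ],
        "improper_torsion": [
            improper("i-c3", "[*:1]~[#6X3:2](~[*:3])~[*:4]", 1.1, 2, 180.0),
            improper("i-n3", "[*:1]~[#7X3:2](~[*:3])~[*:4]", 1.0, 2, 180.0),
        ],
        "vdw": [
            vdw("n-h", "[#1:1]", 0.0157, 1.20),
            vdw("n-h-polar", "[#1:1]-[#7,#8]", 0.0100, 0.60),
            vdw("n-c", "[#6:1]", 0.0860, 1.91),
            vdw("n-c4", "[#6X4:1]", 0.1094, 1.95),
            vdw("n-o", "[#8:1]", 0.2100, 1.66),
            vdw("n-n", "[#7:1]", 0.1700, 1.82),
            vdw("n-s", "[#16:1]", 0.2500, 2.00),
        ],
    }
    return ForceField(params, name="toy-ground-truth", version="1.0")


# ---------------------------------------------------------------------------
# Toy molecule templates
# ---------------------------------------------------------------------------

_H_CHARGE = {"C": 0.06, "N": 0.33, "O": 0.42}
_HEAVY_CHARGE = {7: -0.80, 8: -0.55, 16: 0.40}

R_CC, R_CH, R_CO, R_OH, R_CN, R_NH = 1.526, 1.092, 1.42, 0.97, 1.47, 1.01
T_TET = 109.47


def _assign_toy_charges(atomic_numbers, bonds) -> np.ndarray:
    """Deterministic toy charges: rule-based H and heteroatom charges with
    the residual spread evenly over carbons so each molecule is neutral."""
    n = len(atomic_numbers)
    nbrs = [[] for _ in range(n)]
    for i, j, _ in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    q = np.zeros(n)
    for i, z in enumerate(atomic_numbers):
        if z == 1:
            attached = atomic_numbers[nbrs[i][0]]
            sym = {6: "C", 7: "N", 8: "O", 16: "C"}[attached]
            q[i] = _H_CHARGE[sym]
        elif z in _HEAVY_CHARGE:
            q[i] = _HEAVY_CHARGE[z]
    carbons = [i for i, z in enumerate(atomic_numbers) if z == 6]
    if carbons:
        q[carbons] -= q.sum() / len(carbons)
    else:
        q -= q.sum() / n
    return q


def _finish(name, elements, bonds, coords) -> Molecule:
    charges = _assign_toy_charges(elements, bonds)
    return Molecule(
        atomic_numbers=list(elements),
        bonds=bonds,
        conformers=[coords],
        partial_charges=charges,
        name=name,
    )


def _chain_molecule(name: str, n_carbons: int, terminal: str | None) -> Molecule:
    """Alkane chain, optionally terminated by a hydroxyl or amino group."""
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    zm = ZMatrixBuilder()
    elements: list[int] = []
    bonds: list[tuple[int, int, int]] = []

    chain: list[int] = []
    for i in range(n_carbons):
        if i == 0:
            idx = zm.add()
        elif i == 1:
            idx = zm.add(b=chain[0], r=R_CC)
        elif i == 2:
            idx = zm.add(b=chain[1], r=R_CC, a=chain[0], theta=111.0)
        else:
            idx = zm.add(b=chain[-1], r=R_CC, a=chain[-2], theta=111.0,
                         d=chain[-3], phi=180.0)
        elements.append(6)
        if i:
            bonds.append((chain[-1], idx, 1))
        chain.append(idx)

    hetero = None
    if terminal == "O":
        prevs = chain[-2:][::-1] if n_carbons >= 2 else chain
        hetero = zm.add(
            b=chain[-1], r=R_CO,
            a=prevs[-1] if n_carbons >= 2 else None,
            theta=109.0 if n_carbons >= 2 else None,
            d=chain[-3] if n_carbons >= 3 else None,
            phi=180.0 if n_carbons >= 3 else None,
        )
        elements.append(8)
        bonds.append((chain[-1], hetero, 1))
    elif terminal == "N":
        hetero = zm.add(
            b=chain[-1], r=R_CN,
            a=chain[-2] if n_carbons >= 2 else None,
            theta=110.0 if n_carbons >= 2 else None,
            d=chain[-3] if n_carbons >= 3 else None,
            phi=180.0 if n_carbons >= 3 else None,
        )
        elements.append(7)
        bonds.append((chain[-1], hetero, 1))

    # hydrogens on the carbon chain; all heavy atoms are already placed
    first_h: dict[int, int] = {}  # carbon -> its first hydrogen
    for pos, c in enumerate(chain):
        heavy = []
        if pos > 0:
            heavy.append(chain[pos - 1])
        if pos + 1 < n_carbons:
            heavy.append(chain[pos + 1])
        if pos == n_carbons - 1 and hetero is not None:
            heavy.append(hetero)
        n_h = 4 - len(heavy)
        aref = heavy[0] if heavy else None
        # anti reference for staggering: a heavy atom two bonds away,
        # else a hydrogen on the neighboring carbon, else this atom's own
        # first hydrogen
        if len(heavy) >= 2:
            dref, phis = heavy[1], (120.0, 240.0, 0.0)
        elif pos >= 2:
            dref, phis = chain[pos - 2], (60.0, 180.0, 300.0)
        elif pos == 0 and (n_carbons >= 2 or hetero is not None):
            nxt = chain[1] if n_carbons >= 2 else hetero
            anti = (chain[2] if n_carbons >= 3
                    else hetero if (n_carbons == 2 and hetero is not None)
                    else first_h.get(nxt))
            dref, phis = anti, (60.0, 180.0, 300.0)
        else:
            dref, phis = None, (120.0, 240.0, 0.0)
        placed: list[int] = []
        for m in range(n_h):
            if aref is None:
                # bare methane: build the tetrahedron from its own hydrogens
                if m == 0:
                    h = zm.add(b=c, r=R_CH)
                elif m == 1:
                    h = zm.add(b=c, r=R_CH, a=placed[0], theta=T_TET)
                else:
                    h = zm.add(b=c, r=R_CH, a=placed[0], theta=T_TET,
                               d=placed[1], phi=120.0 * (m - 1))
            elif dref is None:
                if m == 0:
                    h = zm.add(b=c, r=R_CH, a=aref, theta=T_TET)
                else:
                    h = zm.add(b=c, r=R_CH, a=aref, theta=T_TET,
                               d=placed[0], phi=120.0 * m)
            else:
                h = zm.add(b=c, r=R_CH, a=aref, theta=T_TET,
                           d=dref, phi=phis[m])
            elements.append(1)
            bonds.append((c, h, 1))
            placed.append(h)
        if placed:
            first_h[c] = placed[0]

    # hydrogens on the terminal heteroatom
    if terminal == "O":
        dref = chain[-2] if n_carbons >= 2 else first_h[chain[0]]
        h = zm.add(b=hetero, r=R_OH, a=chain[-1], theta=104.5,
                   d=dref, phi=180.0)
        elements.append(1)
        bonds.append((hetero, h, 1))
    elif terminal == "N":
        dref = chain[-2] if n_carbons >= 2 else first_h[chain[0]]
        for phi in (60.0, 300.0):
            h = zm.add(b=hetero, r=R_NH, a=chain[-1], theta=109.0,
                       d=dref, phi=phi)
            elements.append(1)
            bonds.append((hetero, h, 1))

    return _finish(name, elements, bonds, zm.array())


def make_alkane(n: int) -> Molecule:
    return _chain_molecule(f"alkane-{n}", n, None)


def make_alcohol(n: int) -> Molecule:
    return _chain_molecule(f"alcohol-{n}", n, "O")


def make_amine(n: int) -> Molecule:
    return _chain_molecule(f"amine-{n}", n, "N")


def make_amide() -> Molecule:
    """Acetamide-like toy: CH3–C(=O)–NH2."""
    zm = ZMatrixBuilder()
    c0 = zm.add()                                   # methyl C
    c1 = zm.add(b=c0, r=1.50)                       # carbonyl C
    o2 = zm.add(b=c1, r=1.22, a=c0, theta=121.0)    # =O
    n3 = zm.add(b=c1, r=1.35, a=c0, theta=116.0, d=o2, phi=180.0)
    h_n1 = zm.add(b=n3, r=R_NH, a=c1, theta=119.0, d=o2, phi=180.0)
    h_n2 = zm.add(b=n3, r=R_NH, a=c1, theta=119.0, d=o2, phi=0.0)
    h1 = zm.add(b=c0, r=R_CH, a=c1, theta=T_TET, d=o2, phi=0.0)
    h2 = zm.add(b=c0, r=R_CH, a=c1, theta=T_TET, d=o2, phi=120.0)
    h3 = zm.add(b=c0, r=R_CH, a=c1, theta=T_TET, d=o2, phi=240.0)
    elements = [6, 6, 8, 7, 1, 1, 1, 1, 1]
    bonds = [(c0, c1, 1), (c1, o2, 2), (c1, n3, 1),
             (n3, h_n1, 1), (n3, h_n2, 1),
             (c0, h1, 1), (c0, h2, 1), (c0, h3, 1)]
    return _finish("amide", elements, bonds, zm.array())


def make_sulfonamide() -> Molecule:
    """Methanesulfonamide-like toy: CH3–S(=O)(=O)–NH2."""
    zm = ZMatrixBuilder()
    c0 = zm.add()
    s1 = zm.add(b=c0, r=1.81)
    o2 = zm.add(b=s1, r=1.46, a=c0, theta=107.0)
    o3 = zm.add(b=s1, r=1.46, a=c0, theta=107.0, d=o2, phi=125.0)
    n4 = zm.add(b=s1, r=1.70, a=c0, theta=103.0, d=o2, phi=237.5)
    h_n1 = zm.add(b=n4, r=R_NH, a=s1, theta=111.0, d=c0, phi=60.0)
    h_n2 = zm.add(b=n4, r=R_NH, a=s1, theta=111.0, d=c0, phi=300.0)
    h1 = zm.add(b=c0, r=R_CH, a=s1, theta=T_TET, d=o2, phi=60.0)
    h2 = zm.add(b=c0, r=R_CH, a=s1, theta=T_TET, d=o2, phi=180.0)
    h3 = zm.add(b=c0, r=R_CH, a=s1, theta=T_TET, d=o2, phi=300.0)
    elements = [6, 16, 8, 8, 7, 1, 1, 1, 1, 1]
    bonds = [(c0, s1, 1), (s1, o2, 2), (s1, o3, 2), (s1, n4, 1),
             (n4, h_n1, 1), (n4, h_n2, 1),
             (c0, h1, 1), (c0, h2, 1), (c0, h3, 1)]
    return _finish("sulfonamide", elements, bonds, zm.array())


_TEMPLATES = {
    "alkane": lambda n=4: make_alkane(n),
    "alcohol": lambda n=2: make_alcohol(n),
    "amine": lambda n=2: make_amine(n),
    "amide": lambda: make_amide(),
    "sulfonamide": lambda: make_sulfonamide(),
}


def make_toy_molecules(
    spec: Sequence[dict], seed: int = 0, jitter: float = 0.0
) -> list[Molecule]:
    """Build molecules from template specs like {"template": "alkane", "n": 4}.

    ``jitter`` adds seed-deterministic Gaussian coordinate noise (Å) to break
    exact template symmetry when requested; 0 by default.
    """
    rng = np.random.default_rng(seed)
    mols = []
    for entry in spec:
        entry = dict(entry)
        template = entry.pop("template")
        if template not in _TEMPLATES:
            raise ValueError(f"unknown template {template!r}")
        mol = _TEMPLATES[template](**entry)
        if jitter > 0:
            mol.conformers[0] = mol.conformers[0] + rng.normal(
                0.0, jitter, size=mol.conformers[0].shape
            )
        mols.append(mol)
    return mols


def default_molecule_set(seed: int = 0) -> list[Molecule]:
    """The shipped training set: every template, every parameter class used."""
    return make_toy_molecules(
        [
            {"template": "alkane", "n": 2},
            {"template": "alkane", "n": 3},
            {"template": "alkane", "n": 4},
            {"template": "alcohol", "n": 2},
            {"template": "alcohol", "n": 3},
            {"template": "amine", "n": 2},
            {"template": "amide"},
            {"template": "sulfonamide"},
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic "QM" targets
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """A ground-truth parameter set plus the noise model used around it."""

    forcefield: ForceField
    molecules: list[Molecule]
    sigma_energy: float = 0.0  # kcal/mol
    sigma_coords: float = 0.0  # Å
    sigma_property: float = 0.0
    seed: int = 0


def select_scan_dihedral(mol: Molecule) -> tuple[int, int, int, int] | None:
    """Most central rotatable bond: both ends heavy with at least one other
    neighbor, ranked by how many heavy substituents flank the bond so the
    driven dihedral runs heavy-heavy-heavy-heavy where possible."""
    nbrs = mol.neighbors()
    z = mol.atomic_numbers
    best = None
    best_score = None
    for j, k, order in mol.bonds:
        if order != 1 or z[j] == 1 or z[k] == 1:
            continue
        js = [x for x in nbrs[j] if x != k]
        ks = [x for x in nbrs[k] if x != j]
        if not js or not ks:
            continue
        i = max(js, key=lambda x: (z[x], -x))
        l = max(ks, key=lambda x: (z[x], -x))
        heavy_i = sum(1 for x in js if z[x] > 1)
        heavy_l = sum(1 for x in ks if z[x] > 1)
        score = (min(heavy_i, heavy_l), heavy_i + heavy_l, -j)
        if best_score is None or score > best_score:
            best_score = score
            best = (i, j, k, l)
    return best


def make_qm_targets(
    mols: Sequence[Molecule],
    ff: ForceField,
    sigma_coords: float = 0.0,
    sigma_energy: float = 0.0,
    seed: int = 0,
    grid_spacing: float = 15.0,
    include_torsions: bool = True,
) -> tuple[list[OptGeoTarget], list[TorsionProfileTarget], list[str]]:
    """Emulated QM targets: minima and torsion scans under the ground truth.

    With zero noise the valence data term evaluated at the generating
    parameters is zero by construction.  Scan failures omit the target and
    are reported rather than raised.
    """
    rng = np.random.default_rng(seed)
    optgeo: list[OptGeoTarget] = []
    torsions: list[TorsionProfileTarget] = []
    skipped: list[str] = []
    for mol in mols:
        assignment = assign_parameters(mol, ff)
        res = minimize(mol, 0, ff, assignment)
        ref = res.coordinates
        if sigma_coords > 0:
            ref = ref + rng.normal(0.0, sigma_coords, size=ref.shape)
        optgeo.append(
            OptGeoTarget(mol, ref, name=f"optgeo-{mol.name}", weight=0.1)
        )
        if not include_torsions:
            continue
        dihedral = select_scan_dihedral(mol)
        if dihedral is None:
            continue
        relaxed = Molecule(
            list(mol.atomic_numbers), list(mol.formal_charges),
            list(mol.bonds), [res.coordinates], mol.partial_charges, mol.name,
        )
        scan = torsion_scan(
            relaxed, ff, assignment, dihedral,
            grid_deg=make_torsion_grid(grid_spacing),
        )
        if not scan.converged.all():
            skipped.append(f"torsion-{mol.name}: scan not converged")
            continue
        energies = scan.energies.copy()
        if sigma_energy > 0:
            energies = energies + rng.normal(0.0, sigma_energy,
                                             size=energies.shape)
        energies = energies - energies.min()
        torsions.append(
            TorsionProfileTarget(
                mol, dihedral, scan.grid_deg, energies,
                starting_conformers=[s.copy() for s in scan.seeds],
                name=f"torsion-{mol.name}", weight=1.0,
            )
        )
    return optgeo, torsions, skipped


# ---------------------------------------------------------------------------
# Surrogate property model
# ---------------------------------------------------------------------------


@dataclass
class Substance:
    """A liquid characterized by vdW-type composition, not real chemistry."""

    name: str
    type_counts: dict[str, int]  # vdW parameter id -> atom count
    molar_mass: float  # g/mol
    elements: tuple[str, ...] = ("C", "H")
    functional_groups: tuple[str, ...] = ("alkane",)


def default_substances() -> dict[str, Substance]:
    return {
        s.name: s
        for s in [
            Substance("hexane", {"n-c4": 6, "n-h": 14}, 86.18,
                      ("C", "H"), ("alkane",)),
            Substance("ethanol", {"n-c4": 2, "n-h": 5, "n-o": 1,
                                  "n-h-polar": 1}, 46.07,
                      ("C", "H", "O"), ("alcohol",)),
            Substance("ethylamine", {"n-c4": 2, "n-h": 5, "n-n": 1,
                                     "n-h-polar": 2}, 45.08,
                      ("C", "H", "N"), ("amine",)),
            Substance("ether", {"n-c4": 4, "n-h": 10, "n-o": 1}, 74.12,
                      ("C", "H", "O"), ("ether",)),
            Substance("methanol", {"n-c4": 1, "n-h": 3, "n-o": 1,
                                   "n-h-polar": 1}, 32.04,
                      ("C", "H", "O"), ("alcohol",)),
        ]
    }


@dataclass
class SurrogateModel:
    """Analytic map from LJ parameters to densities and mixing enthalpies.

    Declared functional form (any smooth form with these monotonicities
    qualifies; this one ships as the default):

    * molar volume  V_i = v_scale · Σ_t n_t (R_min/2)_t³  — grows with size
    * cohesion      e_i = Σ_t n_t ε_t
    * density       ρ = (Σx M)/(Σx V) · (1 + α·(Σx e)/(Σx n))
      — decreasing in every R_min/2, increasing in every ε
    * ΔH_mix = P·(δ1−δ2)², P = x1V1·x2V2/(x1V1+x2V2), δ_i = c·e_i/V_i
      — a regular-solution (cohesive-energy-density contrast) form

    Gradients with respect to the fit vector are analytic.
    """

    substances: dict[str, Substance] = field(default_factory=default_substances)
    v_scale: float = 2.0  # mL/mol per Å³
    alpha: float = 2.0
    delta_scale: float = 70.0

    def _type_params(self, theta, entries, ff: ForceField):
        params = {
            p.id: dict(p.attributes) for p in ff.parameters["vdw"]
        }
        for (cls, pid, attr), val in zip(entries, theta):
            if cls == "vdw":
                params[pid][attr] = float(val)
        return params

    def _substance_terms(self, sub: Substance, params, entries):
        v = self.v_scale * sum(
            n * params[t]["rmin_half"] ** 3 for t, n in sub.type_counts.items()
        )
        e = sum(n * params[t]["epsilon"] for t, n in sub.type_counts.items())
        natoms = sum(sub.type_counts.values())
        dv = np.zeros(len(entries))
        de = np.zeros(len(entries))
        for p, (cls, pid, attr) in enumerate(entries):
            if cls != "vdw" or pid not in sub.type_counts:
                continue
            n = sub.type_counts[pid]
            if attr == "rmin_half":
                dv[p] = self.v_scale * 3.0 * n * params[pid]["rmin_half"] ** 2
            elif attr == "epsilon":
                de[p] = n
        return v, e, natoms, dv, de

    def density(self, dp: PropertyDataPoint, theta, entries, ff):
        params = self._type_params(theta, entries, ff)
        terms = [
            self._substance_terms(self.substances[c], params, entries)
            for c in dp.components
        ]
        x = np.asarray(dp.mole_fractions)
        m_bar = sum(
            xi * self.substances[c].molar_mass
            for xi, c in zip(x, dp.components)
        )
        v_bar = sum(xi * t[0] for xi, t in zip(x, terms))
        e_bar = sum(xi * t[1] for xi, t in zip(x, terms))
        n_bar = sum(xi * t[2] for xi, t in zip(x, terms))
        dv_bar = sum(xi * t[3] for xi, t in zip(x, terms))
        de_bar = sum(xi * t[4] for xi, t in zip(x, terms))
        factor = 1.0 + self.alpha * e_bar / n_bar
        rho = m_bar / v_bar * factor
        grad = (
            -m_bar / v_bar**2 * factor * dv_bar
            + m_bar / v_bar * self.alpha / n_bar * de_bar
        )
        return rho, grad

    def hmix(self, dp: PropertyDataPoint, theta, entries, ff):
        params = self._type_params(theta, entries, ff)
        (v1, e1, _, dv1, de1), (v2, e2, _, dv2, de2) = (
            self._substance_terms(self.substances[c], params, entries)
            for c in dp.components
        )
        x1, x2 = dp.mole_fractions
        a, b = x1 * v1, x2 * v2
        da, db = x1 * dv1, x2 * dv2
        p_mix = a * b / (a + b)
        dp_mix = (b**2 * da + a**2 * db) / (a + b) ** 2
        d1 = self.delta_scale * e1 / v1
        d2 = self.delta_scale * e2 / v2
        dd1 = self.delta_scale * (de1 / v1 - e1 / v1**2 * dv1)
        dd2 = self.delta_scale * (de2 / v2 - e2 / v2**2 * dv2)
        contrast = d1 - d2
        value = p_mix * contrast**2
        grad = dp_mix * contrast**2 + p_mix * 2.0 * contrast * (dd1 - dd2)
        return value, grad


@dataclass
class SurrogatePropertyBackend:
    """PropertyBackend over the analytic surrogate: deterministic, with
    analytic gradients and zero statistical uncertainty."""

    ff: ForceField
    entries: list[tuple[str, str, str]]
    model: SurrogateModel = field(default_factory=SurrogateModel)

    def estimate(self, theta, datapoints):
        values, grads = [], []
        for dp in datapoints:
            if dp.kind in ("density", "density_mix"):
                v, g = self.model.density(dp, theta, self.entries, self.ff)
            else:
                v, g = self.model.hmix(dp, theta, self.entries, self.ff)
            values.append(v)
            grads.append(g)
        return (
            np.asarray(values),
            np.asarray(grads).reshape(len(values), len(self.entries)),
            np.zeros(len(values)),
        )


def default_property_design() -> list[dict]:
    """Systems at ambient conditions: pure densities plus binary mixtures at
    the three canonical concentrations."""
    subs = sorted(default_substances())
    design = [{"kind": "density", "components": [s], "x": [1.0]} for s in subs]
    for i in range(len(subs)):
        for j in range(i + 1, len(subs)):
            for x1 in (0.25, 0.5, 0.75):
                design.append(
                    {"kind": "density_mix", "components": [subs[i], subs[j]],
                     "x": [x1, 1.0 - x1]}
                )
                design.append(
                    {"kind": "hmix", "components": [subs[i], subs[j]],
                     "x": [x1, 1.0 - x1]}
                )
    return design


def make_property_dataset(
    ff: ForceField,
    entries: Sequence[tuple[str, str, str]] = (),
    design: Sequence[dict] | None = None,
    sigma_rho: float = 0.0,
    sigma_hmix: float = 0.0,
    seed: int = 0,
    model: SurrogateModel | None = None,
    include_filterable: bool = False,
) -> list[PropertyDataPoint]:
    """"Experimental" property data = surrogate(ground truth) + noise.

    With ``include_filterable`` extra points violating the curation windows
    (sub-ambient temperature, below-floor mole fractions) are appended so
    filter behavior is exercisable.
    """
    model = model or SurrogateModel()
    rng = np.random.default_rng(seed)
    design = list(design) if design is not None else default_property_design()
    entries = list(entries)
    theta = np.array(
        [ff.get_parameter(pid).attributes[attr] for _, pid, attr in entries]
    )
    points: list[PropertyDataPoint] = []
    for row in design:
        dp = PropertyDataPoint(
            kind=row["kind"],
            components=list(row["components"]),
            mole_fractions=list(row["x"]),
            temperature_k=row.get("T", 298.15),
            pressure_kpa=row.get("P", 101.325),
            value=0.0,
        )
        if dp.kind in ("density", "density_mix"):
            value, _ = model.density(dp, theta, entries, ff)
            value += rng.normal(0.0, sigma_rho) if sigma_rho > 0 else 0.0
        else:
            value, _ = model.hmix(dp, theta, entries, ff)
            value += rng.normal(0.0, sigma_hmix) if sigma_hmix > 0 else 0.0
        dp.value = float(value)
        elements: set[str] = set()
        groups: set[str] = set()
        for c in dp.components:
            elements.update(model.substances[c].elements)
            groups.update(model.substances[c].functional_groups)
        dp.elements = tuple(sorted(elements))
        dp.functional_groups = tuple(sorted(groups))
        points.append(dp)
    if include_filterable:
        base = points[0]
        for t_k, p_kpa, x1 in ((250.0, 101.325, 0.5),
                               (298.15, 101.325, 0.03),
                               (298.15, 80.0, 0.5)):
            subs = sorted(model.substances)[:2]
            points.append(
                PropertyDataPoint(
                    "density_mix", subs, [x1, 1.0 - x1], t_k, p_kpa,
                    base.value, 0.0,
                    base.elements, base.functional_groups,
                )
            )
    return points


# ---------------------------------------------------------------------------
# Free-energy benchmark tables
# ---------------------------------------------------------------------------


def make_fe_tables(
    n_systems: int,
    bias_ref: float = 1.0,
    bias_new: float = 0.0,
    noise: float = 0.3,
    seed: int = 0,
    exp_mean: float = -3.0,
    exp_sd: float = 2.0,
) -> tuple[list[FreeEnergyRecord], list[FreeEnergyRecord]]:
    """Paired benchmark tables: ("new", "ref") predictions around the same
    experimental values, with stated biases and Gaussian simulation noise.

    The analytic expected mean shift is E|b_new + η| − E|b_ref + η| with η
    the noise (folded-normal means).
    """
    if n_systems < 2:
        raise ValueError("need at least 2 systems")
    rng = np.random.default_rng(seed)
    o_exp = rng.normal(exp_mean, exp_sd, size=n_systems)
    eta_new = rng.normal(0.0, noise, size=n_systems) if noise > 0 else np.zeros(n_systems)
    eta_ref = rng.normal(0.0, noise, size=n_systems) if noise > 0 else np.zeros(n_systems)
    new = [
        FreeEnergyRecord(f"sys-{i}", float(o_exp[i] + bias_new + eta_new[i]),
                         float(o_exp[i]), noise)
        for i in range(n_systems)
    ]
    ref = [
        FreeEnergyRecord(f"sys-{i}", float(o_exp[i] + bias_ref + eta_ref[i]),
                         float(o_exp[i]), noise)
        for i in range(n_systems)
    ]
    return new, ref


def expected_mean_shift(bias_new, bias_ref, noise) -> float:
    """Closed-form folded-normal expectation of the mean shift."""
    from scipy.stats import foldnorm

    def folded_mean(mu, sigma):
        if sigma == 0:
            return abs(mu)
        return float(foldnorm.mean(abs(mu) / sigma, scale=sigma))

    return folded_mean(bias_new, noise) - folded_mean(bias_ref, noise)
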