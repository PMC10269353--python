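"""Valence fitting targets: opt-geo internal-coordinate loss and weighted
torsion-profile loss.

An *opt-geo* target penalizes deviations of the internal coordinates (bond
lengths, bond angles, improper angles — proper torsions deliberately
excluded) of an MM-minimized geometry from a reference minimum, each scaled
by a dimensional divisor (0.05 Å, 8°, 20°) so that fluctuations larger than
"normal" for that coordinate type are penalized comparably.

A *torsion-profile* target penalizes weighted squared differences between MM
and reference relative energy profiles along a driven dihedral grid, both
profiles referenced to their own grid minimum.  The weight function
prioritizes the region near the minima: w = 1 below 1 kcal/mol, falls off as
1/sqrt(1 + (E-1)^2) up to 5 kcal/mol, and is exactly 0 above, so barrier
regions beyond ~5 kcal/mol never drive the fit.

Each target's sum is normalized by its coordinate / grid-point count so that
targets of different sizes contribute comparably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from smirkfit.chem_model import Molecule, canonical_key
from smirkfit.mm_engine import dihedral_angle, _wrap_deg

DEFAULT_DIVISORS = {"bond": 0.05, "angle": 8.0, "improper": 20.0}


@dataclass
class InternalCoordinates:
    """Named internal-coordinate values: bonds Å, angles/impropers degrees."""

    bonds: dict[tuple, float]
    angles: dict[tuple, float]
    impropers: dict[tuple, float]
    degenerate: list[tuple] = field(default_factory=list)

    def as_vector(self, keys: Sequence[tuple[str, tuple]]) -> np.ndarray:
        tables = {"bond": self.bonds, "angle": self.angles,
                  "improper": self.impropers}
        return np.array([tables[kind][key] for kind, key in keys])


def internal_coordinates(
    mol: Molecule, conformer: int | np.ndarray
) -> InternalCoordinates:
    """Bond lengths, bond angles, and improper angles of a conformer.

    The improper angle is the out-of-plane dihedral of the canonical improper
    tuple (n1, center, n2, n3); colinear angle triples are still reported
    (clamped arccos) but flagged as degenerate.
    """
    coords = (
        np.asarray(conformer, dtype=float)
        if not np.isscalar(conformer)
        else mol.conformers[conformer]
    )
    bonds = {}
    for key in mol.bond_tuples():
        bonds[key] = float(np.linalg.norm(coords[key[1]] - coords[key[0]]))

    angles = {}
    degenerate = []
    for key in mol.angle_tuples():
        i, j, k = key
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        cos_t = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if abs(cos_t) > 1.0 - 1e-10:
            degenerate.append(key)
        angles[key] = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))

    impropers = {}
    nbrs = mol.neighbors()
    for center in mol.trivalent_centers():
        n1, n2, n3 = nbrs[center]
        key = canonical_key((n1, center, n2, n3), "improper_torsion")
        phi = dihedral_angle(coords, np.asarray([key]))[0]
        impropers[key] = float(np.degrees(phi))
    return InternalCoordinates(bonds, angles, impropers, degenerate)


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


@dataclass
class OptGeoTarget:
    """Reference-minimum geometry target over internal coordinates."""

    molecule: Molecule
    reference_coords: np.ndarray  # (N, 3) Å, the QM-optimized minimum
    coordinate_keys: list[tuple[str, tuple]] = None  # (kind, atom tuple)
    divisors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVISORS)
    )
    weight: float = 0.1
    name: str = ""

    def __post_init__(self):
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.coordinate_keys is None:
            ics = internal_coordinates(self.molecule, self.reference_coords)
            self.coordinate_keys = (
                [("bond", k) for k in sorted(ics.bonds)]
                + [("angle", k) for k in sorted(ics.angles)]
                + [("improper", k) for k in sorted(ics.impropers)]
            )
        for kind, _ in self.coordinate_keys:
            if kind not in ("bond", "angle", "improper"):
                raise ValueError(
                    f"proper torsions / unknown kind {kind!r} not allowed in "
                    "opt-geo coordinate lists"
                )
        for kind, d in self.divisors.items():
            if d <= 0:
                raise ValueError(f"divisor for {kind} must be > 0")

    @property
    def reference_values(self) -> np.ndarray:
        ics = internal_coordinates(self.molecule, self.reference_coords)
        return ics.as_vector(self.coordinate_keys)


def optgeo_loss(
    target: OptGeoTarget, mm_coords: np.ndarray
) -> tuple[float, dict]:
    """Normalized Σ((x_ref − x_MM)/d)² over the target's internal coordinates.

    Angle-like differences are wrapped to (−180°, 180°].  The sum is divided
    by the number of coordinates.
    """
    ics_mm = internal_coordinates(target.molecule, mm_coords)
    x_ref = target.reference_values
    x_mm = ics_mm.as_vector(target.coordinate_keys)
    contributions = {}
    total = 0.0
    for (kind, key), ref, mm in zip(target.coordinate_keys, x_ref, x_mm):
        diff = ref - mm
        if kind in ("angle", "improper"):
            diff = float(_wrap_deg(diff))
        c = (diff / target.divisors[kind]) ** 2
        contributions[(kind, key)] = c
        total += c
    n = len(target.coordinate_keys)
    return total / n, contributions


@dataclass
class TorsionProfileTarget:
    """Driven-dihedral relative-energy profile target."""

    molecule: Molecule
    dihedral: tuple[int, int, int, int]
    grid_deg: np.ndarray
    qm_energies: np.ndarray  # kcal/mol relative, min exactly 0
    starting_conformers: list[np.ndarray] = None  # per-point MM seeds
    d_e: float = 1.0  # kcal/mol
    weight_low: float = 1.0  # flat-weight region upper edge, kcal/mol
    weight_high: float = 5.0  # zero-weight cutoff, kcal/mol
    weight: float = 1.0
    name: str = ""

    def __post_init__(self):
        self.grid_deg = np.asarray(self.grid_deg, dtype=float)
        self.qm_energies = np.asarray(self.qm_energies, dtype=float)
        if self.grid_deg.shape != self.qm_energies.shape:
            raise ValueError("grid and energies must have equal length")
        if abs(self.qm_energies.min()) > 1e-9:
            raise ValueError("QM relative energies must have min exactly 0")


def torsion_weight(
    e_qm: float | np.ndarray, low: float = 1.0, high: float = 5.0
) -> float | np.ndarray:
    """Energy-dependent weight in [0, 1].

    1 for E < low; 1/sqrt(1 + (E - low)^2) for low <= E < high; 0 above.
    Maximal at E = 0, nonincreasing, exactly 0 at and above the cutoff.
    """
    e = np.asarray(e_qm, dtype=float)
    if np.any(e < 0):
        raise ValueError("relative QM energies must be nonnegative")
    w = np.where(
        e < low,
        1.0,
        np.where(e < high, 1.0 / np.sqrt(1.0 + (e - low) ** 2), 0.0),
    )
    return float(w) if np.isscalar(e_qm) else w


def torsion_profile_loss(
    target: TorsionProfileTarget, mm_energies: np.ndarray
) -> tuple[float, np.ndarray]:
    """Normalized Σ w(E_QM)·((ΔE_MM − ΔE_QM)/d_E)² over the grid.

    Both profiles are re-referenced to their own minima before comparison, so
    the loss is invariant under additive shifts of either absolute profile.
    """
    mm = np.asarray(mm_energies, dtype=float)
    if mm.shape != target.grid_deg.shape:
        raise ValueError("MM profile grid mismatch")
    mm_rel = mm - mm.min()
    qm_rel = target.qm_energies - target.qm_energies.min()
    w = torsion_weight(qm_rel, target.weight_low, target.weight_high)
    per_point = w * ((mm_rel - qm_rel) / target.d_e) ** 2
    return float(per_point.sum() / len(per_point)), per_point


# ---------------------------------------------------------------------------
# Target file I/O (JSON)
# ---------------------------------------------------------------------------


def optgeo_target_to_dict(t: OptGeoTarget) -> dict:
    return {
        "type": "opt_geo",
        "name": t.name,
        "reference_coords": t.reference_coords.tolist(),
        "coordinate_keys": [[kind, list(key)] for kind, key in t.coordinate_keys],
        "divisors": t.divisors,
        "weight": t.weight,
    }


def torsion_target_to_dict(t: TorsionProfileTarget) -> dict:
    return {
        "type": "torsion_profile",
        "name": t.name,
        "dihedral": list(t.dihedral),
        "grid_deg": t.grid_deg.tolist(),
        "qm_energies": t.qm_energies.tolist(),
        "starting_conformers": [c.tolist() for c in (t.starting_conformers or [])],
        "d_e": t.d_e,
        "weight_low": t.weight_low,
        "weight_high": t.weight_high,
        "weight": t.weight,
    }


def target_from_dict(doc: dict, molecule: Molecule):
    if doc["type"] == "opt_geo":
        return OptGeoTarget(
            molecule,
            np.asarray(doc["reference_coords"]),
            [(kind, tuple(key)) for kind, key in doc["coordinate_keys"]],
            dict(doc["divisors"]),
            float(doc["weight"]),
            doc.get("name", ""),
        )
    if doc["type"] == "torsion_profile":
        return TorsionProfileTarget(
            molecule,
            tuple(doc["dihedral"]),
            np.asarray(doc["grid_deg"]),
            np.asarray(doc["qm_energies"]),
            [np.asarray(c) for c in doc.get("starting_conformers", [])] or None,
            float(doc.get("d_e", 1.0)),
            float(doc.get("weight_low", 1.0)),
            float(doc.get("weight_high", 5.0)),
            float(doc.get("weight", 1.0)),
            doc.get("name", ""),
        )
    raise ValueError(f"unknown target type {doc.get('type')!r}")


def save_targets(targets: Sequence, path: str) -> None:
    docs = []
    for t in targets:
        if isinstance(t, OptGeoTarget):
            docs.append(optgeo_target_to_dict(t))
        else:
            docs.append(torsion_target_to_dict(t))
    with open(path, "w") as fh:
        json.dump(docs, fh)
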