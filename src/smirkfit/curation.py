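"""Training-data selection and filtering rules.

QM-facing filters: conformer capping by greedy max-min RMSD diversity,
rejection of geometries whose perceived connectivity changed during
optimization, rejection of conformations with strong intramolecular
hydrogen bonds (a single-structure adaptation of the Baker–Hubbard
geometric criterion), and minimal-overlap torsion-scan selection so each
torsion parameter is exercised as cleanly as possible.

Property-facing filters: element whitelist, close-to-ambient window
(99.9–101.4 kPa, 288.15–318.15 K), a mole-fraction floor of 0.05, selection
of up to three binary-mixture points nearest x1 ∈ {0.25, 0.5, 0.75}, and a
minimum of five surviving measurements per functional group and data type.
LJ types become refit-eligible only with at least five density AND five
enthalpy-of-mixing points.

Every filter is idempotent and reports conserved counts
(input = retained + removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem

from smirkfit.benchmarks import rmsd as kabsch_rmsd
from smirkfit.chem_model import Molecule
from smirkfit.fit_driver import PropertyDataPoint

AMBIENT_PRESSURE_KPA = (99.9, 101.4)
AMBIENT_TEMPERATURE_K = (288.15, 318.15)
MOLE_FRACTION_FLOOR = 0.05
TARGET_CONCENTRATIONS = (0.25, 0.5, 0.75)
ELEMENT_WHITELIST = frozenset({"H", "C", "N", "O", "Cl", "Br"})
MIN_GROUP_MEASUREMENTS = 5
MIN_LJ_DATA_POINTS = 5


@dataclass
class CurationReport:
    """Per-filter removal bookkeeping; input = retained + Σ removed."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    removal_reasons: list[tuple[str, str]] = field(default_factory=list)
    retained_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def drop(self, identifier: str, reason: str) -> None:
        self.removed[reason] = self.removed.get(reason, 0) + 1
        self.removal_reasons.append((identifier, reason))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": dict(self.removed),
            "retained_ids": list(self.retained_ids),
        }


# ---------------------------------------------------------------------------
# Conformer capping
# ---------------------------------------------------------------------------


def cap_conformers(
    conformers: Sequence[np.ndarray],
    cap: int = 10,
    energies: Sequence[float] | None = None,
    heavy_mask: Sequence[bool] | None = None,
) -> list[int]:
    """Greedy max-min diverse subset of conformer indices (size ≤ cap).

    Seeded with the lowest-energy conformer when energies are given (index 0
    otherwise); repeatedly adds the conformer maximizing its minimum RMSD to
    the already-selected set.  RMSD uses optimal superposition over the
    heavy-atom subset when ``heavy_mask`` is provided.
    """
    n = len(conformers)
    if n == 0:
        raise ValueError("need at least one conformer")
    if n <= cap:
        return list(range(n))
    subset = None
    if heavy_mask is not None:
        subset = [i for i, heavy in enumerate(heavy_mask) if heavy]

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kabsch_rmsd(
                conformers[i], conformers[j], subset
            )

    seed = int(np.argmin(energies)) if energies is not None else 0
    selected = [seed]
    remaining = [i for i in range(n) if i != seed]
    while len(selected) < cap:
        best = max(
            remaining,
            key=lambda c: (min(dist[c, s] for s in selected), -c),
        )
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# Connectivity-change filter
# ---------------------------------------------------------------------------


def perceive_bonds(
    atomic_numbers: Sequence[int],
    coords: np.ndarray,
    tolerance: float = 1.2,
) -> set[tuple[int, int]]:
    """Distance-based bond perception: bonded iff
    d(i,j) < tolerance × (r_cov(i) + r_cov(j))."""
    pt = Chem.GetPeriodicTable()
    radii = []
    for z in atomic_numbers:
        try:
            r = pt.GetRcovalent(int(z))
        except Exception as exc:
            raise ValueError(f"unknown element {z}") from exc
        if r <= 0:
            raise ValueError(f"unknown covalent radius for element {z}")
        radii.append(r)
    coords = np.asarray(coords, dtype=float)
    bonds = set()
    for i in range(len(radii)):
        for j in range(i + 1, len(radii)):
            cutoff = tolerance * (radii[i] + radii[j])
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                bonds.add((i, j))
    return bonds


def filter_connectivity_change(
    initial: np.ndarray,
    final: np.ndarray,
    atomic_numbers: Sequence[int],
    tolerance: float = 1.2,
) -> tuple[bool, set[tuple[int, int]], set[tuple[int, int]]]:
    """Keep iff the perceived bond sets of both geometries are identical.

    Returns (keep, bonds_initial, bonds_final).  The classic reject case is
    an intramolecular proton transfer during geometry optimization.
    """
    b0 = perceive_bonds(atomic_numbers, initial, tolerance)
    b1 = perceive_bonds(atomic_numbers, final, tolerance)
    return b0 == b1, b0, b1


# ---------------------------------------------------------------------------
# Intramolecular hydrogen-bond filter
# ---------------------------------------------------------------------------

_HBOND_ELEMENTS = {7, 8}  # N, O donors and acceptors


def detect_internal_hbonds(
    mol: Molecule,
    coords: np.ndarray,
    distance_cutoff: float = 2.5,
    angle_cutoff: float = 120.0,
) -> list[tuple[int, int, int]]:
    """D–H···A hits (donor, hydrogen, acceptor) with D, A ∈ {N, O},
    H···A ≤ distance_cutoff Å and ∠(D–H···A) ≥ angle_cutoff degrees."""
    coords = np.asarray(coords, dtype=float)
    nbrs = mol.neighbors()
    z = mol.atomic_numbers
    hits = []
    for h, zh in enumerate(z):
        if zh != 1 or not nbrs[h]:
            continue
        donor = nbrs[h][0]
        if z[donor] not in _HBOND_ELEMENTS:
            continue
        for acc, za in enumerate(z):
            if za not in _HBOND_ELEMENTS or acc == donor:
                continue
            d_ha = np.linalg.norm(coords[acc] - coords[h])
            if d_ha > distance_cutoff:
                continue
            u = coords[donor] - coords[h]
            v = coords[acc] - coords[h]
            cos_t = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            angle = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
            if angle >= angle_cutoff:
                hits.append((donor, h, acc))
    return hits


def filter_internal_hbonds(
    mol: Molecule,
    conformer: int | np.ndarray = 0,
    distance_cutoff: float = 2.5,
    angle_cutoff: float = 120.0,
) -> tuple[bool, list[tuple[int, int, int]]]:
    """Keep iff no intramolecular hydrogen bond is detected."""
    coords = (
        mol.conformers[conformer]
        if np.isscalar(conformer)
        else np.asarray(conformer, dtype=float)
    )
    hits = detect_internal_hbonds(mol, coords, distance_cutoff, angle_cutoff)
    return len(hits) == 0, hits


# ---------------------------------------------------------------------------
# Torsion-scan selection
# ---------------------------------------------------------------------------


@dataclass
class TorsionCandidate:
    """One candidate 1-D scan: which torsion parameters its central bond
    exercises (the first is the one of interest, the rest are overlaps)."""

    identifier: str
    parameters: tuple[str, ...]


def select_torsions(
    candidates: Sequence[TorsionCandidate],
    parameter_ids: Sequence[str],
) -> tuple[dict[str, str], list[str]]:
    """Minimal-overlap scan selection per torsion parameter.

    For each parameter, prefer a candidate exercising it with no other
    parameters on the central bond; failing that, allow one overlap, then
    two, and so on.  Ties break on identifier order.  Parameters with no
    candidate at any level are reported uncovered, not fatal.
    """
    chosen: dict[str, str] = {}
    uncovered: list[str] = []
    max_overlap = max((len(c.parameters) for c in candidates), default=1)
    for pid in parameter_ids:
        pool = sorted(
            (c for c in candidates if pid in c.parameters),
            key=lambda c: c.identifier,
        )
        if not pool:
            uncovered.append(pid)
            continue
        for allowed in range(max_overlap):
            level = [c for c in pool if len(c.parameters) - 1 <= allowed]
            if level:
                chosen[pid] = level[0].identifier
                break
        else:
            uncovered.append(pid)
    return chosen, uncovered


# ---------------------------------------------------------------------------
# Physical-property data curation
# ---------------------------------------------------------------------------


def filter_property_data(
    datapoints: Sequence[PropertyDataPoint],
    element_whitelist: frozenset[str] = ELEMENT_WHITELIST,
    pressure_window: tuple[float, float] = AMBIENT_PRESSURE_KPA,
    temperature_window: tuple[float, float] = AMBIENT_TEMPERATURE_K,
    mole_fraction_floor: float = MOLE_FRACTION_FLOOR,
    target_concentrations: Sequence[float] = TARGET_CONCENTRATIONS,
    min_group_measurements: int = MIN_GROUP_MEASUREMENTS,
    exclusion_rules: Sequence[Callable[[PropertyDataPoint], bool]] = (),
) -> tuple[list[PropertyDataPoint], CurationReport]:
    """Ordered property-data curation.

    1. element whitelist; 2. ambient window (inclusive boundaries);
    3. mole-fraction floor (inclusive); 4. named substructure exclusions
    (off unless rules are passed); 5. per binary system and data type keep
    up to 3 points nearest the target concentrations; 6. drop functional
    groups with fewer than ``min_group_measurements`` surviving points for
    a data type.
    """
    report = CurationReport(n_input=len(datapoints))
    ids = {id(dp): f"dp-{i}" for i, dp in enumerate(datapoints)}
    survivors: list[PropertyDataPoint] = []
    for dp in datapoints:
        label = ids[id(dp)]
        if not dp.elements or not dp.functional_groups:
            report.drop(label, "missing-metadata")
            continue
        if not set(dp.elements) <= element_whitelist:
            report.drop(label, "element-whitelist")
            continue
        if not (pressure_window[0] <= dp.pressure_kpa <= pressure_window[1]
                and temperature_window[0] <= dp.temperature_k
                <= temperature_window[1]):
            report.drop(label, "ambient-window")
            continue
        if min(dp.mole_fractions) < mole_fraction_floor - 1e-12:
            report.drop(label, "mole-fraction-floor")
            continue
        if any(rule(dp) for rule in exclusion_rules):
            report.drop(label, "substructure-exclusion")
            continue
        survivors.append(dp)

    # 3-concentration selection per binary system and data type
    by_system: dict[tuple, list[PropertyDataPoint]] = {}
    keep: list[PropertyDataPoint] = []
    for dp in survivors:
        if len(dp.components) == 2:
            key = (tuple(dp.components), dp.kind)
            by_system.setdefault(key, []).append(dp)
        else:
            keep.append(dp)
    for (_, _kind), points in sorted(
        by_system.items(), key=lambda kv: kv[0]
    ):
        chosen: list[PropertyDataPoint] = []
        available = list(points)
        for x_target in target_concentrations:
            if not available:
                break
            best = min(
                available,
                key=lambda dp: (abs(dp.mole_fractions[0] - x_target),
                                dp.mole_fractions[0]),
            )
            chosen.append(best)
            available.remove(best)
        for dp in points:
            if dp in chosen:
                keep.append(dp)
            else:
                report.drop(ids[id(dp)], "concentration-selection")

    # group-coverage minimum, applied last, per data type
    group_counts: dict[tuple[str, str], int] = {}
    for dp in keep:
        for g in dp.functional_groups:
            key = (g, "density" if dp.kind != "hmix" else "hmix")
            group_counts[key] = group_counts.get(key, 0) + 1
    final: list[PropertyDataPoint] = []
    for dp in keep:
        kind = "density" if dp.kind != "hmix" else "hmix"
        if any(group_counts[(g, kind)] < min_group_measurements
               for g in dp.functional_groups):
            report.drop(ids[id(dp)], "group-coverage")
        else:
            final.append(dp)

    order = {id(dp): i for i, dp in enumerate(datapoints)}
    final.sort(key=lambda dp: order[id(dp)])
    report.retained_ids = [ids[id(dp)] for dp in final]
    return final, report


def eligible_lj_types(
    datapoints: Sequence[PropertyDataPoint],
    type_coverage: dict[str, dict[str, int]] | None = None,
    substance_types: dict[str, Sequence[str]] | None = None,
    min_points: int = MIN_LJ_DATA_POINTS,
) -> list[str]:
    """vdW types with ≥ min_points density AND ≥ min_points ΔH_mix points.

    Coverage may be supplied directly (type -> {"density": n, "hmix": n}) or
    computed from a substance -> vdW-type map.
    """
    if type_coverage is None:
        if substance_types is None:
            raise ValueError("need type_coverage or substance_types")
        type_coverage = {}
        for dp in datapoints:
            block = "density" if dp.kind != "hmix" else "hmix"
            touched: set[str] = set()
            for comp in dp.components:
                touched.update(substance_types.get(comp, ()))
            for t in touched:
                type_coverage.setdefault(t, {"density": 0, "hmix": 0})
                type_coverage[t][block] += 1
    return sorted(
        t for t, cov in type_coverage.items()
        if cov.get("density", 0) >= min_points
        and cov.get("hmix", 0) >= min_points
    )


# ---------------------------------------------------------------------------
# Functional-group coverage graph
# ---------------------------------------------------------------------------


def coverage_graph(
    mols: Sequence[Molecule],
    group_smarts: dict[str, str],
) -> nx.Graph:
    """Functional-group co-occurrence graph over a molecule set.

    Nodes are groups present in at least one molecule; an edge joins two
    groups found together in the same molecule.  Invalid SMARTS raise.
    """
    queries = {}
    for name, smarts in group_smarts.items():
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"invalid group SMARTS for {name!r}: {smarts!r}")
        queries[name] = q
    graph = nx.Graph()
    for mol in mols:
        rd = mol.to_rdkit()
        present = sorted(
            name for name, q in queries.items() if rd.HasSubstructMatch(q)
        )
        graph.add_nodes_from(present)
        graph.add_edges_from(combinations(present, 2))
    return graph


DEFAULT_GROUP_SMARTS = {
    "alcohol": "[#6][OX2H]",
    "ether": "[#6][OX2H0][#6]",
    "amine": "[NX3;H2,H1;!$(NC=O)][#6]",
    "amide": "[CX3](=[OX1])[NX3]",
    "carbonyl": "[CX3]=[OX1]",
    "sulfonyl": "[#16X4](=[OX1])(=[OX1])",
    "alkane_ch": "[CX4][#1]",
}
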