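"""Molecules, SMIRKS-keyed force fields, and direct chemical perception.

A force field here is a set of *ordered* parameter lists, one per interaction
class (bonds, angles, proper torsions, improper torsions, vdW), keyed by
SMIRKS patterns.  Parameters are assigned to a molecule by substructure
matching: for every bonded tuple the *last* matching parameter in list order
wins, so later (more specific) patterns override earlier (generic) ones.
Substructure matching itself is delegated to RDKit; the ordering,
canonicalization and last-match-wins logic live here.

Serialization supports a documented subset of SMIRNOFF-style XML and an
equivalent JSON form.  Units are fixed: Å, degrees, kcal/mol, with harmonic
force constants in the k/2 (x - x0)^2 convention.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from smirkfit.constants import SCALE_ELEC_14, SCALE_VDW_14

PARAMETER_CLASSES = ("bond", "angle", "proper_torsion", "improper_torsion", "vdw")

_TAGGED_ATOMS_REQUIRED = {
    "bond": 2,
    "angle": 3,
    "proper_torsion": 4,
    "improper_torsion": 4,
    "vdw": 1,
}

_XML_SECTION = {
    "bond": ("Bonds", "Bond"),
    "angle": ("Angles", "Angle"),
    "proper_torsion": ("ProperTorsions", "Proper"),
    "improper_torsion": ("ImproperTorsions", "Improper"),
    "vdw": ("vdW", "Atom"),
}
_XML_CLASS_BY_SECTION = {sec: cls for cls, (sec, _) in _XML_SECTION.items()}


class ForceFieldParseError(ValueError):
    """Malformed force-field document (bad SMIRKS, duplicate id, wrong arity)."""


class UnassignedChemistryError(ValueError):
    """A bonded tuple is matched by no parameter of its class."""

    def __init__(self, parameter_class: str, tuples: Sequence[tuple]):
        self.parameter_class = parameter_class
        self.tuples = list(tuples)
        super().__init__(
            f"no {parameter_class} parameter matches tuples {self.tuples}"
        )


# ---------------------------------------------------------------------------
# Molecule
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """Explicit-topology molecule with optional conformers and charges.

    atomic_numbers : element of each atom.
    formal_charges : per-atom integer formal charge.
    bonds          : (i, j, order) with i < j, no duplicates.
    conformers     : list of (N, 3) coordinate arrays in Å.
    partial_charges: optional per-atom charges in elementary charge units.
    """

    atomic_numbers: list[int]
    formal_charges: list[int] = None
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    conformers: list[np.ndarray] = field(default_factory=list)
    partial_charges: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        n = len(self.atomic_numbers)
        if self.formal_charges is None:
            self.formal_charges = [0] * n
        if len(self.formal_charges) != n:
            raise ValueError("formal_charges length mismatch")
        seen = set()
        norm_bonds = []
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm_bonds.append((key[0], key[1], int(order)))
        self.bonds = norm_bonds
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        for c in self.conformers:
            if c.shape != (n, 3):
                raise ValueError("conformer shape mismatch")
        if self.partial_charges is not None:
            self.partial_charges = np.asarray(self.partial_charges, dtype=float)
            if self.partial_charges.shape != (n,):
                raise ValueError("partial_charges length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    # -- topology helpers ---------------------------------------------------

    def neighbors(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [sorted(x) for x in nbrs]

    def bond_tuples(self) -> list[tuple[int, int]]:
        return [canonical_key((i, j), "bond") for i, j, _ in self.bonds]

    def angle_tuples(self) -> list[tuple[int, int, int]]:
        out = []
        nbrs = self.neighbors()
        for j in range(self.n_atoms):
            ns = nbrs[j]
            for a in range(len(ns)):
                for b in range(a + 1, len(ns)):
                    out.append(canonical_key((ns[a], j, ns[b]), "angle"))
        return sorted(set(out))

    def proper_torsion_tuples(self) -> list[tuple[int, int, int, int]]:
        out = set()
        nbrs = self.neighbors()
        for j, k, _ in self.bonds:
            for i in nbrs[j]:
                if i == k:
                    continue
                for l in nbrs[k]:
                    if l == j or l == i:
                        continue
                    out.add(canonical_key((i, j, k, l), "proper_torsion"))
        return sorted(out)

    def trivalent_centers(self) -> list[int]:
        return [i for i, ns in enumerate(self.neighbors()) if len(ns) == 3]

    # -- RDKit bridge -------------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        """Build an RDKit molecule with explicit atoms/bonds, all conformers."""
        em = Chem.RWMol()
        for z, q in zip(self.atomic_numbers, self.formal_charges):
            atom = Chem.Atom(int(z))
            atom.SetFormalCharge(int(q))
            atom.SetNoImplicit(True)
            em.AddAtom(atom)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE}
        for i, j, order in self.bonds:
            em.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
        mol = em.GetMol()
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS,
        )
        for coords in self.conformers:
            conf = Chem.Conformer(self.n_atoms)
            for idx in range(self.n_atoms):
                conf.SetAtomPosition(idx, tuple(float(v) for v in coords[idx]))
            mol.AddConformer(conf, assignId=True)
        if self.name:
            mol.SetProp("_Name", self.name)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str | None = None) -> "Molecule":
        atomic_numbers = [a.GetAtomicNum() for a in mol.GetAtoms()]
        formal_charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
        bonds = []
        for b in mol.GetBonds():
            order = int(round(b.GetBondTypeAsDouble()))
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(order, 1)))
        conformers = [np.array(c.GetPositions(), dtype=float)
                      for c in mol.GetConformers()]
        charges = None
        if mol.HasProp("partial_charges"):
            charges = np.array(
                [float(x) for x in mol.GetProp("partial_charges").split()]
            )
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return cls(atomic_numbers, formal_charges, bonds, conformers, charges, name)


def write_sdf(molecules: Iterable[Molecule], path: str) -> None:
    """Write molecules (one record per conformer) to a V2000 SDF file.

    Partial charges go into the named SDF property field ``partial_charges``
    as a space-separated list.
    """
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molecules:
            rd = mol.to_rdkit()
            if mol.partial_charges is not None:
                rd.SetProp(
                    "partial_charges",
                    " ".join(f"{q:.6f}" for q in mol.partial_charges),
                )
            conf_ids = [c.GetId() for c in rd.GetConformers()] or [-1]
            for cid in conf_ids:
                writer.write(rd, confId=cid)
    finally:
        writer.close()


def read_sdf(path: str) -> list[Molecule]:
    """Read an SDF file; consecutive records with identical topology and name
    are merged into one molecule with multiple conformers."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list[Molecule] = []
    for rd in supplier:
        if rd is None:
            continue
        Chem.SanitizeMol(
            rd,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS,
        )
        mol = Molecule.from_rdkit(rd)
        if (
            out
            and out[-1].name == mol.name
            and out[-1].atomic_numbers == mol.atomic_numbers
            and out[-1].bonds == mol.bonds
        ):
            out[-1].conformers.extend(mol.conformers)
        else:
            out.append(mol)
    return out


# ---------------------------------------------------------------------------
# Force-field container
# ---------------------------------------------------------------------------


def _count_tagged_atoms(query: Chem.Mol) -> int:
    return sum(1 for a in query.GetAtoms() if a.GetAtomMapNum() > 0)


@dataclass
class SmirksParameter:
    """One SMIRKS-keyed parameter.

    ``attributes`` maps attribute names to float values in fixed units:
    bonds k (kcal/mol/Å²), length (Å); angles k (kcal/mol/rad²), angle (deg);
    torsions k1.., periodicity1.., phase1.. (kcal/mol, –, deg); vdW epsilon
    (kcal/mol) and rmin_half (Å).  ``optimize`` lists the attribute names
    whose values are free during fitting.
    """

    id: str
    smirks: str
    parameter_class: str
    attributes: dict[str, float]
    optimize: tuple[str, ...] = ()

    _query: Chem.Mol = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.parameter_class not in PARAMETER_CLASSES:
            raise ForceFieldParseError(
                f"parameter {self.id!r}: unknown class {self.parameter_class!r}"
            )
        query = Chem.MolFromSmarts(self.smirks)
        if query is None:
            raise ForceFieldParseError(
                f"parameter {self.id!r}: malformed SMIRKS {self.smirks!r}"
            )
        required = _TAGGED_ATOMS_REQUIRED[self.parameter_class]
        n_tagged = _count_tagged_atoms(query)
        if n_tagged != required:
            raise ForceFieldParseError(
                f"parameter {self.id!r}: {self.parameter_class} SMIRKS must tag "
                f"{required} atoms, found {n_tagged}"
            )
        self.attributes = {k: float(v) for k, v in self.attributes.items()}
        self.optimize = tuple(self.optimize)
        object.__setattr__(self, "_query", query)

    @property
    def query(self) -> Chem.Mol:
        return self._query

    def torsion_terms(self) -> list[tuple[float, int, float]]:
        """(k, periodicity, phase_deg) triples for torsion-class parameters."""
        terms = []
        i = 1
        while f"k{i}" in self.attributes:
            terms.append(
                (
                    self.attributes[f"k{i}"],
                    int(self.attributes.get(f"periodicity{i}", 1)),
                    self.attributes.get(f"phase{i}", 0.0),
                )
            )
            i += 1
        return terms

    def copy(self) -> "SmirksParameter":
        return SmirksParameter(
            self.id, self.smirks, self.parameter_class,
            dict(self.attributes), tuple(self.optimize),
        )


@dataclass
class ForceField:
    """Ordered SMIRKS-keyed parameter lists per interaction class."""

    parameters: dict[str, list[SmirksParameter]] = field(
        default_factory=lambda: {cls: [] for cls in PARAMETER_CLASSES}
    )
    combining_rule: str = "Lorentz-Berthelot"
    scale_vdw_14: float = SCALE_VDW_14
    scale_elec_14: float = SCALE_ELEC_14
    name: str = "forcefield"
    version: str = "0.1"
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for cls in PARAMETER_CLASSES:
            self.parameters.setdefault(cls, [])
        for cls, params in self.parameters.items():
            ids = [p.id for p in params]
            if len(ids) != len(set(ids)):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ForceFieldParseError(
                    f"duplicate parameter id(s) {dup} in class {cls!r}"
                )

    def get_parameter(self, param_id: str) -> SmirksParameter:
        for params in self.parameters.values():
            for p in params:
                if p.id == param_id:
                    return p
        raise KeyError(param_id)

    def copy(self) -> "ForceField":
        return ForceField(
            {cls: [p.copy() for p in ps] for cls, ps in self.parameters.items()},
            self.combining_rule,
            self.scale_vdw_14,
            self.scale_elec_14,
            self.name,
            self.version,
            dict(self.extras),
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "version": self.version,
            "combining_rule": self.combining_rule,
            "scale_vdw_14": self.scale_vdw_14,
            "scale_elec_14": self.scale_elec_14,
            "parameters": {
                cls: [
                    {
                        "id": p.id,
                        "smirks": p.smirks,
                        "attributes": p.attributes,
                        "optimize": list(p.optimize),
                    }
                    for p in params
                ]
                for cls, params in self.parameters.items()
            },
            "extras": self.extras,
        }
        return json.dumps(doc, indent=2)

    def to_xml(self) -> str:
        root = ET.Element("SMIRNOFF", version=self.version, name=self.name)
        for cls in PARAMETER_CLASSES:
            sec_name, tag = _XML_SECTION[cls]
            attrib = {}
            if cls == "vdw":
                attrib = {
                    "combining_rule": self.combining_rule,
                    "scale14": repr(self.scale_vdw_14),
                }
            sec = ET.SubElement(root, sec_name, attrib)
            for p in self.parameters[cls]:
                el = ET.SubElement(sec, tag, id=p.id, smirks=p.smirks)
                for key, val in p.attributes.items():
                    el.set(key, repr(val))
                if p.optimize:
                    el.set("parameterize", ",".join(p.optimize))
        ET.SubElement(root, "Electrostatics", scale14=repr(self.scale_elec_14))
        for tag, payload in self.extras.items():
            root.append(ET.fromstring(payload))
        ET.indent(root)
        return ET.tostring(root, encoding="unicode")

    def serialize(self, dialect: str = "xml") -> str:
        return self.to_xml() if dialect == "xml" else self.to_json()


def _forcefield_from_json(text: str) -> ForceField:
    doc = json.loads(text)
    params = {
        cls: [
            SmirksParameter(
                entry["id"], entry["smirks"], cls,
                entry["attributes"], tuple(entry.get("optimize", ())),
            )
            for entry in doc.get("parameters", {}).get(cls, [])
        ]
        for cls in PARAMETER_CLASSES
    }
    return ForceField(
        params,
        doc.get("combining_rule", "Lorentz-Berthelot"),
        float(doc.get("scale_vdw_14", SCALE_VDW_14)),
        float(doc.get("scale_elec_14", SCALE_ELEC_14)),
        doc.get("name", "forcefield"),
        doc.get("version", "0.1"),
        doc.get("extras", {}),
    )


def _forcefield_from_xml(text: str) -> ForceField:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ForceFieldParseError(f"malformed XML: {exc}") from exc
    ff_kwargs = dict(
        name=root.get("name", "forcefield"), version=root.get("version", "0.1")
    )
    params: dict[str, list[SmirksParameter]] = {cls: [] for cls in PARAMETER_CLASSES}
    extras: dict[str, str] = {}
    scale_vdw, scale_elec = SCALE_VDW_14, SCALE_ELEC_14
    combining = "Lorentz-Berthelot"
    for sec in root:
        if sec.tag == "Electrostatics":
            scale_elec = float(sec.get("scale14", SCALE_ELEC_14))
            continue
        cls = _XML_CLASS_BY_SECTION.get(sec.tag)
        if cls is None:
            # unknown sections are preserved verbatim on round-trip
            extras[sec.tag] = ET.tostring(sec, encoding="unicode")
            continue
        if cls == "vdw":
            combining = sec.get("combining_rule", combining)
            scale_vdw = float(sec.get("scale14", scale_vdw))
        for el in sec:
            attrs = {
                k: float(v)
                for k, v in el.attrib.items()
                if k not in ("id", "smirks", "parameterize")
            }
            optimize = tuple(
                s for s in el.get("parameterize", "").split(",") if s
            )
            params[cls].append(
                SmirksParameter(el.get("id"), el.get("smirks"), cls, attrs, optimize)
            )
    return ForceField(
        params, combining, scale_vdw, scale_elec,
        ff_kwargs["name"], ff_kwargs["version"], extras,
    )


def parse_forcefield(text: str) -> ForceField:
    """Parse a force-field document (XML subset or JSON, auto-detected)."""
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _forcefield_from_json(text)
    return _forcefield_from_xml(text)


# ---------------------------------------------------------------------------
# Canonical keys and assignment
# ---------------------------------------------------------------------------


def canonical_key(atom_tuple: Sequence[int], parameter_class: str) -> tuple:
    """Canonical atom-index tuple so a tuple and its reverse collapse to one.

    bond (i,j): i < j.  angle (i,j,k): i < k.  proper torsion (i,j,k,l):
    oriented so the inner pair (j,k) is ascending (ties broken on the outer
    pair).  improper: (n1, center, n2, n3) with the three neighbors sorted,
    center in second position.  vdW: 1-tuple unchanged.
    """
    t = tuple(int(x) for x in atom_tuple)
    if parameter_class == "vdw":
        if len(t) != 1:
            raise ValueError("vdw key must have 1 atom")
        return t
    if parameter_class == "bond":
        if len(t) != 2:
            raise ValueError("bond key must have 2 atoms")
        return (min(t), max(t))
    if parameter_class == "angle":
        if len(t) != 3:
            raise ValueError("angle key must have 3 atoms")
        i, j, k = t
        return (i, j, k) if i <= k else (k, j, i)
    if parameter_class == "proper_torsion":
        if len(t) != 4:
            raise ValueError("torsion key must have 4 atoms")
        i, j, k, l = t
        if (j, k, i, l) <= (k, j, l, i):
            return (i, j, k, l)
        return (l, k, j, i)
    if parameter_class == "improper_torsion":
        if len(t) != 4:
            raise ValueError("improper key must have 4 atoms")
        center = t[1]
        n1, n2, n3 = sorted((t[0], t[2], t[3]))
        return (n1, center, n2, n3)
    raise ValueError(f"unknown parameter class {parameter_class!r}")


@dataclass
class ParameterAssignment:
    """Per-class mapping canonical atom-index tuple -> parameter id."""

    bond: dict[tuple, str] = field(default_factory=dict)
    angle: dict[tuple, str] = field(default_factory=dict)
    proper_torsion: dict[tuple, str] = field(default_factory=dict)
    improper_torsion: dict[tuple, str] = field(default_factory=dict)
    vdw: dict[tuple, str] = field(default_factory=dict)

    def by_class(self, parameter_class: str) -> dict[tuple, str]:
        return getattr(self, parameter_class)

    def parameter_ids(self) -> set[str]:
        out: set[str] = set()
        for cls in PARAMETER_CLASSES:
            out.update(self.by_class(cls).values())
        return out

    def to_json(self) -> str:
        doc = {
            cls: {",".join(map(str, key)): pid
                  for key, pid in sorted(self.by_class(cls).items())}
            for cls in PARAMETER_CLASSES
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _matches(rdmol: Chem.Mol, param: SmirksParameter) -> list[tuple[int, ...]]:
    """Tagged-atom index tuples for every embedding of the pattern."""
    query = param.query
    tag_order = sorted(
        (a.GetAtomMapNum(), a.GetIdx())
        for a in query.GetAtoms()
        if a.GetAtomMapNum() > 0
    )
    positions = [idx for _, idx in tag_order]
    hits = rdmol.GetSubstructMatches(query, uniquify=False, maxMatches=100000)
    return [tuple(hit[p] for p in positions) for hit in hits]


def assign_parameters(mol: Molecule, ff: ForceField) -> ParameterAssignment:
    """Direct chemical perception: last matching parameter in list order wins.

    Raises :class:`UnassignedChemistryError` if any bond/angle/proper-torsion
    tuple or atom receives no parameter.  Impropers apply only where matched.
    """
    rdmol = mol.to_rdkit()
    assignment = ParameterAssignment()

    for cls in PARAMETER_CLASSES:
        table = assignment.by_class(cls)
        for param in ff.parameters[cls]:
            for match in _matches(rdmol, param):
                if cls == "improper_torsion":
                    # tagged order is (n1, center, n2, n3)
                    key = canonical_key(match, cls)
                else:
                    key = canonical_key(match, cls)
                table[key] = param.id

    expected = {
        "bond": mol.bond_tuples(),
        "angle": mol.angle_tuples(),
        "proper_torsion": mol.proper_torsion_tuples(),
        "vdw": [(i,) for i in range(mol.n_atoms)],
    }
    for cls, tuples in expected.items():
        table = assignment.by_class(cls)
        missing = [t for t in tuples if t not in table]
        # drop matches that are not actual bonded tuples of the molecule
        for key in list(table):
            if key not in set(tuples):
                del table[key]
        if missing:
            raise UnassignedChemistryError(cls, missing)

    # impropers: keep only keys whose center is trivalent in the topology
    centers = set(mol.trivalent_centers())
    nbrs = mol.neighbors()
    for key in list(assignment.improper_torsion):
        center = key[1]
        neighbors_ok = centers and center in centers and set(
            (key[0], key[2], key[3])
        ) == set(nbrs[center])
        if not neighbors_ok:
            del assignment.improper_torsion[key]
    return assignment


def applied_parameter_counts(
    mols: Sequence[Molecule], ff: ForceField
) -> dict[str, int]:
    """Number of distinct molecules on which each parameter id is applied."""
    counts: dict[str, int] = {}
    for cls in PARAMETER_CLASSES:
        for p in ff.parameters[cls]:
            counts[p.id] = 0
    for mol in mols:
        used = assign_parameters(mol, ff).parameter_ids()
        for pid in used:
            counts[pid] += 1
    return counts
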