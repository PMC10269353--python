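"""Benchmark statistics for force-field evaluation.

Geometric metrics compare MM-optimized conformers with their reference
(typically QM-optimized) counterparts: optimal-superposition RMSD, torsion
fingerprint deviation (TFD), internal-coordinate RMSDs, and the relative
conformer-energy error ΔΔE (both energy scales referenced to the reference
minimum-energy conformer, which is excluded from summaries).

Free-energy-facing statistics consume result tables of simulated versus
experimental observables: RMSE and mean signed error with percentile
bootstrap CIs, the paired mean shift in unsigned error between a refit and a
reference force field, transfer free energies composed from two solvation
free energies, and a Gaussian deconvolution of the shift variance into
force-field versus simulation-noise contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import TorsionFingerprints

from smirkfit.chem_model import Molecule
from smirkfit.fit_targets import internal_coordinates
from smirkfit.mm_engine import _wrap_deg


@dataclass
class ConformerComparison:
    molecule_id: str
    conformer_id: str
    rmsd: float
    tfd: float | None  # None when undefined (no nonterminal rotatable bonds)
    dde: float | None
    bond_rmsd: float
    angle_rmsd: float
    improper_deviations: dict[tuple, float] = field(default_factory=dict)
    applied_parameters: tuple[str, ...] = ()

    @property
    def tfd_defined(self) -> bool:
        return self.tfd is not None


@dataclass
class FreeEnergyRecord:
    system_id: str
    o_sim: float  # kcal/mol
    o_exp: float  # kcal/mol
    uncertainty: float = 0.0
    solute: str = ""
    solvent: str = ""

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


# ---------------------------------------------------------------------------
# Geometry metrics
# ---------------------------------------------------------------------------


def rmsd(
    conf_a: np.ndarray,
    conf_b: np.ndarray,
    atom_subset: Sequence[int] | None = None,
) -> float:
    """Optimal-superposition (Kabsch) RMSD in Å.

    Both conformers are centered, the optimal proper rotation is found by SVD
    with determinant correction, and the RMSD of the superposed subsets is
    returned.  Symmetric in its arguments and zero iff superposable.
    """
    a = np.asarray(conf_a, dtype=float)
    b = np.asarray(conf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conformers must have the same atom count")
    if atom_subset is not None:
        sel = np.asarray(list(atom_subset), dtype=int)
        a, b = a[sel], b[sel]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (rot @ a.T).T - b
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def tfd(mol: Molecule, conf_a: np.ndarray, conf_b: np.ndarray) -> float | None:
    """Torsion fingerprint deviation in [0, 1], or None when undefined.

    Uses the reference implementation of the TFD method (torsion enumeration
    over nonterminal rotatable bonds and ring systems, deviations normalized
    per torsion, weighted by topological distance from the molecular center).
    A molecule with no nonterminal rotatable bonds has no fingerprint and
    returns None — an explicit flag, never a silent 0.
    """
    work = Molecule(
        list(mol.atomic_numbers),
        list(mol.formal_charges),
        list(mol.bonds),
        [np.asarray(conf_a, float), np.asarray(conf_b, float)],
        None,
        mol.name,
    )
    rd = work.to_rdkit()
    try:
        tl, tlr = TorsionFingerprints.CalculateTorsionLists(rd)
        if not tl and not tlr:
            return None
        values = TorsionFingerprints.GetTFDBetweenConformers(
            rd, confIds1=[0], confIds2=[1]
        )
    except (IndexError, ValueError, ZeroDivisionError):
        return None
    if not values or not np.isfinite(values[0]):
        return None
    return float(values[0])


def internal_coord_rmsd(
    mol: Molecule, conf_ref: np.ndarray, conf_mm: np.ndarray
) -> tuple[float, float, dict[tuple, float]]:
    """(bond RMSD Å, angle RMSD deg, per-center improper deviations deg)."""
    ref = internal_coordinates(mol, conf_ref)
    mm = internal_coordinates(mol, conf_mm)
    bond_dev = np.array([ref.bonds[k] - mm.bonds[k] for k in ref.bonds])
    angle_dev = np.array(
        [_wrap_deg(ref.angles[k] - mm.angles[k]) for k in ref.angles]
    )
    improper_dev = {
        k: float(_wrap_deg(ref.impropers[k] - mm.impropers[k]))
        for k in ref.impropers
    }
    bond_rmsd = float(np.sqrt(np.mean(bond_dev**2))) if len(bond_dev) else 0.0
    angle_rmsd = float(np.sqrt(np.mean(angle_dev**2))) if len(angle_dev) else 0.0
    return bond_rmsd, angle_rmsd, improper_dev


# ---------------------------------------------------------------------------
# Relative conformer energies
# ---------------------------------------------------------------------------


def ddE_stats(
    qm_energies: Sequence[float], mm_energies: Sequence[float]
) -> tuple[np.ndarray, dict]:
    """Per-conformer ΔΔE and summary statistics for one molecule.

    ΔΔE_i = (E_MM,i − E_MM,0) − (E_QM,i − E_QM,0) with conformer 0 the
    reference (QM) minimum-energy conformer.  That conformer has ΔΔE = 0 by
    construction and is excluded from the summary so results are not skewed
    toward zero.  Molecules with fewer than 2 conformers are rejected.
    """
    qm = np.asarray(qm_energies, dtype=float)
    mm = np.asarray(mm_energies, dtype=float)
    if qm.shape != mm.shape:
        raise ValueError("QM and MM energy lists must align")
    if len(qm) < 2:
        raise ValueError("ddE requires at least 2 conformers")
    ref = int(np.argmin(qm))
    dde = (mm - mm[ref]) - (qm - qm[ref])
    rest = np.delete(dde, ref)
    summary = {
        "n": int(len(rest)),
        "reference_conformer": ref,
        "rmse": float(np.sqrt(np.mean(rest**2))),
        "mean": float(np.mean(rest)),
        "mae": float(np.mean(np.abs(rest))),
    }
    return dde, summary


# ---------------------------------------------------------------------------
# Free-energy statistics
# ---------------------------------------------------------------------------


def _pair_records(records_a, records_b):
    a_map = {r.system_id: r for r in records_a}
    b_map = {r.system_id: r for r in records_b}
    common = sorted(set(a_map) & set(b_map))
    if not common:
        raise ValueError("no systems are paired between the two record sets")
    return [(a_map[s], b_map[s]) for s in common]


def mean_shift(
    records_new: Sequence[FreeEnergyRecord],
    records_ref: Sequence[FreeEnergyRecord],
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict:
    """Mean change in unsigned error of the refit vs the reference field.

    shift_s = |O_sim,new − O_exp| − |O_sim,ref − O_exp| per paired system;
    negative means the refit improved.  The 95% CI is a percentile bootstrap
    resampling paired systems with the recorded seed.
    """
    pairs = _pair_records(records_new, records_ref)
    shifts = np.array(
        [abs(n.o_sim - n.o_exp) - abs(r.o_sim - r.o_exp) for n, r in pairs]
    )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(shifts), size=(n_bootstrap, len(shifts)))
    boot = shifts[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {
        "mean_shift": float(shifts.mean()),
        "ci95": (float(lo), float(hi)),
        "shifts": shifts,
        "n": len(shifts),
        "seed": seed,
    }


def transfer_free_energy(dg_solv_aq: float, dg_solv_nonaq: float) -> float:
    """ΔG_trans(aq → nonaq) = ΔG_solv(nonaq) − ΔG_solv(aq), kcal/mol."""
    if dg_solv_aq is None or dg_solv_nonaq is None:
        raise ValueError("both solvation free energies are required")
    return float(dg_solv_nonaq) - float(dg_solv_aq)


def rmse_with_ci(
    records: Sequence[FreeEnergyRecord],
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict:
    """RMSE and mean signed error vs experiment with percentile bootstrap CIs."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    err = np.array([r.o_sim - r.o_exp for r in records])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(err), size=(n_bootstrap, len(err)))
    samples = err[idx]
    boot_rmse = np.sqrt(np.mean(samples**2, axis=1))
    boot_mse = samples.mean(axis=1)
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "rmse_ci95": tuple(float(x) for x in np.percentile(boot_rmse, [2.5, 97.5])),
        "mse": float(err.mean()),
        "mse_ci95": tuple(float(x) for x in np.percentile(boot_mse, [2.5, 97.5])),
        "n": len(err),
        "seed": seed,
    }


def variance_deconvolution(
    shifts: Sequence[float], mean_propagated_uncertainty: float
) -> dict:
    """Fraction of shift variance attributable to the force-field change.

    Fits a Gaussian to the shifts and assumes the simulation noise is
    zero-mean Gaussian with σ equal to the mean propagated uncertainty:
    fraction = max(0, s² − σ_noise²)/s².  Points beyond 2σ of the fitted
    Gaussian are listed as outliers.
    """
    shifts = np.asarray(shifts, dtype=float)
    if len(shifts) < 3:
        raise ValueError("need at least 3 shifts")
    if mean_propagated_uncertainty < 0:
        raise ValueError("uncertainty must be >= 0")
    s2 = float(np.var(shifts, ddof=1))
    if s2 == 0:
        return {"fraction": None, "undefined": True, "outliers": []}
    noise2 = mean_propagated_uncertainty**2
    fraction = max(0.0, s2 - noise2) / s2
    mu, sd = float(np.mean(shifts)), float(np.sqrt(s2))
    outliers = [int(i) for i in np.where(np.abs(shifts - mu) > 2 * sd)[0]]
    return {
        "fraction": fraction,
        "undefined": False,
        "outliers": outliers,
        "sample_variance": s2,
        "noise_variance": noise2,
    }


# ---------------------------------------------------------------------------
# TFD-outlier parameter enrichment
# ---------------------------------------------------------------------------


def enrichment_ratio(
    comparisons: Sequence[ConformerComparison],
    parameter_id: str,
    tfd_threshold: float = 0.1,
    normalized: bool = True,
) -> dict:
    """Over-representation of a parameter among high-TFD molecules.

    normalized (default): [n(param ∧ TFD>thr)/n(TFD>thr)] / [n(param)/n_total]
    — 1 means the parameter is applied at the background rate among high-TFD
    molecules.  The literal ratio n(param ∧ TFD>thr)/n(param) is available
    with ``normalized=False``.  Molecules with undefined TFD are excluded
    from every count; zero denominators yield an undefined-result flag.
    """
    defined = [c for c in comparisons if c.tfd_defined]
    n_total = len(defined)
    high = [c for c in defined if c.tfd > tfd_threshold]
    with_param = [c for c in defined if parameter_id in c.applied_parameters]
    high_with_param = [c for c in high if parameter_id in c.applied_parameters]
    if n_total == 0 or not with_param or (normalized and not high):
        return {"ratio": None, "undefined": True}
    if normalized:
        ratio = (len(high_with_param) / len(high)) / (len(with_param) / n_total)
    else:
        ratio = len(high_with_param) / len(with_param)
    return {
        "ratio": float(ratio),
        "undefined": False,
        "n_total": n_total,
        "n_high": len(high),
        "n_param": len(with_param),
        "n_high_param": len(high_with_param),
    }


def comparisons_to_frame(comparisons: Sequence[ConformerComparison]) -> pd.DataFrame:
    """Tidy per-conformer metric table."""
    return pd.DataFrame(
        {
            "molecule_id": [c.molecule_id for c in comparisons],
            "conformer_id": [c.conformer_id for c in comparisons],
            "rmsd": [c.rmsd for c in comparisons],
            "tfd": [c.tfd for c in comparisons],
            "dde": [c.dde for c in comparisons],
            "bond_rmsd": [c.bond_rmsd for c in comparisons],
            "angle_rmsd": [c.angle_rmsd for c in comparisons],
        }
    )


def records_from_csv(path: str) -> list[FreeEnergyRecord]:
    """Free-energy CSV: system_id, o_sim, o_exp, uncertainty[, solute, solvent]."""
    df = pd.read_csv(path)
    return [
        FreeEnergyRecord(
            str(row["system_id"]),
            float(row["o_sim"]),
            float(row["o_exp"]),
            float(row.get("uncertainty", 0.0) or 0.0),
            str(row.get("solute", "") or ""),
            str(row.get("solvent", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def records_to_csv(records: Sequence[FreeEnergyRecord], path: str) -> None:
    pd.DataFrame(
        {
            "system_id": [r.system_id for r in records],
            "o_sim": [r.o_sim for r in records],
            "o_exp": [r.o_exp for r in records],
            "uncertainty": [r.uncertainty for r in records],
            "solute": [r.solute for r in records],
            "solvent": [r.solvent for r in records],
        }
    ).to_csv(path, index=False)
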