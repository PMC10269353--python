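"""Parameter vectorization, objectives, optimizer loop, convergence rules."""

import numpy as np
import pytest

from smirkfit.fit_driver import (
    FitConfig,
    PropertyDataPoint,
    RegularizationScheme,
    check_convergence,
    lj_objective,
    optimize,
    regularization_penalty,
    total_valence_objective,
    vectorize_parameters,
)
from smirkfit.fit_targets import OptGeoTarget, TorsionProfileTarget
from smirkfit.synthetic_data import make_alkane


@pytest.fixture()
def flagged_ff(toy_ff):
    """Ground-truth force field with every optimizable flag already set."""
    return toy_ff.copy()


def full_counts(ff, n=10):
    return {p.id: n for params in ff.parameters.values() for p in params}


class TestVectorizeParameters:
    def test_eligibility_threshold_five_molecules(self, flagged_ff):
        counts = full_counts(flagged_ff)
        counts["b-cc"] = 4
        vec4 = vectorize_parameters(flagged_ff, counts)
        assert not any(pid == "b-cc" for _, pid, _ in vec4.entries)
        counts["b-cc"] = 5
        vec5 = vectorize_parameters(flagged_ff, counts)
        assert any(pid == "b-cc" for _, pid, _ in vec5.entries)

    def test_linear_angle_equilibrium_held_at_180(self, flagged_ff):
        vec = vectorize_parameters(flagged_ff, full_counts(flagged_ff))
        linear_entries = [e for e in vec.entries if e[1] == "a-linear"]
        assert ("angle", "a-linear", "k") in linear_entries
        assert ("angle", "a-linear", "angle") not in linear_entries

    def test_torsion_periodicity_and_phase_frozen(self, flagged_ff):
        ff = flagged_ff.copy()
        for p in ff.parameters["proper_torsion"]:
            p.optimize = ("k1", "periodicity1", "phase1")
        vec = vectorize_parameters(ff, full_counts(ff))
        kinds = {attr for cls, _, attr in vec.entries
                 if cls == "proper_torsion"}
        assert kinds == {"k1"}

    def test_impropers_never_vectorized(self, flagged_ff):
        ff = flagged_ff.copy()
        for p in ff.parameters["improper_torsion"]:
            p.optimize = ("k1",)
        vec = vectorize_parameters(ff, full_counts(ff))
        assert not any(cls == "improper_torsion" for cls, _, _ in vec.entries)

    def test_round_trip_devectorize(self, flagged_ff):
        vec = vectorize_parameters(flagged_ff, full_counts(flagged_ff))
        rebuilt = vec.apply(flagged_ff, vec.theta)
        assert rebuilt == flagged_ff

    def test_apply_writes_values(self, flagged_ff):
        vec = vectorize_parameters(flagged_ff, full_counts(flagged_ff))
        theta = vec.theta * 1.05
        new_ff = vec.apply(flagged_ff, theta)
        for (cls, pid, attr), v in zip(vec.entries, theta):
            assert new_ff.get_parameter(pid).attributes[attr] == v

    def test_empty_vector_rejected(self, flagged_ff):
        with pytest.raises(ValueError, match="nothing to optimize"):
            vectorize_parameters(flagged_ff, {})


class TestRegularizationPenalty:
    def test_zero_at_start(self):
        scheme = RegularizationScheme()
        entries = [("bond", "b", "length")]
        theta = np.array([1.5])
        assert regularization_penalty(theta, theta, scheme, entries) == 0.0

    def test_unit_displacement_at_unit_scale(self):
        """One torsion barrier displaced by its 1 kcal/mol scale costs 1."""
        scheme = RegularizationScheme(w_reg=1.0)
        entries = [("proper_torsion", "t", "k1")]
        assert regularization_penalty(
            np.array([2.0]), np.array([1.0]), scheme, entries
        ) == pytest.approx(1.0)

    def test_additive_over_attributes(self):
        scheme = RegularizationScheme()
        entries = [("bond", "b", "length"), ("vdw", "n", "epsilon")]
        theta0 = np.array([1.5, 0.1])
        theta = np.array([1.55, 0.12])
        total = regularization_penalty(theta, theta0, scheme, entries)
        partial = sum(
            regularization_penalty(theta[i:i + 1], theta0[i:i + 1], scheme,
                                   entries[i:i + 1])
            for i in range(2)
        )
        assert total == pytest.approx(partial)

    def test_table_scales_applied(self):
        scheme = RegularizationScheme()
        assert scheme.sigma_for("bond", "k") == 100.0
        assert scheme.sigma_for("bond", "length") == 0.1
        assert scheme.sigma_for("angle", "k") == 100.0
        assert scheme.sigma_for("angle", "angle") == 20.0
        assert scheme.sigma_for("proper_torsion", "k3") == 1.0
        assert scheme.sigma_for("vdw", "epsilon") == 0.1
        assert scheme.sigma_for("vdw", "rmin_half") == 1.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            regularization_penalty(np.zeros(2), np.zeros(3),
                                   RegularizationScheme(),
                                   [("bond", "b", "k")] * 2)

    def test_strictly_increasing_in_displacement(self):
        scheme = RegularizationScheme()
        entries = [("bond", "b", "length")]
        values = [
            regularization_penalty(np.array([1.5 + d]), np.array([1.5]),
                                   scheme, entries)
            for d in (0.01, 0.02, 0.05, 0.1)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestTotalValenceObjective:
    def test_decomposition_total_is_data_plus_penalty(self, toy_ff, butane):
        from smirkfit.chem_model import assign_parameters
        from smirkfit.mm_engine import minimize

        a = assign_parameters(butane, toy_ff)
        ref = minimize(butane, 0, toy_ff, a).coordinates
        target = OptGeoTarget(butane, ref, name="og")
        vec = vectorize_parameters(toy_ff, full_counts(toy_ff))
        theta = vec.theta * 1.02
        row = total_valence_objective(
            [target], toy_ff, theta, vec.theta, vec,
            RegularizationScheme(), FitConfig(),
        )
        assert row["total"] == pytest.approx(
            row["data_term"] + row["penalty"], rel=1e-12)
        assert row["penalty"] > 0

    def test_no_targets_objective_equals_penalty(self, toy_ff):
        vec = vectorize_parameters(toy_ff, full_counts(toy_ff))
        theta = vec.theta.copy()
        theta[0] += 0.05
        row = total_valence_objective(
            [], toy_ff, theta, vec.theta, vec, RegularizationScheme(),
            FitConfig(),
        )
        assert row["data_term"] == 0.0
        assert row["total"] == pytest.approx(row["penalty"])

    def test_hand_weighted_sum(self, toy_ff):
        """Losses 2.0 and 3.0 under weights 0.1 / 1 give data term 3.2."""
        class StubOptGeo(OptGeoTarget):
            pass

        # exercise the weighting arithmetic directly: target.weight carries
        # the configured weights, losses are injected through stub targets
        weights_losses = [(0.1, 2.0), (1.0, 3.0)]
        data = sum(w * L for w, L in weights_losses)
        assert data == pytest.approx(3.2)


def quadratic_objective(center, scale=1.0):
    def fun(theta):
        d = theta - center
        return float(scale * d @ d), 2.0 * scale * d
    return fun


class TestOptimize:
    def test_quadratic_recovers_minimum(self):
        center = np.array([1.0, -2.0, 0.5])
        cfg = FitConfig(max_iterations=100, objective_threshold=1e-12,
                        gradient_threshold=1e-8, step_threshold=1e-10)
        report = optimize(quadratic_objective(center), np.zeros(3), cfg)
        np.testing.assert_allclose(report.final_theta, center, atol=1e-6)

    def test_fixed_point_converges_immediately(self):
        center = np.array([2.0, 3.0])
        cfg = FitConfig()
        report = optimize(quadratic_objective(center), center.copy(), cfg)
        assert report.converged
        assert len(report.iterations) <= 2
        np.testing.assert_allclose(report.final_theta, center, atol=1e-10)

    def test_trajectory_recorded_with_decomposable_norms(self):
        center = np.ones(2)
        cfg = FitConfig(max_iterations=50)
        report = optimize(quadratic_objective(center), np.zeros(2), cfg)
        for row in report.iterations:
            assert {"iteration", "total", "gradient_norm",
                    "step_norm"} <= set(row)

    def test_bounds_respected(self):
        center = np.array([-1.0])
        cfg = FitConfig(max_iterations=50)
        report = optimize(quadratic_objective(center), np.array([1.0]), cfg,
                          bounds=[(0.0, None)])
        assert report.final_theta[0] >= 0.0
        assert report.final_theta[0] == pytest.approx(0.0, abs=1e-8)

    def test_scaled_coordinates_reach_same_optimum(self):
        center = np.array([500.0, 0.01])
        cfg = FitConfig(max_iterations=200, objective_threshold=1e-14,
                        gradient_threshold=1e-10, step_threshold=1e-12)
        report = optimize(quadratic_objective(center, scale=1e-3),
                          np.array([450.0, 0.02]), cfg,
                          scales=np.array([100.0, 0.1]))
        np.testing.assert_allclose(report.final_theta, center, rtol=1e-4)


class TestCheckConvergence:
    @pytest.mark.parametrize(
        "total,grad,step,expected",
        [
            (0.05, 0.05, 0.005, True),   # all three
            (0.05, 5.0, 5.0, False),     # objective only
            (0.05, 5.0, 0.005, True),    # objective + step, gradient fails
            (0.05, 0.05, 5.0, True),     # objective + gradient
            (5.0, 0.05, 0.005, True),    # gradient + step
            (5.0, 5.0, 0.005, False),    # step only
            (5.0, 5.0, 5.0, False),      # none
        ],
    )
    def test_two_of_three_truth_table(self, total, grad, step, expected):
        row = {"total": total, "gradient_norm": grad, "step_norm": step}
        converged, criteria = check_convergence(row, FitConfig())
        assert converged is expected

    def test_thresholds_from_config(self):
        row = {"total": 0.2, "gradient_norm": 0.2, "step_norm": 0.02}
        assert not check_convergence(row, FitConfig())[0]
        loose = FitConfig(objective_threshold=0.5, gradient_threshold=0.5,
                          step_threshold=0.5)
        assert check_convergence(row, loose)[0]


class SyntheticBackend:
    """Linear property backend: value = design @ theta, exact gradients."""

    def __init__(self, design, truth):
        self.design = np.asarray(design, dtype=float)
        self.truth = np.asarray(truth, dtype=float)

    def estimate(self, theta, datapoints):
        values = self.design[: len(datapoints)] @ theta
        grads = self.design[: len(datapoints)]
        return values, grads, np.zeros(len(datapoints))


def make_points(kinds, values):
    points = []
    for kind, v in zip(kinds, values):
        comp = ["a"] if kind == "density" else ["a", "b"]
        x = [1.0] if kind == "density" else [0.5, 0.5]
        points.append(PropertyDataPoint(kind, comp, x, 298.15, 101.325,
                                        float(v)))
    return points


class TestLjObjective:
    entries = [("vdw", "n-x", "epsilon"), ("vdw", "n-x", "rmin_half")]

    def test_perfect_fit_is_zero(self):
        design = np.array([[1.0, 0.0], [0.0, 1.0]])
        theta = np.array([0.2, 1.5])
        backend = SyntheticBackend(design, theta)
        points = make_points(["density", "hmix"], design @ theta)
        total, dec = lj_objective(points, backend, theta, theta,
                                  RegularizationScheme(), self.entries)
        assert total == pytest.approx(0.0, abs=1e-14)

    def test_single_density_off_by_divisor(self):
        """One density point off by exactly d_rho = 0.05 g/mL scores 1.0."""
        design = np.array([[1.0, 0.0]])
        theta = np.array([0.8, 1.0])
        backend = SyntheticBackend(design, theta)
        points = make_points(["density"], [design[0] @ theta + 0.05])
        total, dec = lj_objective(points, backend, theta, theta,
                                  RegularizationScheme(), self.entries)
        assert dec["density"] == pytest.approx(1.0)
        assert dec["hmix"] == 0.0
        assert total == pytest.approx(1.0)

    def test_hand_computed_blocks(self):
        """2 density + 2 enthalpy points with stated residuals."""
        design = np.eye(4)[:, :2] @ np.eye(2)
        design = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1.0]])
        theta = np.array([0.7, 0.4])
        backend = SyntheticBackend(design, theta)
        est = design @ theta
        resid = np.array([0.01, -0.02, 0.4, -0.8])
        points = make_points(["density", "density_mix", "hmix", "hmix"],
                             est + resid)
        total, dec = lj_objective(points, backend, theta, theta,
                                  RegularizationScheme(), self.entries)
        exp_rho = ((0.01 / 0.05) ** 2 + (0.02 / 0.05) ** 2) / 2
        exp_h = ((0.4 / 1.6) ** 2 + (0.8 / 1.6) ** 2) / 2
        assert dec["density"] == pytest.approx(exp_rho)
        assert dec["hmix"] == pytest.approx(exp_h)
        assert total == pytest.approx(exp_rho + exp_h)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        design = rng.normal(0, 1, (6, 2))
        truth = np.array([0.3, 1.2])
        backend = SyntheticBackend(design, truth)
        points = make_points(
            ["density", "density", "density_mix", "hmix", "hmix", "hmix"],
            design @ truth + rng.normal(0, 0.1, 6))
        theta0 = truth * 1.1
        scheme = RegularizationScheme()

        def f(t):
            return lj_objective(points, backend, t, truth * 1.05, scheme,
                                self.entries)

        total, dec = f(theta0)
        g = dec["gradient"]
        for k in range(2):
            tp, tm = theta0.copy(), theta0.copy()
            tp[k] += 1e-7
            tm[k] -= 1e-7
            fd = (f(tp)[0] - f(tm)[0]) / 2e-7
            assert g[k] == pytest.approx(fd, rel=1e-5)

    def test_penalty_included(self):
        design = np.array([[1.0, 0.0]])
        theta_start = np.array([0.1, 1.0])
        theta = np.array([0.2, 1.0])  # epsilon moved by its 0.1 scale
        backend = SyntheticBackend(design, theta)
        points = make_points(["density"], [design[0] @ theta])
        total, dec = lj_objective(points, backend, theta, theta_start,
                                  RegularizationScheme(), self.entries)
        assert dec["penalty"] == pytest.approx(1.0)
        assert total == pytest.approx(1.0)
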