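"""Fixed-point finder: Jacobians, oracle equivalence, stability, surveys."""

import numpy as np
import pytest

import actbias as ab
from actbias.fixedpoints import (
    FixedPoint,
    cddm_survey_inputs,
    classify_stability,
    find_fixed_points_for_input,
    rhs_and_jacobian,
    value_task_survey_inputs,
)
from actbias.rnn import ActivationSpec
from helpers import bisection_roots, line_trajectories, scalar_params


class TestRhsAndJacobian:
    def test_trivial_case(self):
        p = scalar_params("tanh", 0.0, 0.0)
        f, j = rhs_and_jacobian(np.zeros(1), np.zeros(1), p)
        assert f[0] == 0.0 and j[0, 0] == -1.0

    def test_scalar_tanh_jacobian(self):
        # J = -1 + w * (1 - tanh(w*y + b)^2); at y=0, b=0, w=2 -> +1
        p = scalar_params("tanh", 2.0)
        _, j = rhs_and_jacobian(np.zeros(1), np.zeros(1), p)
        assert j[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["sigmoid", "tanh"])
    def test_jacobian_matches_finite_differences(self, kind):
        rng = np.random.default_rng(0)
        p = ab.initialize_rnn(kind, False, n_units=6, n_in=2, n_out=1, seed=1)
        y = rng.standard_normal(6) * 0.5
        u = rng.standard_normal(2) * 0.5
        _, j = rhs_and_jacobian(y, u, p)
        h = 1e-6
        fd = np.empty_like(j)
        for k in range(6):
            e = np.zeros(6)
            e[k] = h
            fd[:, k] = (rhs_and_jacobian(y + e, u, p)[0]
                        - rhs_and_jacobian(y - e, u, p)[0]) / (2 * h)
        assert np.allclose(j, fd, atol=1e-5)


class TestScalarOracle:
    def test_bistable_tanh_finds_all_three_roots(self):
        p = scalar_params("tanh", 2.0)
        fps = find_fixed_points_for_input(
            np.zeros(1), line_trajectories(), p, seed=0)
        coords = sorted(fp.coords[0] for fp in fps)
        assert len(coords) == 3
        assert coords[1] == pytest.approx(0.0, abs=1e-6)
        assert coords[2] == pytest.approx(0.957504, abs=1e-4)

    def test_zero_recurrence_unique_fixed_point(self):
        for kind in ("relu", "sigmoid", "tanh"):
            p = scalar_params(kind, 0.0, 1.0)
            u = np.array([0.3])
            fps = find_fixed_points_for_input(u, line_trajectories(), p,
                                              seed=1)
            assert len(fps) == 1
            expected = p.activation.f(np.array([0.3]))[0]
            assert fps[0].coords[0] == pytest.approx(expected, abs=1e-8)

    def test_finder_matches_bisection_over_random_draws(self):
        """Root sets agree with the scalar bisection oracle on 20 random
        (activation, weight, input) draws; degenerate tangencies (|F'| at a
        root below 1e-3) are re-drawn since neither method is well posed
        there."""
        rng = np.random.default_rng(12345)
        kinds = ["relu", "sigmoid", "tanh"]
        checked = 0
        while checked < 20:
            kind = kinds[int(rng.integers(3))]
            w = float(rng.uniform(-2.5, 2.5))
            b = float(rng.uniform(-1.0, 1.0))
            spec = ActivationSpec(kind)
            oracle = bisection_roots(kind, w, b)
            h = 1e-5
            slopes = [abs((-(-r) - spec.f(w * r + b)
                           + (r + h) - spec.f(w * (r + h) + b)) / h)
                      for r in oracle]
            if any(s < 1e-3 for s in slopes):
                continue
            p = scalar_params(kind, w)
            fps = find_fixed_points_for_input(
                np.array([b]), line_trajectories(-4.0, 4.0, 81), p,
                seed=int(rng.integers(2 ** 31)))
            found = sorted(fp.coords[0] for fp in fps)
            assert len(found) == len(oracle), (kind, w, b, found, oracle)
            assert np.allclose(found, oracle, atol=1e-6), (kind, w, b)
            # stability labels must match the analytic Jacobian sign
            for fp in fps:
                _, j = rhs_and_jacobian(fp.coords, np.array([b]), p)
                assert fp.stable == (j[0, 0] <= 0.0)
            checked += 1

    def test_residual_and_separation_thresholds(self):
        p = scalar_params("tanh", 2.0)
        fps = find_fixed_points_for_input(np.zeros(1), line_trajectories(),
                                          p, seed=3)
        for fp in fps:
            assert fp.residual <= 1e-12
        coords = [fp.coords for fp in fps]
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                assert np.linalg.norm(coords[i] - coords[j]) > 1e-7

    def test_dedup_count_stable_across_seeds(self):
        p = scalar_params("tanh", 2.0)
        counts = {len(find_fixed_points_for_input(
            np.zeros(1), line_trajectories(), p, seed=s)) for s in (0, 1, 2)}
        assert counts == {3}


class TestStability:
    def test_contracting_jacobian_is_stable(self):
        p = scalar_params("tanh", 0.0)
        stable, lam = classify_stability(np.zeros(1), np.zeros(1), p)
        assert stable and lam.real == pytest.approx(-1.0)

    def test_bistable_tanh_origin_unstable_branches_stable(self):
        p = scalar_params("tanh", 2.0)
        stable0, lam0 = classify_stability(np.zeros(1), np.zeros(1), p)
        assert not stable0 and lam0.real == pytest.approx(1.0)
        y = np.array([0.957504])
        stable1, lam1 = classify_stability(y, np.zeros(1), p)
        assert stable1
        assert lam1.real == pytest.approx(-1 + 2 * (1 - 0.957504 ** 2),
                                          abs=1e-4)

    def test_stable_points_attract(self):
        """Simulating from a perturbed stable fixed point must not diverge
        (applied to strictly stable points only)."""
        p = scalar_params("tanh", 2.0)
        fps = find_fixed_points_for_input(np.zeros(1), line_trajectories(),
                                          p, seed=0)
        rng = np.random.default_rng(0)
        for fp in fps:
            if not (fp.stable and fp.principal_eigenvalue.real < -1e-3):
                continue
            y = fp.coords + 1e-3 * rng.standard_normal(1)
            d0 = np.linalg.norm(y - fp.coords)
            for _ in range(50):
                y = ab.euler_step(y, np.zeros(1), p)
            assert np.linalg.norm(y - fp.coords) <= 10 * d0


class TestSurveys:
    def test_cddm_survey_has_50_conditions(self):
        conds = cddm_survey_inputs()
        assert len(conds) == 50
        tags = {tag for tag, _ in conds}
        assert len(tags) == 50

    def test_value_task_survey_structure(self):
        conds = value_task_survey_inputs()
        assert len(conds) == 22  # 11 values x (cue off, cue on)
        for (value, cue), u in conds:
            assert u[2] == 1.0  # bias always on
            assert u[1] == float(cue)

    def test_survey_tags_and_caps(self):
        p = ab.initialize_rnn("tanh", False, n_units=6, seed=0)
        batch = ab.build_cddm_batch(ab.enumerate_cddm_conditions([-1.0, 1.0]))
        resp = ab.simulate_batch(p, batch)
        conds = cddm_survey_inputs((-1.0, 1.0))
        pts = ab.fixed_point_survey(p, resp.activity, conditions=conds,
                                    seed=0, max_points=5, patience=5)
        tags = {tag for tag, _ in conds}
        assert pts, "survey found no fixed points"
        for fp in pts:
            assert fp.input_tag in tags
        from collections import Counter

        per_input = Counter(fp.input_tag for fp in pts)
        assert max(per_input.values()) <= 5
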