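"""Geometry summaries, bespoke distances, ICP registration and MDS."""

import numpy as np
import pytest
from scipy.stats import ortho_group

import actbias as ab
from actbias.fixedpoints import FixedPoint
from actbias.geometry import (
    distance_matrix,
    embed_mds,
    icp_distance,
    project_fixed_points,
    reduce_endpoints,
    reduce_selectivity,
    reduce_trajectories,
    trajectory_distance,
)


def low_rank_activity(n_units=20, t=30, k=12, rank=2, seed=0):
    rng = np.random.default_rng(seed)
    basis = rng.standard_normal((n_units, rank))
    coeffs = rng.standard_normal((rank, t * k))
    return (basis @ coeffs).reshape(n_units, t, k)


class TestReductions:
    def test_rank2_trajectories_fully_captured(self):
        s = reduce_trajectories(low_rank_activity())
        assert s.variance_captured == pytest.approx(1.0)
        assert s.reduced.shape[0] == 10

    def test_unit_total_variance_after_normalization(self):
        s = reduce_trajectories(low_rank_activity(seed=1))
        total = np.sum(np.var(s.flat, axis=1))
        assert total == pytest.approx(1.0)

    def test_selectivity_one_row_per_unit(self):
        s = reduce_selectivity(low_rank_activity(n_units=25))
        assert s.reduced.shape == (25, 10)
        assert s.variance_captured == pytest.approx(1.0)

    def test_endpoints_one_row_per_trial(self):
        s = reduce_endpoints(low_rank_activity(k=15))
        assert s.projected.shape == (15, 10)

    def test_identical_endpoints_rejected(self):
        act = np.zeros((8, 5, 12))
        with pytest.raises(ValueError):
            reduce_endpoints(act)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            reduce_trajectories(low_rank_activity(t=3, k=3))

    def test_fixed_point_projection_preserves_tags(self):
        rng = np.random.default_rng(0)
        pts = [FixedPoint(coords=rng.standard_normal(12), residual=0.0,
                          stable=bool(i % 2), input_tag=("ctx", i))
               for i in range(10)]
        s = project_fixed_points(pts)
        assert s.projected.shape == (10, 7)
        assert s.tags[3] == ("ctx", 3, "unstable") or \
            s.tags[3] == ("ctx", 3, "stable")
        assert s.stable[3] == pytest.approx(pts[3].stable)


class TestTrajectoryDistance:
    def test_self_distance_zero(self):
        f = reduce_trajectories(low_rank_activity(rank=5, seed=2))
        assert trajectory_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_invertible_linear_map_gives_zero(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((10, 200))
        m = rng.standard_normal((10, 10)) + 3 * np.eye(10)
        b = (a.T @ m).T
        assert trajectory_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_exact_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((10, 150))
        b = rng.standard_normal((10, 150))
        assert trajectory_distance(a, b) == trajectory_distance(b, a)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            trajectory_distance(rng.standard_normal((10, 100)),
                                rng.standard_normal((10, 120)))

    def test_unit_permutation_invariance(self):
        """Relabeling units acts as an orthogonal map on the summary and
        must leave the distance unchanged."""
        act = low_rank_activity(rank=6, seed=6)
        other = low_rank_activity(rank=6, seed=7)
        f1 = reduce_trajectories(act)
        f2 = reduce_trajectories(act[::-1])  # permuted units
        g = reduce_trajectories(other)
        assert trajectory_distance(f1, g) == pytest.approx(
            trajectory_distance(f2, g), abs=1e-6)


class TestIcpDistance:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(0)
        p = rng.standard_normal((30, 5))
        assert icp_distance(p, p, n_tries=10, seed=0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_transform_recovered(self):
        """Registration of a cloud against an exact rotation of itself:
        median score over 5 seeds below 1e-3 (50 points, 10-d)."""
        rng = np.random.default_rng(1)
        p = rng.standard_normal((50, 10))
        scores = []
        for seed in range(5):
            r = ortho_group.rvs(10, random_state=100 + seed)
            scores.append(icp_distance(p, p @ r, n_tries=60, seed=seed))
        assert np.median(scores) < 1e-3

    def test_tag_restriction_respected(self):
        """With stability tags, a stable point never matches an unstable
        one: two clouds whose tagged halves are far apart register with the
        within-tag error, not the cross-tag one."""
        rng = np.random.default_rng(2)
        base = rng.standard_normal((20, 3))
        tags = ["stable"] * 10 + ["unstable"] * 10
        shifted = base.copy()
        shifted[10:] += 100.0  # unstable points far away in both clouds
        d_tagged = icp_distance(shifted, shifted, tags, tags,
                                n_tries=10, seed=0)
        assert d_tagged < 1e-6

    def test_missing_tag_warns_and_excludes(self):
        rng = np.random.default_rng(3)
        src = rng.standard_normal((10, 3))
        tgt = rng.standard_normal((12, 3))
        tags_src = ["a"] * 10
        tags_tgt = ["a"] * 10 + ["b"] * 2
        with pytest.warns(UserWarning):
            icp_distance(src, tgt, tags_src, tags_tgt, n_tries=4, seed=0)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            icp_distance(np.empty((0, 3)), np.zeros((4, 3)))


class TestMds:
    def test_duplicate_points_coincide(self):
        d = np.array([[0.0, 0.0, 5.0],
                      [0.0, 0.0, 5.0],
                      [5.0, 5.0, 0.0]])
        coords, _ = embed_mds(d, seed=0)
        assert np.linalg.norm(coords[0] - coords[1]) < 0.05 * 5.0

    def test_planar_triangle_reproduced(self):
        d = np.array([[0.0, 3.0, 4.0],
                      [3.0, 0.0, 5.0],
                      [4.0, 5.0, 0.0]])
        coords, stress = embed_mds(d, seed=0)
        emb = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        assert np.allclose(emb, d, atol=1e-6)
        assert stress == pytest.approx(0.0, abs=1e-6)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            embed_mds(d)

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 2))
        d = np.linalg.norm(x[:, None] - x[None], axis=-1)
        c1, s1 = embed_mds(d, seed=3)
        c2, s2 = embed_mds(d, seed=3)
        assert np.array_equal(c1, c2) and s1 == s2


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self):
        summaries = [reduce_trajectories(low_rank_activity(seed=s))
                     for s in range(4)]
        d = distance_matrix(summaries, "trajectory")
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)
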