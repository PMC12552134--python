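"""Network definition, initialization, simulation and training mechanics."""

import numpy as np
import pytest

import actbias as ab
from actbias.rnn import (
    ActivationSpec,
    DaleSpec,
    _forward,
    _backward,
    dale_violations,
    train_population,
    training_loss,
)


class TestActivations:
    def test_scalar_values(self):
        assert ab.apply_activation(0.0, ActivationSpec("sigmoid")) == 0.5
        assert ab.apply_activation(-1.0, ActivationSpec("relu")) == 0.0
        assert ab.apply_activation(0.0, ActivationSpec("tanh")) == 0.0

    def test_sigmoid_slope(self):
        # logistic with slope 7.5 evaluated at 1
        expected = 1.0 / (1.0 + np.exp(-7.5))
        assert ab.apply_activation(1.0, ActivationSpec("sigmoid")) == \
            pytest.approx(expected)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ActivationSpec("softplus")

    @pytest.mark.parametrize("kind", ["relu", "sigmoid", "tanh"])
    def test_derivative_matches_finite_difference(self, kind):
        spec = ActivationSpec(kind)
        x = np.linspace(-2, 2, 41) + 0.013  # avoid the relu kink
        h = 1e-6
        fd = (spec.f(x + h) - spec.f(x - h)) / (2 * h)
        assert np.allclose(spec.df(x), fd, atol=1e-5)


class TestInitialization:
    @pytest.mark.parametrize("kind,dale", ab.ARCHITECTURES)
    def test_spectral_radius(self, kind, dale):
        p = ab.initialize_rnn(kind, dale, n_units=40, seed=0)
        radius = np.max(np.abs(np.linalg.eigvals(p.w_rec)))
        assert radius == pytest.approx(1.2, abs=1e-9)

    def test_tanh_dale_partition_is_balanced(self):
        p = ab.initialize_rnn("tanh", True, n_units=100, seed=1)
        sign = p.dale.sign_vector
        assert (sign > 0).sum() == 50 and (sign < 0).sum() == 50

    def test_relu_dale_partition_is_4_to_1(self):
        p = ab.initialize_rnn("relu", True, n_units=100, seed=1)
        sign = p.dale.sign_vector
        assert (sign > 0).sum() == 80 and (sign < 0).sum() == 20

    def test_input_output_weights_nonnegative(self):
        for kind, dale in ab.ARCHITECTURES:
            p = ab.initialize_rnn(kind, dale, n_units=20, seed=2)
            assert p.w_inp.min() >= 0 and p.w_out.min() >= 0

    def test_dale_sign_pattern_on_columns(self):
        p = ab.initialize_rnn("sigmoid", True, n_units=40, seed=3)
        assert dale_violations(p) == 0

    def test_incompatible_partition_rejected(self):
        with pytest.raises(ValueError):
            ab.initialize_rnn("relu", True, n_units=33, seed=0)


class TestEulerStep:
    def test_zero_everything_is_fixed(self):
        p = ab.RNNParams(w_inp=np.zeros((3, 2)), w_rec=np.zeros((3, 3)),
                         w_out=np.zeros((1, 3)),
                         activation=ActivationSpec("tanh"),
                         dale=DaleSpec(enabled=False))
        y = ab.euler_step(np.zeros(3), np.zeros(2), p)
        assert np.all(y == 0.0)

    def test_gamma_one_reduces_to_pure_map(self):
        p = ab.initialize_rnn("sigmoid", False, n_units=5, n_in=2, n_out=1,
                              seed=0, tau=1.0)
        y = np.linspace(-1, 1, 5)
        u = np.array([0.3, 0.7])
        stepped = ab.euler_step(y, u, p)
        expected = p.activation.f(p.w_rec @ y + p.w_inp @ u)
        assert np.allclose(stepped, expected)

    def test_scalar_network_matches_hand_computation(self):
        # 1 unit, w_rec = 0.5, w_inp = 2, tanh, gamma = 0.1, y = 0.3, u = 0.4
        p = ab.RNNParams(w_inp=np.array([[2.0]]), w_rec=np.array([[0.5]]),
                         w_out=np.array([[1.0]]),
                         activation=ActivationSpec("tanh"),
                         dale=DaleSpec(enabled=False))
        y1 = ab.euler_step(np.array([0.3]), np.array([0.4]), p)
        expected = 0.9 * 0.3 + 0.1 * np.tanh(0.5 * 0.3 + 2.0 * 0.4)
        assert y1[0] == pytest.approx(expected, abs=1e-15)


class TestSimulation:
    @pytest.fixture(scope="class")
    def small_batch(self):
        return ab.build_cddm_batch(ab.enumerate_cddm_conditions([-1.0, 1.0]),
                                   n_steps=80, sensory_onset=20,
                                   decision_onset=50)

    def test_noiseless_determinism(self, small_batch):
        p = ab.initialize_rnn("tanh", False, n_units=10, seed=0)
        r1 = ab.simulate_batch(p, small_batch)
        r2 = ab.simulate_batch(p, small_batch)
        assert np.array_equal(r1.activity, r2.activity)

    def test_seeded_noise_determinism(self, small_batch):
        p = ab.initialize_rnn("relu", False, n_units=10, seed=0)
        r1 = ab.simulate_batch(p, small_batch, noise=True, seed=42)
        r2 = ab.simulate_batch(p, small_batch, noise=True, seed=42)
        assert np.array_equal(r1.activity, r2.activity)

    @pytest.mark.parametrize("kind,lo,hi", [
        ("sigmoid", 0.0, 1.0), ("relu", 0.0, np.inf), ("tanh", -1.0, 1.0)])
    def test_activity_range(self, small_batch, kind, lo, hi):
        p = ab.initialize_rnn(kind, False, n_units=10, seed=1)
        r = ab.simulate_batch(p, small_batch, noise=True, seed=0)
        assert r.activity.min() >= lo and r.activity.max() <= hi


class TestTrainingLoss:
    def test_perfect_fit_zero_loss(self):
        out = np.ones((2, 10, 3))
        mask = np.ones(10, dtype=bool)
        w = np.array([[1.0], [0.0]])  # single column: no off-diagonal Gram
        loss = training_loss(out, out.copy(), mask, np.zeros((4, 10, 3)), w)
        assert loss == 0.0

    def test_orthogonal_columns_no_penalty(self):
        out = np.zeros((1, 4, 2))
        mask = np.ones(4, dtype=bool)
        w_orth = np.array([[1.0, 0.0], [0.0, 2.0]])
        act = np.zeros((2, 4, 2))
        assert training_loss(out, out, mask, act, w_orth) == 0.0

    def test_activity_penalty_quadratic(self):
        out = np.zeros((1, 4, 2))
        mask = np.ones(4, dtype=bool)
        w = np.zeros((3, 1))
        act = np.ones((3, 4, 2))
        l1 = training_loss(out, out, mask, act, w, lam_r=0.5)
        l2 = training_loss(out, out, mask, 2 * act, w, lam_r=0.5)
        assert l2 == pytest.approx(4 * l1)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        batch = ab.build_cddm_batch(
            ab.enumerate_cddm_conditions([-1.0, 1.0]),
            n_steps=30, sensory_onset=8, decision_onset=20)
        p = ab.initialize_rnn("tanh", True, n_units=10, seed=4)
        rng = np.random.default_rng(0)

        def loss_of():
            y, a, u = _forward(p, batch.inputs, False, None)
            out = np.einsum("on,ntk->otk", p.w_out, y)
            return training_loss(out, batch.targets, batch.mask, y, p.w_inp,
                                 0.5, 0.1)

        y, a, u = _forward(p, batch.inputs, False, None)
        grads = _backward(p, batch, y, a, u, 0.5, 0.1)
        h = 1e-6
        for w, g in zip((p.w_inp, p.w_rec, p.w_out), grads):
            for _ in range(4):
                i = tuple(rng.integers(s) for s in w.shape)
                w[i] += h
                up = loss_of()
                w[i] -= 2 * h
                down = loss_of()
                w[i] += h
                fd = (up - down) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-10)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_batch(self):
        return ab.build_cddm_batch(ab.enumerate_cddm_conditions([-1.0, 1.0]))

    def test_loss_decreases_and_constraints_hold(self, tiny_batch):
        p = ab.initialize_rnn("sigmoid", True, n_units=20, seed=0)
        trained, trace = ab.train_rnn(p, tiny_batch, n_iter=60, lr=0.003,
                                      seed=1, check_constraints=True)
        assert trace[-1] < trace[0]
        assert dale_violations(trained) == 0
        assert trained.w_inp.min() >= 0 and trained.w_out.min() >= 0

    def test_two_phase_schedule_runs(self, tiny_batch):
        p = ab.initialize_rnn("tanh", False, n_units=10, seed=0)
        _, trace = ab.train_rnn(p, tiny_batch,
                                schedule=[(0.0, 5), (0.3, 5)], seed=2)
        assert len(trace) == 10

    def test_population_matches_single_net_training(self, tiny_batch):
        p = ab.initialize_rnn("tanh", True, n_units=20, seed=3)
        single, tr1 = ab.train_rnn(p, tiny_batch, n_iter=25, lr=0.003,
                                   noise=False, seed=0)
        [pop], tr2 = train_population([p], tiny_batch, n_iter=25, lr=0.003,
                                      noise=False, seed=0)
        assert np.allclose(single.w_rec, pop.w_rec, atol=1e-12)
        assert np.allclose(tr1, tr2[:, 0], atol=1e-9)


class TestShuffleControl:
    def test_shuffle_preserves_diagonal_and_multisets(self):
        p = ab.initialize_rnn("relu", False, n_units=15, seed=0)
        c = ab.shuffle_connectivity(p, seed=1)
        assert np.array_equal(np.diag(p.w_rec), np.diag(c.w_rec))
        for i in range(p.w_inp.shape[0]):
            assert np.array_equal(np.sort(p.w_inp[i]), np.sort(c.w_inp[i]))
        for j in range(p.n_units):
            off = np.r_[0:j, j + 1:p.n_units]
            assert np.array_equal(np.sort(p.w_rec[off, j]),
                                  np.sort(c.w_rec[off, j]))

    def test_shuffle_leaves_original_untouched(self):
        p = ab.initialize_rnn("relu", False, n_units=10, seed=0)
        w = p.w_rec.copy()
        ab.shuffle_connectivity(p, seed=1)
        assert np.array_equal(w, p.w_rec)


def test_checkpoint_roundtrip(tmp_path):
    p = ab.initialize_rnn("sigmoid", True, n_units=20, seed=0)
    ab.save_checkpoint(p, tmp_path / "net", extra={"task": "cddm"})
    q = ab.load_checkpoint(tmp_path / "net")
    assert np.array_equal(p.w_rec, q.w_rec)
    assert q.activation.kind == "sigmoid"
    assert q.dale.enabled and np.array_equal(p.dale.sign_vector,
                                             q.dale.sign_vector)
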