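"""Continuous-time rate RNNs: definition, initialization, simulation, training.

The model is the leaky firing-rate network

    tau dy/dt = -y + f(W_rec y + W_inp u),

integrated with a first-order Euler scheme at dt = 1 ms (gamma = dt/tau):

    y_{t+1} = (1 - gamma) y_t
              + gamma f(W_rec y_t + W_inp (u_t + s_inp zeta_t) + s_rec xi_t),

with s = sqrt(2 gamma sigma^2) and standard-normal process noise zeta, xi.
Readout is linear, o_t = W_out y_t.  Six architectures are studied:
{relu, sigmoid (slope 7.5), tanh} x {Dale constraint on, off}.  Under Dale's
law every unit is excitatory or inhibitory: each column of W_rec keeps a
fixed sign (or zero), and W_inp / W_out stay elementwise non-negative in all
architectures.

Training minimizes a masked quadratic loss with an activity penalty and an
input-column orthogonality penalty, using backpropagation through time with
analytic gradients and an Adam optimizer (lr 1e-3, beta1 0.9, beta2 0.999,
eps 1e-8).  After every update, constraint-violating entries are zeroed
(projected gradient descent), exactly as in the sign-clipping rule used for
Dale-constrained training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .tasks import TrialBatch

__all__ = [
    "ActivationSpec",
    "DaleSpec",
    "RNNParams",
    "ResponseTensor",
    "ARCHITECTURES",
    "apply_activation",
    "activation_derivative",
    "initialize_rnn",
    "euler_step",
    "simulate_batch",
    "training_loss",
    "train_rnn",
    "shuffle_connectivity",
    "save_checkpoint",
    "load_checkpoint",
]

SIGMOID_SLOPE = 7.5

#: The six architectures studied: (activation kind, Dale constraint).
ARCHITECTURES: tuple[tuple[str, bool], ...] = (
    ("relu", True), ("relu", False),
    ("sigmoid", True), ("sigmoid", False),
    ("tanh", True), ("tanh", False),
)


@dataclass(frozen=True)
class ActivationSpec:
    """Pointwise nonlinearity: relu, logistic sigmoid (slope 7.5), or tanh."""

    kind: str
    slope: float = SIGMOID_SLOPE

    def __post_init__(self):
        if self.kind not in ("relu", "sigmoid", "tanh"):
            raise ValueError(f"unknown activation kind {self.kind!r}")

    def f(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return np.maximum(0.0, x)
        if self.kind == "sigmoid":
            return 1.0 / (1.0 + np.exp(-self.slope * x))
        return np.tanh(x)

    def df(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return (x > 0).astype(float)
        if self.kind == "sigmoid":
            s = self.f(x)
            return self.slope * s * (1.0 - s)
        return 1.0 - np.tanh(x) ** 2


def apply_activation(x: np.ndarray, spec: ActivationSpec) -> np.ndarray:
    """Elementwise activation f(x) for the given spec."""
    return spec.f(np.asarray(x, dtype=float))


def activation_derivative(x: np.ndarray, spec: ActivationSpec) -> np.ndarray:
    """Elementwise derivative f'(x)."""
    return spec.df(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class DaleSpec:
    """Dale's-law constraint: fixed sign per unit's outgoing weights.

    ``r_ei`` is the ratio of excitatory to inhibitory unit counts: 4 for
    relu/sigmoid architectures, 1 for tanh.  ``sign_vector`` holds +1 for
    excitatory and -1 for inhibitory units.
    """

    enabled: bool
    r_ei: float = 4.0
    sign_vector: np.ndarray | None = None

    @staticmethod
    def for_architecture(activation_kind: str, enabled: bool,
                         n_units: int | None = None) -> "DaleSpec":
        r_ei = 1.0 if activation_kind == "tanh" else 4.0
        sign = None
        if enabled and n_units is not None:
            sign = DaleSpec.partition_signs(n_units, r_ei)
        return DaleSpec(enabled=enabled, r_ei=r_ei, sign_vector=sign)

    @staticmethod
    def partition_signs(n_units: int, r_ei: float) -> np.ndarray:
        n_exc = n_units * r_ei / (r_ei + 1.0)
        if abs(n_exc - round(n_exc)) > 1e-9:
            raise ValueError(
                f"N={n_units} incompatible with R_E/I={r_ei} partition")
        n_exc = int(round(n_exc))
        sign = np.ones(n_units)
        sign[n_exc:] = -1.0
        return sign


@dataclass
class RNNParams:
    """Full parameter set of one network."""

    w_inp: np.ndarray  # (N, n_in), >= 0
    w_rec: np.ndarray  # (N, N)
    w_out: np.ndarray  # (n_out, N), >= 0
    activation: ActivationSpec
    dale: DaleSpec
    tau: float = 10.0       # ms
    dt: float = 1.0         # ms
    sigma_inp: float = 0.01
    sigma_rec: float = 0.01

    @property
    def n_units(self) -> int:
        return self.w_rec.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_inp.shape[1]

    @property
    def n_out(self) -> int:
        return self.w_out.shape[0]

    @property
    def gamma(self) -> float:
        g = self.dt / self.tau
        if not 0.0 < g <= 1.0:
            raise ValueError("dt/tau must lie in (0, 1]")
        return g

    def copy(self) -> "RNNParams":
        return replace(self, w_inp=self.w_inp.copy(),
                       w_rec=self.w_rec.copy(), w_out=self.w_out.copy())


@dataclass
class ResponseTensor:
    """Simulated activity (N, T, K) and readout (n_out, T, K)."""

    activity: np.ndarray
    outputs: np.ndarray
    noise: bool = False
    seed: int | None = None


def _spectral_radius(w: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(w))))


def initialize_rnn(
    activation: str | ActivationSpec,
    dale: bool | DaleSpec,
    n_units: int = 100,
    n_in: int = 6,
    n_out: int = 2,
    seed: int | np.random.Generator = 0,
    spectral_radius: float = 1.2,
    **kwargs,
) -> RNNParams:
    """Initialize one network of the given architecture.

    Without Dale's constraint, W_rec entries are drawn N(1/sqrt(N), 1/N^2)
    and rescaled so the spectral radius is exactly 1.2.  With the
    constraint, excitatory columns are |N(1/sqrt(N), 1/N^2)| and inhibitory
    columns -|N(R_EI/sqrt(N), 1/N^2)| before the same rescaling (a positive
    scalar, so the sign pattern is preserved).  W_inp and W_out are
    |N(1/sqrt(N), 1/N^2)| in all architectures.
    """
    rng = np.random.default_rng(seed)
    if isinstance(activation, str):
        activation = ActivationSpec(activation)
    if isinstance(dale, bool):
        dale = DaleSpec.for_architecture(activation.kind, dale, n_units)
    elif dale.enabled and dale.sign_vector is None:
        dale = replace(dale,
                       sign_vector=DaleSpec.partition_signs(n_units, dale.r_ei))
    mu, sd = 1.0 / np.sqrt(n_units), 1.0 / n_units
    if dale.enabled:
        sign = dale.sign_vector
        mu_i = dale.r_ei / np.sqrt(n_units)
        w_rec = np.empty((n_units, n_units))
        for j in range(n_units):
            if sign[j] > 0:
                w_rec[:, j] = np.abs(rng.normal(mu, sd, size=n_units))
            else:
                w_rec[:, j] = -np.abs(rng.normal(mu_i, sd, size=n_units))
    else:
        w_rec = rng.normal(mu, sd, size=(n_units, n_units))
    w_rec *= spectral_radius / _spectral_radius(w_rec)
    w_inp = np.abs(rng.normal(mu, sd, size=(n_units, n_in)))
    w_out = np.abs(rng.normal(mu, sd, size=(n_out, n_units)))
    return RNNParams(w_inp=w_inp, w_rec=w_rec, w_out=w_out,
                     activation=activation, dale=dale, **kwargs)


def euler_step(
    y: np.ndarray,
    u: np.ndarray,
    params: RNNParams,
    noise_inp: np.ndarray | None = None,
    noise_rec: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler update of the discretized dynamics.

    ``noise_inp`` / ``noise_rec`` are standard-normal draws (or None for
    noiseless integration); they are scaled by sqrt(2 gamma sigma^2) here.
    """
    g = params.gamma
    u_eff = np.asarray(u, dtype=float)
    if noise_inp is not None:
        u_eff = u_eff + np.sqrt(2.0 * g * params.sigma_inp ** 2) * noise_inp
    drive = params.w_rec @ y + params.w_inp @ u_eff
    if noise_rec is not None:
        drive = drive + np.sqrt(2.0 * g * params.sigma_rec ** 2) * noise_rec
    return (1.0 - g) * y + g * params.activation.f(drive)


def _forward(params: RNNParams, inputs: np.ndarray, noise: bool,
             rng: np.random.Generator | None):
    """Vectorized forward pass over a (n_in, T, K) input tensor.

    Returns activity ``y`` of shape (N, T, K) (states y_1..y_T, with
    y_0 = 0), pre-activations ``a`` (N, T, K) and the effective inputs
    ``u_eff`` (n_in, T, K) actually fed through W_inp (noise included), as
    needed for backpropagation.
    """
    n_in, T, K = inputs.shape
    N, g = params.n_units, params.gamma
    s_inp = np.sqrt(2.0 * g * params.sigma_inp ** 2)
    s_rec = np.sqrt(2.0 * g * params.sigma_rec ** 2)
    y = np.zeros((N, T, K))
    a = np.zeros((N, T, K))
    if noise:
        u_eff = inputs + s_inp * rng.standard_normal(inputs.shape)
        eta = s_rec * rng.standard_normal((N, T, K))
    else:
        u_eff = inputs
        eta = None
    state = np.zeros((N, K))
    w_inp_u = np.einsum("ni,itk->ntk", params.w_inp, u_eff)
    for t in range(T):
        drive = params.w_rec @ state + w_inp_u[:, t]
        if eta is not None:
            drive += eta[:, t]
        a[:, t] = drive
        state = (1.0 - g) * state + g * params.activation.f(drive)
        y[:, t] = state
    return y, a, u_eff


def simulate_batch(
    params: RNNParams,
    batch: TrialBatch,
    noise: bool = False,
    seed: int | np.random.Generator = 0,
) -> ResponseTensor:
    """Run the network over a batch from the zero initial state.

    Activity at index ``t`` is the state after the update driven by input
    step ``t``; outputs are W_out applied to that activity.  Given the same
    seed (and noise flag) the result is bit-identical across calls.
    """
    rng = np.random.default_rng(seed) if noise else None
    y, _, _ = _forward(params, batch.inputs, noise, rng)
    outputs = np.einsum("on,ntk->otk", params.w_out, y)
    return ResponseTensor(activity=y, outputs=outputs, noise=noise,
                          seed=seed if isinstance(seed, int) else None)


def _masked_mse(outputs: np.ndarray, targets: np.ndarray,
                mask: np.ndarray) -> float:
    return float(np.mean((outputs[:, mask] - targets[:, mask]) ** 2))


def _orth_penalty(w_inp: np.ndarray) -> float:
    gram = w_inp.T @ w_inp
    off = gram - np.diag(np.diag(gram))
    return float(np.mean(off ** 2))


def training_loss(
    outputs: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    activity: np.ndarray,
    w_inp: np.ndarray,
    lam_r: float = 0.5,
    lam_orth: float = 0.1,
) -> float:
    """Masked m.s.e. + activity penalty + input-orthogonality penalty."""
    if not np.any(mask):
        raise ValueError("empty training mask")
    return (_masked_mse(outputs, targets, mask)
            + lam_r * float(np.mean(activity ** 2))
            + lam_orth * _orth_penalty(w_inp))


def _backward(params: RNNParams, batch: TrialBatch, y, a, u_eff,
              lam_r: float, lam_orth: float):
    """Analytic gradients of the training loss wrt (w_inp, w_rec, w_out)."""
    mask = batch.mask
    targets = batch.targets
    g = params.gamma
    N, T, K = y.shape
    n_out = params.n_out
    outputs = np.einsum("on,ntk->otk", params.w_out, y)

    err = np.zeros_like(outputs)
    m = int(mask.sum())
    err[:, mask] = 2.0 * (outputs[:, mask] - targets[:, mask]) / (n_out * m * K)
    d_w_out = np.einsum("otk,ntk->on", err, y)
    # dL/dy from the readout and the activity penalty, per step
    dy_local = np.einsum("on,otk->ntk", params.w_out, err)
    dy_local += 2.0 * lam_r * y / y.size

    d_w_rec = np.zeros_like(params.w_rec)
    d_w_inp = np.zeros_like(params.w_inp)
    grad_state = np.zeros((N, K))
    df = params.activation.df
    for t in range(T - 1, -1, -1):
        grad_state = grad_state + dy_local[:, t]
        delta = g * df(a[:, t]) * grad_state          # (N, K)
        y_prev = y[:, t - 1] if t > 0 else np.zeros((N, K))
        d_w_rec += delta @ y_prev.T
        d_w_inp += delta @ u_eff[:, t].T
        grad_state = (1.0 - g) * grad_state + params.w_rec.T @ delta

    gram = params.w_inp.T @ params.w_inp
    off = gram - np.diag(np.diag(gram))
    d_w_inp += lam_orth * 4.0 * (params.w_inp @ off) / off.size
    return d_w_inp, d_w_rec, d_w_out


def _clip_gradients(grads, max_norm: float):
    """Rescale a gradient list so its global L2 norm is at most max_norm.

    Applied before the Adam update: without it, the enormous gradients of
    an initially exploding network (unbounded relu at spectral radius 1.2)
    poison Adam's second-moment estimates and stall training for thousands
    of iterations afterwards.
    """
    total = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        grads = [g * scale for g in grads]
    return grads


class _Adam:
    """Minimal Adam optimizer over a list of arrays."""

    def __init__(self, shapes, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8,
                 dtype=np.float64):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s, dtype) for s in shapes]
        self.v = [np.zeros(s, dtype) for s in shapes]
        self.t = 0

    def step(self, grads):
        self.t += 1
        updates = []
        for i, gr in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * gr
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * gr ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            updates.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return updates


def _project_constraints(params: RNNParams) -> None:
    """Zero entries that violate sign constraints (in place)."""
    np.maximum(params.w_inp, 0.0, out=params.w_inp)
    np.maximum(params.w_out, 0.0, out=params.w_out)
    if params.dale.enabled:
        sign = params.dale.sign_vector
        violating = params.w_rec * sign[None, :] < 0.0
        params.w_rec[violating] = 0.0


def dale_violations(params: RNNParams) -> int:
    """Number of W_rec entries with the wrong sign (0 when Dale is off)."""
    if not params.dale.enabled:
        return 0
    return int(np.sum(params.w_rec * params.dale.sign_vector[None, :] < 0.0))


def train_rnn(
    params: RNNParams,
    batch: TrialBatch,
    schedule: list[tuple[float, int]] | None = None,
    lam_r: float = 0.5,
    n_iter: int = 5000,
    lam_orth: float = 0.1,
    lr: float = 0.001,
    noise: bool = True,
    seed: int | np.random.Generator = 0,
    grad_clip: float = 1.0,
    check_constraints: bool = False,
) -> tuple[RNNParams, np.ndarray]:
    """Train a network with Adam + BPTT; returns (trained params, loss trace).

    ``schedule`` is a list of (lam_r, n_iter) phases; when None a single
    phase (lam_r, n_iter) is used.  Every iteration presents the full batch
    with fresh process noise; gradients are global-norm clipped to
    ``grad_clip`` before the Adam update.  After each update, negative
    W_inp/W_out entries and Dale-violating W_rec entries are zeroed.  With
    ``check_constraints=True`` the Dale invariant is asserted at every step.
    """
    if schedule is None:
        schedule = [(lam_r, n_iter)]
    rng = np.random.default_rng(seed)
    params = params.copy()
    opt = _Adam([params.w_inp.shape, params.w_rec.shape, params.w_out.shape],
                lr=lr)
    trace = []
    for phase_lam_r, phase_iters in schedule:
        for _ in range(phase_iters):
            y, a, u_eff = _forward(params, batch.inputs, noise, rng)
            outputs = np.einsum("on,ntk->otk", params.w_out, y)
            loss = training_loss(outputs, batch.targets, batch.mask, y,
                                 params.w_inp, phase_lam_r, lam_orth)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss diverged (loss={loss}) at iteration "
                    f"{len(trace)}")
            trace.append(loss)
            grads = _backward(params, batch, y, a, u_eff,
                              phase_lam_r, lam_orth)
            grads = _clip_gradients(grads, grad_clip)
            du_inp, du_rec, du_out = opt.step(grads)
            params.w_inp -= du_inp
            params.w_rec -= du_rec
            params.w_out -= du_out
            _project_constraints(params)
            if check_constraints:
                assert dale_violations(params) == 0
                assert params.w_inp.min() >= 0 and params.w_out.min() >= 0
    return params, np.asarray(trace)


def _pop_stack(population: list[RNNParams]):
    """Stack same-shape networks into (B, ...) weight tensors.

    Networks may differ in activation and Dale signs but must share unit,
    input and output counts and integration constants.
    """
    ref = population[0]
    for p in population:
        if (p.n_units, p.n_in, p.n_out) != (ref.n_units, ref.n_in, ref.n_out):
            raise ValueError("population networks must share dimensions")
        if (p.tau, p.dt) != (ref.tau, ref.dt):
            raise ValueError("population networks must share tau and dt")
    w_inp = np.stack([p.w_inp for p in population])
    w_rec = np.stack([p.w_rec for p in population])
    w_out = np.stack([p.w_out for p in population])
    groups: dict[tuple, list[int]] = {}
    for b, p in enumerate(population):
        groups.setdefault((p.activation.kind, p.activation.slope), []).append(b)
    act_groups = [(np.array(idx), ActivationSpec(k, s))
                  for (k, s), idx in groups.items()]
    sign = np.zeros((len(population), ref.n_units))
    for b, p in enumerate(population):
        if p.dale.enabled:
            sign[b] = p.dale.sign_vector
    return w_inp, w_rec, w_out, act_groups, sign


def _pop_f(drive, act_groups, deriv=False):
    """Activation (or derivative) per net group; groups are index arrays."""
    out = np.empty_like(drive)
    for idx, spec in act_groups:
        out[idx] = spec.df(drive[idx]) if deriv else spec.f(drive[idx])
    return out


def _pop_loss_and_grads(w_inp, w_rec, w_out, act_groups, batch, gamma,
                        sigma_inp, sigma_rec, noise, rng, lam_r, lam_orth):
    """One batched forward + backward pass over the population.

    Works time-major throughout (arrays (T, B, N, K)) so every per-step
    slice is contiguous; process noise is drawn in float32 for speed and
    promoted on use.  Returns per-net losses (B,) and stacked gradients.
    """
    inputs, targets, mask = batch.inputs, batch.targets, batch.mask
    B, N = w_rec.shape[:2]
    n_in, T, K = inputs.shape
    n_out = w_out.shape[1]
    m = int(mask.sum())
    s_inp = np.sqrt(2.0 * gamma * sigma_inp ** 2)
    s_rec = np.sqrt(2.0 * gamma * sigma_rec ** 2)
    w_out_t = np.swapaxes(w_out, 1, 2)
    w_rec_t = np.swapaxes(w_rec, 1, 2)

    if noise:
        zeta = rng.standard_normal((T, B, n_in, K), dtype=np.float32)
        eta = rng.standard_normal((T, B, N, K), dtype=np.float32)
    y = np.empty((T, B, N, K))
    a = np.empty((T, B, N, K))
    u_store = np.empty((T, B, n_in, K)) if noise else None
    state = np.zeros((B, N, K))
    mse_acc = np.zeros(B)
    act_acc = np.zeros(B)
    for t in range(T):
        if noise:
            u_t = inputs[None, :, t] + s_inp * zeta[t]
            u_store[t] = u_t
        else:
            u_t = inputs[None, :, t]
        drive = np.matmul(w_rec, state) + np.matmul(w_inp, u_t)
        if noise:
            drive += s_rec * eta[t]
        a[t] = drive
        state = (1.0 - gamma) * state + gamma * _pop_f(drive, act_groups)
        y[t] = state

    d_w_rec = np.zeros_like(w_rec)
    d_w_inp = np.zeros_like(w_inp)
    d_w_out = np.zeros_like(w_out)
    grad_state = np.zeros((B, N, K))
    zeros = np.zeros((B, N, K))
    for t in range(T - 1, -1, -1):
        y_t = y[t]
        if mask[t]:
            err = np.matmul(w_out, y_t) - targets[None, :, t]
            mse_acc += np.sum(err ** 2, axis=(1, 2))
            err *= 2.0 / (n_out * m * K)
            d_w_out += np.matmul(err, np.swapaxes(y_t, 1, 2))
            grad_state += np.matmul(w_out_t, err)
        act_acc += np.sum(y_t ** 2, axis=(1, 2))
        grad_state += (2.0 * lam_r / (N * T * K)) * y_t
        delta = gamma * _pop_f(a[t], act_groups, deriv=True) * grad_state
        y_prev = y[t - 1] if t > 0 else zeros
        d_w_rec += np.matmul(delta, np.swapaxes(y_prev, 1, 2))
        u_t = u_store[t] if noise else np.broadcast_to(
            inputs[None, :, t], (B, n_in, K))
        d_w_inp += np.matmul(delta, np.swapaxes(u_t, 1, 2))
        grad_state = (1.0 - gamma) * grad_state + np.matmul(w_rec_t, delta)

    gram = np.matmul(np.swapaxes(w_inp, 1, 2), w_inp)
    idx = np.arange(n_in)
    gram[:, idx, idx] = 0.0
    d_w_inp += lam_orth * 4.0 * np.matmul(w_inp, gram) / (n_in ** 2)
    losses = (mse_acc / (n_out * m * K)
              + lam_r * act_acc / (N * T * K)
              + lam_orth * np.sum(gram ** 2, axis=(1, 2)) / (n_in ** 2))
    return losses, d_w_inp, d_w_rec, d_w_out


try:  # compiled inner loop; the numpy path below is the reference
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

if njit is not None:

    @njit(cache=True)
    def _pop_kernel(w_inp, w_rec, w_out, act_code, slope, inputs_tm,
                    targets_tm, mask, zeta, eta, gamma, s_inp, s_rec,
                    use_noise, lam_r, lam_orth):
        B, N, n_in = w_inp.shape
        n_out = w_out.shape[1]
        T, _, K = inputs_tm.shape
        m = 0
        for t in range(T):
            if mask[t]:
                m += 1
        losses = np.zeros(B)
        d_w_inp = np.zeros_like(w_inp)
        d_w_rec = np.zeros_like(w_rec)
        d_w_out = np.zeros_like(w_out)
        dt_ = w_inp.dtype
        for b in range(B):
            code = act_code[b]
            sl = slope[b]
            y = np.empty((T, N, K), dt_)
            a = np.empty((T, N, K), dt_)
            u_eff = np.empty((T, n_in, K), dt_)
            state = np.zeros((N, K), dt_)
            for t in range(T):
                for i in range(n_in):
                    for k in range(K):
                        v = inputs_tm[t, i, k]
                        if use_noise:
                            v += s_inp * zeta[t, b, i, k]
                        u_eff[t, i, k] = v
                drive = np.dot(w_rec[b], state) + np.dot(w_inp[b], u_eff[t])
                for i in range(N):
                    for k in range(K):
                        d = drive[i, k]
                        if use_noise:
                            d += s_rec * eta[t, b, i, k]
                        a[t, i, k] = d
                        if code == 0:
                            fv = d if d > 0.0 else 0.0
                        elif code == 1:
                            fv = 1.0 / (1.0 + np.exp(-sl * d))
                        else:
                            fv = np.tanh(d)
                        state[i, k] = (1.0 - gamma) * state[i, k] + gamma * fv
                        y[t, i, k] = state[i, k]
            # backward
            grad_state = np.zeros((N, K), dt_)
            err = np.empty((n_out, K), dt_)
            mse = 0.0
            act = 0.0
            coef_out = 2.0 / (n_out * m * K)
            coef_r = 2.0 * lam_r / (N * T * K)
            for t in range(T - 1, -1, -1):
                y_t = y[t]
                if mask[t]:
                    out_t = np.dot(w_out[b], y_t)
                    for o in range(n_out):
                        for k in range(K):
                            e = out_t[o, k] - targets_tm[t, o, k]
                            mse += e * e
                            err[o, k] = coef_out * e
                    d_w_out[b] += np.dot(err, y_t.T)
                    grad_state += np.dot(w_out[b].T, err)
                for i in range(N):
                    for k in range(K):
                        act += y_t[i, k] * y_t[i, k]
                        grad_state[i, k] += coef_r * y_t[i, k]
                delta = np.empty((N, K), dt_)
                for i in range(N):
                    for k in range(K):
                        d = a[t, i, k]
                        if code == 0:
                            df = 1.0 if d > 0.0 else 0.0
                        elif code == 1:
                            s = 1.0 / (1.0 + np.exp(-sl * d))
                            df = sl * s * (1.0 - s)
                        else:
                            th = np.tanh(d)
                            df = 1.0 - th * th
                        delta[i, k] = gamma * df * grad_state[i, k]
                if t > 0:
                    d_w_rec[b] += np.dot(delta, y[t - 1].T)
                d_w_inp[b] += np.dot(delta, u_eff[t].T)
                # scalar math stays elementwise so the array dtype is
                # preserved in single precision
                back = np.dot(w_rec[b].T, delta)
                for i in range(N):
                    for k in range(K):
                        grad_state[i, k] = (1.0 - gamma) * grad_state[i, k] \
                            + back[i, k]
            losses[b] = (mse / (n_out * m * K) + lam_r * act / (N * T * K))
        # input-column orthogonality penalty (per net)
        coef_orth = lam_orth * 4.0 / (n_in * n_in)
        for b in range(B):
            gram = np.dot(w_inp[b].T, w_inp[b])
            for i in range(n_in):
                gram[i, i] = 0.0
            s2 = 0.0
            for i in range(n_in):
                for j in range(n_in):
                    s2 += gram[i, j] * gram[i, j]
            losses[b] += lam_orth * s2 / (n_in * n_in)
            og = np.dot(w_inp[b], gram)
            for i in range(N):
                for j in range(n_in):
                    d_w_inp[b, i, j] += coef_orth * og[i, j]
        return losses, d_w_inp, d_w_rec, d_w_out


def _pop_step(w_inp, w_rec, w_out, act_groups, batch, gamma, sigma_inp,
              sigma_rec, noise, rng, lam_r, lam_orth, population):
    """Dispatch one loss+gradient evaluation to the compiled kernel when
    available, otherwise to the numpy reference implementation."""
    if njit is None:
        return _pop_loss_and_grads(w_inp, w_rec, w_out, act_groups, batch,
                                   gamma, sigma_inp, sigma_rec, noise, rng,
                                   lam_r, lam_orth)
    B = w_inp.shape[0]
    n_in, T, K = batch.inputs.shape
    N = w_rec.shape[1]
    codes = {"relu": 0, "sigmoid": 1, "tanh": 2}
    act_code = np.array([codes[p.activation.kind] for p in population],
                        dtype=np.int64)
    slope = np.array([p.activation.slope for p in population])
    g = gamma
    s_inp = np.sqrt(2.0 * g * sigma_inp ** 2)
    s_rec = np.sqrt(2.0 * g * sigma_rec ** 2)
    if noise:
        zeta = rng.standard_normal((T, B, n_in, K), dtype=np.float32)
        eta = rng.standard_normal((T, B, N, K), dtype=np.float32)
    else:
        zeta = np.zeros((1, 1, 1, 1), dtype=np.float32)
        eta = np.zeros((1, 1, 1, 1), dtype=np.float32)
    inputs_tm = np.ascontiguousarray(batch.inputs.transpose(1, 0, 2),
                                     dtype=w_inp.dtype)
    targets_tm = np.ascontiguousarray(batch.targets.transpose(1, 0, 2),
                                      dtype=w_inp.dtype)
    return _pop_kernel(w_inp, w_rec, w_out, act_code, slope, inputs_tm,
                       targets_tm, batch.mask, zeta, eta, g, s_inp, s_rec,
                       noise, lam_r, lam_orth)


def train_population(
    population: list[RNNParams],
    batch: TrialBatch,
    schedule: list[tuple[float, int]] | None = None,
    lam_r: float = 0.5,
    n_iter: int = 5000,
    lam_orth: float = 0.1,
    lr: float = 0.001,
    noise: bool = True,
    seed: int | np.random.Generator = 0,
    grad_clip: float = 1.0,
    precision: str = "double",
) -> tuple[list[RNNParams], np.ndarray]:
    """Train many same-shape networks jointly (independent gradients).

    Networks are stacked along a leading batch axis so every Euler step is
    one batched matrix product for the whole population; each net's loss,
    gradient and clipping are unchanged from :func:`train_rnn`.  Returns
    the trained networks and an (iterations, B) per-net loss trace.

    ``precision="single"`` runs the forward/backward passes and optimizer
    in float32 (roughly 1.5-2x faster); stochastic gradient descent is
    insensitive to the reduced precision, but trajectories differ from the
    double-precision path, so use it only where a particular realization is
    not being compared against one.
    """
    if schedule is None:
        schedule = [(lam_r, n_iter)]
    rng = np.random.default_rng(seed)
    ref = population[0]
    gamma = ref.gamma
    w_inp, w_rec, w_out, act_groups, sign = _pop_stack(population)
    if precision == "single":
        w_inp = w_inp.astype(np.float32)
        w_rec = w_rec.astype(np.float32)
        w_out = w_out.astype(np.float32)
    elif precision != "double":
        raise ValueError("precision must be 'single' or 'double'")
    B, N, T, K = len(population), ref.n_units, batch.n_steps, batch.n_trials
    dale_mask = np.abs(sign)[:, None, :]  # (B, 1, N): 1 where Dale applies
    opt = _Adam([w_inp.shape, w_rec.shape, w_out.shape], lr=lr,
                dtype=w_inp.dtype)
    trace = []
    for phase_lam_r, phase_iters in schedule:
        for _ in range(phase_iters):
            per_net, d_w_inp, d_w_rec, d_w_out = _pop_step(
                w_inp, w_rec, w_out, act_groups, batch, gamma,
                ref.sigma_inp, ref.sigma_rec, noise, rng,
                phase_lam_r, lam_orth, population)
            if not np.all(np.isfinite(per_net)):
                raise RuntimeError("population training loss diverged")
            trace.append(per_net)
            # clip per net so joint training matches the single-net path
            norms = np.sqrt(np.sum(d_w_inp ** 2, axis=(1, 2))
                            + np.sum(d_w_rec ** 2, axis=(1, 2))
                            + np.sum(d_w_out ** 2, axis=(1, 2)))
            scale = np.minimum(1.0, grad_clip / np.maximum(norms, 1e-300))
            d_w_inp *= scale[:, None, None]
            d_w_rec *= scale[:, None, None]
            d_w_out *= scale[:, None, None]
            du_inp, du_rec, du_out = opt.step([d_w_inp, d_w_rec, d_w_out])
            w_inp -= du_inp
            w_rec -= du_rec
            w_out -= du_out
            np.maximum(w_inp, 0.0, out=w_inp)
            np.maximum(w_out, 0.0, out=w_out)
            violating = (w_rec * sign[:, None, :] < 0.0) & (dale_mask > 0)
            w_rec[violating] = 0.0
    trained = []
    for b, p in enumerate(population):
        q = p.copy()
        q.w_inp = w_inp[b].astype(np.float64)
        q.w_rec = w_rec[b].astype(np.float64)
        q.w_out = w_out[b].astype(np.float64)
        trained.append(q)
    return trained, np.asarray(trace)


def shuffle_connectivity(
    params: RNNParams, seed: int | np.random.Generator = 0
) -> RNNParams:
    """Shuffled-connectivity control network.

    Each row of W_inp is independently permuted, and the off-diagonal
    entries of each W_rec column are permuted while the diagonal is kept
    unchanged to preserve each unit's self-excitation.
    """
    rng = np.random.default_rng(seed)
    out = params.copy()
    for i in range(out.w_inp.shape[0]):
        out.w_inp[i] = rng.permutation(out.w_inp[i])
    n = out.n_units
    for j in range(n):
        off = np.r_[0:j, j + 1:n]
        out.w_rec[off, j] = rng.permutation(out.w_rec[off, j])
    return out


def save_checkpoint(params: RNNParams, path, extra: dict | None = None,
                    loss_trace: np.ndarray | None = None) -> None:
    """Write weights to ``<path>.npz`` and metadata to ``<path>.json``."""
    path = str(path)
    arrays = {"w_inp": params.w_inp, "w_rec": params.w_rec,
              "w_out": params.w_out}
    if loss_trace is not None:
        arrays["loss_trace"] = np.asarray(loss_trace)
    if params.dale.sign_vector is not None:
        arrays["dale_sign"] = params.dale.sign_vector
    np.savez(path + ".npz", **arrays)
    meta = {
        "activation": params.activation.kind,
        "slope": params.activation.slope,
        "dale": params.dale.enabled,
        "r_ei": params.dale.r_ei,
        "tau": params.tau, "dt": params.dt,
        "sigma_inp": params.sigma_inp, "sigma_rec": params.sigma_rec,
    }
    meta.update(extra or {})
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(path) -> RNNParams:
    path = str(path)
    arrays = np.load(path + ".npz")
    with open(path + ".json") as fh:
        meta = json.load(fh)
    sign = arrays["dale_sign"] if "dale_sign" in arrays else None
    dale = DaleSpec(enabled=bool(meta["dale"]), r_ei=float(meta["r_ei"]),
                    sign_vector=sign)
    return RNNParams(
        w_inp=arrays["w_inp"], w_rec=arrays["w_rec"], w_out=arrays["w_out"],
        activation=ActivationSpec(meta["activation"], meta["slope"]),
        dale=dale, tau=meta["tau"], dt=meta["dt"],
        sigma_inp=meta["sigma_inp"], sigma_rec=meta["sigma_rec"],
    )
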