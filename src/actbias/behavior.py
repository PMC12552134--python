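"""Behavioral probes: performance ranking, psychometrics, OOD sensitivity,
output-subspace alignment, and the hand-built 3-unit flip-flop.

The out-of-distribution probe extends the stimulus coherence grid beyond the
[-1, 1] training range.  The circuit solutions found by different
activations predict opposite outcomes: saturation-based gating (tanh) keeps
the decision boundary aligned with the relevant axis at any irrelevant
amplitude, while inhibition-based gating (relu / sigmoid) is overcome by
strong irrelevant stimuli, rotating the boundary.  The rotation is
quantified as the slope of the choice fraction on the irrelevant coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rnn import ActivationSpec, DaleSpec, RNNParams, simulate_batch
from .tasks import TrialBatch, build_cddm_batch, build_flipflop_batch

__all__ = [
    "PsychometricMap",
    "task_performance",
    "psychometric_map",
    "irrelevant_sensitivity",
    "output_alignment_rho",
    "handcrafted_flipflop",
    "verify_flipflop",
]


@dataclass
class PsychometricMap:
    """Right-choice fraction on a (motion x colour) coherence grid."""

    motion_grid: np.ndarray
    colour_grid: np.ndarray
    choice_stat: np.ndarray     # (len(motion_grid), len(colour_grid))
    context: str
    n_reps: int
    seed: int | None = None


def task_performance(params: RNNParams, batch: TrialBatch) -> float:
    """Masked m.s.e. of a noiseless pass over all conditions (lower = better)."""
    resp = simulate_batch(params, batch, noise=False)
    mask = batch.mask
    return float(np.mean((resp.outputs[:, mask] - batch.targets[:, mask]) ** 2))


def _choices(outputs: np.ndarray, window: int = 100) -> np.ndarray:
    """Per-trial signed decision: sign of mean (right - left) over the final
    ``window`` steps."""
    dv = np.mean(outputs[0, -window:, :] - outputs[1, -window:, :], axis=0)
    return np.sign(dv)


def psychometric_map(
    params: RNNParams,
    context: str = "motion",
    motion_grid: np.ndarray | None = None,
    colour_grid: np.ndarray | None = None,
    n_reps: int = 64,
    seed: int = 0,
    noise: bool = True,
) -> PsychometricMap:
    """Right-choice fraction per coherence cell, under process noise.

    Grids may extend beyond [-1, 1] (out-of-distribution amplitudes).  Each
    cell is simulated ``n_reps`` times with noise; the statistic is the
    fraction of repetitions whose time-averaged (right - left) output over
    the final 100 ms is positive (sign-zero trials count half).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if motion_grid is None:
        motion_grid = np.linspace(-2.0, 2.0, 21)
    if colour_grid is None:
        colour_grid = np.linspace(-2.0, 2.0, 21)
    motion_grid = np.asarray(motion_grid, dtype=float)
    colour_grid = np.asarray(colour_grid, dtype=float)
    conditions = [(context, cm, cc)
                  for cm in motion_grid for cc in colour_grid] * n_reps
    batch = build_cddm_batch(conditions, ood=True)
    resp = simulate_batch(params, batch, noise=noise, seed=seed)
    signs = _choices(resp.outputs)
    frac = (signs > 0).astype(float) + 0.5 * (signs == 0)
    frac = frac.reshape(n_reps, len(motion_grid), len(colour_grid)).mean(axis=0)
    return PsychometricMap(motion_grid=motion_grid, colour_grid=colour_grid,
                           choice_stat=frac, context=context, n_reps=n_reps,
                           seed=seed)


def irrelevant_sensitivity(pmap: PsychometricMap) -> float:
    """Slope of the choice fraction on the irrelevant coherence.

    A least-squares linear fit of the per-cell choice fraction on
    (1, relevant, irrelevant); the irrelevant-coherence coefficient is 0 for
    a perfectly gated network and grows as the decision boundary rotates.
    """
    stat = pmap.choice_stat
    if np.allclose(stat, stat.flat[0]):
        raise ValueError("degenerate psychometric map: all choices identical")
    mot, col = np.meshgrid(pmap.motion_grid, pmap.colour_grid, indexing="ij")
    rel, irr = (mot, col) if pmap.context == "motion" else (col, mot)
    design = np.column_stack([np.ones(stat.size), rel.ravel(), irr.ravel()])
    coef, *_ = np.linalg.lstsq(design, stat.ravel(), rcond=None)
    return float(coef[2])


def output_alignment_rho(w_out: np.ndarray, x: np.ndarray) -> float:
    """Generalized correlation between activity and the output subspace.

    rho = ||W_out X||_F / (||W_out||_F ||X||_F), where X collects population
    activity over the output epoch; rho is 1 when every activity pattern
    lies along the readout and 0 when activity is orthogonal to it.
    """
    x = np.asarray(x, dtype=float).reshape(x.shape[0], -1)
    nw, nx = np.linalg.norm(w_out), np.linalg.norm(x)
    if nw == 0 or nx == 0:
        raise ValueError("zero-norm readout or activity")
    return float(np.linalg.norm(w_out @ x) / (nw * nx))


def handcrafted_flipflop(
    n_bits: int = 3,
    w_self: float = 2.0,
    input_gain: float = 2.0,
    activation: str = "tanh",
    tau: float = 10.0,
    dt: float = 1.0,
) -> RNNParams:
    """A hand-built ``n_bits``-unit flip-flop network.

    One self-excitatory unit per bit (w_self > 1 gives a tanh unit two
    stable states at +/- the root of y = tanh(w_self * y)), inputs wired
    one-to-one with positive gain so a +/-1 pulse flips the unit, and an
    identity-like readout scaled so the held outputs are +/-1.
    """
    y_star = _bistable_level(w_self)
    eye = np.eye(n_bits)
    return RNNParams(
        w_inp=input_gain * eye,
        w_rec=w_self * eye,
        w_out=eye / y_star,
        activation=ActivationSpec(activation),
        dale=DaleSpec(enabled=False),
        tau=tau, dt=dt, sigma_inp=0.0, sigma_rec=0.0)


def _bistable_level(w_self: float) -> float:
    """Positive root of y = tanh(w * y) (bisection; requires w > 1)."""
    lo, hi = 1e-6, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.tanh(w_self * mid) > mid:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def verify_flipflop(
    params: RNNParams,
    n_bits: int = 3,
    hold_steps: int = 200,
    pulse_width: int = 20,
    margin: float = 0.5,
) -> dict:
    """Exhaustively test storage of all 2^n_bits sign patterns.

    Each pattern is written by one pulse per bit (staggered onsets) and must
    be held: every output must stay within ``margin`` of the written sign
    for the whole post-pulse hold period.  Returns a report with per-pattern
    pass flags and the set of failing bits.
    """
    patterns = [[1 if (p >> b) & 1 else -1 for b in range(n_bits)]
                for p in range(2 ** n_bits)]
    schedules = []
    write_end = 0
    for pat in patterns:
        sched = [(b, b * (pulse_width + 5), s) for b, s in enumerate(pat)]
        write_end = max(write_end,
                        max(t for _, t, _ in sched) + pulse_width)
        schedules.append(sched)
    n_steps = write_end + hold_steps
    batch = build_flipflop_batch(schedules, n_bits=n_bits, n_steps=n_steps,
                                 pulse_width=pulse_width)
    resp = simulate_batch(params, batch, noise=False)
    report = {"patterns": [], "all_pass": True, "failed_bits": set()}
    for k, pat in enumerate(patterns):
        ok = True
        for b, s in enumerate(pat):
            held = resp.outputs[b, write_end:, k]
            if np.max(np.abs(held - s)) > margin:
                ok = False
                report["failed_bits"].add(b)
        report["patterns"].append({"pattern": pat, "pass": ok})
        report["all_pass"] &= ok
    return report
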