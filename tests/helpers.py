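"""Shared oracles and constructions used by several test modules."""

from __future__ import annotations

import numpy as np

import actbias as ab
from actbias.latent import default_input_mask
from actbias.rnn import ActivationSpec, DaleSpec


def scalar_params(kind: str, w: float, w_in: float = 1.0) -> ab.RNNParams:
    """A 1-unit network with recurrent weight w and input weight w_in."""
    return ab.RNNParams(w_inp=np.array([[w_in]]), w_rec=np.array([[w]]),
                        w_out=np.array([[1.0]]),
                        activation=ActivationSpec(kind),
                        dale=DaleSpec(enabled=False))


def bisection_roots(kind: str, w: float, b: float,
                    lo=-4.0, hi=4.0, n_grid=160001) -> list[float]:
    """Independent root oracle for F(y) = -y + f(w y + b) on a scalar net:
    dense sign-change scan followed by bisection on each bracket."""
    spec = ActivationSpec(kind)
    ys = np.linspace(lo, hi, n_grid)
    fs = -ys + spec.f(w * ys + b)
    roots = []
    sign_change = np.where(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0)[0]
    for i in np.where(fs == 0.0)[0]:
        roots.append(ys[i])
    for i in sign_change:
        a_, b_ = ys[i], ys[i + 1]
        fa = fs[i]
        for _ in range(80):
            mid = 0.5 * (a_ + b_)
            fm = -mid + spec.f(w * mid + b)
            if fa * fm <= 0:
                b_ = mid
            else:
                a_, fa = mid, fm
        roots.append(0.5 * (a_ + b_))
    return sorted(set(round(r, 10) for r in roots))


def line_trajectories(lo=-1.5, hi=1.5, n=61) -> np.ndarray:
    """Synthetic (1, T, K) 'trajectories' sweeping the scalar state space
    along the trial axis (the finder samples start states from the second
    half of the time axis, so the sweep must not live on that axis)."""
    return np.tile(np.linspace(lo, hi, n).reshape(1, 1, n), (1, 2, 1))


def teacher_circuit():
    """A hand-designed 8-node context-gating circuit.

    Context nodes suppress the sensory nodes of the irrelevant modality;
    surviving sensory nodes drive two mutually inhibiting choice nodes.
    Weights are moderate so every node spends time in the responsive part
    of its activation function, keeping the connectivity identifiable from
    the dynamics.
    """
    w_rec = np.zeros((8, 8))
    for s in (2, 3, 4, 5):
        w_rec[s, s] = 0.5
    w_rec[4, 0] = w_rec[5, 0] = -0.8   # motion ctx inhibits colour nodes
    w_rec[2, 1] = w_rec[3, 1] = -0.8   # colour ctx inhibits motion nodes
    w_rec[6, 2] = w_rec[6, 4] = 1.0    # right evidence -> choice R
    w_rec[7, 3] = w_rec[7, 5] = 1.0    # left evidence -> choice L
    w_rec[6, 7] = w_rec[7, 6] = -0.7   # winner-take-all
    w_rec[6, 6] = w_rec[7, 7] = 0.4
    w_inp = default_input_mask(8, 6)
    w_out = np.zeros((2, 8))
    w_out[0, 6] = 1.0
    w_out[1, 7] = 1.0
    return w_rec, w_inp, w_out


def match_choice_nodes(w_fit: np.ndarray, w_teacher: np.ndarray) -> float:
    """Best |Pearson r| between recurrent matrices over the two possible
    assignments of the unwired (choice) nodes 6 and 7."""
    return max(
        abs(np.corrcoef(w_fit[np.ix_(p, p)].ravel(),
                        w_teacher.ravel())[0, 1])
        for p in ([0, 1, 2, 3, 4, 5, 6, 7], [0, 1, 2, 3, 4, 5, 7, 6]))
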