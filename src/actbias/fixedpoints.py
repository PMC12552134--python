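"""Fixed-point finding, deduplication and stability classification.

For a constant input u, fixed points are roots of

    F(y, u) = -y + f(W_rec y + W_inp u),

found with a hybrid-Powell root solver supplied with the analytic Jacobian

    J(y, u) = dF/dy = -I + diag(f'(W_rec y + W_inp u)) W_rec.

Candidate starts are drawn from the second half of simulated trajectories
plus per-coordinate Gaussian noise (variance 0.01).  A candidate is accepted
when ||F||^2 <= 1e-12 and discarded when it lies within 1e-7 (Euclidean) of
an already accepted point.  The search for one input stops when 100 distinct
fixed points have been found or 100 consecutive candidates yield nothing
new.  A fixed point is stable when the principal eigenvalue of J (largest
real part) has non-positive real part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .rnn import RNNParams
from .tasks import CDDM_CONTEXTS, coherence_to_channels

__all__ = [
    "FixedPoint",
    "SURVEY_COHERENCES",
    "rhs_and_jacobian",
    "find_fixed_points_for_input",
    "classify_stability",
    "cddm_survey_inputs",
    "value_task_survey_inputs",
    "fixed_point_survey",
]

#: Coherence values for the CDDM fixed-point survey: 2 contexts x 5 relevant
#: x 5 irrelevant = 50 constant-input conditions (symmetric subsample of the
#: training grid).
SURVEY_COHERENCES: tuple[float, ...] = (-1.0, -0.25, 0.0, 0.25, 1.0)

RESIDUAL_TOL = 1e-12
DEDUP_TOL = 1e-7
INIT_NOISE_STD = 0.1  # std of the per-coordinate start jitter (variance 0.01)


@dataclass
class FixedPoint:
    """One fixed point: coordinates, residual, stability, input condition."""

    coords: np.ndarray
    residual: float
    stable: bool
    input_tag: tuple
    principal_eigenvalue: complex = 0.0


def rhs_and_jacobian(
    y: np.ndarray, u: np.ndarray, params: RNNParams
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side F(y, u) and its Jacobian dF/dy."""
    h = params.w_rec @ y + params.w_inp @ u
    f = params.activation.f(h)
    jac = -np.eye(params.n_units) + params.activation.df(h)[:, None] * params.w_rec
    return -y + f, jac


def classify_stability(
    coords: np.ndarray, u: np.ndarray, params: RNNParams
) -> tuple[bool, complex]:
    """(stable?, principal eigenvalue) at a state; stable iff Re(lambda_0) <= 0.

    Ties in the real part are broken by larger |Im| (irrelevant to the
    label, which depends only on the real part).
    """
    _, jac = rhs_and_jacobian(coords, u, params)
    eig = np.linalg.eigvals(jac)
    order = np.lexsort((np.abs(eig.imag), eig.real))
    lam0 = eig[order[-1]]
    return bool(lam0.real <= 0.0), complex(lam0)


def find_fixed_points_for_input(
    u: np.ndarray,
    trajectories: np.ndarray,
    params: RNNParams,
    seed: int | np.random.Generator = 0,
    input_tag: tuple = (),
    max_points: int = 100,
    patience: int = 100,
    max_solver_iter: int = 200,
) -> list[FixedPoint]:
    """Find the fixed points of the network under one constant input.

    ``trajectories`` is an (N, T, K) activity tensor used to seed the root
    search: each start is a random state from the second half of a random
    trial plus N(0, 0.01) per-coordinate noise.
    """
    rng = np.random.default_rng(seed)
    u = np.asarray(u, dtype=float)
    N, T, K = trajectories.shape
    found: list[FixedPoint] = []
    misses = 0
    while len(found) < max_points and misses < patience:
        k = int(rng.integers(K))
        t = int(rng.integers(T // 2, T))
        y0 = trajectories[:, t, k] + INIT_NOISE_STD * rng.standard_normal(N)
        sol = root(lambda y: rhs_and_jacobian(y, u, params)[0], y0,
                   jac=lambda y: rhs_and_jacobian(y, u, params)[1],
                   method="hybr", options={"maxfev": max_solver_iter * (N + 1)})
        y_star = sol.x
        res = float(np.sum(rhs_and_jacobian(y_star, u, params)[0] ** 2))
        if res > RESIDUAL_TOL:
            misses += 1
            continue
        if any(np.linalg.norm(y_star - fp.coords) <= DEDUP_TOL for fp in found):
            misses += 1
            continue
        stable, lam0 = classify_stability(y_star, u, params)
        found.append(FixedPoint(coords=y_star, residual=res, stable=stable,
                                input_tag=tuple(input_tag),
                                principal_eigenvalue=lam0))
        misses = 0
    if not found:
        warnings.warn(f"no fixed points accepted for input tag {input_tag}")
    return found


def cddm_survey_inputs(
    coherences: tuple[float, ...] = SURVEY_COHERENCES,
) -> list[tuple[tuple, np.ndarray]]:
    """Constant-input grid for the CDDM survey (50 conditions by default).

    Tags are (context, relevant coherence, irrelevant coherence); the input
    vector carries the context cue plus both modalities' channel pairs.
    """
    conditions = []
    for ctx in CDDM_CONTEXTS:
        for c_rel in coherences:
            for c_irr in coherences:
                u = np.zeros(6)
                u[CDDM_CONTEXTS.index(ctx)] = 1.0
                c_mot, c_col = (c_rel, c_irr) if ctx == "motion" else (c_irr, c_rel)
                u[2], u[3] = coherence_to_channels(c_mot)
                u[4], u[5] = coherence_to_channels(c_col)
                conditions.append(((ctx, c_rel, c_irr), u))
    return conditions


def value_task_survey_inputs(
    values: np.ndarray | None = None,
) -> list[tuple[tuple, np.ndarray]]:
    """Constant inputs for the Go/NoGo and memory tasks.

    One condition per training value, with and without the Go cue active;
    the bias channel is always 1.
    """
    if values is None:
        values = np.linspace(0.0, 1.0, 11)
    conditions = []
    for v in values:
        for cue in (0.0, 1.0):
            conditions.append(((float(v), bool(cue)), np.array([v, cue, 1.0])))
    return conditions


def fixed_point_survey(
    params: RNNParams,
    trajectories: np.ndarray,
    task: str = "cddm",
    seed: int | np.random.Generator = 0,
    max_points: int = 100,
    patience: int = 100,
    conditions: list[tuple[tuple, np.ndarray]] | None = None,
) -> list[FixedPoint]:
    """Fixed points over the task's constant-input survey grid, tagged."""
    if conditions is None:
        if task == "cddm":
            conditions = cddm_survey_inputs()
        elif task in ("gonogo", "memory"):
            conditions = value_task_survey_inputs()
        else:
            raise ValueError(f"no survey grid defined for task {task!r}")
    rng = np.random.default_rng(seed)
    points: list[FixedPoint] = []
    for tag, u in conditions:
        points.extend(find_fixed_points_for_input(
            u, trajectories, params, seed=rng, input_tag=tag,
            max_points=max_points, patience=patience))
    return points


def survey_to_frame(points: list[FixedPoint]):
    """Tabulate a survey as a pandas DataFrame (one row per fixed point)."""
    import pandas as pd

    rows = []
    for fp in points:
        row = {"stable": fp.stable, "residual": fp.residual,
               "input_tag": str(fp.input_tag)}
        row.update({f"coord_{i}": c for i, c in enumerate(fp.coords)})
        rows.append(row)
    return pd.DataFrame(rows)
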