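"""Trial-batch generators for the cognitive tasks.

Each task produces a :class:`TrialBatch`: an input tensor of shape
``(n_in, T, K)``, a target tensor ``(n_out, T, K)``, a boolean training mask
over time steps, and per-trial condition labels.  Time is discretized on a
0-based step grid with dt = 1 ms; intervals written "t < 100 ms" are
half-open step ranges ``[0, 100)``.

Tasks
-----
* CDDM — context-dependent decision making.  Six input channels
  (context-motion, context-colour, motion-right, motion-left, colour-right,
  colour-left), two output channels (right, left).  Signed coherence
  ``c`` of each modality maps to the channel pair ``((1+c)/2, (1-c)/2)``.
* Go/NoGo — threshold an analog input value at 0.5 after a Go cue.
* Memory number — store a briefly flashed analog value and report it after
  a Go cue.
* 3-bit flip-flop — hold the sign of the last +/-1 pulse on each of three
  independent channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TRAINING_COHERENCES",
    "CDDM_CHANNELS",
    "TrialBatch",
    "coherence_to_channels",
    "enumerate_cddm_conditions",
    "build_cddm_batch",
    "build_gonogo_batch",
    "build_memory_batch",
    "build_flipflop_batch",
    "make_flipflop_schedule",
]

#: The 15-value training coherence grid, symmetric about 0.
TRAINING_COHERENCES: tuple[float, ...] = (
    -1.0, -0.5, -0.25, -0.13, -0.06, -0.03, -0.01,
    0.0,
    0.01, 0.03, 0.06, 0.13, 0.25, 0.5, 1.0,
)

#: CDDM input-channel order.
CDDM_CHANNELS: tuple[str, ...] = (
    "ctx_motion", "ctx_colour", "motion_r", "motion_l", "colour_r", "colour_l",
)

CDDM_CONTEXTS: tuple[str, str] = ("motion", "colour")


@dataclass
class TrialBatch:
    """One batch of task trials.

    Attributes
    ----------
    inputs : (n_in, T, K) float array, all amplitudes >= 0 for sensory tasks
    targets : (n_out, T, K) float array
    mask : (T,) bool array marking loss-bearing time steps
    labels : list of per-trial condition dicts, one per trial
    task : task identifier string
    """

    inputs: np.ndarray
    targets: np.ndarray
    mask: np.ndarray
    labels: list[dict] = field(default_factory=list)
    task: str = ""

    @property
    def n_in(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_out(self) -> int:
        return self.targets.shape[0]

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_trials(self) -> int:
        return self.inputs.shape[2]

    def save(self, path) -> None:
        """Write arrays to ``<path>.npz`` and labels to ``<path>.json``."""
        path = str(path)
        np.savez(path + ".npz", inputs=self.inputs, targets=self.targets,
                 mask=self.mask)
        with open(path + ".json", "w") as fh:
            json.dump({"task": self.task, "labels": self.labels}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrialBatch":
        path = str(path)
        arrays = np.load(path + ".npz")
        with open(path + ".json") as fh:
            meta = json.load(fh)
        return cls(inputs=arrays["inputs"], targets=arrays["targets"],
                   mask=arrays["mask"].astype(bool), labels=meta["labels"],
                   task=meta["task"])


def coherence_to_channels(c: float, ood: bool = False) -> tuple[float, float]:
    """Map a signed coherence to the (right, left) channel amplitude pair.

    ``c`` in [-1, 1] maps to ``((1 + c)/2, (1 - c)/2)``; both amplitudes are
    non-negative and sum to 1.  Values outside [-1, 1] are only admitted with
    ``ood=True`` (out-of-distribution probes with amplified stimuli).
    """
    if not ood and not -1.0 <= c <= 1.0:
        raise ValueError(f"coherence {c} outside [-1, 1]; pass ood=True to allow")
    return (1.0 + c) / 2.0, (1.0 - c) / 2.0


def enumerate_cddm_conditions(
    grid: Sequence[float] = TRAINING_COHERENCES,
) -> list[tuple[str, float, float]]:
    """Cartesian product {motion, colour} x grid x grid of trial conditions.

    The full 15-value training grid yields 2 * 15 * 15 = 450 conditions.
    """
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("empty coherence grid")
    if len(set(grid)) != len(grid):
        raise ValueError("duplicate values in coherence grid")
    for c in grid:
        if not -1.0 <= c <= 1.0:
            raise ValueError(f"coherence {c} outside [-1, 1]")
    return [
        (ctx, cm, cc) for ctx in CDDM_CONTEXTS for cm in grid for cc in grid
    ]


def build_cddm_batch(
    conditions: Sequence[tuple[str, float, float]] | None = None,
    n_steps: int = 300,
    sensory_onset: int = 100,
    decision_onset: int = 200,
    ood: bool = False,
) -> TrialBatch:
    """Build a CDDM trial batch from (context, c_motion, c_colour) triplets.

    The context channel is on at amplitude 1 for the whole trial; sensory
    channels switch on at ``sensory_onset``.  Targets are 0 before the
    decision period and, from ``decision_onset`` on, 1 on the 'right' output
    if the relevant coherence is positive, 1 on 'left' if negative, and 0 on
    both if it is exactly zero.  The training mask covers
    ``[0, sensory_onset) U [decision_onset, n_steps)``; the integration
    window in between is unpenalized.
    """
    if conditions is None:
        conditions = enumerate_cddm_conditions()
    if sensory_onset >= n_steps:
        raise ValueError("sensory_onset must precede the end of the trial")
    K = len(conditions)
    inputs = np.zeros((6, n_steps, K))
    targets = np.zeros((2, n_steps, K))
    labels: list[dict] = []
    for k, (ctx, c_mot, c_col) in enumerate(conditions):
        if ctx not in CDDM_CONTEXTS:
            raise ValueError(f"unknown context {ctx!r}")
        inputs[CDDM_CONTEXTS.index(ctx), :, k] = 1.0
        mr, ml = coherence_to_channels(c_mot, ood=ood)
        cr, cl = coherence_to_channels(c_col, ood=ood)
        inputs[2, sensory_onset:, k] = mr
        inputs[3, sensory_onset:, k] = ml
        inputs[4, sensory_onset:, k] = cr
        inputs[5, sensory_onset:, k] = cl
        relevant = c_mot if ctx == "motion" else c_col
        if relevant > 0:
            targets[0, decision_onset:, k] = 1.0
        elif relevant < 0:
            targets[1, decision_onset:, k] = 1.0
        labels.append({
            "context": ctx, "c_motion": c_mot, "c_colour": c_col,
            "relevant": relevant, "sensory_onset": sensory_onset,
        })
    mask = np.zeros(n_steps, dtype=bool)
    mask[:sensory_onset] = True
    mask[decision_onset:] = True
    return TrialBatch(inputs=inputs, targets=targets, mask=mask,
                      labels=labels, task="cddm")


def _heaviside_target(value: float) -> float:
    """Go/NoGo target after the cue: Theta(value - 0.5), with 0.5 at threshold."""
    if value > 0.5:
        return 1.0
    if value < 0.5:
        return 0.0
    return 0.5


def _cue_mask(n_steps: int, t_go_cue: int, grace: int = 5) -> np.ndarray:
    # All steps are loss-bearing except a short grace window after cue onset,
    # mirroring the unpenalized integration window of the CDDM mask.
    mask = np.ones(n_steps, dtype=bool)
    mask[t_go_cue:min(t_go_cue + grace, n_steps)] = False
    return mask


def build_gonogo_batch(
    values: Sequence[float] | None = None,
    t_go_cue: int = 30,
    n_steps: int = 60,
) -> TrialBatch:
    """Go/NoGo batch: sustained analog value, thresholded response after cue.

    Input channels: (value, go-cue, bias).  The value channel is constant for
    the whole trial, the go-cue channel is on at amplitude 1 from
    ``t_go_cue`` to trial end, and the bias channel is constant 1.  The
    target is 0 before the cue and Theta(value - 0.5) after (0.5 exactly at
    threshold).
    """
    if values is None:
        values = np.linspace(0.0, 1.0, 11)
    if t_go_cue >= n_steps:
        raise ValueError("t_go_cue must precede the end of the trial")
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("input values must lie in [0, 1]")
    K = len(values)
    inputs = np.zeros((3, n_steps, K))
    targets = np.zeros((1, n_steps, K))
    labels = []
    for k, v in enumerate(values):
        inputs[0, :, k] = v
        inputs[1, t_go_cue:, k] = 1.0
        inputs[2, :, k] = 1.0
        targets[0, t_go_cue:, k] = _heaviside_target(v)
        labels.append({"value": float(v), "t_go_cue": t_go_cue})
    return TrialBatch(inputs=inputs, targets=targets,
                      mask=_cue_mask(n_steps, t_go_cue),
                      labels=labels, task="gonogo")


def build_memory_batch(
    values: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    t_go_cue: int = 70,
    n_steps: int = 100,
    stim_duration: int = 10,
    onset_range: int = 20,
) -> TrialBatch:
    """Memory-number batch: flashed analog value, recalled after the cue.

    The value channel equals the trial's value on a ``stim_duration``-step
    window starting at a per-trial onset drawn uniformly from
    ``[0, onset_range]`` ms, and is 0 elsewhere.  Target is 0 before the cue
    and the stored value afterwards.
    """
    if values is None:
        values = np.linspace(0.0, 1.0, 11)
    if t_go_cue >= n_steps:
        raise ValueError("t_go_cue must precede the end of the trial")
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("input values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    K = len(values)
    inputs = np.zeros((3, n_steps, K))
    targets = np.zeros((1, n_steps, K))
    labels = []
    onsets = rng.integers(0, onset_range + 1, size=K)
    for k, (v, t0) in enumerate(zip(values, onsets)):
        inputs[0, t0:t0 + stim_duration, k] = v
        inputs[1, t_go_cue:, k] = 1.0
        inputs[2, :, k] = 1.0
        targets[0, t_go_cue:, k] = v
        labels.append({"value": float(v), "t_stim": int(t0),
                       "t_go_cue": t_go_cue})
    return TrialBatch(inputs=inputs, targets=targets,
                      mask=_cue_mask(n_steps, t_go_cue),
                      labels=labels, task="memory")


def make_flipflop_schedule(
    n_bits: int = 3,
    n_steps: int = 256,
    seed: int | np.random.Generator = 0,
    n_pulses: int = 8,
    pulse_width: int = 10,
) -> list[tuple[int, int, int]]:
    """Random non-overlapping (bit, onset, sign) pulse schedule."""
    rng = np.random.default_rng(seed)
    schedule: list[tuple[int, int, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {b: [] for b in range(n_bits)}
    attempts = 0
    while len(schedule) < n_pulses and attempts < 100 * n_pulses:
        attempts += 1
        bit = int(rng.integers(n_bits))
        t0 = int(rng.integers(0, n_steps - pulse_width))
        if any(t0 < e and t0 + pulse_width > s for s, e in occupied[bit]):
            continue
        occupied[bit].append((t0, t0 + pulse_width))
        schedule.append((bit, t0, int(rng.choice([-1, 1]))))
    return sorted(schedule, key=lambda p: p[1])


def build_flipflop_batch(
    schedules: Sequence[Sequence[tuple[int, int, int]]],
    n_bits: int = 3,
    n_steps: int = 256,
    pulse_width: int = 10,
) -> TrialBatch:
    """Flip-flop batch from per-trial pulse schedules.

    Each schedule entry is ``(bit, onset, sign)`` with sign in {-1, +1}.  The
    input channel for a bit carries the signed pulse for ``pulse_width``
    steps; the matching output target holds the sign of the last pulse from
    the end of that pulse until the next one (0 before the first pulse).
    """
    K = len(schedules)
    inputs = np.zeros((n_bits, n_steps, K))
    targets = np.zeros((n_bits, n_steps, K))
    labels = []
    for k, schedule in enumerate(schedules):
        per_bit: dict[int, list[tuple[int, int]]] = {}
        for bit, t0, sign in schedule:
            if sign not in (-1, 1):
                raise ValueError("pulse amplitude must be -1 or +1")
            if not 0 <= bit < n_bits:
                raise ValueError(f"bit index {bit} out of range")
            per_bit.setdefault(bit, []).append((t0, sign))
        for bit, pulses in per_bit.items():
            pulses = sorted(pulses)
            for i, (t0, _) in enumerate(pulses[:-1]):
                if pulses[i + 1][0] < t0 + pulse_width:
                    raise ValueError("overlapping pulses on one channel")
            for t0, sign in pulses:
                inputs[bit, t0:t0 + pulse_width, k] = sign
                targets[bit, t0 + pulse_width:, k] = sign
        labels.append({"schedule": [list(p) for p in schedule]})
    mask = np.ones(n_steps, dtype=bool)
    return TrialBatch(inputs=inputs, targets=targets, mask=mask,
                      labels=labels, task="flipflop")
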