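"""Shared fixtures: small trial batches and session-scoped trained networks.

Training is expensive, so trained networks are built once per session at a
reduced scale (fewer units, conditions and iterations than the full study)
and shared across the geometry, latent-circuit and behavioral tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import actbias as ab
from actbias.rnn import train_population

#: Reduced CDDM coherence grid used for scaled-down training and analyses
#: (50 conditions).  Zero coherence is kept: the zero-evidence trials anchor
#: the balanced context-gating solutions.
SMALL_GRID = (-1.0, -0.25, 0.0, 0.25, 1.0)


@pytest.fixture(scope="session")
def cddm_small_batch():
    return ab.build_cddm_batch(ab.enumerate_cddm_conditions(SMALL_GRID))


@pytest.fixture(scope="session")
def cddm_full_batch():
    return ab.build_cddm_batch()


@pytest.fixture(scope="session")
def deep_nets(cddm_small_batch):
    """Three relu+Dale and three tanh+Dale 50-unit networks, well trained.

    Used for the latent-circuit fit-quality, variance-capture and
    out-of-distribution dissociation tests, which need networks that
    genuinely solve the task at a size where the architecture-specific
    gating solutions emerge.  Trained in single precision for speed; the
    realizations are not compared against a double-precision reference.
    """
    pop = ([ab.initialize_rnn("relu", True, n_units=50, seed=s)
            for s in (0, 1, 2)]
           + [ab.initialize_rnn("tanh", True, n_units=50, seed=s)
              for s in (10, 11, 12)])
    trained, trace = train_population(pop, cddm_small_batch, n_iter=2500,
                                      lr=0.003, seed=5, precision="single")
    assert np.all(trace[-1] < trace[0])
    return {"relu": trained[:3], "tanh": trained[3:]}
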