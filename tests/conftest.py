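"""Shared fixtures: small simulated events and the benchmark cohort.

The cohort fixture mirrors the study conditions the package targets:
2-second scan paths at 1000 Hz on a 1024x768 screen, alternating
fixations and saccades, several subjects with clearly separated O-U
parameter sets.  It is session-scoped because per-event inference over
~900 events is the dominant cost of the suite.
"""

import numpy as np
import pytest

import ougaze as og
from ougaze.io import RunConfig
from ougaze.pipeline import infer_descriptors
from ougaze.segmentation import GazeEvent

COHORT_SEED = 1234


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)


def make_event(params: og.OUParams, n: int, seed: int, kind: str = "fixation") -> GazeEvent:
    """Simulate one O-U event and wrap it with its true attractor attached."""
    r = np.random.default_rng(seed)
    x0 = params.mu + r.normal(0, 1, 2)
    x = og.simulate_event(params, x0, n, r)
    return GazeEvent(kind, 0, n, samples=x, attractor_mu=params.mu.copy())


@pytest.fixture(scope="session")
def cohort():
    spec = og.CohortSpec(
        n_subjects=5, n_scanpaths_per_subject=12, scanpath_len=2000,
        separation=1.5, seed=COHORT_SEED,
    )
    return og.generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_descriptors(cohort):
    """Segment every trajectory and infer per-event descriptors (MAP-Laplace)."""
    config = RunConfig()
    events = []
    for traj in cohort.trajectories:
        events.extend(og.segment_velocity(traj))
    descriptors, _ = infer_descriptors(events, config)
    return descriptors


@pytest.fixture(scope="session")
def cohort_scanpath_groups(cohort_descriptors):
    groups = {}
    for d in cohort_descriptors:
        groups.setdefault((d.subject_id, d.stimulus_id), []).append(d)
    return list(groups.values())
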