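"""Parsing raw gaze trajectories into fixation and saccade events.

Fixations are periods in which gaze is held nearly stationary on a
region of interest; saccades are the fast relocations between them.  The
default parser is a standard velocity-threshold (I-VT-style) classifier:
sample speeds below the threshold are fixational, above it saccadic, and
runs shorter than a per-kind minimum duration are absorbed into their
neighbours.  An adapter accepts per-sample labels produced by an
external event classifier instead.

Each parsed event carries its attractor point ``mu``: the centroid of a
fixation's samples, or the final (landing) sample of a saccade.  The
attractor is fixed by segmentation and excluded from later Bayesian
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ContractError, ValidationError
from .io import GazeTrajectory

logger = logging.getLogger(__name__)

FIXATION = "fixation"
SACCADE = "saccade"
KINDS = (FIXATION, SACCADE)

_MIN_EVENT_SAMPLES = 2


@dataclass
class GazeEvent:
    """A fixation or saccade slice of a parent trajectory.

    Spans are 0-based half-open sample indices ``[start, end)`` into the
    parent trajectory; ``samples`` is the corresponding (n, 2) slice.
    """

    kind: str
    start: int
    end: int
    samples: np.ndarray | None = None
    attractor_mu: np.ndarray | None = None
    subject_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.end - self.start < _MIN_EVENT_SAMPLES:
            raise ValidationError(
                f"event span [{self.start}, {self.end}) is shorter than 2 samples"
            )
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float)
            if len(self.samples) != self.end - self.start:
                raise ValidationError("sample slice length does not match the span")

    @property
    def n_transitions(self) -> int:
        return self.end - self.start - 1


def _smoothed_speed(samples: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-sample speed: centred finite differences, boxcar-smoothed.

    The velocity *vectors* are smoothed before taking the norm: zero-mean
    fixational noise averages out while coherent saccadic drift is
    preserved, which keeps the two regimes separable even for noisy
    fixations.
    """
    v = np.gradient(samples, axis=0)  # centred differences, one-sided ends
    kernel = np.ones(window) / window
    pad = window // 2
    smooth = np.empty_like(v)
    for d in range(2):
        padded = np.pad(v[:, d], pad, mode="edge")
        smooth[:, d] = np.convolve(padded, kernel, mode="valid")
    return np.hypot(smooth[:, 0], smooth[:, 1])


def _runs(mask: np.ndarray) -> list[list]:
    """Maximal runs of a boolean/label array as [value, start, end) triples."""
    mask = np.asarray(mask)
    edges = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    bounds = np.concatenate(([0], edges, [len(mask)]))
    return [[mask[a], int(a), int(b)] for a, b in zip(bounds[:-1], bounds[1:])]


def _merge_short_runs(runs: list[list], minima: dict) -> list[list]:
    """Flip sub-minimal runs into the other kind until all runs qualify."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [(r[2] - r[1]) - minima[r[0]] for r in runs]
        worst = int(np.argmin(lengths))
        if lengths[worst] >= 0:
            break
        runs[worst][0] = not runs[worst][0]
        merged: list[list] = []
        for r in runs:  # coalesce adjacent runs of the same kind
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged
    return runs


def segment_velocity(
    traj: GazeTrajectory,
    vel_threshold: float = 0.8,
    min_fix_samples: int = 40,
    min_sac_samples: int = 10,
) -> list[GazeEvent]:
    """Velocity-threshold parse into alternating fixations and saccades.

    Samples with smoothed speed (px/sample) below ``vel_threshold`` are
    fixational, above it saccadic; runs shorter than the per-kind minimum
    are merged into the neighbouring event of the other kind.
    """
    if vel_threshold <= 0 or min_fix_samples <= 0 or min_sac_samples <= 0:
        raise ContractError("segmentation thresholds must be positive")
    if len(traj) < min_fix_samples:
        logger.warning(
            "trajectory (%s, %s) shorter than min_fix_samples; no events",
            traj.subject_id,
            traj.stimulus_id,
        )
        return []
    fast = _smoothed_speed(traj.samples) > vel_threshold
    minima = {False: min_fix_samples, True: min_sac_samples}
    runs = _merge_short_runs(_runs(fast), minima)
    events = [
        GazeEvent(
            kind=SACCADE if is_fast else FIXATION,
            start=a,
            end=b,
            samples=traj.samples[a:b],
            subject_id=traj.subject_id,
            stimulus_id=traj.stimulus_id,
        )
        for is_fast, a, b in runs
        if b - a >= _MIN_EVENT_SAMPLES
    ]
    return attach_attractors(events)


def attach_attractors(events: Sequence[GazeEvent]) -> list[GazeEvent]:
    """Set each event's attractor: fixation centroid or saccade landing point."""
    for ev in events:
        if ev.samples is None or len(ev.samples) == 0:
            raise ContractError("attach_attractors requires events with sample slices")
        if ev.kind == FIXATION:
            ev.attractor_mu = ev.samples.mean(axis=0)
        else:
            ev.attractor_mu = ev.samples[-1].copy()
    return list(events)


def import_external_segmentation(
    traj: GazeTrajectory, labels: Sequence[str]
) -> list[GazeEvent]:
    """Build events from per-sample labels of an external event classifier.

    Labels must be one of ``fixation``, ``saccade`` or ``other``; runs of
    ``other`` (smooth pursuit, post-saccadic oscillations, ...) are dropped,
    as are degenerate single-sample runs.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(traj):
        raise ValidationError(
            f"label count {len(labels)} does not match trajectory length {len(traj)}"
        )
    bad = set(labels) - {FIXATION, SACCADE, "other"}
    if bad:
        raise ValidationError(f"unknown labels in external segmentation: {sorted(bad)}")
    events = []
    for value, a, b in _runs(labels):
        if value == "other":
            continue
        if b - a < _MIN_EVENT_SAMPLES:
            logger.warning("dropping single-sample %s run at index %d", value, a)
            continue
        events.append(
            GazeEvent(
                kind=str(value),
                start=a,
                end=b,
                samples=traj.samples[a:b],
                subject_id=traj.subject_id,
                stimulus_id=traj.stimulus_id,
            )
        )
    return attach_attractors(events)
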