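"""Tabular input/output for gaze trajectories, events and feature tables.

There is no standard interchange format for raw gaze recordings, so the
package defines a minimal CSV dialect (comma-separated, UTF-8, header
row):

* gaze table      — ``subject_id,stimulus_id,t_ms,x_px,y_px`` (``t_ms``
  optional; sample order within a trajectory is file order);
* events table    — ``subject_id,stimulus_id,kind,start,end,mu_x,mu_y``
  with 0-based half-open sample spans ``[start, end)``;
* features table  — one row per event: ids, kind and the twelve
  descriptor columns in their canonical order (see :mod:`ougaze.features`).

Coordinates are screen pixels, origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

GAZE_COLUMNS = ("subject_id", "stimulus_id", "t_ms", "x_px", "y_px")
EVENT_COLUMNS = ("subject_id", "stimulus_id", "kind", "start", "end", "mu_x", "mu_y")


@dataclass
class GazeTrajectory:
    """An ordered 2-D gaze recording for one (subject, stimulus) pair."""

    subject_id: str
    stimulus_id: str
    sample_rate_hz: float
    samples: np.ndarray  # (n, 2) px
    t: np.ndarray | None = None  # optional timestamps, ms

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValidationError("samples must be an (n, 2) array")
        if len(self.samples) < 2:
            raise ValidationError(
                f"trajectory ({self.subject_id}, {self.stimulus_id}) needs >= 2 samples"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(
                f"trajectory ({self.subject_id}, {self.stimulus_id}) has non-finite samples"
            )
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)
            if len(self.t) != len(self.samples):
                raise ValidationError("timestamp count must match sample count")
            if np.any(np.diff(self.t) <= 0):
                raise ValidationError(
                    "timestamps must be strictly increasing in trajectory "
                    f"({self.subject_id}, {self.stimulus_id})"
                )

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class SegmentationConfig:
    vel_threshold: float = 0.8      # px/sample
    min_fix_samples: int = 40
    min_sac_samples: int = 10

    def validate(self) -> None:
        if self.vel_threshold <= 0 or self.min_fix_samples <= 0 or self.min_sac_samples <= 0:
            raise ConfigError("segmentation thresholds must be positive")


@dataclass
class InferenceConfig:
    method: str = "map_laplace"     # "map_laplace" | "vi"
    n_draws: int = 1000
    vi_iterations: int = 5000
    hdi_mass: float = 0.94
    min_transitions: int = 5
    jitter: float = 1e-9
    seed: int = 0

    def validate(self) -> None:
        if self.method not in ("map_laplace", "vi"):
            raise ConfigError(f"unknown inference method {self.method!r}")
        if not 0.0 < self.hdi_mass < 1.0:
            raise ConfigError("hdi_mass must lie in (0, 1)")
        if self.n_draws < 2 or self.vi_iterations < 1 or self.min_transitions < 1:
            raise ConfigError("inference counts must be positive")


@dataclass
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "median"   # median heuristic or explicit value

    def validate(self) -> None:
        if self.C <= 0:
            raise ConfigError("regularisation constant C must be positive")


@dataclass
class CVConfig:
    k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ConfigError("cross-validation needs k >= 2")


@dataclass
class RunConfig:
    """Bundle of per-stage settings; serialisable to/from JSON."""

    sample_rate_hz: float = 1000.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    simulator: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        self.segmentation.validate()
        self.inference.validate()
        self.classifier.validate()
        self.cv.validate()

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        cfg = cls(
            sample_rate_hz=raw.get("sample_rate_hz", 1000.0),
            segmentation=SegmentationConfig(**raw.get("segmentation", {})),
            inference=InferenceConfig(**raw.get("inference", {})),
            classifier=ClassifierConfig(**raw.get("classifier", {})),
            cv=CVConfig(**raw.get("cv", {})),
            simulator=raw.get("simulator", {}),
        )
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# gaze tables

def read_gaze_table(
    path,
    schema: Mapping[str, str] | None = None,
    sample_rate_hz: float = 1000.0,
) -> list[GazeTrajectory]:
    """Read a gaze CSV into one trajectory per (subject, stimulus) pair.

    ``schema`` maps canonical column names (``subject_id``, ``stimulus_id``,
    ``t_ms``, ``x_px``, ``y_px``) to the names used in the file.  ``t_ms``
    may be absent, in which case sample indices at the stated rate stand in.
    """
    schema = dict(schema or {})
    names = {c: schema.get(c, c) for c in GAZE_COLUMNS}
    df = pd.read_csv(path, float_precision="round_trip")
    for canon in ("subject_id", "stimulus_id", "x_px", "y_px"):
        if names[canon] not in df.columns:
            raise SchemaError(f"gaze table is missing required column {names[canon]!r}")
    has_t = names["t_ms"] in df.columns

    trajectories: list[GazeTrajectory] = []
    n_rows = 0
    for (subj, stim), grp in df.groupby(
        [names["subject_id"], names["stimulus_id"]], sort=False
    ):
        samples = grp[[names["x_px"], names["y_px"]]].to_numpy(dtype=float)
        t = grp[names["t_ms"]].to_numpy(dtype=float) if has_t else None
        trajectories.append(
            GazeTrajectory(str(subj), str(stim), sample_rate_hz, samples, t)
        )
        n_rows += len(samples)
    if n_rows != len(df):  # pragma: no cover - defensive
        raise ValidationError("reader dropped rows; input is inconsistent")
    return trajectories


def write_gaze_table(trajectories: Sequence[GazeTrajectory], path) -> None:
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": traj.subject_id,
                    "stimulus_id": traj.stimulus_id,
                    "t_ms": traj.t
                    if traj.t is not None
                    else np.arange(len(traj)) * 1000.0 / traj.sample_rate_hz,
                    "x_px": traj.samples[:, 0],
                    "y_px": traj.samples[:, 1],
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(GAZE_COLUMNS))
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event tables

def write_events(events: Sequence, path) -> None:
    """Write GazeEvents (see :mod:`ougaze.segmentation`) as a CSV table."""
    rows = []
    for ev in events:
        mu = ev.attractor_mu
        rows.append(
            {
                "subject_id": ev.subject_id,
                "stimulus_id": ev.stimulus_id,
                "kind": ev.kind,
                "start": ev.start,
                "end": ev.end,
                "mu_x": np.nan if mu is None else mu[0],
                "mu_y": np.nan if mu is None else mu[1],
            }
        )
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def read_events(path, trajectories: Sequence[GazeTrajectory] | None = None) -> list:
    """Read an events CSV; re-attaches sample slices if trajectories given."""
    from .segmentation import GazeEvent  # deferred: avoid import cycle

    df = pd.read_csv(path, float_precision="round_trip")
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"events table is missing required column {col!r}")
    by_key = {}
    if trajectories is not None:
        by_key = {(t.subject_id, t.stimulus_id): t for t in trajectories}
    events = []
    for row in df.itertuples(index=False):
        key = (str(row.subject_id), str(row.stimulus_id))
        samples = None
        if by_key:
            if key not in by_key:
                raise ValidationError(f"events reference unknown trajectory {key}")
            samples = by_key[key].samples[int(row.start): int(row.end)]
        mu = None
        if np.isfinite(row.mu_x) and np.isfinite(row.mu_y):
            mu = np.array([row.mu_x, row.mu_y], dtype=float)
        events.append(
            GazeEvent(
                kind=str(row.kind),
                start=int(row.start),
                end=int(row.end),
                samples=samples,
                attractor_mu=mu,
                subject_id=key[0],
                stimulus_id=key[1],
            )
        )
    return events


# ---------------------------------------------------------------------------
# feature tables

def write_features(descriptors: Sequence, path) -> None:
    """Write per-event 12-component descriptors as a CSV table."""
    from .features import DESCRIPTOR_NAMES

    rows = []
    for d in descriptors:
        row = {"subject_id": d.subject_id, "stimulus_id": d.stimulus_id, "kind": d.kind}
        row.update(dict(zip(DESCRIPTOR_NAMES, d.vector)))
        rows.append(row)
    cols = ["subject_id", "stimulus_id", "kind", *DESCRIPTOR_NAMES]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_features(path) -> list:
    from .features import DESCRIPTOR_NAMES, EventDescriptor

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("subject_id", "stimulus_id", "kind", *DESCRIPTOR_NAMES):
        if col not in df.columns:
            raise SchemaError(f"features table is missing required column {col!r}")
    return [
        EventDescriptor(
            vector=np.array([getattr(row, c) for c in DESCRIPTOR_NAMES], dtype=float),
            kind=str(row.kind),
            subject_id=str(row.subject_id),
            stimulus_id=str(row.stimulus_id),
        )
        for row in df.itertuples(index=False)
    ]
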