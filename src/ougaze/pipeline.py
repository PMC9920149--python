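"""End-to-end orchestration: simulate -> segment -> fit -> featurize ->
train -> evaluate, with inspectable CSV/JSON artefacts per stage."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io
from .evaluate import cohort_scanpath_descriptors, crossvalidate
from .exceptions import ConfigError, ContractError, DependencyError
from .features import EventDescriptor, event_descriptor
from .identify import IdModel, fuse_and_identify, train_models
from .inference import PriorSpec, infer_event_posterior
from .io import RunConfig
from .segmentation import GazeEvent, segment_velocity
from .simulate import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "fit", "featurize", "train", "evaluate")

ARTEFACTS = {
    "simulate": ("gaze.csv", "events_true.csv", "cohort.json"),
    "segment": ("events.csv",),
    "fit": ("features.csv",),
    "featurize": ("scanpaths.csv",),
    "train": ("model.json",),
    "evaluate": ("report.json",),
}


def infer_descriptors(
    events: Sequence[GazeEvent],
    config: RunConfig,
    prior: PriorSpec | None = None,
) -> tuple[list[EventDescriptor], int]:
    """Per-event posterior inference over a cohort's events.

    Events with fewer transitions than the configured minimum are counted
    and excluded (flagged in the log, not silently dropped).  Each event
    gets its own deterministic seed derived from the run seed.
    """
    inf_cfg = config.inference
    descriptors: list[EventDescriptor] = []
    excluded = 0
    for a, ev in enumerate(events):
        if ev.n_transitions < inf_cfg.min_transitions:
            excluded += 1
            continue
        ev_cfg = io.InferenceConfig(**{**asdict(inf_cfg),
                                       "seed": (inf_cfg.seed + a) % (2**31 - 1)})
        summary = infer_event_posterior(ev, prior, method=inf_cfg.method, config=ev_cfg)
        if not summary.converged:
            logger.warning("inference flagged non-convergence for event %d", a)
        descriptors.append(
            event_descriptor(summary, ev.kind, ev.subject_id, ev.stimulus_id)
        )
    logger.info("inferred %d events, excluded %d too-short events",
                len(descriptors), excluded)
    return descriptors, excluded


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = STAGES,
    out_dir: str | Path = "ougaze_run",
) -> dict:
    """Run the requested stages in dependency order.

    Every stage reads and writes the documented tabular artefacts under
    ``out_dir``; a stage whose upstream artefact is absent raises
    :class:`DependencyError` naming the stage.  Returns artefact paths
    plus the metrics report when ``evaluate`` is included.
    """
    config.validate()
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for stage in STAGES for name in ARTEFACTS[stage]}
    result: dict = {"out_dir": str(out), "config_hash": _config_hash(config)}

    def require(stage: str, *names: str):
        for name in names:
            if not paths[name].exists():
                raise DependencyError(
                    f"stage {stage!r} requires missing artefact {name!r}"
                )

    if "simulate" in stages:
        spec = CohortSpec(**config.simulator) if config.simulator else CohortSpec()
        cohort = generate_cohort(spec)
        io.write_gaze_table(cohort.trajectories, paths["gaze.csv"])
        io.write_events(
            [e for evs in cohort.events.values() for e in evs],
            paths["events_true.csv"],
        )
        spec.to_json(paths["cohort.json"])

    if "segment" in stages:
        require("segment", "gaze.csv")
        trajs = io.read_gaze_table(paths["gaze.csv"],
                                   sample_rate_hz=config.sample_rate_hz)
        seg = config.segmentation
        events = []
        for traj in trajs:
            events.extend(
                segment_velocity(traj, seg.vel_threshold,
                                 seg.min_fix_samples, seg.min_sac_samples)
            )
        io.write_events(events, paths["events.csv"])

    if "fit" in stages:
        require("fit", "gaze.csv", "events.csv")
        trajs = io.read_gaze_table(paths["gaze.csv"],
                                   sample_rate_hz=config.sample_rate_hz)
        events = io.read_events(paths["events.csv"], trajs)
        descriptors, excluded = infer_descriptors(events, config)
        io.write_features(descriptors, paths["features.csv"])
        result["n_events_excluded"] = excluded

    if "featurize" in stages:
        require("featurize", "features.csv")
        descriptors = io.read_features(paths["features.csv"])
        import pandas as pd

        from .features import DESCRIPTOR_NAMES

        rows = []
        for sp in cohort_scanpath_descriptors(descriptors):
            row = {"subject_id": sp.subject_id, "stimulus_id": sp.stimulus_id,
                   "F": sp.F, "S": sp.S}
            names = [f"fix_{n}" for n in DESCRIPTOR_NAMES] + [
                f"sac_{n}" for n in DESCRIPTOR_NAMES
            ]
            row.update(dict(zip(names, sp.vector)))
            rows.append(row)
        pd.DataFrame(rows).to_csv(paths["scanpaths.csv"], index=False)

    if "train" in stages:
        require("train", "features.csv")
        descriptors = io.read_features(paths["features.csv"])
        model = train_models(descriptors, config.classifier)
        model.to_json(paths["model.json"])

    if "evaluate" in stages:
        require("evaluate", "features.csv", "model.json")
        descriptors = io.read_features(paths["features.csv"])
        groups: dict[tuple, list] = {}
        for d in descriptors:
            groups.setdefault((d.subject_id, d.stimulus_id), []).append(d)
        report = crossvalidate(
            list(groups.values()), k=config.cv.k, seed=config.cv.seed,
            classifier=config.classifier,
        )
        with open(paths["report.json"], "w", encoding="utf-8") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        result["report"] = report

    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"config_hash": result["config_hash"],
             "stages": list(stages),
             "artefacts": {n: str(p) for n, p in paths.items() if p.exists()}},
            fh, indent=2,
        )
    result["artefacts"] = {n: str(p) for n, p in paths.items() if p.exists()}
    return result


def identify_trajectories(model: IdModel, descriptors: Sequence[EventDescriptor]):
    """Fused identification of every (subject, stimulus) group of descriptors."""
    groups: dict[tuple, list] = {}
    for d in descriptors:
        groups.setdefault((d.subject_id, d.stimulus_id), []).append(d)
    if not groups:
        raise ContractError("no descriptors to identify")
    out = []
    for (subj, stim), evs in groups.items():
        pred, fused = fuse_and_identify(model, evs)
        out.append({"subject_id": subj, "stimulus_id": stim,
                    "predicted_id": pred,
                    "fused_scores": fused.tolist()})
    return out
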