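"""Event, scan-path and subject descriptors built from posterior summaries.

The per-event descriptor is a fixed-order 12-vector: for each of the six
free matrix components (B_ii, B_ij, B_jj, Gamma_ii, Gamma_ij, Gamma_jj)
the posterior mean followed by the HDI width (the scalar uncertainty of
the estimate).  A scan path is summarised by the componentwise mean of
its fixation descriptors concatenated with the mean of its saccade
descriptors (24 entries, fixation block first); a subject by the mean of
their scan-path descriptors over the viewed stimuli.

A kind absent from a scan path (e.g. a recording whose saccades all fall
below the minimum-length filter) leaves its block as NaN sentinels with a
zero contributing count; subject summaries renormalise over the scan
paths where each block is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ContractError
from .inference import COMPONENTS, PosteriorSummary
from .segmentation import FIXATION, SACCADE

DESCRIPTOR_NAMES = tuple(
    f"{comp}_{stat}" for comp in COMPONENTS for stat in ("avg", "hdi")
)
N_EVENT_FEATURES = len(DESCRIPTOR_NAMES)  # 12


@dataclass
class EventDescriptor:
    vector: np.ndarray  # (12,)
    kind: str
    subject_id: str
    stimulus_id: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (N_EVENT_FEATURES,):
            raise ContractError("event descriptor must have 12 components")
        if np.any(self.vector[1::2] < 0):
            raise ContractError("HDI-width entries must be non-negative")


@dataclass
class ScanpathDescriptor:
    vector: np.ndarray  # (24,) fixation block then saccade block
    F: int
    S: int
    subject_id: str
    stimulus_id: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (2 * N_EVENT_FEATURES,):
            raise ContractError("scan-path descriptor must have 24 components")
        if self.F < 1 and self.S < 1:
            raise ContractError("scan path must contribute at least one event")


@dataclass
class SubjectSummary:
    vector: np.ndarray  # (24,)
    K: int
    subject_id: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (2 * N_EVENT_FEATURES,):
            raise ContractError("subject summary must have 24 components")


def event_descriptor(
    summary: PosteriorSummary, kind: str, subject_id: str = "", stimulus_id: str = ""
) -> EventDescriptor:
    """Flatten a posterior summary into the fixed-order 12-vector."""
    vec = np.empty(N_EVENT_FEATURES)
    for a, comp in enumerate(COMPONENTS):
        if comp not in summary.mean:
            raise ContractError(f"posterior summary is missing component {comp}")
        vec[2 * a] = summary.mean[comp]
        vec[2 * a + 1] = summary.hdi_width(comp)
    return EventDescriptor(vec, kind, subject_id, stimulus_id)


def scanpath_descriptor(events: Sequence[EventDescriptor]) -> ScanpathDescriptor:
    """Mean-within-kind concatenation over one trajectory's event descriptors."""
    if not events:
        raise ContractError("scan path has no event descriptors")
    blocks = {}
    counts = {}
    for kind in (FIXATION, SACCADE):
        vecs = [e.vector for e in events if e.kind == kind]
        counts[kind] = len(vecs)
        blocks[kind] = (
            np.mean(vecs, axis=0) if vecs else np.full(N_EVENT_FEATURES, np.nan)
        )
    return ScanpathDescriptor(
        vector=np.concatenate([blocks[FIXATION], blocks[SACCADE]]),
        F=counts[FIXATION],
        S=counts[SACCADE],
        subject_id=events[0].subject_id,
        stimulus_id=events[0].stimulus_id,
    )


def subject_summary(scanpaths: Sequence[ScanpathDescriptor]) -> SubjectSummary:
    """Componentwise mean over a subject's scan-path descriptors.

    NaN sentinel blocks (absent kinds) are ignored with renormalised
    counts; a component that is missing everywhere stays NaN.
    """
    if not scanpaths:
        raise ContractError("subject has no scan-path descriptors")
    stacked = np.vstack([sp.vector for sp in scanpaths])
    with np.errstate(invalid="ignore"):
        vec = np.where(
            np.all(np.isnan(stacked), axis=0),
            np.nan,
            np.nanmean(stacked, axis=0),
        )
    return SubjectSummary(vector=vec, K=len(scanpaths), subject_id=scanpaths[0].subject_id)
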