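"""Synthetic scan-path generation from the switching O-U gaze model.

A scan path alternates fixations and saccades.  Each regime is an O-U
process with its own drift and diffusion matrices: fixations revert to a
local centre, saccades are pulled toward a freshly chosen on-screen
target; each fixation centre is the landing point of the preceding
saccade, so trajectories are continuous.  Event durations are drawn from
configurable distributions (log-normal fixations, uniform saccades, in
samples).

Cohort generation draws one parameter set per subject from log-normal
hyper-distributions around a common base; the ``separation`` knob scales
the between-subject spread and is the single control for how
discriminable the synthetic population is (0 = identical subjects).

Defaults emulate free viewing of static images at 1000 Hz on a
1024x768 px screen with 2-second recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, ContractError
from .io import GazeTrajectory
from .ou import OUParams, TransitionMoments, _eigen_terms, _symmetrize_clip
from .segmentation import FIXATION, SACCADE, GazeEvent, attach_attractors

_TARGET_INSET_PX = 50.0


@dataclass(frozen=True)
class DurationSpec:
    """Event-duration distribution, in samples."""

    family: str  # "lognormal" (mean, sd of the distribution) | "uniform" (low, high)
    a: float
    b: float

    def draw(self, rng: np.random.Generator) -> int:
        if self.family == "lognormal":
            mean, sd = self.a, self.b
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - 0.5 * sigma2
            d = rng.lognormal(mu, np.sqrt(sigma2))
        elif self.family == "uniform":
            d = rng.uniform(self.a, self.b)
        else:
            raise ConfigError(f"unknown duration family {self.family!r}")
        return max(2, int(round(d)))


def spd_from_scales(diag: np.ndarray, rho: float) -> np.ndarray:
    """Symmetric positive-definite 2x2 from diagonal entries and correlation."""
    d1, d2 = float(diag[0]), float(diag[1])
    off = rho * np.sqrt(d1 * d2)
    return np.array([[d1, off], [off, d2]])


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject O-U regimes and duration distributions."""

    B_fix: np.ndarray
    Gamma_fix: np.ndarray
    B_sac: np.ndarray
    Gamma_sac: np.ndarray
    fix_duration: DurationSpec = field(
        default_factory=lambda: DurationSpec("lognormal", 250.0, 80.0)
    )
    sac_duration: DurationSpec = field(
        default_factory=lambda: DurationSpec("uniform", 20.0, 60.0)
    )

    def params_for(self, kind: str, mu: np.ndarray) -> OUParams:
        if kind == FIXATION:
            return OUParams(self.B_fix, self.Gamma_fix, mu)
        return OUParams(self.B_sac, self.Gamma_sac, mu)


# base hyper-means: gentle local drift with small diffusion for fixations,
# strong pull with larger diffusion for saccades (px, samples at 1 kHz)
_BASE = {
    "B_fix_diag": (0.03, 0.03),
    "Gamma_fix_diag": (0.5, 0.5),
    "B_sac_diag": (0.2, 0.2),
    "Gamma_sac_diag": (2.0, 2.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic multi-subject cohort."""

    n_subjects: int = 5
    n_scanpaths_per_subject: int = 12
    scanpath_len: int = 2000
    screen: tuple = (1024, 768)
    separation: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_scanpaths_per_subject < 1:
            raise ConfigError("cohort counts must be >= 1")
        if self.scanpath_len < 4:
            raise ConfigError("scanpath_len is too short")
        if self.screen[0] <= 0 or self.screen[1] <= 0:
            raise ConfigError("screen dimensions must be positive")
        if self.separation < 0:
            raise ConfigError("separation must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "n_subjects": self.n_subjects,
                    "n_scanpaths_per_subject": self.n_scanpaths_per_subject,
                    "scanpath_len": self.scanpath_len,
                    "screen": list(self.screen),
                    "separation": self.separation,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["screen"] = tuple(raw.get("screen", (1024, 768)))
        spec = cls(**raw)
        spec.validate()
        return spec


@dataclass
class Cohort:
    """Simulated cohort: trajectories, per-trajectory truth, subject params."""

    spec: CohortSpec
    trajectories: list
    events: dict          # (subject_id, stimulus_id) -> list[GazeEvent]
    subject_params: dict  # subject_id -> SubjectParams


def simulate_event(
    params: OUParams, x0, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Iterate exact unit-step transitions from ``x0``; returns n samples."""
    if n < 2:
        raise ContractError("simulate_event needs n >= 2")
    w, Q, Dp, denom = _eigen_terms(params.B, params.Gamma)
    ew = np.exp(-w)
    Psi = _symmetrize_clip(Q @ (Dp * (1.0 - np.exp(-denom))) @ Q.T)
    pw, pV = np.linalg.eigh(Psi)
    root = pV * np.sqrt(np.clip(pw, 0.0, None))
    eps = rng.standard_normal((n - 1, 2))
    out = np.empty((n, 2))
    out[0] = np.asarray(x0, dtype=float)
    mu = params.mu
    for i in range(1, n):
        yp = Q.T @ (out[i - 1] - mu)
        out[i] = mu + Q @ (ew * yp) + root @ eps[i - 1]
    return out


def simulate_scanpath(
    subject: SubjectParams,
    screen,
    total: int,
    rng: np.random.Generator,
    subject_id: str = "s0",
    stimulus_id: str = "k0",
    sample_rate_hz: float = 1000.0,
) -> tuple[GazeTrajectory, list[GazeEvent]]:
    """Simulate one scan path and its ground-truth event list.

    The path starts with a fixation at a uniformly drawn on-screen point;
    each saccade aims at a fresh uniform target (50 px inset) and the next
    fixation reverts to that saccade's landing point.  Event spans are
    contiguous half-open intervals; each event's first sample is produced
    by its predecessor, so the trajectory is continuous.
    """
    if screen[0] <= 0 or screen[1] <= 0:
        raise ConfigError("screen dimensions must be positive")
    if total < 4:
        raise ContractError("total must allow at least one short event")
    lo = np.array([_TARGET_INSET_PX, _TARGET_INSET_PX])
    hi = np.array(screen, dtype=float) - _TARGET_INSET_PX

    start_mu = rng.uniform(lo, hi)
    samples = [start_mu.copy()]
    spans: list[tuple[str, int, int]] = []
    kind = FIXATION
    mu = start_mu
    generated = 1  # samples produced so far; event spans tile [0, generated)
    while generated < total:
        dur = (subject.fix_duration if kind == FIXATION else subject.sac_duration).draw(rng)
        a = 0 if not spans else generated
        b = min(a + dur, total)
        n_new = b - generated
        if b - a < 2 or n_new < 1:
            break
        params = subject.params_for(kind, mu)
        seg = simulate_event(params, samples[-1], n_new + 1, rng)
        samples.extend(seg[1:])
        generated = b
        spans.append((kind, a, b))
        if kind == FIXATION:
            kind = SACCADE
            mu = rng.uniform(lo, hi)  # fresh saccade target
        else:
            kind = FIXATION
            mu = seg[-1].copy()  # fixate the landing point
    traj = GazeTrajectory(
        subject_id, stimulus_id, sample_rate_hz, np.asarray(samples)
    )
    events = [
        GazeEvent(
            kind=k,
            start=a,
            end=b,
            samples=traj.samples[a:b],
            subject_id=subject_id,
            stimulus_id=stimulus_id,
        )
        for k, a, b in spans
    ]
    return traj, attach_attractors(events)


def draw_subject_params(
    rng: np.random.Generator, separation: float = 1.0
) -> SubjectParams:
    """One subject's parameter set from the cohort hyper-distributions.

    Diagonal entries are log-normal around the base values with log-sd
    ``0.4 * separation``, the normal deviate truncated at +-1.5 so that
    every subject stays physiologically plausible (in particular,
    fixational diffusion never reaches saccadic speeds, which would make
    the regime labels self-contradictory); correlations are ``tanh`` of a
    centred normal with sd ``0.5 * separation``, clipped to (-0.8, 0.8).
    """
    def diag(base):
        z = np.clip(rng.standard_normal(2), -1.5, 1.5)
        return np.asarray(base) * np.exp(0.4 * separation * z)

    def rho():
        return float(np.clip(np.tanh(0.5 * separation * rng.standard_normal()), -0.8, 0.8))

    return SubjectParams(
        B_fix=spd_from_scales(diag(_BASE["B_fix_diag"]), rho()),
        Gamma_fix=spd_from_scales(diag(_BASE["Gamma_fix_diag"]), rho()),
        B_sac=spd_from_scales(diag(_BASE["B_sac_diag"]), rho()),
        Gamma_sac=spd_from_scales(diag(_BASE["Gamma_sac_diag"]), rho()),
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a labelled multi-subject cohort with ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subject_params = {
        f"s{a:02d}": draw_subject_params(rng, spec.separation)
        for a in range(spec.n_subjects)
    }
    trajectories = []
    events = {}
    for subj, params in subject_params.items():
        for k in range(spec.n_scanpaths_per_subject):
            stim = f"k{k:03d}"
            traj, evs = simulate_scanpath(
                params,
                spec.screen,
                spec.scanpath_len,
                rng,
                subject_id=subj,
                stimulus_id=stim,
            )
            trajectories.append(traj)
            events[(subj, stim)] = evs
    return Cohort(spec, trajectories, events, subject_params)
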