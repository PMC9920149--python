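"""Subject identification from event descriptors.

Two one-vs-rest margin-classifier banks are trained separately — one on
fixation descriptors, one on saccade descriptors — over the same class
list.  For a probe trajectory, each event is scored by the bank matching
its kind, decision vectors are averaged per kind, and the two averages
are summed (score-level fusion); the predicted identity is the argmax.

Features are z-scored per kind with statistics fitted on the training
data only.  The kernel is RBF with the regularisation constant C and a
median-heuristic bandwidth by default.  Trained models serialise to a
documented JSON form (class list, standardiser, kernel spec, support
vectors and dual weights) and decision values are computed directly from
those arrays, so a reloaded model is bit-identical in behaviour.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .exceptions import ContractError, ValidationError
from .features import EventDescriptor, N_EVENT_FEATURES
from .io import ClassifierConfig
from .segmentation import FIXATION, SACCADE

logger = logging.getLogger(__name__)


@dataclass
class _BinaryMargin:
    """One class's decision function: f(x) = sum_a alpha_a K(sv_a, x) + b."""

    support_vectors: np.ndarray  # (m, 12) standardised
    dual_coef: np.ndarray        # (m,) signed alphas
    intercept: float
    gamma: float

    def decide(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept


@dataclass
class IdModel:
    """Per-kind one-vs-rest classifier banks with their standardisers."""

    classes: list
    scalers: dict = field(default_factory=dict)      # kind -> (loc, scale)
    classifiers: dict = field(default_factory=dict)  # kind -> {class: _BinaryMargin|None}
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def standardize(self, kind: str, X: np.ndarray) -> np.ndarray:
        if kind not in self.scalers:
            raise ValidationError(f"model has no classifier bank for kind {kind!r}")
        loc, scale = self.scalers[kind]
        return (X - loc) / scale

    def to_json(self, path) -> None:
        blob = {
            "classes": self.classes,
            "config": {"kernel": self.config.kernel, "C": self.config.C,
                       "gamma": self.config.gamma},
            "scalers": {
                k: {"loc": loc.tolist(), "scale": scale.tolist()}
                for k, (loc, scale) in self.scalers.items()
            },
            "classifiers": {
                k: {
                    cls: None
                    if clf is None
                    else {
                        "support_vectors": clf.support_vectors.tolist(),
                        "dual_coef": clf.dual_coef.tolist(),
                        "intercept": clf.intercept,
                        "gamma": clf.gamma,
                    }
                    for cls, clf in bank.items()
                }
                for k, bank in self.classifiers.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(blob, fh)

    @classmethod
    def from_json(cls, path) -> "IdModel":
        with open(path, encoding="utf-8") as fh:
            blob = json.load(fh)
        model = cls(
            classes=blob["classes"],
            config=ClassifierConfig(**blob["config"]),
        )
        for k, sc in blob["scalers"].items():
            model.scalers[k] = (np.asarray(sc["loc"]), np.asarray(sc["scale"]))
        for k, bank in blob["classifiers"].items():
            model.classifiers[k] = {
                c: None
                if spec is None
                else _BinaryMargin(
                    np.asarray(spec["support_vectors"]),
                    np.asarray(spec["dual_coef"]),
                    float(spec["intercept"]),
                    float(spec["gamma"]),
                )
                for c, spec in bank.items()
            }
        return model


def _median_heuristic_gamma(X: np.ndarray, rng_cap: int = 2000) -> float:
    """RBF bandwidth gamma = 1 / (2 * median pairwise distance^2)."""
    if len(X) > rng_cap:
        X = X[:: int(np.ceil(len(X) / rng_cap))]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    med2 = float(np.median(d2[np.triu_indices(len(X), 1)]))
    if med2 <= 0:
        return 1.0 / X.shape[1]
    return 1.0 / (2.0 * med2)


def train_models(
    descriptors: Sequence[EventDescriptor],
    config: ClassifierConfig | None = None,
) -> IdModel:
    """Fit per-kind OvR classifier banks on labelled event descriptors."""
    config = config or ClassifierConfig()
    config.validate()
    classes = sorted({d.subject_id for d in descriptors})
    if len(classes) < 2:
        raise ContractError("training needs at least 2 classes")
    model = IdModel(classes=classes, config=config)
    for kind in (FIXATION, SACCADE):
        of_kind = [d for d in descriptors if d.kind == kind]
        if not of_kind:
            logger.warning("no %s descriptors in training data; bank skipped", kind)
            continue
        X = np.vstack([d.vector for d in of_kind])
        y = np.array([d.subject_id for d in of_kind])
        loc = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0
        model.scalers[kind] = (loc, scale)
        Xs = (X - loc) / scale
        gamma = (
            _median_heuristic_gamma(Xs)
            if config.gamma == "median"
            else float(config.gamma)
        )
        bank = {}
        for cls in classes:
            y_bin = np.where(y == cls, 1, -1)
            if (y_bin == 1).sum() == 0:
                logger.warning("class %s has no %s training events", cls, kind)
                bank[cls] = None
                continue
            svc = SVC(kernel=config.kernel, C=config.C, gamma=gamma)
            svc.fit(Xs, y_bin)
            sign = 1.0 if svc.classes_[1] == 1 else -1.0
            bank[cls] = _BinaryMargin(
                support_vectors=svc.support_vectors_.copy(),
                dual_coef=sign * svc.dual_coef_[0].copy(),
                intercept=sign * float(svc.intercept_[0]),
                gamma=gamma,
            )
        model.classifiers[kind] = bank
    return model


def decision_vectors(
    model: IdModel, events: Sequence[EventDescriptor]
) -> list[tuple[str, np.ndarray]]:
    """Per-event decision vectors (one value per enrolled class)."""
    out = []
    for ev in events:
        if ev.kind not in model.classifiers:
            raise ValidationError(f"model has no classifier bank for kind {ev.kind!r}")
        X = model.standardize(ev.kind, ev.vector.reshape(1, N_EVENT_FEATURES))
        vec = np.array(
            [
                0.0 if clf is None else float(clf.decide(X)[0])
                for clf in (model.classifiers[ev.kind][c] for c in model.classes)
            ]
        )
        out.append((ev.kind, vec))
    return out


def fuse_and_identify(
    model: IdModel, events: Sequence[EventDescriptor]
) -> tuple[str, np.ndarray]:
    """Average decision vectors per kind, sum, and take the argmax identity.

    An absent kind contributes a zero vector, which is neutral under the
    additive fusion.  Ties are broken by class-list order.
    """
    dvs = decision_vectors(model, events)
    if not dvs:
        raise ContractError("no usable events to identify from")
    fused = np.zeros(len(model.classes))
    for kind in (FIXATION, SACCADE):
        vecs = [v for k, v in dvs if k == kind]
        if vecs:
            fused = fused + np.mean(vecs, axis=0)
    best = int(np.argmax(fused))
    ties = np.flatnonzero(fused == fused[best])
    if len(ties) > 1:
        logger.info("fused-score tie between %s; class-list order breaks it",
                    [model.classes[t] for t in ties])
    return model.classes[best], fused
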