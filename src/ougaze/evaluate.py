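"""Cross-validated biometric benchmarking and correlation analyses.

Identification quality is reported as accuracy, macro-averaged F1, the
equal error rate (EER) and area under the ROC curve (AUC) of the
micro-averaged one-vs-rest score pooling, the confusion matrix, and the
cumulative match score curve (CMS: fraction of probes whose true
identity ranks within the top k).  Cross-validation splits at the
scan-path level — all events of a trajectory stay in one fold — because
events within a scan path are statistically dependent and would leak
identity across the split.

The correlation analyses quantify how individual the descriptors are:
between-subject correlations of summary vectors, and the intra-subject
(same subject, different stimuli) versus inter-subject ensembles of
scan-path descriptor correlations with Gaussian kernel density
estimates of each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .exceptions import StratificationError, ValidationError
from .features import (
    EventDescriptor,
    ScanpathDescriptor,
    SubjectSummary,
    scanpath_descriptor,
    subject_summary,
)
from .identify import fuse_and_identify, train_models
from .io import ClassifierConfig

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    classes: list
    accuracy: float
    f1: float
    eer: float
    auc: float
    confusion: np.ndarray
    cms: np.ndarray
    per_fold: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "classes": self.classes,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "eer": self.eer,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "cms": self.cms.tolist(),
            "per_fold": self.per_fold,
        }


def _micro_roc(scores: np.ndarray, y_idx: np.ndarray):
    """Pooled one-vs-rest ROC: every (probe, class) pair is a binary case."""
    n, n_classes = scores.shape
    onehot = np.zeros_like(scores)
    onehot[np.arange(n), y_idx] = 1.0
    fpr, tpr, _ = roc_curve(onehot.ravel(), scores.ravel())
    auc = float(np.trapezoid(tpr, fpr))
    # EER: crossing of FAR = fpr with FRR = 1 - tpr, linearly interpolated
    frr = 1.0 - tpr
    diff = fpr - frr
    k = int(np.searchsorted(diff, 0.0))
    if k == 0:
        eer = float((fpr[0] + frr[0]) / 2.0)
    elif k >= len(diff):
        eer = float((fpr[-1] + frr[-1]) / 2.0)
    else:
        w = diff[k - 1] / (diff[k - 1] - diff[k])
        eer = float((1 - w) * fpr[k - 1] + w * fpr[k])
    return eer, auc


def compute_metrics(
    scores: np.ndarray, labels: Sequence[str], classes: Sequence[str]
) -> MetricsReport:
    """Biometric metrics from fused score vectors and true labels."""
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    classes = list(classes)
    if scores.ndim != 2 or scores.shape != (len(labels), len(classes)):
        raise ValidationError(
            f"scores shape {scores.shape} does not match "
            f"{len(labels)} probes x {len(classes)} classes"
        )
    class_index = {c: a for a, c in enumerate(classes)}
    try:
        y_idx = np.array([class_index[lab] for lab in labels])
    except KeyError as exc:  # pragma: no cover
        raise ValidationError(f"label {exc} not in class list") from exc
    pred_idx = scores.argmax(axis=1)
    preds = [classes[p] for p in pred_idx]
    acc = float(accuracy_score(labels, preds))
    f1 = float(f1_score(labels, preds, labels=classes, average="macro", zero_division=0))
    eer, auc = _micro_roc(scores, y_idx)
    conf = confusion_matrix(labels, preds, labels=classes)
    # CMS[k-1]: fraction of probes whose true class is within the top k
    order = np.argsort(-scores, axis=1)
    ranks = np.argmax(order == y_idx[:, None], axis=1)  # 0-based rank
    cms = np.array([(ranks <= k).mean() for k in range(len(classes))])
    return MetricsReport(
        classes=classes, accuracy=acc, f1=f1, eer=eer, auc=auc,
        confusion=conf, cms=cms,
    )


def crossvalidate(
    scanpaths: Sequence[Sequence[EventDescriptor]],
    k: int = 5,
    seed: int = 0,
    classifier: ClassifierConfig | None = None,
    shuffle_labels: bool = False,
) -> MetricsReport:
    """k-fold CV over scan paths, stratified by subject.

    Each entry of ``scanpaths`` is the list of event descriptors of one
    trajectory; the trajectory's subject label is taken from them.
    ``shuffle_labels`` permutes the scan-path labels (null control).
    """
    scanpaths = [list(sp) for sp in scanpaths]
    labels = np.array([sp[0].subject_id for sp in scanpaths])
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1)
        labels = rng.permutation(labels)
        scanpaths = [
            [
                EventDescriptor(e.vector, e.kind, lab, e.stimulus_id)
                for e in sp
            ]
            for sp, lab in zip(scanpaths, labels)
        ]
    classes = sorted(set(labels))
    counts = {c: int((labels == c).sum()) for c in classes}
    short = [c for c, n in counts.items() if n < k]
    if short:
        raise StratificationError(
            f"subjects {short} have fewer than k={k} scan paths"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    all_scores, all_labels, per_fold = [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(labels, labels)):
        train_desc = [e for a in train_idx for e in scanpaths[a]]
        model = train_models(train_desc, classifier)
        fold_scores, fold_labels = [], []
        for a in test_idx:
            _, fused = fuse_and_identify(model, scanpaths[a])
            full = np.full(len(classes), -np.inf)
            for c, v in zip(model.classes, fused):
                full[classes.index(c)] = v
            fold_scores.append(full)
            fold_labels.append(labels[a])
        rep = compute_metrics(np.vstack(fold_scores), fold_labels, classes)
        per_fold.append({"fold": fold, "accuracy": rep.accuracy, "f1": rep.f1})
        all_scores.append(np.vstack(fold_scores))
        all_labels.extend(fold_labels)
    pooled = compute_metrics(np.vstack(all_scores), all_labels, classes)
    pooled.per_fold = per_fold
    return pooled


# ---------------------------------------------------------------------------
# correlation analyses

@dataclass
class CorrelationReport:
    subjects: list
    between: np.ndarray       # subject-by-subject correlation of summaries
    intra: np.ndarray         # same-subject, different-stimuli ensemble
    inter: np.ndarray         # different-subject ensemble
    intra_density: object     # gaussian_kde over the intra ensemble
    inter_density: object


def _pair_corr(u: np.ndarray, v: np.ndarray) -> float | None:
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 3:
        return None
    u, v = u[ok], v[ok]
    if u.std() < 1e-12 or v.std() < 1e-12:
        return None
    return float(np.corrcoef(u, v)[0, 1])


def correlation_analyses(
    scanpaths: Sequence[ScanpathDescriptor],
    summaries: Sequence[SubjectSummary] | None = None,
) -> CorrelationReport:
    """Between-subject and intra/inter-subject correlation structure."""
    by_subject: dict[str, list[ScanpathDescriptor]] = {}
    for sp in scanpaths:
        by_subject.setdefault(sp.subject_id, []).append(sp)
    subjects = sorted(by_subject)
    if len(subjects) < 2 or any(len(v) < 2 for v in by_subject.values()):
        raise ValidationError("correlation analyses need >= 2 subjects with >= 2 stimuli")
    if summaries is None:
        summaries = [subject_summary(by_subject[s]) for s in subjects]
    summary_map = {s.subject_id: s.vector for s in summaries}

    n = len(subjects)
    between = np.eye(n)
    for a, b in combinations(range(n), 2):
        rho = _pair_corr(summary_map[subjects[a]], summary_map[subjects[b]])
        if rho is None:
            logger.warning("undefined correlation between %s and %s excluded",
                           subjects[a], subjects[b])
            rho = np.nan
        between[a, b] = between[b, a] = rho

    intra, inter = [], []
    for a, b in combinations(range(len(scanpaths)), 2):
        u, v = scanpaths[a], scanpaths[b]
        if u.subject_id == v.subject_id and u.stimulus_id == v.stimulus_id:
            continue
        rho = _pair_corr(u.vector, v.vector)
        if rho is None:
            logger.warning("undefined scan-path correlation excluded")
            continue
        (intra if u.subject_id == v.subject_id else inter).append(rho)
    intra = np.asarray(intra)
    inter = np.asarray(inter)
    return CorrelationReport(
        subjects=subjects,
        between=between,
        intra=intra,
        inter=inter,
        intra_density=gaussian_kde(intra) if len(intra) > 1 else None,
        inter_density=gaussian_kde(inter) if len(inter) > 1 else None,
    )


def cohort_scanpath_descriptors(
    descriptors: Sequence[EventDescriptor],
) -> list[ScanpathDescriptor]:
    """Group event descriptors by (subject, stimulus) into scan-path vectors."""
    groups: dict[tuple, list[EventDescriptor]] = {}
    for d in descriptors:
        groups.setdefault((d.subject_id, d.stimulus_id), []).append(d)
    return [scanpath_descriptor(evs) for evs in groups.values()]
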