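"""Breathing-pattern classification with a one-vs-one multiclass SVM.

Each labelled breathing-pattern section is condensed into four medians —
rate, amplitude and their 30 s moving variances — taken over the section's
valid samples.  A support vector machine is trained for every pair of
classes (one-vs-one voting, with ties broken by aggregate decision-function
margin) and evaluated with seeded stratified 10-fold cross-validation;
features are standardized with training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import RobustFeatures
from .protocol import PATTERN_CLASSES, ProtocolAnnotation

__all__ = ["SegmentFeatureVector", "ClassificationReport", "segment_medians", "train_eval_ovo_svm"]


@dataclass
class SegmentFeatureVector:
    """Median features of one complete breathing-pattern section."""

    label: str
    rr_med: float
    amp_med: float
    rr_var_med: float
    amp_var_med: float
    flagged: bool = False  # fewer than half the section's samples were valid

    def as_array(self) -> np.ndarray:
        return np.array([self.rr_med, self.amp_med, self.rr_var_med, self.amp_var_med])


@dataclass
class ClassificationReport:
    """Cross-validated confusion counts and accuracies."""

    labels: list[str]
    confusion: np.ndarray  # rows = true class, cols = predicted
    fold_accuracies: np.ndarray
    accuracy: float

    def most_confused_pair(self) -> tuple[str, str, int]:
        """The class pair with the largest symmetric off-diagonal count."""
        C = self.confusion
        best, pair = -1, (0, 1)
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                c = int(C[i, j] + C[j, i])
                if c > best:
                    best, pair = c, (i, j)
        return self.labels[pair[0]], self.labels[pair[1]], best

    def per_class_error(self) -> dict[str, float]:
        totals = self.confusion.sum(axis=1)
        out = {}
        for i, lab in enumerate(self.labels):
            out[lab] = 1.0 - (self.confusion[i, i] / totals[i] if totals[i] else 0.0)
        return out


def segment_medians(
    F: RobustFeatures,
    labels: ProtocolAnnotation,
    allow_empty: bool = False,
) -> list[SegmentFeatureVector]:
    """One median feature vector per labelled section.

    Medians are taken over the *complete* section of the zero-filled
    feature tracks (invalid samples are zero by construction), so a section
    that is mostly unreliable — the apnea signature — robustly collapses to
    the zero vector.  Sections with less than half their samples valid are
    flagged.  A section with *no* valid sample raises unless
    ``allow_empty`` is set, in which case it yields the all-zero vector.
    """
    n = len(F)
    out = []
    for seg in labels:
        i0 = int(round(seg.start * F.fs))
        i1 = int(round(seg.end * F.fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(f"segment [{seg.start}, {seg.end}) s outside feature extent")
        v = F.valid[i0:i1]
        if not v.any():
            if not allow_empty:
                raise ValueError(f"segment {seg.label} at {seg.start} s has no valid samples")
            out.append(SegmentFeatureVector(seg.label, 0.0, 0.0, 0.0, 0.0, flagged=True))
            continue
        sl = slice(i0, i1)
        out.append(
            SegmentFeatureVector(
                label=seg.label,
                rr_med=float(np.median(F.rr[sl])),
                amp_med=float(np.median(F.amp[sl])),
                rr_var_med=float(np.median(F.rr_var[sl])),
                amp_var_med=float(np.median(F.amp_var[sl])),
                flagged=bool(v.mean() < 0.5),
            )
        )
    return out


def train_eval_ovo_svm(
    vectors: list[SegmentFeatureVector],
    folds: int = 10,
    seed: int = 0,
    kernel: str = "linear",
    C: float = 1.0,
) -> ClassificationReport:
    """Seeded stratified k-fold cross-validation of the one-vs-one SVM.

    The default is a linear kernel with C=1 on standardized features
    (median features of the patterns are largely axis-separable); an RBF
    kernel is available via ``kernel``.  The report aggregates out-of-fold
    predictions into a confusion matrix whose rows are the true classes in
    canonical pattern order.
    """
    y = np.array([v.label for v in vectors])
    X = np.stack([v.as_array() for v in vectors])
    classes = [c for c in PATTERN_CLASSES if c in set(y)] + sorted(set(y) - set(PATTERN_CLASSES))
    if len(classes) < 2:
        raise ValueError("need at least two classes for one-vs-one classification")
    counts = {c: int(np.sum(y == c)) for c in classes}
    short = [c for c, k in counts.items() if k < folds]
    if short:
        raise ValueError(f"classes with fewer samples than folds: {short}")

    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel=kernel, C=C, decision_function_shape="ovo", break_ties=False),
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        fold_acc.append(float(np.mean(pred == y[test])))
        for t, p in zip(y[test], pred):
            confusion[idx[t], idx[p]] += 1

    accuracy = float(np.trace(confusion) / confusion.sum())
    return ClassificationReport(
        labels=classes,
        confusion=confusion,
        fold_accuracies=np.array(fold_acc),
        accuracy=accuracy,
    )
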