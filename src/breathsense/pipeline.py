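"""End-to-end composition: synthetic study from protocol to classifier.

Mirrors the full processing chain on simulated data: synthesize the
reference protocol, simulate a cohort breathing along it, align every
subject to the reference (cross-correlation offsets), normalize amplitudes
to the eupnea section, augment into a balanced labelled dataset, extract
robust features per segment and cross-validate the one-vs-one SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassificationReport, SegmentFeatureVector, segment_medians, train_eval_ovo_svm
from .dataset import LabelledSegment, augment, estimate_offsets, normalize_to_eupnea
from .features import artifact_correct, cwt_ridge_features, fuse_features, peak_features, smooth
from .protocol import ProtocolAnnotation, ReferenceSignal, Segment, default_protocol, synth_protocol
from .signals import RespiratorySignal
from .simulate import simulate_cohort

__all__ = ["segment_feature_vector", "prepare_cohort", "run_synthetic_study", "StudyResult"]


def segment_feature_vector(seg: LabelledSegment) -> SegmentFeatureVector:
    """Robust median features of one labelled segment.

    Runs the full feature path (smoothing, peak and CWT-ridge tracks,
    artifact correction, fusion) on the segment alone and condenses it to
    the four medians.  A segment with no valid feature samples (no
    detectable breathing) yields the all-zero vector.
    """
    sig = RespiratorySignal(samples=seg.samples, fs=seg.fs)
    sm = smooth(sig) if len(sig) >= int(round(1.5 * seg.fs)) + 2 else sig
    Fp = artifact_correct(peak_features(sm))
    Fs = artifact_correct(cwt_ridge_features(sm))
    merged = fuse_features(Fp, Fs)
    ann = ProtocolAnnotation([Segment(seg.label, 0.0, len(seg.samples) / seg.fs)])
    return segment_medians(merged, ann, allow_empty=True)[0]


def prepare_cohort(
    ref: ReferenceSignal,
    n_subjects: int = 10,
    seed: int = 0,
) -> list[RespiratorySignal]:
    """Simulate, align and normalize a cohort against the reference.

    The reference participates in the offset estimation as the anchor, so
    all subjects end up on the reference time base and carry its protocol
    annotation; each subject is then normalized to unit eupnea amplitude.
    """
    subjects, _ = simulate_cohort(ref, n_subjects=n_subjects, seed=seed)
    ref_sig = RespiratorySignal(samples=ref.samples, fs=ref.fs, annotation=ref.annotation)
    sol = estimate_offsets([ref_sig] + subjects)
    aligned = []
    for s, d in zip(subjects, sol.offsets[1:]):
        a = s.shifted(d)
        a.annotation = ref.annotation
        aligned.append(normalize_to_eupnea(a))
    return aligned


@dataclass
class StudyResult:
    report: ClassificationReport
    vectors: list[SegmentFeatureVector]
    n_subjects: int
    n_per_pattern: int
    seed: int


def run_synthetic_study(
    n_subjects: int = 10,
    n_per_pattern: int = 1000,
    seed: int = 0,
    folds: int = 10,
) -> StudyResult:
    """The complete synthetic classification experiment."""
    specs = default_protocol()
    ref = synth_protocol(specs)
    cohort = prepare_cohort(ref, n_subjects=n_subjects, seed=seed)
    segments = augment(cohort, specs=specs, n_per_pattern=n_per_pattern, seed=seed + 1)
    vectors = [segment_feature_vector(seg) for seg in segments]
    report = train_eval_ovo_svm(vectors, folds=folds, seed=seed)
    return StudyResult(
        report=report,
        vectors=vectors,
        n_subjects=n_subjects,
        n_per_pattern=n_per_pattern,
        seed=seed,
    )
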