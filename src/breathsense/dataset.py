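"""Dataset creation: normalization, alignment, mixing and augmentation.

Extracted respiratory signals differ in amplitude scale (modality, subject)
and are not perfectly synchronous.  This module

* normalizes each signal so its eupnea section has amplitude 1 n.u.
  (amplitude taken as the maximum of the amplitude-scaled FFT magnitude of
  that section),
* aligns signals by converting pairwise cross-correlation delays into
  per-signal offsets through a least-squares system (the system is
  rank-deficient by one — a common time shift — and is anchored at
  ``d_1 = 0``),
* recovers systematic sampling-rate errors by a grid search over resampling
  factors,
* and augments the labelled dataset by convex mixing of subject pairs
  (``s_gen = p*s_i + (1-p)*s_j``) followed by per-segment time scaling that
  redistributes each pattern's rate uniformly over its target range.
  Kussmaul segments are sourced from time-compressed hyperpnea segments
  (subjects could not produce the demanded Kussmaul effort, so recorded
  Kussmaul sections are discarded by design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .protocol import PatternSpec, ProtocolAnnotation, default_protocol
from .signals import RespiratorySignal

__all__ = [
    "DatasetRecord",
    "AlignmentSolution",
    "LabelledSegment",
    "eupnea_fft_amplitude",
    "normalize_to_eupnea",
    "estimate_offsets",
    "grid_resample",
    "mix_signals",
    "augment",
]


@dataclass
class DatasetRecord:
    """One labelled recording of one subject and modality."""

    signal: RespiratorySignal
    subject: int
    modality: str = "synthetic"

    @property
    def labels(self) -> ProtocolAnnotation:
        if self.signal.annotation is None:
            raise ValueError("record has no annotation")
        return self.signal.annotation


@dataclass
class AlignmentSolution:
    """Pairwise delays and the per-signal offsets explaining them."""

    pairwise: dict[tuple[int, int], float]  # d_ij = d_i - d_j, seconds
    offsets: np.ndarray  # d_i, seconds, anchored d_0 = 0
    residual: float  # RMS of unexplained pairwise delay, seconds


@dataclass
class LabelledSegment:
    """One augmented breathing-pattern sample."""

    label: str
    samples: np.ndarray
    fs: float


def eupnea_fft_amplitude(x: np.ndarray) -> float:
    """Sinusoid amplitude of a section from its scaled FFT magnitude.

    Uses the single-sided magnitude spectrum scaled by 2/N so a pure
    sinusoid of amplitude A yields a peak of height A.  The DC bin is
    excluded (a baseline offset is not a breathing amplitude).
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty section")
    spec = np.abs(np.fft.rfft(x)) * 2.0 / len(x)
    if len(spec) < 2:
        raise ValueError("section too short for amplitude estimation")
    return float(spec[1:].max())


def normalize_to_eupnea(
    s: RespiratorySignal,
    eupnea_span: tuple[float, float] | None = None,
) -> RespiratorySignal:
    """Scale the whole signal so the eupnea section has amplitude 1 n.u.

    ``eupnea_span`` is (start, end) in seconds; if omitted, the first
    annotated eupnea segment is used.
    """
    if eupnea_span is None:
        if s.annotation is None:
            raise ValueError("no eupnea span given and signal has no annotation")
        spans = [seg for seg in s.annotation if seg.label == "eupnea"]
        if not spans:
            raise ValueError("annotation contains no eupnea segment")
        eupnea_span = (spans[0].start, spans[0].end)
    i0 = int(round(eupnea_span[0] * s.fs))
    i1 = int(round(eupnea_span[1] * s.fs))
    if i1 <= i0:
        raise ValueError("empty eupnea span")
    amp = eupnea_fft_amplitude(s.samples[i0:i1])
    if amp <= 1e-12:
        raise ValueError("zero eupnea amplitude; cannot normalize")
    return s.copy_with(samples=s.samples / amp)


def _xcorr_lag(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    """Lag (samples) maximizing cross-correlation of a against b.

    Positive lag means ``a`` is delayed relative to ``b``.  Also returns
    the normalized peak correlation.
    """
    a = a - a.mean()
    b = b - b.mean()
    c = sps.correlate(a, b, mode="full", method="fft")
    lag = int(np.argmax(c)) - (len(b) - 1)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    peak = float(c.max() / denom) if denom > 0 else 0.0
    return lag, peak


def estimate_offsets(signals: list[RespiratorySignal]) -> AlignmentSolution:
    """Per-signal time offsets from all pairwise cross-correlation delays.

    Each pairwise delay observes ``d_ij = d_i - d_j``; the offsets ``d_i``
    are the least-squares solution of the resulting linear system, anchored
    at ``d_0 = 0`` (offsets are only defined up to a common shift).
    """
    n = len(signals)
    if n < 2:
        raise ValueError("need at least two signals")
    fs = signals[0].fs
    if any(s.fs != fs for s in signals):
        raise ValueError("signals must share a sampling rate")
    min_len = min(len(s) for s in signals)
    if min_len < int(2 * fs):
        raise ValueError("signals too short for reliable correlation")

    pairs: dict[tuple[int, int], float] = {}
    rows, rhs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            lag, _ = _xcorr_lag(signals[i].samples, signals[j].samples)
            d_ij = lag / fs
            pairs[(i, j)] = d_ij
            row = np.zeros(n)
            row[i], row[j] = 1.0, -1.0
            rows.append(row)
            rhs.append(d_ij)
    A = np.asarray(rows)[:, 1:]  # anchor d_0 = 0
    b = np.asarray(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    offsets = np.concatenate([[0.0], sol])
    resid = b - A @ sol
    residual = float(np.sqrt(np.mean(resid**2))) if len(resid) else 0.0
    return AlignmentSolution(pairwise=pairs, offsets=offsets, residual=residual)


def grid_resample(
    s: RespiratorySignal,
    ref: RespiratorySignal,
    factors: np.ndarray | None = None,
    reliability_floor: float = 0.3,
) -> tuple[float, float, float, bool]:
    """Grid search for the resampling factor best matching the reference.

    A factor ``f`` models a clock error: the signal is read as if its true
    sampling rate were ``f * fs``.  For every factor on the grid (default
    0.9-1.1, step 0.001 — realistic oscillator drift), the signal is
    resampled and cross-correlated with ``ref``; the factor and lag with the
    highest normalized correlation win.  Returns
    ``(factor, lag_seconds, peak_correlation, reliable)``.
    """
    if factors is None:
        factors = np.arange(0.9, 1.1 + 1e-9, 0.001)
    factors = np.asarray(factors, dtype=float)
    if factors.size == 0:
        raise ValueError("empty factor grid")
    fs = s.fs
    x = s.samples
    best = (1.0, 0.0, -np.inf)
    for f in factors:
        n_new = int(round(len(x) / f))
        if n_new < 2:
            continue
        y = np.interp(np.arange(n_new) * f, np.arange(len(x)), x)
        lag, peak = _xcorr_lag(y, ref.samples)
        if peak > best[2]:
            best = (float(f), lag / fs, peak)
    factor, lag_s, peak = best
    return factor, lag_s, peak, bool(peak >= reliability_floor)


def mix_signals(si: RespiratorySignal, sj: RespiratorySignal, p: float) -> RespiratorySignal:
    """Convex combination ``p*si + (1-p)*sj`` of two aligned signals."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if len(si) != len(sj):
        raise ValueError("length mismatch")
    if si.fs != sj.fs:
        raise ValueError("sampling-rate mismatch")
    return RespiratorySignal(
        samples=p * si.samples + (1.0 - p) * sj.samples,
        fs=si.fs,
        valid=si.valid & sj.valid,
        modality=si.modality,
        annotation=si.annotation,
    )


def _time_scale(x: np.ndarray, factor: float) -> np.ndarray:
    """Band-limited time scaling: duration multiplied by ``factor``,
    amplitude preserved."""
    n_new = max(2, int(round(len(x) * factor)))
    return sps.resample(x, n_new)


def augment(
    records: list[RespiratorySignal],
    specs: list[PatternSpec] | None = None,
    n_per_pattern: int = 1000,
    seed: int = 0,
) -> list[LabelledSegment]:
    """Balanced augmented dataset: ``n_per_pattern`` segments per class.

    For every generated sample a random pair of records is mixed with a
    uniform percentage, one protocol occurrence of the target class is cut
    out, and the segment is time-scaled so its rate lands uniformly in the
    class's target range (active-phase rate for intermittent patterns).
    Kussmaul samples are cut from hyperpnea occurrences and compressed into
    the Kussmaul rate range instead.  Reproducible under ``seed``.
    """
    if specs is None:
        specs = default_protocol()
    if not records:
        raise ValueError("no records to augment")
    ann = records[0].annotation
    if ann is None or len(ann) != len(specs):
        raise ValueError("records must carry the protocol annotation matching specs")

    # occurrences per class: (segment index, nominal active rate, range)
    occ: dict[str, list[int]] = {}
    for idx, spec in enumerate(specs):
        occ.setdefault(spec.label, []).append(idx)

    rng = np.random.default_rng(seed)
    n_rec = len(records)
    out: list[LabelledSegment] = []
    classes = sorted(occ.keys())
    for label in classes:
        if label == "kussmaul":
            if "hyperpnea" not in occ:
                raise ValueError("kussmaul augmentation requires hyperpnea segments")
            sources = occ["hyperpnea"]
            lo, hi = specs[occ["kussmaul"][0]].rr_range
        else:
            sources = occ[label]
            lo, hi = specs[sources[0]].rr_range
        for _ in range(n_per_pattern):
            if n_rec >= 2:
                i, j = rng.choice(n_rec, size=2, replace=False)
            else:
                i = j = 0
            p = float(rng.uniform())
            seg_idx = int(sources[rng.integers(len(sources))])
            seg = ann.segments[seg_idx]
            nominal = specs[seg_idx].rr
            ri, rj = records[int(i)], records[int(j)]
            sl = ri.segment_slice(seg)
            x = p * ri.samples[sl] + (1.0 - p) * rj.samples[sl]
            if hi > lo or lo > 0:
                target = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                x = _time_scale(x, nominal / target)
            out.append(LabelledSegment(label=label, samples=x, fs=ri.fs))
    return out
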