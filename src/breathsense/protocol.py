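"""Reference breathing-protocol synthesis.

A study protocol is a labelled sequence of breathing patterns.  Each pattern
is modelled as a sinusoidal thorax movement

    s(t) = RE * sin(2*pi * RR/60 * t)

where ``RR`` is the respiratory rate in breaths/min and ``RE`` the
respiratory effort (motion amplitude) in normalized units, with eupnea
defined as RE = 1.  Complex patterns modulate this carrier:

* Biot's breathing interleaves two 20 s active sections with two 20 s apnea
  sections (80 s total).
* Cheyne-Stokes respiration uses 15 s crescendo sections, whose envelope
  rises linearly from 0 to RE (``RE(t) = RE/15 * t``), interleaved with 20 s
  apnea sections.

The full default protocol consists of twelve segments covering nine pattern
classes, separated by pauses of at least 5 s during which the signal is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PATTERN_CLASSES",
    "PatternSpec",
    "Segment",
    "ProtocolAnnotation",
    "ReferenceSignal",
    "synth_segment",
    "default_protocol",
    "synth_protocol",
]

#: Canonical order of the nine breathing-pattern classes.
PATTERN_CLASSES = (
    "bradypnea",
    "eupnea",
    "hypopnea",
    "hyperpnea",
    "tachypnea",
    "kussmaul",
    "cheyne_stokes",
    "biot",
    "apnea",
)

CONSTANT = "constant"
BIOT_INTERMITTENT = "biot_intermittent"
CHEYNE_CRESCENDO = "cheyne_crescendo"

#: Section layout of the intermittent structures, in seconds.
_BIOT_ACTIVE_S = 20.0
_BIOT_APNEA_S = 20.0
_CHEYNE_ACTIVE_S = 15.0
_CHEYNE_APNEA_S = 20.0


@dataclass(frozen=True)
class PatternSpec:
    """Declarative description of one protocol segment.

    ``rr`` is the breathing rate of the *active* phase (intermittent
    patterns pause between active phases); ``re`` is the motion amplitude in
    normalized units, interpreted as the envelope peak for the crescendo
    structure.  ``rr_range`` is the rate interval used by the data
    augmentation to redistribute the rate of this pattern class.
    """

    label: str
    rr: float
    re: float
    duration: float = 60.0
    structure: str = CONSTANT
    rr_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.label not in PATTERN_CLASSES:
            raise ValueError(f"unknown pattern label {self.label!r}")
        if self.rr < 0 or self.re < 0:
            raise ValueError("rr and re must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rr_range[0] > self.rr_range[1]:
            raise ValueError("rr_range must be (min, max) with min <= max")
        if self.label == "apnea" and self.re != 0:
            raise ValueError("apnea requires re = 0")
        if self.structure not in (CONSTANT, BIOT_INTERMITTENT, CHEYNE_CRESCENDO):
            raise ValueError(f"unknown structure tag {self.structure!r}")


@dataclass(frozen=True)
class Segment:
    """One annotated span: pattern label plus [start, end) in seconds."""

    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ProtocolAnnotation:
    """Ordered, non-overlapping labelled segments of a recording."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end:
                raise ValueError("annotation segments must be sorted and non-overlapping")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def shifted(self, dt: float) -> "ProtocolAnnotation":
        """Annotation with all spans delayed by ``dt`` seconds."""
        return ProtocolAnnotation(
            [replace(s, start=s.start + dt, end=s.end + dt) for s in self.segments]
        )

    def clipped(self, t_max: float) -> "ProtocolAnnotation":
        """Drop or truncate segments extending beyond ``t_max`` seconds."""
        out = []
        for s in self.segments:
            if s.start >= t_max:
                continue
            out.append(replace(s, end=min(s.end, t_max)))
        return ProtocolAnnotation(out)


@dataclass
class ReferenceSignal:
    """The synthesized protocol signal subjects breathe along with."""

    samples: np.ndarray
    fs: float
    annotation: ProtocolAnnotation

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def _sine(rr: float, re: float, duration: float, fs: float) -> np.ndarray:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return re * np.sin(2.0 * math.pi * rr / 60.0 * t)


def synth_segment(spec: PatternSpec, fs: float = 10.0) -> np.ndarray:
    """Synthesize the sample vector of a single protocol segment.

    Each segment starts at phase zero, so peak counts and timings are
    reproducible.  ``fs`` must satisfy the Nyquist bound for the active
    breathing frequency.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if spec.rr > 0 and fs <= 2.0 * spec.rr / 60.0:
        raise ValueError(f"fs={fs} too low for rr={spec.rr} breaths/min")

    if spec.structure == CONSTANT:
        return _sine(spec.rr, spec.re, spec.duration, fs)

    if spec.structure == BIOT_INTERMITTENT:
        active = _sine(spec.rr, spec.re, _BIOT_ACTIVE_S, fs)
        pause = np.zeros(int(round(_BIOT_APNEA_S * fs)))
        return np.concatenate([active, pause, active, pause])

    if spec.structure == CHEYNE_CRESCENDO:
        cycle_s = _CHEYNE_ACTIVE_S + _CHEYNE_APNEA_S
        n_cycles = max(1, int(round(spec.duration / cycle_s)))
        t_act = np.arange(int(round(_CHEYNE_ACTIVE_S * fs))) / fs
        envelope = spec.re / _CHEYNE_ACTIVE_S * t_act
        active = envelope * np.sin(2.0 * math.pi * spec.rr / 60.0 * t_act)
        pause = np.zeros(int(round(_CHEYNE_APNEA_S * fs)))
        return np.concatenate([np.concatenate([active, pause])] * n_cycles)

    raise ValueError(f"unknown structure tag {spec.structure!r}")


def cheyne_envelope(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    """Instantaneous envelope of a crescendo segment at times ``t`` (s, from
    segment start), zero during the apnea phases."""
    cycle_s = _CHEYNE_ACTIVE_S + _CHEYNE_APNEA_S
    phase = np.asarray(t) % cycle_s
    env = np.where(phase < _CHEYNE_ACTIVE_S, spec.re / _CHEYNE_ACTIVE_S * phase, 0.0)
    return env


def default_protocol() -> list[PatternSpec]:
    """The twelve-segment study protocol.

    Segment order, rates, efforts and augmentation rate ranges follow the
    published breath-protocol table; intermittent/crescendo structure
    durations follow the protocol description (80 s Biot's, 15 s + 20 s
    Cheyne-Stokes cycles, 60 s otherwise).
    """
    return [
        PatternSpec("bradypnea", 5, 1, 60, CONSTANT, (5, 10)),
        PatternSpec("eupnea", 12, 1, 60, CONSTANT, (12, 18)),
        PatternSpec("hypopnea", 12, 0.25, 60, CONSTANT, (12, 18)),
        PatternSpec("hyperpnea", 10, 2.5, 60, CONSTANT, (12, 18)),
        PatternSpec("tachypnea", 35, 1, 60, CONSTANT, (20, 35)),
        PatternSpec("eupnea", 15, 1, 60, CONSTANT, (12, 25)),
        PatternSpec("kussmaul", 30, 2.5, 60, CONSTANT, (20, 35)),
        PatternSpec("cheyne_stokes", 20, 4.5, 70, CHEYNE_CRESCENDO, (12, 25)),
        PatternSpec("tachypnea", 35, 0.25, 60, CONSTANT, (20, 35)),
        PatternSpec("biot", 15, 1, 80, BIOT_INTERMITTENT, (12, 25)),
        PatternSpec("biot", 10, 2.5, 80, BIOT_INTERMITTENT, (12, 25)),
        PatternSpec("apnea", 0, 0, 60, CONSTANT, (0, 0)),
    ]


def synth_protocol(
    specs: list[PatternSpec] | None = None,
    pause: float = 5.0,
    fs: float = 10.0,
    pause_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ReferenceSignal:
    """Concatenate protocol segments with zero-valued pauses in between.

    ``pause`` is the minimum pause length in seconds (the protocol demands
    at least 5 s so subjects can breathe freely); ``pause_jitter`` optionally
    adds a uniform random extension, drawn from ``rng``.
    """
    if pause < 0:
        raise ValueError("pause must be non-negative")
    if specs is None:
        specs = default_protocol()
    if pause_jitter > 0 and rng is None:
        rng = np.random.default_rng()

    chunks: list[np.ndarray] = []
    segments: list[Segment] = []
    t = 0.0
    for i, spec in enumerate(specs):
        if i > 0:
            p = pause + (rng.uniform(0, pause_jitter) if pause_jitter > 0 else 0.0)
            n_pause = int(round(p * fs))
            chunks.append(np.zeros(n_pause))
            t += n_pause / fs
        x = synth_segment(spec, fs)
        chunks.append(x)
        segments.append(Segment(spec.label, t, t + len(x) / fs))
        t += len(x) / fs

    samples = np.concatenate(chunks) if chunks else np.zeros(0)
    return ReferenceSignal(samples=samples, fs=fs, annotation=ProtocolAnnotation(segments))
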