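"""Uniformly sampled 1-D respiratory signals."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolAnnotation, Segment

__all__ = ["RespiratorySignal"]


@dataclass
class RespiratorySignal:
    """A breathing motion signal in normalized units with a validity mask.

    ``valid`` marks samples that carry usable respiratory information;
    extraction and correction stages may invalidate spans (e.g. motion
    artifacts).  ``annotation`` optionally labels breathing-pattern spans.
    """

    samples: np.ndarray
    fs: float = 10.0
    valid: np.ndarray | None = None
    modality: str = "synthetic"
    annotation: ProtocolAnnotation | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.samples), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != len(self.samples):
            raise ValueError("valid mask length must match samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def segment_slice(self, seg: Segment) -> slice:
        """Sample-index slice covering an annotated segment."""
        i0 = int(round(seg.start * self.fs))
        i1 = int(round(seg.end * self.fs))
        if i0 < 0 or i1 > len(self.samples):
            raise ValueError(f"segment [{seg.start}, {seg.end}) s outside signal extent")
        return slice(i0, i1)

    def copy_with(self, **kwargs) -> "RespiratorySignal":
        base = dict(
            samples=self.samples.copy(),
            fs=self.fs,
            valid=self.valid.copy(),
            modality=self.modality,
            annotation=self.annotation,
        )
        base.update(kwargs)
        return RespiratorySignal(**base)

    def shifted(self, dt: float) -> "RespiratorySignal":
        """Signal advanced by ``dt`` seconds (``dt`` > 0 removes a delay):
        ``y(t) = x(t + dt)``, zero-padded at the vacated end, with the
        annotation moved accordingly."""
        t = self.time() + dt
        y = np.interp(t, self.time(), self.samples, left=0.0, right=0.0)
        ann = self.annotation.shifted(-dt).clipped(self.duration) if self.annotation else None
        return self.copy_with(samples=y, annotation=ann)
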