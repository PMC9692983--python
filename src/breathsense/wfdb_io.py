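"""Minimal native MIT Waveform-Database (WFDB) record I/O.

Writes and reads single- or multi-channel records in WFDB *format 16*
(little-endian 16-bit two's-complement samples in a ``.dat`` file, described
by a plain-text ``.hea`` header).  Physical units are mapped to ADC units by
a per-channel gain chosen to use the 16-bit range; reading inverts the gain,
so a round trip reproduces samples within the ADC quantization step.

Breathing-pattern annotations are stored alongside the record as a
plain-text table (``<record>.pat``, one ``start_sample  end_sample  label``
line per segment) rather than in WFDB's binary annotation encoding, keeping
them diff- and grep-friendly while preserving exact sample indices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .protocol import ProtocolAnnotation, Segment
from .signals import RespiratorySignal

__all__ = ["write_record", "read_record", "write_annotation", "read_annotation",
           "write_signal", "read_signal"]

_FMT = 16
_ADC_MAX = 32000  # headroom below int16 limits


def write_record(
    base: str | Path,
    signals: np.ndarray,
    fs: float,
    names: list[str] | None = None,
    units: str = "nu",
) -> None:
    """Write ``signals`` (m samples x n channels) as ``base.hea``/``base.dat``."""
    base = Path(base)
    X = np.asarray(signals, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m, n = X.shape
    names = names or [f"sig{i}" for i in range(n)]

    gains = []
    adc = np.empty((m, n), dtype="<i2")
    for j in range(n):
        peak = float(np.max(np.abs(X[:, j]))) if m else 0.0
        gain = _ADC_MAX / peak if peak > 0 else 1.0
        gains.append(gain)
        adc[:, j] = np.clip(np.round(X[:, j] * gain), -32768, 32767).astype("<i2")

    dat_name = base.with_suffix(".dat").name
    lines = [f"{base.stem} {n} {_fmt_num(fs)} {m}"]
    for j in range(n):
        checksum = int(np.sum(adc[:, j], dtype=np.int64) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        first = int(adc[0, j]) if m else 0
        lines.append(
            f"{dat_name} {_FMT} {_fmt_num(gains[j])}({0})/{units} 16 0 {first} {checksum} 0 {names[j]}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    base.with_suffix(".dat").write_bytes(adc.reshape(-1).tobytes())


def _fmt_num(x: float) -> str:
    return f"{x:.10g}"


def read_record(base: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read a format-16 record; returns (signals m x n, fs, channel names)."""
    base = Path(base)
    header = base.with_suffix(".hea").read_text().strip().splitlines()
    rec = header[0].split()
    n, fs, m = int(rec[1]), float(rec[2]), int(rec[3])
    gains, names = [], []
    for line in header[1 : 1 + n]:
        parts = line.split()
        if int(parts[1]) != _FMT:
            raise ValueError(f"unsupported WFDB format {parts[1]} (only format 16)")
        gain_field = parts[2].split("(")[0]
        gains.append(float(gain_field.split("/")[0]))
        names.append(parts[-1])
    raw = np.frombuffer(base.with_suffix(".dat").read_bytes(), dtype="<i2")
    X = raw.reshape(m, n).astype(float) / np.asarray(gains)[None, :]
    return X, fs, names


def write_annotation(base: str | Path, ann: ProtocolAnnotation, fs: float) -> None:
    """Write a pattern annotation table next to the record."""
    base = Path(base)
    lines = ["# start_sample\tend_sample\tlabel"]
    for seg in ann:
        lines.append(f"{int(round(seg.start * fs))}\t{int(round(seg.end * fs))}\t{seg.label}")
    base.with_suffix(".pat").write_text("\n".join(lines) + "\n")


def read_annotation(base: str | Path, fs: float) -> ProtocolAnnotation:
    base = Path(base)
    segs = []
    for line in base.with_suffix(".pat").read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        i0, i1, label = line.split("\t")
        segs.append(Segment(label, int(i0) / fs, int(i1) / fs))
    return ProtocolAnnotation(segs)


def write_signal(base: str | Path, sig: RespiratorySignal, name: str = "resp") -> None:
    """Persist a respiratory signal (and its annotation, if any) as a record."""
    write_record(base, sig.samples, sig.fs, names=[name])
    if sig.annotation is not None:
        write_annotation(base, sig.annotation, sig.fs)


def read_signal(base: str | Path, modality: str = "synthetic") -> RespiratorySignal:
    X, fs, _ = read_record(base)
    ann = None
    if Path(base).with_suffix(".pat").exists():
        ann = read_annotation(base, fs)
    return RespiratorySignal(samples=X[:, 0], fs=fs, modality=modality, annotation=ann)
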