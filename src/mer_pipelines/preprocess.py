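"""Trace selection and the common analysis band-pass.

Three steps shared by every pipeline variant: keep only depths within the
EDT window where the two classes are reasonably balanced (default
[-5 mm, +2 mm], boundaries inclusive); resolve repeat recordings at the
same (patient, hemisphere, electrode, depth) by keeping the latest; and
band-pass to the 300-3000 Hz band where extracellular spiking lives,
with a second-order elliptic filter applied forward and backward for zero
phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .synth import MerTrace

__all__ = ["PreprocessConfig", "select_edt", "deduplicate", "bandpass"]


@dataclass(frozen=True)
class PreprocessConfig:
    edt_lo: float = -5.0
    edt_hi: float = 2.0
    band_lo: float = 300.0
    band_hi: float = 3000.0
    filter_order: int = 2
    passband_ripple: float = 0.5  # dB
    stopband_atten: float = 40.0  # dB

    def __post_init__(self) -> None:
        if self.edt_lo > self.edt_hi:
            raise ValueError("edt_lo must be <= edt_hi")
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("band edges must satisfy 0 < band_lo < band_hi")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def select_edt(
    traces: Iterable[MerTrace], cfg: PreprocessConfig = PreprocessConfig()
) -> list[MerTrace]:
    """Keep traces with edt_lo <= edt_mm <= edt_hi (inclusive); order kept."""
    return [t for t in traces if cfg.edt_lo <= t.edt_mm <= cfg.edt_hi]


def deduplicate(traces: Sequence[MerTrace]) -> list[MerTrace]:
    """Keep, per (patient, hemisphere, electrode, depth), the trace with the
    latest timestamp.  Ties are an error: timestamps must order repeats."""
    best: dict[tuple, MerTrace] = {}
    for t in traces:
        k = t.key
        prev = best.get(k)
        if prev is None:
            best[k] = t
        elif t.timestamp == prev.timestamp:
            raise ValueError(f"tied timestamps for duplicate key {k!r}")
        elif t.timestamp > prev.timestamp:
            best[k] = t
    # preserve first-appearance order of surviving keys
    seen: set[tuple] = set()
    out: list[MerTrace] = []
    for t in traces:
        k = t.key
        if k in seen:
            continue
        seen.add(k)
        out.append(best[k])
    return out


def bandpass_sos(fs: float, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    if cfg.band_hi >= fs / 2:
        raise ValueError("band_hi must be below the Nyquist frequency")
    return signal.ellip(
        cfg.filter_order,
        cfg.passband_ripple,
        cfg.stopband_atten,
        [cfg.band_lo, cfg.band_hi],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass(trace: MerTrace, cfg: PreprocessConfig = PreprocessConfig()) -> MerTrace:
    """Zero-phase elliptic band-pass (forward-backward, squared magnitude)."""
    sos = bandpass_sos(trace.fs, cfg)
    y = signal.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=y)
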