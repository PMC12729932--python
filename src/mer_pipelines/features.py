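"""The 22 per-trace MER features.

Twelve time/amplitude-domain scalars and ten relative band powers are
computed from each surviving (cleaned, band-passed) trace:

* time domain — curve length WL, deadband zero crossings ZC, suprathreshold
  peak rate PKS, average non-linear (Teager-like) energy ANE;
* amplitude domain — MAV, MED (mean/median absolute amplitude), TH (3x
  sample SD spike threshold), RMS, PWRA (= RMS^2), amplitude-distribution
  kurtosis AKUR and skewness ASKW, background-noise level NL (median
  analytic envelope);
* frequency domain — relative powers on a 1 Hz Welch grid (1 s windows,
  50% overlap, Hann).  The three very-high-frequency bands (300-1000,
  1000-2000, 2000-3000 Hz) come from the direct PSD and are normalized by
  the direct power in 300-3000 Hz.  The two high- and five low-frequency
  bands (70-220, 220-320; 1-4, 4-8, 8-13, 13-30, 30-70 Hz) come from the
  PSD of the mean-subtracted rectified signal — the envelope spectrum,
  which exposes firing-rate modulations below the 300 Hz analysis
  band-edge — normalized by the rectified power in 1-320 Hz.

Counting features (ZC, PKS) and sums (WL, MAV, PWRA, ANE) are normalized
by the sample count N so traces of different residual lengths are
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .artifacts import background_level
from .synth import MerTrace

__all__ = [
    "FEATURE_NAMES",
    "METADATA_COLUMNS",
    "PsdEstimate",
    "compute_time_features",
    "compute_amplitude_features",
    "compute_psd",
    "compute_spectral_features",
    "compute_features",
    "extract_table",
]

logger = logging.getLogger(__name__)

VHF_BANDS = ((300, 1000), (1000, 2000), (2000, 3000))
HF_BANDS = ((70, 220), (220, 320))
LF_BANDS = ((1, 4), (4, 8), (8, 13), (13, 30), (30, 70))

FEATURE_NAMES: tuple[str, ...] = (
    "WL", "ZC", "PKS", "MAV", "MED", "TH", "RMS", "AKUR", "ASKW", "NL",
    "PWRA", "ANE",
    "powVHFrel_1", "powVHFrel_2", "powVHFrel_3",
    "powHFrel_1", "powHFrel_2",
    "powLFrel_1", "powLFrel_2", "powLFrel_3", "powLFrel_4", "powLFrel_5",
)

METADATA_COLUMNS = ("patient_id", "hemisphere", "electrode", "edt_mm", "label")


@dataclass
class PsdEstimate:
    """Welch PSD on a 1 Hz grid; ``source`` is ``direct`` or ``rectified``."""

    freqs: np.ndarray
    power: np.ndarray
    source: str

    def band_power(self, lo: float, hi: float) -> float:
        """Total power in [lo, hi) on the frequency grid."""
        sel = (self.freqs >= lo) & (self.freqs < hi)
        return float(self.power[sel].sum())


def compute_time_features(
    x: np.ndarray, fs: float, nl: float | None = None, th: float | None = None,
    curve_length_mode: str = "difference",
) -> dict[str, float]:
    """WL, ZC, PKS, ANE.

    ZC counts zero-line crossings whose flanking excursions both leave the
    noise deadband [-NL, +NL]; PKS counts strict local maxima above the TH
    threshold.  Both are normalized by N, as are WL and ANE.
    ``curve_length_mode='sum'`` switches WL to the literal printed variant
    sum|x(n) + x(n+1)| instead of the first-difference curve length.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("time-domain features need at least 3 samples")
    if curve_length_mode == "difference":
        wl = float(np.abs(np.diff(x)).sum() / n)
    elif curve_length_mode == "sum":
        wl = float(np.abs(x[:-1] + x[1:]).sum() / n)
    else:
        raise ValueError(f"unknown curve_length_mode {curve_length_mode!r}")
    if nl is None:
        nl = background_level(x)
    if th is None:
        th = 3.0 * float(np.std(x, ddof=1))
    zc = _deadband_crossings(x, nl) / n
    pks = _count_peaks(x, th) / n
    ane = float(np.sum(x[1:-1] ** 2 - x[:-2] * x[2:]) / (n - 2))
    return {"WL": wl, "ZC": zc, "PKS": pks, "ANE": ane}


def _deadband_crossings(x: np.ndarray, deadband: float) -> int:
    """Sign alternations between successive excursions beyond +/-deadband."""
    above = np.flatnonzero(np.abs(x) > deadband)
    if len(above) == 0:
        return 0
    signs = np.sign(x[above])
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def _count_peaks(x: np.ndarray, height: float) -> int:
    """Strict local maxima (greater than both neighbours) above ``height``."""
    inner = x[1:-1]
    is_peak = (inner > x[:-2]) & (inner > x[2:]) & (inner > height)
    return int(np.count_nonzero(is_peak))


def compute_amplitude_features(x: np.ndarray) -> dict[str, float]:
    """MAV, MED, TH, RMS, AKUR, ASKW, NL, PWRA.

    Kurtosis and skewness use the trace's amplitude distribution with the
    (N-1) normalization; a zero-variance trace yields NaN for both (the
    record is later flagged invalid and dropped).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("amplitude features need at least 2 samples")
    absx = np.abs(x)
    mav = float(absx.mean())
    med = float(np.median(absx))
    sd = float(np.std(x, ddof=1))
    th = 3.0 * sd
    pwra = float(np.mean(x**2))
    rms = float(np.sqrt(pwra))
    mean = float(x.mean())
    if sd > 0:
        dev = x - mean
        akur = float(np.sum(dev**4) / ((n - 1) * sd**4))
        askw = float(np.sum(dev**3) / ((n - 1) * sd**3))
    else:
        akur = np.nan
        askw = np.nan
    nl = background_level(x)
    return {
        "MAV": mav, "MED": med, "TH": th, "RMS": rms,
        "AKUR": akur, "ASKW": askw, "NL": nl, "PWRA": pwra,
    }


def compute_psd(x: np.ndarray, fs: float, source: str = "direct") -> PsdEstimate:
    """Welch PSD with 1 s Hann windows, 50% overlap -> 1 Hz resolution.

    ``source='rectified'`` computes the PSD of |x| - mean(|x|), the
    envelope spectrum used for the sub-300 Hz bands.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(fs))
    if len(x) < nperseg:
        raise ValueError("trace shorter than one 1 s Welch window")
    if source == "direct":
        y = x
    elif source == "rectified":
        absx = np.abs(x)
        y = absx - absx.mean()
    else:
        raise ValueError(f"unknown PSD source {source!r}")
    freqs, power = _signal.welch(
        y, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return PsdEstimate(freqs=freqs, power=power, source=source)


def compute_spectral_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """The ten relative band powers; NaN-filled if a denominator is zero."""
    direct = compute_psd(x, fs, "direct")
    rect = compute_psd(x, fs, "rectified")
    out: dict[str, float] = {}
    vhf_tot = direct.band_power(VHF_BANDS[0][0], VHF_BANDS[-1][1])
    for i, (lo, hi) in enumerate(VHF_BANDS, start=1):
        out[f"powVHFrel_{i}"] = (
            direct.band_power(lo, hi) / vhf_tot if vhf_tot > 0 else np.nan
        )
    env_tot = rect.band_power(LF_BANDS[0][0], HF_BANDS[-1][1])
    for i, (lo, hi) in enumerate(HF_BANDS, start=1):
        out[f"powHFrel_{i}"] = (
            rect.band_power(lo, hi) / env_tot if env_tot > 0 else np.nan
        )
    for i, (lo, hi) in enumerate(LF_BANDS, start=1):
        out[f"powLFrel_{i}"] = (
            rect.band_power(lo, hi) / env_tot if env_tot > 0 else np.nan
        )
    return out


def compute_features(
    x: np.ndarray, fs: float, curve_length_mode: str = "difference"
) -> dict[str, float]:
    """All 22 features of one signal, in FEATURE_NAMES order."""
    amp = compute_amplitude_features(x)
    time = compute_time_features(
        x, fs, nl=amp["NL"], th=amp["TH"], curve_length_mode=curve_length_mode
    )
    spec = compute_spectral_features(x, fs)
    merged = {**time, **amp, **spec}
    return {name: merged[name] for name in FEATURE_NAMES}


def extract_table(
    traces: Iterable[MerTrace], curve_length_mode: str = "difference"
) -> pd.DataFrame:
    """One row per trace: metadata keys then the 22 features.

    Records with any non-finite feature (zero-variance or silent traces)
    are dropped; the drop count is logged.
    """
    rows: list[dict] = []
    dropped = 0
    for t in traces:
        feats = compute_features(t.samples, t.fs, curve_length_mode)
        if not all(np.isfinite(v) for v in feats.values()):
            dropped += 1
            continue
        rows.append(
            {
                "patient_id": t.patient_id,
                "hemisphere": t.hemisphere,
                "electrode": t.electrode,
                "edt_mm": t.edt_mm,
                "label": t.label,
                **feats,
            }
        )
    if dropped:
        logger.warning("dropped %d record(s) with invalid features", dropped)
    columns = list(METADATA_COLUMNS) + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=columns)
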