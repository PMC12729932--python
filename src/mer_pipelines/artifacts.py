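"""Automatic artifact rejection for MER traces.

Two unsupervised detectors operate on a shared grid of 0.5 s segments:

* **COV** — a stationarity scan.  Each segment's autocorrelation is
  computed (biased estimator, all lags); the variance of that
  autocorrelation sequence summarizes the segment, and any two segments
  are compared by the ratio of their variances (larger over smaller, so
  the distance is >= 1).  Ratios above a threshold (default 1.8) mark the
  pair as mutually non-stationary; the trace is reduced to the longest
  contiguous run of segments that are pairwise stationary, found by
  greedy rightward expansion from every start index.

* **BCK** — a background-noise detector.  The noise level of a signal is
  the median of its analytic (Hilbert) envelope.  A segment is flagged
  when its noise level exceeds 20x the whole-trace level (amplitude
  check) or when the maximum of its FFT magnitude exceeds 2.5x the median
  of the per-segment maxima (frequency check).  Flagged segments are
  removed and the remainder concatenated.

All three thresholds use strict ``>``: a value exactly at threshold is
clean.  A third, label-driven path (**EXP**) removes whole traces that an
external annotation marks as artifactual, and a minimum-residual-length
rule (default 4 s) drops traces left too short by either detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .synth import MerTrace

__all__ = [
    "CovScan",
    "BckScan",
    "cov_scan",
    "bck_scan",
    "background_level",
    "amplitude_flags",
    "frequency_flags",
    "longest_clean_run",
    "exp_filter",
    "enforce_min_length",
    "apply_artifact_method",
    "ARTIFACT_METHODS",
]

SEGMENT_LEN_S = 0.5
ARTIFACT_METHODS = ("RAW", "EXP", "COV", "BCK")


def _segment(x: np.ndarray, fs: float, segment_len: float) -> np.ndarray:
    """Split into full segments of ``segment_len`` seconds, shape (m, L)."""
    seg = int(round(segment_len * fs))
    if seg <= 0 or abs(segment_len * fs - seg) > 1e-9:
        raise ValueError("segment_len * fs must be a positive integer")
    m = len(x) // seg
    if m < 1:
        raise ValueError("trace shorter than one segment")
    return x[: m * seg].reshape(m, seg)


def biased_autocorr(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation r[l] = (1/L) sum_n x[n] x[n+l], l = 0..L-1.

    Unnormalized and without mean removal, so amplitude bursts inflate the
    variance of the sequence — the property the COV scan relies on.
    """
    L = len(x)
    nfft = 1 << (2 * L - 1).bit_length()
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:L]
    return r / L


@dataclass
class CovScan:
    """Result of the COV stationarity scan over one trace."""

    segment_len: float
    m: int
    variances: np.ndarray          # v_k, variance of each segment's autocorrelation
    distances: np.ndarray          # D, m x m, unit diagonal, d_kl >= 1
    threshold: float
    adjacency: np.ndarray          # A = D > threshold (strict)
    retained_run: tuple[int, int]  # inclusive segment interval [i, j]
    rejected_fraction: float
    segment_rejected: np.ndarray   # per-segment verdict (True = rejected)


@dataclass
class BckScan:
    """Result of the BCK background-noise scan over one trace."""

    segment_len: float
    m: int
    bck_tot: float
    bck_seg: np.ndarray
    amp_factor: float
    fft_max: np.ndarray
    freq_factor: float
    amp_flags: np.ndarray
    freq_flags: np.ndarray
    combined_flags: np.ndarray
    rejected_fraction: float

    @property
    def segment_rejected(self) -> np.ndarray:
        return self.combined_flags


def _pairwise_variance_distance(v: np.ndarray) -> np.ndarray:
    """d_kl = max(v_k, v_l) / min(v_k, v_l); +inf if either variance is 0."""
    v = np.asarray(v, dtype=float)
    hi = np.maximum.outer(v, v)
    lo = np.minimum.outer(v, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(lo > 0, hi / lo, np.inf)
    np.fill_diagonal(d, 1.0)
    return d


def longest_clean_run(adjacency: np.ndarray) -> tuple[int, int]:
    """Longest contiguous interval whose induced adjacency submatrix is
    all-zero: greedy rightward expansion from each start, earliest start on
    ties.  Returns the inclusive (i, j) interval."""
    A = np.asarray(adjacency, bool)
    m = A.shape[0]
    best = (0, 0)
    best_len = 1
    for i in range(m):
        if m - i <= best_len - 1:
            break
        j = i
        while j + 1 < m and not A[j + 1, i : j + 1].any():
            j += 1
        if j - i + 1 > best_len:
            best, best_len = (i, j), j - i + 1
    return best


def cov_scan(
    trace: MerTrace,
    threshold: float = 1.8,
    segment_len: float = SEGMENT_LEN_S,
) -> tuple[CovScan, MerTrace]:
    """Run the COV stationarity scan; returns the scan and the cleaned
    trace (samples of the longest mutually stationary run)."""
    segs = _segment(trace.samples, trace.fs, segment_len)
    m = segs.shape[0]
    if m < 2:
        raise ValueError("COV scan needs at least 2 segments")
    v = np.array([np.var(biased_autocorr(s)) for s in segs])
    D = _pairwise_variance_distance(v)
    A = D > threshold
    np.fill_diagonal(A, False)
    i, j = longest_clean_run(A)
    rejected = np.ones(m, dtype=bool)
    rejected[i : j + 1] = False
    frac = 1.0 - (j - i + 1) / m
    scan = CovScan(
        segment_len=segment_len,
        m=m,
        variances=v,
        distances=D,
        threshold=threshold,
        adjacency=A,
        retained_run=(i, j),
        rejected_fraction=frac,
        segment_rejected=rejected,
    )
    seg_n = segs.shape[1]
    cleaned = _slice_trace(trace, np.arange(i * seg_n, (j + 1) * seg_n))
    return scan, cleaned


def background_level(x: np.ndarray) -> float:
    """Background-noise level: median magnitude of the analytic envelope."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if not x.any():
        return 0.0
    return float(np.median(np.abs(_signal.hilbert(x))))


def amplitude_flags(
    bck_seg: np.ndarray, bck_tot: float, amp_factor: float = 20.0
) -> np.ndarray:
    """Amplitude check: segment noise level strictly above amp_factor x
    the whole-trace level; a segment exactly at threshold is clean."""
    return np.asarray(bck_seg, float) > amp_factor * bck_tot


def frequency_flags(fft_max: np.ndarray, freq_factor: float = 2.5) -> np.ndarray:
    """Frequency check: per-segment FFT maximum strictly above freq_factor
    x the median of the per-segment maxima."""
    fft_max = np.asarray(fft_max, float)
    return fft_max > freq_factor * np.median(fft_max)


def bck_scan(
    trace: MerTrace,
    amp_factor: float = 20.0,
    freq_factor: float = 2.5,
    segment_len: float = SEGMENT_LEN_S,
) -> tuple[BckScan, MerTrace]:
    """Run the BCK amplitude + frequency checks; returns the scan and the
    cleaned trace (unflagged segments concatenated in time order)."""
    segs = _segment(trace.samples, trace.fs, segment_len)
    m = segs.shape[0]
    if m < 2:
        raise ValueError("BCK scan needs at least 2 segments")
    bck_tot = background_level(trace.samples)
    bck_seg = np.array([background_level(s) for s in segs])
    amp = amplitude_flags(bck_seg, bck_tot, amp_factor)
    # FFT magnitude of each mean-removed segment, so the DC bin never
    # dominates the maximum
    demeaned = segs - segs.mean(axis=1, keepdims=True)
    fft_max = np.abs(np.fft.rfft(demeaned, axis=1)).max(axis=1)
    freq = frequency_flags(fft_max, freq_factor)
    combined = amp | freq
    scan = BckScan(
        segment_len=segment_len,
        m=m,
        bck_tot=bck_tot,
        bck_seg=bck_seg,
        amp_factor=amp_factor,
        fft_max=fft_max,
        freq_factor=freq_factor,
        amp_flags=amp,
        freq_flags=freq,
        combined_flags=combined,
        rejected_fraction=float(combined.mean()),
    )
    seg_n = segs.shape[1]
    keep_idx = np.flatnonzero(~combined)
    sample_idx = (keep_idx[:, None] * seg_n + np.arange(seg_n)[None, :]).ravel()
    cleaned = _slice_trace(trace, sample_idx)
    return scan, cleaned


def _slice_trace(trace: MerTrace, sample_idx: np.ndarray) -> MerTrace:
    mask = (
        trace.truth_artifact_mask[sample_idx]
        if trace.truth_artifact_mask is not None
        else None
    )
    return replace(
        trace, samples=trace.samples[sample_idx], truth_artifact_mask=mask
    )


def exp_filter(
    traces: Sequence[MerTrace], rejection_labels: Mapping[str, bool]
) -> list[MerTrace]:
    """Remove whole traces flagged by an external (expert) annotation.

    ``rejection_labels`` maps trace ids to booleans; ids not present are
    treated as clean, ids that match no trace are an error.
    """
    ids = {t.trace_id for t in traces}
    unknown = set(rejection_labels) - ids
    if unknown:
        raise KeyError(f"rejection labels for unknown traces: {sorted(unknown)[:5]}")
    return [t for t in traces if not rejection_labels.get(t.trace_id, False)]


def truth_rejection_labels(traces: Sequence[MerTrace]) -> dict[str, bool]:
    """Expert-style whole-trace labels derived from ground-truth masks:
    any trace containing any injected artifact sample is rejected."""
    return {
        t.trace_id: bool(
            t.truth_artifact_mask is not None and t.truth_artifact_mask.any()
        )
        for t in traces
    }


def enforce_min_length(trace: MerTrace, min_s: float = 4.0) -> bool:
    """Keep a (possibly cleaned) trace iff its residual duration is at
    least ``min_s`` seconds (inclusive)."""
    return trace.duration >= min_s


def apply_artifact_method(
    traces: Sequence[MerTrace],
    method: str,
    rejection_labels: Mapping[str, bool] | None = None,
    min_s: float = 4.0,
) -> tuple[list[MerTrace], dict[str, CovScan | BckScan]]:
    """Produce one artifact-cleaned dataset variant (RAW/EXP/COV/BCK).

    RAW passes traces through; EXP drops labeled traces whole (labels
    default to ground-truth-derived ones); COV/BCK clean per segment and
    then apply the minimum-residual-length rule.  Returns the surviving
    traces and the per-trace scans (empty for RAW/EXP).
    """
    method = method.upper()
    if method not in ARTIFACT_METHODS:
        raise ValueError(f"unknown artifact method {method!r}")
    scans: dict[str, CovScan | BckScan] = {}
    if method == "RAW":
        return list(traces), scans
    if method == "EXP":
        labels = (
            rejection_labels
            if rejection_labels is not None
            else truth_rejection_labels(traces)
        )
        return exp_filter(traces, labels), scans
    out: list[MerTrace] = []
    for t in traces:
        scan, cleaned = cov_scan(t) if method == "COV" else bck_scan(t)
        scans[t.trace_id] = scan
        if enforce_min_length(cleaned, min_s):
            out.append(cleaned)
    return out, scans
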