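"""Synthetic microelectrode-recording (MER) cohort generator.

Emulates the acquisition geometry of intraoperative STN exploration:
each patient contributes two hemispheres, each explored by three parallel
microelectrodes (anterior, central, posterior) advancing in 1 mm steps,
with one >=10 s trace recorded at 24 kHz per depth.  Traces whose depth
falls inside a per-trajectory STN interval are labeled ``STN``; all others
``NOT_STN``.  The STN class has elevated firing rate, spike amplitude
(relative to noise), background-noise level and a 20 Hz (beta-band)
amplitude modulation of its spiking — the statistical structure a
feature-based STN classifier relies on.

Signals are background Gaussian noise plus a Poisson spike train convolved
with a ~1.2 ms biphasic template.  Electromagnetic-interference and
mechanical-transient artifacts can be injected with exact ground-truth
per-sample masks.  Cohorts are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "MerTrace",
    "biphasic_template",
    "simulate_trace",
    "iter_cohort",
    "simulate_cohort",
    "inject_artifacts",
]

HEMISPHERES = ("left", "right")

STN = "STN"
NOT_STN = "NOT_STN"


def _default_edt_levels() -> tuple[int, ...]:
    # +10 mm above target down to -5 mm beyond it, 1 mm steps
    return tuple(range(10, -6, -1))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated cohort.

    Amplitudes are in microvolts, rates in Hz.  ``stn_start_range`` /
    ``stn_length_range`` define the per-trajectory STN interval: an entry
    depth drawn uniformly in ``stn_start_range`` (mm EDT) and an extent
    drawn uniformly in ``stn_length_range`` (mm); the trajectory is inside
    the STN for EDT in [start - length, start].
    """

    n_patients: int
    fs: int = 24_000
    trace_duration: float = 10.0
    edt_levels: tuple[int, ...] = field(default_factory=_default_edt_levels)
    electrodes: tuple[str, ...] = ("anterior", "central", "posterior")
    stn_start_range: tuple[float, float] = (-1.0, 1.0)
    stn_length_range: tuple[float, float] = (3.0, 5.0)
    firing_rate_stn: float = 35.0
    firing_rate_out: float = 8.0
    spike_amplitude_snr_stn: float = 4.0
    spike_amplitude_snr_out: float = 1.5
    noise_sd_stn: float = 12.0
    noise_sd_out: float = 6.0
    beta_mod_depth_stn: float = 0.4
    beta_mod_freq: float = 20.0
    artifact_rate: float = 0.3
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "fs": self.fs,
            "trace_duration": self.trace_duration,
            "firing_rate_stn": self.firing_rate_stn,
            "firing_rate_out": self.firing_rate_out,
            "spike_amplitude_snr_stn": self.spike_amplitude_snr_stn,
            "spike_amplitude_snr_out": self.spike_amplitude_snr_out,
            "noise_sd_stn": self.noise_sd_stn,
            "noise_sd_out": self.noise_sd_out,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.artifact_rate < 0 or self.duplicate_fraction < 0:
            raise ValueError("artifact_rate and duplicate_fraction must be >= 0")
        if not 0 <= self.beta_mod_depth_stn <= 1:
            raise ValueError("beta_mod_depth_stn must lie in [0, 1]")
        if len(self.edt_levels) < 1 or np.any(np.diff(self.edt_levels) >= 0):
            raise ValueError("edt_levels must be strictly decreasing")
        if not len(self.electrodes):
            raise ValueError("electrodes must be non-empty")
        n = self.fs * self.trace_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trace_duration * fs must be an integer sample count")
        for lo, hi in (self.stn_start_range, self.stn_length_range):
            if lo > hi:
                raise ValueError("range bounds must be ordered (lo <= hi)")
        if self.stn_length_range[0] <= 0:
            raise ValueError("stn length must be strictly positive")
        # generator contract: STN parameters strictly dominate, so the two
        # classes are learnably different
        if not (
            self.firing_rate_stn > self.firing_rate_out
            and self.spike_amplitude_snr_stn > self.spike_amplitude_snr_out
            and self.noise_sd_stn > self.noise_sd_out
        ):
            raise ValueError("STN parameters must strictly dominate non-STN ones")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trace_duration))


@dataclass(eq=False)  # identity equality; ndarray fields don't compare well
class MerTrace:
    """One recording at one depth of one electrode trajectory."""

    samples: np.ndarray
    fs: int
    patient_id: str
    hemisphere: str
    electrode: str
    edt_mm: float
    timestamp: int
    label: str
    truth_artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.label not in (STN, NOT_STN):
            raise ValueError(f"label must be {STN!r} or {NOT_STN!r}")
        if self.truth_artifact_mask is not None:
            mask = np.asarray(self.truth_artifact_mask, dtype=bool)
            if mask.shape != self.samples.shape:
                raise ValueError("truth_artifact_mask must match samples in length")
            self.truth_artifact_mask = mask

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def key(self) -> tuple[str, str, str, float]:
        """Deduplication key: (patient, hemisphere, electrode, depth)."""
        return (self.patient_id, self.hemisphere, self.electrode, self.edt_mm)

    @property
    def trace_id(self) -> str:
        return (
            f"{self.patient_id}_{self.hemisphere}_{self.electrode}_"
            f"{_format_edt(self.edt_mm)}_t{self.timestamp}"
        )


def _format_edt(edt_mm: float) -> str:
    sign = "p" if edt_mm >= 0 else "m"
    mag = abs(edt_mm)
    return f"{sign}{mag:g}"


def biphasic_template(fs: int, duration_ms: float = 1.2) -> np.ndarray:
    """Biphasic extracellular spike template (difference of Gaussians).

    A fast positive lobe followed by a slower negative after-wave, with
    ~``duration_ms`` support; peak normalized to 1.
    """
    n = max(3, int(round(duration_ms * 1e-3 * fs)))
    t = np.arange(n) / fs * 1e3  # ms
    pos = np.exp(-((t - 0.35 * duration_ms / 1.2) ** 2) / (2 * 0.12**2))
    neg = np.exp(-((t - 0.75 * duration_ms / 1.2) ** 2) / (2 * 0.22**2))
    w = pos - 0.55 * neg
    return w / np.max(np.abs(w))


def simulate_trace(
    cfg: CohortConfig,
    is_stn: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one trace; returns (samples, spike_sample_indices)."""
    n = cfg.n_samples
    if is_stn:
        rate, snr, sd = cfg.firing_rate_stn, cfg.spike_amplitude_snr_stn, cfg.noise_sd_stn
    else:
        rate, snr, sd = cfg.firing_rate_out, cfg.spike_amplitude_snr_out, cfg.noise_sd_out
    x = rng.normal(0.0, sd, size=n)

    n_spikes = rng.poisson(rate * cfg.trace_duration)
    template = biphasic_template(cfg.fs)
    if n_spikes:
        starts = np.sort(rng.integers(0, n - len(template), size=n_spikes))
        amp = np.full(n_spikes, snr * sd)
        if is_stn and cfg.beta_mod_depth_stn > 0:
            t_spk = starts / cfg.fs
            amp = amp * (
                1.0
                + cfg.beta_mod_depth_stn * np.sin(2 * np.pi * cfg.beta_mod_freq * t_spk)
            )
        spikes = np.zeros(n)
        np.add.at(spikes, starts, amp)
        x += np.convolve(spikes, template)[:n]
    else:
        starts = np.empty(0, dtype=np.int64)
    return x, starts


def _trajectory_stn_interval(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[float, float]:
    start = rng.uniform(*cfg.stn_start_range)
    length = rng.uniform(*cfg.stn_length_range)
    return start - length, start


def iter_cohort(cfg: CohortConfig) -> Iterator[MerTrace]:
    """Yield cohort traces one at a time (memory-friendly).

    Deterministic: the stream is a pure function of ``cfg`` (including its
    seed).  With ``duplicate_fraction`` > 0, some depths additionally yield
    a repeat recording with an earlier timestamp, exercising downstream
    deduplication.
    """
    if cfg.n_patients <= 0:
        return
    root = np.random.SeedSequence(cfg.seed)
    for p in range(cfg.n_patients):
        patient_id = f"P{p:03d}"
        for h, hemisphere in enumerate(HEMISPHERES):
            for e, electrode in enumerate(cfg.electrodes):
                traj_ss = np.random.SeedSequence(
                    entropy=cfg.seed, spawn_key=(p, h, e)
                )
                traj_rng = np.random.default_rng(traj_ss)
                lo, hi = _trajectory_stn_interval(cfg, traj_rng)
                for d, edt in enumerate(cfg.edt_levels):
                    trace_rng = np.random.default_rng(
                        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(p, h, e, d))
                    )
                    is_stn = lo <= edt <= hi
                    timestamp = d * 10 + 5  # monotone within trajectory
                    x, _ = simulate_trace(cfg, is_stn, trace_rng)
                    trace = MerTrace(
                        samples=x,
                        fs=cfg.fs,
                        patient_id=patient_id,
                        hemisphere=hemisphere,
                        electrode=electrode,
                        edt_mm=float(edt),
                        timestamp=timestamp,
                        label=STN if is_stn else NOT_STN,
                    )
                    trace = _maybe_inject(trace, cfg, trace_rng)
                    if cfg.duplicate_fraction > 0 and trace_rng.random() < cfg.duplicate_fraction:
                        # an earlier, discarded attempt at the same depth
                        dup_x, _ = simulate_trace(cfg, is_stn, trace_rng)
                        yield MerTrace(
                            samples=dup_x,
                            fs=cfg.fs,
                            patient_id=patient_id,
                            hemisphere=hemisphere,
                            electrode=electrode,
                            edt_mm=float(edt),
                            timestamp=timestamp - 1,
                            label=trace.label,
                        )
                    yield trace


def _maybe_inject(
    trace: MerTrace, cfg: CohortConfig, rng: np.random.Generator
) -> MerTrace:
    if cfg.artifact_rate <= 0:
        return trace
    n_events = rng.poisson(cfg.artifact_rate)
    if n_events == 0:
        return trace
    duration = trace.duration
    for _ in range(n_events):
        kind = "em_interference" if rng.random() < 0.5 else "mechanical"
        dur = rng.uniform(0.2, 1.0)
        start = rng.uniform(0.0, max(duration - dur, 0.0))
        gain = rng.uniform(5.0, 15.0)
        trace = inject_artifacts(
            trace, kind, [(start, dur, gain)], seed=int(rng.integers(2**31))
        )
    return trace


def simulate_cohort(cfg: CohortConfig) -> tuple[list[MerTrace], pd.DataFrame]:
    """Simulate the full cohort: one trace per patient x hemisphere x
    electrode x depth (plus optional duplicates); returns the traces and a
    manifest table."""
    traces = list(iter_cohort(cfg))
    manifest = build_manifest(traces)
    return traces, manifest


def build_manifest(traces: Sequence[MerTrace]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": t.patient_id,
            "hemisphere": t.hemisphere,
            "electrode": t.electrode,
            "edt_mm": t.edt_mm,
            "timestamp": t.timestamp,
            "label": t.label,
            "has_artifact": bool(
                t.truth_artifact_mask is not None and t.truth_artifact_mask.any()
            ),
        }
        for t in traces
    ]
    columns = [
        "patient_id", "hemisphere", "electrode", "edt_mm",
        "timestamp", "label", "has_artifact",
    ]
    return pd.DataFrame(rows, columns=columns)


def inject_artifacts(
    trace: MerTrace,
    kind: str,
    events: Iterable[tuple[float, float, float]],
    seed: int = 0,
) -> MerTrace:
    """Add artifact events to a trace and record them in the truth mask.

    ``kind`` is ``em_interference`` (50 Hz mains sinusoid plus a 150 Hz
    harmonic at half amplitude, random phase) or ``mechanical`` (a step
    with exponential decay, emulating an electrode shift).  Each event is
    ``(start_s, duration_s, gain)``; the added waveform's amplitude is
    ``gain`` times the trace RMS.  Overlapping events merge in the mask;
    events running past the trace end are truncated with a warning.
    """
    if kind not in ("em_interference", "mechanical"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    x = trace.samples.copy()
    n = len(x)
    fs = trace.fs
    mask = (
        trace.truth_artifact_mask.copy()
        if trace.truth_artifact_mask is not None
        else np.zeros(n, dtype=bool)
    )
    rms = float(np.sqrt(np.mean(trace.samples**2)))
    rng = np.random.default_rng(seed)
    for start_s, dur_s, gain in events:
        if start_s < 0 or dur_s <= 0:
            raise ValueError("event start must be >= 0 and duration > 0")
        i0 = int(round(start_s * fs))
        i1 = int(round((start_s + dur_s) * fs))
        if i0 >= n:
            raise ValueError("event starts past the end of the trace")
        if i1 > n:
            warnings.warn(
                "artifact event extends past trace end; truncating", stacklevel=2
            )
            i1 = n
        t = np.arange(i0, i1) / fs
        amp = gain * rms
        if kind == "em_interference":
            phase = rng.uniform(0, 2 * np.pi)
            x[i0:i1] += amp * (
                np.sin(2 * np.pi * 50.0 * t + phase)
                + 0.5 * np.sin(2 * np.pi * 150.0 * t + 3 * phase)
            )
        else:  # mechanical
            tau = max(dur_s / 4.0, 1.0 / fs)
            x[i0:i1] += amp * np.exp(-(t - t[0]) / tau)
        mask[i0:i1] = True
    return replace(trace, samples=x, truth_artifact_mask=mask)
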