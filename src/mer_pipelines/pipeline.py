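"""End-to-end orchestration: cohort -> four cleaned feature tables ->
24 dataset variants -> grid evaluation.

The streaming path (`prepare_feature_tables`) processes one trace at a
time so a full cohort never has to sit in memory: each selected trace is
scanned by both automatic detectors on the raw signal (artifact detection
precedes the analysis band-pass, whose 300 Hz edge would hide mains
interference), then each surviving variant of the trace is band-passed
and reduced to its 22 features.  The RAW and EXP variants of a surviving
trace share one feature computation since EXP only drops whole traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .artifacts import (
    ARTIFACT_METHODS,
    BckScan,
    CovScan,
    bck_scan,
    cov_scan,
    enforce_min_length,
)
from .evaluate import AgreementResult, GridResult, detector_agreement, run_grid
from .features import FEATURE_NAMES, METADATA_COLUMNS, compute_features
from .outliers import DatasetVariant, build_variants
from .preprocess import PreprocessConfig, bandpass, deduplicate, select_edt
from .synth import CohortConfig, MerTrace, iter_cohort

__all__ = ["PreparedDatasets", "prepare_feature_tables", "run_framework"]

logger = logging.getLogger(__name__)


@dataclass
class PreparedDatasets:
    """The four artifact-cleaned feature tables plus detector scans."""

    tables: dict[str, pd.DataFrame]
    cov_scans: dict[str, CovScan] = field(default_factory=dict)
    bck_scans: dict[str, BckScan] = field(default_factory=dict)

    def agreement(self) -> AgreementResult:
        cov_masks = {k: s.segment_rejected for k, s in self.cov_scans.items()}
        bck_masks = {k: s.segment_rejected for k, s in self.bck_scans.items()}
        subjects = {k: k.split("_", 1)[0] for k in cov_masks}
        return detector_agreement(cov_masks, bck_masks, subjects)

    def rejected_signal_fraction(self, method: str) -> float:
        """Fraction of scanned signal rejected by COV or BCK (0..1)."""
        scans = self.cov_scans if method.upper() == "COV" else self.bck_scans
        if not scans:
            raise ValueError("no scans recorded for this method")
        fractions = [s.rejected_fraction for s in scans.values()]
        return float(np.mean(fractions))

    def variants(self) -> list[DatasetVariant]:
        return build_variants(self.tables)


def _feature_row(trace: MerTrace, cfg: PreprocessConfig) -> dict | None:
    filtered = bandpass(trace, cfg)
    feats = compute_features(filtered.samples, filtered.fs)
    if not all(np.isfinite(v) for v in feats.values()):
        return None
    return {
        "patient_id": trace.patient_id,
        "hemisphere": trace.hemisphere,
        "electrode": trace.electrode,
        "edt_mm": trace.edt_mm,
        "label": trace.label,
        **feats,
    }


def prepare_feature_tables(
    traces: Iterable[MerTrace],
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
    min_residual_s: float = 4.0,
    methods: tuple[str, ...] = ARTIFACT_METHODS,
) -> PreparedDatasets:
    """Build the RAW/EXP/COV/BCK feature tables from a trace stream.

    Steps per the common pipeline: EDT window selection, duplicate
    resolution (latest timestamp wins), per-method artifact cleaning with
    the minimum-residual-length rule, analysis band-pass, feature
    extraction.  EXP rejection labels come from the traces' ground-truth
    artifact masks (any artifactual sample rejects the whole trace).
    """
    methods = tuple(m.upper() for m in methods)
    unknown = set(methods) - set(ARTIFACT_METHODS)
    if unknown:
        raise ValueError(f"unknown artifact method(s): {sorted(unknown)}")
    selected = deduplicate(select_edt(traces, preprocess_cfg))
    rows: dict[str, list[dict]] = {m: [] for m in methods}
    cov_scans: dict[str, CovScan] = {}
    bck_scans: dict[str, BckScan] = {}
    dropped = 0
    for trace in selected:
        if "RAW" in methods or "EXP" in methods:
            raw_row = _feature_row(trace, preprocess_cfg)
            if raw_row is None:
                dropped += 1
            else:
                if "RAW" in methods:
                    rows["RAW"].append(raw_row)
                has_artifact = bool(
                    trace.truth_artifact_mask is not None
                    and trace.truth_artifact_mask.any()
                )
                if "EXP" in methods and not has_artifact:
                    rows["EXP"].append(dict(raw_row))
        for method, scan_fn, store in (
            ("COV", cov_scan, cov_scans),
            ("BCK", bck_scan, bck_scans),
        ):
            if method not in methods:
                continue
            scan, cleaned = scan_fn(trace)
            store[trace.trace_id] = scan
            if not enforce_min_length(cleaned, min_residual_s):
                continue
            row = _feature_row(cleaned, preprocess_cfg)
            if row is None:
                dropped += 1
                continue
            rows[method].append(row)
    if dropped:
        logger.warning("dropped %d record(s) with invalid features", dropped)
    columns = list(METADATA_COLUMNS) + list(FEATURE_NAMES)
    tables = {m: pd.DataFrame(r, columns=columns) for m, r in rows.items()}
    return PreparedDatasets(tables=tables, cov_scans=cov_scans, bck_scans=bck_scans)


def run_framework(
    cohort_cfg: CohortConfig,
    seed: int = 0,
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
    **grid_kwargs,
) -> tuple[PreparedDatasets, GridResult]:
    """Simulate a cohort and run the full 24 x 6 evaluation grid."""
    prepared = prepare_feature_tables(iter_cohort(cohort_cfg), preprocess_cfg)
    grid = run_grid(prepared.variants(), seed=seed, **grid_kwargs)
    return prepared, grid
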