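"""WAV + manifest interchange for simulated cohorts.

One IEEE float-32 WAV per trace plus a ``manifest.csv`` holding the
acquisition metadata; ground-truth artifact masks are stored run-length
encoded as small CSV sidecars.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import MerTrace, build_manifest

__all__ = ["write_cohort", "read_cohort", "mask_to_rle", "rle_to_mask"]

MANIFEST_NAME = "manifest.csv"


def mask_to_rle(mask: np.ndarray) -> pd.DataFrame:
    """Run-length encode a boolean mask: (start, length) of True runs."""
    mask = np.asarray(mask, bool)
    padded = np.diff(np.r_[0, mask.view(np.int8), 0])
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return pd.DataFrame({"start": starts, "length": ends - starts})


def rle_to_mask(rle: pd.DataFrame, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for start, length in zip(rle["start"], rle["length"]):
        mask[int(start) : int(start) + int(length)] = True
    return mask


def write_cohort(traces: Iterable[MerTrace], out_dir: str | Path) -> Path:
    """Write traces as float-32 WAVs plus manifest.csv; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces = list(traces)
    manifest = build_manifest(traces)
    files, mask_files = [], []
    for t in traces:
        stem = t.trace_id
        fname = f"{stem}.wav"
        wavfile.write(out / fname, t.fs, t.samples.astype(np.float32))
        files.append(fname)
        if t.truth_artifact_mask is not None and t.truth_artifact_mask.any():
            mname = f"{stem}_mask.csv"
            mask_to_rle(t.truth_artifact_mask).to_csv(out / mname, index=False)
            mask_files.append(mname)
        else:
            mask_files.append("")
    manifest["file"] = files
    manifest["artifact_mask_file"] = mask_files
    manifest.to_csv(out / MANIFEST_NAME, index=False)
    return out


def read_cohort(in_dir: str | Path) -> Iterator[MerTrace]:
    """Stream traces back from a cohort directory written by write_cohort."""
    root = Path(in_dir)
    manifest = pd.read_csv(root / MANIFEST_NAME, keep_default_na=False)
    for row in manifest.itertuples(index=False):
        fs, samples = wavfile.read(root / row.file)
        mask = None
        if row.artifact_mask_file:
            rle = pd.read_csv(root / row.artifact_mask_file)
            mask = rle_to_mask(rle, len(samples))
        yield MerTrace(
            samples=np.asarray(samples, dtype=np.float64),
            fs=int(fs),
            patient_id=str(row.patient_id),
            hemisphere=str(row.hemisphere),
            electrode=str(row.electrode),
            edt_mm=float(row.edt_mm),
            timestamp=int(row.timestamp),
            label=str(row.label),
            truth_artifact_mask=mask,
        )
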