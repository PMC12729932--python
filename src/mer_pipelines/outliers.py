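"""Outlier management and hemisphere-wise feature normalization.

Three per-cohort options operate on the feature table before modeling:

* NONE — leave the table untouched;
* ORH — quartile fences per (patient, hemisphere) group: a row is removed
  when any of its features lies strictly outside
  [Q1 - 3*IQR, Q3 + 3*IQR];
* ORM — the local outlier factor (LOF), run per patient on the 22-feature
  vectors with neighborhood 20 (or group size - 1) and automatic
  contamination.

An independent toggle applies Min-Max scaling of every feature within
each (patient, hemisphere) group, mapping it to [0, 1] before any
modeling; crossing {RAW, EXP, COV, BCK} x {NONE, ORH, ORM} x {plain,
hemisphere-normalized} yields the 24 dataset variants under comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from .features import FEATURE_NAMES

__all__ = [
    "OUTLIER_METHODS",
    "DatasetVariant",
    "orh_filter",
    "orm_filter",
    "hemisphere_minmax",
    "apply_outlier_method",
    "build_variants",
]

logger = logging.getLogger(__name__)

OUTLIER_METHODS = ("NONE", "ORH", "ORM")
ORH_TOLERANCE = 3.0
ORH_MIN_GROUP = 4
ORM_MIN_GROUP = 3
ORM_NEIGHBORS = 20


@dataclass(frozen=True)
class DatasetVariant:
    """One cell of the preprocessing grid with its provenance triple."""

    artifact_method: str
    outlier_method: str
    pre_normalized: bool
    table: pd.DataFrame

    @property
    def name(self) -> str:
        norm = "norm" if self.pre_normalized else "plain"
        return f"{self.artifact_method}-{self.outlier_method}-{norm}"


def orh_filter(
    table: pd.DataFrame,
    tolerance: float = ORH_TOLERANCE,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Quartile-fence outlier rejection per (patient, hemisphere).

    Quartiles use linear interpolation; a row is removed iff any feature
    strictly exceeds a fence.  Groups with fewer than 4 rows pass through
    unfiltered.
    """
    if table.empty:
        return table.copy()
    keep = pd.Series(True, index=table.index)
    for _, group in table.groupby(["patient_id", "hemisphere"], sort=False):
        if len(group) < ORH_MIN_GROUP:
            continue
        values = group[list(feature_names)].to_numpy(float)
        q1 = np.percentile(values, 25, axis=0)
        q3 = np.percentile(values, 75, axis=0)
        iqr = q3 - q1
        lower = q1 - tolerance * iqr
        upper = q3 + tolerance * iqr
        outside = (values < lower) | (values > upper)
        keep.loc[group.index[outside.any(axis=1)]] = False
    return table.loc[keep].copy()


def orm_filter(
    table: pd.DataFrame,
    n_neighbors: int = ORM_NEIGHBORS,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Local-outlier-factor rejection per patient on the feature vectors.

    Neighborhood size is min(n_neighbors, group size - 1); contamination
    is LOF's automatic setting.  Patients with fewer than 3 rows pass
    through unfiltered (logged).  Deterministic for a fixed table.
    """
    if table.empty:
        return table.copy()
    keep = pd.Series(True, index=table.index)
    for patient, group in table.groupby("patient_id", sort=False):
        if len(group) < ORM_MIN_GROUP:
            logger.warning(
                "ORM: patient %s has %d row(s); passed through unfiltered",
                patient, len(group),
            )
            continue
        k = min(n_neighbors, len(group) - 1)
        lof = LocalOutlierFactor(n_neighbors=k, contamination="auto")
        verdict = lof.fit_predict(group[list(feature_names)].to_numpy(float))
        keep.loc[group.index[verdict == -1]] = False
    return table.loc[keep].copy()


def hemisphere_minmax(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> pd.DataFrame:
    """Min-Max scale each feature to [0, 1] within each (patient,
    hemisphere) group; a feature constant within a group maps to 0."""
    out = table.copy()
    cols = list(feature_names)
    for _, group in table.groupby(["patient_id", "hemisphere"], sort=False):
        values = group[cols].to_numpy(float)
        lo = values.min(axis=0)
        span = values.max(axis=0) - lo
        scaled = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
        out.loc[group.index, cols] = scaled
    return out


def apply_outlier_method(table: pd.DataFrame, method: str) -> pd.DataFrame:
    method = method.upper()
    if method == "NONE":
        return table.copy()
    if method == "ORH":
        return orh_filter(table)
    if method == "ORM":
        return orm_filter(table)
    raise ValueError(f"unknown outlier method {method!r}")


def build_variants(
    cleaned_tables: Mapping[str, pd.DataFrame]
) -> list[DatasetVariant]:
    """Cross the four artifact-cleaned tables with the three outlier
    methods and the normalization toggle -> the 24 dataset variants."""
    from .artifacts import ARTIFACT_METHODS

    missing = [m for m in ARTIFACT_METHODS if m not in cleaned_tables]
    if missing:
        raise KeyError(f"missing artifact-cleaned table(s): {missing}")
    variants: list[DatasetVariant] = []
    for artifact_method in ARTIFACT_METHODS:
        base = cleaned_tables[artifact_method]
        for outlier_method in OUTLIER_METHODS:
            filtered = apply_outlier_method(base, outlier_method)
            for pre_normalized in (False, True):
                table = hemisphere_minmax(filtered) if pre_normalized else filtered.copy()
                variants.append(
                    DatasetVariant(
                        artifact_method=artifact_method,
                        outlier_method=outlier_method,
                        pre_normalized=pre_normalized,
                        table=table,
                    )
                )
    return variants
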