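import numpy as np
import pandas as pd
import pytest

from mer_pipelines import CohortConfig, MerTrace
from mer_pipelines.features import FEATURE_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(
    samples,
    fs=2000,
    patient_id="P000",
    hemisphere="left",
    electrode="central",
    edt_mm=0.0,
    timestamp=0,
    label="NOT_STN",
    mask=None,
):
    return MerTrace(
        samples=np.asarray(samples, float),
        fs=fs,
        patient_id=patient_id,
        hemisphere=hemisphere,
        electrode=electrode,
        edt_mm=edt_mm,
        timestamp=timestamp,
        label=label,
        truth_artifact_mask=mask,
    )


def noise_trace(rng, fs=2000, duration=10.0, sd=1.0, **kw):
    return make_trace(rng.normal(0, sd, int(fs * duration)), fs=fs, **kw)


def synthetic_feature_table(
    rng,
    n_patients=4,
    rows_per_hemisphere=12,
    class_shift=2.0,
    stn_fraction=0.4,
):
    """A labeled 22-feature table drawn directly from Gaussians (no signal
    processing), with an additive mean shift on every feature for the STN
    class so the classes are separable but not trivially so."""
    rows = []
    for p in range(n_patients):
        for hemi in ("left", "right"):
            for i in range(rows_per_hemisphere):
                is_stn = rng.random() < stn_fraction
                base = rng.normal(0, 1.0, len(FEATURE_NAMES))
                if is_stn:
                    base = base + class_shift
                rows.append(
                    {
                        "patient_id": f"P{p:03d}",
                        "hemisphere": hemi,
                        "electrode": "central",
                        "edt_mm": float(-i % 8),
                        "label": "STN" if is_stn else "NOT_STN",
                        **dict(zip(FEATURE_NAMES, base)),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def feature_table(rng):
    return synthetic_feature_table(rng)


@pytest.fixture(scope="session")
def small_cohort_tables():
    """Feature tables from a small low-rate cohort, shared across tests."""
    from mer_pipelines import prepare_feature_tables, iter_cohort
    from mer_pipelines.preprocess import PreprocessConfig

    cfg = CohortConfig(n_patients=2, fs=8000, trace_duration=10.0, seed=0)
    return prepare_feature_tables(iter_cohort(cfg))
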