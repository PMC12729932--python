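"""Grid evaluation, factor-wise ANOVA, detector agreement and feature
presence ranking.

The full comparison runs every one of the 24 dataset variants through the
six model configurations (3 classifiers x RFE on/off) with a shared fold
seed, tabulating five metrics per fold with complete provenance.  Factor
effects are compared by fixed-effects three-way ANOVA on the fold-level
metrics — the model kind ('ML') and feature-selection toggle always enter
as the first two factors, the factor under test ('DATASET', 'OUTLIER' or
'NORMALIZATION') as the third — with Bonferroni-corrected pairwise post
hoc tests on the factor of interest.  Agreement between the two automatic
artifact detectors is measured per 0.5 s segment (percent agreement plus
per-subject Cohen's kappa), and feature importance is summarized as the
percentage of (pipeline, fold) cells in which a feature ranks in the
top ten by mean |Shapley| attribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .classify import MODEL_KINDS, CvResult, ModelSpec, run_model
from .outliers import DatasetVariant

__all__ = [
    "GridResult",
    "run_grid",
    "anova_factors",
    "detector_agreement",
    "cohen_kappa",
    "shap_presence",
    "FACTOR_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")
FACTOR_COLUMNS = {
    "DATASET": "artifact_method",
    "OUTLIER": "outlier_method",
    "NORMALIZATION": "pre_normalized",
}
PROVENANCE = ("artifact_method", "outlier_method", "pre_normalized",
              "model_kind", "use_rfe")


@dataclass
class GridResult:
    """Fold-level metrics for every (variant, model configuration) cell."""

    metrics: pd.DataFrame  # provenance + fold + the five metrics
    rankings: dict[tuple, list[str]] = field(default_factory=dict)
    # rankings key: (artifact, outlier, pre_norm, kind, use_rfe, fold)
    # value: features ordered by decreasing mean |Shapley|
    failures: list[tuple] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.metrics.groupby(list(PROVENANCE)))

    def cell_means(self) -> pd.DataFrame:
        return (
            self.metrics.groupby(list(PROVENANCE))[list(METRIC_NAMES)]
            .mean()
            .reset_index()
        )


def run_grid(
    variants: Sequence[DatasetVariant],
    seed: int = 0,
    model_kinds: Sequence[str] = MODEL_KINDS,
    rfe_options: Sequence[bool] = (False, True),
    k: int = 5,
    compute_shap: bool = True,
    shap_max_points: int = 40,
    shap_permutations: int = 12,
    rfe_score_step: int = 1,
) -> GridResult:
    """Evaluate every variant x model configuration.

    The fold seed is shared across model configurations within a variant,
    so every model sees the same splits.  Degenerate variants (a missing
    class, too few rows to stratify) are recorded as failures, never
    silently dropped.
    """
    rows = []
    rankings: dict[tuple, list[str]] = {}
    failures: list[tuple] = []
    for variant in variants:
        for kind, use_rfe in itertools.product(model_kinds, rfe_options):
            spec = ModelSpec(kind=kind, use_rfe=use_rfe, seed=seed)
            provenance = (
                variant.artifact_method,
                variant.outlier_method,
                variant.pre_normalized,
                kind,
                use_rfe,
            )
            try:
                result: CvResult = run_model(
                    variant,
                    spec,
                    k=k,
                    compute_shap=compute_shap,
                    shap_max_points=shap_max_points,
                    shap_permutations=shap_permutations,
                    rfe_score_step=rfe_score_step,
                )
            except ValueError as exc:
                logger.warning("cell %s failed: %s", provenance, exc)
                failures.append(provenance)
                continue
            for fold, metric_row in result.fold_metrics.iterrows():
                rows.append(
                    dict(zip(PROVENANCE, provenance))
                    | {"fold": int(fold)}
                    | {m: float(metric_row[m]) for m in METRIC_NAMES}
                )
                if compute_shap:
                    series = result.shap_mean_abs[int(fold)]
                    ordered = series.sort_values(ascending=False).index.tolist()
                    rankings[provenance + (int(fold),)] = ordered
    metrics = pd.DataFrame(
        rows, columns=list(PROVENANCE) + ["fold"] + list(METRIC_NAMES)
    )
    return GridResult(metrics=metrics, rankings=rankings, failures=failures)


def anova_factors(
    grid: GridResult, factor: str, metric: str = "accuracy"
) -> dict[str, pd.DataFrame]:
    """Three-way fixed-effects ANOVA (ML x FeatureSelection x factor).

    Observations are the fold-level metric values; sums of squares are
    type II.  Returns the ANOVA table and Bonferroni-corrected pairwise
    Welch t-tests between the levels of the factor of interest.
    """
    if factor not in FACTOR_COLUMNS:
        raise ValueError(f"factor must be one of {sorted(FACTOR_COLUMNS)}")
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    col = FACTOR_COLUMNS[factor]
    df = grid.metrics.copy()
    expected = None
    if col == "artifact_method":
        expected = {"RAW", "EXP", "COV", "BCK"}
    elif col == "outlier_method":
        expected = {"NONE", "ORH", "ORM"}
    if expected is not None:
        present = set(df[col].unique())
        if present != expected:
            raise ValueError(f"missing {factor} level(s): {sorted(expected - present)}")
    df = df.rename(columns={metric: "y", col: "factor_level"})
    df["factor_level"] = df["factor_level"].astype(str)
    df["use_rfe"] = df["use_rfe"].astype(str)
    if df["factor_level"].nunique() < 2:
        raise ValueError(f"factor {factor} has fewer than two levels")
    # drop degenerate factors (a single model kind / RFE setting) from the
    # design so reduced grids remain analyzable
    terms = [
        f"C({t})"
        for t in ("model_kind", "use_rfe", "factor_level")
        if df[t].nunique() > 1
    ]
    model = smf.ols("y ~ " + " * ".join(terms), data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    if np.ptp(df["y"].to_numpy()) == 0:
        # zero variance: no effect exists; numerical residuals would
        # otherwise produce meaningless F ratios
        table["F"] = np.where(table["F"].notna(), 0.0, np.nan)
        table["PR(>F)"] = np.where(table["PR(>F)"].notna(), 1.0, np.nan)

    levels = sorted(df["factor_level"].unique())
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        ya = df.loc[df["factor_level"] == a, "y"]
        yb = df.loc[df["factor_level"] == b, "y"]
        t, p = stats.ttest_ind(ya, yb, equal_var=False)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_a": ya.mean(),
                "mean_b": yb.mean(),
                "t": t,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    posthoc = pd.DataFrame(rows)
    return {"anova": table, "posthoc": posthoc}


def cohen_kappa(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa of a 2x2 agreement table [[a, b], [c, d]].

    ``a`` and ``d`` are the agreeing cells.  When expected agreement is 1
    (both raters constant), kappa is 1 if observed agreement is also 1,
    else 0.
    """
    total = a + b + c + d
    if total <= 0:
        raise ValueError("empty agreement table")
    po = (a + d) / total
    p_yes_1 = (a + b) / total
    p_yes_2 = (a + c) / total
    pe = p_yes_1 * p_yes_2 + (1 - p_yes_1) * (1 - p_yes_2)
    if pe >= 1.0:
        return 1.0 if po >= 1.0 else 0.0
    return (po - pe) / (1 - pe)


@dataclass
class AgreementResult:
    percent_agreement: float          # 0..100, over all segments
    per_subject_kappa: pd.Series      # kappa per subject
    mean_kappa: float
    n_segments: int


def detector_agreement(
    cov_masks: Mapping[str, np.ndarray],
    bck_masks: Mapping[str, np.ndarray],
    subjects: Mapping[str, str] | None = None,
) -> AgreementResult:
    """Per-segment agreement between the COV and BCK verdicts.

    ``cov_masks``/``bck_masks`` map trace ids to per-segment boolean
    rejection verdicts on the same 0.5 s grid; segments neither detector
    rejects count as agreeing "clean".  ``subjects`` maps trace ids to
    subject ids for the per-subject kappa (defaults to the prefix of the
    trace id before the first underscore).
    """
    ids = sorted(cov_masks)
    if set(ids) != set(bck_masks):
        raise ValueError("COV and BCK masks cover different traces")
    if subjects is None:
        subjects = {tid: tid.split("_", 1)[0] for tid in ids}
    per_subject: dict[str, np.ndarray] = {}
    agree = 0
    total = 0
    tables: dict[str, list[int]] = {}
    for tid in ids:
        cov = np.asarray(cov_masks[tid], bool)
        bck = np.asarray(bck_masks[tid], bool)
        if cov.shape != bck.shape:
            raise ValueError(f"misaligned segment grids for trace {tid!r}")
        agree += int(np.sum(cov == bck))
        total += cov.size
        t = tables.setdefault(subjects[tid], [0, 0, 0, 0])
        t[0] += int(np.sum(cov & bck))      # both reject
        t[1] += int(np.sum(cov & ~bck))
        t[2] += int(np.sum(~cov & bck))
        t[3] += int(np.sum(~cov & ~bck))    # both clean
    if total == 0:
        raise ValueError("no segments to compare")
    kappas = pd.Series(
        {subj: cohen_kappa(t[0], t[1], t[2], t[3]) for subj, t in tables.items()}
    ).sort_index()
    return AgreementResult(
        percent_agreement=100.0 * agree / total,
        per_subject_kappa=kappas,
        mean_kappa=float(kappas.mean()),
        n_segments=total,
    )


def shap_presence(grid: GridResult, top_k: int = 10) -> pd.DataFrame:
    """Percentage of (pipeline, fold) cells in which each feature ranks in
    the top ``top_k`` by mean |Shapley|.

    Counting is kept separate per model kind and per pipeline family
    (hemisphere-normalized vs not, RFE on/off).  Folds with fewer than
    ``top_k`` surviving features contribute all of them and are flagged.
    """
    if not grid.rankings:
        raise ValueError("grid carries no Shapley rankings")
    rows = []
    flagged = 0
    for key, ordered in grid.rankings.items():
        artifact, outlier, pre_norm, kind, use_rfe, fold = key
        top = ordered[:top_k]
        if len(ordered) < top_k:
            flagged += 1
        for feat in top:
            rows.append(
                {
                    "model_kind": kind,
                    "pre_normalized": pre_norm,
                    "use_rfe": use_rfe,
                    "feature": feat,
                }
            )
    if flagged:
        logger.warning(
            "%d fold(s) had fewer than %d surviving features", flagged, top_k
        )
    counts = (
        pd.DataFrame(rows)
        .groupby(["model_kind", "pre_normalized", "use_rfe", "feature"])
        .size()
        .rename("count")
        .reset_index()
    )
    # cells per family = number of (pipeline, fold) observations
    family_cells = {}
    for key in grid.rankings:
        fam = (key[3], key[2], key[4])
        family_cells[fam] = family_cells.get(fam, 0) + 1
    cells = counts.apply(
        lambda r: family_cells[(r["model_kind"], r["pre_normalized"], r["use_rfe"])],
        axis=1,
    )
    counts["percentage"] = 100.0 * counts["count"] / cells
    return counts.sort_values(
        ["model_kind", "pre_normalized", "use_rfe", "percentage"],
        ascending=[True, True, True, False],
    ).reset_index(drop=True)
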