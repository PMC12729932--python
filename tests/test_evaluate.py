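import itertools

import numpy as np
import pandas as pd
import pytest

from mer_pipelines import (
    anova_factors,
    build_variants,
    cohen_kappa,
    detector_agreement,
    run_grid,
    shap_presence,
)
from mer_pipelines.evaluate import GridResult, METRIC_NAMES, PROVENANCE
from mer_pipelines.features import FEATURE_NAMES
from conftest import synthetic_feature_table


def synthetic_grid_metrics(
    rng,
    effect=0.0,
    noise=0.02,
    artifact_levels=("RAW", "EXP", "COV", "BCK"),
    outlier_levels=("NONE", "ORH", "ORM"),
):
    """A balanced fold-level metrics table with an optional additive
    accuracy boost on non-normalized cells."""
    rows = []
    for art, out, norm, kind, rfe, fold in itertools.product(
        artifact_levels, outlier_levels, (False, True), ("SVC", "EN", "RF"),
        (False, True), range(5),
    ):
        acc = 0.8 + rng.normal(0, noise) + (effect if not norm else 0.0)
        rows.append(
            {
                "artifact_method": art,
                "outlier_method": out,
                "pre_normalized": norm,
                "model_kind": kind,
                "use_rfe": rfe,
                "fold": fold,
                "accuracy": acc,
                "precision": acc,
                "recall": acc,
                "f1": acc,
                "auc": acc,
            }
        )
    return pd.DataFrame(rows)


class TestRunGrid:
    def make_variants(self, rng):
        tables = {
            m: synthetic_feature_table(rng, n_patients=2, rows_per_hemisphere=10)
            for m in ("RAW", "EXP", "COV", "BCK")
        }
        return build_variants(tables)

    def test_all_cells_present_with_full_provenance(self, rng):
        variants = self.make_variants(rng)
        grid = run_grid(
            variants,
            seed=0,
            model_kinds=("EN",),
            rfe_options=(False,),
            compute_shap=True,
            shap_max_points=5,
            shap_permutations=2,
        )
        assert grid.n_cells == 24
        assert len(grid.metrics) == 24 * 5
        assert not grid.failures
        vals = grid.metrics[list(METRIC_NAMES)]
        assert ((vals >= 0) & (vals <= 1)).all().all()
        assert len(grid.rankings) == 24 * 5

    def test_rerun_identical(self, rng):
        variants = self.make_variants(rng)[:2]
        kw = dict(
            seed=1, model_kinds=("EN", "SVC"), rfe_options=(False,),
            compute_shap=True, shap_max_points=4, shap_permutations=2,
        )
        a = run_grid(variants, **kw)
        b = run_grid(variants, **kw)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        assert a.rankings == b.rankings

    def test_rfe_cells_carry_reduced_feature_sets(self, rng):
        variants = self.make_variants(rng)[:1]
        grid = run_grid(
            variants, seed=0, model_kinds=("EN",), rfe_options=(True,),
            compute_shap=True, shap_max_points=4, shap_permutations=2,
            rfe_score_step=7,
        )
        assert grid.n_cells == 1
        for key, ranking in grid.rankings.items():
            assert key[4] is True
            assert len(ranking) <= len(FEATURE_NAMES)

    def test_degenerate_variant_recorded_as_failure(self, rng):
        variants = self.make_variants(rng)[:1]
        bad = variants[0].table.copy()
        bad["label"] = "STN"
        from mer_pipelines import DatasetVariant

        broken = DatasetVariant("RAW", "NONE", False, bad)
        grid = run_grid(
            [broken], seed=0, model_kinds=("EN",), rfe_options=(False,),
            compute_shap=False,
        )
        assert grid.failures and grid.metrics.empty

    def test_grid_marginal_consistency(self, rng):
        # balanced grid: per-cell-then-level averaging equals pooled means
        metrics = synthetic_grid_metrics(rng)
        grid = GridResult(metrics=metrics)
        cell = grid.cell_means()
        by_cells = cell.groupby("outlier_method")["accuracy"].mean()
        pooled = metrics.groupby("outlier_method")["accuracy"].mean()
        pd.testing.assert_series_equal(by_cells, pooled)


class TestAnova:
    def test_constant_metric_no_significance(self, rng):
        metrics = synthetic_grid_metrics(rng, noise=0.0)
        metrics["accuracy"] = 0.9
        res = anova_factors(GridResult(metrics=metrics), "OUTLIER")
        pvals = res["anova"]["PR(>F)"].dropna()
        assert not (pvals < 0.05).any()

    def test_planted_normalization_effect_detected(self, rng):
        metrics = synthetic_grid_metrics(rng, effect=0.05)
        res = anova_factors(GridResult(metrics=metrics), "NORMALIZATION")
        p = res["anova"].loc["C(factor_level)", "PR(>F)"]
        assert p < 0.05

    def test_outlier_posthoc_has_three_bonferroni_pairs(self, rng):
        metrics = synthetic_grid_metrics(rng)
        res = anova_factors(GridResult(metrics=metrics), "OUTLIER")
        posthoc = res["posthoc"]
        assert len(posthoc) == 3
        assert set(zip(posthoc.level_a, posthoc.level_b)) == {
            ("NONE", "ORH"), ("NONE", "ORM"), ("ORH", "ORM"),
        }
        assert (posthoc.p_bonferroni >= np.minimum(1.0, posthoc.p_raw * 3) - 1e-12).all()

    def test_missing_level_error(self, rng):
        metrics = synthetic_grid_metrics(rng, artifact_levels=("RAW", "EXP"))
        with pytest.raises(ValueError, match="BCK"):
            anova_factors(GridResult(metrics=metrics), "DATASET")

    def test_unknown_factor_or_metric_rejected(self, rng):
        metrics = synthetic_grid_metrics(rng)
        with pytest.raises(ValueError):
            anova_factors(GridResult(metrics=metrics), "WEATHER")
        with pytest.raises(ValueError):
            anova_factors(GridResult(metrics=metrics), "OUTLIER", metric="brier")


class TestDetectorAgreement:
    def test_identical_masks_perfect_agreement(self):
        masks = {"P0_a": np.array([True, False, True]), "P1_b": np.zeros(4, bool)}
        res = detector_agreement(masks, {k: v.copy() for k, v in masks.items()})
        assert res.percent_agreement == 100.0
        assert res.mean_kappa == 1.0

    def test_closed_form_two_by_two(self):
        # a=40 both-reject, d=40 both-clean, 10+10 disagreements
        assert cohen_kappa(40, 10, 10, 40) == pytest.approx(0.6)
        verdict_a = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        verdict_b = np.r_[np.ones(40, bool), np.zeros(10, bool),
                          np.ones(10, bool), np.zeros(40, bool)]
        res = detector_agreement({"S_x": verdict_a}, {"S_x": verdict_b})
        assert res.percent_agreement == pytest.approx(80.0)
        assert res.mean_kappa == pytest.approx(0.6)

    def test_independent_masks_kappa_near_zero(self, rng):
        a = {"S_x": rng.random(10_000) < 0.5}
        b = {"S_x": rng.random(10_000) < 0.5}
        res = detector_agreement(a, b)
        assert abs(res.mean_kappa) < 0.05

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            detector_agreement(
                {"S_x": np.zeros(3, bool)}, {"S_x": np.zeros(4, bool)}
            )
        with pytest.raises(ValueError, match="different traces"):
            detector_agreement({"S_x": np.zeros(3, bool)}, {"S_y": np.zeros(3, bool)})


def make_rankings_grid(rankings):
    metrics = pd.DataFrame(columns=list(PROVENANCE) + ["fold"] + list(METRIC_NAMES))
    return GridResult(metrics=metrics, rankings=rankings)


class TestShapPresence:
    def test_single_fold_top_ten_at_full_presence(self):
        features = [f"f{i}" for i in range(15)]
        key = ("RAW", "NONE", False, "RF", False, 0)
        out = shap_presence(make_rankings_grid({key: features}))
        assert len(out) == 10
        assert (out["percentage"] == 100.0).all()
        assert set(out["feature"]) == set(features[:10])

    def test_disjoint_top_tens_split_presence(self):
        fold0 = [f"a{i}" for i in range(10)]
        fold1 = [f"b{i}" for i in range(10)]
        rankings = {
            ("RAW", "NONE", False, "RF", False, 0): fold0,
            ("RAW", "NONE", False, "RF", False, 1): fold1,
        }
        out = shap_presence(make_rankings_grid(rankings))
        assert (out["percentage"] == 50.0).all()
        assert len(out) == 20

    def test_short_ranking_counts_all_and_flags(self, caplog):
        key = ("RAW", "NONE", False, "EN", False, 0)
        with caplog.at_level("WARNING"):
            out = shap_presence(make_rankings_grid({key: ["x", "y"]}))
        assert len(out) == 2
        assert "fewer than 10" in caplog.text

    def test_families_counted_separately(self):
        rankings = {
            ("RAW", "NONE", False, "RF", False, 0): [f"f{i}" for i in range(10)],
            ("RAW", "NONE", True, "RF", False, 0): [f"g{i}" for i in range(10)],
        }
        out = shap_presence(make_rankings_grid(rankings))
        norm = out[out.pre_normalized]
        plain = out[~out.pre_normalized]
        assert set(norm.feature) == {f"g{i}" for i in range(10)}
        assert set(plain.feature) == {f"f{i}" for i in range(10)}
        assert (out.percentage == 100.0).all()
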