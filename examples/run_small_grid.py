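"""Run a reduced slice of the pipeline-comparison grid.

Builds the 24 dataset variants from a two-patient cohort, evaluates one
classifier per variant without feature selection, and compares the
hemisphere-normalization factor by three-way ANOVA.  (The full grid —
three classifiers, with and without recursive feature elimination — runs
the same way via run_grid's defaults; see scripts/acceptance.py.)
"""

from mer_pipelines import (
    CohortConfig, anova_factors, iter_cohort, prepare_feature_tables,
    run_grid, shap_presence,
)

cfg = CohortConfig(n_patients=2, fs=8000, trace_duration=10.0, seed=0)
prepared = prepare_feature_tables(iter_cohort(cfg))
grid = run_grid(
    prepared.variants(), seed=0,
    model_kinds=("RF",), rfe_options=(False,),
    shap_max_points=10, shap_permutations=4,
)

cells = grid.cell_means()
print("mean 5-fold accuracy per variant (RF, no feature selection):")
print(
    cells.pivot_table(
        index=["artifact_method", "outlier_method"],
        columns="pre_normalized", values="accuracy",
    ).round(3)
)

agreement = prepared.agreement()
print(f"\nCOV/BCK detector agreement: {agreement.percent_agreement:.1f}% "
      f"(mean per-patient kappa {agreement.mean_kappa:.2f})")

res = anova_factors(grid, "NORMALIZATION", "accuracy")
p = res["anova"].loc["C(factor_level)", "PR(>F)"]
print(f"NORMALIZATION main effect on accuracy: p = {p:.3g}")

presence = shap_presence(grid)
top = presence[~presence.pre_normalized].head(5)
print("\nmost frequently top-ranked features (non-normalized family):")
print(top[["feature", "percentage"]].to_string(index=False))
# Presence = how often a feature lands in a fold's top ten by mean
# absolute Shapley attribution, across pipelines and folds.
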