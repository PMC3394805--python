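"""Double-loop cross-validated error of one classifier on one data view.

Runs the nearest-mean classifier on the expression view with the full
protocol: stratified outer folds for validation, an inner 10-fold loop that
picks the number of top-ranked features, and the class-balance-insensitive
eFPFN error (mean of the false-positive and false-negative rates).
"""

from progfuse import (
    CohortConfig,
    DlcvConfig,
    IntegrationSpec,
    dlcv_run,
    final_feature_count,
    generate_cohort,
    prepare_views,
)

cohort = generate_cohort(CohortConfig(n_samples=300, seed=7))
E, C, meta_C, y = prepare_views(cohort)

spec = IntegrationSpec(classifier="NMC", mode="none_E")
config = DlcvConfig(n_repeats=5, seed=0)
result = dlcv_run(E, C, meta_C, y, spec, config)

print(f"{spec.name}: mean DLCV eFPFN = {result.mean_metric:.3f} "
      f"over {len(result.metric_values)} repeat x fold values")
print(f"mean selected features: {final_feature_count(result)}")
# eFPFN = 1 - (sensitivity + specificity)/2: 0 is perfect, 0.5 is chance.
# The selected feature count is the average of the inner-loop optima.
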