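"""Full detection pipeline on a synthetic two-class study.

Simulates a small study with the default fronto-central theta/beta
effect, runs preprocessing, all four representations, ANOVA feature
selection inside each training fold, and a cubic-kernel SVM under
stratified cross-validation, then prints the pooled results.
"""

from adhdaid import SimConfig, simulate_dataset
from adhdaid.pipeline import PipelineConfig, run_pipeline

records = simulate_dataset(SimConfig(
    n_subjects_per_class=6, duration_s=24.0, effect=0.5, seed=11))
cfg = PipelineConfig(selection_method="anova", selection_k=500,
                     classifiers=("svm_cubic",), cv_folds=6, seed=11)
result = run_pipeline(records, cfg)

rep = result.reports["svm_cubic"]
print(f"config hash: {result.config_hash}")
print(f"segments: {result.features.X.shape[0]}, "
      f"features: {result.features.n_features}")
print(f"pooled confusion counts: TP={rep.pooled.tp} TN={rep.pooled.tn} "
      f"FP={rep.pooled.fp} FN={rep.pooled.fn}")
for name, value in rep.metrics.items():
    print(f"  {name:12s} {value:.3f}")
print(f"  {'auc':12s} {rep.auc:.3f}")
# Accuracy near 1 reflects the strong planted effect (delta = 0.5); with
# effect=0.0 the same pipeline sits at chance — try it.
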