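"""Build a survival nomogram and evaluate it with time-dependent ROC AUC.

Stepwise (backward) multivariable Cox selection picks the independent
predictors among the composite score, predicted ctDNA fraction and the
univariately significant log2 clinical biomarkers. The nomogram maps each
predictor affinely to points (the strongest spans 0-100); total points are
a bijection of the Cox linear predictor, so chart-read survival equals the
model's prediction. AUC uses the IPCW cumulative/dynamic estimator.
"""

from mhlkit.nomogram import predict_survival
from mhlkit.pipeline import PipelineConfig, run_pipeline
from mhlkit.simulate import default_config, generate_cohort

cfg = default_config(seed=3, n_target_regions=30, n_dmr_regions=20,
                     n_pos_control=3, n_neg_control=3)
cohort = generate_cohort(cfg)
result = run_pipeline(PipelineConfig(), cohort=cohort)

spec = result.nomogram
print("selected predictors:", spec.predictors)
print("coefficients:", {p: round(b, 3) for p, b in spec.betas.items()})

patient = {p: sum(spec.ranges[p]) / 2 for p in spec.predictors}
points = spec.total_points(patient)
print(f"\nmid-range patient: total points = {points:.1f}")
for t in (6, 12, 24):
    s = predict_survival(spec, patient, t)
    print(f"  predicted survival at {t:>2} months: {s:.3f}")
# reading the chart and evaluating the Cox model agree to 1e-6 by design

print("\ntime-dependent AUC of the model's linear predictor:")
print(result.auc.to_string(index=False))
# 0.5 would be uninformative ranking; 1.0 perfect separation of patients
# who die by the horizon from those still at risk past it
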