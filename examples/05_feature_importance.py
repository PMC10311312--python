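"""Attribute a trained model's predictions to longitudinal features.

One biomarker is planted as the sole carrier of the disease signal; the
others are pure noise.  Sampling-based Shapley attribution (features
toggled between observed values and training-mean background, all time
steps together) should rank the planted biomarker first, with per-visit
age also informative because elapsed time drives progression.
"""

import numpy as np
import adprog as ap
from adprog.explain import feature_importance, importance_plot_data

loadings = np.zeros(6)
loadings[0] = 1.0  # biomarker_01 carries the signal
cohort = ap.simulate_cohort(ap.SimulationConfig(
    n_patients=300, n_features=6, feature_loadings=loadings,
    visits_per_patient=(7, 10), interval_months=(6, 6),
    baseline_severity_mean=-0.5, drift_rate=0.03, noise_sd=0.3,
    missing_rate=0.0, seed=9))
prep = ap.preprocess_pipeline(cohort, seed=0)
train = ap.build_sequences(prep.train, 3, 1, prep.demo_encoder)
test = ap.build_sequences(prep.test, 3, 1, prep.demo_encoder)

model, _ = ap.train_model(ap.ModelConfig(epochs=40, hidden_dim=16, seed=0),
                          train, "ppad")

for method in ("shapley-sampling", "permutation"):
    report = feature_importance(model, test[:40], method,
                                n_permutations=10, seed=0)
    table = importance_plot_data(report, top_k=3)
    print(f"\n{method} top features:")
    print(table.round(4).to_string(index=False))

# Shapley values are on the probability scale (mean absolute change in the
# predicted conversion probability); permutation importances are mean F2
# drops.  Both should put biomarker_01 at rank 1.
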