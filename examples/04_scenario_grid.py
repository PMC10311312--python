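"""Run a scenario grid: window lengths x horizons with repeated seeds.

Mirrors the standard evaluation design for conversion prediction: one
model per (t, n) cell — next-visit architecture for n = 1, encoder-decoder
for n >= 2 — each retrained over several seeds on a fixed stratified
split, reporting mean F2 and sensitivity per cell.
"""

import adprog as ap
from adprog.train import run_scenarios, summarize_scenarios

cohort = ap.simulate_cohort(ap.SimulationConfig(
    n_patients=800, visits_per_patient=(12, 16), interval_months=(6, 12),
    baseline_severity_mean=-0.25, baseline_severity_sd=0.4,
    drift_rate=0.008, drift_sd=0.012, innovation_sd=0.02,
    conversion_threshold=0.5, prodrome_band=0.2, prodrome_multiplier=8.0,
    post_conversion_dropout=0.7, noise_sd=0.2, missing_rate=0.05, seed=13))
prep = ap.preprocess_pipeline(cohort, seed=0)

results = run_scenarios(
    prep.train, prep.test, prep.demo_encoder,
    t_list=(2, 3), n_list=(1, 2, 3), repeats=3, seed=0,
    config=ap.ModelConfig(epochs=60, hidden_dim=16, learning_rate=0.003))

summary = summarize_scenarios(results)
print(summary[["t", "n", "f2_mean", "f2_sd", "sensitivity_mean",
               "n_train", "test_converters"]].round(3).to_string(index=False))

# Each row aggregates the repeats of one (t, n) cell.  On cohorts with
# realistic attrition and hidden progression-rate heterogeneity, F2 tends
# to rise with the window length t and fall with the horizon n.
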