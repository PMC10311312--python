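"""Run the preprocessing pipeline on a simulated cohort.

Stages run in a fixed order with train-only statistics: drop visits with
more than 40% missing features, drop features missing in more than 60% of
the remaining visits, impute the rest with diagnosis-constrained 5-NN
(neighbours must share the row's MCI/AD label), split 70/30 stratified by
ever-converter status at the patient level, then min-max normalise with
the training partition's minima/maxima.
"""

import adprog as ap

cohort = ap.simulate_cohort(ap.SimulationConfig(
    n_patients=200, missing_rate=0.15, seed=3))
prep = ap.preprocess_pipeline(cohort, k=5, test_fraction=0.30, seed=0)

for stage, counts in prep.log.items():
    print(f"{stage:14s} {counts}")

samples = ap.build_sequences(prep.train, t=3, n=1, demo_encoder=prep.demo_encoder)
x = samples[0]
print(f"\n(t=3, n=1) training samples: {len(samples)}")
print(f"one sample: X {x.X.shape} (3 visits x features+age), "
      f"D length {len(x.D)} (encoded demographics), y={x.y}")

# No missing values survive imputation; test-set features may fall outside
# [0, 1] because the normalisation state is deliberately train-only.
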