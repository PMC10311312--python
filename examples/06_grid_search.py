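"""Hyperparameter selection with stratified 5-fold cross-validated grid search.

The tuned axes follow standard practice for these architectures: recurrent
cell type, epochs, batch size, dropout and L2 — scored by mean CV F2, ties
broken toward the smaller model.
"""

import adprog as ap
from adprog.train import GridSpec, grid_search_cv

cohort = ap.simulate_cohort(ap.SimulationConfig(
    n_patients=300, visits_per_patient=(6, 9), interval_months=(6, 6),
    baseline_severity_mean=-0.3, baseline_severity_sd=0.5, drift_rate=0.03,
    innovation_sd=0.05, conversion_threshold=0.5, noise_sd=0.2,
    missing_rate=0.0, seed=17))
prep = ap.preprocess_pipeline(cohort, seed=0)
samples = ap.build_sequences(prep.train, 2, 1, prep.demo_encoder)

grid = GridSpec(cell=["GRU", "LSTM"], epochs=[20, 60], hidden_dim=[16],
                dropout=[0.0], l2=[0.0])
best, table = grid_search_cv(grid, samples, folds=5, seed=0)

print("cross-validation table (one row per grid point x fold):")
print(table.round(3).to_string(index=False))
print(f"\nselected: cell={best.cell}, epochs={best.epochs} "
      f"(mean CV F2 decides; smaller model wins ties)")
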