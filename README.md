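# adprog

Predicting conversion from mild cognitive impairment (MCI) to Alzheimer's
disease (AD) from irregular longitudinal clinical visits.

## The problem

MCI is the intermediate stage between normal cognition and AD; only some
MCI patients convert, and catching likely converters early matters because
a missed conversion (false negative) is far costlier than a false alarm.
Observational AD cohorts are awkward for sequence models: patients have
anywhere from one to twenty-odd visits, gaps between visits range from 3
to 60 months, many feature values are missing, and patients tend to leave
the study soon after diagnosis.  This package implements a
recurrent-network framework built around those realities, together with a
synthetic cohort simulator so that every stage is testable without
access-restricted clinical data (real cohorts such as ADNI and NACC
require data-use agreements).

## The models

**PPAD** (next-visit prediction).  A recurrent encoder — GRU, LSTM, or a
bidirectional variant — reads the first *t* visits of a patient,
`X ∈ R^{t×F}`, into a latent state `x̂_t`.  For the GRU the per-step
update is

    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)          reset gate
    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)          update gate
    h̃_t = tanh(W_h x_t + U_h (r_t ⊙ h_{t−1}) + b_h)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t

A one-hidden-layer MLP head classifies the latent concatenated with the
encoded cross-sectional demographics `D` (gender, race, ethnicity,
education, APOE-ε4 count):

    y' = σ(W_1 ReLU(W_2 (x̂_t ⊕ D) + b_2) + b_1)

**PPAD-AE** (multiple visits ahead).  The same encoder feeds a recurrent
decoder of the same cell type, initialised with the encoder's final state
and stepped *n* times; the head reads the last generated latent to
predict the diagnosis *n* visits past the window.

**Sensitivity-weighted loss.**  All parameters train jointly with Adam
against

    Loss = −(1/N) Σ [ α·y·log y' + (1−α)·(1−y)·log(1−y') ],  α = 0.7

so missed converters are penalised more than false alarms.  Evaluation
uses sensitivity and the F2 score, `F_β = (1+β²)·p·r / (β²·p + r)` with
β = 2, which weights recall four-fold against precision.

**Irregular time.**  Rather than a time-decay cell, per-visit age rides
along as an ordinary longitudinal feature column: it is the model's only
exact record of elapsed time between visits.

The package also provides the published preprocessing pipeline
(missing-rate filtering at 40%/60%, diagnosis-constrained 5-NN
imputation, stratified 70/30 patient-level splitting, train-only min-max
normalisation), mean-aggregation baselines (random forest, SVM),
grid-search with stratified 5-fold CV, demographic and age ablation
harnesses, and model-agnostic feature attribution (sampling Shapley and
permutation importance).

## Worked example

```python
import adprog as ap

cohort = ap.simulate_cohort(ap.SimulationConfig(
    n_patients=600, visits_per_patient=(7, 12), interval_months=(6, 6),
    baseline_severity_mean=-0.5, baseline_severity_sd=0.5, drift_rate=0.03,
    innovation_sd=0.05, conversion_threshold=0.5, noise_sd=0.2,
    missing_rate=0.05, seed=5))
prep = ap.preprocess_pipeline(cohort, seed=0)

train = ap.build_sequences(prep.train, t=3, n=1, demo_encoder=prep.demo_encoder)
test = ap.build_sequences(prep.test, t=3, n=1, demo_encoder=prep.demo_encoder)
model, trace = ap.train_model(
    ap.ModelConfig(cell="GRU", hidden_dim=16, epochs=40, alpha=0.7, seed=0),
    train, "ppad")
print(ap.evaluate(model, test).f2)
```

Running `python examples/03_train_and_predict.py` (which does the above
for both architectures) prints:

```
ppad     t=3 n=1: loss 0.226 -> 0.079, test F2 0.714, sensitivity 0.680 (17/25 converters caught)
ppad_ae  t=3 n=2: loss 0.328 -> 0.095, test F2 0.882, sensitivity 0.906 (48/53 converters caught)
```

The loss trace shows training converged; F2 and sensitivity are held-out
scores — at (t=3, n=1) the next-visit model catches 17 of 25 true
converters, and the encoder-decoder variant predicting two visits ahead
catches 48 of 53.  The other scripts in `examples/` walk through
simulation, preprocessing, the scenario grid, feature attribution and
grid search, each printing a few annotated numbers.

A thin CLI mirrors the pipeline for shell use:

```bash
adprog simulate --seed 1 --out cohort.csv
adprog preprocess --in cohort.csv --out prep/ --seed 0
adprog scenarios --in cohort.csv --repeats 15 --seed 0 --out results.csv
adprog explain --model model.pkl --data prep/ --method permutation --out imp.csv
```

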