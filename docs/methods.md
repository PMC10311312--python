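# Methods

This note documents the models, the preprocessing pipeline, the synthetic
cohort generator, and the numerical and design choices behind them.

## Task and notation

A cohort holds N patients; patient i contributes an ordered visit
sequence `X_i ∈ R^{T_i × F}` (F longitudinal features per visit, plus age
in years) and a per-visit diagnosis in {CN, MCI, AD}.  The binary outcome
codes MCI as 0 and AD as 1; a *converter* is a patient whose record
reaches AD.  A supervised sample for scenario (t, n) is the first t
visits of a patient as input and the outcome at visit t + n as target;
patients qualify only if they have at least t + n visits, no AD diagnosis
inside the input window, and an MCI/AD diagnosis at the target visit.
Windows containing CN visits are excluded by default (`include_cn`
reverses this).  The first-window policy yields at most one sample per
patient, which keeps evaluation patient-level; a sliding-window mode
exists behind a flag.

## Architectures

Two architectures share an encoder and a classification head:

* **Next-visit model (PPAD)** — a recurrent encoder (GRU by default;
  LSTM, Bi-GRU and Bi-LSTM selectable) summarises the window into its
  final hidden state.  For bidirectional cells the latent is the
  concatenation of each direction's terminal state (the forward state
  after visit t and the backward state after visit 1), so the latent
  width is 2H.  The head is `σ(W1 ReLU(W2 (latent ⊕ D) + b2) + b1)`.
* **Multi-horizon model (PPAD-AE)** — a decoder cell of the same type,
  hidden width equal to the latent width, starts from the encoder latent
  and steps n times on zero input vectors; the head reads the last
  generated latent.  The zero-input design makes the hidden state the
  sole information carrier; an autoregressive mode (previous latent fed
  back as input) exists behind a flag.  For LSTM decoders the memory cell
  starts at zero and only the hidden state is seeded from the encoder.

All parameters (encoder, decoder, head) are trained jointly against one
loss; there is no separate reconstruction objective.  We considered a
reconstruction term for the decoder but rejected it: the decoder's
outputs are latent representations rather than feature vectors, and
supervising them would require both a projection head and future-visit
targets, complicating the sample contract for no demonstrated gain.

Forward and backward passes are hand-written NumPy.  Gradient correctness
is enforced in the test-suite by finite-difference checks on every
architecture variant and by scalar-loop oracles for the recurrences.

## Loss, metrics, optimisation

The loss is a weighted binary cross-entropy with batch-mean reduction and
natural logarithms; the positive (conversion) term carries weight α, the
negative term 1 − α, with α = 0.7 by default.  Predictions are clipped to
(1e-7, 1 − 1e-7) before the logarithm.  At α = 0.5 the loss is exactly
half the standard BCE, a convenient identity used in testing.

Evaluation reports confusion counts at a 0.5 probability threshold
(configurable), sensitivity (= recall), precision, and F2.  F-beta
returns 0 whenever its denominator vanishes.  Note a subtlety: at fixed
p + r, F-beta is maximised at r = β·p, so "recall matters more" holds
only up to that point; the property tests encode the correct local
statement.

Optimisation is Adam (lr 0.001 by default, β1 = 0.9, β2 = 0.999).  L2
regularisation, when enabled, adds `l2 · Σ‖W‖²` over weight matrices
(biases exempt) with gradient `2·l2·W`.  Dropout, when enabled, is
inverted dropout applied to the encoder (or decoder) latent before the
head.  Initialisation is Glorot-uniform from a seeded generator;
training shuffling, dropout masks and all derived seeds come from the
same root seed, making every run bit-reproducible.  LSTM forget-gate
biases start at 1 so early training retains memory.

Hyperparameter selection uses exhaustive grid search over cell type,
epochs, batch size, dropout, L2 (and hidden width), scored by mean F2
over stratified 5-fold CV; folds are stratified by target label, which
under the first-window policy is also a patient-level partition.  Ties
break toward fewer epochs, then smaller hidden width, then grid order.

## Preprocessing pipeline

Order is fixed: filter → impute → split → normalise.

1. **Filtering**: visits with > 40% missing feature values are dropped,
   then features missing in > 60% of the remaining visits; patients left
   with no visits are removed and visit indices re-ranked.
2. **Imputation**: k-nearest-neighbour (k = 5) with candidate neighbours
   restricted to visit records sharing the row's diagnosis.  Distance is
   Euclidean over mutually observed features scaled by
   `sqrt(F / #shared)`; the imputed value is the mean of the k nearest
   records observing the feature.  This is exactly scikit-learn's
   `KNNImputer` with nan-euclidean distance, applied per diagnosis
   group, which is how it is implemented; fallbacks (feature unobserved
   within a class) use the class mean, then the overall mean, and are
   logged.  Imputation precedes splitting by design; the ordering is a
   deliberate mirror of common practice for this pipeline, and the
   normalisation step that follows is strictly train-only.
3. **Splitting**: patient-level 70/30, stratified by ever-converter
   status (the outcome of interest); strata with fewer than two patients
   go to the training side with a warning.
4. **Normalisation**: per-feature min-max from the training partition
   (age included, since age enters the model as a feature column).  Test
   values extrapolate outside [0, 1] unclipped; constant features map
   to 0.

Demographics are encoded once from training data: categoricals one-hot
with sorted category order, education min-max scaled by train range,
APOE-ε4 kept as an allele count.  Unseen categories at transform time
encode as all-zero blocks and are logged.

## Synthetic cohort generator

The generator is a latent-severity threshold model chosen to reproduce
the *structural* irregularities of observational AD cohorts, not the
marginal distributions of any real dataset.

Each patient draws demographics, a baseline severity
`s_0 ~ N(μ_0, σ_0)`, and a visit schedule: a visit count in a configured
range (default 1–21) and inter-visit gaps in months (default uniform
3–60; with `per_patient_tempo` each patient instead has a characteristic
mean gap, individual gaps varying ±30% around it).  Severity evolves per
visit as

    s_j = s_{j−1} + d_i · mult · gap_j + ε_j

where `d_i` is the patient's progression rate (`drift_rate`, optionally
heterogeneous across patients via `drift_sd`, truncated at zero), `mult`
collects risk modifiers — APOE-ε4 carriers progress faster
(`apoe4_drift_multiplier`), optionally a steep age dependence
(`(age/70)^age_drift_exponent`), and an accelerating pre-conversion
phase: within `prodrome_band` below the conversion threshold the rate is
multiplied by `prodrome_multiplier`, mimicking the well-documented
speed-up of cognitive decline shortly before an AD diagnosis.  The
innovation ε is Gaussian, either per-visit or scaled with the square
root of elapsed months (`innovation_per_month`, a diffusion in continuous
time).  Diagnosis becomes AD once severity crosses the threshold and is
absorbing.  With `post_conversion_dropout`, each visit after the first
AD-labelled one is retained only with probability 1 − dropout, mirroring
the attrition of diagnosed patients from observational studies.
Feature f at a visit is `loading_f · s + N(0, noise_sd)`; each value is
masked missing with probability `missing_rate` (missingness is therefore
MCAR — real cohorts are likely not, and no claim about informative
missingness is supported by tests on this generator).  Age accumulates
the sampled gaps from a Gaussian baseline age.

Default parameters (drift 0.006/month, baseline severity −1.5 ± 0.6,
threshold 1.0) were set once so that roughly 40–50% of patients convert
during follow-up, in line with multi-year MCI cohorts; the Monte-Carlo
oracle `converter_fraction_oracle` replays the severity process at 10×
size to anchor that fraction in tests.

### Study conditions used by the tests and the acceptance script

* *Strong-signal cohort* (learnability): 1000 patients, regular 6-month
  visits, noise 0.05, no missingness — conversion timing is essentially
  determined by observable baseline severity, so both architectures
  should score high F2 (≥ 0.9 next-visit, ≥ 0.8 two-ahead, 5 seeds).
* *Trend cohort* (scenario grid): 800 patients, 12–16 visits, 6–12 month
  gaps, hidden progression-rate heterogeneity (drift 0.008 ± 0.012),
  prodrome acceleration ×8 over a 0.2 band, post-diagnosis dropout 0.7,
  feature noise 0.2.  The design rationale: the prodrome makes imminent
  conversion visible (near horizons easy); heterogeneous rates hidden by
  feature noise make far horizons intrinsically uncertain; dropout keeps
  per-scenario prevalence roughly flat in the horizon, so F2 tracks
  difficulty rather than base rate.  Mean F2 then rises with window
  length t and falls with horizon n (Spearman-checked at 10 repeats).
* *Imbalanced cohort* (loss weighting): ~1:4 positives at (t=3, n=1)
  with boundary noise; sensitivity at α = 0.9 must not fall below
  α = 0.5, 15 paired seeds.
* *Age cohort* (age-as-time): per-patient tempos spanning 3–36 month
  gaps plus steeply age-dependent progression; ages are the model's only
  access to elapsed time and chronological age, so removing the age
  column costs F2.  The negative control fixes 12-month gaps and an
  age-independent rate, where the two arms must agree within 0.05 (two
  different input widths cannot match bitwise).
* *Planted-feature cohort* (attribution): one biomarker carries the
  whole signal; aggregated over 10 seeds its mean absolute Shapley value
  must rank first.

These sizes and repeat counts are the package's chosen experiment scale;
they keep the full test-suite around five minutes on one CPU while
leaving comfortable statistical margins (the trend and ablation effects
were designed into the generator mechanism, not tuned post hoc).

## Attribution

Attribution operates per longitudinal feature, toggling all of a
feature's time steps together between observed values and a background
reference (training-set feature means) — clinicians read biomarker-level
importances, and per-time-step attribution remains available through the
raw per-sample matrices.  The sampling estimator walks random feature
permutations and accumulates marginal probability changes; with
`n_permutations=None` it enumerates every permutation, which equals the
exact Shapley value (guarded to F ≤ 8) and is cross-checked in tests
against an independent weighted-subset-sum oracle, including the
efficiency identity (attributions sum to the output gap from background).
Permutation importance reports the mean F2 drop over seeded column
shuffles, floored at zero for report comparability.

## Known limitations

* The generator's missingness is MCAR and its features are linear in a
  single latent severity; passing tests say nothing about model
  performance under informative missingness, multi-factor biology, or
  real ADNI/NACC marginals.
* Min-max normalisation is sensitive to outliers by construction; robust
  scaling is out of scope.
* The decoder carries no explicit notion of future inter-visit gaps; at
  inference the horizon is counted in visits, not months — exactly as in
  the evaluation design, but worth remembering when interpreting
  "n visits ahead".
* Training is plain NumPy on CPU: adequate for cohort-scale data
  (thousands of patients, tens of visits), not for very large EHR
  corpora.
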