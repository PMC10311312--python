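"""Training loop, evaluation metrics, grid-search CV, scenario runner,
mean-aggregation baselines and ablation harnesses.

The evaluation regime mirrors longitudinal conversion-prediction practice:
models are trained on the first ``t`` visits of each training patient and
scored on held-out patients with the F2 score (recall weighted four-fold
against precision in the denominator) and sensitivity, since missing a
true converter is costlier than a false alarm.  Scenario grids cover
window lengths t in {2, 3, 5, 6} and horizons n in {1, 2, 3, 4}: the
next-visit model handles n = 1 and the encoder-decoder model n >= 2, with
the whole procedure repeated over seeds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import Cohort
from .errors import ConfigError, DegenerateDataError
from .networks import (Adam, ModelConfig, add_l2_gradients, init_model,
                       weighted_bce, weighted_bce_logit_grad)
from .preprocess import (DemographicsEncoder, FilterThresholds,
                         SequenceSample, build_sequences, preprocess_pipeline,
                         stack_samples)

logger = logging.getLogger("adprog")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def f_beta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F-beta score; recall counts beta times more than precision.

    Returns 0 when the denominator vanishes (e.g. recall = precision = 0).
    """
    denom = beta ** 2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta ** 2) * precision * recall / denom


@dataclass
class EvaluationResult:
    """Confusion counts and derived scores for one scenario/repeat."""

    tp: int
    fp: int
    tn: int
    fn: int
    scenario: tuple[int, int] = (0, 0)  # (t, n)
    repeat: int = 0
    seed: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    #: sensitivity is the clinical name for recall
    sensitivity = recall

    @property
    def f2(self) -> float:
        return f_beta(self.precision, self.recall, beta=2.0)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "precision": self.precision, "sensitivity": self.recall,
                "f2": self.f2, "t": self.scenario[0], "n": self.scenario[1],
                "repeat": self.repeat, "seed": self.seed}


def confusion_from_predictions(y_true: np.ndarray,
                               y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def evaluate(model, samples: list[SequenceSample],
             threshold: float = 0.5) -> EvaluationResult:
    """Score a trained model on held-out samples at a probability cut-off."""
    if not samples:
        raise DegenerateDataError("empty evaluation set")
    X, D, y = stack_samples(samples)
    pred = (model.predict_proba(X, D) >= threshold).astype(int)
    tp, fp, tn, fn = confusion_from_predictions(y, pred)
    return EvaluationResult(tp, fp, tn, fn,
                            scenario=(samples[0].t, samples[0].n))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(config: ModelConfig, samples: list[SequenceSample],
                architecture: str = "ppad", model=None):
    """Fit a model with Adam against the sensitivity-weighted loss.

    Returns ``(model, loss_trace)`` where the trace holds the mean training
    loss per epoch (including any L2 penalty).  Fully reproducible given
    ``config.seed``.
    """
    if not samples:
        raise DegenerateDataError("no training samples")
    X, D, y = stack_samples(samples)
    if len(np.unique(y)) < 2:
        logger.warning("training set has a single class; learning will be "
                       "degenerate")

    if model is None:
        model = init_model(config, input_dim=X.shape[2], demo_dim=D.shape[1],
                           architecture=architecture)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))

    trace = []
    n = len(samples)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            prob, cache = model.forward(X[idx], D[idx], train=True, rng=rng)
            loss = weighted_bce(y[idx], prob, config.alpha)
            dlogit = weighted_bce_logit_grad(y[idx], prob, config.alpha)
            grads = model.backward(cache, dlogit)
            loss += add_l2_gradients(model, grads, config.l2)
            opt.step(model.params, grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


# ---------------------------------------------------------------------------
# grid search with stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Candidate hyperparameter values; every axis must be non-empty."""

    cell: list[str] = field(default_factory=lambda: ["GRU"])
    epochs: list[int] = field(default_factory=lambda: [30])
    batch_size: list[int] = field(default_factory=lambda: [32])
    dropout: list[float] = field(default_factory=lambda: [0.0])
    l2: list[float] = field(default_factory=lambda: [0.0])
    hidden_dim: list[int] = field(default_factory=lambda: [32])

    def axes(self) -> dict[str, list]:
        d = {"cell": self.cell, "epochs": self.epochs,
             "batch_size": self.batch_size, "dropout": self.dropout,
             "l2": self.l2, "hidden_dim": self.hidden_dim}
        for name, vals in d.items():
            if not vals:
                raise ConfigError(f"grid axis {name!r} is empty")
        return d


def grid_search_cv(grid: GridSpec, samples: list[SequenceSample],
                   base_config: ModelConfig | None = None,
                   architecture: str = "ppad", folds: int = 5,
                   seed: int = 0) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive grid search scored by mean F2 over stratified K-fold CV.

    Folds are stratified by the target label; with the first-window policy
    each patient contributes one sample, so sample-level folding is
    patient-level folding (no patient straddles folds).  Ties are broken
    toward the smaller model: fewer epochs, then smaller hidden width, then
    grid order.
    """
    base = base_config or ModelConfig()
    axes = grid.axes()
    _, _, y = stack_samples(samples)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise DegenerateDataError(
            f"need >= {folds} samples of each class for {folds}-fold CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sample_arr = np.array(samples, dtype=object)
    rows = []
    scored: list[tuple[float, int, int, int, ModelConfig]] = []
    for gi, values in enumerate(itertools.product(*axes.values())):
        point = dict(zip(axes.keys(), values))
        cfg = replace(base, **point, seed=seed)
        fold_scores = []
        for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
            model, _ = train_model(cfg, list(sample_arr[tr]), architecture)
            res = evaluate(model, list(sample_arr[va]), cfg.threshold)
            fold_scores.append(res.f2)
            rows.append({**point, "fold": fold, "f2": res.f2,
                         "sensitivity": res.recall})
        mean_f2 = float(np.mean(fold_scores))
        scored.append((mean_f2, -cfg.epochs, -cfg.hidden_dim, -gi, cfg))
        logger.info("grid point %s -> mean F2 %.3f", point, mean_f2)

    best = max(scored, key=lambda s: s[:4])[4]
    return best, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def _scenario_seeds(master_seed: int, t: int, n: int, repeat: int,
                    arm: int = 0) -> int:
    """Stable per-(scenario, repeat, arm) seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, t, n, repeat, arm])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_scenarios(train: Cohort, test: Cohort,
                  demo_encoder: DemographicsEncoder | None = None,
                  t_list=(2, 3, 5, 6), n_list=(1, 2, 3, 4),
                  repeats: int = 15, seed: int = 0,
                  config: ModelConfig | None = None,
                  include_age: bool = True, include_cn: bool = False
                  ) -> pd.DataFrame:
    """Train and score every (t, n) scenario over repeated seeds.

    The next-visit architecture is used for n = 1, the encoder-decoder for
    n >= 2.  Repeats reinitialise parameters and batch order with distinct
    derived seeds while reusing the same train/test partition.  Returns a
    tidy frame: one row per (t, n, repeat) with confusion counts, F2,
    sensitivity and cohort bookkeeping.  Scenarios with no eligible
    samples, or with a single-class training set, are skipped with a log
    entry.
    """
    base = config or ModelConfig()
    rows = []
    for t in t_list:
        for n in n_list:
            tr_samples = build_sequences(train, t, n, demo_encoder,
                                         include_cn, include_age)
            te_samples = build_sequences(test, t, n, demo_encoder,
                                         include_cn, include_age)
            if not tr_samples or not te_samples:
                logger.info("scenario (t=%d, n=%d): no eligible samples; "
                            "skipped", t, n)
                continue
            y_tr = np.array([s.y for s in tr_samples])
            y_te = np.array([s.y for s in te_samples])
            if len(np.unique(y_tr)) < 2:
                logger.info("scenario (t=%d, n=%d): single-class training "
                            "set; skipped", t, n)
                continue
            arch = "ppad" if n == 1 else "ppad_ae"
            for rep in range(repeats):
                s = _scenario_seeds(seed, t, n, rep)
                cfg = replace(base, seed=s, horizon=n)
                model, _ = train_model(cfg, tr_samples, arch)
                res = evaluate(model, te_samples, cfg.threshold)
                rows.append({
                    "t": t, "n": n, "repeat": rep, "architecture": arch,
                    "seed": s, "tp": res.tp, "fp": res.fp, "tn": res.tn,
                    "fn": res.fn, "precision": round(res.precision, 10),
                    "sensitivity": round(res.recall, 10),
                    "f2": round(res.f2, 10),
                    "n_train": len(tr_samples), "n_test": len(te_samples),
                    "train_converters": int(y_tr.sum()),
                    "test_converters": int(y_te.sum()),
                })
    return pd.DataFrame(rows)


def summarize_scenarios(results: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario mean and standard deviation of F2 and sensitivity."""
    return results.groupby(["t", "n"]).agg(
        f2_mean=("f2", "mean"), f2_sd=("f2", "std"),
        sensitivity_mean=("sensitivity", "mean"),
        sensitivity_sd=("sensitivity", "std"),
        n_train=("n_train", "first"), n_test=("n_test", "first"),
        train_converters=("train_converters", "first"),
        test_converters=("test_converters", "first"),
    ).reset_index()


# ---------------------------------------------------------------------------
# mean-aggregation baselines
# ---------------------------------------------------------------------------

def baseline_mean_aggregate(samples: list[SequenceSample]) -> pd.DataFrame:
    """Flatten each input window to its per-feature mean over the t visits.

    Demographics are not included: the flat table has exactly one column
    per longitudinal feature (age included, since it enters the windows as
    a feature column).
    """
    if not samples:
        raise DegenerateDataError("no samples to aggregate")
    X, _, y = stack_samples(samples)
    table = pd.DataFrame(X.mean(axis=1), columns=samples[0].feature_names)
    table["_y"] = y.astype(int)
    return table


def run_baselines(train_samples: list[SequenceSample],
                  test_samples: list[SequenceSample],
                  alpha: float = 0.7, seed: int = 0
                  ) -> dict[str, EvaluationResult]:
    """Random-forest and RBF-SVM references on mean-aggregated windows.

    Class weights follow the spirit of the weighted loss: the positive
    class gets weight ``alpha``, the negative ``1 - alpha``.
    """
    tr = baseline_mean_aggregate(train_samples)
    te = baseline_mean_aggregate(test_samples)
    Xtr, ytr = tr.drop(columns="_y").to_numpy(), tr["_y"].to_numpy()
    Xte, yte = te.drop(columns="_y").to_numpy(), te["_y"].to_numpy()
    weights = {0: 1.0 - alpha, 1: alpha}

    out = {}
    models = {
        "random_forest": RandomForestClassifier(
            n_estimators=100, class_weight=weights, random_state=seed),
        "svm": SVC(kernel="rbf", class_weight=weights, random_state=seed),
    }
    for name, clf in models.items():
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        tp, fp, tn, fn = confusion_from_predictions(yte, pred)
        out[name] = EvaluationResult(
            tp, fp, tn, fn,
            scenario=(train_samples[0].t, train_samples[0].n))
    return out


# ---------------------------------------------------------------------------
# ablation harnesses
# ---------------------------------------------------------------------------

def ablation_demographics(train: Cohort, test: Cohort,
                          demo_encoder: DemographicsEncoder,
                          t_list=(2, 3), n_list=(1, 2), repeats: int = 5,
                          seed: int = 0,
                          config: ModelConfig | None = None) -> pd.DataFrame:
    """Run every scenario with and without the demographic vector.

    Both arms share the same longitudinal inputs and derived seeds per
    (scenario, repeat), so rows pair exactly; the returned frame has two
    rows per (t, n, repeat) distinguished by the ``arm`` column.
    """
    with_d = run_scenarios(train, test, demo_encoder, t_list, n_list,
                           repeats, seed, config)
    without = run_scenarios(train, test, None, t_list, n_list,
                            repeats, seed, config)
    with_d["arm"] = "with_demographics"
    without["arm"] = "without_demographics"
    return pd.concat([with_d, without], ignore_index=True)


def age_ablation(train: Cohort, test: Cohort,
                 demo_encoder: DemographicsEncoder | None = None,
                 t_list=(3,), n_list=(1,), repeats: int = 15, seed: int = 0,
                 config: ModelConfig | None = None) -> pd.DataFrame:
    """Run scenarios with and without the per-visit age column.

    Age is the model's only handle on irregular elapsed time between
    visits; dropping it reduces the input width by one column.  Arms are
    paired by derived seed.
    """
    with_age = run_scenarios(train, test, demo_encoder, t_list, n_list,
                             repeats, seed, config, include_age=True)
    without = run_scenarios(train, test, demo_encoder, t_list, n_list,
                            repeats, seed, config, include_age=False)
    with_age["arm"] = "with_age"
    without["arm"] = "without_age"
    return pd.concat([with_age, without], ignore_index=True)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def scenarios_from_cohort(cohort: Cohort, t_list=(2, 3, 5, 6),
                          n_list=(1, 2, 3, 4), repeats: int = 15,
                          seed: int = 0, config: ModelConfig | None = None,
                          thresholds: FilterThresholds | None = None,
                          k: int = 5, test_fraction: float = 0.30,
                          include_demographics: bool = True) -> pd.DataFrame:
    """Full pipeline: preprocess a raw cohort once (filter, impute, split,
    normalise — split seeded by the master seed) and run all scenarios."""
    prep = preprocess_pipeline(cohort, thresholds, k, test_fraction, seed)
    encoder = prep.demo_encoder if include_demographics else None
    return run_scenarios(prep.train, prep.test, encoder, t_list, n_list,
                         repeats, seed, config)
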