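"""Per-feature importance for trained conversion models.

Two model-agnostic attribution methods are provided, both operating at the
granularity of one longitudinal feature (all of its time steps toggled
together, matching how clinicians read per-biomarker importances):

* ``shapley-sampling`` — Monte-Carlo Shapley value estimation.  The value
  of a feature coalition is the model probability when coalition features
  keep their observed values and the rest are replaced by a background
  reference (training-set feature means).  Marginal contributions are
  averaged over random feature permutations; with ``n_permutations=None``
  every permutation is enumerated, which equals the exact Shapley value.
  The report holds the mean absolute attribution over evaluation samples.

* ``permutation`` — classic permutation importance: a feature's columns are
  shuffled across samples and the importance is the resulting drop in F2.

Both are deterministic given a seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError
from .preprocess import SequenceSample, stack_samples
from .train import confusion_from_predictions, f_beta

METHODS = ("shapley-sampling", "permutation")


@dataclass
class ImportanceReport:
    """Mean absolute attribution per longitudinal feature."""

    feature_names: list[str]
    values: np.ndarray  # >= 0, one per feature
    method: str
    scenario: tuple[int, int] = (0, 0)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.feature_names,
                         name=self.method)


def _masked_probability(model, X, D, background, mask):
    """Model output with only the masked-in features at observed values."""
    Xm = np.where(mask[None, None, :], X, background[None, None, :])
    return model.predict_proba(Xm, D)


def shapley_attributions(model, samples: list[SequenceSample],
                         background: np.ndarray | None = None,
                         n_permutations: int | None = 20,
                         seed: int = 0) -> np.ndarray:
    """Per-sample, per-feature Shapley estimates; shape (B, F).

    ``n_permutations=None`` enumerates all F! permutations (exact Shapley;
    guarded to small F).
    """
    X, D, _ = stack_samples(samples)
    B, T, F = X.shape
    if background is None:
        background = X.mean(axis=(0, 1))
    background = np.asarray(background, dtype=float)

    if n_permutations is None:
        if F > 8:
            raise ConfigError("exhaustive enumeration limited to F <= 8")
        perms = list(itertools.permutations(range(F)))
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(F) for _ in range(n_permutations)]

    phi = np.zeros((B, F))
    for perm in perms:
        mask = np.zeros(F, dtype=bool)
        prev = _masked_probability(model, X, D, background, mask)
        for f in perm:
            mask[f] = True
            cur = _masked_probability(model, X, D, background, mask)
            phi[:, f] += cur - prev
            prev = cur
    return phi / len(perms)


def exact_shapley_oracle(value_fn, n_features: int) -> np.ndarray:
    """Independent exact Shapley computation by subset enumeration.

    ``value_fn(frozenset)`` maps a coalition to a scalar value.  Used as
    the cross-check for the permutation-sampling estimator; intentionally
    a different algorithm (weighted subset sums, not permutation walks).
    """
    n = n_features
    phi = np.zeros(n)
    others = list(range(n))
    for f in range(n):
        rest = [o for o in others if o != f]
        for size in range(n):
            weight = (math.factorial(size) * math.factorial(n - size - 1)
                      / math.factorial(n))
            for subset in itertools.combinations(rest, size):
                s = frozenset(subset)
                phi[f] += weight * (value_fn(s | {f}) - value_fn(s))
    return phi


def permutation_importance(model, samples: list[SequenceSample],
                           threshold: float = 0.5, n_repeats: int = 10,
                           seed: int = 0) -> np.ndarray:
    """Mean F2 drop when one feature's columns are permuted across samples."""
    X, D, y = stack_samples(samples)
    B, T, F = X.shape
    rng = np.random.default_rng(seed)

    def f2_of(Xe):
        pred = (model.predict_proba(Xe, D) >= threshold).astype(int)
        tp, fp, tn, fn = confusion_from_predictions(y, pred)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        return f_beta(p, r, 2.0)

    base = f2_of(X)
    drops = np.zeros(F)
    for f in range(F):
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, :, f] = X[rng.permutation(B), :, f]
            vals.append(base - f2_of(Xp))
        drops[f] = np.mean(vals)
    return drops


def feature_importance(model, samples: list[SequenceSample],
                       method: str = "shapley-sampling",
                       background: np.ndarray | None = None,
                       n_permutations: int | None = 20,
                       n_repeats: int = 10, threshold: float = 0.5,
                       seed: int = 0) -> ImportanceReport:
    """Aggregate per-feature importance for a trained model.

    For ``shapley-sampling`` the report holds mean absolute Shapley values
    over the evaluation samples; for ``permutation`` the mean F2 drop,
    floored at zero so values remain comparable magnitudes.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")
    if not samples:
        raise DegenerateDataError("no samples for importance estimation")

    if method == "shapley-sampling":
        phi = shapley_attributions(model, samples, background,
                                   n_permutations, seed)
        values = np.abs(phi).mean(axis=0)
    else:
        values = np.maximum(
            permutation_importance(model, samples, threshold, n_repeats,
                                   seed), 0.0)
    return ImportanceReport(list(samples[0].feature_names), values, method,
                            scenario=(samples[0].t, samples[0].n))


def importance_plot_data(report: ImportanceReport,
                         top_k: int | None = None) -> pd.DataFrame:
    """Features ranked by descending importance; ties keep input order."""
    order = np.argsort(-report.values, kind="stable")
    df = pd.DataFrame({
        "feature": [report.feature_names[i] for i in order],
        "importance": report.values[order],
        "rank": np.arange(1, len(order) + 1),
    })
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)
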