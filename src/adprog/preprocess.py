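"""Preprocessing pipeline for longitudinal visit tables.

Stages, applied in this order (train statistics only, no test leakage):

1. :func:`filter_missingness` — drop visits then features with high missing
   rates (defaults 40% / 60%).
2. :func:`impute_knn` — k-nearest-neighbour imputation (k=5) where candidate
   neighbours are restricted to visit records with the same diagnosis;
   distance is Euclidean over mutually observed features, scaled by
   sqrt(F / #shared).
3. :func:`split_stratified` — patient-level 70/30 split stratified by
   ever-converter status.
4. :func:`fit_minmax` / :func:`apply_minmax` — per-feature min-max
   normalization fitted on the training partition only.
5. :func:`build_sequences` — fixed-length input windows (first t visits) with
   a binary conversion target n visits ahead; age rides along as a
   longitudinal feature column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.model_selection import train_test_split

from .cohort import Cohort, Demographics
from .errors import ConfigError, DegenerateDataError, SchemaError

logger = logging.getLogger("adprog")


@dataclass
class FilterThresholds:
    """Missing-rate cutoffs: a visit (row) is dropped when more than
    ``visit_missing_max`` of its feature values are missing; then a feature
    (column) is dropped when missing in more than ``feature_missing_max`` of
    the remaining visits."""

    visit_missing_max: float = 0.40
    feature_missing_max: float = 0.60

    def validate(self) -> None:
        for v in (self.visit_missing_max, self.feature_missing_max):
            if not 0.0 < v <= 1.0:
                raise ConfigError("filter thresholds must lie in (0, 1]")


def filter_missingness(cohort: Cohort,
                       thresholds: FilterThresholds | None = None) -> Cohort:
    """Drop high-missingness visits, then high-missingness features.

    Patients left without any visit are removed entirely.  Raises
    :class:`DegenerateDataError` if no feature survives.
    """
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    feats = cohort.feature_names

    visit_frac = cohort.visits[feats].isna().mean(axis=1)
    visits = cohort.visits[visit_frac <= thresholds.visit_missing_max].copy()

    feat_frac = visits[feats].isna().mean(axis=0) if len(visits) else \
        pd.Series(1.0, index=feats)
    kept = [f for f in feats if feat_frac[f] <= thresholds.feature_missing_max]
    if not kept:
        raise DegenerateDataError("all features exceed the missing-rate cutoff")
    dropped = [f for f in feats if f not in kept]
    if dropped:
        logger.info("filter_missingness dropped features: %s", dropped)

    visits = visits[["patient_id", "visit_index", "visit_month", "age",
                     "diagnosis"] + kept]
    # re-rank visit_index so windows stay contiguous after row drops
    visits = visits.sort_values(["patient_id", "visit_index"], kind="stable")
    visits["visit_index"] = visits.groupby("patient_id").cumcount() + 1

    remaining = visits["patient_id"].unique()
    demo = cohort.demographics.loc[[p for p in cohort.patient_ids
                                    if p in set(remaining)]]
    return Cohort(visits.reset_index(drop=True), demo, kept)


def impute_knn(cohort: Cohort, k: int = 5) -> Cohort:
    """Diagnosis-constrained k-NN imputation of missing feature values.

    For each missing cell, neighbours are sought only among visit records
    sharing the row's diagnosis; the imputed value is the mean of the k
    nearest neighbours that observe that feature (distance: Euclidean over
    mutually observed features, scaled by sqrt(F / #shared) — sklearn's
    nan-euclidean metric).  When no same-diagnosis record observes the
    feature, the same-diagnosis feature mean is used; if the diagnosis group
    observes nothing at all for that feature, the overall feature mean is
    the last resort (both fallbacks logged).  Observed values are never
    modified.
    """
    feats = cohort.feature_names
    visits = cohort.visits.copy()

    for diag, idx in visits.groupby("diagnosis").groups.items():
        block = visits.loc[idx, feats]
        if not block.isna().any().any():
            continue
        n_eff = min(k, max(len(block) - 1, 1))
        if n_eff < k:
            logger.info("impute_knn: diagnosis %s has only %d records; "
                        "using k=%d", diag, len(block), n_eff)
        imputer = KNNImputer(n_neighbors=n_eff, weights="uniform",
                             keep_empty_features=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-nan column warnings
            filled = imputer.fit_transform(block.to_numpy(dtype=float))
        visits.loc[idx, feats] = filled

    # last-resort fallback: feature entirely unobserved within a diagnosis
    still = visits[feats].isna()
    if still.any().any():
        for f in feats:
            if still[f].any():
                overall = visits[f].mean()
                logger.warning("impute_knn: feature %s unobserved in some "
                               "diagnosis group; overall mean fallback", f)
                visits[f] = visits[f].fillna(overall)

    # age is time, not a biomarker: interpolate within patient if ever missing
    if visits["age"].isna().any():
        visits["age"] = visits.groupby("patient_id")["age"].transform(
            lambda s: s.interpolate(limit_direction="both"))

    return Cohort(visits, cohort.demographics.copy(), feats)


def split_stratified(cohort: Cohort, test_fraction: float = 0.30,
                     seed: int = 0) -> tuple[Cohort, Cohort]:
    """Patient-level train/test split stratified by ever-converter status.

    A stratum with fewer than 2 patients cannot be split; its patients go to
    the training partition with a warning.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError("test_fraction must lie in (0, 1)")
    pids = cohort.patient_ids
    strata = np.array([int(cohort.is_converter(p)) for p in pids])

    counts = pd.Series(strata).value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        logger.warning("split_stratified: strata %s have < 2 patients; "
                       "assigned to train", small)
        forced = [p for p, s in zip(pids, strata) if s in small]
        rest = [(p, s) for p, s in zip(pids, strata) if s not in small]
        pids = [p for p, _ in rest]
        strata = np.array([s for _, s in rest])
    else:
        forced = []

    train_ids, test_ids = train_test_split(
        pids, test_size=test_fraction, stratify=strata, random_state=seed)
    return cohort.subset(sorted(train_ids) + sorted(forced)), \
        cohort.subset(sorted(test_ids))


@dataclass
class NormalizationState:
    """Per-feature train minimum/maximum for min-max scaling.

    Fitted on the training partition only; applying it to a test cohort may
    produce values outside [0, 1] (deliberately unclipped).  A constant
    feature maps to 0 everywhere.
    """

    minima: dict[str, float]
    maxima: dict[str, float]

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        if name not in self.minima:
            raise SchemaError(f"feature {name!r} missing from normalization state")
        lo, hi = self.minima[name], self.maxima[name]
        if hi == lo:
            return np.zeros_like(values, dtype=float)
        return (values - lo) / (hi - lo)


def fit_minmax(train: Cohort, include_age: bool = True) -> NormalizationState:
    """Capture per-feature min/max over all training visits (age included by
    default, since age enters the model as a longitudinal feature)."""
    cols = train.feature_names + (["age"] if include_age else [])
    minima = {c: float(train.visits[c].min()) for c in cols}
    maxima = {c: float(train.visits[c].max()) for c in cols}
    return NormalizationState(minima, maxima)


def apply_minmax(cohort: Cohort, state: NormalizationState) -> Cohort:
    """Scale a cohort's feature (and age) columns with a fitted state."""
    visits = cohort.visits.copy()
    for c in cohort.feature_names + (["age"] if "age" in state.minima else []):
        visits[c] = state.transform_column(c, visits[c].to_numpy(dtype=float))
    return Cohort(visits, cohort.demographics.copy(), cohort.feature_names)


class DemographicsEncoder:
    """One-hot encodes the categorical demographics with category orders
    captured from the training cohort; education is min-max scaled from
    train statistics; the APOE-e4 allele count passes through as a number.
    Unseen categories at transform time encode as all-zeros (logged)."""

    CATEGORICAL = ("gender", "race", "ethnicity")

    def __init__(self):
        self.categories_: dict[str, list[str]] = {}
        self.education_range_: tuple[float, float] = (0.0, 1.0)
        self.fitted = False

    def fit(self, cohort: Cohort) -> "DemographicsEncoder":
        demo = cohort.demographics
        self.categories_ = {
            c: sorted(demo[c].astype(str).unique()) for c in self.CATEGORICAL
        }
        lo, hi = float(demo["education"].min()), float(demo["education"].max())
        self.education_range_ = (lo, hi)
        self.fitted = True
        return self

    @property
    def dim(self) -> int:
        return sum(len(v) for v in self.categories_.values()) + 2

    def encode(self, demographics: Demographics) -> np.ndarray:
        if not self.fitted:
            raise ConfigError("DemographicsEncoder used before fit()")
        parts = []
        for c in self.CATEGORICAL:
            cats = self.categories_[c]
            value = str(getattr(demographics, c))
            onehot = np.zeros(len(cats))
            if value in cats:
                onehot[cats.index(value)] = 1.0
            else:
                logger.info("unseen %s category %r -> zero vector", c, value)
            parts.append(onehot)
        lo, hi = self.education_range_
        edu = 0.0 if hi == lo else (demographics.education - lo) / (hi - lo)
        parts.append(np.array([edu, float(demographics.apoe4)]))
        return np.concatenate(parts)

    def encode_all(self, cohort: Cohort) -> dict[str, np.ndarray]:
        return {p: self.encode(cohort.get_demographics(p))
                for p in cohort.patient_ids}


@dataclass
class SequenceSample:
    """One model input/target pair: the first ``t`` visits of a patient
    (matrix ``X``, visits x features, fully observed and normalized), the
    encoded demographic vector ``D``, and the binary diagnosis ``y`` at the
    visit ``n`` steps past the window (0 = MCI, 1 = AD)."""

    patient_id: str
    X: np.ndarray  # (t, n_inputs)
    D: np.ndarray  # (demo_dim,) — may be length 0 in ablation mode
    y: int
    t: int
    n: int
    feature_names: list[str] = field(default_factory=list)


def build_sequences(cohort: Cohort, t: int, n: int,
                    demo_encoder: DemographicsEncoder | None = None,
                    include_cn: bool = False, include_age: bool = True,
                    policy: str = "first") -> list[SequenceSample]:
    """Construct supervised samples for the (t visits -> n ahead) scenario.

    A patient is eligible when they have at least ``t + n`` visits, no visit
    inside the input window is already AD, and the target visit's diagnosis
    is MCI or AD.  Windows containing CN visits are excluded unless
    ``include_cn`` is set.  The default policy takes the first ``t`` visits
    (one sample per patient); ``policy="sliding"`` emits every valid start
    offset.
    """
    if t < 1 or n < 1:
        raise ConfigError("window length t and horizon n must be >= 1")
    if policy not in ("first", "sliding"):
        raise ConfigError(f"unknown window policy {policy!r}")

    cols = cohort.feature_names + (["age"] if include_age else [])
    samples: list[SequenceSample] = []
    for pid, sub in cohort.iter_patients():
        diags = sub["diagnosis"].to_numpy()
        Xfull = sub[cols].to_numpy(dtype=float)
        starts = range(0, len(sub) - (t + n) + 1) if policy == "sliding" \
            else range(0, 1)
        for s in starts:
            if s + t + n > len(sub):
                continue
            window = diags[s:s + t]
            target = diags[s + t + n - 1]
            if (window == "AD").any():
                continue
            if not include_cn and (window == "CN").any():
                continue
            if target not in ("MCI", "AD"):
                continue
            D = demo_encoder.encode(cohort.get_demographics(pid)) \
                if demo_encoder is not None else np.zeros(0)
            samples.append(SequenceSample(
                patient_id=pid, X=Xfull[s:s + t].copy(), D=D,
                y=int(target == "AD"), t=t, n=n, feature_names=cols))
    return samples


def stack_samples(samples: list[SequenceSample]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a homogeneous sample list into (X [B,t,F], D [B,d], y [B])."""
    if not samples:
        raise DegenerateDataError("no samples to stack")
    X = np.stack([s.X for s in samples])
    D = np.stack([s.D for s in samples])
    y = np.array([s.y for s in samples], dtype=float)
    return X, D, y


@dataclass
class PreprocessResult:
    train: Cohort
    test: Cohort
    norm_state: NormalizationState
    demo_encoder: DemographicsEncoder
    log: dict


def preprocess_pipeline(cohort: Cohort,
                        thresholds: FilterThresholds | None = None,
                        k: int = 5, test_fraction: float = 0.30,
                        seed: int = 0) -> PreprocessResult:
    """Run filter -> impute -> split -> normalize and record stage counts."""
    log = {"input": {"patients": cohort.n_patients, "visits": cohort.n_visits,
                     "features": len(cohort.feature_names)}}
    filtered = filter_missingness(cohort, thresholds)
    log["after_filter"] = {"patients": filtered.n_patients,
                           "visits": filtered.n_visits,
                           "features": len(filtered.feature_names)}
    imputed = impute_knn(filtered, k=k)
    train, test = split_stratified(imputed, test_fraction, seed)
    log["split"] = {"train_patients": train.n_patients,
                    "test_patients": test.n_patients}
    state = fit_minmax(train)
    train_n = apply_minmax(train, state)
    test_n = apply_minmax(test, state)
    encoder = DemographicsEncoder().fit(train_n)
    return PreprocessResult(train_n, test_n, state, encoder, log)
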