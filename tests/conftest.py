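"""Shared fixtures: scripted toy cohorts and study-condition presets."""

import numpy as np
import pandas as pd
import pytest

from adprog.cohort import Cohort
from adprog.simulate import SimulationConfig


def make_toy_cohort(rows, feature_names, demo=None):
    """Build a cohort from literal row tuples:
    (patient_id, visit_month, age, diagnosis, *features)."""
    records = []
    for pid, month, age, diag, *feats in rows:
        records.append({"patient_id": pid, "visit_month": float(month),
                        "age": float(age), "diagnosis": diag,
                        **dict(zip(feature_names, feats))})
    visits = pd.DataFrame(records)
    visits = visits.sort_values(["patient_id", "visit_month"],
                                kind="stable").reset_index(drop=True)
    visits["visit_index"] = visits.groupby("patient_id").cumcount() + 1
    visits = visits[["patient_id", "visit_index", "visit_month", "age",
                     "diagnosis"] + list(feature_names)]
    pids = list(dict.fromkeys(visits["patient_id"]))
    if demo is None:
        demo = {p: ("F", "White", "NotHispanic", 16.0, 0) for p in pids}
    demographics = pd.DataFrame(
        [(p, *demo[p]) for p in pids],
        columns=["patient_id", "gender", "race", "ethnicity", "education",
                 "apoe4"]).set_index("patient_id")
    return Cohort(visits, demographics, list(feature_names))


@pytest.fixture
def toy_cohort():
    """Two patients, one converter, complete data."""
    rows = [
        ("A", 0, 70.0, "MCI", 1.0, 5.0),
        ("A", 6, 70.5, "MCI", 2.0, 6.0),
        ("A", 12, 71.0, "AD", 3.0, 7.0),
        ("B", 0, 65.0, "MCI", 0.5, 4.0),
        ("B", 12, 66.0, "MCI", 0.6, 4.2),
        ("B", 24, 67.0, "MCI", 0.7, 4.4),
    ]
    return make_toy_cohort(rows, ["f1", "f2"])


# ---------------------------------------------------------------------------
# study-condition presets shared by tests and the acceptance script
# ---------------------------------------------------------------------------

def strong_signal_config(n_patients=1000, seed=0):
    """Near-separable cohort: regular 6-month visits, tiny noise, severity
    drift strong enough that conversion timing is essentially determined by
    the observable baseline severity."""
    return SimulationConfig(
        n_patients=n_patients, n_features=10, visits_per_patient=(7, 12),
        interval_months=(6, 6), baseline_severity_mean=-0.5,
        baseline_severity_sd=0.5, drift_rate=0.03, drift_sd=0.0,
        innovation_sd=0.01, apoe4_drift_multiplier=1.0,
        conversion_threshold=0.5, noise_sd=0.05, missing_rate=0.0,
        seed=seed)


def trend_config(n_patients=800, seed=21):
    """ADNI-like regime for scenario-grid experiments: accelerating
    pre-conversion decline (prodrome) makes imminent conversion visible,
    hidden per-patient drift makes far horizons intrinsically noisy, and
    post-diagnosis attrition keeps scenario prevalences realistic."""
    return SimulationConfig(
        n_patients=n_patients, n_features=10, visits_per_patient=(12, 16),
        interval_months=(6, 12), baseline_severity_mean=-0.25,
        baseline_severity_sd=0.4, drift_rate=0.008, drift_sd=0.012,
        innovation_sd=0.02, apoe4_drift_multiplier=1.3,
        conversion_threshold=0.5, prodrome_band=0.2,
        prodrome_multiplier=8.0, post_conversion_dropout=0.7,
        noise_sd=0.2, missing_rate=0.05, seed=seed)


def imbalanced_config(n_patients=600, seed=5):
    """Roughly 1:4 positive:negative samples at the (t=3, n=1) scenario,
    with enough boundary noise that the loss weighting has room to act."""
    return SimulationConfig(
        n_patients=n_patients, n_features=10, visits_per_patient=(7, 12),
        interval_months=(6, 6), baseline_severity_mean=-0.25,
        baseline_severity_sd=0.5, drift_rate=0.03, drift_sd=0.01,
        innovation_sd=0.1, apoe4_drift_multiplier=1.0,
        conversion_threshold=0.5, noise_sd=0.3, missing_rate=0.0,
        seed=seed)


def age_signal_config(n_patients=1200, irregular=True, seed=33):
    """Cohort where per-visit age is the model's only access to elapsed
    time and chronological age, and progression accrues per elapsed month
    with a steeply age-dependent rate.  The irregular arm combines wide
    per-patient visit tempos (gaps 3-36 months) with age-dependent drift;
    the negative control fixes 12-month gaps and an age-independent rate,
    making the age column uninformative."""
    return SimulationConfig(
        n_patients=n_patients, n_features=4, visits_per_patient=(7, 10),
        interval_months=(3, 36) if irregular else (12, 12),
        per_patient_tempo=irregular, baseline_age_sd=7.0,
        baseline_severity_mean=-0.5, baseline_severity_sd=0.35,
        drift_rate=0.01, drift_sd=0.0, innovation_sd=0.05,
        age_dependent_drift=irregular, age_drift_exponent=8.0,
        apoe4_drift_multiplier=1.0, conversion_threshold=0.0,
        noise_sd=0.3, missing_rate=0.0, seed=seed)


def planted_feature_config(n_patients=400, seed=44):
    """One biomarker carries the whole severity signal; the rest are pure
    noise.  Used to check that attribution methods recover the planted
    driver."""
    import numpy as np
    loadings = np.zeros(6)
    loadings[0] = 1.0
    return SimulationConfig(
        n_patients=n_patients, n_features=6, visits_per_patient=(7, 10),
        interval_months=(6, 6), baseline_severity_mean=-0.5,
        baseline_severity_sd=0.5, drift_rate=0.03, innovation_sd=0.02,
        apoe4_drift_multiplier=1.0, conversion_threshold=0.5,
        feature_loadings=loadings, noise_sd=0.3, missing_rate=0.0,
        seed=seed)
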