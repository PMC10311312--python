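"""Synthetic longitudinal cohort generator.

Emulates the structure of real AD study cohorts (ADNI-like) so the full
pipeline is testable without access-restricted data: patients with a
varying number of visits (default 1-21), irregular inter-visit gaps
(default 3-60 months), per-visit diagnosis labels, missing feature values,
and cross-sectional demographics.

The generative model is a latent-severity threshold process.  Each patient
carries a scalar disease severity ``s`` that starts at a Gaussian baseline
and drifts upward by ``drift_rate`` per elapsed month (APOE-e4 carriers
drift faster by ``apoe4_drift_multiplier``), plus a small Gaussian
innovation per visit.  Diagnosis is AD once severity crosses
``conversion_threshold`` and the label is absorbing (no AD -> MCI
reversions).  Observed feature ``f`` at a visit is
``feature_loadings[f] * s + Normal(0, noise_sd)``; each feature value is
independently masked missing with probability ``missing_rate`` (MCAR).
Age accumulates the sampled irregular gaps, so the age column is the only
exact record of elapsed time between visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigError, DegenerateDataError


@dataclass
class SimulationConfig:
    """Parameters of the latent-severity cohort simulator.

    Defaults are chosen to resemble an ADNI-like MCI cohort: ~20
    longitudinal biomarkers, follow-up visits every 3-60 months, around a
    third to a half of patients converting during follow-up, and ~8%
    missingness.
    """

    n_patients: int = 500
    n_features: int = 19  # biomarker columns; age is carried separately

    visits_per_patient: tuple[int, int] = (1, 21)
    interval_months: tuple[int, int] = (3, 60)
    # if set, each patient gets a characteristic mean gap drawn uniformly
    # from interval_months and individual gaps vary +/-30% around it
    # (some patients visit every few months, others rarely)
    per_patient_tempo: bool = False

    baseline_age_mean: float = 73.0
    baseline_age_sd: float = 6.0

    baseline_severity_mean: float = -1.5
    baseline_severity_sd: float = 0.6
    drift_rate: float = 0.006  # severity units per elapsed month
    drift_sd: float = 0.0  # per-patient drift heterogeneity (truncated at 0)
    innovation_sd: float = 0.05  # per-visit Gaussian innovation on severity
    # diffusion-style innovation: sd scales with sqrt(months elapsed) so a
    # long gap carries proportionally more outcome uncertainty
    innovation_per_month: bool = False
    apoe4_drift_multiplier: float = 1.6  # drift scale for e4 carriers
    age_dependent_drift: bool = False  # if set, drift also scales with age
    age_drift_exponent: float = 1.0  # drift *= (age/70)**exponent when set
    conversion_threshold: float = 1.0
    cn_threshold: float | None = None  # below this, label CN (off by default)
    # accelerating pre-conversion decline: within `prodrome_band` below the
    # conversion threshold, drift is scaled by `prodrome_multiplier`
    # (cognitive decline speeds up shortly before an AD diagnosis)
    prodrome_band: float = 0.0
    prodrome_multiplier: float = 1.0
    # informative attrition: after the first AD-labelled visit, each further
    # visit is retained only with probability 1 - post_conversion_dropout
    # (patients tend to leave observational studies soon after diagnosis)
    post_conversion_dropout: float = 0.0

    feature_loadings: np.ndarray | None = None  # default: linspace(1.0, 0.25)
    noise_sd: float = 0.5
    missing_rate: float = 0.08

    # demographics
    gender_probs: dict[str, float] = field(
        default_factory=lambda: {"F": 0.47, "M": 0.53})
    race_probs: dict[str, float] = field(
        default_factory=lambda: {"White": 0.85, "Black": 0.08, "Asian": 0.04,
                                 "Other": 0.03})
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: {"NotHispanic": 0.95, "Hispanic": 0.05})
    education_mean: float = 16.0
    education_sd: float = 2.6
    apoe4_probs: tuple[float, float, float] = (0.55, 0.36, 0.09)

    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_features < 1:
            raise ConfigError("n_patients and n_features must be >= 1")
        for name in ("visits_per_patient", "interval_months"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"{name} range ({lo}, {hi}) is degenerate")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must be a probability")
        if self.feature_loadings is not None \
                and len(self.feature_loadings) != self.n_features:
            raise ConfigError("feature_loadings length != n_features")

    def resolved_loadings(self) -> np.ndarray:
        if self.feature_loadings is not None:
            return np.asarray(self.feature_loadings, dtype=float)
        return np.linspace(1.0, 0.25, self.n_features)


def _severity_path(rng: np.random.Generator, cfg: SimulationConfig,
                   s0: float, ages: np.ndarray, gaps: np.ndarray,
                   apoe4: int, base_drift: float | None = None) -> np.ndarray:
    """Latent severity at each visit; shared by simulator and oracle tests."""
    mult = cfg.apoe4_drift_multiplier if apoe4 > 0 else 1.0
    if base_drift is None:
        base_drift = cfg.drift_rate
    s = np.empty(len(ages))
    s[0] = s0
    for j in range(1, len(ages)):
        drift = base_drift * mult
        if cfg.age_dependent_drift:
            drift *= (ages[j - 1] / 70.0) ** cfg.age_drift_exponent
        if cfg.prodrome_band > 0 and \
                s[j - 1] >= cfg.conversion_threshold - cfg.prodrome_band:
            drift *= cfg.prodrome_multiplier
        sd = cfg.innovation_sd * np.sqrt(gaps[j - 1]) \
            if cfg.innovation_per_month else cfg.innovation_sd
        s[j] = s[j - 1] + drift * gaps[j - 1] + rng.normal(0.0, sd)
    return s


def _sample_gaps(rng: np.random.Generator, cfg: SimulationConfig,
                 n_gaps: int) -> np.ndarray:
    """Inter-visit gaps in months, bounded by cfg.interval_months."""
    lo, hi = cfg.interval_months
    if n_gaps == 0:
        return np.zeros(0)
    if cfg.per_patient_tempo:
        tempo = rng.uniform(lo, hi)
        gaps = tempo * rng.uniform(0.7, 1.3, size=n_gaps)
        return np.clip(np.round(gaps), lo, hi)
    return rng.integers(lo, hi + 1, size=n_gaps).astype(float)


def _patient_drift(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    """Per-patient progression rate: heterogeneous when drift_sd > 0."""
    if cfg.drift_sd <= 0:
        return cfg.drift_rate
    return max(rng.normal(cfg.drift_rate, cfg.drift_sd), 0.0)


def _diagnose(cfg: SimulationConfig, severity: np.ndarray) -> list[str]:
    """Threshold the severity path; the AD label is absorbing."""
    labels, converted = [], False
    for s in severity:
        if converted or s >= cfg.conversion_threshold:
            converted = True
            labels.append("AD")
        elif cfg.cn_threshold is not None and s < cfg.cn_threshold:
            labels.append("CN")
        else:
            labels.append("MCI")
    return labels


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a full synthetic cohort; reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    loadings = config.resolved_loadings()
    feature_names = [f"biomarker_{i+1:02d}" for i in range(config.n_features)]

    rows, demo_rows = [], []
    for i in range(config.n_patients):
        pid = f"P{i+1:05d}"
        gender = rng.choice(list(config.gender_probs),
                            p=list(config.gender_probs.values()))
        race = rng.choice(list(config.race_probs),
                          p=list(config.race_probs.values()))
        eth = rng.choice(list(config.ethnicity_probs),
                         p=list(config.ethnicity_probs.values()))
        education = float(np.clip(rng.normal(config.education_mean,
                                             config.education_sd), 6, 24))
        apoe4 = int(rng.choice(3, p=config.apoe4_probs))
        demo_rows.append((pid, gender, race, eth, round(education, 1), apoe4))

        n_visits = int(rng.integers(config.visits_per_patient[0],
                                    config.visits_per_patient[1] + 1))
        gaps = _sample_gaps(rng, config, max(n_visits - 1, 0))
        months = np.concatenate([[0.0], np.cumsum(gaps)])
        age0 = rng.normal(config.baseline_age_mean, config.baseline_age_sd)
        ages = age0 + months / 12.0

        s0 = rng.normal(config.baseline_severity_mean,
                        config.baseline_severity_sd)
        drift_i = _patient_drift(rng, config)
        severity = _severity_path(rng, config, s0, ages, gaps, apoe4, drift_i)
        labels = _diagnose(config, severity)

        if config.post_conversion_dropout > 0 and "AD" in labels:
            first_ad = labels.index("AD")
            keep = first_ad + 1
            while keep < n_visits and \
                    rng.random() >= config.post_conversion_dropout:
                keep += 1
            n_visits = keep
            months, ages = months[:keep], ages[:keep]
            severity, labels = severity[:keep], labels[:keep]

        feats = loadings[None, :] * severity[:, None] \
            + rng.normal(0.0, config.noise_sd, size=(n_visits, config.n_features))
        if config.missing_rate > 0:
            mask = rng.random(feats.shape) < config.missing_rate
            feats[mask] = np.nan

        for j in range(n_visits):
            rows.append((pid, j + 1, months[j], round(ages[j], 3), labels[j],
                         *feats[j]))

    visits = pd.DataFrame(
        rows, columns=["patient_id", "visit_index", "visit_month", "age",
                       "diagnosis"] + feature_names)
    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "gender", "race", "ethnicity",
                            "education", "apoe4"]).set_index("patient_id")
    return Cohort(visits, demographics, feature_names)


def converter_fraction_oracle(config: SimulationConfig,
                              replications: int = 10) -> float:
    """Monte-Carlo estimate of the probability a patient converts.

    Replays the severity/threshold process alone (no features, no
    missingness) at ``replications`` times the configured cohort size with
    an independent seed stream; used as the analytic anchor for the
    simulator's converter fraction.
    """
    cfg = replace(config, seed=config.seed + 1_000_003)
    rng = np.random.default_rng(cfg.seed)
    n = config.n_patients * replications
    converted = 0
    for _ in range(n):
        apoe4 = int(rng.choice(3, p=cfg.apoe4_probs))
        n_visits = int(rng.integers(cfg.visits_per_patient[0],
                                    cfg.visits_per_patient[1] + 1))
        gaps = _sample_gaps(rng, cfg, max(n_visits - 1, 0))
        months = np.concatenate([[0.0], np.cumsum(gaps)])
        age0 = rng.normal(cfg.baseline_age_mean, cfg.baseline_age_sd)
        ages = age0 + months / 12.0
        s0 = rng.normal(cfg.baseline_severity_mean, cfg.baseline_severity_sd)
        drift_i = _patient_drift(rng, cfg)
        severity = _severity_path(rng, cfg, s0, ages, gaps, apoe4, drift_i)
        if (severity >= cfg.conversion_threshold).any():
            converted += 1
    return converted / n


def cohort_summary(cohort: Cohort,
                   t_list=(2, 3, 5, 6), n_list=(1, 2, 3, 4)) -> dict:
    """Descriptive summary: sizes, visit-count histogram, converter counts,
    per-feature missing rates and per-(t, n) scenario eligibility counts."""
    if cohort.n_patients == 0:
        raise DegenerateDataError("empty cohort")

    counts = cohort.visits.groupby("patient_id").size()
    hist = counts.value_counts().sort_index().to_dict()
    converters = sum(cohort.is_converter(p) for p in cohort.patient_ids)

    miss = {
        f: float(cohort.visits[f].isna().mean()) for f in cohort.feature_names
    }

    scenarios = {}
    for t in t_list:
        for n in n_list:
            eligible = conv = 0
            for pid, sub in cohort.iter_patients():
                if len(sub) < t + n:
                    continue
                diags = sub["diagnosis"].to_numpy()
                if (diags[:t] == "AD").any() or diags[t + n - 1] == "CN":
                    continue
                eligible += 1
                conv += int(diags[t + n - 1] == "AD")
            scenarios[(t, n)] = {"eligible": eligible, "converters": conv,
                                 "nonconverters": eligible - conv}

    return {
        "n_patients": cohort.n_patients,
        "n_visits": cohort.n_visits,
        "visit_count_histogram": hist,
        "converters": converters,
        "nonconverters": cohort.n_patients - converters,
        "feature_missing_rates": miss,
        "scenario_counts": scenarios,
    }
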