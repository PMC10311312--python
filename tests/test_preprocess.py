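"""Preprocessing pipeline: each stage against exhaustive brute-force oracles."""

import numpy as np
import pytest

from adprog.cohort import Demographics
from adprog.errors import ConfigError, DegenerateDataError
from adprog.preprocess import (DemographicsEncoder, FilterThresholds,
                               apply_minmax, build_sequences,
                               filter_missingness, fit_minmax, impute_knn,
                               preprocess_pipeline, split_stratified)
from adprog.simulate import SimulationConfig, simulate_cohort

from conftest import make_toy_cohort


# ---------------------------------------------------------------------------
# filter_missingness
# ---------------------------------------------------------------------------

def _nan_row(pid, month, diag, values):
    return (pid, month, 70.0 + month / 12, diag, *values)


class TestFilterMissingness:
    def test_visit_above_threshold_removed(self):
        # 9 of 20 features missing = 45% > 40%
        feats = [f"x{i}" for i in range(20)]
        bad = [np.nan] * 9 + [1.0] * 11
        good = [1.0] * 20
        cohort = make_toy_cohort(
            [_nan_row("A", 0, "MCI", bad), _nan_row("A", 6, "MCI", good)],
            feats)
        out = filter_missingness(cohort)
        assert out.n_visits == 1
        assert out.patient_visits("A")["visit_month"].iloc[0] == 6.0

    def test_feature_above_threshold_removed(self):
        # feature missing in 13 of 20 visits = 65% > 60%; one missing cell
        # out of 20 features keeps each visit itself below the 40% cutoff
        feats = [f"x{i}" for i in range(20)]
        rows = []
        for i in range(20):
            vals = [np.nan if i < 13 else 1.0] + [1.0] * 19
            rows.append(_nan_row("A", 6 * i, "MCI", vals))
        out = filter_missingness(make_toy_cohort(rows, feats))
        assert out.n_visits == 20
        assert out.feature_names == feats[1:]

    def test_matches_brute_force_recount(self):
        """Scripted 8-visit cohort: surviving counts equal an exhaustive
        recount applying the two rules by hand."""
        rng = np.random.default_rng(3)
        feats = [f"x{i}" for i in range(5)]
        rows = []
        for i in range(8):
            vals = [np.nan if rng.random() < 0.45 else float(rng.normal())
                    for _ in feats]
            rows.append(_nan_row("A" if i < 4 else "B", 6 * (i % 4),
                                 "MCI", vals))
        cohort = make_toy_cohort(rows, feats)
        thresholds = FilterThresholds(0.40, 0.60)
        out = filter_missingness(cohort, thresholds)

        # oracle: independent recount on the raw table
        raw = cohort.visits[feats].to_numpy()
        keep_rows = [i for i in range(8)
                     if np.isnan(raw[i]).mean() <= 0.40]
        kept = raw[keep_rows]
        keep_cols = [j for j in range(5)
                     if np.isnan(kept[:, j]).mean() <= 0.60]
        assert out.n_visits == len(keep_rows)
        assert len(out.feature_names) == len(keep_cols)

    def test_all_features_dropped_raises(self):
        rows = [_nan_row("A", 0, "MCI", [np.nan]),
                _nan_row("A", 6, "MCI", [np.nan])]
        cohort = make_toy_cohort(rows, ["f1"])
        with pytest.raises(DegenerateDataError):
            filter_missingness(cohort, FilterThresholds(1.0, 0.60))

    def test_visit_reindexing_contiguous(self):
        rows = [_nan_row("A", 0, "MCI", [np.nan, np.nan]),
                _nan_row("A", 6, "MCI", [1.0, 1.0]),
                _nan_row("A", 12, "MCI", [2.0, 2.0])]
        out = filter_missingness(make_toy_cohort(rows, ["f1", "f2"]))
        assert list(out.patient_visits("A")["visit_index"]) == [1, 2]


# ---------------------------------------------------------------------------
# impute_knn
# ---------------------------------------------------------------------------

class TestImputeKnn:
    def test_six_identical_records_average_of_five(self):
        """Six MCI records identical except f1 = {1..5, missing}; all
        distances tie, so the five observed values average to 3."""
        rows = [_nan_row("P", 6 * i, "MCI", [v, 7.0])
                for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0, np.nan])]
        out = impute_knn(make_toy_cohort(rows, ["f1", "f2"]), k=5)
        assert out.visits["f1"].iloc[5] == pytest.approx(3.0)

    def test_complete_records_unchanged(self):
        rows = [_nan_row("P", 0, "MCI", [1.0, 2.0]),
                _nan_row("P", 6, "MCI", [np.nan, 2.5]),
                _nan_row("P", 12, "MCI", [3.0, 4.0])]
        cohort = make_toy_cohort(rows, ["f1", "f2"])
        out = impute_knn(cohort, k=2)
        assert out.visits["f1"].iloc[0] == 1.0
        assert out.visits["f2"].iloc[1] == 2.5
        assert not out.visits[["f1", "f2"]].isna().any().any()

    def test_diagnosis_restriction_ignores_closer_other_class(self):
        """An AD record's missing value is imputed from AD records only,
        even though MCI records are nearer in feature space; verified
        against a brute-force oracle that filters by diagnosis first."""
        rows = [
            _nan_row("P", 0, "AD", [np.nan, 10.0]),
            _nan_row("P", 6, "AD", [50.0, 60.0]),   # distant, same class
            _nan_row("P", 12, "AD", [40.0, 55.0]),  # distant, same class
            _nan_row("Q", 0, "MCI", [1.0, 10.0]),   # near, other class
            _nan_row("Q", 6, "MCI", [1.1, 10.1]),
        ]
        cohort = make_toy_cohort(rows, ["f1", "f2"])
        out = impute_knn(cohort, k=5)
        imputed = out.visits["f1"].iloc[0]

        # oracle: among AD rows observing f1, pick k nearest by euclidean
        # distance over mutually observed features, average f1
        oracle = np.mean([50.0, 40.0])
        assert imputed == pytest.approx(oracle)
        assert imputed > 10.0  # untouched by the nearby MCI values

    def test_idempotent(self):
        cfg = SimulationConfig(n_patients=30, missing_rate=0.15, seed=7)
        cohort = simulate_cohort(cfg)
        once = impute_knn(cohort, k=5)
        twice = impute_knn(once, k=5)
        assert once.equals(twice)

    def test_no_missing_values_remain(self):
        cfg = SimulationConfig(n_patients=40, missing_rate=0.25, seed=9)
        out = impute_knn(simulate_cohort(cfg), k=5)
        assert not out.visits[out.feature_names].isna().any().any()

    def test_fallback_to_class_mean_when_feature_unobserved_nearby(self):
        # only one MCI record observes f1 -> neighbour averaging degenerates
        # to that single value; a fully unobserved class falls back to the
        # overall mean
        rows = [_nan_row("P", 0, "MCI", [np.nan, 1.0]),
                _nan_row("P", 6, "MCI", [4.0, 2.0]),
                _nan_row("Q", 0, "AD", [8.0, 3.0])]
        out = impute_knn(make_toy_cohort(rows, ["f1", "f2"]), k=5)
        assert out.visits["f1"].iloc[0] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# split_stratified
# ---------------------------------------------------------------------------

def _mini_cohort(n_converters, n_stable):
    rows = []
    for i in range(n_converters):
        rows += [_nan_row(f"C{i}", 0, "MCI", [1.0]),
                 _nan_row(f"C{i}", 6, "AD", [2.0])]
    for i in range(n_stable):
        rows += [_nan_row(f"S{i}", 0, "MCI", [1.0]),
                 _nan_row(f"S{i}", 6, "MCI", [1.1])]
    return make_toy_cohort(rows, ["f1"])


class TestSplitStratified:
    def test_exact_fractions_balanced(self):
        cohort = _mini_cohort(10, 10)
        train, test = split_stratified(cohort, 0.30, seed=0)
        test_conv = sum(test.is_converter(p) for p in test.patient_ids)
        assert test.n_patients == 6
        assert test_conv == 3

    def test_deterministic_given_seed(self):
        cohort = _mini_cohort(10, 10)
        a = split_stratified(cohort, 0.30, seed=42)
        b = split_stratified(cohort, 0.30, seed=42)
        assert a[0].patient_ids == b[0].patient_ids
        assert a[1].patient_ids == b[1].patient_ids

    def test_patient_level_disjoint(self):
        cohort = _mini_cohort(8, 12)
        train, test = split_stratified(cohort, 0.30, seed=1)
        assert not set(train.patient_ids) & set(test.patient_ids)
        assert train.n_patients + test.n_patients == 20

    def test_converter_fraction_preserved_within_5pct(self):
        cfg = SimulationConfig(n_patients=100, seed=19)
        cohort = simulate_cohort(cfg)
        overall = np.mean([cohort.is_converter(p)
                           for p in cohort.patient_ids])
        train, test = split_stratified(cohort, 0.30, seed=3)
        for part in (train, test):
            frac = np.mean([part.is_converter(p) for p in part.patient_ids])
            assert abs(frac - overall) <= 0.05

    def test_tiny_stratum_goes_to_train(self):
        cohort = _mini_cohort(1, 10)
        train, test = split_stratified(cohort, 0.30, seed=0)
        assert "C0" in train.patient_ids


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

class TestMinMax:
    def _cohort_with(self, values):
        rows = [_nan_row("A", 6 * i, "MCI", [v]) for i, v in enumerate(values)]
        return make_toy_cohort(rows, ["f1"])

    def test_train_mapped_to_unit_interval(self):
        cohort = self._cohort_with([2.0, 4.0, 6.0])
        state = fit_minmax(cohort, include_age=False)
        out = apply_minmax(cohort, state)
        np.testing.assert_allclose(out.visits["f1"], [0.0, 0.5, 1.0])

    def test_test_values_extrapolate_unclipped(self):
        train = self._cohort_with([2.0, 6.0])
        state = fit_minmax(train, include_age=False)
        test = self._cohort_with([8.0])
        out = apply_minmax(test, state)
        assert out.visits["f1"].iloc[0] == pytest.approx(1.5)

    def test_constant_feature_maps_to_zero(self):
        train = self._cohort_with([7.0, 7.0, 7.0])
        state = fit_minmax(train, include_age=False)
        out = apply_minmax(train, state)
        assert (out.visits["f1"] == 0.0).all()

    def test_unknown_feature_raises_schema_error(self):
        from adprog.errors import SchemaError
        train = self._cohort_with([1.0, 2.0])
        state = fit_minmax(train, include_age=False)
        other = make_toy_cohort([_nan_row("A", 0, "MCI", [1.0, 2.0])],
                                ["f1", "g9"])
        with pytest.raises(SchemaError):
            apply_minmax(other, state)

    def test_state_fitted_on_train_only_no_leakage(self):
        """Transforming the test partition with its own statistics changes
        the output, proving the applied state really is train-derived."""
        cfg = SimulationConfig(n_patients=60, missing_rate=0.0, seed=23)
        cohort = simulate_cohort(cfg)
        train, test = split_stratified(cohort, 0.30, seed=0)
        by_train = apply_minmax(test, fit_minmax(train))
        by_test = apply_minmax(test, fit_minmax(test))
        f = cohort.feature_names[0]
        assert not np.allclose(by_train.visits[f], by_test.visits[f])


# ---------------------------------------------------------------------------
# build_sequences
# ---------------------------------------------------------------------------

class TestBuildSequences:
    def test_direct_read_of_future_label(self):
        rows = [_nan_row("A", 6 * i, d, [float(i)])
                for i, d in enumerate(["MCI", "MCI", "MCI", "AD"])]
        cohort = make_toy_cohort(rows, ["f1"])
        samples = build_sequences(cohort, t=2, n=2)
        assert len(samples) == 1
        assert samples[0].y == 1
        assert samples[0].X.shape == (2, 2)  # f1 + age

    def test_short_record_excluded(self):
        rows = [_nan_row("A", 6 * i, "MCI", [1.0]) for i in range(3)]
        cohort = make_toy_cohort(rows, ["f1"])
        assert build_sequences(cohort, t=3, n=1) == []

    def test_ad_inside_window_excluded(self):
        rows = [_nan_row("A", 6 * i, d, [1.0])
                for i, d in enumerate(["MCI", "AD", "AD", "AD"])]
        cohort = make_toy_cohort(rows, ["f1"])
        assert build_sequences(cohort, t=2, n=1) == []

    def test_cn_window_gated_by_flag(self):
        rows = [_nan_row("A", 6 * i, d, [1.0])
                for i, d in enumerate(["CN", "MCI", "MCI", "MCI"])]
        cohort = make_toy_cohort(rows, ["f1"])
        assert build_sequences(cohort, t=2, n=1, include_cn=False) == []
        assert len(build_sequences(cohort, t=2, n=1, include_cn=True)) == 1

    def test_age_column_optional(self):
        rows = [_nan_row("A", 6 * i, "MCI", [1.0]) for i in range(4)]
        cohort = make_toy_cohort(rows, ["f1"])
        with_age = build_sequences(cohort, t=2, n=1, include_age=True)
        without = build_sequences(cohort, t=2, n=1, include_age=False)
        assert with_age[0].X.shape == (2, 2)
        assert without[0].X.shape == (2, 1)

    def test_invalid_parameters_rejected(self):
        rows = [_nan_row("A", 0, "MCI", [1.0])]
        cohort = make_toy_cohort(rows, ["f1"])
        with pytest.raises(ConfigError):
            build_sequences(cohort, t=0, n=1)
        with pytest.raises(ConfigError):
            build_sequences(cohort, t=1, n=0)

    def test_scripted_cohort_matches_exhaustive_scan(self):
        """Sample and label counts equal an independent exhaustive scan
        over a 12-patient simulated cohort."""
        cfg = SimulationConfig(n_patients=12, missing_rate=0.0, seed=29)
        cohort = simulate_cohort(cfg)
        for t, n in [(2, 1), (3, 2)]:
            samples = build_sequences(cohort, t, n)
            expected, positives = 0, 0
            for pid in cohort.patient_ids:
                diags = list(cohort.patient_visits(pid)["diagnosis"])
                if len(diags) < t + n or "AD" in diags[:t] \
                        or "CN" in diags[:t] or diags[t + n - 1] == "CN":
                    continue
                expected += 1
                positives += diags[t + n - 1] == "AD"
            assert len(samples) == expected
            assert sum(s.y for s in samples) == positives

    def test_at_most_one_sample_per_patient_first_window(self):
        cfg = SimulationConfig(n_patients=50, seed=31)
        cohort = simulate_cohort(cfg)
        samples = build_sequences(cohort, t=2, n=1)
        assert len(samples) <= cohort.n_patients
        assert len({s.patient_id for s in samples}) == len(samples)

    def test_sliding_policy_emits_multiple_windows(self):
        rows = [_nan_row("A", 6 * i, "MCI", [1.0]) for i in range(6)]
        cohort = make_toy_cohort(rows, ["f1"])
        sliding = build_sequences(cohort, t=2, n=1, policy="sliding")
        assert len(sliding) == 4


# ---------------------------------------------------------------------------
# demographics encoding
# ---------------------------------------------------------------------------

class TestDemographicsEncoder:
    def _fit_encoder(self):
        rows = [_nan_row("A", 0, "MCI", [1.0]), _nan_row("B", 0, "MCI", [2.0])]
        demo = {"A": ("F", "White", "NotHispanic", 12.0, 0),
                "B": ("M", "Black", "Hispanic", 20.0, 2)}
        cohort = make_toy_cohort(rows, ["f1"], demo)
        return DemographicsEncoder().fit(cohort)

    def test_onehot_prefix_order(self):
        enc = self._fit_encoder()
        vec = enc.encode(Demographics("F", "White", "NotHispanic", 12.0, 0))
        assert list(vec[:2]) == [1.0, 0.0]  # gender categories sorted [F, M]

    def test_apoe4_passes_through_as_count(self):
        enc = self._fit_encoder()
        vec = enc.encode(Demographics("M", "Black", "Hispanic", 20.0, 2))
        assert vec[-1] == 2.0

    def test_education_minmax_scaled(self):
        enc = self._fit_encoder()
        vec = enc.encode(Demographics("F", "White", "NotHispanic", 16.0, 1))
        assert vec[-2] == pytest.approx((16.0 - 12.0) / (20.0 - 12.0))

    def test_vector_length_is_cardinalities_plus_two(self):
        enc = self._fit_encoder()
        vec = enc.encode(Demographics("F", "White", "NotHispanic", 12.0, 0))
        expected = 2 + 2 + 2 + 2  # gender + race + ethnicity + (edu, apoe4)
        assert len(vec) == expected == enc.dim

    def test_unseen_category_encodes_as_zeros(self):
        enc = self._fit_encoder()
        vec = enc.encode(Demographics("X", "White", "NotHispanic", 12.0, 0))
        assert list(vec[:2]) == [0.0, 0.0]


# ---------------------------------------------------------------------------
# pipeline composition
# ---------------------------------------------------------------------------

class TestPipeline:
    def test_stage_counts_logged_and_outputs_clean(self):
        cfg = SimulationConfig(n_patients=50, missing_rate=0.2, seed=37)
        prep = preprocess_pipeline(simulate_cohort(cfg), seed=0)
        assert prep.log["input"]["patients"] == 50
        assert prep.train.n_patients + prep.test.n_patients \
            == prep.log["after_filter"]["patients"]
        for part in (prep.train, prep.test):
            assert not part.visits[part.feature_names].isna().any().any()

    def test_train_features_within_unit_interval(self):
        cfg = SimulationConfig(n_patients=50, missing_rate=0.1, seed=41)
        prep = preprocess_pipeline(simulate_cohort(cfg), seed=0)
        vals = prep.train.visits[prep.train.feature_names].to_numpy()
        assert vals.min() >= -1e-12 and vals.max() <= 1.0 + 1e-12
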