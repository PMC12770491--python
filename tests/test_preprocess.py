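"""Preprocessing contracts: filters, condition assignment, binning,
imputation, normalisation, stratified splits and label construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knowrare.config import TaskSpec
from knowrare.preprocess import (NormalizationStats, apply_normalization,
                                 assign_condition, bin_time_series, build_labels,
                                 drop_small_conditions, filter_stays, fit_normalization,
                                 flag_rare, impute, stratified_patient_split)


def _patients(durations):
    return pd.DataFrame({"patient_id": [f"P{i}" for i in range(len(durations))],
                         "stay_hours": durations})


class TestFilters:
    def test_stay_duration_boundary(self):
        out = filter_stays(_patients([47.9, 48.0, 48.1]), min_hours=48)
        assert list(out["stay_hours"]) == [48.0, 48.1]

    def test_missing_duration_dropped(self):
        out = filter_stays(_patients([np.nan, 50.0]), min_hours=48)
        assert list(out["patient_id"]) == ["P1"]

    def test_empty_input(self):
        assert len(filter_stays(_patients([]), 48)) == 0

    @pytest.mark.parametrize("count,n,rare", [(1, 2000, False), (5, 20000, True),
                                              (1, 2001, True), (3, 2000, False)])
    def test_rare_flag_strict_inequality(self, count, n, rare):
        flagged = flag_rare({"428": count}, n)
        assert ("428" in flagged) == rare

    def test_rare_flag_absent_condition(self):
        assert flag_rare({}, 1000) == set()

    def test_drop_small_conditions_boundary(self):
        df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(19)],
                           "condition_code": ["428"] * 10 + ["038"] * 9})
        out = drop_small_conditions(df, min_patients=10)
        assert set(out["condition_code"]) == {"428"}
        # removing a condition removes its patients (recount oracle)
        assert len(out) == 10
        assert out["patient_id"].is_unique


class TestConditionAssignment:
    def test_truncation_and_first_listed(self):
        diag = pd.DataFrame({
            "patient_id": ["A", "A", "B", "C"],
            "icd9_code": ["0389", "42731", "4280x", "V450"],
            "rank": [0, 1, 0, 0]})
        out = assign_condition(diag)
        assert out["A"] == "038"
        assert out["B"] == "428"
        assert out["C"] == "V45"

    def test_no_diagnoses_empty(self):
        assert len(assign_condition(pd.DataFrame(columns=["patient_id", "icd9_code"]))) == 0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            assign_condition(pd.DataFrame(), rule="longest")


class TestBinning:
    def test_mean_within_bin(self, icu_task):
        ev = pd.DataFrame({"patient_id": "P", "variable_id": [0, 0],
                           "hours_from_admit": [0.2, 0.8], "value": [3.0, 5.0]})
        X, mask = bin_time_series(ev, icu_task, n_variables=2)
        assert X[0, 0] == 4.0
        assert mask[0, 0]
        assert not mask[0, 1] and np.isnan(X[0, 1])
        assert X.shape == (24, 2)

    def test_brute_force_oracle(self, rng, icu_task):
        n_ev = 500
        ev = pd.DataFrame({"patient_id": "P",
                           "variable_id": rng.integers(0, 4, n_ev),
                           "hours_from_admit": rng.uniform(0, 24, n_ev),
                           "value": rng.normal(size=n_ev)})
        X, mask = bin_time_series(ev, icu_task, n_variables=4)
        for t in range(24):
            for v in range(4):
                sel = ev[(ev.variable_id == v)
                         & (ev.hours_from_admit >= t) & (ev.hours_from_admit < t + 1)]
                if len(sel):
                    assert mask[t, v]
                    np.testing.assert_allclose(X[t, v], sel.value.mean())
                else:
                    assert not mask[t, v]

    def test_events_outside_window_ignored(self, icu_task):
        ev = pd.DataFrame({"patient_id": "P", "variable_id": [0, 0],
                           "hours_from_admit": [25.0, -1.0], "value": [1.0, 2.0]})
        _, mask = bin_time_series(ev, icu_task, n_variables=1)
        assert not mask.any()

    def test_last_window_alignment(self):
        spec = TaskSpec.named("mortality_90d")  # last 48 h, 2 h bins
        ev = pd.DataFrame({"patient_id": "P", "variable_id": [0, 0],
                           "hours_from_admit": [11.0, 13.0], "value": [7.0, 9.0]})
        # stay of 60 h: window covers [12, 60); 11 h falls outside, 13 h in bin 0
        X, mask = bin_time_series(ev, spec, stay_hours=60.0, n_variables=1)
        assert mask[0, 0] and X[0, 0] == 9.0
        assert mask.sum() == 1
        with pytest.raises(ValueError):
            bin_time_series(ev, spec, n_variables=1)


class TestImputation:
    stats = NormalizationStats(impute_mean=np.array([0.7]))

    def _col(self, values):
        return np.array(values, dtype=float).reshape(-1, 1)

    def test_locf_then_nocb(self):
        out = impute(self._col([np.nan, 2, np.nan, 4]), self.stats)
        np.testing.assert_allclose(out.ravel(), [2, 2, 2, 4])

    def test_all_missing_uses_train_mean(self):
        out = impute(self._col([np.nan] * 4), self.stats)
        np.testing.assert_allclose(out.ravel(), 0.7)

    def test_fully_observed_unchanged(self):
        x = self._col([1, 2, 3])
        np.testing.assert_array_equal(impute(x, self.stats), x)

    @given(st.lists(st.one_of(st.none(), st.floats(-5, 5)), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_idempotence(self, values):
        x = self._col([np.nan if v is None else v for v in values])
        once = impute(x, self.stats)
        np.testing.assert_array_equal(impute(once, self.stats), once)
        assert not np.isnan(once).any()

    def test_stats_must_cover_variables(self):
        with pytest.raises(ValueError):
            impute(np.zeros((3, 2)), self.stats)


class TestNormalization:
    def test_train_moments(self, rng):
        X = rng.normal(2.0, 3.0, size=(20, 6, 4))
        mean, std = fit_normalization(X)
        stats = NormalizationStats(np.zeros(4), mean, std)
        z = apply_normalization(X, stats)
        flat = z.reshape(-1, 4)
        np.testing.assert_allclose(flat.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(flat.std(axis=0), 1, atol=1e-9)

    def test_constant_variable_maps_to_zero(self):
        X = np.full((5, 3, 1), 4.2)
        mean, std = fit_normalization(X)
        z = apply_normalization(X, NormalizationStats(np.zeros(1), mean, std))
        np.testing.assert_array_equal(z, 0)

    def test_heldout_value_at_train_mean_is_zero(self, rng):
        X = rng.normal(size=(10, 4, 2))
        mean, std = fit_normalization(X)
        held = np.broadcast_to(mean, (1, 4, 2))
        z = apply_normalization(held, NormalizationStats(np.zeros(2), mean, std))
        np.testing.assert_allclose(z, 0, atol=1e-12)


class TestSplit:
    def _cohort(self, n=100, code="428"):
        return pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                             "condition_code": code})

    def test_67_16_17_counts(self):
        split = stratified_patient_split(self._cohort(100), seed=0)
        assert (len(split.train), len(split.valid), len(split.test)) == (67, 16, 17)

    def test_disjoint_and_deterministic(self):
        df = pd.concat([self._cohort(40, "428"), self._cohort(25, "038").assign(
            patient_id=lambda d: "Q" + d.patient_id)])
        a = stratified_patient_split(df, seed=5)
        b = stratified_patient_split(df, seed=5)
        assert set(a.train) | set(a.valid) | set(a.test) == set(df.patient_id)
        assert not (set(a.train) & set(a.valid)) and not (set(a.train) & set(a.test))
        np.testing.assert_array_equal(a.train, b.train)
        c = stratified_patient_split(df, seed=6)
        assert set(c.train) != set(a.train)  # different assignment
        assert len(c.train) == len(a.train)  # same counts

    def test_tiny_condition_all_to_train(self):
        df = pd.concat([self._cohort(10, "428"),
                        self._cohort(2, "284").assign(
                            patient_id=lambda d: "R" + d.patient_id)])
        split = stratified_patient_split(df, seed=0)
        assert {"RP0", "RP1"} <= set(split.train)

    def test_prevalence_sums_to_one(self):
        df = pd.concat([self._cohort(30, "428"), self._cohort(12, "038").assign(
            patient_id=lambda d: "Q" + d.patient_id)])
        split = stratified_patient_split(df, seed=1)
        assert np.isclose(sum(split.prevalence.values()), 1.0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            stratified_patient_split(self._cohort(10), fractions=(0.5, 0.2, 0.2))


class TestLabels:
    spec = TaskSpec.named("remaining_los")

    @pytest.mark.parametrize("days,cls", [(0.5, 0), (1.0, 1), (8.0, 7),
                                          (20.0, 9), (10.0, 8), (6.99, 6)])
    def test_los_bins(self, days, cls):
        df = pd.DataFrame({"remaining_los_days": [days]})
        assert build_labels(df, self.spec)[0] == cls

    def test_binary_passthrough(self):
        spec = TaskSpec.named("icu_mortality")
        df = pd.DataFrame({"label_icu_mortality": [0, 1, 1]})
        np.testing.assert_array_equal(build_labels(df, spec), [0, 1, 1])

    def test_phenotype_matrix(self):
        spec = TaskSpec.named("phenotyping")
        df = pd.DataFrame({"phenotypes": ["01" * 12 + "1", "0" * 25]})
        y = build_labels(df, spec)
        assert y.shape == (2, 25)
        assert y[0, 1] == 1 and y[1].sum() == 0

    def test_missing_label_column_rejected(self):
        spec = TaskSpec.named("icu_mortality")
        with pytest.raises(KeyError):
            build_labels(pd.DataFrame({"x": [1]}), spec)
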