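"""Hybrid feature extraction and group-comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sskeca.calibration import REFERENCE_SUMMARIES
from sskeca.events import FixationEvent, GazeSample, SaccadeEvent, clean_trial
from sskeca.features import (
    EmptyTableError,
    FEATURE_NAMES,
    METADATA_COLUMNS,
    build_feature_table,
    chi2_yates,
    cohens_d,
    extract_features,
    group_stats_table,
    welch_t,
)
from sskeca.synth import SyntheticProfile, generate_trials

from conftest import make_trial


def features_of(trial):
    cleaned, stats = clean_trial(trial)
    return extract_features(trial, cleaned, stats)


class TestExtraction:
    def test_fixation_block_arithmetic(self):
        t = make_trial(
            fixations=[
                FixationEvent(0, 100, 400, 300, 23.0, 22.7),
                FixationEvent(200, 300, 400, 300, 23.2, 22.9),
            ]
        )
        f = features_of(t).values
        assert f["fix_count"] == 2
        assert f["avg_fix_duration"] == 200
        assert f["max_fix_duration"] == 300
        assert f["min_fix_duration"] == 100
        assert f["fix_duration"] == 400
        assert f["avg_fix_x_res"] == pytest.approx(23.1)
        assert f["avg_fix_y_res"] == pytest.approx(22.8)

    def test_outside_fixation_counted_from_precleaning_record(self):
        t = make_trial(
            fixations=[
                FixationEvent(0, 200, 900, 300),  # outside 800x600
                FixationEvent(300, 250, 400, 300),
            ]
        )
        f = features_of(t).values
        assert f["outside_fix_count"] == 1
        assert f["fix_count"] == 1  # outside one was cleaned away
        assert f["valid_viewing_duration"] == 250  # outside excluded from VVD

    def test_vvd_includes_subthreshold_inside_fixations(self):
        t = make_trial(
            fixations=[
                FixationEvent(0, 50, 400, 300),  # cleaned (too short) but inside
                FixationEvent(100, 250, 400, 300),
            ]
        )
        f = features_of(t).values
        assert f["fix_duration"] == 250
        assert f["valid_viewing_duration"] == 300

    def test_pupil_ratio_definitions_reproduce_reference_means(self):
        # samples engineered to the reference HC min/avg/max pupil means
        pmin, pavg, pmax = 1439.83, 1823.20, 2096.02
        mid = 3 * pavg - pmin - pmax
        t = make_trial(
            samples=[
                GazeSample(1, 100, 100, pmin),
                GazeSample(2, 381, 325, pmax),
                GazeSample(3, 200, 200, mid),
            ]
        )
        f = features_of(t).values
        assert round(f["dr_pupil_size"], 2) == 0.36
        assert round(f["pupil_size_ratio"], 2) == 1.15
        assert (f["x_to_max_pupil"], f["y_to_max_pupil"]) == (381, 325)

    def test_saccade_amplitude_is_per_trial_total(self):
        t = make_trial(
            saccades=[
                SaccadeEvent(0, 5, 4.0, 120),
                SaccadeEvent(10, 6, 5.0, 130),
                SaccadeEvent(20, 7, 6.0, 140),
            ]
        )
        f = features_of(t).values
        assert f["sac_count"] == 3
        assert f["sac_amplitude"] == pytest.approx(15.0)
        assert f["avg_sac_velocity"] == pytest.approx(130.0)
        assert f["avg_sac_duration"] == pytest.approx(6.0)

    def test_degenerate_blocks(self):
        t = make_trial(saccades=[], blinks=[])
        f = features_of(t).values
        assert f["sac_count"] == 0 and f["sac_amplitude"] == 0
        assert f["blink_count"] == 0

    def test_no_cleaned_fixations_flags_invalid(self):
        t = make_trial(fixations=[FixationEvent(0, 50, 400, 300)])
        vec = features_of(t)
        assert not vec.valid

    def test_permutation_invariance(self, trial):
        f1 = features_of(trial).values
        shuffled = make_trial(
            fixations=trial.fixations[::-1],
            saccades=trial.saccades[::-1],
            blinks=trial.blinks,
            samples=trial.samples,
        )
        f2 = features_of(shuffled).values
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name]), name

    def test_skewness_decreases_toward_center(self):
        far = make_trial(fixations=[FixationEvent(0, 200, 100, 100)])
        near = make_trial(fixations=[FixationEvent(0, 200, 390, 295)])
        assert features_of(near).values["fix_skewness"] < features_of(far).values["fix_skewness"]

    def test_ordering_invariants_on_generated_trials(self):
        trials = generate_trials(
            SyntheticProfile(n_sz=2, n_hc=2, trials_per_subject=2), seed=9
        )
        for t in trials:
            f = features_of(t).values
            assert f["min_fix_duration"] <= f["avg_fix_duration"] <= f["max_fix_duration"]
            assert f["min_pupil_size"] <= f["avg_pupil_size"] <= f["max_pupil_size"]
            assert f["pupil_size_ratio"] >= 1
            assert f["dr_pupil_size"] >= 0
            assert f["valid_viewing_duration"] >= f["fix_duration"]


class TestFeatureTable:
    def test_one_row_per_valid_trial_and_schema(self):
        trials = generate_trials(
            SyntheticProfile(n_sz=2, n_hc=3, trials_per_subject=2), seed=5
        )
        table = build_feature_table(trials)
        assert len(table) == 10
        assert list(table.columns) == METADATA_COLUMNS + FEATURE_NAMES

    def test_invalid_trial_dropped(self):
        good = make_trial(subject="A")
        bad = make_trial(subject="B", fixations=[FixationEvent(0, 50, 400, 300)])
        table = build_feature_table([good, bad])
        assert len(table) == 1 and table["subject_id"].iloc[0] == "A"

    def test_all_invalid_raises(self):
        bad = make_trial(fixations=[FixationEvent(0, 50, 400, 300)])
        with pytest.raises(EmptyTableError):
            build_feature_table([bad])
        with pytest.raises(EmptyTableError):
            build_feature_table([])


class TestSummaryStatistics:
    def test_welch_reference_rows(self):
        t, _, _ = welch_t(144.72, 38.59, 50, 79.44, 31.54, 40)
        assert round(t, 3) == 8.830
        t, _, _ = welch_t(13.40, 1.39, 50, 11.90, 1.13, 40)
        assert round(t, 2) == 5.65

    def test_welch_identical_groups_zero(self):
        t, df, p = welch_t(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert t == 0 and p == pytest.approx(1.0)

    def test_welch_matches_scipy_oracle(self, rng):
        for _ in range(50):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.1, 3, size=2)
            n1, n2 = rng.integers(3, 80, size=2)
            t, df, p = welch_t(m1, s1, n1, m2, s2, n2)
            ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_degenerate_inputs(self):
        with pytest.raises(ValueError):
            welch_t(1, 0, 10, 1, 0, 10)
        with pytest.raises(ValueError):
            welch_t(1, 1, 1, 2, 1, 10)

    def test_cohens_d_reference_rows(self):
        assert round(cohens_d(144.72, 38.59, 50, 79.44, 31.54, 40), 3) == 1.832
        assert round(cohens_d(132.73, 75.80, 50, 63.72, 20.30, 40), 3) == 1.187
        assert cohens_d(5, 1, 20, 5, 2, 20) == 0

    def test_cohens_d_textbook_oracle(self, rng):
        for _ in range(50):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.1, 3, size=2)
            n1, n2 = int(rng.integers(3, 50)), int(rng.integers(3, 50))
            sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
            assert cohens_d(m1, s1, n1, m2, s2, n2) == pytest.approx((m1 - m2) / sp, abs=1e-12)

    def test_chi2_yates_gender_table(self):
        chi2, p = chi2_yates([[28, 12], [29, 21]])
        assert round(chi2, 2) == 0.91
        assert round(p, 2) == 0.34

    def test_chi2_proportional_table_floors_at_zero(self):
        chi2, _ = chi2_yates([[20, 10], [40, 20]])
        assert chi2 == 0

    def test_chi2_matches_direct_formula(self, rng):
        for _ in range(20):
            obs = rng.integers(3, 40, size=(2, 2)).astype(float)
            chi2, _ = chi2_yates(obs)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            direct = (np.maximum(np.abs(obs - exp) - 0.5, 0) ** 2 / exp).sum()
            assert chi2 == pytest.approx(direct, abs=1e-10)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_yates([[0, 0], [5, 5]])


class TestGroupStats:
    def _table(self, hc, sz):
        rows = []
        for i, vals in enumerate(hc):
            rows.append(["H%d" % i, "HC", 1, 1, 1, *vals])
        for i, vals in enumerate(sz):
            rows.append(["Z%d" % i, "SZ", 1, 1, 1, *vals])
        return pd.DataFrame(rows, columns=METADATA_COLUMNS + FEATURE_NAMES)

    def test_identical_groups_give_zero_d(self, rng):
        vals = rng.normal(size=(4, 24))
        table = self._table(vals, vals)
        gs = group_stats_table(table)
        assert np.allclose(gs["cohens_d"], 0)

    def test_constant_feature_flagged_nan(self, rng):
        vals = rng.normal(size=(4, 24))
        vals[:, 0] = 1.0
        gs = group_stats_table(self._table(vals, vals + 0.0))
        assert np.isnan(gs.loc[FEATURE_NAMES[0], "t"])

    def test_single_group_rejected(self, rng):
        table = self._table(rng.normal(size=(4, 24)), rng.normal(size=(4, 24)))
        with pytest.raises(ValueError):
            group_stats_table(table[table["group"] == "HC"])

    def test_subject_level_t_tracks_reference(self, medium_table):
        """Welch t on subject means of the calibrated cohort approximates
        the reference table's t-values (single draw, generous band)."""
        gs = group_stats_table(medium_table, by_subject=True)
        for name in ("avg_sac_velocity", "fix_count", "duration"):
            ref_t, _, _ = welch_t(
                REFERENCE_SUMMARIES[name].hc_mean,
                REFERENCE_SUMMARIES[name].hc_sd,
                50,
                REFERENCE_SUMMARIES[name].sz_mean,
                REFERENCE_SUMMARIES[name].sz_sd,
                40,
            )
            assert gs.loc[name, "t"] == pytest.approx(ref_t, abs=3.0), name
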