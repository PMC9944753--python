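"""Study-design rules: entry, cleaning, exposure, exclusions, outcomes,
folds, sensitivity variants, and flow conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehrcausal import (StudyConfig, SimConfig, generate_population,
                       build_cohort, apply_sensitivity_filter,
                       find_study_entry, clean_sbp, compute_baseline_exposure,
                       categorize_sbp, apply_exclusions, ascertain_outcome)
from ehrcausal.cohort import DataError, EmptyCohortError, assign_folds
from ehrcausal.synth import HF_CODE, STROKE_CODE, CV_DEATH, NON_CV_DEATH

from conftest import make_patient, day_of_year


class TestStudyEntry:
    def test_first_qualifying_measurement_respects_age_bounds(self, study_config):
        # measurements at ages 48 and 51, both inside 1990-2005
        p = make_patient(birth_year=1945.0,
                         sbp=[(day_of_year(1993.0), 130.0),
                              (day_of_year(1996.0), 140.0)])
        entry = find_study_entry(p, study_config)
        assert entry == day_of_year(1996.0)

    def test_no_measurements_gives_absent(self, study_config):
        assert find_study_entry(make_patient(), study_config) is None

    def test_out_of_window_years_excluded(self, study_config):
        p = make_patient(birth_year=1930.0, sbp=[(day_of_year(1988.0), 130.0),
                                                 (day_of_year(2007.0), 140.0)])
        assert find_study_entry(p, study_config) is None

    def test_same_day_duplicate_measurement_single_entry(self, study_config):
        d = day_of_year(1995.0)
        p = make_patient(birth_year=1940.0, sbp=[(d, 130.0), (d, 150.0)])
        assert find_study_entry(p, study_config) == d


class TestCleanSBP:
    def test_strictly_out_of_range_dropped(self):
        vals = clean_sbp([(0, 49.0), (1, 120.0), (2, 301.0)])
        assert [v for _, v in vals] == [120.0]

    def test_bounds_retained(self):
        vals = clean_sbp([(0, 50.0), (1, 300.0)])
        assert [v for _, v in vals] == [50.0, 300.0]

    def test_empty_input(self):
        assert clean_sbp([]) == []

    def test_non_numeric_raises_with_context(self):
        with pytest.raises(DataError, match="pid=42"):
            clean_sbp([(0, "high")], pid=42)


class TestBaselineExposure:
    def test_mean_of_window_values(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(sbp=[(e, 130.0), (e + 50, 140.0), (e + 100, 150.0),
                              (e + 200, 160.0)])
        assert compute_baseline_exposure(p, e, study_config) == 145.0

    def test_single_value(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(sbp=[(e, 118.0)])
        assert compute_baseline_exposure(p, e, study_config) == 118.0

    def test_window_half_open_at_day_365(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(sbp=[(e, 120.0), (e + 365, 180.0)])
        assert compute_baseline_exposure(p, e, study_config) == 120.0

    def test_all_values_cleaned_away_gives_absent(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(sbp=[(e, 40.0), (e + 10, 320.0)])
        assert compute_baseline_exposure(p, e, study_config) is None


class TestCategorize:
    @pytest.mark.parametrize("sbp,cat", [
        (119.9, 0), (120.0, 1), (129.99, 1), (130.0, 2), (145.0, 3),
        (150.0, 4), (159.999, 4), (160.0, 5), (300.0, 5), (50.0, 0)])
    def test_category_bounds(self, study_config, sbp, cat):
        assert categorize_sbp(sbp, study_config) == cat

    def test_out_of_range_is_logic_error(self, study_config):
        with pytest.raises(ValueError):
            categorize_sbp(40.0, study_config)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=50.0, max_value=300.0, allow_nan=False))
    def test_partition_exhaustive_and_exclusive(self, study_config, sbp):
        cat = categorize_sbp(sbp, study_config)
        edges = (50.0,) + study_config.category_edges + (300.0 + 1e-9,)
        lo = edges[cat] if cat > 0 else 0.0
        hi = edges[cat + 1] if cat < 5 else np.inf
        assert (sbp >= lo or cat == 0) and (sbp < hi or cat == 5)


class TestExclusions:
    def test_prior_hf_excludes(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(events=[(e - 100, HF_CODE, "dx")], sbp=[(e, 130.0)])
        ok, reason = apply_exclusions(p, e, study_config)
        assert not ok and reason == "prior_hf"

    def test_event_in_exposure_period_excludes(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(events=[(e + 200, STROKE_CODE, "dx")], sbp=[(e, 130.0)])
        ok, reason = apply_exclusions(p, e, study_config)
        assert not ok and reason == "event_in_exposure_period"

    def test_event_in_followup_is_eligible(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(events=[(e + 400, STROKE_CODE, "dx")], sbp=[(e, 130.0)])
        ok, reason = apply_exclusions(p, e, study_config)
        assert ok and reason is None

    def test_dropout_in_exposure_period_excludes(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(sbp=[(e, 130.0)], censor_day=e + 100)
        ok, reason = apply_exclusions(p, e, study_config)
        assert not ok and reason == "dropout_in_exposure_period"

    def test_precedence_prior_hf_first(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(events=[(e - 100, HF_CODE, "dx"),
                                 (e + 50, STROKE_CODE, "dx")],
                         sbp=[(e, 130.0)], censor_day=e + 60)
        assert apply_exclusions(p, e, study_config)[1] == "prior_hf"


class TestOutcome:
    def test_cv_death_in_followup_counts(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(sbp=[(e, 130.0)], death_day=e + 60 * 30,
                         death_cause=CV_DEATH)
        outcome, ev, cens = ascertain_outcome(p, e, study_config)
        assert (outcome, ev, cens) == (1, e + 1800, None)

    def test_non_cv_death_censors(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(sbp=[(e, 130.0)], death_day=e + 1800,
                         death_cause=NON_CV_DEATH, censor_day=e + 1800)
        outcome, ev, cens = ascertain_outcome(p, e, study_config)
        assert (outcome, ev, cens) == (0, None, e + 1800)

    def test_event_at_followup_boundary_belongs_to_exposure_period(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(events=[(e + 365, STROKE_CODE, "dx")], sbp=[(e, 130.0)])
        # excluded upstream as an exposure-period event ...
        ok, reason = apply_exclusions(p, e, study_config)
        assert not ok and reason == "event_in_exposure_period"
        # ... and not counted by the follow-up window either
        assert ascertain_outcome(p, e, study_config)[0] == 0

    def test_event_after_followup_end_ignored(self, study_config):
        e = day_of_year(1995.0)
        p = make_patient(events=[(e + 3700, STROKE_CODE, "dx")], sbp=[(e, 130.0)])
        assert ascertain_outcome(p, e, study_config)[0] == 0


class TestBuildCohort:
    def test_flow_conserves_on_generated_populations(self, study_config):
        for seed in (1, 2, 3):
            pats = generate_population(SimConfig(n_patients=400, seed=seed))
            _, flow = build_cohort(pats, study_config, fold_seed=seed)
            flow.check_balance()   # raises on imbalance
            assert flow.n_final == sum(flow.per_category_n)
            assert sum(flow.per_category_events) <= flow.n_final

    def test_prior_hf_counted(self, study_config):
        e = day_of_year(1995.0)
        pats = [make_patient(pid=i, sbp=[(e, 120.0 + i)]) for i in range(8)]
        for i in (0, 1):
            pats[i].events.append((e - 50, HF_CODE, "dx"))
        cohort, flow = build_cohort(pats, study_config, fold_seed=0)
        assert flow.n_prior_hf == 2 and flow.n_final == 6 and len(cohort) == 6

    def test_fold_assignment_deterministic(self, small_population, study_config):
        c1, _ = build_cohort(small_population, study_config, fold_seed=5)
        c2, _ = build_cohort(small_population, study_config, fold_seed=5)
        assert (c1["fold"] == c2["fold"]).all()

    def test_fold_stratification_balanced(self, small_cohort):
        cohort, _ = small_cohort
        for cat, grp in cohort.groupby("exposure_cat"):
            counts = grp["fold"].value_counts()
            assert counts.max() - counts.min() <= 1

    def test_empty_cohort_raises(self, study_config):
        p = make_patient()  # no measurements at all
        with pytest.raises(EmptyCohortError):
            build_cohort([p], study_config, fold_seed=0)

    def test_mean_sbp_consistent_with_category(self, small_cohort, study_config):
        cohort, _ = small_cohort
        recomputed = [categorize_sbp(v, study_config) for v in cohort["mean_sbp"]]
        assert (cohort["exposure_cat"] == recomputed).all()

    def test_outcome_event_day_inside_followup_window(self, small_cohort):
        cohort, _ = small_cohort
        ev = cohort[cohort["outcome"] == 1]
        rel = ev["event_day"] - ev["entry_day"]
        assert ((rel > 365) & (rel <= 3650)).all()


def test_assign_folds_cyclic_property():
    rng = np.random.default_rng(0)
    cats = rng.integers(0, 6, 500)
    folds = assign_folds(cats, 5, seed=3)
    for c in range(6):
        counts = np.bincount(folds[cats == c], minlength=5)
        assert counts.max() - counts.min() <= 1


class TestSensitivityVariants:
    def test_sex_filter_counts(self, small_cohort):
        cohort, _ = small_cohort
        fem = apply_sensitivity_filter(cohort, "sex:F")
        assert len(fem) == (cohort["sex"] == "F").sum()

    def test_age_partition_reunites(self, small_cohort):
        cohort, _ = small_cohort
        lo = apply_sensitivity_filter(cohort, "age<=75")
        hi = apply_sensitivity_filter(cohort, "age>75")
        assert len(lo) + len(hi) == len(cohort)
        assert set(lo["pid"]) | set(hi["pid"]) == set(cohort["pid"])

    def test_drop_early_followup_events(self, small_cohort):
        cohort, _ = small_cohort
        sub = apply_sensitivity_filter(cohort, "drop_events_first_12m_followup")
        kept = sub[sub["outcome"] == 1]
        assert (kept["event_day"] > kept["entry_day"] + 730).all()

    def test_include_exposure_period_events_enlarges(self, small_population,
                                                     study_config, small_cohort):
        cohort, _ = small_cohort
        sub = apply_sensitivity_filter(cohort, "include_exposure_period_events",
                                       patients=small_population,
                                       config=study_config, fold_seed=9)
        assert len(sub) >= len(cohort)

    def test_no_antihypertensives_after_entry(self, small_population, small_cohort):
        cohort, _ = small_cohort
        sub = apply_sensitivity_filter(cohort, "no_antihypertensives_after_entry",
                                       patients=small_population)
        assert len(sub) < len(cohort)

    def test_unknown_variant_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown"):
            apply_sensitivity_filter(small_cohort[0], "bogus")
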