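"""Study design: entry, exposure construction, exclusions, outcomes, folds.

Implements the cohort rules: study entry at the first qualifying SBP
measurement (calendar window 1990-2005, age 50-90), exposure as the mean of
cleaned SBP values over the first 12 months after entry binned into six
categories (<120 reference ... >=160 mm Hg), exclusion of prior heart
failure and of patients with an event or dropout during the exposure
period, and a binary composite cardiovascular outcome (IHD, incident HF,
stroke, CV death) ascertained in months 12-120 of follow-up.

Window conventions are half-open and exact in integer days: exposure
period [entry, entry+365); follow-up (entry+365, entry+3650].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import StudyConfig, DAYS_PER_YEAR
from .synth import (PatientRecord, OUTCOME_CODES, HF_CODE, CV_DEATH,
                    ANTIHTN_CODE, N_CATEGORIES)


class DataError(ValueError):
    """Malformed input data (names the offending patient and row)."""


class EmptyCohortError(RuntimeError):
    """No patient survived entry and exclusion rules."""


COVARIATE_COLUMNS = ["age_at_entry", "sex", "smoking", "bmi", "hdl",
                     "total_chol", "triglycerides", "antihypertensive_baseline",
                     "af", "ckd"]
EXTENDED_COLUMNS = ["insulin_baseline", "hba1c_mean", "diabetes_duration"]

SENSITIVITY_VARIANTS = (
    "sex:F", "sex:M", "age<=75", "age>75",
    "no_antihypertensives_after_entry",
    "baseline_antihypertensive:yes", "baseline_antihypertensive:no",
    "drop_events_first_12m_followup", "drop_events_first_24m_followup",
    "include_exposure_period_events",
)


@dataclass
class FlowCounts:
    """Patient-flow accounting; exclusion counts balance exactly."""

    n_input: int = 0
    n_no_entry: int = 0
    n_prior_hf: int = 0
    n_event_or_dropout_in_exposure_period: int = 0
    n_no_valid_sbp: int = 0
    n_final: int = 0
    per_category_n: list = field(default_factory=lambda: [0] * N_CATEGORIES)
    per_category_events: list = field(default_factory=lambda: [0] * N_CATEGORIES)

    def check_balance(self) -> None:
        total = (self.n_no_entry + self.n_prior_hf
                 + self.n_event_or_dropout_in_exposure_period
                 + self.n_no_valid_sbp + self.n_final)
        if total != self.n_input:
            raise AssertionError(
                f"flow counts do not balance: {total} != {self.n_input}")

    def to_dict(self) -> dict:
        return asdict(self)


def find_study_entry(patient: PatientRecord, config: StudyConfig) -> int | None:
    """Day of the first SBP measurement inside the calendar window with
    age in range; ``None`` if no measurement qualifies."""
    y0, y1 = config.entry_window
    day_lo = round((y0 - 1970) * DAYS_PER_YEAR)
    day_hi = round((y1 + 1 - 1970) * DAYS_PER_YEAR)  # window covers all of y1
    a0, a1 = config.age_range
    for day, _ in sorted(patient.sbp_measurements):
        if day_lo <= day < day_hi and a0 <= patient.age_at(day) <= a1:
            return day
    return None


def clean_sbp(measurements, pid=None, lo: float = 50.0, hi: float = 300.0):
    """Drop SBP values strictly below ``lo`` or above ``hi`` mm Hg
    (bounds themselves are retained); keep order."""
    out = []
    for i, (day, value) in enumerate(measurements):
        try:
            v = float(value)
        except (TypeError, ValueError):
            raise DataError(f"non-numeric SBP value {value!r} "
                            f"(pid={pid}, row={i})") from None
        if np.isnan(v):
            raise DataError(f"non-numeric SBP value {value!r} (pid={pid}, row={i})")
        if lo <= v <= hi:
            out.append((day, v))
    return out


def compute_baseline_exposure(patient: PatientRecord, entry_day: int,
                              config: StudyConfig) -> float | None:
    """Mean of cleaned SBP values in [entry, entry + exposure_period_days)."""
    lo, hi = config.sbp_valid
    vals = [v for d, v in clean_sbp(patient.sbp_measurements, patient.pid,
                                    lo=lo, hi=hi)
            if entry_day <= d < entry_day + config.exposure_period_days]
    return float(np.mean(vals)) if vals else None


def categorize_sbp(mean_sbp: float, config: StudyConfig) -> int:
    """Half-open bins [edge_i, edge_{i+1}); 0 for <120, 5 for >=160."""
    if not 50.0 <= mean_sbp <= 300.0:
        raise ValueError(f"mean SBP {mean_sbp} outside [50, 300]; "
                         "cleaning must precede categorization")
    return int(np.searchsorted(config.category_edges, mean_sbp, side="right"))


def _first_composite_event_day(patient: PatientRecord, lo: int, hi: int,
                               code_set=OUTCOME_CODES,
                               include_cv_death: bool = True) -> int | None:
    """Earliest composite-outcome day in the half-open-(lo, hi] interval;
    interval endpoints are used as given by callers."""
    days = [d for d, c, m in patient.events
            if m == "dx" and c in code_set and lo < d <= hi]
    if include_cv_death and patient.death_cause == CV_DEATH \
            and patient.death_day is not None and lo < patient.death_day <= hi:
        days.append(patient.death_day)
    return min(days) if days else None


def apply_exclusions(patient: PatientRecord, entry_day: int,
                     config: StudyConfig) -> tuple[bool, str | None]:
    """Eligibility after entry; reason is the first matching rule in order
    prior_hf -> event_in_exposure_period -> dropout_in_exposure_period."""
    if any(c == HF_CODE and m == "dx" and d < entry_day
           for d, c, m in patient.events):
        return False, "prior_hf"
    # events up to and including entry+365 precede the (strictly open)
    # follow-up start, so day 365 itself counts as exposure-period
    end = entry_day + config.exposure_period_days
    if _first_composite_event_day(patient, entry_day - 1, end) is not None:
        return False, "event_in_exposure_period"
    for day in (patient.censor_day, patient.death_day):
        if day is not None and entry_day <= day < end:
            return False, "dropout_in_exposure_period"
    return True, None


def ascertain_outcome(patient: PatientRecord, entry_day: int,
                      config: StudyConfig, code_set=OUTCOME_CODES,
                      include_cv_death: bool = True):
    """Binary outcome in the follow-up window (entry+365, entry+3650].

    Returns ``(outcome, event_day, censor_day)``. Patients censored before
    the window closes without an event get outcome 0 with the censoring day
    recorded — the binary-framework treatment of dropout.
    """
    lo = entry_day + config.followup_start_day
    hi = entry_day + config.followup_end_day
    ev = _first_composite_event_day(patient, lo, hi, code_set, include_cv_death)
    if ev is not None:
        return 1, ev, None
    censor = None
    for day in (patient.censor_day, patient.death_day):
        if day is not None and lo < day <= hi:
            censor = day if censor is None else min(censor, day)
    return 0, None, censor


def assign_folds(categories: np.ndarray, n_folds: int,
                 seed: int) -> np.ndarray:
    """Seeded fold assignment stratified on exposure category: within each
    category, a random permutation is dealt cyclically over folds, so fold
    sizes per category differ by at most one."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(categories), dtype=int)
    for cat in np.unique(categories):
        idx = np.flatnonzero(categories == cat)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


def build_cohort(patients: list[PatientRecord], config: StudyConfig,
                 fold_seed: int = 0,
                 include_exposure_period_events: bool = False
                 ) -> tuple[pd.DataFrame, FlowCounts]:
    """Apply entry -> cleaning -> exposure -> exclusions -> outcome in order.

    Returns the analysis-ready cohort (one row per patient) and the
    patient-flow accounting. ``include_exposure_period_events`` skips the
    exposure-period event exclusion (a sensitivity design).
    """
    flow = FlowCounts(n_input=len(patients))
    rows = []
    for p in patients:
        entry = find_study_entry(p, config)
        if entry is None:
            flow.n_no_entry += 1
            continue
        eligible, reason = apply_exclusions(p, entry, config)
        if not eligible and reason == "event_in_exposure_period" \
                and include_exposure_period_events:
            eligible, reason = True, None
            # dropout during the exposure period still excludes
            for day in (p.censor_day, p.death_day):
                if day is not None and entry <= day < entry + config.exposure_period_days:
                    eligible, reason = False, "dropout_in_exposure_period"
        if not eligible:
            if reason == "prior_hf":
                flow.n_prior_hf += 1
            else:
                flow.n_event_or_dropout_in_exposure_period += 1
            continue
        mean_sbp = compute_baseline_exposure(p, entry, config)
        if mean_sbp is None or not 50.0 <= mean_sbp <= 300.0:
            flow.n_no_valid_sbp += 1
            continue
        cat = categorize_sbp(mean_sbp, config)
        outcome, event_day, censor_day = ascertain_outcome(p, entry, config)
        cov = p.covariates
        rows.append({
            "pid": p.pid, "entry_day": entry, "exposure_cat": cat,
            "mean_sbp": mean_sbp, "age_at_entry": p.age_at(entry),
            "sex": p.sex, "smoking": p.smoking,
            "bmi": cov.get("bmi"), "hdl": cov.get("hdl"),
            "total_chol": cov.get("total_chol"),
            "triglycerides": cov.get("triglycerides"),
            "antihypertensive_baseline": cov.get("antihypertensive_baseline", 0),
            "af": cov.get("af", 0), "ckd": cov.get("ckd", 0),
            "insulin_baseline": cov.get("insulin_baseline", 0),
            "hba1c_mean": cov.get("hba1c_mean"),
            "diabetes_duration": cov.get("diabetes_duration"),
            "outcome": outcome, "event_day": event_day,
            "censor_day": censor_day,
        })
        flow.n_final += 1
        flow.per_category_n[cat] += 1
        flow.per_category_events[cat] += outcome
    if not rows:
        raise EmptyCohortError("no patient survived entry and exclusion rules")
    cohort = pd.DataFrame(rows)
    cohort["fold"] = assign_folds(cohort["exposure_cat"].to_numpy(),
                                  config.n_folds, fold_seed)
    flow.check_balance()
    return cohort, flow


def apply_sensitivity_filter(cohort: pd.DataFrame, variant: str,
                             patients: list[PatientRecord] | None = None,
                             config: StudyConfig | None = None,
                             fold_seed: int = 0) -> pd.DataFrame:
    """Return the cohort restricted/rebuilt per a named sensitivity design.

    ``include_exposure_period_events`` needs the pre-exclusion patient pool
    (``patients`` + ``config``); all other variants filter rows in place.
    """
    if variant == "sex:F":
        return cohort[cohort["sex"] == "F"].reset_index(drop=True)
    if variant == "sex:M":
        return cohort[cohort["sex"] == "M"].reset_index(drop=True)
    if variant == "age<=75":
        return cohort[cohort["age_at_entry"] <= 75.0].reset_index(drop=True)
    if variant == "age>75":
        return cohort[cohort["age_at_entry"] > 75.0].reset_index(drop=True)
    if variant == "baseline_antihypertensive:yes":
        return cohort[cohort["antihypertensive_baseline"] == 1].reset_index(drop=True)
    if variant == "baseline_antihypertensive:no":
        return cohort[cohort["antihypertensive_baseline"] == 0].reset_index(drop=True)
    if variant == "no_antihypertensives_after_entry":
        if patients is None:
            raise ValueError("variant needs the patient records")
        by_pid = {p.pid: p for p in patients}
        keep = []
        for _, row in cohort.iterrows():
            p = by_pid[row["pid"]]
            used_after = any(c == ANTIHTN_CODE and m == "rx" and d >= row["entry_day"]
                             for d, c, m in p.events)
            keep.append(not used_after)
        return cohort[np.asarray(keep)].reset_index(drop=True)
    if variant in ("drop_events_first_12m_followup", "drop_events_first_24m_followup"):
        months = 365 if variant.endswith("12m_followup") else 730
        cutoff = cohort["entry_day"] + 365 + months
        drop = (cohort["outcome"] == 1) & (cohort["event_day"] <= cutoff)
        return cohort[~drop].reset_index(drop=True)
    if variant == "include_exposure_period_events":
        if patients is None or config is None:
            raise ValueError("variant needs patients and config to rebuild")
        rebuilt, _ = build_cohort(patients, config, fold_seed=fold_seed,
                                  include_exposure_period_events=True)
        return rebuilt
    raise ValueError(f"unknown sensitivity variant {variant!r}")
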