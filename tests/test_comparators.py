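"""Crude RR, chained-equation imputation, adjusted LR, Cox comparator."""

import numpy as np
import pandas as pd
import pytest

from ehrcausal import SimConfig, StudyConfig, generate_population, build_cohort
from ehrcausal.comparators import (crude_rr, mice_impute, adjusted_lr_rr,
                                   cox_hazard_check, _median_fill,
                                   MAIN_COVARIATES)


def _toy_cohort(n1=100, n0=100, a=20, c=10, seed=0, folds=2):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n1):
        rows.append({"pid": i, "exposure_cat": 5, "outcome": int(i < a)})
    for i in range(n0):
        rows.append({"pid": n1 + i, "exposure_cat": 0, "outcome": int(i < c)})
    df = pd.DataFrame(rows)
    df["fold"] = rng.integers(0, folds, len(df))
    return df


class TestCrudeRR:
    def test_ratio_of_proportions(self):
        df = _toy_cohort(a=20, c=10)
        assert crude_rr(df, 5).rr == pytest.approx(2.0)

    def test_textbook_log_se(self):
        est = crude_rr(_toy_cohort(a=20, c=10), 5)
        assert est.log_se == pytest.approx(
            np.sqrt(1 / 20 - 1 / 100 + 1 / 10 - 1 / 100))

    def test_identical_groups_unit_rr(self):
        assert crude_rr(_toy_cohort(a=15, c=15), 5).rr == pytest.approx(1.0)

    def test_reference_row_has_no_ci(self):
        est = crude_rr(_toy_cohort(), 0)
        assert est.rr == 1.0 and est.ci_low is None and est.ci_high is None

    def test_zero_reference_events_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            crude_rr(_toy_cohort(c=0), 5)


@pytest.fixture(scope="module")
def missing_cohort():
    pats = generate_population(SimConfig(n_patients=700, seed=31))
    cohort, _ = build_cohort(pats, StudyConfig(), fold_seed=2)
    return cohort


class TestMICE:
    def test_no_missing_gives_identical_copies(self, missing_cohort):
        filled = _median_fill(missing_cohort, MAIN_COVARIATES)
        out = mice_impute(filled, m=3, iterations=2, seed=1)
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t, filled)

    def test_deterministic_given_seed(self, missing_cohort):
        a = mice_impute(missing_cohort, m=2, iterations=2, seed=5)
        b = mice_impute(missing_cohort, m=2, iterations=2, seed=5)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_completed_tables_have_no_missing(self, missing_cohort):
        out = mice_impute(missing_cohort, m=2, iterations=2, seed=3)
        for t in out:
            for c in ("bmi", "hdl", "total_chol", "triglycerides", "smoking"):
                assert not t[c].isna().any()
        # observed values untouched
        obs = missing_cohort["bmi"].notna()
        np.testing.assert_allclose(out[0].loc[obs, "bmi"],
                                   missing_cohort.loc[obs, "bmi"])

    def test_mcar_preserves_mean(self):
        """Under MCAR the pooled imputed mean tracks the complete-data mean
        (within 3 SE over replicates)."""
        rng = np.random.default_rng(8)
        diffs = []
        for rep in range(20):
            n = 500
            df = pd.DataFrame({
                "pid": np.arange(n),
                "age_at_entry": rng.uniform(50, 90, n),
                "sex": rng.choice(["F", "M"], n),
                "bmi": rng.normal(29, 4.5, n),
                "hdl": rng.normal(1.3, 0.3, n),
                "total_chol": rng.normal(5.2, 1.1, n),
                "triglycerides": rng.normal(1.9, 0.9, n),
                "smoking": rng.choice(["never", "former", "current"], n),
                "af": rng.integers(0, 2, n), "ckd": rng.integers(0, 2, n),
                "antihypertensive_baseline": rng.integers(0, 2, n),
                "exposure_cat": rng.integers(0, 6, n),
                "outcome": rng.integers(0, 2, n),
            })
            full_mean = df["bmi"].mean()
            df.loc[rng.random(n) < 0.2, "bmi"] = np.nan
            out = mice_impute(df, m=3, iterations=3, seed=rep)
            pooled = np.mean([t["bmi"].mean() for t in out])
            diffs.append(pooled - full_mean)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 0.05

    def test_fully_missing_column_rejected(self, missing_cohort):
        df = missing_cohort.copy()
        df["bmi"] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            mice_impute(df, m=1, iterations=1, seed=0)


@pytest.fixture(scope="module")
def filled_pair(missing_cohort):
    filled = _median_fill(missing_cohort, MAIN_COVARIATES)
    return filled[filled["exposure_cat"].isin([0, 5])].reset_index(drop=True)


class TestAdjustedLR:
    def test_exposure_only_model_reproduces_training_crude_rr(self, filled_pair):
        est = adjusted_lr_rr(filled_pair, None, "none", 5)
        for f in sorted(filled_pair["fold"].unique()):
            train = filled_pair[filled_pair["fold"] != f]
            assert est.extra["fold_rrs"][0][f] == pytest.approx(
                crude_rr(train, 5).rr, abs=1e-12)

    def test_binary_confounder_standardization_matches_two_level_closed_form(self):
        """Single binary confounder W: per fold, the standardized risk must
        equal the closed-form sum over W's two levels,
        psi_a = P_test(W=0) p(a,0) + P_test(W=1) p(a,1), with p from an
        independently fitted unpenalized logistic model."""
        import statsmodels.api as sm
        from scipy.special import expit as _expit
        rng = np.random.default_rng(2)
        n = 600
        W = rng.integers(0, 2, n)
        arm = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.15 + 0.25 * W + 0.1 * arm).astype(int)
        df = pd.DataFrame({"pid": np.arange(n), "exposure_cat": 5 * arm,
                           "outcome": y, "w": W.astype(float),
                           "fold": rng.integers(0, 2, n)})
        est = adjusted_lr_rr(df, None, ["w"], 5)
        for f in (0, 1):
            tr = df[df["fold"] != f]
            te = df[df["fold"] == f]
            X = np.column_stack([np.ones(len(tr)), tr["exposure_cat"] == 5,
                                 tr["w"]]).astype(float)
            beta = sm.GLM(tr["outcome"].to_numpy(), X,
                          family=sm.families.Binomial()).fit(tol=1e-12).params
            pw = np.array([(te["w"] == w).mean() for w in (0, 1)])
            p = lambda a, w: _expit(beta[0] + beta[1] * a + beta[2] * w)
            hand = (pw[0] * p(1, 0) + pw[1] * p(1, 1)) / \
                   (pw[0] * p(0, 0) + pw[1] * p(0, 1))
            assert est.extra["fold_rrs"][0][f] == pytest.approx(hand, abs=1e-10)

    def test_randomized_exposure_adjusted_close_to_crude(self):
        rng = np.random.default_rng(9)
        n = 4000
        X = rng.standard_normal(n)
        arm = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.5 * X + 0.2 * arm)))).astype(int)
        df = pd.DataFrame({"pid": np.arange(n), "exposure_cat": 5 * arm,
                           "outcome": y, "x": X,
                           "fold": rng.integers(0, 5, n)})
        adj = adjusted_lr_rr(df, None, ["x"], 5)
        cr = crude_rr(df, 5)
        assert adj.rr == pytest.approx(cr.rr, abs=3 * cr.log_se * cr.rr)

    def test_main_covariate_set_runs_and_orders_ci(self, filled_pair):
        est = adjusted_lr_rr(filled_pair, [filled_pair], "main", 5)
        assert est.ci_low <= est.rr <= est.ci_high
        assert est.method == "adjusted-lr-main"


class TestCox:
    @staticmethod
    def _exp_frame(rng, n=400, scale=1.0):
        arm = rng.integers(0, 2, n)
        t = rng.exponential(2.0, n) * np.exp(-0.4 * arm)
        c = rng.exponential(3.0, n)
        days = np.minimum((np.minimum(t, c) * 300 * scale).astype(int), 1500) + 366
        return pd.DataFrame({
            "pid": np.arange(n), "exposure_cat": 5 * arm, "entry_day": 0,
            "event_day": np.where(t <= c, days, np.nan),
            "censor_day": np.where(t > c, days, np.nan),
            "outcome": (t <= c).astype(int)})

    def test_time_scale_invariance(self):
        """Doubling every duration leaves the partial-likelihood HR
        unchanged (ranks are all that matter)."""
        rng = np.random.default_rng(21)
        df = self._exp_frame(rng)
        hr1, _, _, _ = cox_hazard_check(df, "none", 5)
        doubled = df.copy()
        for col in ("event_day", "censor_day"):
            doubled[col] = 2 * (doubled[col] - 365) + 365
        hr2, _, _, _ = cox_hazard_check(doubled, "none", 5)
        assert hr1 == pytest.approx(hr2, rel=1e-9)

    def test_partial_likelihood_matches_bruteforce_six_subjects(self):
        """Single covariate, no ties: the fitted coefficient maximizes the
        enumerated risk-set partial likelihood."""
        from scipy.optimize import minimize_scalar
        from lifelines import CoxPHFitter
        times = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([0.5, -0.2, 1.0, 0.0, 0.3, -0.5])
        df = pd.DataFrame({"duration": times, "event": event, "x": x})
        cph = CoxPHFitter().fit(df, "duration", "event")
        beta_ll = cph.params_["x"]

        def neg_pl(b):
            ll = 0.0
            for i in np.flatnonzero(event):
                risk = times >= times[i]
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return -ll

        brute = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                options={"xatol": 1e-12})
        # the two optimizers must agree on the maximized partial likelihood
        # to 1e-8 and on the coefficient to the fitter's own tolerance
        assert abs(neg_pl(beta_ll) - brute.fun) < 1e-8
        assert abs(beta_ll - brute.x) < 1e-3

    def test_null_survival_ci_covers_unity(self):
        """Exponential survival with no arm effect: the HR CI covers 1 in
        >= 90% of replicates."""
        rng = np.random.default_rng(15)
        covered = 0
        reps = 20
        for _ in range(reps):
            n = 800
            arm = rng.integers(0, 2, n)
            t = rng.exponential(10.0, n)
            c = rng.exponential(25.0, n)
            df = pd.DataFrame({
                "pid": np.arange(n), "exposure_cat": 5 * arm,
                "entry_day": 0,
                "event_day": np.where(t <= c, 365 + (t * 300).astype(int) + 1, np.nan),
                "censor_day": np.where(t > c, 365 + (c * 300).astype(int) + 1, np.nan),
                "outcome": (t <= c).astype(int),
            })
            hr, (lo, hi), _, _ = cox_hazard_check(df, "none", 5)
            covered += lo <= 1.0 <= hi
        assert covered >= int(0.9 * reps)

    def test_schoenfeld_outputs_present(self, filled_pair):
        hr, ci, p, resid = cox_hazard_check(filled_pair, "main", 5)
        assert 0.0 <= p <= 1.0
        assert {"time", "scaled_schoenfeld_arm"} <= set(resid.columns)
        assert len(resid) > 0
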