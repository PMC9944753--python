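"""Synthetic longitudinal EHR cohort with known causal ground truth.

Generates patients with a latent frailty ``U ~ N(0,1)`` that drives
comorbidity-code emission, mean systolic blood pressure and cardiovascular
outcome risk simultaneously, so that crude SBP-outcome contrasts are
confounded by construction. Potential outcome risks under all six exposure
categories are stored on every record *before* exposure is realized, giving
an exact oracle for the marginal risk ratios the estimators target.

Outputs round-trip losslessly through three delimited text files
(patients.csv, events.csv, measurements.csv) plus an aggregate ground-truth
sidecar (truth.json).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimConfig, DAYS_PER_YEAR

# Fixed category edges of the exposure (mm Hg); <120 is the reference.
CATEGORY_EDGES = (120.0, 130.0, 140.0, 150.0, 160.0)
N_CATEGORIES = 6

# Outcome-component diagnosis codes (composite = IHD + HF + stroke + CV death).
IHD_CODE = "d000"
HF_CODE = "d001"
STROKE_CODE = "d002"
OUTCOME_CODES = (IHD_CODE, HF_CODE, STROKE_CODE)
CV_DEATH = "cvd"
NON_CV_DEATH = "non_cvd"

ANTIHTN_CODE = "r000"
INSULIN_CODE = "r001"

# dx tokens whose emission probability is tied to the latent frailty.
FIRST_FRAILTY_CODE = 10

SMOKING_LEVELS = ("never", "former", "current")
SMOKING_PROBS = (0.61, 0.24, 0.15)

MISSING_RATES = {
    "bmi": 0.20, "hdl": 0.25, "total_chol": 0.20,
    "triglycerides": 0.25, "smoking": 0.10, "hba1c_mean": 0.451,
}


def dx_code(i: int) -> str:
    return f"d{i:03d}"


def rx_code(i: int) -> str:
    return f"r{i:03d}"


def categorize(mean_sbp: float) -> int:
    """Map an SBP value to its exposure category (0 = <120 ... 5 = >=160)."""
    return int(np.searchsorted(CATEGORY_EDGES, mean_sbp, side="right"))


@dataclass
class PatientRecord:
    """One simulated (or ingested) patient.

    ``events`` are (day, code, modality) triples sorted by day; modality is
    ``dx`` or ``rx``. ``sbp_measurements`` are (day, value mm Hg) pairs.
    ``latent_u`` and ``potential_risks`` are present only on synthetic
    records: the latter holds the patient's outcome risk under each of the
    six exposure categories, fixed before exposure realization.
    """

    pid: int
    sex: str
    birth_day: int
    smoking: Optional[str]
    covariates: dict = field(default_factory=dict)
    events: list = field(default_factory=list)
    sbp_measurements: list = field(default_factory=list)
    censor_day: Optional[int] = None
    death_day: Optional[int] = None
    death_cause: Optional[str] = None
    latent_u: Optional[float] = None
    potential_risks: Optional[tuple] = None

    def age_at(self, day: int) -> float:
        return (day - self.birth_day) / DAYS_PER_YEAR


def _smoking_dummies(smoking: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    former = (smoking == 1).astype(float)
    current = (smoking == 2).astype(float)
    return former, current


def _draw_risk_components(cfg: SimConfig, rng: np.random.Generator, n: int) -> dict:
    """Vectorized draw of everything upstream of exposure realization.

    Shared by the population generator and the Monte-Carlo oracle so both
    see the identical risk law.
    """
    lo, hi = cfg.age_range_years
    age = rng.uniform(lo, hi, n)
    sex_m = rng.random(n) < 0.55
    smoking = rng.choice(3, size=n, p=SMOKING_PROBS)
    u = rng.standard_normal(n)

    bmi = rng.normal(29.0 + 0.5 * u, 4.5)
    hdl = rng.normal(1.3 - 0.05 * u, 0.35)
    chol = rng.normal(5.2, 1.1, n)
    trig = rng.normal(1.9 + 0.1 * u, 0.9)
    af = rng.random(n) < expit(-2.6 + 0.4 * u + 0.04 * (age - 65.0))
    ckd = rng.random(n) < expit(-2.8 + 0.5 * u + 0.05 * (age - 65.0))

    # "onesided" confines the frailty->SBP shift to frail (U>0) patients,
    # the reverse-causation mechanism behind spurious low-SBP risk excess
    u_sbp = u if cfg.frailty_sbp_shape == "linear" else np.maximum(u, 0.0)
    mu_sbp = (cfg.sbp_mean
              + cfg.sbp_age_slope * (age - 65.0)
              + cfg.conf_strength * cfg.sbp_conf_slope * u_sbp
              + rng.normal(0.0, cfg.sbp_between_sd, n))
    antihtn = rng.random(n) < expit(-1.2 + 0.03 * (mu_sbp - 140.0))

    former, current = _smoking_dummies(smoking)
    ce = cfg.covariate_effects
    lin = (cfg.baseline_logodds
           + ce.get("age_std", 0.0) * (age - 65.0) / 10.0
           + ce.get("sex_M", 0.0) * sex_m
           + ce.get("smoking_former", 0.0) * former
           + ce.get("smoking_current", 0.0) * current
           + ce.get("bmi_std", 0.0) * (bmi - 29.0) / 4.5
           + ce.get("hdl_std", 0.0) * (hdl - 1.3) / 0.35
           + ce.get("total_chol_std", 0.0) * (chol - 5.2) / 1.1
           + ce.get("triglycerides_std", 0.0) * (trig - 1.9) / 0.9
           + ce.get("af", 0.0) * af
           + ce.get("ckd", 0.0) * ckd
           + ce.get("antihypertensive_baseline", 0.0) * antihtn)

    cat_eff = np.asarray(cfg.category_effects)
    # n x 6 matrix of potential risks: expit(lin + beta_a + beta_U * U)
    logits = lin[:, None] + cat_eff[None, :] + cfg.conf_strength * u[:, None]
    potential = expit(logits)

    realized_cat = np.searchsorted(
        CATEGORY_EDGES, np.clip(mu_sbp, 50.0, 300.0), side="right")
    y = rng.random(n) < potential[np.arange(n), realized_cat]

    return {
        "age": age, "sex_m": sex_m, "smoking": smoking, "u": u,
        "bmi": bmi, "hdl": hdl, "total_chol": chol, "triglycerides": trig,
        "af": af, "ckd": ckd, "antihtn": antihtn, "mu_sbp": mu_sbp,
        "potential": potential, "realized_cat": realized_cat, "y": y,
    }


def generate_population(cfg: SimConfig) -> list[PatientRecord]:
    """Simulate ``cfg.n_patients`` longitudinal records; deterministic given seed.

    Latent frailty confounds exposure and outcome; dropout and non-CV death
    are generated from observed covariates only (ignorable censoring) unless
    ``cfg.frailty_dropout`` adds a frailty term to the dropout hazard.
    """
    if cfg.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    comp = _draw_risk_components(cfg, rng, n)

    y0, y1 = cfg.entry_year_range
    entry_year = rng.uniform(y0, y1 + 1.0, n)
    # A small fraction of records fails eligibility (age or calendar window)
    # so that the cohort builder's entry logic is exercised on realistic input.
    inelig = rng.random(n) < cfg.ineligible_rate
    flip_age = rng.random(n) < 0.5
    age = comp["age"].copy()
    age[inelig & flip_age] = rng.uniform(42.0, 48.0, int((inelig & flip_age).sum()))
    entry_year[inelig & ~flip_age] = rng.uniform(
        y1 + 1.5, y1 + 4.0, int((inelig & ~flip_age).sum()))
    entry_day = np.round((entry_year - 1970.0) * DAYS_PER_YEAR).astype(int)
    birth_day = entry_day - np.round(age * DAYS_PER_YEAR).astype(int)

    insulin = rng.random(n) < 0.25
    hba1c = rng.normal(7.8 + 0.3 * comp["u"], 1.2)
    diab_dur = rng.exponential(6.0, n)

    # Censoring hazard from covariates (per-year), optionally frailty-linked.
    log_rate = (np.log(max(cfg.dropout_rate, 1e-12))
                + 0.20 * (comp["smoking"] == 2)
                + 0.01 * (age - 65.0))
    if cfg.frailty_dropout:
        log_rate = log_rate + cfg.frailty_dropout_strength * comp["u"]
    censor_offset = np.round(
        rng.exponential(1.0, n) / np.exp(log_rate) * DAYS_PER_YEAR).astype(int)

    event_offset = rng.integers(366, 3651, n)           # used only when y
    early = rng.random(n) < cfg.early_event_rate
    early_offset = rng.integers(30, 365, n)
    prior_hf = rng.random(n) < cfg.prior_hf_rate
    is_cv_death = rng.random(n) < 0.25                  # share of fatal events
    death_given_censor = rng.random(n) < 0.4

    miss = {k: rng.random(n) < r for k, r in MISSING_RATES.items()}

    event_kind = rng.choice(len(OUTCOME_CODES), size=n)
    frailty_codes = [dx_code(FIRST_FRAILTY_CODE + i) for i in range(cfg.n_frailty_codes)]
    other_dx = [dx_code(i) for i in range(3, cfg.vocab_size_dx)
                if not (FIRST_FRAILTY_CODE <= i < FIRST_FRAILTY_CODE + cfg.n_frailty_codes)]
    other_rx = [rx_code(i) for i in range(2, cfg.vocab_size_rx)]
    p_frail = expit(-3.0 + cfg.code_frailty_loading * comp["u"])
    p_prior_ihd = expit(-2.2 + 0.6 * comp["u"])

    # Gamma-Poisson visit counts: overdispersed, median near 10 with wide IQR,
    # matching routine primary-care contact patterns.
    lam = rng.gamma(1.3, cfg.visit_rate_pre_entry * 10.0 / 1.3, n)
    n_visits = rng.poisson(lam)

    records: list[PatientRecord] = []
    for i in range(n):
        e_day = int(entry_day[i])
        events: list[tuple[int, str, str]] = []

        # pre-entry coded history
        if n_visits[i] > 0:
            days = np.sort(rng.integers(e_day - 3650, e_day, n_visits[i]))
            for d in days:
                d = int(d)
                events.append((d, other_dx[int(rng.integers(len(other_dx)))], "dx"))
                for fc in frailty_codes:
                    if rng.random() < p_frail[i]:
                        events.append((d, fc, "dx"))
                if rng.random() < 0.4:
                    events.append((d, other_rx[int(rng.integers(len(other_rx)))], "rx"))
        if rng.random() < p_prior_ihd[i]:
            events.append((int(rng.integers(e_day - 3650, e_day)), IHD_CODE, "dx"))
        if prior_hf[i]:
            events.append((e_day - int(rng.integers(100, 2000)), HF_CODE, "dx"))
        if comp["antihtn"][i]:
            events.append((e_day - int(rng.integers(1, 365)), ANTIHTN_CODE, "rx"))
            # repeat prescription continuing after entry for most users
            if rng.random() < 0.8:
                events.append((e_day + int(rng.integers(30, 400)), ANTIHTN_CODE, "rx"))
        if insulin[i]:
            events.append((e_day - int(rng.integers(1, 365)), INSULIN_CODE, "rx"))

        # follow-up outcome / censoring
        c_off = int(censor_offset[i])
        censor_day = e_day + c_off if c_off <= 3650 else None
        death_day = None
        death_cause = None
        if comp["y"][i]:
            ev_off = int(event_offset[i])
            if censor_day is None or ev_off <= c_off:
                if is_cv_death[i]:
                    death_day = e_day + ev_off
                    death_cause = CV_DEATH
                    censor_day = None
                else:
                    events.append((e_day + ev_off, OUTCOME_CODES[int(event_kind[i])], "dx"))
                    censor_day = None
        if death_cause is None and censor_day is not None and death_given_censor[i]:
            death_day = censor_day
            death_cause = NON_CV_DEATH
        if early[i]:
            eo = int(early_offset[i])
            if censor_day is None or eo < (censor_day - e_day):
                events.append((e_day + eo, OUTCOME_CODES[int(event_kind[i])], "dx"))

        # SBP measurements over the two years from entry; first at entry day
        n_meas = 1 + rng.poisson(cfg.measurement_rate * 2.0)
        meas_days = np.concatenate(
            [[0], np.sort(rng.integers(1, 731, n_meas - 1))]) if n_meas > 1 else np.array([0])
        vals = rng.normal(comp["mu_sbp"][i], cfg.sbp_noise_sd, len(meas_days))
        gross = rng.random(len(vals)) < 0.01
        vals[gross] = np.where(rng.random(gross.sum()) < 0.5,
                               rng.uniform(10.0, 45.0, gross.sum()),
                               rng.uniform(305.0, 400.0, gross.sum()))
        sbp = [(e_day + int(d), float(v)) for d, v in zip(meas_days, vals)]

        cov = {
            "bmi": None if miss["bmi"][i] else float(comp["bmi"][i]),
            "hdl": None if miss["hdl"][i] else float(comp["hdl"][i]),
            "total_chol": None if miss["total_chol"][i] else float(comp["total_chol"][i]),
            "triglycerides": None if miss["triglycerides"][i] else float(comp["triglycerides"][i]),
            "af": int(comp["af"][i]),
            "ckd": int(comp["ckd"][i]),
            "antihypertensive_baseline": int(comp["antihtn"][i]),
            "insulin_baseline": int(insulin[i]),
            "hba1c_mean": None if miss["hba1c_mean"][i] else float(hba1c[i]),
            "diabetes_duration": float(diab_dur[i]),
        }

        events.sort(key=lambda t: (t[0], t[1]))
        records.append(PatientRecord(
            pid=i,
            sex="M" if comp["sex_m"][i] else "F",
            birth_day=int(birth_day[i]),
            smoking=None if miss["smoking"][i] else SMOKING_LEVELS[int(comp["smoking"][i])],
            covariates=cov,
            events=events,
            sbp_measurements=sbp,
            censor_day=censor_day,
            death_day=death_day,
            death_cause=death_cause,
            latent_u=float(comp["u"][i]),
            potential_risks=tuple(float(v) for v in comp["potential"][i]),
        ))
    return records


def oracle_true_rr(cfg: SimConfig, category: int, n_mc: int,
                   seed: int) -> tuple[float, float]:
    """True marginal risk ratio psi_a / psi_0 by fresh Monte-Carlo draws.

    Returns ``(rr, se)`` where the standard error comes from the delta
    method on the two correlated risk means. Category 0 returns (1.0, 0.0)
    exactly.
    """
    if not 0 <= category < N_CATEGORIES:
        raise ValueError(f"category must be in 0..5, got {category}")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if category == 0:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    comp = _draw_risk_components(cfg, rng, n_mc)
    pa = comp["potential"][:, category]
    p0 = comp["potential"][:, 0]
    psi_a, psi_0 = pa.mean(), p0.mean()
    rr = psi_a / psi_0
    cov = np.cov(pa, p0) / n_mc
    var_log = (cov[0, 0] / psi_a**2 + cov[1, 1] / psi_0**2
               - 2.0 * cov[0, 1] / (psi_a * psi_0))
    return float(rr), float(rr * np.sqrt(max(var_log, 0.0)))


def true_marginal_risks(cfg: SimConfig, n_mc: int, seed: int) -> np.ndarray:
    """Monte-Carlo true marginal risk per exposure category (length 6)."""
    rng = np.random.default_rng(seed)
    comp = _draw_risk_components(cfg, rng, n_mc)
    return comp["potential"].mean(axis=0)


def jshape_scenario(n_patients: int = 20_000, seed: int = 0) -> SimConfig:
    """Study conditions for the spurious-J-shape demonstration.

    An unmeasured frailty lowers SBP (one-sided: only frail patients are
    shifted down, the reverse-causation mechanism) while raising outcome
    risk, against a steeply monotone true risk gradient. Histories are
    dense (mean ~25 pre-entry visits) with ten strongly frailty-linked
    comorbidity tokens, so the coded history carries enough information
    about the latent confounder for a history-based estimator to remove
    the bias that covariate-free and covariate-only estimators cannot.
    The true gradient is steeper than a realistic SBP effect because the
    demonstration runs at a fraction of registry scale: contrast-level
    noise shrinks as 1/sqrt(n), so the scaled-down design raises the
    signal instead of the sample size.
    """
    return SimConfig(
        n_patients=n_patients, seed=seed,
        conf_strength=1.2, sbp_conf_slope=-16.0, frailty_sbp_shape="onesided",
        code_frailty_loading=3.0, n_frailty_codes=10,
        measurement_rate=6.0, visit_rate_pre_entry=2.5,
        category_effects=(0.0, 0.35, 0.7, 1.05, 1.4, 1.75),
    )


# ---------------------------------------------------------------------------
# delimited-text writers / readers (lossless round-trip)

_COV_COLS = ["bmi", "hdl", "total_chol", "triglycerides", "af", "ckd",
             "antihypertensive_baseline", "insulin_baseline", "hba1c_mean",
             "diabetes_duration"]
_INT_COV = {"af", "ckd", "antihypertensive_baseline", "insulin_baseline"}


def write_population(records: list[PatientRecord], outdir: str | Path,
                     cfg: SimConfig | None = None,
                     truth_mc: int = 200_000) -> None:
    """Write patients.csv / events.csv / measurements.csv (+ truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for r in records:
        row = {
            "pid": r.pid, "sex": r.sex, "birth_day": r.birth_day,
            "smoking": r.smoking, "censor_day": r.censor_day,
            "death_day": r.death_day, "death_cause": r.death_cause,
            "latent_u": r.latent_u,
        }
        row.update({c: r.covariates.get(c) for c in _COV_COLS})
        if r.potential_risks is not None:
            row.update({f"pr{a}": r.potential_risks[a] for a in range(N_CATEGORIES)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "patients.csv", index=False)

    ev = [(r.pid, d, c, m) for r in records for d, c, m in r.events]
    pd.DataFrame(ev, columns=["pid", "day", "code", "modality"]).to_csv(
        outdir / "events.csv", index=False)
    ms = [(r.pid, d, v) for r in records for d, v in r.sbp_measurements]
    pd.DataFrame(ms, columns=["pid", "day", "sbp"]).to_csv(
        outdir / "measurements.csv", index=False)

    if cfg is not None:
        risks = true_marginal_risks(cfg, truth_mc, cfg.seed + 991)
        truth = {
            "seed": cfg.seed,
            "true_marginal_risks": [float(v) for v in risks],
            "true_rr": [float(v / risks[0]) for v in risks],
            "config": cfg.to_dict(),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def _opt(v, conv=float):
    return None if pd.isna(v) else conv(v)


def read_population(indir: str | Path) -> list[PatientRecord]:
    indir = Path(indir)
    pats = pd.read_csv(indir / "patients.csv", float_precision="round_trip")
    evs = pd.read_csv(indir / "events.csv", float_precision="round_trip")
    meas = pd.read_csv(indir / "measurements.csv", float_precision="round_trip")
    ev_by = {pid: g for pid, g in evs.groupby("pid")}
    ms_by = {pid: g for pid, g in meas.groupby("pid")}

    records = []
    has_pr = "pr0" in pats.columns
    for _, p in pats.iterrows():
        pid = int(p["pid"])
        cov = {}
        for c in _COV_COLS:
            v = p.get(c)
            cov[c] = _opt(v, int if c in _INT_COV else float)
        g = ev_by.get(pid)
        events = ([(int(d), str(c), str(m)) for d, c, m in
                   zip(g["day"], g["code"], g["modality"])] if g is not None else [])
        g = ms_by.get(pid)
        sbp = ([(int(d), float(v)) for d, v in zip(g["day"], g["sbp"])]
               if g is not None else [])
        pr = (tuple(float(p[f"pr{a}"]) for a in range(N_CATEGORIES))
              if has_pr and not pd.isna(p["pr0"]) else None)
        records.append(PatientRecord(
            pid=pid, sex=str(p["sex"]), birth_day=int(p["birth_day"]),
            smoking=_opt(p["smoking"], str), covariates=cov,
            events=sorted(events, key=lambda t: (t[0], t[1])),
            sbp_measurements=sbp,
            censor_day=_opt(p["censor_day"], int),
            death_day=_opt(p["death_day"], int),
            death_cause=_opt(p["death_cause"], str),
            latent_u=_opt(p["latent_u"]),
            potential_risks=pr,
        ))
    return records
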