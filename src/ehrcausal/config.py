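"""Configuration objects for the simulation, study design, sequence model and pipeline.

All time quantities are integer day indices (day 0 = 1970-01-01); a year is
365.25 days and "12 months" is 365 days throughout, so that windows are
bit-exactly testable without a calendar library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

DAYS_PER_YEAR = 365.25
EXPOSURE_PERIOD_DAYS = 365
FOLLOWUP_END_DAYS = 3650


def _default_category_effects() -> tuple[float, ...]:
    # Monotone, modest log-odds gradient across the six SBP categories
    # (reference anchored at 0), of the magnitude seen for adjusted
    # cardiovascular risk gradients in diabetic cohorts.
    return (0.0, 0.03, 0.05, 0.08, 0.11, 0.17)


def _default_covariate_effects() -> dict[str, float]:
    return {
        "age_std": 0.50,
        "sex_M": 0.20,
        "smoking_former": 0.10,
        "smoking_current": 0.30,
        "bmi_std": 0.15,
        "hdl_std": -0.15,
        "total_chol_std": 0.10,
        "triglycerides_std": 0.10,
        "af": 0.50,
        "ckd": 0.40,
        "antihypertensive_baseline": 0.20,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic longitudinal EHR cohort generator.

    The generator emulates a primary/secondary-care-linked diabetic cohort:
    repeated SBP measurements clustered per patient, variable-length coded
    dx/rx histories, baseline covariates with missingness, a latent frailty
    ``U ~ N(0,1)`` that confounds SBP with cardiovascular outcome risk,
    covariate-driven dropout, and a composite cardiovascular outcome over a
    nine-year follow-up window.

    Parameters whose units matter:

    conf_strength
        beta_U, the additive log-odds of outcome per unit of latent frailty U.
        The same U also shifts the patient's latent mean SBP by
        ``conf_strength * sbp_conf_slope`` mm Hg, so setting it to 0 removes
        all confounding.
    sbp_conf_slope
        mm Hg of latent-mean-SBP shift per unit of (conf_strength * U).
        Positive: frail patients run high SBP (crude estimates biased up at
        high SBP). Negative: frailty lowers SBP while raising risk, the
        mechanism that produces a spurious J-shape at the low end.
    category_effects
        beta_a, additive outcome log-odds per exposure category; entry 0 is
        the <120 mm Hg reference and must be 0.
    measurement_rate
        expected SBP measurements per year after entry.
    dropout_rate
        per-year hazard of leaving the study (loss to follow-up / non-CV
        death pooled), chosen so roughly a quarter of the cohort is censored
        over the nine-year window.
    """

    n_patients: int = 2000
    seed: int = 0
    vocab_size_dx: int = 60
    vocab_size_rx: int = 20
    conf_strength: float = 0.8
    sbp_conf_slope: float = 8.0
    frailty_sbp_shape: str = "linear"  # or "onesided": only U>0 shifts SBP
    category_effects: tuple[float, ...] = field(default_factory=_default_category_effects)
    baseline_logodds: float = -1.1
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    sbp_mean: float = 141.0
    sbp_between_sd: float = 17.0
    sbp_age_slope: float = 0.3
    sbp_noise_sd: float = 10.0
    measurement_rate: float = 4.0
    dropout_rate: float = 0.040
    frailty_dropout: bool = False
    frailty_dropout_strength: float = 0.5
    early_event_rate: float = 0.03
    prior_hf_rate: float = 0.05
    ineligible_rate: float = 0.04
    visit_rate_pre_entry: float = 1.2
    code_frailty_loading: float = 1.0
    n_frailty_codes: int = 5
    entry_year_range: tuple[int, int] = (1990, 2005)
    age_range_years: tuple[float, float] = (50.0, 90.0)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.category_effects) != 6:
            raise ValueError("category_effects must have 6 entries")
        if self.category_effects[0] != 0.0:
            raise ValueError("category_effects[0] is the reference and must be 0")
        if self.sbp_noise_sd <= 0:
            raise ValueError("sbp_noise_sd must be > 0")
        for name in ("measurement_rate", "dropout_rate", "early_event_rate",
                     "prior_hf_rate", "ineligible_rate", "visit_rate_pre_entry"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_effects"] = list(self.category_effects)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["category_effects"] = tuple(d["category_effects"])
        d["entry_year_range"] = tuple(d["entry_year_range"])
        d["age_range_years"] = tuple(d["age_range_years"])
        return cls(**d)


@dataclass
class StudyConfig:
    """The study design: entry window, exposure rules, outcome window.

    Exposure is the mean of cleaned SBP values in the half-open window
    [entry, entry + exposure_period_days); follow-up is the half-open
    window (entry + followup_start_day, entry + followup_end_day].
    """

    entry_window: tuple[int, int] = (1990, 2005)
    age_range: tuple[float, float] = (50.0, 90.0)
    sbp_valid: tuple[float, float] = (50.0, 300.0)
    exposure_period_days: int = EXPOSURE_PERIOD_DAYS
    followup_start_day: int = EXPOSURE_PERIOD_DAYS
    followup_end_day: int = FOLLOWUP_END_DAYS
    category_edges: tuple[float, ...] = (120.0, 130.0, 140.0, 150.0, 160.0)
    n_folds: int = 5

    def __post_init__(self) -> None:
        edges = self.category_edges
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("category_edges must be strictly increasing")
        if self.followup_start_day >= self.followup_end_day:
            raise ValueError("followup_start_day must precede followup_end_day")

    @property
    def n_categories(self) -> int:
        return len(self.category_edges) + 1


@dataclass
class ModelConfig:
    """Hyperparameters of the compact EHR transformer.

    Defaults are sized for desk-scale experiments: a 2-layer, 4-head encoder
    with hidden width 96. ``mask_rate`` is the per-token masking probability
    of the masked-EHR-modeling objective; ``lambda_mem``, ``lambda_prop`` and
    ``lambda_out`` weight the masked-code, propensity and outcome losses in
    the joint objective; ``propensity_clip`` is the positivity truncation
    delta applied to held-out propensities.
    """

    layers: int = 2
    heads: int = 4
    hidden_size: int = 96
    intermediate_size: int = 192
    max_len: int = 256
    mask_rate: float = 0.15
    lambda_mem: float = 1.0
    lambda_prop: float = 1.0
    lambda_out: float = 1.0
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 3e-4
    seed: int = 0
    propensity_clip: float = 0.01
    valid_fraction: float = 0.1
    patience: int = 2
    pretrain_epochs: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size % self.heads != 0:
            raise ValueError("hidden_size must be divisible by heads")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must be in [0, 1]")
        if not 0.0 < self.propensity_clip < 0.5:
            raise ValueError("propensity_clip must be in (0, 0.5)")
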