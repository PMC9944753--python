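"""Cross-validated targeted maximum likelihood estimation of risk ratios.

Given held-out nuisance estimates — a clipped propensity ``g`` for the
non-reference arm and initial outcome risks ``q1, q0`` under each arm — the
targeting step fits a one-parameter logistic fluctuation with the clever
covariate ``H = A/g - (1-A)/(1-g)`` as offset regression, updates the
per-arm predictions, standardizes them over the whole cohort to marginal
risks, and reports the risk ratio with an efficient-influence-curve 95% CI.

Cross-fitted inputs (one model per held-out fold) are pooled and a single
fluctuation is fitted on the pooled set; per-fold targeting with averaged
risks is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

Z_95 = 1.959963984540054  # normal 97.5% quantile

_QEPS = 1e-12


class EstimationError(RuntimeError):
    pass


@dataclass
class TMLEInputs:
    """Per-patient arm, outcome and nuisance estimates for one contrast."""

    A: np.ndarray   # arm indicator, 1 = non-reference category
    Y: np.ndarray   # binary outcome
    g: np.ndarray   # clipped propensity of arm 1
    q1: np.ndarray  # initial risk under arm 1
    q0: np.ndarray  # initial risk under arm 0
    fold: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.q1 = np.clip(np.asarray(self.q1, dtype=float), _QEPS, 1 - _QEPS)
        self.q0 = np.clip(np.asarray(self.q0, dtype=float), _QEPS, 1 - _QEPS)
        if np.any((self.g <= 0) | (self.g >= 1)):
            raise EstimationError("propensities must lie strictly inside (0,1); "
                                  "clip upstream")

    @property
    def q_obs(self) -> np.ndarray:
        return np.where(self.A == 1, self.q1, self.q0)


@dataclass
class RREstimate:
    """A risk ratio with its 95% CI and targeting diagnostics."""

    rr: float
    ci_low: float | None
    ci_high: float | None
    log_se: float | None
    epsilon: float
    score_residual: float
    method: str
    contrast: str
    psi1: float
    psi0: float
    n1: int
    n0: int
    events1: int
    events0: int
    extra: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def clever_covariate(A: np.ndarray, g: np.ndarray):
    """Arm-specific clever covariates H1 = 1/g, H0 = -1/(1-g) and the
    observed-arm value H_obs = A/g - (1-A)/(1-g)."""
    A = np.asarray(A, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any((g <= 0.0) | (g >= 1.0)):
        raise EstimationError("propensity at 0 or 1; clipping must precede")
    H1 = 1.0 / g
    H0 = -1.0 / (1.0 - g)
    H_obs = A * H1 + (1.0 - A) * H0
    return H1, H0, H_obs


def fit_fluctuation(inputs: TMLEInputs, tol: float = 1e-10,
                    max_iter: int = 100) -> float:
    """Solve for the fluctuation coefficient epsilon by Newton iterations.

    epsilon maximizes the binomial log-likelihood of Y under
    ``expit(logit(q_obs) + eps * H_obs)`` (offset logistic regression with a
    single covariate, no intercept); convergence when the mean score drops
    below ``tol``.
    """
    _, _, H = clever_covariate(inputs.A, inputs.g)
    off = logit(inputs.q_obs)
    Y = inputs.Y
    eps = 0.0
    for _ in range(max_iter):
        p = expit(off + eps * H)
        score = np.mean(H * (Y - p))
        if abs(score) < tol:
            return float(eps)
        info = np.mean(H * H * p * (1.0 - p))
        if info <= 0:
            raise EstimationError(f"singular information in targeting step "
                                  f"(score={score:.3e})")
        eps = eps + score / info
    raise EstimationError(f"fluctuation did not converge after {max_iter} "
                          f"iterations (last score {score:.3e}, eps {eps:.3e})")


def update_predictions(inputs: TMLEInputs, epsilon: float):
    """Targeted predictions q_a* = expit(logit(q_a) + eps * H_a)."""
    H1, H0, _ = clever_covariate(inputs.A, inputs.g)
    q1s = expit(logit(inputs.q1) + epsilon * H1)
    q0s = expit(logit(inputs.q0) + epsilon * H0)
    return q1s, q0s


def marginal_risks(q1_star: np.ndarray, q0_star: np.ndarray):
    """Directly standardized risks: mean of each arm's prediction over the
    full cohort (both arms)."""
    if len(q1_star) == 0:
        raise EstimationError("empty cohort")
    return float(np.mean(q1_star)), float(np.mean(q0_star))


def rr_with_ci(inputs: TMLEInputs, q1_star: np.ndarray, q0_star: np.ndarray,
               epsilon: float = 0.0, method: str = "tmle",
               contrast: str = "") -> RREstimate:
    """Risk ratio psi1/psi0 with influence-curve CI on the log scale."""
    psi1, psi0 = marginal_risks(q1_star, q0_star)
    if psi0 <= 0.0:
        raise EstimationError("reference marginal risk is zero")
    A, Y, g = inputs.A, inputs.Y, inputs.g
    ic1 = (A / g) * (Y - q1_star) + q1_star - psi1
    ic0 = ((1.0 - A) / (1.0 - g)) * (Y - q0_star) + q0_star - psi0
    ic_log = ic1 / psi1 - ic0 / psi0
    n = len(Y)
    log_se = float(np.sqrt(np.var(ic_log, ddof=1) / n))
    rr = psi1 / psi0
    q_obs_star = np.where(A == 1, q1_star, q0_star)
    _, _, H = clever_covariate(A, g)
    return RREstimate(
        rr=float(rr),
        ci_low=float(rr * np.exp(-Z_95 * log_se)),
        ci_high=float(rr * np.exp(Z_95 * log_se)),
        log_se=log_se,
        epsilon=float(epsilon),
        score_residual=float(np.mean(H * (Y - q_obs_star))),
        method=method,
        contrast=contrast,
        psi1=psi1, psi0=psi0,
        n1=int((A == 1).sum()), n0=int((A == 0).sum()),
        events1=int(Y[A == 1].sum()), events0=int(Y[A == 0].sum()),
    )


def tmle_rr(inputs: TMLEInputs, contrast: str = "",
            method: str = "tmle", force_epsilon: float | None = None) -> RREstimate:
    """Single targeting pass: fluctuate, update, standardize, report.

    ``force_epsilon=0`` gives the untargeted g-computation plug-in of the
    initial outcome model (used for doubly-robust comparisons).
    """
    eps = fit_fluctuation(inputs) if force_epsilon is None else float(force_epsilon)
    q1s, q0s = update_predictions(inputs, eps)
    return rr_with_ci(inputs, q1s, q0s, epsilon=eps, method=method,
                      contrast=contrast)


def cv_tmle_rr(nuisances: pd.DataFrame, contrast: str = "",
               per_fold: bool = False, n_folds: int | None = None) -> RREstimate:
    """CV-TMLE over held-out nuisance estimates.

    ``nuisances`` must hold one row per patient with columns
    ``A, y, g, q1, q0, fold`` (the cross-fitting contract: each row's
    predictions come from the model trained without that row's fold).
    Default pools all folds and fits one fluctuation; ``per_fold`` targets
    each fold separately and averages the marginal risks.
    """
    req = {"A", "y", "g", "q1", "q0", "fold"}
    missing = req - set(nuisances.columns)
    if missing:
        raise ValueError(f"nuisance table lacks columns {sorted(missing)}")
    if nuisances["pid"].duplicated().any() if "pid" in nuisances.columns else False:
        raise ValueError("duplicate pid in nuisance table")
    folds = np.sort(nuisances["fold"].unique())
    if n_folds is not None and len(folds) != n_folds:
        raise ValueError(f"expected {n_folds} folds, found {len(folds)}; "
                         "held-out coverage is incomplete")

    if not per_fold:
        inputs = TMLEInputs(A=nuisances["A"].to_numpy(),
                            Y=nuisances["y"].to_numpy(),
                            g=nuisances["g"].to_numpy(),
                            q1=nuisances["q1"].to_numpy(),
                            q0=nuisances["q0"].to_numpy(),
                            fold=nuisances["fold"].to_numpy())
        return tmle_rr(inputs, contrast=contrast, method="cv-tmle")

    # per-fold variant: target within folds, average risks, pool ICs
    psi1s, psi0s, ics = [], [], []
    eps_list = []
    for f in folds:
        sub = nuisances[nuisances["fold"] == f]
        inputs = TMLEInputs(A=sub["A"].to_numpy(), Y=sub["y"].to_numpy(),
                            g=sub["g"].to_numpy(), q1=sub["q1"].to_numpy(),
                            q0=sub["q0"].to_numpy())
        eps = fit_fluctuation(inputs)
        eps_list.append(eps)
        q1s, q0s = update_predictions(inputs, eps)
        p1, p0 = marginal_risks(q1s, q0s)
        psi1s.append(p1)
        psi0s.append(p0)
        ic1 = (inputs.A / inputs.g) * (inputs.Y - q1s) + q1s - p1
        ic0 = ((1 - inputs.A) / (1 - inputs.g)) * (inputs.Y - q0s) + q0s - p0
        ics.append(ic1 / p1 - ic0 / p0)
    psi1, psi0 = float(np.mean(psi1s)), float(np.mean(psi0s))
    ic = np.concatenate(ics)
    n = len(ic)
    log_se = float(np.sqrt(np.var(ic, ddof=1) / n))
    rr = psi1 / psi0
    A = nuisances["A"].to_numpy()
    Y = nuisances["y"].to_numpy()
    return RREstimate(
        rr=float(rr), ci_low=float(rr * np.exp(-Z_95 * log_se)),
        ci_high=float(rr * np.exp(Z_95 * log_se)), log_se=log_se,
        epsilon=float(np.mean(eps_list)), score_residual=float("nan"),
        method="cv-tmle-perfold", contrast=contrast, psi1=psi1, psi0=psi0,
        n1=int((A == 1).sum()), n0=int((A == 0).sum()),
        events1=int(Y[A == 1].sum()), events0=int(Y[A == 0].sum()),
    )
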