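"""Cross-fitted logistic nuisance models on tabular features.

A fast alternative nuisance learner with the same held-out contract as the
transformer path: per fold, a logistic propensity model and a logistic
outcome model (arm included as a covariate, risks evaluated under both
arms) are fitted on the training folds and evaluated on the held-out fold.
Used for estimator-calibration studies, as a baseline nuisance option in
the pipeline, and wherever the nuisance functions are genuinely low
dimensional.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .synth import PatientRecord, dx_code, FIRST_FRAILTY_CODE


def _logreg(C: float = 1e6) -> LogisticRegression:
    return LogisticRegression(C=C, solver="lbfgs", max_iter=2000)


def crossfit_logistic_nuisances(X: np.ndarray, A: np.ndarray, Y: np.ndarray,
                                folds: np.ndarray, clip: float = 0.01,
                                pids: np.ndarray | None = None,
                                outcome_intercept_only: bool = False,
                                C: float = 1e6) -> pd.DataFrame:
    """Held-out (g, q1, q0) estimates from logistic regressions.

    ``outcome_intercept_only`` deliberately misspecifies the outcome model
    (empirical mean only), used to probe double robustness.
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    folds = np.asarray(folds)
    n = len(A)
    g = np.empty(n)
    q1 = np.empty(n)
    q0 = np.empty(n)
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        gm = _logreg(C).fit(X[tr], A[tr])
        g[te] = gm.predict_proba(X[te])[:, 1]
        if outcome_intercept_only:
            q1[te] = q0[te] = Y[tr].mean()
        else:
            Xa_tr = np.column_stack([X[tr], A[tr]])
            qm = _logreg(C).fit(Xa_tr, Y[tr])
            q1[te] = qm.predict_proba(np.column_stack([X[te], np.ones(te.sum())]))[:, 1]
            q0[te] = qm.predict_proba(np.column_stack([X[te], np.zeros(te.sum())]))[:, 1]
    out = pd.DataFrame({
        "pid": pids if pids is not None else np.arange(n),
        "fold": folds, "A": A.astype(int), "y": Y.astype(int),
        "g": np.clip(g, clip, 1.0 - clip),
        "q1": q1, "q0": q0,
    })
    return out


def frailty_history_features(patients: list[PatientRecord], cohort: pd.DataFrame,
                             n_frailty_codes: int = 10) -> np.ndarray:
    """Design matrix summarizing the frailty-linked part of the history.

    Per-code pre-entry counts, age, sex, log total pre-entry event volume,
    the empirical log-odds of a history token being frailty-linked (an
    approximately linear readout of the latent frailty), and the observed
    comorbidity/medication flags. This is the tabular summary a logistic
    nuisance model needs to absorb the confounding that the transformer
    reads directly from the sequence.
    """
    codes = [dx_code(FIRST_FRAILTY_CODE + i) for i in range(n_frailty_codes)]
    X = history_code_features(patients, cohort, codes=codes)
    by_pid = {p.pid: p for p in patients}
    tot = np.array([sum(1 for d, _, _ in by_pid[p].events if d < e)
                    for p, e in zip(cohort["pid"], cohort["entry_day"])], float)
    fr = X[:, :n_frailty_codes].sum(axis=1)
    flags = cohort[["af", "ckd", "antihypertensive_baseline"]].to_numpy(float)
    return np.column_stack([X, np.log1p(tot),
                            np.log((fr + 0.5) / (tot + 0.5)), flags])


def history_code_features(patients: list[PatientRecord], cohort: pd.DataFrame,
                          codes: list[str] | None = None,
                          window_days: int = 3650) -> np.ndarray:
    """Pre-entry code-count design matrix (plus age and sex) per cohort row.

    Default code set: the frailty-linked comorbidity tokens, i.e. the part
    of the coded history that proxies the latent confounder.
    """
    if codes is None:
        codes = [dx_code(FIRST_FRAILTY_CODE + i) for i in range(5)]
    by_pid = {p.pid: p for p in patients}
    rows = []
    for pid, entry, age, sex in zip(cohort["pid"], cohort["entry_day"],
                                    cohort["age_at_entry"], cohort["sex"]):
        p = by_pid[pid]
        counts = dict.fromkeys(codes, 0)
        for d, c, _ in p.events:
            if entry - window_days <= d < entry and c in counts:
                counts[c] += 1
        rows.append([counts[c] for c in codes] + [age, 1.0 if sex == "M" else 0.0])
    return np.asarray(rows, dtype=float)
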