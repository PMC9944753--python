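"""One-command pipeline, cohort summaries and forest-table reporting.

``run_pipeline`` chains simulate -> build cohort -> per-contrast nuisance
cross-fitting -> CV-TMLE -> comparators -> reports, writing every number
to JSON/CSV artifacts first; the forest renderer only reads those
artifacts. A single global seed fans out to per-stage seeds by fixed
offsets so any stage can be re-run reproducibly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, StudyConfig, ModelConfig
from . import synth
from .cohort import build_cohort, apply_sensitivity_filter, FlowCounts
from .sequences import Vocabulary, tokenize_history
from .training import train_crossfit, write_nuisances_jsonl
from .nuisance import crossfit_logistic_nuisances, history_code_features
from .tmle import cv_tmle_rr, RREstimate
from .comparators import (crude_rr, mice_impute, adjusted_lr_rr,
                          cox_hazard_check, IMPUTABLE_MAIN)

log = logging.getLogger("ehrcausal")

CATEGORY_LABELS = ["<120", "120-129", "130-139", "140-149", "150-159", ">=160"]
FOREST_COLUMNS = ["group", "events", "total", "method", "rr", "ci_low", "ci_high"]


def percentage(count: int, total: int) -> float:
    """Percentages as printed in cohort summaries: 100*count/total to 1 dp."""
    return round(100.0 * count / total, 1)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; sub-configs validate themselves."""

    sim: SimConfig = field(default_factory=SimConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    nuisance: str = "transformer"          # or "logistic"
    contrasts: tuple[int, ...] = (1, 2, 3, 4, 5)
    mice_m: int = 25
    mice_iterations: int = 10
    run_comparators: bool = True
    sensitivity_variants: tuple[str, ...] = ()
    seed: int = 0
    outdir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "sim" in raw:
            kw["sim"] = SimConfig.from_dict({**SimConfig().to_dict(), **raw["sim"]})
        if "study" in raw:
            kw["study"] = StudyConfig(**raw["study"])
        if "model" in raw:
            kw["model"] = ModelConfig(**raw["model"])
        for k in ("nuisance", "mice_m", "mice_iterations", "run_comparators",
                  "seed", "outdir"):
            if k in raw:
                kw[k] = raw[k]
        if "contrasts" in raw:
            kw["contrasts"] = tuple(raw["contrasts"])
        if "sensitivity_variants" in raw:
            kw["sensitivity_variants"] = tuple(raw["sensitivity_variants"])
        return cls(**kw)


def summarize_cohort(cohort: pd.DataFrame, flow: FlowCounts) -> pd.DataFrame:
    """Per-category n, events, event %, censored %, median follow-up years."""
    rows = []
    for cat in range(6):
        sub = cohort[cohort["exposure_cat"] == cat]
        n = len(sub)
        events = int(sub["outcome"].sum())
        censored = int(sub["censor_day"].notna().sum())
        fu_end = np.where(sub["outcome"] == 1, sub["event_day"],
                          np.where(sub["censor_day"].notna(), sub["censor_day"],
                                   sub["entry_day"] + 3650))
        median_fu = float(np.median((fu_end - sub["entry_day"]) / 365.25)) if n else 0.0
        rows.append({
            "category": CATEGORY_LABELS[cat], "n": n, "events": events,
            "event_pct": percentage(events, n) if n else 0.0,
            "censored_pct": percentage(censored, n) if n else 0.0,
            "median_followup_years": round(median_fu, 2),
        })
    total_events = int(cohort["outcome"].sum())
    total_censored = int(cohort["censor_day"].notna().sum())
    rows.append({
        "category": "all", "n": len(cohort), "events": total_events,
        "event_pct": percentage(total_events, len(cohort)),
        "censored_pct": percentage(total_censored, len(cohort)),
        "median_followup_years": np.nan,
    })
    return pd.DataFrame(rows)


def render_forest_table(estimates: dict[str, dict[int, dict]],
                        cohort: pd.DataFrame | None = None,
                        plot_path: str | Path | None = None) -> pd.DataFrame:
    """Forest table: 6 exposure rows per method, reference row without CI.

    ``estimates[method][category]`` is an RREstimate dict; a missing
    contrast yields an explicit gap row (NaN estimate, method suffixed
    ``/missing``) rather than a silent omission.
    """
    rows = []
    for method, per_cat in estimates.items():
        for cat in range(6):
            group = CATEGORY_LABELS[cat]
            if cohort is not None:
                sub = cohort[cohort["exposure_cat"] == cat]
                events, total = int(sub["outcome"].sum()), len(sub)
            else:
                events = total = np.nan
            if cat == 0:
                rows.append({"group": group, "events": events, "total": total,
                             "method": method, "rr": 1.0,
                             "ci_low": np.nan, "ci_high": np.nan})
            elif cat in per_cat:
                e = per_cat[cat]
                rows.append({"group": group, "events": events, "total": total,
                             "method": method, "rr": e["rr"],
                             "ci_low": e["ci_low"], "ci_high": e["ci_high"]})
            else:
                rows.append({"group": group, "events": events, "total": total,
                             "method": f"{method}/missing", "rr": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan})
    table = pd.DataFrame(rows, columns=FOREST_COLUMNS)
    if plot_path is not None:
        _plot_forest(table, plot_path)
    return table


def _plot_forest(table: pd.DataFrame, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = [m for m in table["method"].unique() if not m.endswith("/missing")]
    fig, ax = plt.subplots(figsize=(7, 0.5 + 0.35 * 6 * max(len(methods), 1)))
    ypos = 0
    yticks, ylabels = [], []
    for m in methods:
        sub = table[table["method"] == m]
        for _, row in sub.iterrows():
            if np.isfinite(row["rr"]):
                ax.plot(row["rr"], ypos, "s", color="k", ms=4)
                if np.isfinite(row["ci_low"]):
                    ax.plot([row["ci_low"], row["ci_high"]], [ypos, ypos],
                            "-", color="k", lw=1)
            yticks.append(ypos)
            ylabels.append(f"{m}: {row['group']}")
            ypos += 1
        ypos += 1
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("risk ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
def _transformer_nuisances(cohort_pair, patients_by_pid, model_cfg, vocab,
                           category):
    seqs = {}
    for pid, entry in zip(cohort_pair["pid"], cohort_pair["entry_day"]):
        seqs[pid] = tokenize_history(patients_by_pid[pid], int(entry), vocab,
                                     model_cfg.max_len)
    return train_crossfit(cohort_pair, seqs, model_cfg, vocab, category)


def _logistic_nuisances(cohort_pair, patients, model_cfg, category):
    X = history_code_features(patients, cohort_pair)
    A = (cohort_pair["exposure_cat"] == category).to_numpy().astype(float)
    Y = cohort_pair["outcome"].to_numpy().astype(float)
    return crossfit_logistic_nuisances(
        X, A, Y, cohort_pair["fold"].to_numpy(),
        clip=model_cfg.propensity_clip, pids=cohort_pair["pid"].to_numpy())


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Bit-identical outputs under a fixed config (all randomness flows from
    ``config.seed`` by fixed per-stage offsets).
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    seed = config.seed

    log.info("stage=simulate seed=%d n=%d", seed, config.sim.n_patients)
    sim_cfg = SimConfig(**{**config.sim.to_dict(), "seed": seed})
    sim_cfg.covariate_effects = dict(config.sim.covariate_effects)
    patients = synth.generate_population(sim_cfg)
    synth.write_population(patients, outdir / "data", sim_cfg, truth_mc=100_000)
    patients_by_pid = {p.pid: p for p in patients}

    log.info("stage=build_cohort")
    cohort, flow = build_cohort(patients, config.study, fold_seed=seed + 1)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    (outdir / "flow.json").write_text(json.dumps(flow.to_dict(), indent=2))

    vocab = Vocabulary.from_records(patients)
    estimates: dict[str, dict[int, dict]] = {"cv-tmle": {}}
    comparator_results: dict[str, dict[int, dict]] = {}

    imputations = None
    if config.run_comparators:
        log.info("stage=mice m=%d", config.mice_m)
        imputations = mice_impute(cohort, m=config.mice_m,
                                  iterations=config.mice_iterations,
                                  seed=seed + 100, imputable=IMPUTABLE_MAIN)
        comparator_results = {"crude": {}, "adjusted-lr": {}, "cox": {}}

    for cat in config.contrasts:
        log.info("stage=contrast category=%d nuisance=%s", cat, config.nuisance)
        pair = cohort[cohort["exposure_cat"].isin([0, cat])].reset_index(drop=True)
        model_cfg = ModelConfig(**{**config.model.__dict__,
                                   "seed": seed + 10 * cat + 2})
        if config.nuisance == "transformer":
            nuis = _transformer_nuisances(pair, patients_by_pid, model_cfg,
                                          vocab, cat)
        elif config.nuisance == "logistic":
            nuis = _logistic_nuisances(pair, patients, model_cfg, cat)
        else:
            raise ValueError(f"unknown nuisance learner {config.nuisance!r}")
        write_nuisances_jsonl(nuis, outdir / f"nuisances_cat{cat}.jsonl")
        est = cv_tmle_rr(nuis, contrast=f"cat{cat}_vs_cat0",
                         n_folds=config.study.n_folds)
        estimates["cv-tmle"][cat] = est.to_dict()

        if config.run_comparators:
            comparator_results["crude"][cat] = crude_rr(cohort, cat).to_dict()
            imp_pairs = [t[t["exposure_cat"].isin([0, cat])].reset_index(drop=True)
                         for t in imputations]
            comparator_results["adjusted-lr"][cat] = adjusted_lr_rr(
                pair, imp_pairs, covariate_set="main", category=cat).to_dict()
            hr, ci, p_sch, resid = cox_hazard_check(imp_pairs[0], "main", cat)
            comparator_results["cox"][cat] = {
                "rr": hr, "ci_low": ci[0], "ci_high": ci[1],
                "schoenfeld_p": p_sch, "method": "cox",
                "contrast": f"cat{cat}_vs_cat0"}
            resid.to_csv(outdir / f"schoenfeld_cat{cat}.csv", index=False)

    (outdir / "estimates.json").write_text(json.dumps(estimates, indent=2))
    if comparator_results:
        (outdir / "comparators.json").write_text(
            json.dumps(comparator_results, indent=2))

    for variant in config.sensitivity_variants:
        log.info("stage=sensitivity variant=%s", variant)
        sub = apply_sensitivity_filter(cohort, variant, patients=patients,
                                       config=config.study, fold_seed=seed + 1)
        var_est = {}
        for cat in config.contrasts:
            pairv = sub[sub["exposure_cat"].isin([0, cat])].reset_index(drop=True)
            if pairv["exposure_cat"].nunique() < 2:
                continue
            var_est[cat] = cv_tmle_rr(
                _logistic_nuisances(pairv, patients, config.model, cat),
                contrast=f"cat{cat}_vs_cat0").to_dict()
        safe = variant.replace(":", "_").replace("<", "le").replace(">", "gt")
        (outdir / f"sensitivity_{safe}.json").write_text(json.dumps(var_est, indent=2))

    summary = summarize_cohort(cohort, flow)
    summary.to_csv(outdir / "summary.csv", index=False)
    all_methods = {**estimates, **comparator_results}
    table = render_forest_table(all_methods, cohort,
                                plot_path=outdir / "forest.png")
    table.to_csv(outdir / "forest.csv", index=False)
    log.info("pipeline done in %.1fs -> %s", time.time() - t0, outdir)
    return outdir
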