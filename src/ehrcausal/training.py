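"""Cross-fitted nuisance estimation with the EHR transformer.

For one pairwise contrast (reference SBP category vs one comparison
category), trains one model per fold on the remaining folds and predicts
propensity and per-arm outcome risk on the held-out fold, so every
patient's nuisance estimates come from a model that never saw them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .nn import EHRTransformer, Adam
from .sequences import TokenSequence, Vocabulary, mask_tokens, pad_batch


class DegenerateFoldError(RuntimeError):
    """A training fold carries a single exposure arm or a single outcome."""


NUISANCE_COLUMNS = ["pid", "fold", "A", "y", "g", "q1", "q0"]


def write_nuisances_jsonl(nuisances: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in nuisances[NUISANCE_COLUMNS].itertuples(index=False):
            fh.write(json.dumps({
                "pid": int(row.pid), "fold": int(row.fold), "A": int(row.A),
                "y": int(row.y), "g": float(row.g), "q1": float(row.q1),
                "q0": float(row.q0)}) + "\n")


def read_nuisances_jsonl(path: str | Path) -> pd.DataFrame:
    rows = [json.loads(line) for line in open(path) if line.strip()]
    return pd.DataFrame(rows, columns=NUISANCE_COLUMNS)


def _epoch_batches(idx: np.ndarray, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(idx)
    for start in range(0, len(order), batch_size):
        yield order[start:start + batch_size]


def _make_batch(seqs, arm, y, cfg: ModelConfig, vocab: Vocabulary,
                mask_seed: int | None):
    if mask_seed is not None and cfg.mask_rate > 0:
        seqs = [mask_tokens(s, cfg.mask_rate, mask_seed + 7919 * i, vocab)
                for i, s in enumerate(seqs)]
    batch = pad_batch(seqs)
    batch["arm"] = np.asarray(arm, dtype=float)
    batch["y"] = np.asarray(y, dtype=float)
    return batch


def _eval_loss(model: EHRTransformer, seqs, arm, y, cfg, vocab, seed) -> float:
    total, n = 0.0, 0
    for start in range(0, len(seqs), cfg.batch_size):
        sl = slice(start, start + cfg.batch_size)
        batch = _make_batch(seqs[sl], arm[sl], y[sl], cfg, vocab, None)
        losses, _ = model.loss_and_grads(batch, compute_grads=False)
        b = len(arm[sl])
        total += (losses["prop"] + losses["out"]) * b
        n += b
    return total / max(n, 1)


def train_one_model(seqs: list[TokenSequence], arm: np.ndarray, y: np.ndarray,
                    cfg: ModelConfig, vocab: Vocabulary,
                    seed: int) -> EHRTransformer:
    """Train a joint model on one training split with early stopping on an
    inner validation split (propensity + outcome loss)."""
    rng = np.random.default_rng(seed)
    model_cfg = ModelConfig(**{**cfg.__dict__, "seed": seed})
    model = EHRTransformer(model_cfg, vocab_size=len(vocab))
    opt = Adam(model.params, lr=cfg.learning_rate)

    n = len(seqs)
    n_val = max(1, int(round(cfg.valid_fraction * n))) if n >= 20 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    seqs_arr = np.asarray(seqs, dtype=object)
    val_seqs = list(seqs_arr[val_idx])
    val_arm, val_y = arm[val_idx], y[val_idx]

    # optional MEM-only pretraining phase
    for epoch in range(cfg.pretrain_epochs):
        for bi, bidx in enumerate(_epoch_batches(train_idx, cfg.batch_size, rng)):
            batch = _make_batch(list(seqs_arr[bidx]), arm[bidx], y[bidx],
                                cfg, vocab, mask_seed=seed + 101 * epoch + bi)
            batch.pop("arm"), batch.pop("y")
            _, grads = model.loss_and_grads(batch)
            opt.step(model.params, grads)

    best_loss, best_params, bad = np.inf, None, 0
    for epoch in range(cfg.epochs):
        for bi, bidx in enumerate(_epoch_batches(train_idx, cfg.batch_size, rng)):
            batch = _make_batch(list(seqs_arr[bidx]), arm[bidx], y[bidx],
                                cfg, vocab, mask_seed=seed + 313 * epoch + bi)
            _, grads = model.loss_and_grads(batch)
            opt.step(model.params, grads)
        if n_val > 0:
            vl = _eval_loss(model, val_seqs, val_arm, val_y, cfg, vocab, seed)
            if vl < best_loss - 1e-6:
                best_loss = vl
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad = 0
            else:
                bad += 1
                if bad > cfg.patience:
                    break
    if best_params is not None:
        model.params = best_params
    return model


def train_crossfit(cohort_pair: pd.DataFrame, sequences: dict[int, TokenSequence],
                   cfg: ModelConfig, vocab: Vocabulary,
                   comparison_category: int) -> pd.DataFrame:
    """Held-out nuisance estimates for one contrast by k-fold cross-fitting.

    ``cohort_pair`` must contain only the reference category (0) and
    ``comparison_category``, with a ``fold`` column. Returns one row per
    patient with columns pid, fold, A, y, g, q1, q0; the propensity g is
    clipped to [delta, 1-delta]. Deterministic given ``cfg.seed``.
    """
    cats = set(cohort_pair["exposure_cat"].unique())
    if not cats <= {0, comparison_category}:
        raise ValueError(f"cohort subset contains categories {sorted(cats)}; "
                         f"expected only 0 and {comparison_category}")
    folds = np.sort(cohort_pair["fold"].unique())
    arm_all = (cohort_pair["exposure_cat"] == comparison_category).to_numpy().astype(float)
    y_all = cohort_pair["outcome"].to_numpy().astype(float)
    pid_all = cohort_pair["pid"].to_numpy()
    fold_all = cohort_pair["fold"].to_numpy()
    seq_all = np.asarray([sequences[p] for p in pid_all], dtype=object)

    out = []
    for f in folds:
        tr = fold_all != f
        te = ~tr
        if len(np.unique(arm_all[tr])) < 2 or len(np.unique(y_all[tr])) < 2:
            raise DegenerateFoldError(
                f"training folds != {f} carry a single exposure arm or outcome class")
        model = train_one_model(list(seq_all[tr]), arm_all[tr], y_all[tr],
                                cfg, vocab, seed=cfg.seed + 1000 * int(f) + 17)
        g_list, q1_list, q0_list = [], [], []
        te_idx = np.flatnonzero(te)
        for start in range(0, len(te_idx), cfg.batch_size):
            bidx = te_idx[start:start + cfg.batch_size]
            batch = pad_batch(list(seq_all[bidx]))
            pred = model.predict(batch)
            g_list.append(pred["g"])
            q1_list.append(pred["q1"])
            q0_list.append(pred["q0"])
        g = np.clip(np.concatenate(g_list), cfg.propensity_clip,
                    1.0 - cfg.propensity_clip)
        out.append(pd.DataFrame({
            "pid": pid_all[te_idx], "fold": int(f),
            "A": arm_all[te_idx].astype(int), "y": y_all[te_idx].astype(int),
            "g": g, "q1": np.concatenate(q1_list), "q0": np.concatenate(q0_list),
        }))
    res = pd.concat(out, ignore_index=True)
    assert res["pid"].is_unique and len(res) == len(cohort_pair)
    return res
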