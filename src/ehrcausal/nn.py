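"""A compact bidirectional transformer encoder over coded EHR sequences.

Pure-numpy implementation (forward and analytic backward passes) of a
pre-layer-norm BERT-style encoder with token/age/segment/position
embeddings, a masked-code prediction head over the full vocabulary, and a
pooled CLS representation feeding three logistic heads: a propensity head
(probability of the non-reference exposure arm) and two arm-specific
outcome-risk heads, so the joint objective

    L = lambda_mem * CE(masked codes) + lambda_prop * BCE(arm)
        + lambda_out * BCE(outcome | observed arm)

is optimized end to end with Adam. Gradients are exact (checked against
finite differences in the test suite); everything is float64 and
deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit

from .config import ModelConfig
from .sequences import IGNORE_LABEL, MAX_AGE

_LN_EPS = 1e-5
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(u):
    phi = 0.5 * (1.0 + erf(u / _SQRT2))
    return u * phi, phi


def _gelu_grad(u, phi):
    return phi + u * np.exp(-0.5 * u * u) * _INV_SQRT_2PI


def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(-1, keepdims=True) + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _ln_bwd(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxh = dy * g
    dx = inv * (dxh - dxh.mean(-1, keepdims=True)
                - xhat * (dxh * xhat).mean(-1, keepdims=True))
    return dx, dg, db


class EHRTransformer:
    """Joint propensity/outcome/masked-code model; one instance per contrast."""

    def __init__(self, config: ModelConfig, vocab_size: int):
        self.cfg = config
        self.V = vocab_size
        d, m = config.hidden_size, config.intermediate_size
        rng = np.random.default_rng(config.seed)

        def w(*shape):
            return rng.normal(0.0, 0.02, shape)

        p = {
            "Etok": w(vocab_size, d),
            "Eage": w(MAX_AGE + 1, d),
            "Eseg": w(2, d),
            "Epos": w(config.max_len + 1, d),
            "ln_in_g": np.ones(d), "ln_in_b": np.zeros(d),
            "ln_f_g": np.ones(d), "ln_f_b": np.zeros(d),
            "W_mem": w(d, vocab_size), "b_mem": np.zeros(vocab_size),
            "W_pool": w(d, d), "b_pool": np.zeros(d),
            "w_g": w(d), "b_g": np.zeros(()),
            "w_q1": w(d), "b_q1": np.zeros(()),
            "w_q0": w(d), "b_q0": np.zeros(()),
        }
        for layer in range(config.layers):
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{nm}{layer}"] = w(d, d)
                p[f"{nm.replace('W', 'b')}{layer}"] = np.zeros(d)
            p[f"W1{layer}"] = w(d, m)
            p[f"b1{layer}"] = np.zeros(m)
            p[f"W2{layer}"] = w(m, d)
            p[f"b2{layer}"] = np.zeros(d)
            for nm in ("ln1", "ln2"):
                p[f"{nm}_g{layer}"] = np.ones(d)
                p[f"{nm}_b{layer}"] = np.zeros(d)
        self.params = p

    # ------------------------------------------------------------------
    def _encode(self, batch):
        """Forward pass of the encoder; returns final hidden states + cache."""
        p = self.params
        cfg = self.cfg
        d = cfg.hidden_size
        nh = cfg.heads
        dh = d // nh
        tok = batch["tokens"]
        B, T = tok.shape
        if T > cfg.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {cfg.max_len}")
        pos = np.minimum(batch["positions"], cfg.max_len)
        age = np.minimum(batch["ages"], MAX_AGE)

        emb = (p["Etok"][tok] + p["Eage"][age]
               + p["Eseg"][batch["segments"]] + p["Epos"][pos])
        x, ln_in_cache = _ln_fwd(emb, p["ln_in_g"], p["ln_in_b"])

        # additive attention mask: -inf on PAD keys
        bias = np.where(batch["attn"], 0.0, -1e30)[:, None, None, :]
        scale = 1.0 / np.sqrt(dh)
        caches = []
        for layer in range(cfg.layers):
            h1, c_ln1 = _ln_fwd(x, p[f"ln1_g{layer}"], p[f"ln1_b{layer}"])
            Q = (h1 @ p[f"Wq{layer}"] + p[f"bq{layer}"]).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            K = (h1 @ p[f"Wk{layer}"] + p[f"bk{layer}"]).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            Vv = (h1 @ p[f"Wv{layer}"] + p[f"bv{layer}"]).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            S = Q @ K.transpose(0, 1, 3, 2) * scale + bias
            S = S - S.max(-1, keepdims=True)
            A = np.exp(S)
            A /= A.sum(-1, keepdims=True)
            C = (A @ Vv).transpose(0, 2, 1, 3).reshape(B, T, d)
            O = C @ p[f"Wo{layer}"] + p[f"bo{layer}"]
            x2 = x + O
            h2, c_ln2 = _ln_fwd(x2, p[f"ln2_g{layer}"], p[f"ln2_b{layer}"])
            u = h2 @ p[f"W1{layer}"] + p[f"b1{layer}"]
            a, phi = _gelu(u)
            f = a @ p[f"W2{layer}"] + p[f"b2{layer}"]
            x3 = x2 + f
            caches.append((x, h1, c_ln1, Q, K, Vv, A, C, x2, h2, c_ln2, u, phi, a))
            x = x3
        hfin, c_lnf = _ln_fwd(x, p["ln_f_g"], p["ln_f_b"])
        cache = {"emb_inputs": (tok, age, batch["segments"], pos),
                 "ln_in": ln_in_cache, "layers": caches, "ln_f": c_lnf,
                 "shape": (B, T, nh, dh), "scale": scale}
        return hfin, cache

    def _decode_bwd(self, dhfin, cache, grads):
        """Backward pass through final LN, layers and embeddings."""
        p = self.params
        cfg = self.cfg
        B, T, nh, dh = cache["shape"]
        d = cfg.hidden_size
        scale = cache["scale"]

        dx, dg, db = _ln_bwd(dhfin, cache["ln_f"], p["ln_f_g"])
        grads["ln_f_g"] += dg
        grads["ln_f_b"] += db

        for layer in reversed(range(cfg.layers)):
            (x, h1, c_ln1, Q, K, Vv, A, C, x2, h2, c_ln2, u, phi, a) = cache["layers"][layer]
            # FFN branch
            df = dx                       # dx3 wrt f
            da = df @ p[f"W2{layer}"].T
            grads[f"W2{layer}"] += a.reshape(-1, a.shape[-1]).T @ df.reshape(-1, d)
            grads[f"b2{layer}"] += df.sum((0, 1))
            du = da * _gelu_grad(u, phi)
            dh2 = du @ p[f"W1{layer}"].T
            grads[f"W1{layer}"] += h2.reshape(-1, d).T @ du.reshape(-1, du.shape[-1])
            grads[f"b1{layer}"] += du.sum((0, 1))
            dx2_ln, dg, db = _ln_bwd(dh2, c_ln2, p[f"ln2_g{layer}"])
            grads[f"ln2_g{layer}"] += dg
            grads[f"ln2_b{layer}"] += db
            dx2 = dx + dx2_ln
            # attention branch
            dO = dx2
            dC = (dO @ p[f"Wo{layer}"].T).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            grads[f"Wo{layer}"] += C.reshape(-1, d).T @ dO.reshape(-1, d)
            grads[f"bo{layer}"] += dO.sum((0, 1))
            dA = dC @ Vv.transpose(0, 1, 3, 2)
            dV = A.transpose(0, 1, 3, 2) @ dC
            dS = A * (dA - (dA * A).sum(-1, keepdims=True))
            dQ = dS @ K * scale
            dK = dS.transpose(0, 1, 3, 2) @ Q * scale
            dQf = dQ.transpose(0, 2, 1, 3).reshape(B, T, d)
            dKf = dK.transpose(0, 2, 1, 3).reshape(B, T, d)
            dVf = dV.transpose(0, 2, 1, 3).reshape(B, T, d)
            h1_2d = h1.reshape(-1, d)
            grads[f"Wq{layer}"] += h1_2d.T @ dQf.reshape(-1, d)
            grads[f"Wk{layer}"] += h1_2d.T @ dKf.reshape(-1, d)
            grads[f"Wv{layer}"] += h1_2d.T @ dVf.reshape(-1, d)
            grads[f"bq{layer}"] += dQf.sum((0, 1))
            grads[f"bk{layer}"] += dKf.sum((0, 1))
            grads[f"bv{layer}"] += dVf.sum((0, 1))
            dh1 = dQf @ p[f"Wq{layer}"].T + dKf @ p[f"Wk{layer}"].T + dVf @ p[f"Wv{layer}"].T
            dx1_ln, dg, db = _ln_bwd(dh1, c_ln1, p[f"ln1_g{layer}"])
            grads[f"ln1_g{layer}"] += dg
            grads[f"ln1_b{layer}"] += db
            dx = dx2 + dx1_ln

        demb, dg, db = _ln_bwd(dx, cache["ln_in"], p["ln_in_g"])
        grads["ln_in_g"] += dg
        grads["ln_in_b"] += db
        tok, age, seg, pos = cache["emb_inputs"]
        np.add.at(grads["Etok"], tok, demb)
        np.add.at(grads["Eage"], age, demb)
        np.add.at(grads["Eseg"], seg, demb)
        np.add.at(grads["Epos"], pos, demb)

    # ------------------------------------------------------------------
    def _heads_fwd(self, hfin):
        p = self.params
        c = hfin[:, 0, :]
        zp = c @ p["W_pool"] + p["b_pool"]
        pool = np.tanh(zp)
        zg = pool @ p["w_g"] + p["b_g"]
        z1 = pool @ p["w_q1"] + p["b_q1"]
        z0 = pool @ p["w_q0"] + p["b_q0"]
        return c, pool, zg, z1, z0

    def predict(self, batch) -> dict:
        """Held-out predictions: propensity g and arm-specific risks q1, q0."""
        hfin, _ = self._encode(batch)
        _, _, zg, z1, z0 = self._heads_fwd(hfin)
        return {"g": expit(zg), "q1": expit(z1), "q0": expit(z0)}

    def mem_logits(self, batch) -> np.ndarray:
        hfin, _ = self._encode(batch)
        return hfin @ self.params["W_mem"] + self.params["b_mem"]

    # ------------------------------------------------------------------
    def loss_and_grads(self, batch, compute_grads: bool = True):
        """Joint loss (and exact parameter gradients) on one padded batch.

        ``batch`` carries the padded arrays from :func:`pad_batch` plus
        optional supervision: ``arm`` (0/1 propensity labels) and ``y``
        (binary outcomes). Masked-code supervision comes from
        ``mem_labels``; rows without supervision contribute only MEM loss.
        """
        cfg = self.cfg
        p = self.params
        hfin, cache = self._encode(batch)
        B = hfin.shape[0]
        d = cfg.hidden_size

        losses = {}
        grads = {k: np.zeros_like(v) for k, v in p.items()} if compute_grads else None
        dhfin = np.zeros_like(hfin)

        # masked-EHR-modeling head
        labels = batch["mem_labels"]
        sel = labels != IGNORE_LABEL
        n_sel = int(sel.sum())
        if n_sel > 0 and cfg.lambda_mem > 0:
            hs = hfin[sel]
            logits = hs @ p["W_mem"] + p["b_mem"]
            logits -= logits.max(-1, keepdims=True)
            logp = logits - np.log(np.exp(logits).sum(-1, keepdims=True))
            lab = labels[sel]
            losses["mem"] = float(-logp[np.arange(n_sel), lab].mean())
            if compute_grads:
                dlog = np.exp(logp)
                dlog[np.arange(n_sel), lab] -= 1.0
                dlog *= cfg.lambda_mem / n_sel
                grads["W_mem"] += hs.T @ dlog
                grads["b_mem"] += dlog.sum(0)
                dhfin[sel] += dlog @ p["W_mem"].T
        else:
            losses["mem"] = 0.0

        # pooled heads
        c, pool, zg, z1, z0 = self._heads_fwd(hfin)
        dpool = np.zeros_like(pool)
        arm = batch.get("arm")
        y = batch.get("y")
        if arm is not None and cfg.lambda_prop > 0:
            pg = expit(zg)
            losses["prop"] = float(-(arm * np.log(pg + 1e-12)
                                     + (1 - arm) * np.log(1 - pg + 1e-12)).mean())
            if compute_grads:
                dz = (pg - arm) * (cfg.lambda_prop / B)
                grads["w_g"] += pool.T @ dz
                grads["b_g"] += dz.sum()
                dpool += dz[:, None] * p["w_g"][None, :]
        else:
            losses["prop"] = 0.0
        if y is not None and arm is not None and cfg.lambda_out > 0:
            p1 = expit(z1)
            p0 = expit(z0)
            m1 = arm == 1
            m0 = ~m1
            bce1 = -(y[m1] * np.log(p1[m1] + 1e-12)
                     + (1 - y[m1]) * np.log(1 - p1[m1] + 1e-12)).sum()
            bce0 = -(y[m0] * np.log(p0[m0] + 1e-12)
                     + (1 - y[m0]) * np.log(1 - p0[m0] + 1e-12)).sum()
            losses["out"] = float((bce1 + bce0) / B)
            if compute_grads:
                dz1 = np.where(m1, p1 - y, 0.0) * (cfg.lambda_out / B)
                dz0 = np.where(m0, p0 - y, 0.0) * (cfg.lambda_out / B)
                grads["w_q1"] += pool.T @ dz1
                grads["b_q1"] += dz1.sum()
                grads["w_q0"] += pool.T @ dz0
                grads["b_q0"] += dz0.sum()
                dpool += dz1[:, None] * p["w_q1"][None, :]
                dpool += dz0[:, None] * p["w_q0"][None, :]
        else:
            losses["out"] = 0.0

        losses["total"] = (cfg.lambda_mem * losses["mem"]
                           + cfg.lambda_prop * losses["prop"]
                           + cfg.lambda_out * losses["out"])
        if not compute_grads:
            return losses, None

        if np.any(dpool):
            dzp = dpool * (1.0 - pool * pool)
            grads["W_pool"] += c.T @ dzp
            grads["b_pool"] += dzp.sum(0)
            dhfin[:, 0, :] += dzp @ p["W_pool"].T
        self._decode_bwd(dhfin, cache, grads)
        return losses, grads


class Adam:
    """Plain Adam over a parameter dict."""

    def __init__(self, params: dict, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
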