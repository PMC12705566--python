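"""Patch-attention classifier for EEMs, emission spectra and feature vectors.

A small vision-transformer-style network maps a spectrum to a stress
concentration class (0 / 10 / 100 mg/L). The input is cut into fixed-size
patches (2-D blocks of the EEM, 1-D windows of an emission spectrum, or a
single token for a short feature vector), linearly embedded, tagged with an
additive positional encoding and a prepended classification token, and pushed
through pre-norm transformer encoder blocks: layer norm -> multi-head scaled
dot-product attention -> residual, layer norm -> two-layer MLP (GELU) ->
residual. The classification token feeds a layer-norm + MLP head with dropout.

Everything is NumPy with hand-written backpropagation and Adam; training is
deterministic given the config seed, and dropout is disabled at inference so
repeated prediction is bit-stable. The models are deliberately small: a few
hundred labelled spectra cannot support more capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import erf

__all__ = [
    "AttentionConfig",
    "scaled_dot_product_attention",
    "attention_weights",
    "MHAWeights",
    "multi_head_attention",
    "patchify",
    "num_patches",
    "encoder_block_forward",
    "ViTClassifier",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Architecture and training hyperparameters of the attention classifier."""

    patch_size_2d: tuple[int, int] = (8, 32)
    patch_size_1d: int = 16
    embed_dim: int = 64
    n_heads: int = 4
    depth: int = 2
    mlp_hidden: int = 128
    dropout_rate: float = 0.1
    n_classes: int = 3
    learning_rate: float = 3e-3
    epochs: int = 80
    batch_size: int = 32
    seed: int = 0
    early_stopping: bool = True
    patience: int = 15
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


# ---------------------------------------------------------------------------
# functional pieces (also exposed for direct use / testing)
# ---------------------------------------------------------------------------


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_weights(Q: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Row-stochastic attention matrix softmax(Q K^T / sqrt(d_k))."""
    Q, K = np.asarray(Q, float), np.asarray(K, float)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"Q/K inner dimensions differ: {Q.shape[-1]} vs {K.shape[-1]}")
    return _softmax(Q @ np.swapaxes(K, -1, -2) / math.sqrt(Q.shape[-1]), axis=-1)


def scaled_dot_product_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, return_weights: bool = False
):
    """softmax(Q K^T / sqrt(d_k)) V with row-wise softmax.

    Q: (..., n_q, d_k); K: (..., n_k, d_k); V: (..., n_k, d_v).
    """
    K, V = np.asarray(K, float), np.asarray(V, float)
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(f"K/V token counts differ: {K.shape[-2]} vs {V.shape[-2]}")
    W = attention_weights(Q, K)
    out = W @ V
    return (out, W) if return_weights else out


@dataclass
class MHAWeights:
    """Learned projections of one multi-head attention layer (all d x d)."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    Wo: np.ndarray
    bq: np.ndarray
    bk: np.ndarray
    bv: np.ndarray
    bo: np.ndarray

    @classmethod
    def identity(cls, d: int) -> "MHAWeights":
        eye, zero = np.eye(d), np.zeros(d)
        return cls(eye.copy(), eye.copy(), eye.copy(), eye.copy(), zero.copy(), zero.copy(), zero.copy(), zero.copy())


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    # (T, d) -> (h, T, d/h)
    T, d = x.shape
    return x.reshape(T, h, d // h).transpose(1, 0, 2)


def multi_head_attention(x: np.ndarray, weights: MHAWeights, n_heads: int) -> np.ndarray:
    """Multi-head self-attention on a (n_tokens x d) token matrix."""
    x = np.asarray(x, float)
    d = x.shape[-1]
    if d % n_heads != 0:
        raise ValueError("token dimension must be divisible by n_heads")
    Q = _split_heads(x @ weights.Wq + weights.bq, n_heads)
    K = _split_heads(x @ weights.Wk + weights.bk, n_heads)
    V = _split_heads(x @ weights.Wv + weights.bv, n_heads)
    O = scaled_dot_product_attention(Q, K, V)  # (h, T, d/h)
    merged = O.transpose(1, 0, 2).reshape(x.shape)
    return merged @ weights.Wo + weights.bo


def num_patches(shape, config: AttentionConfig) -> int:
    """Number of patches a 1-D or 2-D input yields (inputs are zero-padded up)."""
    if len(shape) == 1:
        return math.ceil(shape[0] / config.patch_size_1d)
    ph, pw = config.patch_size_2d
    return math.ceil(shape[0] / ph) * math.ceil(shape[1] / pw)


def patchify(x: np.ndarray, config: AttentionConfig) -> np.ndarray:
    """Cut an EEM (2-D) or emission spectrum (1-D) into flattened patches.

    Returns an (n_patches x patch_dim) matrix of raw patch vectors; embedding,
    positional encoding and the class token are added by the classifier.
    Feature vectors shorter than one 1-D patch become a single token.
    """
    x = np.asarray(x, float)
    if x.ndim == 1:
        w = config.patch_size_1d
        if x.size <= w:
            return x[None, :]
        n = math.ceil(x.size / w)
        padded = np.zeros(n * w)
        padded[: x.size] = x
        return padded.reshape(n, w)
    if x.ndim == 2:
        ph, pw = config.patch_size_2d
        if ph > x.shape[0] and pw > x.shape[1]:
            raise ValueError(f"patch size {config.patch_size_2d} larger than input {x.shape}")
        nh, nw = math.ceil(x.shape[0] / ph), math.ceil(x.shape[1] / pw)
        padded = np.zeros((nh * ph, nw * pw))
        padded[: x.shape[0], : x.shape[1]] = x
        blocks = padded.reshape(nh, ph, nw, pw).transpose(0, 2, 1, 3)
        return blocks.reshape(nh * nw, ph * pw)
    raise ValueError(f"patchify expects a 1-D or 2-D input, got ndim={x.ndim}")


# ---------------------------------------------------------------------------
# layer forward/backward
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _ln_backward(dout, cache):
    xhat, inv, g = cache
    dg = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    db = dout.sum(axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * g
    d = xhat.shape[-1]
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True) - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x):
    cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
    pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return cdf + x * pdf


def encoder_block_forward(tokens: np.ndarray, params: dict, n_heads: int) -> np.ndarray:
    """One pre-norm encoder block (inference path, no dropout).

    ``params`` uses the same keys as :class:`ViTClassifier` blocks.
    """
    x = np.asarray(tokens, float)
    h1, _ = _ln_forward(x, params["ln1_g"], params["ln1_b"])
    mha = MHAWeights(
        params["Wq"], params["Wk"], params["Wv"], params["Wo"],
        params["bq"], params["bk"], params["bv"], params["bo"],
    )
    if x.ndim == 2:
        x = x + multi_head_attention(h1, mha, n_heads)
    else:
        x = x + np.stack([multi_head_attention(h, mha, n_heads) for h in h1])
    h2, _ = _ln_forward(x, params["ln2_g"], params["ln2_b"])
    m = _gelu(h2 @ params["W1"] + params["b1"]) @ params["W2"] + params["b2"]
    return x + m


# ---------------------------------------------------------------------------
# the trainable network
# ---------------------------------------------------------------------------


class ViTClassifier:
    """Small transformer classifier over pre-cut patch sequences.

    Operates on batches shaped (B, n_patches, patch_dim). Use
    :func:`patchify` to build the patch sequences.
    """

    def __init__(self, patch_dim: int, n_patches: int, config: AttentionConfig):
        self.config = config
        self.patch_dim = patch_dim
        self.n_patches = n_patches
        self.n_tokens = n_patches + 1  # + classification token
        rng = np.random.default_rng(config.seed)
        d, m, c = config.embed_dim, config.mlp_hidden, config.n_classes

        def lin(fan_in, fan_out):
            return rng.normal(0.0, math.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out))

        p: dict[str, np.ndarray] = {
            "We": lin(patch_dim, d),
            "be": np.zeros(d),
            "cls": rng.normal(0.0, 0.02, d),
            "pos": rng.normal(0.0, 0.02, (self.n_tokens, d)),
            "lnf_g": np.ones(d),
            "lnf_b": np.zeros(d),
            "Wh1": lin(d, m),
            "bh1": np.zeros(m),
            "Wh2": lin(m, c),
            "bh2": np.zeros(c),
        }
        for l in range(config.depth):
            p[f"b{l}.ln1_g"] = np.ones(d)
            p[f"b{l}.ln1_b"] = np.zeros(d)
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"b{l}.{w}"] = lin(d, d)
            for b in ("bq", "bk", "bv", "bo"):
                p[f"b{l}.{b}"] = np.zeros(d)
            p[f"b{l}.ln2_g"] = np.ones(d)
            p[f"b{l}.ln2_b"] = np.zeros(d)
            p[f"b{l}.W1"] = lin(d, m)
            p[f"b{l}.b1"] = np.zeros(m)
            p[f"b{l}.W2"] = lin(m, d)
            p[f"b{l}.b2"] = np.zeros(d)
        self.params = p
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self._drop_rng = np.random.default_rng(config.seed + 1)

    # -- forward ------------------------------------------------------------

    def _dropout(self, x, train):
        rate = self.config.dropout_rate
        if not train or rate == 0.0:
            return x, None
        mask = (self._drop_rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * mask, mask

    def forward(self, Xp: np.ndarray, train: bool = False):
        """Logits (B, n_classes) plus a cache for backprop."""
        p, cfg = self.params, self.config
        h = cfg.n_heads
        B = Xp.shape[0]
        E = Xp @ p["We"] + p["be"]
        cls = np.broadcast_to(p["cls"], (B, 1, cfg.embed_dim))
        x = np.concatenate([cls, E], axis=1) + p["pos"][None]
        cache: dict = {"Xp": Xp, "blocks": []}
        for l in range(cfg.depth):
            pre = f"b{l}."
            bc: dict = {"x_in": x}
            h1, bc["ln1"] = _ln_forward(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            bc["h1"] = h1
            Q = h1 @ p[pre + "Wq"] + p[pre + "bq"]
            K = h1 @ p[pre + "Wk"] + p[pre + "bk"]
            V = h1 @ p[pre + "Wv"] + p[pre + "bv"]
            dk = cfg.head_dim
            Qh = Q.reshape(B, -1, h, dk).transpose(0, 2, 1, 3)
            Kh = K.reshape(B, -1, h, dk).transpose(0, 2, 1, 3)
            Vh = V.reshape(B, -1, h, dk).transpose(0, 2, 1, 3)
            S = Qh @ Kh.transpose(0, 1, 3, 2) / math.sqrt(dk)
            P = _softmax(S, axis=-1)
            Oh = P @ Vh
            O = Oh.transpose(0, 2, 1, 3).reshape(B, -1, cfg.embed_dim)
            attn = O @ p[pre + "Wo"] + p[pre + "bo"]
            attn, bc["drop1"] = self._dropout(attn, train)
            bc.update(Qh=Qh, Kh=Kh, Vh=Vh, P=P, O=O)
            x = x + attn
            bc["x_mid"] = x
            h2, bc["ln2"] = _ln_forward(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            bc["h2"] = h2
            z1 = h2 @ p[pre + "W1"] + p[pre + "b1"]
            a1 = _gelu(z1)
            m = a1 @ p[pre + "W2"] + p[pre + "b2"]
            m, bc["drop2"] = self._dropout(m, train)
            bc.update(z1=z1, a1=a1)
            x = x + m
            cache["blocks"].append(bc)
        t0 = x[:, 0]
        c, cache["lnf"] = _ln_forward(t0, p["lnf_g"], p["lnf_b"])
        cache["c"] = c
        zh = c @ p["Wh1"] + p["bh1"]
        ah = _gelu(zh)
        ah_d, cache["droph"] = self._dropout(ah, train)
        cache.update(zh=zh, ah=ah_d, x_final=x)
        logits = ah_d @ p["Wh2"] + p["bh2"]
        return logits, cache

    def predict_proba(self, Xp: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(Xp, train=False)
        return _softmax(logits, axis=-1)

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, Xp: np.ndarray, y: np.ndarray):
        p, cfg = self.params, self.config
        B = Xp.shape[0]
        logits, cache = self.forward(Xp, train=True)
        probs = _softmax(logits, axis=-1)
        loss = float(-np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean())
        g = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        g["Wh2"] = cache["ah"].T @ dlogits
        g["bh2"] = dlogits.sum(0)
        dah = dlogits @ p["Wh2"].T
        if cache["droph"] is not None:
            dah = dah * cache["droph"]
        dzh = dah * _gelu_grad(cache["zh"])
        g["Wh1"] = cache["c"].T @ dzh
        g["bh1"] = dzh.sum(0)
        dc = dzh @ p["Wh1"].T
        dt0, g["lnf_g"], g["lnf_b"] = _ln_backward(dc, cache["lnf"])
        dx = np.zeros_like(cache["x_final"])
        dx[:, 0] = dt0

        h, dk = cfg.n_heads, cfg.head_dim
        for l in reversed(range(cfg.depth)):
            pre = f"b{l}."
            bc = cache["blocks"][l]
            # MLP sub-block: x_out = x_mid + drop(W2 gelu(W1 ln2(x_mid)))
            dm = dx.copy()
            if bc["drop2"] is not None:
                dm = dm * bc["drop2"]
            g[pre + "W2"] = np.einsum("btm,btd->md", bc["a1"], dm)
            g[pre + "b2"] = dm.sum((0, 1))
            da1 = dm @ p[pre + "W2"].T
            dz1 = da1 * _gelu_grad(bc["z1"])
            g[pre + "W1"] = np.einsum("btd,btm->dm", bc["h2"], dz1)
            g[pre + "b1"] = dz1.sum((0, 1))
            dh2 = dz1 @ p[pre + "W1"].T
            dx_mid, g[pre + "ln2_g"], g[pre + "ln2_b"] = _ln_backward(dh2, bc["ln2"])
            dx = dx + dx_mid
            # attention sub-block: x_mid = x_in + drop(MHA(ln1(x_in)))
            dattn = dx.copy()
            if bc["drop1"] is not None:
                dattn = dattn * bc["drop1"]
            g[pre + "Wo"] = np.einsum("btd,bte->de", bc["O"], dattn)
            g[pre + "bo"] = dattn.sum((0, 1))
            dO = dattn @ p[pre + "Wo"].T
            dOh = dO.reshape(B, -1, h, dk).transpose(0, 2, 1, 3)
            P, Qh, Kh, Vh = bc["P"], bc["Qh"], bc["Kh"], bc["Vh"]
            dP = dOh @ Vh.transpose(0, 1, 3, 2)
            dVh = P.transpose(0, 1, 3, 2) @ dOh
            dS = P * (dP - (dP * P).sum(-1, keepdims=True))
            dS /= math.sqrt(dk)
            dQh = dS @ Kh
            dKh = dS.transpose(0, 1, 3, 2) @ Qh
            dQ = dQh.transpose(0, 2, 1, 3).reshape(B, -1, cfg.embed_dim)
            dK = dKh.transpose(0, 2, 1, 3).reshape(B, -1, cfg.embed_dim)
            dV = dVh.transpose(0, 2, 1, 3).reshape(B, -1, cfg.embed_dim)
            h1 = bc["h1"]
            g[pre + "Wq"] = np.einsum("btd,bte->de", h1, dQ)
            g[pre + "Wk"] = np.einsum("btd,bte->de", h1, dK)
            g[pre + "Wv"] = np.einsum("btd,bte->de", h1, dV)
            g[pre + "bq"] = dQ.sum((0, 1))
            g[pre + "bk"] = dK.sum((0, 1))
            g[pre + "bv"] = dV.sum((0, 1))
            dh1 = dQ @ p[pre + "Wq"].T + dK @ p[pre + "Wk"].T + dV @ p[pre + "Wv"].T
            dx_in, g[pre + "ln1_g"], g[pre + "ln1_b"] = _ln_backward(dh1, bc["ln1"])
            dx = dx + dx_in
        g["pos"] = dx.sum(0)
        g["cls"] = dx[:, 0].sum(0)
        dE = dx[:, 1:]
        g["We"] = np.einsum("btp,btd->pd", cache["Xp"], dE)
        g["be"] = dE.sum((0, 1))
        return loss, g

    def adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk * gk
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def snapshot(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap: dict) -> None:
        self.params = {k: v.copy() for k, v in snap.items()}
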