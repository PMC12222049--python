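"""Transformer encoder with a sequence-classification head, in numpy.

The encoder is a BERT-style stack: token + learned absolute position
embeddings (with embedding LayerNorm), ``n_layers`` post-LayerNorm blocks of
multi-head self-attention and a GELU feed-forward network, a tanh pooler on
the [CLS] hidden state, and a linear softmax classifier. Multi-head
attention follows

    MultiHead(M) = Concat(head_1, ..., head_h) W_O,
    head_i = softmax( M W_Q_i (M W_K_i)^T / sqrt(d_k) ) M W_V_i,

with padded key positions excluded from the softmax. Forward and backward
passes are implemented explicitly (no autograd framework), which keeps the
model runnable anywhere numpy runs and makes every intermediate — notably
the per-head attention matrices used for interpretability — directly
inspectable.

The paper-scale configuration (12 layers, 768 hidden, 12 heads) is
constructible; the desk-scale default (2 layers, 64 hidden, 4 heads) is the
configuration exercised by the test-suite and the synthetic benchmarks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .tokenizer import TokenSequence

_NEG_INF = -1e9
_GELU_C = float(np.sqrt(2.0 / np.pi))
_GELU_A = 0.044715


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``d_hidden`` must be divisible by ``n_heads``; ``d_head`` is their
    quotient. ``max_positions`` is 512 for the CDS task and 57 for TIS.
    """

    vocab_size: int
    max_positions: int
    n_layers: int = 2
    d_hidden: int = 64
    n_heads: int = 4
    d_ff: Optional[int] = None
    n_classes: int = 2
    dropout: float = 0.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.d_hidden % self.n_heads != 0:
            raise ValueError("d_hidden must be divisible by n_heads")
        if self.max_positions < 3:
            raise ValueError("max_positions must be >= 3")
        if self.d_ff is None:
            self.d_ff = 4 * self.d_hidden

    @property
    def d_head(self) -> int:
        return self.d_hidden // self.n_heads


@dataclass(frozen=True)
class AttentionMap:
    """Per-head attention matrices of one layer, trimmed to real tokens.

    ``weights`` has shape (n_heads, n_real, n_real); rows are query
    positions and sum to 1, and padding positions carry zero mass.
    """

    layer: int
    weights: np.ndarray


def gelu(x: np.ndarray) -> np.ndarray:
    """tanh-approximation GELU."""
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + _GELU_A * x ** 3)))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    t = np.tanh(_GELU_C * (x + _GELU_A * x ** 3))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * _GELU_C * (
        1.0 + 3.0 * _GELU_A * x ** 2)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_head(M: np.ndarray, Wq: np.ndarray, Wk: np.ndarray,
                   Wv: np.ndarray,
                   mask: Optional[np.ndarray] = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Single attention head on a (L, d) embedding matrix.

    Returns ``(values, weights)`` where ``weights`` is the (L, L)
    row-stochastic attention matrix and ``values = weights @ (M Wv)``.
    Masked (padding) key positions are excluded before the softmax.
    """
    if mask is not None and not np.any(mask):
        raise ValueError("attention over an all-masked input is undefined")
    q, k, v = M @ Wq, M @ Wk, M @ Wv
    d_k = q.shape[-1]
    scores = q @ k.T / np.sqrt(d_k)
    if mask is not None:
        scores = scores + np.where(np.asarray(mask) > 0, 0.0, _NEG_INF)
    weights = softmax(scores, axis=-1)
    return weights @ v, weights


def multi_head_attention(M: np.ndarray,
                         heads: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                         Wo: np.ndarray,
                         mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Concat-and-project multi-head attention on a single sequence."""
    outs = [attention_head(M, Wq, Wk, Wv, mask)[0] for Wq, Wk, Wv in heads]
    concat = np.concatenate(outs, axis=-1)
    if concat.shape[-1] != Wo.shape[0]:
        raise ValueError(
            f"concatenated head dim {concat.shape[-1]} does not match "
            f"output projection rows {Wo.shape[0]}")
    return concat @ Wo


def _layer_norm(x, g, b, eps=1e-12):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc ** 2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


class TransformerClassifier:
    """Encoder + [CLS] pooler + softmax head with explicit backprop."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.params = self._init_params(seed)

    # ------------------------------------------------------------------ init
    def _init_params(self, seed: int) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(seed)
        dtype = np.dtype(cfg.dtype)

        def w(*shape):
            # normal(0, 0.02) truncated at 2 sigma
            return np.clip(rng.normal(0.0, 0.02, size=shape),
                           -0.04, 0.04).astype(dtype)

        def zeros(*shape):
            return np.zeros(shape, dtype=dtype)

        def ones(*shape):
            return np.ones(shape, dtype=dtype)

        D, F = cfg.d_hidden, cfg.d_ff
        p = {
            "tok_emb": w(cfg.vocab_size, D),
            "pos_emb": w(cfg.max_positions, D),
            "ln_emb_g": ones(D), "ln_emb_b": zeros(D),
            "Wp": w(D, D), "bp": zeros(D),
            "Wc": w(D, cfg.n_classes), "bc": zeros(cfg.n_classes),
        }
        for l in range(cfg.n_layers):
            p.update({
                f"l{l}.Wq": w(D, D), f"l{l}.bq": zeros(D),
                f"l{l}.Wk": w(D, D), f"l{l}.bk": zeros(D),
                f"l{l}.Wv": w(D, D), f"l{l}.bv": zeros(D),
                f"l{l}.Wo": w(D, D), f"l{l}.bo": zeros(D),
                f"l{l}.ln1_g": ones(D), f"l{l}.ln1_b": zeros(D),
                f"l{l}.W1": w(D, F), f"l{l}.b1": zeros(F),
                f"l{l}.W2": w(F, D), f"l{l}.b2": zeros(D),
                f"l{l}.ln2_g": ones(D), f"l{l}.ln2_b": zeros(D),
            })
        return p

    # --------------------------------------------------------------- forward
    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        B, L, D = x.shape
        H = self.config.n_heads
        return x.reshape(B, L, H, D // H).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: np.ndarray) -> np.ndarray:
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def forward(self, ids: np.ndarray, mask: np.ndarray,
                train: bool = False,
                rng: Optional[np.random.Generator] = None,
                collect_attention: bool = False) -> dict:
        """Run the model on a (B, L) id batch; returns a cache dict.

        The cache holds ``probs`` (B, n_classes), ``logits``, per-layer
        attention tensors when ``collect_attention`` is set, and every
        intermediate :meth:`backward` needs.
        """
        cfg = self.config
        p = self.params
        ids = np.atleast_2d(ids)
        mask = np.atleast_2d(mask)
        B, L = ids.shape
        if L > cfg.max_positions:
            raise ValueError(f"sequence length {L} exceeds "
                             f"max_positions={cfg.max_positions}")
        if np.any(mask.sum(axis=1) == 0):
            raise ValueError("all-masked sequence in batch")
        drop = cfg.dropout if train else 0.0
        if drop > 0 and rng is None:
            raise ValueError("dropout requires an rng in training mode")

        key_bias = np.where(mask[:, None, None, :] > 0, 0.0, _NEG_INF)
        x0 = p["tok_emb"][ids] + p["pos_emb"][:L][None, :, :]
        x, ln_emb_cache = _layer_norm(x0, p["ln_emb_g"], p["ln_emb_b"])

        cache = {"ids": ids, "mask": mask, "ln_emb": ln_emb_cache,
                 "layers": [], "attentions": [], "drop": drop}
        scale = 1.0 / np.sqrt(cfg.d_head)
        for l in range(cfg.n_layers):
            lc: dict = {"x_in": x}
            q = self._split_heads(x @ p[f"l{l}.Wq"] + p[f"l{l}.bq"])
            k = self._split_heads(x @ p[f"l{l}.Wk"] + p[f"l{l}.bk"])
            v = self._split_heads(x @ p[f"l{l}.Wv"] + p[f"l{l}.bv"])
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale + key_bias
            A = softmax(scores, axis=-1)
            ctx = self._merge_heads(A @ v)
            attn_out = ctx @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]
            if drop > 0:
                m1 = (rng.random(attn_out.shape) >= drop) / (1.0 - drop)
                attn_out = attn_out * m1
                lc["drop1"] = m1
            h1, ln1_cache = _layer_norm(x + attn_out,
                                        p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            z1 = h1 @ p[f"l{l}.W1"] + p[f"l{l}.b1"]
            a1 = gelu(z1)
            ff = a1 @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
            if drop > 0:
                m2 = (rng.random(ff.shape) >= drop) / (1.0 - drop)
                ff = ff * m2
                lc["drop2"] = m2
            h2, ln2_cache = _layer_norm(h1 + ff,
                                        p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            lc.update(q=q, k=k, v=v, A=A, ctx=ctx, ln1=ln1_cache,
                      h1=h1, z1=z1, a1=a1, ln2=ln2_cache)
            cache["layers"].append(lc)
            if collect_attention:
                cache["attentions"].append(A)
            x = h2

        cls_h = x[:, 0, :]
        zp = cls_h @ p["Wp"] + p["bp"]
        pooled = np.tanh(zp)
        logits = pooled @ p["Wc"] + p["bc"]
        probs = softmax(logits, axis=-1)
        cache.update(x_final=x, cls_h=cls_h, pooled=pooled,
                     logits=logits, probs=probs)
        return cache

    # -------------------------------------------------------------- backward
    def backward(self, cache: dict, dlogits: np.ndarray
                 ) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss wrt every parameter, given dL/dlogits."""
        cfg = self.config
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        ids, mask = cache["ids"], cache["mask"]
        B, L = ids.shape
        scale = 1.0 / np.sqrt(cfg.d_head)

        grads["Wc"] += cache["pooled"].T @ dlogits
        grads["bc"] += dlogits.sum(0)
        dpooled = dlogits @ p["Wc"].T
        dzp = dpooled * (1.0 - cache["pooled"] ** 2)
        grads["Wp"] += cache["cls_h"].T @ dzp
        grads["bp"] += dzp.sum(0)
        dx = np.zeros_like(cache["x_final"])
        dx[:, 0, :] = dzp @ p["Wp"].T

        def mm_acc(a, b):
            # (B,L,i)^T x (B,L,j) summed over batch and positions
            return np.tensordot(a, b, axes=([0, 1], [0, 1]))

        for l in range(cfg.n_layers - 1, -1, -1):
            lc = cache["layers"][l]
            dr2, dg, db = _layer_norm_backward(dx, lc["ln2"])
            grads[f"l{l}.ln2_g"] += dg
            grads[f"l{l}.ln2_b"] += db
            dff = dr2
            dh1 = dr2.copy()
            if "drop2" in lc:
                dff = dff * lc["drop2"]
            grads[f"l{l}.W2"] += mm_acc(lc["a1"], dff)
            grads[f"l{l}.b2"] += dff.sum((0, 1))
            da1 = dff @ p[f"l{l}.W2"].T
            dz1 = da1 * gelu_grad(lc["z1"])
            grads[f"l{l}.W1"] += mm_acc(lc["h1"], dz1)
            grads[f"l{l}.b1"] += dz1.sum((0, 1))
            dh1 += dz1 @ p[f"l{l}.W1"].T

            dr1, dg, db = _layer_norm_backward(dh1, lc["ln1"])
            grads[f"l{l}.ln1_g"] += dg
            grads[f"l{l}.ln1_b"] += db
            dattn = dr1
            dx = dr1.copy()
            if "drop1" in lc:
                dattn = dattn * lc["drop1"]
            grads[f"l{l}.Wo"] += mm_acc(lc["ctx"], dattn)
            grads[f"l{l}.bo"] += dattn.sum((0, 1))
            dctx = self._split_heads(dattn @ p[f"l{l}.Wo"].T)

            A, q, k, v = lc["A"], lc["q"], lc["k"], lc["v"]
            dA = dctx @ v.transpose(0, 1, 3, 2)
            dv = A.transpose(0, 1, 3, 2) @ dctx
            dscores = A * (dA - (dA * A).sum(-1, keepdims=True))
            dq = (dscores @ k) * scale
            dk = (dscores.transpose(0, 1, 3, 2) @ q) * scale

            x_in = lc["x_in"]
            for name, dmat in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                dmerged = self._merge_heads(dmat)
                grads[f"l{l}.{name}"] += mm_acc(x_in, dmerged)
                grads[f"l{l}.b{name[1].lower()}"] += dmerged.sum((0, 1))
                dx += dmerged @ p[f"l{l}.{name}"].T

        dx0, dg, db = _layer_norm_backward(dx, cache["ln_emb"])
        grads["ln_emb_g"] += dg
        grads["ln_emb_b"] += db
        np.add.at(grads["tok_emb"], ids, dx0)
        grads["pos_emb"][:L] += dx0.sum(0)
        return grads

    # ------------------------------------------------------------- inference
    def classify(self, tokens: TokenSequence) -> tuple[float, float]:
        """Probabilities (p_neg, p_pos) for one fixed-length token sequence."""
        if len(tokens.ids) != self.config.max_positions:
            raise ValueError(
                f"token sequence length {len(tokens.ids)} != "
                f"max_positions={self.config.max_positions}")
        n = tokens.n_real
        cache = self.forward(tokens.ids[None, :n], tokens.mask[None, :n])
        p_neg, p_pos = cache["probs"][0]
        return float(p_neg), float(p_pos)

    def classify_batch(self, ids: np.ndarray, mask: np.ndarray,
                       batch_size: int = 64) -> np.ndarray:
        """p_pos for a (N, L) id matrix, trimming shared padding per batch."""
        out = np.empty(len(ids), dtype=np.float64)
        for i in range(0, len(ids), batch_size):
            bids, bmask = ids[i:i + batch_size], mask[i:i + batch_size]
            L = max(int(bmask.sum(1).max()), 1)
            cache = self.forward(bids[:, :L], bmask[:, :L])
            out[i:i + batch_size] = cache["probs"][:, 1]
        return out

    def get_attention_maps(self, tokens: TokenSequence) -> list[AttentionMap]:
        """Per-layer, per-head attention matrices trimmed to real tokens."""
        n = tokens.n_real
        cache = self.forward(tokens.ids[None, :n], tokens.mask[None, :n],
                             collect_attention=True)
        return [AttentionMap(layer=l, weights=A[0])
                for l, A in enumerate(cache["attentions"])]

    # ----------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        meta = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "TransformerClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["__config__"]).decode())
        model = cls.__new__(cls)
        model.config = ModelConfig(**meta)
        model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model

    def weight_hash(self) -> int:
        """Order-independent fingerprint of all parameters."""
        h = 0
        for k in sorted(self.params):
            h ^= hash((k, self.params[k].tobytes()))
        return h
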