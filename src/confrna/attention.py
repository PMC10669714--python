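"""Scaled dot-product and cross multi-head attention.

The model's residual blocks do not add deep features to shallow ones
directly; instead the shallow features query the deep ones through
multi-head attention and the attended result is added back to the
shallow path (``shallow + MHA(Q=shallow, K=deep, V=deep)``).  This keeps
shallow information intact while letting the block express disparities
between the two depths.

Similarity is the scaled dot product (1/sqrt(d_head)); no positional
encoding is used inside attention — sequence order is supplied upstream
by the BiLSTM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor

__all__ = [
    "MHAParams",
    "mha_params",
    "scaled_dot_attention",
    "multi_head",
    "cross_residual_fuse",
]


@dataclass
class MHAParams:
    """Per-head Q/K/V projections (stacked) and the output projection.

    w_q, w_k, w_v: (h, d_model, d_head); w_o: (h * d_head, d_model).
    ``d_head * h = d_model`` so head concatenation restores model width.
    """

    n_heads: int
    w_q: Tensor
    w_k: Tensor
    w_v: Tensor
    w_o: Tensor

    @property
    def d_model(self) -> int:
        return self.w_q.shape[1]

    @property
    def d_head(self) -> int:
        return self.w_q.shape[2]

    def tensors(self) -> list[Tensor]:
        return [self.w_q, self.w_k, self.w_v, self.w_o]


def mha_params(d_model: int, n_heads: int, rng: np.random.Generator) -> MHAParams:
    """Glorot-uniform initialized parameters for one attention site."""
    if d_model % n_heads != 0:
        raise ValueError(f"n_heads={n_heads} does not divide d_model={d_model}")
    d_head = d_model // n_heads

    def glorot(*shape):
        fan_in, fan_out = shape[-2], shape[-1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    return MHAParams(
        n_heads=n_heads,
        w_q=glorot(n_heads, d_model, d_head),
        w_k=glorot(n_heads, d_model, d_head),
        w_v=glorot(n_heads, d_model, d_head),
        w_o=glorot(n_heads * d_head, d_model),
    )


def scaled_dot_attention(q, k, v) -> Tensor:
    """softmax(Q Kᵀ / sqrt(d)) V over the last two axes.

    Accepts (..., n, d) stacks; every leading axis is treated as batch.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(f"query width {q.shape[-1]} != key width {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"key count {k.shape[-2]} != value count {v.shape[-2]}")
    d = q.shape[-1]
    scores = (q @ _swap_last(k)) * (1.0 / np.sqrt(d))
    return ag.softmax(scores, axis=-1) @ v


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(tuple(axes))


def multi_head(q_in, k_in, v_in, params: MHAParams) -> Tensor:
    """Project per head, attend per head, concatenate, project out."""
    q_in, k_in, v_in = as_tensor(q_in), as_tensor(k_in), as_tensor(v_in)
    d_model = params.d_model
    for name, t in (("query", q_in), ("key", k_in), ("value", v_in)):
        if t.shape[-1] != d_model:
            raise ValueError(f"{name} width {t.shape[-1]} != d_model {d_model}")

    def heads(x: Tensor, w: Tensor) -> Tensor:
        # (..., L, D) -> (..., 1, L, D) @ (h, D, dh) -> (..., h, L, dh)
        expanded = x.reshape(x.shape[:-2] + (1,) + x.shape[-2:])
        return expanded @ w

    attended = scaled_dot_attention(
        heads(q_in, params.w_q), heads(k_in, params.w_k), heads(v_in, params.w_v)
    )  # (..., h, L_q, d_head)
    n = attended.ndim
    axes = tuple(range(n - 3)) + (n - 2, n - 3, n - 1)  # h <-> L_q
    merged = attended.transpose(axes).reshape(
        attended.shape[:-3] + (attended.shape[-2], params.n_heads * params.d_head)
    )
    return merged @ params.w_o


def cross_residual_fuse(shallow, deep, params: MHAParams) -> Tensor:
    """shallow + MHA(Q=shallow, K=deep, V=deep); shape preserved."""
    shallow, deep = as_tensor(shallow), as_tensor(deep)
    if shallow.shape != deep.shape:
        raise ValueError(f"shape mismatch: shallow {shallow.shape} vs deep {deep.shape}")
    return shallow + multi_head(shallow, deep, deep, params)
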