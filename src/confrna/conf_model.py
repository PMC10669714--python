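"""The ConF network for ncRNA family classification.

Pipeline (default configuration, window 224, thirteen families)::

    tokens (224,) --embed--> 224x16
      --[BiLSTM 16+16 || dual-layer CNN 96]--> 224x128   (front-end)
      --MLP + cross-attention residual-->      224x128
      --Block1 (convs 16 / 10d2 / 18d2)-->     224x128
      --downsample (reshape)-->                112x256
      --Block2 (same kernels, 2x filters)-->   112x256
      --global average pool + FC + softmax-->  13 probabilities

Residual fusion everywhere is attention-based: the shallow features
query the deep ones and the attended difference is added to the shallow
path (see :mod:`confrna.attention`).  Convolutions are same-padded and
dilated where configured; the LSTM gates follow the standard
forget/input/candidate/output equations exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import autograd as ag
from .attention import MHAParams, cross_residual_fuse, mha_params
from .autograd import Tensor, as_tensor
from .representation import TokenSequence

__all__ = [
    "ConvLayerParams",
    "LSTMParams",
    "MLPParams",
    "BlockParams",
    "HeadParams",
    "ConFParams",
    "ModelConfig",
    "small_config",
    "conv1d",
    "lstm_step",
    "bilstm_encode",
    "frontend",
    "mlp_attention_fuse",
    "block",
    "downsample",
    "forward",
    "ConF",
]


# ---------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------

@dataclass
class ConvLayerParams:
    """One same-padded (optionally dilated) conv layer.

    weights: (kernel_size, fan_in, n_filters); bias: (n_filters,).
    ``activation`` is "relu" or "linear".
    """

    kernel_size: int
    n_filters: int
    weights: Tensor
    bias: Tensor
    dilation: int = 1
    activation: str = "relu"

    def tensors(self) -> list[Tensor]:
        return [self.weights, self.bias]


@dataclass
class LSTMParams:
    """Gate weights over the concatenated [h_{t-1}, x_t] input.

    Each W_* has shape (H + E, H); each b_* has shape (H,).
    """

    w_f: Tensor
    w_i: Tensor
    w_c: Tensor
    w_o: Tensor
    b_f: Tensor
    b_i: Tensor
    b_c: Tensor
    b_o: Tensor

    @property
    def hidden_size(self) -> int:
        return self.w_f.shape[1]

    def tensors(self) -> list[Tensor]:
        return [self.w_f, self.w_i, self.w_c, self.w_o,
                self.b_f, self.b_i, self.b_c, self.b_o]


@dataclass
class MLPParams:
    """Two position-wise fully connected layers with a ReLU between."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


@dataclass
class BlockParams:
    """Three parallel conv branches + width-1 projection + attention residual."""

    branches: list[ConvLayerParams]
    projection: ConvLayerParams
    mha: MHAParams

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for branch in self.branches:
            out.extend(branch.tensors())
        out.extend(self.projection.tensors())
        out.extend(self.mha.tensors())
        return out


@dataclass
class HeadParams:
    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


@dataclass
class ConFParams:
    embedding: Tensor
    lstm_fwd: LSTMParams
    lstm_bwd: LSTMParams
    cnn: list[ConvLayerParams]
    fuse_mlp: MLPParams
    fuse_mha: MHAParams
    block1: BlockParams
    block2: BlockParams
    head: HeadParams

    def tensors(self) -> list[Tensor]:
        out = [self.embedding]
        out.extend(self.lstm_fwd.tensors())
        out.extend(self.lstm_bwd.tensors())
        for layer in self.cnn:
            out.extend(layer.tensors())
        out.extend(self.fuse_mlp.tensors())
        out.extend(self.fuse_mha.tensors())
        out.extend(self.block1.tensors())
        out.extend(self.block2.tensors())
        out.extend(self.head.tensors())
        return out


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the reference ConF layout: 2-mer tokens in a window of
    224, embedding width 16, BiLSTM with 16 hidden units per direction,
    a 96-filter dual-layer CNN branch (so 32 + 96 = 128 front-end
    channels), residual blocks with conv windows 16 / 10 / 18 (the last
    two dilated), and a 13-class softmax head.
    """

    max_len: int = 224
    k: int = 2
    embedding_dim: int = 16
    lstm_hidden: int = 16
    cnn_filters: int = 96
    cnn_kernels: tuple[int, ...] = (5, 5)
    block_kernels: tuple[int, int, int] = (16, 10, 18)
    block_dilations: tuple[int, int, int] = (1, 2, 2)
    n_heads: int = 4
    n_classes: int = 13
    mlp_hidden: int = 128

    def __post_init__(self):
        if self.max_len % 2 != 0:
            raise ValueError("max_len must be even (downsampling halves it)")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide d_model={self.d_model}"
            )
        if (2 * self.d_model) % self.n_heads != 0:
            raise ValueError("n_heads must also divide the post-downsample width")

    @property
    def d_model(self) -> int:
        """Front-end channel count: BiLSTM width + CNN filters."""
        return 2 * self.lstm_hidden + self.cnn_filters

    @property
    def vocab_size(self) -> int:
        return 4 ** self.k + 1

    def to_dict(self) -> dict:
        return {
            "max_len": self.max_len,
            "k": self.k,
            "embedding_dim": self.embedding_dim,
            "lstm_hidden": self.lstm_hidden,
            "cnn_filters": self.cnn_filters,
            "cnn_kernels": list(self.cnn_kernels),
            "block_kernels": list(self.block_kernels),
            "block_dilations": list(self.block_dilations),
            "n_heads": self.n_heads,
            "n_classes": self.n_classes,
            "mlp_hidden": self.mlp_hidden,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("cnn_kernels", "block_kernels", "block_dilations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def small_config(n_classes: int = 4, max_len: int = 96) -> ModelConfig:
    """A narrow configuration for desk-scale experiments and tests.

    Same topology as the default, with channel widths cut so a CPU-only
    training run finishes in minutes: 8-dim embeddings, 4+4 BiLSTM,
    8-filter CNN branch (d_model 16), two attention heads, and
    proportionally shrunk block kernels.
    """
    return ModelConfig(
        max_len=max_len,
        embedding_dim=8,
        lstm_hidden=4,
        cnn_filters=8,
        cnn_kernels=(3, 3),
        block_kernels=(8, 5, 9),
        block_dilations=(1, 2, 2),
        n_heads=2,
        n_classes=n_classes,
        mlp_hidden=16,
    )


# ---------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------

def _glorot(rng: np.random.Generator, *shape) -> Tensor:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _conv_layer(rng, kernel, fan_in, n_filters, dilation=1, activation="relu") -> ConvLayerParams:
    return ConvLayerParams(
        kernel_size=kernel,
        n_filters=n_filters,
        weights=_glorot(rng, kernel, fan_in, n_filters),
        bias=_zeros(n_filters),
        dilation=dilation,
        activation=activation,
    )


def _lstm_params(rng, input_size, hidden) -> LSTMParams:
    def w():
        return _glorot(rng, hidden + input_size, hidden)

    return LSTMParams(
        w_f=w(), w_i=w(), w_c=w(), w_o=w(),
        b_f=_zeros(hidden), b_i=_zeros(hidden),
        b_c=_zeros(hidden), b_o=_zeros(hidden),
    )


def _block_params(rng, cfg: ModelConfig, d_model: int) -> BlockParams:
    branches = [
        _conv_layer(rng, k, d_model, d_model, dilation=d, activation="relu")
        for k, d in zip(cfg.block_kernels, cfg.block_dilations)
    ]
    projection = _conv_layer(rng, 1, 3 * d_model, d_model, activation="linear")
    return BlockParams(
        branches=branches,
        projection=projection,
        mha=mha_params(d_model, cfg.n_heads, rng),
    )


def init_params(cfg: ModelConfig, seed: int) -> ConFParams:
    rng = np.random.default_rng(seed)
    embedding = Tensor(rng.normal(0.0, 0.1, size=(cfg.vocab_size, cfg.embedding_dim)),
                       requires_grad=True)
    cnn = []
    fan_in = cfg.embedding_dim
    for kernel in cfg.cnn_kernels:
        cnn.append(_conv_layer(rng, kernel, fan_in, cfg.cnn_filters))
        fan_in = cfg.cnn_filters
    d1 = cfg.d_model
    d2 = 2 * cfg.d_model
    return ConFParams(
        embedding=embedding,
        lstm_fwd=_lstm_params(rng, cfg.embedding_dim, cfg.lstm_hidden),
        lstm_bwd=_lstm_params(rng, cfg.embedding_dim, cfg.lstm_hidden),
        cnn=cnn,
        fuse_mlp=MLPParams(
            w1=_glorot(rng, d1, cfg.mlp_hidden), b1=_zeros(cfg.mlp_hidden),
            w2=_glorot(rng, cfg.mlp_hidden, d1), b2=_zeros(d1),
        ),
        fuse_mha=mha_params(d1, cfg.n_heads, rng),
        block1=_block_params(rng, cfg, d1),
        block2=_block_params(rng, cfg, d2),
        head=HeadParams(
            w1=_glorot(rng, d2, cfg.mlp_hidden), b1=_zeros(cfg.mlp_hidden),
            w2=_glorot(rng, cfg.mlp_hidden, cfg.n_classes), b2=_zeros(cfg.n_classes),
        ),
    )


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def conv1d(x, params: ConvLayerParams) -> Tensor:
    """Same-padded dilated convolution with the layer's activation."""
    y = ag.conv1d_raw(as_tensor(x), params.weights, params.bias, params.dilation)
    if params.activation == "relu":
        return ag.relu(y)
    if params.activation == "linear":
        return y
    raise ValueError(f"unknown activation {params.activation!r}")


def lstm_step(x_t, h_prev, c_prev, params: LSTMParams):
    """One LSTM cell update.

    f_t = sigma(W_f.[h,x] + b_f);  i_t = sigma(W_i.[h,x] + b_i)
    c~_t = tanh(W_C.[h,x] + b_C);  C_t = f_t*C_{t-1} + i_t*c~_t
    o_t = sigma(W_o.[h,x] + b_o);  h_t = o_t * tanh(C_t)

    Operates on single vectors or batched (..., E) / (..., H) stacks.
    """
    x_t, h_prev, c_prev = as_tensor(x_t), as_tensor(h_prev), as_tensor(c_prev)
    hidden = params.hidden_size
    if h_prev.shape[-1] != hidden or c_prev.shape[-1] != hidden:
        raise ValueError("state width does not match the LSTM hidden size")
    if h_prev.shape[-1] + x_t.shape[-1] != params.w_f.shape[0]:
        raise ValueError("input width does not match the gate weight fan-in")
    hx = ag.concatenate([h_prev, x_t], axis=-1)
    f_t = ag.sigmoid(hx @ params.w_f + params.b_f)
    i_t = ag.sigmoid(hx @ params.w_i + params.b_i)
    c_tilde = ag.tanh(hx @ params.w_c + params.b_c)
    c_t = f_t * c_prev + i_t * c_tilde
    o_t = ag.sigmoid(hx @ params.w_o + params.b_o)
    h_t = o_t * ag.tanh(c_t)
    return h_t, c_t


def _lstm_scan(x: Tensor, params: LSTMParams, reverse: bool) -> Tensor:
    """Run one direction over (..., L, E); returns hidden states (..., L, H).

    Equivalent to iterating :func:`lstm_step`, but the four gate weight
    matrices are fused into one and the input projections for every
    timestep are computed in a single matmul up front, leaving only the
    recurrent half inside the loop.  Gate layout: sigmoid gates (f, i, o)
    first, candidate last, so each step needs one sigmoid and one tanh.
    """
    hidden = params.hidden_size
    length = x.shape[-2]
    batch_shape = x.shape[:-2]
    w_all = ag.concatenate([params.w_f, params.w_i, params.w_o, params.w_c], axis=1)
    b_all = ag.concatenate([params.b_f, params.b_i, params.b_o, params.b_c], axis=0)
    w_h = w_all[:hidden]
    w_x = w_all[hidden:]
    xproj = x @ w_x + b_all  # (..., L, 4H)
    h = Tensor(np.zeros(batch_shape + (hidden,)))
    c = Tensor(np.zeros(batch_shape + (hidden,)))
    order = range(length - 1, -1, -1) if reverse else range(length)
    states: list[Tensor | None] = [None] * length
    for t in order:
        z = xproj[..., t, :] + (h @ w_h)
        gates = ag.sigmoid(z[..., : 3 * hidden])
        f_t = gates[..., :hidden]
        i_t = gates[..., hidden:2 * hidden]
        o_t = gates[..., 2 * hidden:]
        c = f_t * c + i_t * ag.tanh(z[..., 3 * hidden:])
        h = o_t * ag.tanh(c)
        states[t] = h.reshape(batch_shape + (1, hidden))
    return ag.concatenate(states, axis=-2)


def bilstm_encode(embedded, fwd: LSTMParams, bwd: LSTMParams) -> Tensor:
    """Per-position concatenation of forward and backward hidden states.

    (..., L, E) -> (..., L, 2H): channels [0, H) are the left-to-right
    pass, [H, 2H) the right-to-left pass.
    """
    embedded = as_tensor(embedded)
    return ag.concatenate(
        [_lstm_scan(embedded, fwd, reverse=False),
         _lstm_scan(embedded, bwd, reverse=True)],
        axis=-1,
    )


def _as_token_array(tokens) -> np.ndarray:
    if isinstance(tokens, TokenSequence):
        return tokens.indices
    return np.asarray(tokens, dtype=np.intp)


def frontend(tokens, cfg: ModelConfig, params: ConFParams) -> Tensor:
    """Embedding -> parallel BiLSTM and dual-layer CNN -> channel concat.

    Output channels: [0, 2H) from the BiLSTM, [2H, d_model) from the CNN
    branch.  For the default configuration this is the 224 x 128 feature
    sequence.
    """
    idx = _as_token_array(tokens)
    if idx.shape[-1] != cfg.max_len:
        raise ValueError(f"token sequence length {idx.shape[-1]} != window {cfg.max_len}")
    embedded = ag.embedding(params.embedding, idx)
    recurrent = bilstm_encode(embedded, params.lstm_fwd, params.lstm_bwd)
    convolved = embedded
    for layer in params.cnn:
        convolved = conv1d(convolved, layer)
    return ag.concatenate([recurrent, convolved], axis=-1)


def _position_wise_mlp(x: Tensor, mlp: MLPParams) -> Tensor:
    return ag.relu(x @ mlp.w1 + mlp.b1) @ mlp.w2 + mlp.b2


def mlp_attention_fuse(x, mlp: MLPParams, mha: MHAParams) -> Tensor:
    """Attention residual between features and their MLP transform."""
    x = as_tensor(x)
    return cross_residual_fuse(x, _position_wise_mlp(x, mlp), mha)


def block(x, params: BlockParams) -> Tensor:
    """Multi-scale residual block with attention-based fusion.

    Deep path F(x): three parallel same-padded conv branches (one plain,
    two dilated), channel-concatenated and projected back to the input
    width by a width-1 convolution.  Output: shallow x fused with F(x)
    through cross multi-head attention (zero output projection recovers
    the classic identity mapping H(x) = x).
    """
    x = as_tensor(x)
    d_model = params.projection.n_filters
    if x.shape[-1] != d_model:
        raise ValueError(f"block expects {d_model} channels, got {x.shape[-1]}")
    deep = conv1d(
        ag.concatenate([conv1d(x, branch) for branch in params.branches], axis=-1),
        params.projection,
    )
    return cross_residual_fuse(x, deep, params.mha)


def downsample(x) -> Tensor:
    """Lossless positional reshape: (..., L, C) -> (..., L/2, 2C).

    Positions 2t and 2t+1 are stacked channel-wise into position t, so
    out[t, c] = in[2t + c // C, c mod C].
    """
    x = as_tensor(x)
    length, channels = x.shape[-2], x.shape[-1]
    if length % 2 != 0:
        raise ValueError(f"cannot halve odd length {length}")
    return x.reshape(x.shape[:-2] + (length // 2, 2 * channels))


def logits(tokens, cfg: ModelConfig, params: ConFParams) -> Tensor:
    """Unnormalized class scores; `forward` applies the softmax."""
    x = frontend(tokens, cfg, params)
    x = mlp_attention_fuse(x, params.fuse_mlp, params.fuse_mha)
    x = block(x, params.block1)
    x = downsample(x)
    x = block(x, params.block2)
    pooled = x.mean(axis=-2)  # global average over positions
    hidden = ag.relu(pooled @ params.head.w1 + params.head.b1)
    return hidden @ params.head.w2 + params.head.b2


def forward(tokens, cfg: ModelConfig, params: ConFParams) -> Tensor:
    """Class probability vector(s); rows sum to 1."""
    return ag.softmax(logits(tokens, cfg, params), axis=-1)


# ---------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------

class ConF:
    """Configuration + parameters + convenience prediction methods."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0,
                 params: ConFParams | None = None):
        self.cfg = cfg if cfg is not None else ModelConfig()
        self.params = params if params is not None else init_params(self.cfg, seed)

    def parameters(self) -> list[Tensor]:
        return self.params.tensors()

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.parameters()))

    def logits(self, tokens) -> Tensor:
        return logits(tokens, self.cfg, self.params)

    def predict_proba(self, tokens) -> np.ndarray:
        return forward(tokens, self.cfg, self.params).numpy()

    def predict(self, tokens) -> np.ndarray:
        return self.predict_proba(tokens).argmax(axis=-1)

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.zero_grad()

    # -- checkpointing -------------------------------------------------
    def save(self, archive: str | Path) -> None:
        """Write parameters (.npz) and a YAML config sidecar."""
        archive = Path(archive)
        arrays = {f"p{i}": t.data for i, t in enumerate(self.parameters())}
        np.savez(archive, **arrays)
        sidecar = archive.with_suffix(".yaml")
        sidecar.write_text(yaml.safe_dump(self.cfg.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, archive: str | Path) -> "ConF":
        archive = Path(archive)
        if archive.suffix != ".npz":
            archive = archive.with_suffix(".npz")
        cfg = ModelConfig.from_dict(yaml.safe_load(archive.with_suffix(".yaml").read_text()))
        model = cls(cfg, seed=0)
        with np.load(archive) as data:
            for i, t in enumerate(model.parameters()):
                stored = data[f"p{i}"]
                if stored.shape != t.data.shape:
                    raise ValueError("checkpoint does not match the configuration")
                t.data = stored.astype(np.float64)
        return model
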