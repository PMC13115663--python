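"""The hybrid-attention graph convolutional model.

Pipeline per forward pass: efficient channel attention (ECA) recalibrates
the RWR input features; a first graph convolution captures length-1
meta-paths; multi-head self-attention models global node dependencies; a
second graph convolution captures length-2 meta-paths; the two layer
outputs are adaptively fused; and an MLP scores miRNA-disease pairs with a
sigmoid output trained under binary cross-entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, concat
from .data_io import ContractError

__all__ = [
    "ModelConfig",
    "eca_kernel_size",
    "init_params",
    "eca_recalibrate",
    "gcn_layer",
    "multi_head_self_attention",
    "adaptive_fuse",
    "score_pairs",
    "bce_loss",
    "embed",
    "forward",
    "attention_matrices",
    "normalize_adjacency",
]

ABLATIONS = ("attention", "egcn", "multisource")


def eca_kernel_size(n_channels: int) -> int:
    """Adaptive ECA kernel: nearest odd integer to |log2(C)/2 + 1/2|."""
    t = abs(math.log2(n_channels) / 2.0 + 0.5)
    k = 2 * round((t - 1.0) / 2.0) + 1
    return max(k, 1)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    embed_dim is the per-layer embedding size; n_heads splits it into
    head_dim-wide attention subspaces; eca_kernel defaults to the adaptive
    rule based on the input channel count; ablate names components to
    disable ("attention" removes ECA + self-attention, "egcn" removes the
    self-attention between the convolutions, "multisource" collapses the
    similarity fusion to the GIP view only).
    """

    n_layers: int = 2
    embed_dim: int = 256
    n_heads: int = 4
    eca_kernel: int | None = None
    mlp_hidden: int = 256
    seed: int = 0
    ablate: tuple[str, ...] = ()
    attention_residual: bool = False
    normalize_adjacency: bool = True
    dtype: str = "float32"

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ContractError("embed_dim must be divisible by n_heads")
        if self.n_layers < 1:
            raise ContractError("n_layers must be at least 1")
        for a in self.ablate:
            if a not in ABLATIONS:
                raise ContractError(f"unknown ablation {a!r}")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[1] if len(shape) > 1 else shape[0]
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def init_params(config: ModelConfig, in_dim: int) -> dict[str, Tensor]:
    """Seeded symmetric-uniform (Glorot-style) parameter initialization."""
    rng = np.random.default_rng(config.seed)
    dt = config.np_dtype
    d = config.embed_dim
    dk = config.head_dim
    k = config.eca_kernel or eca_kernel_size(in_dim)

    def p(shape):
        return Tensor(_glorot(rng, shape, dt), requires_grad=True)

    params: dict[str, Tensor] = {
        "eca_kernel": p((k,)),
        "W1": p((in_dim, d)),
        "W2": p((d, d)),
        "WO": p((d, d)),
        "mlp_Wm": p((d, config.mlp_hidden)),
        "mlp_Wd": p((d, config.mlp_hidden)),
        "mlp_b1": Tensor(np.zeros(config.mlp_hidden, dtype=dt), requires_grad=True),
        "mlp_w2": p((config.mlp_hidden, 1)),
        "mlp_b2": Tensor(np.zeros(1, dtype=dt), requires_grad=True),
    }
    for i in range(config.n_heads):
        params[f"WQ{i}"] = p((d, dk))
        params[f"WK{i}"] = p((d, dk))
        params[f"WV{i}"] = p((d, dk))
    return params


def eca_recalibrate(X: Tensor, eca_kernel: Tensor) -> Tensor:
    """Channel recalibration: sigmoid(Conv1D(global average pool)) scales
    each feature channel of X; shape is preserved."""
    if X.shape[1] < 1:
        raise ContractError("eca_recalibrate needs at least one feature channel")
    n = X.shape[0]
    pool = Tensor(np.full((1, n), 1.0 / n, dtype=X.dtype))
    channel_means = (pool @ X).reshape(X.shape[1])
    weights = channel_means.conv1d_same(eca_kernel).sigmoid()
    return X * weights.reshape(1, X.shape[1])


def gcn_layer(M: Tensor, H: Tensor, W: Tensor) -> Tensor:
    """One graph convolution: ReLU(M @ H @ W)."""
    out = ((M @ H) @ W).relu()
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite values in graph convolution output")
    return out


def multi_head_self_attention(
    H: Tensor,
    params: dict[str, Tensor],
    n_heads: int,
    residual: bool = False,
) -> Tensor:
    """Scaled dot-product self-attention over nodes, heads concatenated and
    linearly recombined; output shape equals input shape."""
    dk = H.shape[1] // n_heads
    scale = 1.0 / math.sqrt(dk)
    heads = []
    for i in range(n_heads):
        Q = H @ params[f"WQ{i}"]
        K = H @ params[f"WK{i}"]
        V = H @ params[f"WV{i}"]
        att = ((Q @ K.T) * scale).softmax(axis=-1)
        heads.append(att @ V)
    out = concat(heads, axis=1) @ params["WO"]
    if residual:
        out = out + H
    return out


def attention_matrices(
    H: np.ndarray, params: dict[str, Tensor], n_heads: int
) -> list[np.ndarray]:
    """Row-stochastic attention matrices per head (diagnostic view)."""
    Ht = Tensor(np.asarray(H))
    dk = Ht.shape[1] // n_heads
    scale = 1.0 / math.sqrt(dk)
    mats = []
    for i in range(n_heads):
        Q = (Ht @ params[f"WQ{i}"]).data
        K = (Ht @ params[f"WK{i}"]).data
        z = Q @ K.T * scale
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        mats.append(e / e.sum(axis=1, keepdims=True))
    return mats


def adaptive_fuse(H1: Tensor, H2: Tensor, gamma: Tensor) -> Tensor:
    """Convex layer fusion gamma1*H1 + gamma2*H2 with softmax-mapped gamma."""
    if H1.shape != H2.shape:
        raise ContractError("layer outputs must share a shape for fusion")
    g1 = gamma.take_rows(np.array([0])).reshape(1, 1)
    g2 = gamma.take_rows(np.array([1])).reshape(1, 1)
    return H1 * g1 + H2 * g2


def score_pairs(
    H: Tensor,
    pairs: np.ndarray,
    params: dict[str, Tensor],
    n_mirna: int,
) -> Tensor:
    """MLP scoring of (miRNA, disease) pairs from the fused embeddings.

    The hidden layer acts on the concatenated pair representation
    [h_mi ; h_dj]; it is evaluated as h_mi @ Wm + h_dj @ Wd (the same linear
    map, with the per-node projections computed once for all pairs).
    """
    pairs = np.asarray(pairs, dtype=np.intp)
    n_nodes = H.shape[0]
    n_disease = n_nodes - n_mirna
    if pairs.size and (
        pairs[:, 0].min() < 0
        or pairs[:, 0].max() >= n_mirna
        or pairs[:, 1].min() < 0
        or pairs[:, 1].max() >= n_disease
    ):
        raise ContractError("pair indices out of range")
    U = H.take_rows(np.arange(n_mirna)) @ params["mlp_Wm"]
    V = H.take_rows(np.arange(n_mirna, n_nodes)) @ params["mlp_Wd"]
    hidden = (
        U.take_rows(pairs[:, 0]) + V.take_rows(pairs[:, 1]) + params["mlp_b1"]
    ).relu()
    logits = hidden @ params["mlp_w2"] + params["mlp_b2"]
    return logits.reshape(pairs.shape[0]).sigmoid()


def bce_loss(labels: np.ndarray, scores: Tensor | np.ndarray) -> Tensor:
    """Mean binary cross-entropy; scores clipped to [1e-7, 1-1e-7]."""
    labels = np.asarray(labels, dtype=np.float64)
    if labels.size == 0:
        raise ContractError("empty pair set")
    if not np.isin(labels, (0, 1)).all():
        raise ContractError("labels must be binary")
    if not isinstance(scores, Tensor):
        scores = Tensor(np.asarray(scores, dtype=np.float64))
    y = Tensor(labels.astype(scores.dtype))
    s = scores.clip(1e-7, 1.0 - 1e-7)
    return -(y * s.log() + (1.0 - y) * (1.0 - s).log()).mean()


def normalize_adjacency(M: np.ndarray) -> np.ndarray:
    """Optional symmetric normalization D^-1/2 (M) D^-1/2."""
    deg = M.sum(axis=1)
    deg[deg == 0] = 1.0
    inv = 1.0 / np.sqrt(deg)
    return M * inv[:, None] * inv[None, :]


def embed(
    M: Tensor,
    X: Tensor,
    params: dict[str, Tensor],
    gamma: Tensor,
    config: ModelConfig,
) -> Tensor:
    """Node embeddings: ECA -> GCN(1) -> self-attention -> GCN(2) ->
    adaptive layer fusion. Ablation flags replace the attention stages with
    identities."""
    no_attention = "attention" in config.ablate
    no_egcn = "egcn" in config.ablate

    H0 = X if no_attention else eca_recalibrate(X, params["eca_kernel"])
    H1 = gcn_layer(M, H0, params["W1"])
    if config.n_layers == 1:
        return H1
    if no_attention or no_egcn:
        Hmid = H1
    else:
        Hmid = multi_head_self_attention(
            H1, params, config.n_heads, residual=config.attention_residual
        )
    H2 = gcn_layer(M, Hmid, params["W2"])
    return adaptive_fuse(H1, H2, gamma)


def forward(
    M: Tensor,
    X: Tensor,
    params: dict[str, Tensor],
    gamma: Tensor,
    pairs: np.ndarray,
    n_mirna: int,
    config: ModelConfig,
) -> Tensor:
    """Full composition ending in pair scores in (0, 1)."""
    H = embed(M, X, params, gamma, config)
    return score_pairs(H, pairs, params, n_mirna)
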