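"""The CDR3 recognition network and its stages.

Architecture (all sizes configurable, defaults follow the published wiring):

* input: one CDR3 encoded as a zero-padded ``20 x 15`` matrix;
* multi-scale 1D convolution: kernels of heights 2, 3, 4, 5 spanning the full
  encoding width, 4 filters per height, ReLU;
* k-max pooling (k = 3) per filter, preserving the original order of the
  selected activations, giving one ``3 x 4`` block P per kernel height;
* multi-head self-attention (2 heads, model dim 4) applied within each block
  over its 3 pooled positions;
* the four attention-weighted blocks are concatenated along the channel
  dimension into a ``3 x 16`` sequence;
* a BiLSTM (hidden size m per direction, default 8) consumes that sequence,
  emitting ``3 x 2m`` concatenated forward/backward states;
* flatten -> fully connected hidden layer (6 units, ReLU, dropout 0.5 during
  training) -> linear output -> softmax over {non-cancer, cancer}.

Ablation flags bypass the attention and/or BiLSTM stages (identity
pass-through), leaving every tensor interface intact.

Everything operates on :class:`deepcatcr._autodiff.Tensor`; batching is over
the leading axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, concatenate, kmax_pool, log_softmax, softmax
from .encoding import AminoAcidProjection, PADDED_LENGTH, encode_cdr3

__all__ = [
    "ModelConfig", "init_parameters", "conv_multiscale", "self_attention",
    "bilstm", "forward", "forward_parts", "MotifImportance", "motif_importance",
]


class NumericError(RuntimeError):
    """A forward-pass stage produced non-finite values."""


@dataclass
class ModelConfig:
    """Architectural hyperparameters (defaults follow the published setup)."""

    kernel_heights: tuple[int, ...] = (2, 3, 4, 5)
    filters_per_height: int = 4
    kernel_width: int = 15  # must equal the encoding dimension
    k_pool: int = 3
    attn_heads: int = 2
    attn_hidden: int = 4  # model dim of the per-block attention (= filters)
    lstm_hidden: int = 8  # per direction
    fc_units: int = 6
    dropout: float = 0.5
    use_bilstm: bool = True
    use_mhsa: bool = True
    value_projection: bool = True  # False: attention weights the inputs directly
    padded_length: int = PADDED_LENGTH

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.attn_hidden % self.attn_heads:
            raise ValueError("attn_heads must divide attn_hidden")
        if self.k_pool > self.padded_length - max(self.kernel_heights) + 1:
            raise ValueError("k_pool larger than the shortest feature map")

    @property
    def n_blocks(self) -> int:
        return len(self.kernel_heights)

    @property
    def channels(self) -> int:
        return self.n_blocks * self.filters_per_height

    @property
    def flat_dim(self) -> int:
        width = 2 * self.lstm_hidden if self.use_bilstm else self.channels
        return self.k_pool * width

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_heights"] = list(self.kernel_heights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["kernel_heights"] = tuple(d["kernel_heights"])
        return cls(**d)


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def init_parameters(config: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """Fan-in uniform initialization of all learnable weights."""
    p: dict[str, Tensor] = {}
    d = config.kernel_width
    for k in config.kernel_heights:
        p[f"conv{k}.W"] = _uniform(rng, (k * d, config.filters_per_height), k * d)
        p[f"conv{k}.b"] = _uniform(rng, (config.filters_per_height,), k * d)
    if config.use_mhsa:
        h = config.attn_hidden
        for k in config.kernel_heights:
            p[f"attn{k}.Wq"] = _uniform(rng, (config.filters_per_height, h), h)
            p[f"attn{k}.Wk"] = _uniform(rng, (config.filters_per_height, h), h)
            if config.value_projection:
                p[f"attn{k}.Wv"] = _uniform(rng, (config.filters_per_height, h), h)
    if config.use_bilstm:
        c, m = config.channels, config.lstm_hidden
        for direction in ("fwd", "bwd"):
            p[f"lstm.{direction}.Wx"] = _uniform(rng, (c, 4 * m), c)
            p[f"lstm.{direction}.Wh"] = _uniform(rng, (m, 4 * m), m)
            p[f"lstm.{direction}.b"] = _uniform(rng, (4 * m,), m)
    p["fc.W"] = _uniform(rng, (config.flat_dim, config.fc_units), config.flat_dim)
    p["fc.b"] = _uniform(rng, (config.fc_units,), config.flat_dim)
    p["out.W"] = _uniform(rng, (config.fc_units, 2), config.fc_units)
    p["out.b"] = _uniform(rng, (2,), config.fc_units)
    return p


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def conv_multiscale(x: Tensor, params: dict[str, Tensor],
                    config: ModelConfig) -> dict[int, Tensor]:
    """Multi-scale 1D convolution with ReLU.

    ``x`` has shape (B, L, d).  For each kernel height k the kernel spans the
    full width d and slides over positions, producing a feature map of shape
    (B, L - k + 1, filters).
    """
    B, L, d = x.shape
    if d != config.kernel_width:
        raise ValueError(
            f"input width {d} != configured kernel width {config.kernel_width}")
    maps: dict[int, Tensor] = {}
    for k in config.kernel_heights:
        n_win = L - k + 1
        # gather sliding windows: (B, n_win, k*d); fancy-index through the
        # autodiff getitem so gradients scatter back
        idx = (np.arange(n_win)[:, None] + np.arange(k)[None, :])  # (n_win, k)
        windows = x[:, idx, :].reshape(B, n_win, k * d)
        maps[k] = (windows @ params[f"conv{k}.W"] + params[f"conv{k}.b"]).relu()
    return maps


def self_attention(H: Tensor, params_Wq: Tensor, params_Wk: Tensor,
                   params_Wv: Tensor | None, heads: int,
                   return_weights: bool = False):
    """Scaled dot-product multi-head self-attention over positions.

    ``H``: (B, n, c).  Q = H Wq, K = H Wk (and V = H Wv when a value
    projection is used; otherwise the attention weights are applied to the
    head-split input directly).  Heads attend in subspaces of size
    c_h = hidden / heads; outputs are concatenated back to the model width.
    """
    B, n, _ = H.shape
    hidden = params_Wq.shape[1]
    c_h = hidden // heads

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(B, n, heads, c_h).swapaxes(1, 2)  # (B, heads, n, c_h)

    Q = split_heads(H @ params_Wq)
    K = split_heads(H @ params_Wk)
    V = split_heads(H @ params_Wv) if params_Wv is not None else split_heads(H)
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(c_h))  # (B, heads, n, n)
    alpha = softmax(scores, axis=-1)
    out = (alpha @ V).swapaxes(1, 2).reshape(B, n, heads * c_h)
    if return_weights:
        return out, alpha
    return out


def _lstm_direction(steps: list[Tensor], Wx: Tensor, Wh: Tensor, b: Tensor,
                    m: int, B: int) -> list[Tensor]:
    h = Tensor(np.zeros((B, m)))
    c = Tensor(np.zeros((B, m)))
    outs = []
    for x_t in steps:
        gates = x_t @ Wx + h @ Wh + b  # (B, 4m): input, forget, cell, output
        i = gates[:, 0 * m:1 * m].sigmoid()
        f = gates[:, 1 * m:2 * m].sigmoid()
        g = gates[:, 2 * m:3 * m].tanh()
        o = gates[:, 3 * m:4 * m].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outs.append(h)
    return outs


def bilstm(A: Tensor, params: dict[str, Tensor], config: ModelConfig) -> Tensor:
    """Bidirectional LSTM over (B, T, c); output (B, T, 2m) = fwd || bwd."""
    B, T, _ = A.shape
    if T == 0:
        raise ValueError("empty sequence")
    m = config.lstm_hidden
    steps = [A[:, t, :] for t in range(T)]
    fwd = _lstm_direction(steps, params["lstm.fwd.Wx"], params["lstm.fwd.Wh"],
                          params["lstm.fwd.b"], m, B)
    bwd = _lstm_direction(steps[::-1], params["lstm.bwd.Wx"],
                          params["lstm.bwd.Wh"], params["lstm.bwd.b"], m, B)
    bwd = bwd[::-1]
    per_step = [concatenate([f.reshape(B, 1, m), r.reshape(B, 1, m)], axis=2)
                for f, r in zip(fwd, bwd)]
    return concatenate(per_step, axis=1)


def forward_parts(x: Tensor, params: dict[str, Tensor], config: ModelConfig,
                  train: bool = False,
                  rng: np.random.Generator | None = None) -> dict:
    """Full forward pass, returning logits and named intermediates."""
    maps = conv_multiscale(x, params, config)
    blocks = []
    for k in config.kernel_heights:
        pooled = kmax_pool(maps[k], config.k_pool, axis=1)  # (B, k_pool, filters)
        if config.use_mhsa:
            pooled = self_attention(
                pooled, params[f"attn{k}.Wq"], params[f"attn{k}.Wk"],
                params.get(f"attn{k}.Wv"), config.attn_heads)
        blocks.append(pooled)
    H = concatenate(blocks, axis=2)  # (B, k_pool, channels)
    if config.use_bilstm:
        H = bilstm(H, params, config)
    B = H.shape[0]
    flat = H.reshape(B, config.flat_dim)
    hidden = (flat @ params["fc.W"] + params["fc.b"]).relu()
    if train and config.dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - config.dropout
        mask = (rng.random(hidden.shape) < keep) / keep  # inverted dropout
        hidden = hidden * Tensor(mask)
    logits = hidden @ params["out.W"] + params["out.b"]
    for name, t in (("conv+pool+attn", H), ("logits", logits)):
        if not np.all(np.isfinite(t.data)):
            raise NumericError(f"non-finite values after stage {name!r}")
    return {"logits": logits, "H": H, "flat": flat}


def forward(x: Tensor | np.ndarray, params: dict[str, Tensor],
            config: ModelConfig, train: bool = False,
            rng: np.random.Generator | None = None) -> Tensor:
    """Class-probability output, shape (B, 2); column 1 is the cancer score."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    parts = forward_parts(x, params, config, train=train, rng=rng)
    return softmax(parts["logits"], axis=-1)


def batch_loss(x: Tensor, y: np.ndarray, params: dict[str, Tensor],
               config: ModelConfig, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
    """Mean cross-entropy of the batch (labels in {0, 1})."""
    parts = forward_parts(x, params, config, train=train, rng=rng)
    ls = log_softmax(parts["logits"], axis=-1)  # (B, 2)
    onehot = np.zeros((len(y), 2))
    onehot[np.arange(len(y)), y] = 1.0
    return -(ls * Tensor(onehot)).sum() * (1.0 / len(y))


# --------------------------------------------------------------------------
# Motif importance (occlusion)
# --------------------------------------------------------------------------

@dataclass
class MotifImportance:
    sequence: str
    residue_scores: np.ndarray  # one nonnegative score per residue
    top_motifs: list[tuple[str, float]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def motif_importance(
    sequence: str,
    params: dict[str, Tensor],
    config: ModelConfig,
    projection: AminoAcidProjection,
    window_lengths: tuple[int, ...] = (2, 3, 4, 5),
    n_top: int = 5,
    trained: bool = True,
) -> MotifImportance:
    """Occlusion-based per-residue importance and top contiguous motifs.

    Each residue's encoding row is zeroed in turn; the importance is the
    nonnegative drop in the cancer score.  Contiguous windows (lengths
    matching the convolution kernel heights by default) are ranked by the
    sum of their residue importances.
    """
    enc = encode_cdr3(sequence, projection)
    n = enc.true_length
    batch = np.repeat(enc.matrix[None], n + 1, axis=0)
    for i in range(n):
        batch[i + 1, i, :] = 0.0  # occlude residue i
    scores = forward(batch, params, config, train=False).data[:, 1]
    base = scores[0]
    residue_scores = np.maximum(0.0, base - scores[1:])
    windows: list[tuple[str, float, int]] = []
    for w in window_lengths:
        for start in range(0, n - w + 1):
            windows.append((sequence[start:start + w],
                            float(residue_scores[start:start + w].sum()), start))
    windows.sort(key=lambda t: (-t[1], t[2], t[0]))
    top = [(motif, score) for motif, score, _ in windows[:n_top]]
    return MotifImportance(
        sequence=sequence,
        residue_scores=residue_scores,
        top_motifs=top,
        metadata={
            "base_score": float(base),
            "trained": bool(trained),
            # (start, length, score) for each reported window, so callers can
            # disambiguate repeated substrings
            "top_windows": [(start, len(motif), score)
                            for motif, score, start in windows[:n_top]],
        },
    )
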