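"""Triple cross-attention fusion of the three source embeddings.

Six directed cross-attention interactions (every ordered pair of
{remote sensing, climate, soil}) are computed with an efficient additive
attention, concatenated along the channel axis, refined by a
convolutional residual block, and gated:

    x_end = x * LayerNorm(Sigmoid(Linear(ReLU(Dropout(Linear(x))))))

Simple fusion baselines (concat / add / avg / max over the aligned
embeddings) are provided as drop-in alternatives for ablation studies.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .autograd import Tensor, cat, maximum
from .features import CRB, CRBSpec, SourceEmbedding
from .nn import Dropout, LayerNorm, Linear, Module

__all__ = [
    "CrossPair", "ALL_PAIRS", "FusedFeature", "EfficientAdditiveAttention",
    "TCAFM", "SimpleFusion", "align_tokens", "resample_matrix",
]

SOURCES = ("rs", "cl", "so")


@dataclasses.dataclass(frozen=True)
class CrossPair:
    query: str
    key: str

    def __post_init__(self):
        if self.query not in SOURCES or self.key not in SOURCES:
            raise ValueError(f"unknown source in pair {self}")
        if self.query == self.key:
            raise ValueError("cross-attention pair needs two distinct sources")


#: the six directed pairs, in a fixed canonical order
ALL_PAIRS: tuple[CrossPair, ...] = tuple(
    CrossPair(q, k) for q, k in itertools.permutations(SOURCES, 2))


@dataclasses.dataclass
class FusedFeature:
    """Fusion output: (batch, tokens, d_fused) plus pair provenance."""

    tensor: Tensor
    provenance: tuple[CrossPair, ...]

    def __post_init__(self):
        if not np.isfinite(self.tensor.data).all():
            raise ValueError("non-finite fused feature")

    @property
    def n_tokens(self) -> int:
        return self.tensor.shape[1]

    @property
    def d_fused(self) -> int:
        return self.tensor.shape[2]


def resample_matrix(t_in: int, t_out: int) -> np.ndarray:
    """Linear-interpolation resampling matrix R (t_out x t_in): y = R @ x."""
    if t_in == t_out:
        return np.eye(t_in)
    r = np.zeros((t_out, t_in))
    if t_in == 1:
        r[:, 0] = 1.0
        return r
    pos = np.linspace(0.0, t_in - 1.0, t_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, t_in - 1)
    frac = pos - lo
    r[np.arange(t_out), lo] += 1.0 - frac
    r[np.arange(t_out), hi] += frac
    return r


def align_tokens(x: Tensor, t_out: int) -> Tensor:
    """Resample the token axis of (B, T, d) to t_out tokens."""
    t_in = x.shape[1]
    if t_in == t_out:
        return x
    return Tensor(resample_matrix(t_in, t_out)) @ x


class EfficientAdditiveAttention(Module):
    """Linear-complexity additive attention with a learned global query.

    scores  a_i = (Q_i . w) / sqrt(d)
    alpha   = softmax(a)
    g       = sum_i alpha_i Q_i
    out_i   = LayerNorm(Q_i + Linear(g * K_i))
    """

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.d = d
        from .autograd import Parameter
        self.w = Parameter(rng.standard_normal(d) / np.sqrt(d))
        self.proj = Linear(d, d, rng)
        self.norm = LayerNorm(d)

    def attention_weights(self, q: Tensor) -> Tensor:
        scores = (q @ self.w.reshape(self.d, 1))[:, :, 0] * (self.d ** -0.5)
        return scores.softmax(axis=-1)  # (B, T)

    def __call__(self, q: Tensor, k: Tensor) -> Tensor:
        if q.shape[1] != k.shape[1]:
            raise ValueError(
                f"token counts differ after alignment: {q.shape[1]} vs {k.shape[1]}")
        alpha = self.attention_weights(q)                      # (B, T)
        b, t, d = q.shape
        g = (alpha.reshape(b, t, 1) * q).sum(axis=1)           # (B, d)
        interact = self.proj(g.reshape(b, 1, d) * k)           # (B, T, d)
        return self.norm(q + interact)


class _FusionGate(Module):
    """g = LayerNorm(Sigmoid(Linear(ReLU(Dropout(Linear(x))))))"""

    def __init__(self, d: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(d, d, rng)
        self.drop = Dropout(dropout, rng)
        self.lin2 = Linear(d, d, rng)
        self.norm = LayerNorm(d)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.lin2(self.drop(self.lin1(x)).relu()).sigmoid())


class TCAFM(Module):
    """Triple cross-attention fusion over the three source embeddings.

    Each of the six directed pairs has its own Q/K projections and
    attention parameters (the shared-weights reading is ambiguous in the
    source; independent weights are the default here).
    """

    def __init__(self, d_model: int, d_attn: int | None = None,
                 dropout: float = 0.1, crb_blocks: int = 1,
                 crb_kernel: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d_model = d_model
        self.d_attn = d_attn or d_model
        self.d_fused = d_model
        self.q_projs = {}
        self.k_projs = {}
        self.attns = {}
        for pair in ALL_PAIRS:
            name = f"{pair.query}2{pair.key}"
            self.q_projs[name] = Linear(d_model, self.d_attn, rng)
            self.k_projs[name] = Linear(d_model, self.d_attn, rng)
            self.attns[name] = EfficientAdditiveAttention(self.d_attn, rng)
        self.crb = CRB(CRBSpec(6 * self.d_attn, self.d_fused,
                               kernel=crb_kernel, n_blocks=crb_blocks), rng)
        self.gate = _FusionGate(self.d_fused, dropout, rng)

    def project_qk(self, pair: CrossPair,
                   query_emb: SourceEmbedding,
                   key_emb: SourceEmbedding) -> tuple[Tensor, Tensor]:
        name = f"{pair.query}2{pair.key}"
        return (self.q_projs[name](query_emb.tensor),
                self.k_projs[name](key_emb.tensor))

    def __call__(self, rs: SourceEmbedding, cl: SourceEmbedding,
                 so: SourceEmbedding) -> FusedFeature:
        embs = {"rs": rs, "cl": cl, "so": so}
        for tag, emb in embs.items():
            if emb is None:
                raise ValueError(f"missing source embedding {tag!r}")
        if not (rs.d_model == cl.d_model == so.d_model):
            raise ValueError("source embeddings disagree on d_model")
        t_max = max(e.n_tokens for e in embs.values())
        aligned = {tag: SourceEmbedding(tag, align_tokens(e.tensor, t_max))
                   for tag, e in embs.items()}
        outputs = []
        for pair in ALL_PAIRS:
            q, k = self.project_qk(pair, aligned[pair.query], aligned[pair.key])
            name = f"{pair.query}2{pair.key}"
            outputs.append(self.attns[name](q, k))
        x = cat(outputs, axis=-1)                              # (B, T, 6*d_attn)
        x = self.crb(x.swapaxes(-1, -2)).swapaxes(-1, -2)      # (B, T, d_fused)
        x_end = x * self.gate(x)
        return FusedFeature(tensor=x_end, provenance=ALL_PAIRS)


class SimpleFusion(Module):
    """Baseline fusion of the three embeddings: concat/add/avg/max.

    Token counts are aligned first; add/avg/max additionally require the
    embeddings to share d_model (enforced upstream by construction).
    ``concat`` stacks channels (3 * d_model).
    """

    METHODS = ("concat", "add", "avg", "max")

    def __init__(self, d_model: int, method: str):
        super().__init__()
        if method not in self.METHODS:
            raise ValueError(f"unknown fusion method {method!r}")
        self.method = method
        self.d_fused = 3 * d_model if method == "concat" else d_model

    def __call__(self, rs: SourceEmbedding, cl: SourceEmbedding,
                 so: SourceEmbedding) -> FusedFeature:
        t_max = max(e.n_tokens for e in (rs, cl, so))
        xs = [align_tokens(e.tensor, t_max) for e in (rs, cl, so)]
        if self.method == "concat":
            out = cat(xs, axis=-1)
        elif self.method == "add":
            out = xs[0] + xs[1] + xs[2]
        elif self.method == "avg":
            out = (xs[0] + xs[1] + xs[2]) * (1.0 / 3.0)
        else:
            out = maximum(maximum(xs[0], xs[1]), xs[2])
        return FusedFeature(tensor=out, provenance=())
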