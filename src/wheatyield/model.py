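"""Yield prediction head.

Covariate tokens (time, region, area) are prepended to the fused feature
tokens, sinusoidal positional encoding is added, a 2-layer dual-branch
encoder (multi-head self-attention in parallel with graph attention over
a local token graph) processes the sequence, and a 2-layer Fourier
decoder with a linear head produces the scalar yield.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autograd import Tensor, cat
from .dataset import CovariateEncoding, Preprocessor
from .features import MultiSourceExtractor, TFESpec
from .fusion import TCAFM, FusedFeature, SimpleFusion, SourceEmbedding
from .nn import Dropout, LayerNorm, Linear, Module, sinusoidal_positions

__all__ = [
    "ModelConfig", "EncoderLayerSpec", "FANLayerSpec", "MultiHeadSelfAttention",
    "GraphAttention", "EncoderLayer", "FANLayer", "YieldModel",
    "build_adjacency", "save_checkpoint", "load_checkpoint",
]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class EncoderLayerSpec:
    d_model: int = 32
    n_heads: int = 4
    graph: str = "window_k"          # {"full", "window_k"}
    graph_radius: int = 2
    merge: str = "sum"               # {"sum", "concat_project"}
    ffn_dim: int = 64

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"n_heads ({self.n_heads}) must divide d_model ({self.d_model})")
        if self.graph not in ("full", "window_k"):
            raise ConfigError(f"unknown graph rule {self.graph!r}")
        if self.merge not in ("sum", "concat_project"):
            raise ConfigError(f"unknown merge rule {self.merge!r}")


@dataclasses.dataclass(frozen=True)
class FANLayerSpec:
    d_in: int
    d_p: int = 16
    d_pbar: int = 32

    @property
    def d_out(self) -> int:
        return 2 * self.d_p + self.d_pbar


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """All hyperparameters in one place."""

    n_regions: int = 196
    d_model: int = 32
    d_attn: int = 32
    n_heads: int = 4
    tfe_window: int = 3
    tfe_stride: int = 1
    gru_layers: int = 2
    crb_blocks: int = 2
    crb_kernel: int = 3
    dropout: float = 0.1
    encoder_layers: int = 2
    ffn_dim: int = 64
    graph: str = "window_k"
    graph_radius: int = 2
    merge: str = "sum"
    fan_dp: int = 16
    fan_dpbar: int = 32
    use_tfe: bool = True
    use_gat: bool = True
    fusion: str = "tcafm"            # {"tcafm", "concat", "add", "avg", "max"}
    sources: tuple[str, ...] = ("rs", "cl", "so")
    n_months: int = 9
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sources"] = list(self.sources)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["sources"] = tuple(d["sources"])
        return cls(**d)


def build_adjacency(n_tokens: int, rule: str = "window_k",
                    radius: int = 2) -> np.ndarray:
    """Symmetric 0/1 adjacency with self-loops over the token chain."""
    if rule == "full":
        return np.ones((n_tokens, n_tokens))
    if rule != "window_k":
        raise ConfigError(f"unknown adjacency rule {rule!r}")
    idx = np.arange(n_tokens)
    adj = (np.abs(idx[:, None] - idx[None, :]) <= radius).astype(float)
    return adj


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ConfigError("n_heads must divide d_model")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        def split(z):  # (B, T, d) -> (B, h, T, dk)
            return z.reshape(b, t, self.h, self.dk).swapaxes(1, 2)
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (self.dk ** -0.5)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).swapaxes(1, 2).reshape(b, t, d)
        return self.wo(out)


class GraphAttention(Module):
    """Single-layer graph attention over tokens-as-nodes.

    Edge score e_ij = LeakyReLU(a_src . Wh_i + a_dst . Wh_j), masked
    softmax over each node's neighbourhood, aggregation of value
    projections.
    """

    def __init__(self, d_model: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        super().__init__()
        from .autograd import Parameter
        self.w = Linear(d_model, d_model, rng, bias=False)
        self.a_src = Parameter(rng.standard_normal(d_model) / np.sqrt(d_model))
        self.a_dst = Parameter(rng.standard_normal(d_model) / np.sqrt(d_model))
        self.slope = negative_slope

    def __call__(self, x: Tensor, adjacency: np.ndarray) -> Tensor:
        t = x.shape[1]
        adjacency = np.asarray(adjacency, dtype=float)
        if adjacency.shape != (t, t):
            raise ValueError(f"adjacency shape {adjacency.shape} != ({t}, {t})")
        if not np.allclose(adjacency, adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.diag(adjacency) > 0):
            raise ValueError("adjacency must include self-loops")
        h = self.w(x)                                           # (B, T, d)
        b, _, d = h.shape
        s_src = (h @ self.a_src.reshape(d, 1))                  # (B, T, 1)
        s_dst = (h @ self.a_dst.reshape(d, 1))
        e = s_src + s_dst.swapaxes(-1, -2)                      # (B, T, T)
        e = _leaky_relu(e, self.slope)
        neg = Tensor(np.where(adjacency > 0, 0.0, -1e30)[None, :, :])
        alpha = (e + neg).softmax(axis=-1)
        return alpha @ h


def _leaky_relu(x: Tensor, slope: float) -> Tensor:
    return x.relu() - (-x).relu() * slope


class EncoderLayer(Module):
    """One dual-branch encoder layer: MHSA parallel to graph attention,
    branch merge, residual + LayerNorm, position-wise FFN, residual +
    LayerNorm.  With ``use_gat=False`` this is a vanilla Transformer
    encoder layer."""

    def __init__(self, spec: EncoderLayerSpec, rng: np.random.Generator,
                 use_gat: bool = True, dropout: float = 0.0,
                 drop_rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        self.use_gat = use_gat
        self.mhsa = MultiHeadSelfAttention(spec.d_model, spec.n_heads, rng)
        if use_gat:
            self.gat = GraphAttention(spec.d_model, rng)
            if spec.merge == "concat_project":
                self.merge_proj = Linear(2 * spec.d_model, spec.d_model, rng)
        self.norm1 = LayerNorm(spec.d_model)
        self.ffn1 = Linear(spec.d_model, spec.ffn_dim, rng)
        self.ffn2 = Linear(spec.ffn_dim, spec.d_model, rng)
        self.norm2 = LayerNorm(spec.d_model)
        self.drop = Dropout(dropout, drop_rng or rng)

    def __call__(self, x: Tensor, adjacency: np.ndarray) -> Tensor:
        b1 = self.mhsa(x)
        if self.use_gat:
            b2 = self.gat(x, adjacency)
            if self.spec.merge == "sum":
                merged = b1 + b2
            else:
                merged = self.merge_proj(cat([b1, b2], axis=-1))
        else:
            merged = b1
        x = self.norm1(x + self.drop(merged))
        f = self.ffn2(self.ffn1(x).relu())
        return self.norm2(x + self.drop(f))


class FANLayer(Module):
    """Fourier layer: [cos(Wp x) || sin(Wp x) || gelu(Bp + Wpbar x)]."""

    def __init__(self, spec: FANLayerSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.wp = Linear(spec.d_in, spec.d_p, rng, bias=False)
        self.wpbar = Linear(spec.d_in, spec.d_pbar, rng)

    def __call__(self, x: Tensor) -> Tensor:
        p = self.wp(x)
        return cat([p.cos(), p.sin(), self.wpbar(x).gelu()], axis=-1)


class YieldModel(Module):
    """End-to-end model: extract -> fuse -> encode -> decode.

    Operates on normalized inputs/targets; the surrounding
    :class:`~wheatyield.dataset.Preprocessor` owns de-normalization.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
        self.drop_rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, 0xD0)).generate_state(4))
        window = min(cfg.tfe_window, cfg.n_months)
        tfe = TFESpec(window=window, stride=cfg.tfe_stride,
                      gru_layers=cfg.gru_layers, hidden=cfg.d_model)
        self.extractor = MultiSourceExtractor(
            cfg.d_model, rng, tfe_spec=tfe, use_tfe=cfg.use_tfe)
        if cfg.fusion == "tcafm":
            self.fuser = TCAFM(cfg.d_model, cfg.d_attn, dropout=cfg.dropout,
                               crb_blocks=1, crb_kernel=cfg.crb_kernel, rng=rng)
        elif cfg.fusion in SimpleFusion.METHODS:
            self.fuser = SimpleFusion(cfg.d_model, cfg.fusion)
        elif cfg.fusion == "none":
            self.fuser = None
        else:
            raise ConfigError(f"unknown fusion {cfg.fusion!r}")
        d_fused = self.fuser.d_fused if self.fuser is not None else cfg.d_model
        self.input_proj = Linear(d_fused, cfg.d_model, rng)
        self.time_proj = Linear(1, cfg.d_model, rng)
        self.region_proj = Linear(cfg.n_regions, cfg.d_model, rng)
        self.area_proj = Linear(1, cfg.d_model, rng)
        spec = EncoderLayerSpec(d_model=cfg.d_model, n_heads=cfg.n_heads,
                                graph=cfg.graph, graph_radius=cfg.graph_radius,
                                merge=cfg.merge, ffn_dim=cfg.ffn_dim)
        self.encoder_layers = [
            EncoderLayer(spec, rng, use_gat=cfg.use_gat, dropout=cfg.dropout,
                         drop_rng=self.drop_rng)
            for _ in range(cfg.encoder_layers)
        ]
        fan1 = FANLayerSpec(cfg.d_model, cfg.fan_dp, cfg.fan_dpbar)
        fan2 = FANLayerSpec(fan1.d_out, cfg.fan_dp, cfg.fan_dpbar)
        self.fan1 = FANLayer(fan1, rng)
        self.fan2 = FANLayer(fan2, rng)
        self.head = Linear(fan2.d_out, 1, rng)

    # -- stages ---------------------------------------------------------------

    def fuse(self, rs: SourceEmbedding, cl: SourceEmbedding,
             so: SourceEmbedding) -> FusedFeature:
        if self.fuser is None:  # single-source ablation
            embs = {"rs": rs, "cl": cl, "so": so}
            only = embs[self.cfg.sources[0]]
            return FusedFeature(tensor=only.tensor, provenance=())
        return self.fuser(rs, cl, so)

    def assemble_input(self, fused: FusedFeature,
                       cov: CovariateEncoding) -> Tensor:
        """Project covariates to d_model, prepend as tokens, add positions."""
        x = self.input_proj(fused.tensor)
        b = x.shape[0]
        toks = [
            self.time_proj(Tensor(cov.time)).reshape(b, 1, self.cfg.d_model),
            self.region_proj(Tensor(cov.region)).reshape(b, 1, self.cfg.d_model),
            self.area_proj(Tensor(cov.area)).reshape(b, 1, self.cfg.d_model),
            x,
        ]
        seq = cat(toks, axis=1)
        pos = sinusoidal_positions(seq.shape[1], self.cfg.d_model)
        return seq + Tensor(pos[None, :, :])

    def encode(self, tokens: Tensor) -> Tensor:
        adj = build_adjacency(tokens.shape[1], self.cfg.graph,
                              self.cfg.graph_radius)
        for layer in self.encoder_layers:
            tokens = layer(tokens, adj)
        return tokens

    def decode(self, tokens: Tensor) -> Tensor:
        pooled = tokens.mean(axis=1)                 # mean over tokens
        return self.head(self.fan2(self.fan1(pooled)))[:, 0]

    def forward(self, batch: dict, cov: CovariateEncoding) -> Tensor:
        """batch: normalized arrays/Tensors keyed rs/cl/sd/ss -> (B,) yields
        on the normalized scale."""
        rs, cl, so = self.extractor(batch)
        fused = self.fuse(rs, cl, so)
        tokens = self.assemble_input(fused, cov)
        tokens = self.encode(tokens)
        out = self.decode(tokens)
        if not np.isfinite(out.data).all():
            raise FloatingPointError("non-finite prediction at decode stage")
        return out

    __call__ = forward

    def predict(self, arrays: dict, prep: Preprocessor) -> np.ndarray:
        """De-normalized yield predictions (kg/hm^2) for raw stacked arrays."""
        was_training = self.training
        self.eval()
        try:
            batch = {k: Tensor(v) for k, v in prep.encode_series(arrays).items()}
            cov = prep.encode_covariates(arrays)
            z = self.forward(batch, cov)
        finally:
            if was_training:
                self.train()
        return prep.decode_target(z.data)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: YieldModel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    path.with_suffix(".config.json").write_text(model.cfg.to_json())


def load_checkpoint(path) -> YieldModel:
    path = Path(path)
    cfg = ModelConfig.from_json(path.with_suffix(".config.json").read_text())
    model = YieldModel(cfg)
    npz = path if path.exists() else Path(str(path) + ".npz")
    with np.load(npz) as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model
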