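"""Per-source deep feature extraction.

Dynamic sources (remote sensing, climate, dynamic soil) go through a
temporal feature extractor: sliding windows over the month axis, a stack
of GRUs per window, and a convolutional residual block (CRB) over the
resulting token sequence.  The static soil vector is lifted to a single
token and refined by a CRB.  All sources emit embeddings with a common
model dimension so the fusion stage can cross-attend between them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autograd import Tensor, cat
from .nn import Conv1d, GRU, LayerNorm, Linear, Module

__all__ = [
    "CRBSpec", "TFESpec", "SourceEmbedding", "CRB", "TFE",
    "MultiSourceExtractor", "n_windows",
]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class CRBSpec:
    channels_in: int
    channels_out: int
    kernel: int = 3
    n_blocks: int = 2

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ConfigError(f"CRB kernel must be odd positive, got {self.kernel}")
        if min(self.channels_in, self.channels_out, self.n_blocks) < 1:
            raise ConfigError("CRB channels and block count must be positive")


@dataclasses.dataclass(frozen=True)
class TFESpec:
    window: int = 3
    stride: int = 1
    gru_layers: int = 2
    hidden: int = 64
    crb: CRBSpec = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.window < 1 or self.stride < 1:
            raise ConfigError("window and stride must be positive")
        if self.gru_layers < 2:
            raise ConfigError("TFE uses at least 2 stacked GRUs")
        if self.crb is None:
            object.__setattr__(self, "crb", CRBSpec(self.hidden, self.hidden))

    def n_tokens(self, n_months: int) -> int:
        return n_windows(n_months, self.window, self.stride)


def n_windows(length: int, window: int, stride: int) -> int:
    """Number of sliding windows: floor((L - window)/stride) + 1."""
    if window > length:
        raise ConfigError(f"window {window} exceeds series length {length}")
    return (length - window) // stride + 1


@dataclasses.dataclass
class SourceEmbedding:
    """Embedding of one source: (batch, tokens, d_model)."""

    tag: str  # {"rs", "cl", "so"}
    tensor: Tensor

    def __post_init__(self):
        if not np.isfinite(self.tensor.data).all():
            raise ValueError(f"non-finite values in {self.tag} embedding")

    @property
    def n_tokens(self) -> int:
        return self.tensor.shape[1]

    @property
    def d_model(self) -> int:
        return self.tensor.shape[2]


class CRB(Module):
    """Stack of convolutional residual blocks over (B, C, L) tensors.

    Each block: conv -> layer norm (over channels, per position) -> ReLU
    -> conv, added to the skip path.  The first block projects the skip
    with a 1x1 convolution when channel counts differ.
    """

    def __init__(self, spec: CRBSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c_in, c_out = spec.channels_in, spec.channels_out
        self.blocks = []
        self.projections = []
        for b in range(spec.n_blocks):
            ci = c_in if b == 0 else c_out
            conv1 = Conv1d(ci, c_out, spec.kernel, rng)
            norm = LayerNorm(c_out)
            conv2 = Conv1d(c_out, c_out, spec.kernel, rng)
            self.blocks.append(_CRBBlock(conv1, norm, conv2))
            if ci != c_out:
                self.projections.append(Conv1d(ci, c_out, 1, rng, bias=False))
            else:
                self.projections.append(None)

    def __call__(self, x: Tensor) -> Tensor:
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite input to CRB")
        for block, proj in zip(self.blocks, self.projections):
            skip = x if proj is None else proj(x)
            x = skip + block(x)
        return x


class _CRBBlock(Module):
    def __init__(self, conv1: Conv1d, norm: LayerNorm, conv2: Conv1d):
        super().__init__()
        self.conv1 = conv1
        self.norm = norm
        self.conv2 = conv2

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        # LayerNorm normalizes the last axis; swap channels there and back
        h = self.norm(h.swapaxes(-1, -2)).swapaxes(-1, -2)
        return self.conv2(h.relu())


class TFE(Module):
    """Temporal feature extractor for one dynamic source.

    Sliding windows over months -> stacked GRU per window (the final
    hidden state of the top layer is the window's token) -> CRB over the
    token axis.
    """

    def __init__(self, n_vars: int, spec: TFESpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.gru = GRU(n_vars, spec.hidden, spec.gru_layers, rng)
        self.crb = CRB(spec.crb, rng)

    def __call__(self, series: Tensor) -> Tensor:
        """series: (B, months, vars) -> (B, n_windows, hidden)."""
        if not np.isfinite(series.data).all():
            raise ValueError("non-finite input to TFE")
        b, months, n_vars = series.shape
        w, s = self.spec.window, self.spec.stride
        nw = n_windows(months, w, s)
        # gather windows into the batch axis: (B * nw, w, vars)
        starts = [i * s for i in range(nw)]
        windows = cat([series[:, st:st + w, :] for st in starts], axis=0)
        tokens = self.gru.final_state(windows)           # (nw * B, hidden)
        tokens = tokens.reshape(nw, b, self.spec.hidden).swapaxes(0, 1)
        refined = self.crb(tokens.swapaxes(-1, -2))       # channels x tokens
        return refined.swapaxes(-1, -2)


class MultiSourceExtractor(Module):
    """Extract aligned embeddings for remote sensing, climate and soil.

    Each dynamic source has independent TFE weights.  The soil embedding
    concatenates the dynamic-soil TFE tokens with one static-soil token
    (linear lift of the 16-vector refined by a CRB) along the token axis.
    ``use_tfe=False`` swaps each TFE for a per-month linear embedding
    (ablation path).
    """

    def __init__(self, d_model: int, rng: np.random.Generator,
                 tfe_spec: TFESpec | None = None, use_tfe: bool = True,
                 static_dim: int = 16, rs_vars: int = 2, cl_vars: int = 7,
                 sd_vars: int = 4):
        super().__init__()
        spec = tfe_spec or TFESpec(hidden=d_model)
        if spec.hidden != d_model:
            raise ConfigError(
                f"TFE hidden ({spec.hidden}) must equal d_model ({d_model})")
        self.d_model = d_model
        self.spec = spec
        self.use_tfe = use_tfe
        if use_tfe:
            self.tfe_rs = TFE(rs_vars, spec, rng)
            self.tfe_cl = TFE(cl_vars, spec, rng)
            self.tfe_sd = TFE(sd_vars, spec, rng)
        else:
            self.embed_rs = Linear(rs_vars, d_model, rng)
            self.embed_cl = Linear(cl_vars, d_model, rng)
            self.embed_sd = Linear(sd_vars, d_model, rng)
        self.static_lift = Linear(static_dim, d_model, rng)
        self.static_crb = CRB(CRBSpec(d_model, d_model, kernel=1, n_blocks=1), rng)

    def _dynamic(self, key: str, x: Tensor) -> Tensor:
        if self.use_tfe:
            return getattr(self, f"tfe_{key}")(x)
        return getattr(self, f"embed_{key}")(x)

    def __call__(self, batch: dict[str, Tensor | np.ndarray]
                 ) -> tuple[SourceEmbedding, SourceEmbedding, SourceEmbedding]:
        rs = Tensor._lift(batch["rs"])
        cl = Tensor._lift(batch["cl"])
        sd = Tensor._lift(batch["sd"])
        ss = Tensor._lift(batch["ss"])
        e_rs = self._dynamic("rs", rs)
        e_cl = self._dynamic("cl", cl)
        e_sd = self._dynamic("sd", sd)
        b = ss.shape[0]
        static_tok = self.static_lift(ss).reshape(b, 1, self.d_model)
        static_tok = self.static_crb(static_tok.swapaxes(-1, -2)).swapaxes(-1, -2)
        e_so = cat([e_sd, static_tok], axis=1)
        return (SourceEmbedding("rs", e_rs), SourceEmbedding("cl", e_cl),
                SourceEmbedding("so", e_so))
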