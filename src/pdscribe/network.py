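"""The drawing classifier: depthwise-separable backbone with multiscale gated
multi-head attention fusion.

Architecture, in the order data flows through it:

1. Five convolutional stages. Each stage applies two convolution blocks
   (conv -> batch norm -> ReLU) followed by max-pooling; stages 1-2 use
   depthwise-separable convolutions throughout, stages 3-5 open with one
   standard convolution and stay separable after that. Default filter counts
   are (64, 128, 256, 512, 512) with stride-2 pooling at every stage, so a
   256x256x3 input yields stage maps of spatial size 128, 64, 32, 16, 8.
2. Three attention branches tap stages 3, 4, 5 (fine, medium, coarse).
   Each branch projects its feature map with a pointwise convolution to depth
   d = 192, adaptively average-pools to 7x7, flattens to L = 49 tokens, and
   runs multi-head self-attention (scaled dot product, heads concatenated,
   output-projected, residual added; no positional encoding).
3. A shared gating network turns each branch's spatially averaged descriptor
   into a scalar score; a softmax over the three scores yields gate weights
   alpha_b that scale the branches before channel-wise concatenation
   (7x7x3d). A pointwise reduction to 32 channels and global average pooling
   produce the 32-vector fed to the softmax classification head
   (class index 0 = PD, 1 = healthy).

Everything runs on plain NumPy arrays (NHWC layout). The backward pass is
hand-wired for this fixed graph and validated by finite differences.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConvSpec",
    "BackboneConfig",
    "BranchConfig",
    "AttentionParams",
    "GateParams",
    "HeadParams",
    "ModelConfig",
    "MgmaDscnn",
    "conv_standard",
    "depthwise_separable",
    "ccr",
    "params_standard_conv",
    "params_separable_conv",
    "backbone_forward",
    "project_branch",
    "multi_head_attention",
    "gate_weights",
    "fuse_reduce_pool",
    "classify",
    "count_parameters",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    kernel_size: int
    in_channels: int
    out_channels: int
    stride: int = 1
    padding: str = "same"
    separable: bool = True

    def __post_init__(self) -> None:
        if min(self.kernel_size, self.in_channels, self.out_channels) < 1:
            raise ValueError("kernel size and channel counts must be >= 1")


@dataclass(frozen=True)
class BackboneConfig:
    filters: tuple = (64, 128, 256, 512, 512)
    pool_strides: tuple = (2, 2, 2, 2, 2)
    kernel_size: int = 3
    activation: str = "relu"
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if len(self.filters) != 5 or len(self.pool_strides) != 5:
            raise ValueError("backbone has exactly 5 stages")


@dataclass(frozen=True)
class BranchConfig:
    source_stages: tuple = (3, 4, 5)  # 1-based stage indices (fine->coarse)
    proj_hw: int = 7
    depth: int = 192

    def __post_init__(self) -> None:
        if len(self.source_stages) != 3:
            raise ValueError("exactly three attention branches")


@dataclass
class AttentionParams:
    heads: int
    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray

    def __post_init__(self) -> None:
        d = self.wq.shape[0]
        if d % self.heads != 0:
            raise ValueError("head count must divide the embedding dimension")
        for w in (self.wq, self.wk, self.wv, self.wo):
            if w.shape != (d, d):
                raise ValueError("attention projections must be d x d")


@dataclass
class GateParams:
    """Shared across branches: hidden projection W_g, bias b_g, score vector w_g."""

    W: np.ndarray  # (hidden, d)
    b: np.ndarray  # (hidden,)
    w: np.ndarray  # (hidden,)


@dataclass
class HeadParams:
    reduce_w: np.ndarray  # (3d, D')
    reduce_b: np.ndarray  # (D',)
    W: np.ndarray         # (C, D')
    b: np.ndarray         # (C,)


@dataclass(frozen=True)
class ModelConfig:
    input_hw: int = 256
    input_channels: int = 3
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    branches: BranchConfig = field(default_factory=BranchConfig)
    attn_heads: int = 4
    gate_hidden: int = 48
    reduced_dim: int = 32
    n_classes: int = 2
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.branches.depth % self.attn_heads != 0:
            raise ValueError("attn_heads must divide the branch depth")

    @staticmethod
    def reduced(input_hw: int = 64) -> "ModelConfig":
        """Width-reduced variant: stage filters divided by 8, smaller input.
        Pooling switches to stride 1 in stages 4-5 so the coarse branches
        keep at least a 7x7 grid for the attention projections."""
        return ModelConfig(
            input_hw=input_hw,
            backbone=BackboneConfig(filters=(8, 16, 32, 64, 64),
                                    pool_strides=(2, 2, 2, 1, 1)),
        )


# stages 1-2 fully separable; stages 3-5 open with one standard conv
_STAGE_LAYOUT = (("sep", "sep"), ("sep", "sep"),
                 ("std", "sep"), ("std", "sep"), ("std", "sep"))


# --------------------------------------------------------------------------
# convolution primitives (stride 1, zero-padded 'same'); NHWC batched
# --------------------------------------------------------------------------

def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    return np.pad(x, ((0, 0), (p, k - 1 - p), (p, k - 1 - p), (0, 0)))


def _conv_std_fwd(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (N,H,W,M), w (K,K,M,Nout) -> (N,H,W,Nout); shift-and-matmul."""
    k = w.shape[0]
    n, h, wd, _ = x.shape
    xp = _pad_same(x, k)
    out = np.zeros((n, h, wd, w.shape[3]))
    for u in range(k):
        for v in range(k):
            out += xp[:, u:u + h, v:v + wd, :] @ w[u, v]
    return out


def _conv_std_bwd(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    k = w.shape[0]
    n, h, wd, _ = x.shape
    xp = _pad_same(x, k)
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for u in range(k):
        for v in range(k):
            sl = xp[:, u:u + h, v:v + wd, :]
            dw[u, v] = np.tensordot(sl, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, u:u + h, v:v + wd, :] += dout @ w[u, v].T
    p = k // 2
    dx = dxp[:, p:p + h, p:p + wd, :]
    return dx, dw


def _conv_dw_fwd(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Depthwise: x (N,H,W,M), w (K,K,M) -> (N,H,W,M)."""
    k = w.shape[0]
    n, h, wd, _ = x.shape
    xp = _pad_same(x, k)
    out = np.zeros_like(x)
    for u in range(k):
        for v in range(k):
            out += xp[:, u:u + h, v:v + wd, :] * w[u, v]
    return out


def _conv_dw_bwd(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    k = w.shape[0]
    n, h, wd, _ = x.shape
    xp = _pad_same(x, k)
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for u in range(k):
        for v in range(k):
            sl = xp[:, u:u + h, v:v + wd, :]
            dw[u, v] = np.sum(sl * dout, axis=(0, 1, 2))
            dxp[:, u:u + h, v:v + wd, :] += dout * w[u, v]
    p = k // 2
    return dxp[:, p:p + h, p:p + wd, :], dw


def conv_standard(x, w, bias=None) -> np.ndarray:
    """Standard 2-D convolution (same padding, stride 1) by direct
    sliding-window summation; costs K^2*M*N parameters.

    Accepts a single (H, W, M) map or a batch (N, H, W, M).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.ndim != 4:
        raise ValueError("standard kernel must be K x K x M x N")
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.shape[3] != w.shape[2]:
        raise ValueError("input channels do not match the kernel")
    out = _conv_std_fwd(x, w)
    if bias is not None:
        out = out + np.asarray(bias)
    return out[0] if single else out


def depthwise_separable(x, dw, pw, bias=None) -> np.ndarray:
    """Depthwise spatial filtering (K x K x M) followed by a pointwise 1x1
    channel mix (M x N); costs K^2*M + M*N parameters."""
    x = np.asarray(x, dtype=float)
    dw = np.asarray(dw, dtype=float)
    pw = np.asarray(pw, dtype=float)
    if dw.ndim != 3 or pw.ndim != 2:
        raise ValueError("depthwise kernel must be KxKxM and pointwise MxN")
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.shape[3] != dw.shape[2] or dw.shape[2] != pw.shape[0]:
        raise ValueError("channel counts do not match the kernels")
    out = _conv_dw_fwd(x, dw) @ pw
    if bias is not None:
        out = out + np.asarray(bias)
    return out[0] if single else out


def ccr(k: int, n: int) -> float:
    """Computational cost ratio of separable vs. standard convolution:
    1/N + 1/K^2."""
    if k < 1 or n < 1:
        raise ValueError("K and N must be >= 1")
    return 1.0 / n + 1.0 / (k * k)


def params_standard_conv(k: int, m: int, n: int, bias: bool = False) -> int:
    return k * k * m * n + (n if bias else 0)


def params_separable_conv(k: int, m: int, n: int, bias: bool = False) -> int:
    return k * k * m + m * n + (n if bias else 0)


# --------------------------------------------------------------------------
# other primitives
# --------------------------------------------------------------------------

def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _pool_windows(size_in: int, size_out: int):
    """Adaptive average-pool window bounds: [floor(i*S/O), ceil((i+1)*S/O))."""
    starts = [(i * size_in) // size_out for i in range(size_out)]
    ends = [-(-((i + 1) * size_in) // size_out) for i in range(size_out)]
    return starts, ends


def _adaptive_avgpool_fwd(x: np.ndarray, out_hw: int) -> np.ndarray:
    n, h, w, c = x.shape
    rs, re = _pool_windows(h, out_hw)
    cs, ce = _pool_windows(w, out_hw)
    out = np.empty((n, out_hw, out_hw, c))
    for i in range(out_hw):
        for j in range(out_hw):
            out[:, i, j, :] = x[:, rs[i]:re[i], cs[j]:ce[j], :].mean(axis=(1, 2))
    return out


def _adaptive_avgpool_bwd(dout: np.ndarray, in_hw: tuple, out_hw: int) -> np.ndarray:
    n, _, _, c = dout.shape
    h, w = in_hw
    rs, re = _pool_windows(h, out_hw)
    cs, ce = _pool_windows(w, out_hw)
    dx = np.zeros((n, h, w, c))
    for i in range(out_hw):
        for j in range(out_hw):
            area = (re[i] - rs[i]) * (ce[j] - cs[j])
            dx[:, rs[i]:re[i], cs[j]:ce[j], :] += dout[:, i:i + 1, j:j + 1, :] / area
    return dx


def _maxpool2_fwd(x: np.ndarray):
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("max-pool expects even spatial dimensions")
    win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    win = win.reshape(n, h // 2, w // 2, 4, c)
    idx = np.argmax(win, axis=3)
    out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def _maxpool2_bwd(dout: np.ndarray, idx: np.ndarray, in_hw: tuple) -> np.ndarray:
    n, ho, wo, c = dout.shape
    h, w = in_hw
    dwin = np.zeros((n, ho, wo, 4, c))
    np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = dwin.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return dx.reshape(n, h, w, c)


_BN_EPS = 1e-5


def _bn_fwd(x, gamma, beta, running, train, momentum=0.9):
    if train:
        mean = x.mean(axis=(0, 1, 2))
        var = x.var(axis=(0, 1, 2))
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean) * inv
    return xhat * gamma + beta, (xhat, inv)


def _bn_bwd(dout, cache, gamma):
    xhat, inv = cache
    m = dout.shape[0] * dout.shape[1] * dout.shape[2]
    dgamma = np.sum(dout * xhat, axis=(0, 1, 2))
    dbeta = np.sum(dout, axis=(0, 1, 2))
    dxhat = dout * gamma
    dx = (inv / m) * (m * dxhat - np.sum(dxhat, axis=(0, 1, 2))
                      - xhat * np.sum(dxhat * xhat, axis=(0, 1, 2)))
    return dx, dgamma, dbeta


def _mhsa_fwd(x: np.ndarray, p: "AttentionParams"):
    """x (N, L, d) -> (N, L, d) with residual; returns cache for backward."""
    n, L, d = x.shape
    hds = p.heads
    dh = d // hds
    scale = 1.0 / math.sqrt(dh)

    def split(t):  # (N,L,d) -> (N,H,L,dh)
        return t.reshape(n, L, hds, dh).transpose(0, 2, 1, 3)

    q, k, v = split(x @ p.wq), split(x @ p.wk), split(x @ p.wv)
    s = (q @ k.transpose(0, 1, 3, 2)) * scale
    a = softmax(s, axis=-1)
    o = a @ v                               # (N,H,L,dh)
    om = o.transpose(0, 2, 1, 3).reshape(n, L, d)
    y = om @ p.wo
    return x + y, (x, q, k, v, a, om, scale)


def _mhsa_bwd(dout: np.ndarray, cache, p: "AttentionParams"):
    x, q, k, v, a, om, scale = cache
    n, L, d = x.shape
    hds = p.heads
    dh = d // hds

    def split(t):
        return t.reshape(n, L, hds, dh).transpose(0, 2, 1, 3)

    def merge(t):
        return t.transpose(0, 2, 1, 3).reshape(n, L, d)

    dwo = np.tensordot(om, dout, axes=([0, 1], [0, 1]))
    dom = dout @ p.wo.T
    do = split(dom)
    da = do @ v.transpose(0, 1, 3, 2)
    dv = a.transpose(0, 1, 3, 2) @ do
    ds = a * (da - np.sum(da * a, axis=-1, keepdims=True))
    dq = (ds @ k) * scale
    dk = (ds.transpose(0, 1, 3, 2) @ q) * scale
    dqm, dkm, dvm = merge(dq), merge(dk), merge(dv)
    dwq = np.tensordot(x, dqm, axes=([0, 1], [0, 1]))
    dwk = np.tensordot(x, dkm, axes=([0, 1], [0, 1]))
    dwv = np.tensordot(x, dvm, axes=([0, 1], [0, 1]))
    dx = dout + dqm @ p.wq.T + dkm @ p.wk.T + dvm @ p.wv.T
    return dx, {"wq": dwq, "wk": dwk, "wv": dwv, "wo": dwo}


# --------------------------------------------------------------------------
# spec-level functional operations (single-sample convenience wrappers)
# --------------------------------------------------------------------------

def multi_head_attention(tokens: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Multi-head self-attention with residual connection; no positional
    encoding, so permuting the token order permutes the output rows."""
    tokens = np.asarray(tokens, dtype=float)
    single = tokens.ndim == 2
    if single:
        tokens = tokens[None]
    out, _ = _mhsa_fwd(tokens, params)
    return out[0] if single else out


def project_branch(fmap: np.ndarray, pw: np.ndarray, bias: np.ndarray,
                   out_hw: int = 7) -> np.ndarray:
    """Pointwise projection to the branch depth, then adaptive average
    pooling to ``out_hw`` x ``out_hw``."""
    fmap = np.asarray(fmap, dtype=float)
    single = fmap.ndim == 3
    if single:
        fmap = fmap[None]
    if fmap.shape[1] < out_hw or fmap.shape[2] < out_hw:
        raise ValueError(f"branch input must be at least {out_hw}x{out_hw}")
    z = _adaptive_avgpool_fwd(fmap @ pw + bias, out_hw)
    return z[0] if single else z


def gate_weights(branch_outputs, gate: GateParams) -> np.ndarray:
    """Softmax gate over the three scale branches.

    Each branch's 7x7xd map is averaged into a descriptor u_b; the shared
    gating network scores it via w_g . relu(W_g u_b + b_g) and a softmax over
    branches yields weights that sum to 1.
    """
    us = [np.asarray(z, dtype=float).reshape(-1, z.shape[-1]).mean(axis=0)
          for z in branch_outputs]
    scores = np.array([gate.w @ np.maximum(gate.W @ u + gate.b, 0.0) for u in us])
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite gate scores")
    return softmax(scores)


def fuse_reduce_pool(branch_outputs, alphas, head: HeadParams) -> np.ndarray:
    """Concatenate the alpha-scaled branches channel-wise (7x7x3d), reduce to
    D' channels with a pointwise convolution and spatially average."""
    zs = [np.asarray(z, dtype=float) for z in branch_outputs]
    if len({z.shape for z in zs}) != 1:
        raise ValueError("branch outputs must share a shape")
    fused = np.concatenate([a * z for a, z in zip(alphas, zs)], axis=-1)
    reduced = fused @ head.reduce_w + head.reduce_b
    return reduced.reshape(-1, reduced.shape[-1]).mean(axis=0)


def classify(z: np.ndarray, head: HeadParams) -> np.ndarray:
    """Class posteriors softmax(Wz + b); index 0 = PD, 1 = healthy."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("feature vector must be finite")
    return softmax(head.W @ z + head.b)


# --------------------------------------------------------------------------
# parameter accounting
# --------------------------------------------------------------------------

def count_parameters(config: ModelConfig, breakdown: bool = False):
    """Analytic trainable-parameter count for a configuration; optionally a
    per-group breakdown. Matches the enumerated size of an instantiated model."""
    bb = config.backbone
    k = bb.kernel_size
    groups = {}
    cin = config.input_channels
    for idx, (f, layout) in enumerate(zip(bb.filters, _STAGE_LAYOUT), start=1):
        n = 0
        for kind in layout:
            count = params_standard_conv(k, cin, f, bias=True) if kind == "std" \
                else params_separable_conv(k, cin, f, bias=True)
            n += count
            if bb.batch_norm:
                n += 2 * f
            cin = f
        groups[f"stage{idx}"] = n
    d = config.branches.depth
    for b, src in enumerate(config.branches.source_stages, start=1):
        m = bb.filters[src - 1]
        groups[f"branch{b}"] = m * d + d          # pointwise projection + bias
        groups[f"attention{b}"] = 4 * d * d       # wq, wk, wv, wo
    groups["gate"] = config.gate_hidden * d + 2 * config.gate_hidden
    groups["reduce"] = 3 * d * config.reduced_dim + config.reduced_dim
    groups["head"] = config.n_classes * config.reduced_dim + config.n_classes
    total = sum(groups.values())
    return (total, groups) if breakdown else total


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class MgmaDscnn:
    """Full classifier with forward and backward passes.

    Parameters live in ``self.params`` (name -> array); batch-norm running
    statistics in ``self.buffers``. ``loss_and_grad`` returns the mean
    cross-entropy over a batch and gradients for every parameter.
    """

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.params: dict = {}
        self.buffers: dict = {}
        self._init_params(np.random.default_rng(seed))
        self._cache = None

    # -- initialization (He-normal for conv/dense weights) -----------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        bb = cfg.backbone
        k = bb.kernel_size

        def he(shape, fan_in):
            return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)

        cin = cfg.input_channels
        for idx, (f, layout) in enumerate(zip(bb.filters, _STAGE_LAYOUT), start=1):
            for half, kind in zip("ab", layout):
                name = f"s{idx}{half}"
                if kind == "std":
                    self.params[f"{name}_w"] = he((k, k, cin, f), k * k * cin)
                else:
                    self.params[f"{name}_dw"] = he((k, k, cin), k * k)
                    self.params[f"{name}_pw"] = he((cin, f), cin)
                self.params[f"{name}_b"] = np.zeros(f)
                if bb.batch_norm:
                    self.params[f"{name}_gamma"] = np.ones(f)
                    self.params[f"{name}_beta"] = np.zeros(f)
                    self.buffers[name] = {"mean": np.zeros(f), "var": np.ones(f)}
                cin = f

        d = cfg.branches.depth
        for b, src in enumerate(cfg.branches.source_stages, start=1):
            m = bb.filters[src - 1]
            self.params[f"br{b}_pw"] = he((m, d), m)
            self.params[f"br{b}_b"] = np.zeros(d)
            for w in ("wq", "wk", "wv", "wo"):
                self.params[f"attn{b}_{w}"] = he((d, d), d)
        self.params["gate_W"] = he((cfg.gate_hidden, d), d)
        self.params["gate_b"] = np.zeros(cfg.gate_hidden)
        self.params["gate_w"] = he((cfg.gate_hidden,), cfg.gate_hidden)
        self.params["reduce_pw"] = he((3 * d, cfg.reduced_dim), 3 * d)
        self.params["reduce_b"] = np.zeros(cfg.reduced_dim)
        self.params["head_W"] = he((cfg.n_classes, cfg.reduced_dim), cfg.reduced_dim)
        self.params["head_b"] = np.zeros(cfg.n_classes)

    def num_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- attention / gate / head views over the flat parameter store -------

    def attention_params(self, b: int) -> AttentionParams:
        p = self.params
        return AttentionParams(self.config.attn_heads, p[f"attn{b}_wq"],
                               p[f"attn{b}_wk"], p[f"attn{b}_wv"], p[f"attn{b}_wo"])

    def gate_params(self) -> GateParams:
        return GateParams(self.params["gate_W"], self.params["gate_b"],
                          self.params["gate_w"])

    def head_params(self) -> HeadParams:
        return HeadParams(self.params["reduce_pw"], self.params["reduce_b"],
                          self.params["head_W"], self.params["head_b"])

    # -- forward ------------------------------------------------------------

    def _stage_layers(self):
        for idx, layout in enumerate(_STAGE_LAYOUT, start=1):
            for half, kind in zip("ab", layout):
                yield idx, half, kind

    def backbone(self, x: np.ndarray, train: bool = False):
        """Run the five stages; returns (stage_maps, per-stage caches)."""
        cfg = self.config
        p = self.params
        stage_caches = []
        stage_maps = []
        h = x
        for idx, layout in enumerate(_STAGE_LAYOUT, start=1):
            conv_caches = []
            for half, kind in zip("ab", layout):
                name = f"s{idx}{half}"
                x_in = h
                if kind == "std":
                    h = _conv_std_fwd(h, p[f"{name}_w"])
                    dw_cache = None
                else:
                    dw_cache = _conv_dw_fwd(h, p[f"{name}_dw"])
                    h = dw_cache @ p[f"{name}_pw"]
                h = h + p[f"{name}_b"]
                bn_cache = None
                if cfg.backbone.batch_norm:
                    h, bn_cache = _bn_fwd(h, p[f"{name}_gamma"], p[f"{name}_beta"],
                                          self.buffers[name], train)
                relu_mask = h > 0
                h = h * relu_mask
                conv_caches.append((name, kind, x_in, dw_cache, bn_cache, relu_mask))
            pool_cache = None
            if cfg.backbone.pool_strides[idx - 1] == 2:
                in_hw = h.shape[1:3]
                h, idx_cache = _maxpool2_fwd(h)
                pool_cache = (in_hw, idx_cache)
            stage_caches.append((conv_caches, pool_cache))
            stage_maps.append(h)
        return stage_maps, stage_caches

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Posterior probabilities (N, 2); column 0 = PD. Caches intermediates
        for a subsequent ``backward`` call when ``train`` is True."""
        cfg = self.config
        p = self.params
        x = np.asarray(x, dtype=float)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[1] != cfg.input_hw or x.shape[3] != cfg.input_channels:
            raise ValueError(
                f"expected input {cfg.input_hw}x{cfg.input_hw}x{cfg.input_channels},"
                f" got {x.shape[1:]}")

        stage_maps, bb_caches = self.backbone(x, train=train)

        hw = cfg.branches.proj_hw
        d = cfg.branches.depth
        zs, br_caches = [], []
        for b, src in enumerate(cfg.branches.source_stages, start=1):
            f = stage_maps[src - 1]
            if f.shape[1] < hw or f.shape[2] < hw:
                raise ValueError("branch source map smaller than the projection grid")
            proj = f @ p[f"br{b}_pw"] + p[f"br{b}_b"]
            pooled = _adaptive_avgpool_fwd(proj, hw)
            n = pooled.shape[0]
            tokens = pooled.reshape(n, hw * hw, d)
            attn_out, attn_cache = _mhsa_fwd(tokens, self.attention_params(b))
            zs.append(attn_out.reshape(n, hw, hw, d))
            br_caches.append((f, proj.shape[1:3], attn_cache))

        # gating
        us = [z.mean(axis=(1, 2)) for z in zs]                    # (N, d) each
        hpre = [u @ p["gate_W"].T + p["gate_b"] for u in us]      # (N, hidden)
        hact = [np.maximum(t, 0.0) for t in hpre]
        scores = np.stack([t @ p["gate_w"] for t in hact], axis=1)  # (N, 3)
        alphas = softmax(scores, axis=1)

        fused = np.concatenate(
            [alphas[:, b][:, None, None, None] * zs[b] for b in range(3)], axis=-1)
        reduced = fused @ p["reduce_pw"] + p["reduce_b"]          # (N,7,7,D')
        zvec = reduced.mean(axis=(1, 2))                          # (N, D')

        drop_mask = None
        if train and cfg.dropout > 0:
            rng = rng or np.random.default_rng()
            drop_mask = (rng.random(zvec.shape) >= cfg.dropout) / (1 - cfg.dropout)
            zvec = zvec * drop_mask

        logits = zvec @ p["head_W"].T + p["head_b"]
        probs = softmax(logits, axis=1)

        self._cache = (x, bb_caches, br_caches, zs, us, hpre, hact, alphas,
                       fused.shape, reduced.shape, zvec, drop_mask, probs)
        return probs[0] if single else probs

    # -- loss and gradients --------------------------------------------------

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray, train: bool = True,
                      rng=None):
        """Mean 2-class cross-entropy (labels 1 = PD -> class index 0) and the
        gradient for every parameter."""
        probs = self.forward(x, train=train, rng=rng)
        probs = np.atleast_2d(probs)
        labels = np.asarray(labels, dtype=int).reshape(-1)
        cls = 1 - labels                       # label 1 (PD) -> column 0
        n = probs.shape[0]
        eps = 1e-12
        loss = -float(np.mean(np.log(np.clip(probs[np.arange(n), cls], eps, None))))
        dlogits = probs.copy()
        dlogits[np.arange(n), cls] -= 1.0
        dlogits /= n
        grads = self._backward(dlogits)
        return loss, grads

    def _backward(self, dlogits: np.ndarray) -> dict:
        cfg = self.config
        p = self.params
        (x, bb_caches, br_caches, zs, us, hpre, hact, alphas,
         fused_shape, reduced_shape, zvec, drop_mask, _) = self._cache
        g = {k: np.zeros_like(v) for k, v in p.items()}
        hw = cfg.branches.proj_hw
        d = cfg.branches.depth

        # head
        g["head_W"] = dlogits.T @ zvec
        g["head_b"] = dlogits.sum(axis=0)
        dzvec = dlogits @ p["head_W"]
        if drop_mask is not None:
            dzvec = dzvec * drop_mask

        # GAP and pointwise reduction
        n, rh, rw, dp = reduced_shape
        dreduced = np.broadcast_to(dzvec[:, None, None, :] / (rh * rw),
                                   reduced_shape).copy()
        fused = np.concatenate(
            [alphas[:, b][:, None, None, None] * zs[b] for b in range(3)], axis=-1)
        g["reduce_pw"] = np.tensordot(fused, dreduced, axes=([0, 1, 2], [0, 1, 2]))
        g["reduce_b"] = dreduced.sum(axis=(0, 1, 2))
        dfused = dreduced @ p["reduce_pw"].T

        # split the concatenation; gradients w.r.t. alphas and branch outputs
        dzs = []
        dalphas = np.zeros_like(alphas)
        for b in range(3):
            df = dfused[..., b * d:(b + 1) * d]
            dalphas[:, b] = np.sum(df * zs[b], axis=(1, 2, 3))
            dzs.append(df * alphas[:, b][:, None, None, None])

        # softmax gate backward
        dscores = alphas * (dalphas - np.sum(dalphas * alphas, axis=1, keepdims=True))
        for b in range(3):
            ds = dscores[:, b]                                  # (N,)
            dh = ds[:, None] * p["gate_w"][None, :]             # (N, hidden)
            g["gate_w"] += (hact[b] * ds[:, None]).sum(axis=0)
            dh_pre = dh * (hpre[b] > 0)
            g["gate_W"] += dh_pre.T @ us[b]
            g["gate_b"] += dh_pre.sum(axis=0)
            du = dh_pre @ p["gate_W"]                           # (N, d)
            dzs[b] = dzs[b] + du[:, None, None, :] / (hw * hw)

        # branches backward
        dstage_by_src: dict = {}
        for b, src in enumerate(cfg.branches.source_stages, start=1):
            fmap, proj_hw_in, attn_cache = br_caches[b - 1]
            nb = dzs[b - 1].shape[0]
            dtok = dzs[b - 1].reshape(nb, hw * hw, d)
            dtok, attn_grads = _mhsa_bwd(dtok, attn_cache, self.attention_params(b))
            for wname, gw in attn_grads.items():
                g[f"attn{b}_{wname}"] = gw
            dpooled = dtok.reshape(nb, hw, hw, d)
            dproj = _adaptive_avgpool_bwd(dpooled, proj_hw_in, hw)
            g[f"br{b}_pw"] = np.tensordot(fmap, dproj, axes=([0, 1, 2], [0, 1, 2]))
            g[f"br{b}_b"] = dproj.sum(axis=(0, 1, 2))
            dsrc = dproj @ p[f"br{b}_pw"].T
            dstage_by_src[src] = dstage_by_src.get(src, 0) + dsrc

        # backbone backward, stage by stage in reverse; branch gradients enter
        # at the stage outputs they were tapped from
        dh = None
        for sidx in range(5, 0, -1):
            conv_caches, pool_cache = bb_caches[sidx - 1]
            dstage = dstage_by_src.pop(sidx, None)
            if dstage is not None:
                dh = dstage if dh is None else dh + dstage
            if dh is None:
                continue
            if pool_cache is not None:
                in_hw, idx_cache = pool_cache
                dh = _maxpool2_bwd(dh, idx_cache, in_hw)
            for name, kind, x_in, dw_cache, bn_cache, relu_mask in reversed(conv_caches):
                dh = dh * relu_mask
                if bn_cache is not None:
                    dh, dgamma, dbeta = _bn_bwd(dh, bn_cache, p[f"{name}_gamma"])
                    g[f"{name}_gamma"] = dgamma
                    g[f"{name}_beta"] = dbeta
                g[f"{name}_b"] = dh.sum(axis=(0, 1, 2))
                if kind == "std":
                    dh, gw = _conv_std_bwd(x_in, p[f"{name}_w"], dh)
                    g[f"{name}_w"] = gw
                else:
                    dmid = dh @ p[f"{name}_pw"].T
                    g[f"{name}_pw"] = np.tensordot(dw_cache, dh,
                                                   axes=([0, 1, 2], [0, 1, 2]))
                    dh, gdw = _conv_dw_bwd(x_in, p[f"{name}_dw"], dmid)
                    g[f"{name}_dw"] = gdw
        return g


def backbone_forward(x: np.ndarray, model: MgmaDscnn):
    """The three multiscale feature maps (fine, medium, coarse) produced by the
    backbone for input ``x`` (H, W, C) or (N, H, W, C)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.shape[1] != model.config.input_hw or x.shape[3] != model.config.input_channels:
        raise ValueError("input shape does not match the model configuration")
    stage_maps, _ = model.backbone(x, train=False)
    maps = tuple(stage_maps[s - 1] for s in model.config.branches.source_stages)
    return tuple(m[0] for m in maps) if single else maps


# --------------------------------------------------------------------------
# checkpointing: named arrays + JSON config in one zip archive
# --------------------------------------------------------------------------

def save_checkpoint(model: MgmaDscnn, path) -> None:
    cfg = model.config
    meta = {
        "input_hw": cfg.input_hw, "input_channels": cfg.input_channels,
        "filters": list(cfg.backbone.filters),
        "pool_strides": list(cfg.backbone.pool_strides),
        "kernel_size": cfg.backbone.kernel_size,
        "batch_norm": cfg.backbone.batch_norm,
        "source_stages": list(cfg.branches.source_stages),
        "proj_hw": cfg.branches.proj_hw, "depth": cfg.branches.depth,
        "attn_heads": cfg.attn_heads, "gate_hidden": cfg.gate_hidden,
        "reduced_dim": cfg.reduced_dim, "n_classes": cfg.n_classes,
        "dropout": cfg.dropout, "n_params": model.num_params(),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta))
        buf = io.BytesIO()
        arrays = dict(model.params)
        for name, run in model.buffers.items():
            arrays[f"_run_{name}_mean"] = run["mean"]
            arrays[f"_run_{name}_var"] = run["var"]
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path) -> MgmaDscnn:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        data = np.load(io.BytesIO(zf.read("arrays.npz")))
        cfg = ModelConfig(
            input_hw=meta["input_hw"], input_channels=meta["input_channels"],
            backbone=BackboneConfig(filters=tuple(meta["filters"]),
                                    pool_strides=tuple(meta["pool_strides"]),
                                    kernel_size=meta["kernel_size"],
                                    batch_norm=meta["batch_norm"]),
            branches=BranchConfig(source_stages=tuple(meta["source_stages"]),
                                  proj_hw=meta["proj_hw"], depth=meta["depth"]),
            attn_heads=meta["attn_heads"], gate_hidden=meta["gate_hidden"],
            reduced_dim=meta["reduced_dim"], n_classes=meta["n_classes"],
            dropout=meta["dropout"])
        model = MgmaDscnn(cfg, seed=0)
        for name in model.params:
            model.params[name] = data[name]
        for name in model.buffers:
            model.buffers[name] = {"mean": data[f"_run_{name}_mean"],
                                   "var": data[f"_run_{name}_var"]}
    expected = count_parameters(model.config)
    if model.num_params() != expected:
        raise ValueError("checkpoint parameter count does not match its config")
    return model
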