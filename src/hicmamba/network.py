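"""UNet auto-encoder built from holistic scan blocks (SS2D + LEFN).

The network maps a single-channel low-coverage contact-map patch
(1, H, W) to an enhanced patch of the same shape.  An input 3x3
convolution lifts the patch to ``C`` channels; two encoder stages (each
``blocks_per_stage`` holistic scan blocks followed by a 2x2 stride-2
downsampling convolution that doubles the channels) produce features at
C x H x W, 2C x H/2 x W/2 and 4C x H/4 x W/4; a bottleneck of holistic
blocks operates at 4C; the decoder mirrors the encoder with 2x2
transposed convolutions, skip concatenation with the matching encoder
stage and a 1x1 fusion convolution; a final 3x3 convolution projects
back to one channel, and the input patch is added as a global residual
so the network learns a correction term.

Each holistic scan block is pre-norm residual, Transformer style:

    x = x + SS2D(LayerNorm(x));   x = x + LEFN(LayerNorm(x))

SS2D flattens the feature map along four traversal paths (row-major,
reversed row-major, column-major, reversed column-major), runs an
independent S6 selective scan per path, restores each sequence to its
2-D layout and sums the four maps.  LEFN is a 1x1 -> 3x3 -> 1x1
convolution stack with GELU after each convolution, supplying the local
receptive field the sequential scan lacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn.autograd import Tensor, concatenate
from .nn.layers import (Module, Linear, Conv2d, Downsample, Upsample, LayerNorm,
                        DTYPE, glorot)
from .nn.scan_core import selective_scan_core


# ---------------------------------------------------------------------------
# configuration

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    base_channels is the predefined feature dimension C (32 by default);
    blocks_per_stage holistic scan blocks are used in each encoder stage,
    decoder stage and the bottleneck (2 by default).  d_state is the SSM
    state size per channel.  ``ss2d_variant`` selects the minimal literal
    form (per-path linear in/out projections at d_inner = channels) or a
    gated variant (input projection to 2 x channels with a SiLU gate).
    ``input_dependent_a`` makes the state decay A a learned linear
    function of the input (parameterized A = -exp(.) for stability), with
    ``False`` selecting the standard static A = -exp(A_log).
    ``use_ss2d`` / ``use_lefn`` disable one branch for ablation probes.
    """

    base_channels: int = 32
    patch_size: int = 40
    blocks_per_stage: int = 2
    n_stages: int = 2
    lefn_expansion: int = 1
    d_state: int = 16
    merge_mode: str = "sum"
    ss2d_variant: str = "minimal"
    input_dependent_a: bool = True
    global_residual: bool = True
    use_ss2d: bool = True
    use_lefn: bool = True
    scan_chunk: int = 64

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.patch_size % (2 ** self.n_stages):
            raise ValueError("patch_size must be divisible by 2**n_stages")
        if self.merge_mode != "sum":
            raise ValueError("only merge_mode='sum' is supported")
        if self.ss2d_variant not in ("minimal", "gated"):
            raise ValueError("ss2d_variant must be 'minimal' or 'gated'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# cross scan / cross merge (array-level reference operations)

def cross_scan(fm: np.ndarray) -> list[np.ndarray]:
    """Flatten a (C, H, W) feature map along the four traversal paths.

    Returns four (H*W, C) sequences: row-major, reversed row-major,
    column-major, reversed column-major.  Each path visits every pixel
    exactly once.
    """
    C, H, W = fm.shape
    p1 = fm.reshape(C, H * W).T
    p2 = p1[::-1]
    p3 = fm.transpose(0, 2, 1).reshape(C, H * W).T
    p4 = p3[::-1]
    return [p1.copy(), p2.copy(), p3.copy(), p4.copy()]


def cross_merge(paths: list[np.ndarray], H: int, W: int) -> np.ndarray:
    """Un-permute four (H*W, C) sequences to (C, H, W) maps and sum them."""
    if len(paths) != 4:
        raise ValueError("expected four path sequences")
    for p in paths:
        if p.shape[0] != H * W:
            raise ValueError("sequence length must equal H*W")
    C = paths[0].shape[1]
    m1 = paths[0].T.reshape(C, H, W)
    m2 = paths[1][::-1].T.reshape(C, H, W)
    m3 = paths[2].T.reshape(C, W, H).transpose(0, 2, 1)
    m4 = paths[3][::-1].T.reshape(C, W, H).transpose(0, 2, 1)
    return m1 + m2 + m3 + m4


# ---------------------------------------------------------------------------
# chunked batched selective scan (autograd)

class S6Scan(Module):
    """One S6 selective-scan head operating on (B, T, d) sequences.

    B, C and the timescale dt are linear functions of the input token;
    the decay A is likewise input-dependent (A = -exp(proj(x)), zero-
    initialized so A = -1 at start) unless ``input_dependent_a`` is off,
    in which case a static A = -exp(A_log) is learned.  The recurrence is
    evaluated by the fused chunked float64 scan primitive
    (:func:`hicmamba.nn.scan_core.selective_scan_core`).
    """

    def __init__(self, rng, d: int, d_state: int, input_dependent_a: bool = True,
                 chunk: int = 64):
        super().__init__()
        self.d, self.s, self.chunk = d, d_state, chunk
        self.input_dependent_a = input_dependent_a
        p = lambda a: Tensor(a.astype(DTYPE), requires_grad=True)
        self.W_B = p(glorot(rng, (d, d_state), d, d_state))
        self.b_B = p(np.zeros(d_state))
        self.W_C = p(glorot(rng, (d, d_state), d, d_state))
        self.b_C = p(np.zeros(d_state))
        self.W_dt = p(glorot(rng, (d, d), d, d) * 0.1)
        dt0 = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), size=d))
        self.b_dt = p(np.log(np.expm1(dt0)))  # softplus inverse
        if input_dependent_a:
            self.W_A = p(np.zeros((d, d_state)))
            self.b_A = p(np.zeros(d_state))
        else:
            self.A_log = p(np.tile(np.log(np.arange(1, d_state + 1, dtype=float)),
                                   (d, 1)))
        self.D = p(np.ones(d))

    def forward(self, u: Tensor) -> Tensor:
        Bt = u @ self.W_B + self.b_B                      # (B,T,s)
        Ct = u @ self.W_C + self.b_C                      # (B,T,s)
        dt = (u @ self.W_dt + self.b_dt).softplus()       # (B,T,d)
        if self.input_dependent_a:
            At = -((u @ self.W_A + self.b_A).exp())       # (B,T,s) < 0
        else:
            At = -(self.A_log.exp())                      # (d,s) < 0
        y = selective_scan_core(dt, At, Bt, Ct, u, self.chunk)
        return y + self.D * u


# ---------------------------------------------------------------------------
# SS2D

def _path_forward(fm: Tensor, path: int, H: int, W: int) -> Tensor:
    """(B,C,H,W) -> (B,T,C) along one of the four traversal paths."""
    B_, C = fm.shape[0], fm.shape[1]
    if path >= 2:
        fm = fm.transpose(0, 1, 3, 2)
    seq = fm.reshape(B_, C, H * W).transpose(0, 2, 1)
    if path % 2 == 1:
        seq = seq.flip(axis=1)
    return seq

def _path_inverse(seq: Tensor, path: int, H: int, W: int) -> Tensor:
    """(B,T,C) -> (B,C,H,W), inverting :func:`_path_forward`."""
    B_, T, C = seq.shape
    if path % 2 == 1:
        seq = seq.flip(axis=1)
    if path >= 2:
        fm = seq.transpose(0, 2, 1).reshape(B_, C, W, H).transpose(0, 1, 3, 2)
    else:
        fm = seq.transpose(0, 2, 1).reshape(B_, C, H, W)
    return fm


class SS2D(Module):
    """Cross scan -> four independent S6 heads -> cross merge (sum).

    The four paths have independent projection and scan parameters,
    stored stacked along a leading path axis so that a single fused
    scan call processes all paths (they are mathematically independent;
    stacking only batches the computation).
    """

    def __init__(self, rng, channels: int, d_state: int, variant: str = "minimal",
                 input_dependent_a: bool = True, chunk: int = 64):
        super().__init__()
        self.channels = channels
        self.variant = variant
        self.input_dependent_a = input_dependent_a
        self.chunk = chunk
        self.d_state = d_state
        d = channels
        dp = 2 * d if variant == "gated" else d
        p = lambda a: Tensor(np.asarray(a, dtype=DTYPE), requires_grad=True)
        stack = lambda f: p(np.stack([f() for _ in range(4)]))
        self.W_in = stack(lambda: glorot(rng, (channels, dp), channels, dp))
        self.b_in = p(np.zeros((4, 1, dp)))
        self.W_B = stack(lambda: glorot(rng, (d, d_state), d, d_state))
        self.b_B = p(np.zeros((4, 1, d_state)))
        self.W_C = stack(lambda: glorot(rng, (d, d_state), d, d_state))
        self.b_C = p(np.zeros((4, 1, d_state)))
        self.W_dt = stack(lambda: glorot(rng, (d, d), d, d) * 0.1)
        dt0 = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), size=(4, 1, d)))
        self.b_dt = p(np.log(np.expm1(dt0)))
        if input_dependent_a:
            self.W_A = p(np.zeros((4, d, d_state)))
            self.b_A = p(np.zeros((4, 1, d_state)))
        else:
            self.A_log = p(np.tile(np.log(np.arange(1, d_state + 1, dtype=float)),
                                   (4, d, 1)))
        self.D = p(np.ones((4, 1, d)))
        self.W_out = stack(lambda: glorot(rng, (d, channels), d, channels))
        self.b_out = p(np.zeros((4, 1, channels)))

    def forward(self, fm: Tensor) -> Tensor:
        B_, C, H, W = fm.shape
        T = H * W
        d, s = self.channels, self.d_state
        seqs = concatenate([_path_forward(fm, p, H, W).reshape(B_, 1, T, C)
                            for p in range(4)], axis=1)       # (B,4,T,C)
        v = seqs @ self.W_in + self.b_in
        if self.variant == "gated":
            x, z = v[..., :d], v[..., d:]
        else:
            x = v
        Bt = (x @ self.W_B + self.b_B).reshape(B_ * 4, T, s)
        Ct = (x @ self.W_C + self.b_C).reshape(B_ * 4, T, s)
        dt = (x @ self.W_dt + self.b_dt).softplus().reshape(B_ * 4, T, d)
        xf = x.reshape(B_ * 4, T, d)
        if self.input_dependent_a:
            At = -((x @ self.W_A + self.b_A).exp()).reshape(B_ * 4, T, s)
            y = selective_scan_core(dt, At, Bt, Ct, xf, self.chunk,
                                    a_mode="per_step")
        else:
            At = Tensor(np.zeros((B_, 4, d, s), dtype=DTYPE)) + (
                -(self.A_log.exp()))
            y = selective_scan_core(dt, At.reshape(B_ * 4, d, s), Bt, Ct, xf,
                                    self.chunk, a_mode="static_batch")
        y = y.reshape(B_, 4, T, d) + self.D * x
        if self.variant == "gated":
            y = y * z.silu()
        o = y @ self.W_out + self.b_out                        # (B,4,T,C)
        out = None
        for p in range(4):
            m = _path_inverse(o[:, p], p, H, W)
            out = m if out is None else out + m
        return out


class LEFN(Module):
    """Locally-enhanced feedforward: 1x1 -> GELU -> 3x3 -> GELU -> 1x1 -> GELU."""

    def __init__(self, rng, channels: int, expansion: int = 1):
        super().__init__()
        hidden = channels * expansion
        self.conv1 = Conv2d(rng, channels, hidden, 1)
        self.conv2 = Conv2d(rng, hidden, hidden, 3)
        self.conv3 = Conv2d(rng, hidden, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1(x).gelu()
        x = self.conv2(x).gelu()
        return self.conv3(x).gelu()


class HolisticBlock(Module):
    """Pre-norm residual block: x + SS2D(LN(x)), then + LEFN(LN(.))."""

    def __init__(self, rng, channels: int, cfg: NetworkConfig):
        super().__init__()
        self.use_ss2d, self.use_lefn = cfg.use_ss2d, cfg.use_lefn
        if cfg.use_ss2d:
            self.norm1 = LayerNorm(channels)
            self.ss2d = SS2D(rng, channels, cfg.d_state, cfg.ss2d_variant,
                             cfg.input_dependent_a, cfg.scan_chunk)
        if cfg.use_lefn:
            self.norm2 = LayerNorm(channels)
            self.lefn = LEFN(rng, channels, cfg.lefn_expansion)

    def forward(self, x: Tensor) -> Tensor:
        if self.use_ss2d:
            x = x + self.ss2d(self.norm1(x))
        if self.use_lefn:
            x = x + self.lefn(self.norm2(x))
        return x


# ---------------------------------------------------------------------------
# full network

class HiCMambaNet(Module):
    """The full UNet auto-encoder; see the module docstring."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        C = config.base_channels
        nb = config.blocks_per_stage
        self.in_conv = Conv2d(rng, 1, C, 3)
        self.enc1 = [HolisticBlock(rng, C, config) for _ in range(nb)]
        self.down1 = Downsample(rng, C, 2 * C)
        self.enc2 = [HolisticBlock(rng, 2 * C, config) for _ in range(nb)]
        self.down2 = Downsample(rng, 2 * C, 4 * C)
        self.bottleneck = [HolisticBlock(rng, 4 * C, config) for _ in range(nb)]
        self.up1 = Upsample(rng, 4 * C, 2 * C)
        self.fuse1 = Conv2d(rng, 4 * C, 2 * C, 1)
        self.dec2 = [HolisticBlock(rng, 2 * C, config) for _ in range(nb)]
        self.up2 = Upsample(rng, 2 * C, C)
        self.fuse2 = Conv2d(rng, 2 * C, C, 1)
        self.dec1 = [HolisticBlock(rng, C, config) for _ in range(nb)]
        # small-scale init keeps the network near the identity at start
        # (global residual), standard restoration practice
        self.out_conv = Conv2d(rng, C, 1, 3, init_scale=0.1)

    def forward(self, x: Tensor, return_features: bool = False):
        B_, c_in, H, W = x.shape
        if H % 4 or W % 4:
            raise ValueError("input height and width must be divisible by 4")
        e1 = self.in_conv(x)
        for blk in self.enc1:
            e1 = blk(e1)
        e2 = self.down1(e1)
        for blk in self.enc2:
            e2 = blk(e2)
        z = self.down2(e2)
        for blk in self.bottleneck:
            z = blk(z)
        d2 = self.up1(z)
        d2 = self.fuse1(concatenate([d2, e2], axis=1))
        for blk in self.dec2:
            d2 = blk(d2)
        d1 = self.up2(d2)
        d1 = self.fuse2(concatenate([d1, e1], axis=1))
        for blk in self.dec1:
            d1 = blk(d1)
        out = self.out_conv(d1)
        if self.config.global_residual:
            out = out + x
        if return_features:
            return out, {"E1": e1, "E2": e2, "E3": z}
        return out


def hicmamba_forward(patch: np.ndarray, net: HiCMambaNet) -> np.ndarray:
    """Inference on a (1, H, W) or (B, 1, H, W) array; returns same shape."""
    arr = np.asarray(patch, dtype=DTYPE)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = net(Tensor(arr)).data
    return out[0] if squeeze else out


def l1_loss(pred, target):
    """Mean absolute elementwise difference (works on arrays or Tensors)."""
    if isinstance(pred, Tensor) or isinstance(target, Tensor):
        p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred))
        t = target if isinstance(target, Tensor) else Tensor(np.asarray(target))
        if p.shape != t.shape:
            raise ValueError("shape mismatch")
        return (p - t).abs().mean()
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    return float(np.abs(pred - target).mean())


# ---------------------------------------------------------------------------
# analytic MACs counter

def count_macs(config: NetworkConfig, input_side: int, per_layer: bool = False):
    """Analytic multiply-accumulate count of one forward pass, in GMACs.

    Convention: 1 MAC = one multiply-accumulate.  Convolutions cost
    output_elements * k^2 * C_in * C_out; the 2x2 stride-2 transposed
    convolution has exactly one kernel tap per output element and costs
    output_elements * C_in * C_out; linear projections cost in * out per
    position.  The selective scan is counted op-by-op per time step,
    channel and state: the B/C/dt (and, when input-dependent, A)
    projections as linears, ZOH discretization as 4 multiplies per
    (channel, state) and the recurrence (decay, injection, readout) as 3,
    plus one multiply per channel for the D skip.  Additions from
    residuals, biases, normalizations and activations are excluded.
    """
    if input_side % 4:
        raise ValueError("input_side must be divisible by 4")
    C = config.base_channels
    s = config.d_state
    e = config.lefn_expansion
    layers: list[tuple[str, float]] = []

    def ss2d_macs(c: int, N: int) -> float:
        if not config.use_ss2d:
            return 0.0
        d = c
        per_path = 0.0
        if config.ss2d_variant == "gated":
            per_path += N * c * 2 * d          # input projection (x and gate)
            per_path += N * d                  # gate multiply
        else:
            per_path += N * c * d              # input projection
        per_path += N * d * s * 2              # B and C projections
        per_path += N * d * d                  # dt projection
        if config.input_dependent_a:
            per_path += N * d * s              # A projection
        per_path += N * d * s * 4              # ZOH discretization
        per_path += N * d * s * 3              # recurrence + readout
        per_path += N * d                      # D skip
        per_path += N * d * c                  # output projection
        return 4.0 * per_path

    def lefn_macs(c: int, N: int) -> float:
        if not config.use_lefn:
            return 0.0
        h = c * e
        return N * (c * h + 9 * h * h + h * c)

    def block_macs(c: int, N: int) -> float:
        return ss2d_macs(c, N) + lefn_macs(c, N)

    side = input_side
    N = side * side
    layers.append(("in_conv", N * 9 * 1 * C))
    widths = [C, 2 * C]
    for i, c in enumerate(widths):
        for b in range(config.blocks_per_stage):
            layers.append((f"enc{i+1}.block{b}", block_macs(c, N)))
        layers.append((f"down{i+1}", (N // 4) * 4 * c * (2 * c)))
        N //= 4
    cb = 4 * C
    for b in range(config.blocks_per_stage):
        layers.append((f"bottleneck.block{b}", block_macs(cb, N)))
    for i, c in enumerate([2 * C, C]):
        N *= 4
        layers.append((f"up{i+1}", N * (2 * c) * c))
        layers.append((f"fuse{i+1}", N * (2 * c) * c))
        for b in range(config.blocks_per_stage):
            layers.append((f"dec{2-i}.block{b}", block_macs(c, N)))
    layers.append(("out_conv", N * 9 * C * 1))
    total = sum(v for _, v in layers) / 1e9
    if per_layer:
        return total, {k: v / 1e9 for k, v in layers}
    return total


def parameter_count(net: HiCMambaNet) -> int:
    return sum(p.data.size for p in net.parameters())


def effective_receptive_field(net: HiCMambaNet, input_side: int,
                              n_inputs: int = 16, seed: int = 0,
                              batch: int = 2) -> np.ndarray:
    """Input-gradient magnitude of the centre output pixel.

    Averages |d y_center / d x| over ``n_inputs`` standard-normal random
    inputs (processed ``batch`` at a time to bound memory) and
    max-normalizes the result to [0, 1].
    """
    rng = np.random.default_rng(seed)
    acc = np.zeros((input_side, input_side))
    for a in range(0, n_inputs, batch):
        nb = min(batch, n_inputs - a)
        x = Tensor(rng.standard_normal((nb, 1, input_side, input_side))
                   .astype(DTYPE), requires_grad=True)
        y = net(x)
        center = y[:, 0, input_side // 2, input_side // 2]
        center.sum().backward()
        acc += np.abs(x.grad).sum(axis=0)[0]
    erf = acc / n_inputs
    m = erf.max()
    return erf / m if m > 0 else erf


__all__ = ["NetworkConfig", "cross_scan", "cross_merge", "S6Scan", "SS2D",
           "LEFN", "HolisticBlock", "HiCMambaNet", "hicmamba_forward",
           "l1_loss", "count_macs", "parameter_count",
           "effective_receptive_field"]
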