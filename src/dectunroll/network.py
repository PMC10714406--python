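"""The unrolled reconstruction network.

A stack of update blocks, each combining the data-consistency (DC) layer
with a small attention-gated U-Net image updater:

    c^k = c^{k-1} + Psi_k( stack(c^{k-1}, DC(c^{k-1}, d)) ),

with unshared weights Psi_k across blocks.  The DC layer enters the
computation graph as a custom operation whose backward rule is the
hand-derived approximate Jacobian transpose (or zero, detaching the DC
path).  The U-Net is "shrunken": the first-level channel count N_chl is
small and doubles per encoder level (N, 2N, 4N, 8N), halving again after
each decoder concatenation; attention gates scale each skip connection by a
learned coefficient in (0, 1) before concatenation; group normalization is
used throughout (no cross-sample statistics, so gradient accumulation over
singleton samples is exact).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dc import dc_backward, dc_forward
from .spectral import BasisImage, SinogramSet

__all__ = [
    "UpdateBlockConfig",
    "NetworkConfig",
    "DCContext",
    "AttentionGate",
    "ShrunkenUNet",
    "UpdateBlock",
    "UnrolledNet",
    "attention_gate",
    "norm_group_count",
    "resolve_parity",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class UpdateBlockConfig:
    """Architecture of one update block's image updater."""

    n_chl: int = 8
    depth: int = 4
    norm_groups: int | None = None  # default: largest divisor <= min(8, C)
    attention: bool = True

    def __post_init__(self):
        if self.n_chl < 2 or self.depth < 2:
            raise ValueError("need n_chl >= 2 and depth >= 2")


@dataclass(frozen=True)
class NetworkConfig:
    """Whole-network layout; weights are never shared across blocks."""

    n_blocks: int = 1
    block: UpdateBlockConfig = field(default_factory=UpdateBlockConfig)
    dc_mode: str = "approx"  # backward rule: approx | zero

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.dc_mode not in ("approx", "zero"):
            raise ValueError("dc_mode must be 'approx' or 'zero'")


@dataclass
class DCContext:
    """Physics context the DC layer needs (fixed during a forward pass)."""

    op: object
    spec: object
    basis: object
    Z: np.ndarray
    d: SinogramSet
    mode: str = "approx"


def norm_group_count(channels: int, requested: int | None = None) -> int:
    """Largest group count <= min(8, C) (or the request) dividing C."""
    cap = min(8 if requested is None else requested, channels)
    for g in range(cap, 0, -1):
        if channels % g == 0:
            return g
    return 1


def _he(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class _Module:
    """Tiny parameter-container base class."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "_Module"] = {}

    def _add(self, name, tensor: Tensor):
        self._params[name] = tensor
        return tensor

    def _sub(self, name, module: "_Module"):
        self._children[name] = module
        return module

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters().values()))

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()


class Conv(_Module):
    def __init__(self, rng, cin, cout, nd, ksize=3, zero=False):
        super().__init__()
        shape = (cout, cin) + (ksize,) * nd
        fan_in = cin * ksize**nd
        w = np.zeros(shape) if zero else _he(rng, shape, fan_in)
        self.w = self._add("w", Tensor(w, requires_grad=True))
        self.b = self._add("b", Tensor(np.zeros(cout), requires_grad=True))

    def __call__(self, x):
        return ad.convnd(x, self.w, self.b)


class GroupNorm(_Module):
    def __init__(self, channels, requested=None):
        super().__init__()
        self.groups = norm_group_count(channels, requested)
        self.gamma = self._add("gamma", Tensor(np.ones(channels), requires_grad=True))
        self.beta = self._add("beta", Tensor(np.zeros(channels), requires_grad=True))

    def __call__(self, x):
        return ad.group_norm(x, self.gamma, self.beta, self.groups)


class ConvBlock(_Module):
    """Two 3^nd convolutions, each followed by group norm and ReLU."""

    def __init__(self, rng, cin, cout, nd, norm_groups=None):
        super().__init__()
        self.c1 = self._sub("c1", Conv(rng, cin, cout, nd))
        self.n1 = self._sub("n1", GroupNorm(cout, norm_groups))
        self.c2 = self._sub("c2", Conv(rng, cout, cout, nd))
        self.n2 = self._sub("n2", GroupNorm(cout, norm_groups))

    def __call__(self, x):
        x = ad.relu(self.n1(self.c1(x)))
        return ad.relu(self.n2(self.c2(x)))


class AttentionGate(_Module):
    """Additive attention: skip scaled by a coefficient in (0, 1).

    The coefficient combines the skip input with the gating signal from the
    coarser scale, then ReLU, a linear (1x1 convolution) map to one channel,
    and a logistic activation.
    """

    def __init__(self, rng, ch_skip, ch_gate, nd):
        super().__init__()
        inter = max(ch_skip // 2, 1)
        self.wx = self._sub("wx", Conv(rng, ch_skip, inter, nd, ksize=1))
        self.wg = self._sub("wg", Conv(rng, ch_gate, inter, nd, ksize=1))
        self.psi = self._sub("psi", Conv(rng, inter, 1, nd, ksize=1))
        self.nd = nd

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        if gate.shape[1:] != skip.shape[1:]:
            factor = skip.shape[1] // gate.shape[1]
            gate = ad.upsample_nearest(gate, factor)
        if skip.shape[1:] != gate.shape[1:]:
            raise ValueError("gate not resamplable onto the skip grid")
        a = ad.relu(self.wx(skip) + self.wg(gate))
        coeff = ad.sigmoid(self.psi(a))
        return skip * coeff


def attention_gate(skip: Tensor, gate: Tensor, rng=None) -> Tensor:
    """Functional form with freshly initialized weights (testing helper)."""
    rng = np.random.default_rng() if rng is None else rng
    g = AttentionGate(rng, skip.shape[0], gate.shape[0], skip.ndim - 1)
    return g(skip, gate)


class ShrunkenUNet(_Module):
    """Encoder-decoder image updater with attention-gated skips.

    Input: 4 channels (c1, c2 and the two DC components); output: a
    2-channel residual.  The final 1x1 convolution is zero-initialized so an
    untrained update block is the identity map on the image.
    """

    def __init__(self, cfg: UpdateBlockConfig, nd: int, rng,
                 in_channels: int = 4, out_channels: int = 2):
        super().__init__()
        self.cfg = cfg
        self.nd = nd
        chans = [cfg.n_chl * 2**l for l in range(cfg.depth)]
        self.chans = chans
        cin = in_channels
        for l, ch in enumerate(chans):
            self._sub(f"enc{l}", ConvBlock(rng, cin, ch, nd, cfg.norm_groups))
            cin = ch
        for l in range(cfg.depth - 2, -1, -1):
            self._sub(f"up{l}", Conv(rng, chans[l + 1], chans[l], nd))
            if cfg.attention:
                self._sub(f"att{l}", AttentionGate(rng, chans[l], chans[l + 1], nd))
            self._sub(f"dec{l}", ConvBlock(rng, 2 * chans[l], chans[l], nd,
                                           cfg.norm_groups))
        self._sub("head", Conv(rng, chans[0], out_channels, nd, ksize=1,
                               zero=True))

    def __call__(self, x: Tensor) -> Tensor:
        div = 2 ** (self.cfg.depth - 1)
        pads = []
        for s in x.shape[1:]:
            short = (-s) % div
            pads.append((short // 2, short - short // 2))
        padded = any(p != (0, 0) for p in pads)
        if padded:
            x = ad.pad_spatial(x, pads)
        skips = []
        for l in range(self.cfg.depth):
            x = self._children[f"enc{l}"](x)
            if l < self.cfg.depth - 1:
                skips.append(x)
                x = ad.avg_pool(x, 2)
        for l in range(self.cfg.depth - 2, -1, -1):
            gate = x
            x = self._children[f"up{l}"](ad.upsample_nearest(x, 2))
            skip = skips[l]
            if self.cfg.attention:
                skip = self._children[f"att{l}"](skip, gate)
            x = ad.concat([x, skip], axis=0)
            x = self._children[f"dec{l}"](x)
        out = self._children["head"](x)
        if padded:
            out = ad.crop_spatial(out, pads)
        return out


def dc_layer_op(c: Tensor, ctx: DCContext) -> Tensor:
    """DC layer as a graph node with the hand-written backward rule.

    In ``zero`` mode the DC path contributes no gradient to the input image
    (the layer output is treated as a constant of the backward pass).
    """
    ud = dc_forward(BasisImage(c.data.copy()), ctx.d, ctx.op, ctx.spec,
                    ctx.basis, ctx.Z)

    def bw(upstream):
        if ctx.mode == "zero":
            return (None,)
        return (dc_backward(ud.cache, upstream, ctx.mode,
                            strict_serial=False),)

    return ad.custom_op([c], ud.delta_c, bw)


class UpdateBlock(_Module):
    """One unrolled iteration: residual U-Net update driven by the DC layer."""

    def __init__(self, cfg: UpdateBlockConfig, nd: int, rng):
        super().__init__()
        self.nd = nd
        self.unet = self._sub("unet", ShrunkenUNet(cfg, nd, rng))

    def __call__(self, c: Tensor, ctx: DCContext) -> Tensor:
        delta = dc_layer_op(c, ctx)
        x = ad.concat([c, delta], axis=0)  # (c1, c2, dc1, dc2)
        thin = self.nd == 2 and x.ndim == 4 and x.shape[-1] == 1
        if thin:
            x = x.reshape(x.shape[:-1])
        r = self.unet(x)
        if thin:
            r = r.reshape(r.shape + (1,))
        return c + r


class UnrolledNet(_Module):
    """The full unrolled network: composition of unshared update blocks."""

    def __init__(self, cfg: NetworkConfig, grid_shape: tuple[int, ...],
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.grid_shape = tuple(grid_shape)
        nd = 2 if len(grid_shape) < 3 or grid_shape[2] == 1 else 3
        self.nd = nd
        rng = np.random.default_rng(seed)
        for k in range(cfg.n_blocks):
            self._sub(f"block{k}", UpdateBlock(cfg.block, nd, rng))

    def block(self, k: int) -> UpdateBlock:
        return self._children[f"block{k}"]

    def forward(self, c_init: BasisImage, d: SinogramSet, op, spec, basis,
                Z: np.ndarray, dc_mode: str | None = None) -> list[Tensor]:
        """Return every intermediate iterate [c^1 ... c^N] (graph tensors)."""
        mode = self.cfg.dc_mode if dc_mode is None else dc_mode
        ctx = DCContext(op=op, spec=spec, basis=basis, Z=Z, d=d, mode=mode)
        c = Tensor(c_init.c)
        outputs = []
        for k in range(self.cfg.n_blocks):
            c = self.block(k)(c, ctx)
            outputs.append(c)
        return outputs

    def infer(self, c_init: BasisImage, d: SinogramSet, op, spec, basis,
              Z: np.ndarray) -> BasisImage:
        return BasisImage(self.forward(c_init, d, op, spec, basis, Z)[-1].data)

    # -- weights --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)[:5]} ...")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=float).reshape(p.data.shape)

    def copy_block_weights(self, src: int, dst: int):
        """Propagate one block's weights to another (pretrain -> all blocks)."""
        sp = self.block(src).parameters()
        dp = self.block(dst).parameters()
        for k in sp:
            dp[k].data = sp[k].data.copy()


def resolve_parity(n_blocks_list=(1, 2, 4), target_params: int | None = None,
                   grid_shape=(64, 64, 1), depth: int = 4,
                   base_n_chl: int = 12, tol: float = 0.10) -> dict[int, dict]:
    """Choose N_chl per variant so learnable-parameter totals agree.

    Returns {n_blocks: {"n_chl": int, "params": int}} with every total
    within ``tol`` of the reference (the single-block net at ``base_n_chl``
    unless ``target_params`` is given).
    """
    def count(nb, nc):
        cfg = NetworkConfig(n_blocks=nb,
                            block=UpdateBlockConfig(n_chl=nc, depth=depth))
        return UnrolledNet(cfg, grid_shape, seed=0).parameter_count()

    if target_params is None:
        target_params = count(1, base_n_chl)
    # counts are quantized in N_chl, so match variants to their common mean
    # rather than pinning one variant as the exact reference
    per_variant = []
    for nb in n_blocks_list:
        cands = sorted(((abs(count(nb, nc) - target_params), nc)
                        for nc in range(2, 65)))[:6]
        per_variant.append([(nc, count(nb, nc)) for _, nc in cands])
    best = None
    import itertools
    for combo in itertools.product(*per_variant):
        vals = np.array([c for _, c in combo], dtype=float)
        spread = (vals.max() - vals.min()) / vals.mean()
        if best is None or spread < best[0]:
            best = (spread, combo)
    spread, combo = best
    if spread > tol:
        raise ValueError(f"no N_chl combination within {tol:.0%} parity")
    return {nb: {"n_chl": nc, "params": c}
            for nb, (nc, c) in zip(n_blocks_list, combo)}


def save_checkpoint(path, net: UnrolledNet, extra: dict | None = None):
    meta = {
        "n_blocks": net.cfg.n_blocks,
        "dc_mode": net.cfg.dc_mode,
        "block": {"n_chl": net.cfg.block.n_chl, "depth": net.cfg.block.depth,
                  "norm_groups": net.cfg.block.norm_groups,
                  "attention": net.cfg.block.attention},
        "grid_shape": list(net.grid_shape),
        "extra": extra or {},
    }
    np.savez(path, __meta__=json.dumps(meta), **net.state_dict())


def load_checkpoint(path) -> UnrolledNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = NetworkConfig(n_blocks=meta["n_blocks"], dc_mode=meta["dc_mode"],
                        block=UpdateBlockConfig(**meta["block"]))
    net = UnrolledNet(cfg, tuple(meta["grid_shape"]), seed=0)
    net.load_state_dict(state)
    return net
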