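"""Losses, schedules, and the two-stage training procedure.

Stage 1 (pretrain) trains the first update block alone; because its inputs
(initializer image and its DC update) are fixed across epochs, the DC layer
output is computed once per sample and reused.  Stage 2 (end2end) seeds all
blocks with the pretrained weights and trains the whole unrolled network
under a weighted sum of intermediate losses whose weights follow a
three-phase epoch schedule.  Optimization is ADAM with step-decay, gradient
accumulation over singleton samples (exact, since group normalization has no
cross-sample statistics), and validation-based epoch selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import ScanGeometry, slice_view_support
from .network import DCContext, UnrolledNet, dc_layer_op
from .spectral import BasisImage, MaterialBasis

__all__ = [
    "LossSchedule",
    "TrainConfig",
    "TrainResult",
    "bvm_loss",
    "composite_loss",
    "slice_weight_profile",
    "Adam",
    "train",
]

# Loss weights w_{t,n} per epoch phase and block count.
_WEIGHT_TABLE = {
    1: [[1.00], [1.00], [1.00]],
    2: [[0.50, 1.00], [0.30, 1.00], [0.01, 1.00]],
    4: [[0.30, 0.40, 0.50, 1.00], [0.10, 0.10, 0.10, 1.00],
        [0.01, 0.01, 0.01, 1.00]],
}
_PHASE_EDGES = (10, 20)  # phase 0: epochs 0-10, phase 1: 11-20, phase 2: 21+


@dataclass(frozen=True)
class LossSchedule:
    """Per-epoch intermediate-loss weights plus peripheral-slice weights."""

    slice_weights: np.ndarray | None = None  # per-slice multipliers, or None
    peripheral_weight: float = 0.2

    def weights_for(self, epoch: int, n_blocks: int) -> np.ndarray:
        phase = 0 if epoch <= _PHASE_EDGES[0] else \
            1 if epoch <= _PHASE_EDGES[1] else 2
        if n_blocks in _WEIGHT_TABLE:
            return np.array(_WEIGHT_TABLE[n_blocks][phase])
        w4 = _WEIGHT_TABLE[4][phase]
        return np.array([w4[0]] * (n_blocks - 1) + [1.00])


def slice_weight_profile(geom: ScanGeometry,
                         peripheral_weight: float = 0.2) -> np.ndarray:
    """Down-weighting profile along z: full-rotation slices get weight 1.

    Slices outside the full-rotation window are reconstructed from fewer
    views (margin effect) and are down-weighted in the loss.
    """
    if geom.mode != "helical3d":
        return np.ones(geom.voxel_grid[2])
    lo, hi = slice_view_support(geom).full_range
    idx = np.arange(geom.voxel_grid[2]) % geom.slices_per_rotation
    w = np.where((idx >= lo) & (idx <= hi), 1.0, peripheral_weight)
    return w


def _energy_gram(basis: MaterialBasis, psi_L: np.ndarray) -> np.ndarray:
    """A_ii' = sum_E psi_L(E) mu_i(E) mu_i'(E); the spectral loss term
    sum_E psi_L ||sum_i mu_i dc_i||^2 equals sum_ii' A_ii' <dc_i, dc_i'>."""
    return np.einsum("e,ae,be->ab", psi_L, basis.mu, basis.mu)


def bvm_loss(c_truth, c_est, basis: MaterialBasis, psi_L: np.ndarray,
             slice_weights: np.ndarray | None = None):
    """Basis-vector-model loss: componentwise MSE plus a fluence-weighted
    monoenergetic-image consistency term coupling the two components.

    Accepts a graph Tensor (training) or an array/BasisImage (evaluation);
    symmetric in its two image arguments.
    """
    t = c_truth.c if isinstance(c_truth, BasisImage) else c_truth
    e = c_est.c if isinstance(c_est, BasisImage) else c_est
    A = _energy_gram(basis, psi_L)
    if slice_weights is not None:
        w = np.asarray(slice_weights).reshape((1,) * (np.ndim(t) - 1) + (-1,))
    else:
        w = None

    if isinstance(e, Tensor) or isinstance(t, Tensor):
        diff = (t - e) if isinstance(t, Tensor) else \
            (e - t) * -1.0  # keep Tensor on the left
        d1, d2 = diff[0], diff[1]
        if w is not None:
            ww = w.reshape(w.shape[1:])
            p11 = (d1 * d1 * ww).sum()
            p22 = (d2 * d2 * ww).sum()
            p12 = (d1 * d2 * ww).sum()
        else:
            p11 = (d1 * d1).sum()
            p22 = (d2 * d2).sum()
            p12 = (d1 * d2).sum()
        return (p11 * (1.0 + A[0, 0]) + p22 * (1.0 + A[1, 1])
                + p12 * (2.0 * A[0, 1]))
    diff = np.asarray(t) - np.asarray(e)
    ww = 1.0 if w is None else w.reshape(w.shape[1:])
    p = np.array([[(diff[a] * diff[b] * ww).sum() for b in range(2)]
                  for a in range(2)])
    return float(p[0, 0] + p[1, 1] + (A * p).sum())


def composite_loss(outputs: list, c_truth, schedule: LossSchedule, epoch: int,
                   basis: MaterialBasis, psi_L: np.ndarray):
    """Weighted sum of the per-block losses (final block weight 1)."""
    wts = schedule.weights_for(epoch, len(outputs))
    total = None
    for w, out in zip(wts, outputs):
        term = bvm_loss(c_truth, out, basis, psi_L,
                        slice_weights=schedule.slice_weights) * float(w)
        total = term if total is None else total + term
    return total


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    pretrain_epochs: int = 100
    pretrain_decay_every: int = 10
    end2end_epochs: int = 50
    end2end_decay_every: int = 5
    decay: float = 0.8
    accum: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.accum < 1:
            raise ValueError("need positive lr and accum >= 1")

    def lr_at(self, epoch: int, stage: str) -> float:
        every = (self.pretrain_decay_every if stage == "pretrain"
                 else self.end2end_decay_every)
        return self.lr * self.decay ** (epoch // every)


class Adam:
    """Standard ADAM on a named parameter dict."""

    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: dict, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            p.data = p.data - lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class TrainResult:
    net: UnrolledNet
    train_loss: list
    val_loss: list
    best_epoch: int
    best_state: dict = field(repr=False, default=None)


def _block1_forward(net: UnrolledNet, c_init: np.ndarray, delta: np.ndarray):
    """Run block 1's image updater on a cached DC output."""
    block = net.block(0)
    c = Tensor(c_init)
    x = ad.concat([c, Tensor(delta)], axis=0)
    thin = block.nd == 2 and x.ndim == 4 and x.shape[-1] == 1
    if thin:
        x = x.reshape(x.shape[:-1])
    r = block.unet(x)
    if thin:
        r = r.reshape(r.shape + (1,))
    return c + r


def train(dataset, net: UnrolledNet, cfg: TrainConfig, stage: str,
          op, spec, basis, Z: np.ndarray,
          schedule: LossSchedule | None = None,
          val_dataset=None, pretrained_state: dict | None = None,
          verbose: bool = False) -> TrainResult:
    """Train the network on SimSample triplets (init, target, sinogram).

    ``stage='pretrain'`` trains block 1 only, reusing one cached DC update
    per sample; ``stage='end2end'`` first propagates block-1 (or provided)
    weights to all blocks, then trains jointly with the approximate DC
    backward rule.  Deterministic under a fixed config seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if stage not in ("pretrain", "end2end"):
        raise ValueError(f"unknown stage {stage!r}")
    schedule = schedule or LossSchedule()
    psi_L = spec.psi_L
    rng = np.random.default_rng(cfg.seed)
    params = (net.block(0).parameters() if stage == "pretrain"
              else net.parameters())
    opt = Adam(params)
    n_epochs = cfg.pretrain_epochs if stage == "pretrain" else cfg.end2end_epochs

    if stage == "pretrain":
        cached = []
        for s in dataset:
            from .dc import dc_forward
            ud = dc_forward(s.init, s.d, op, spec, basis, Z)
            cached.append(ud.delta_c)
    elif pretrained_state is not None:
        net.block(0).parameters()  # ensure built
        net.load_state_dict({**net.state_dict(), **pretrained_state})
        for k in range(1, net.cfg.n_blocks):
            net.copy_block_weights(0, k)

    def sample_loss(idx: int, epoch: int):
        s = dataset[idx]
        if stage == "pretrain":
            out = _block1_forward(net, s.init.c, cached[idx])
            return bvm_loss(s.target.c, out, basis, psi_L,
                            slice_weights=schedule.slice_weights)
        outs = net.forward(s.init, s.d, op, spec, basis, Z)
        return composite_loss(outs, s.target.c, schedule, epoch, basis, psi_L)

    def val_loss_value(epoch: int) -> float:
        tot = 0.0
        for s in val_dataset:
            if stage == "pretrain":
                from .dc import dc_forward
                ud = dc_forward(s.init, s.d, op, spec, basis, Z)
                out = _block1_forward(net, s.init.c, ud.delta_c)
                tot += bvm_loss(s.target.c, out, basis, psi_L).item()
            else:
                outs = net.forward(s.init, s.d, op, spec, basis, Z)
                tot += composite_loss(outs, s.target.c, schedule, epoch,
                                      basis, psi_L).item()
        return tot / len(val_dataset)

    history, val_history = [], []
    best = (np.inf, -1, None)
    for epoch in range(n_epochs):
        order = rng.permutation(len(dataset))
        lr = cfg.lr_at(epoch, stage)
        acc_grads, n_acc, epoch_loss = {}, 0, 0.0
        for idx in order:
            net.zero_grad()
            loss = sample_loss(int(idx), epoch)
            loss.backward()
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss.item()
            for k, p in params.items():
                if p.grad is not None:
                    acc_grads[k] = acc_grads.get(k, 0.0) + p.grad
            n_acc += 1
            if n_acc == cfg.accum:
                opt.step({k: g / n_acc for k, g in acc_grads.items()}, lr)
                acc_grads, n_acc = {}, 0
        if n_acc:
            opt.step({k: g / n_acc for k, g in acc_grads.items()}, lr)
        history.append(epoch_loss / len(dataset))
        if val_dataset:
            v = val_loss_value(epoch)
            val_history.append(v)
            if v < best[0]:
                best = (v, epoch, net.state_dict())
        if verbose:
            print(f"[{stage}] epoch {epoch}: train {history[-1]:.5g}"
                  + (f" val {val_history[-1]:.5g}" if val_dataset else ""))
    if val_dataset and best[2] is not None:
        net.load_state_dict(best[2])
    return TrainResult(net=net, train_loss=history, val_loss=val_history,
                       best_epoch=best[1] if val_dataset else n_epochs - 1,
                       best_state=best[2])
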