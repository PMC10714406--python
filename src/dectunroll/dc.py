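"""Data-consistency layer: one alternating-minimization update direction with
a hand-derived backward rule.

Forward: the update direction for both basis components,

    DC(c, d)_i(x) = -(1/Z_i(x)) * log( b~_i(x) / b^_i(x) ),

where b^ and b~ are the mu-weighted backprojections of the modeled (q) and
measured-count-matched (p) energy-resolved sinograms.  The quantities q and
b^ computed here are cached for the backward pass.

Backward modes:

``approx``
    The transposed Jacobian-vector product of the rank-reduced Jacobian
    obtained by assuming g ~ d and q ~ p (the data-consistent regime).  Costs
    exactly 2 forward-projection and 2 back-projection applications on top of
    the cached forward quantities.

``exact``
    The full analytic Jacobian, materialized densely (small instances only).
    Includes the cross-energy coupling terms that the approximate rule
    discards, so it matches finite differences of the forward map anywhere,
    not only at data consistency.

``zero``
    Pass-through of the upstream gradient (the variant that treats the DC
    layer as gradient-free; inside the unrolled network this corresponds to
    detaching the DC path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import (BasisImage, MaterialBasis, SinogramSet, SpectrumPair,
                       compute_qp, project_components)

__all__ = ["DCCache", "UpdateDirection", "dc_forward", "dc_backward"]

_EXACT_VOXEL_GUARD = 10_000


@dataclass
class DCCache:
    """Forward-pass quantities reused by the backward rule."""

    q: np.ndarray        # (2, n_rays, n_E)
    S: np.ndarray        # (2, n_rays) = sum_E q
    bhat: np.ndarray     # (2, *grid)
    btilde: np.ndarray   # (2, *grid)
    Z: np.ndarray        # (2, *grid)
    d: np.ndarray        # (2, n_rays)
    supported: np.ndarray  # (2, *grid) bool
    op: object
    basis: MaterialBasis
    serial: int


@dataclass
class UpdateDirection:
    """DC-layer output (same shape as the basis image) plus its cache."""

    delta_c: np.ndarray  # (2, *grid)
    cache: DCCache


def dc_forward(c: BasisImage, d: SinogramSet, op, spec: SpectrumPair,
               basis: MaterialBasis, Z: np.ndarray) -> UpdateDirection:
    """One update direction; identical to a DEAM step minus the iterate."""
    lines = project_components(op, c)                     # 2 forward
    q, p = compute_qp(op, spec, basis, c, d, lines=lines)
    S = q.sum(axis=2)
    sino_q = np.einsum("ie,jye->iy", basis.mu, q)
    sino_p = np.einsum("ie,jye->iy", basis.mu, p)
    bhat = op.back(sino_q)                                # 2 back
    btilde = op.back(sino_p)                              # 2 back
    supported = (bhat > 0) & (btilde > 0) & np.isfinite(Z)
    delta = np.zeros_like(bhat)
    delta[supported] = -(1.0 / Z[supported]) * np.log(
        btilde[supported] / bhat[supported])
    op.dc_serial += 1
    cache = DCCache(q=q, S=S, bhat=bhat, btilde=btilde, Z=Z, d=d.d,
                    supported=supported, op=op, basis=basis,
                    serial=op.dc_serial)
    return UpdateDirection(delta_c=delta, cache=cache)


def _check_cache(cache: DCCache) -> None:
    if cache.serial != cache.op.dc_serial:
        raise RuntimeError(
            "stale DC cache: another dc_forward ran on this operator since "
            "this cache was produced")


def dc_backward(cache: DCCache, upstream: np.ndarray, mode: str,
                strict_serial: bool = True) -> np.ndarray:
    """Vector-Jacobian product of the DC layer for an upstream gradient.

    By default the cache must come from the operator's most recent
    ``dc_forward`` (stale-cache guard); the unrolled network disables the
    strict check because it pairs each backward with its own block's cache
    while later blocks have already run their forwards.
    """
    upstream = np.asarray(upstream, dtype=float)
    if upstream.shape != cache.bhat.shape:
        raise ValueError("upstream gradient shape mismatch")
    if mode == "zero":
        return upstream.copy()
    if strict_serial:
        _check_cache(cache)
    if mode == "approx":
        return _backward_approx(cache, upstream)
    if mode == "exact":
        return _exact_jacobian(cache).T.dot(
            upstream.reshape(-1)).reshape(upstream.shape)
    raise ValueError(f"unknown backward mode {mode!r}")


def _backward_approx(cache: DCCache, upstream: np.ndarray) -> np.ndarray:
    """Transposed JVP of  J ~ -(1/(Z_i b^_i)) h K_ii' h^T  using cached q, b^."""
    op, mu = cache.op, cache.basis.mu
    scale = np.zeros_like(upstream)
    scale[cache.supported] = upstream[cache.supported] / (
        cache.Z[cache.supported] * cache.bhat[cache.supported])
    F = op.forward(scale)                                  # 2 forward
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(cache.d[:, :, None] > 0,
                     cache.q**2 / cache.d[:, :, None], 0.0)
    w = w.sum(axis=0)                                      # (n_rays, n_E)
    a = np.einsum("ie,iy->ye", mu, F)
    G = np.einsum("ie,ye->iy", mu, w * a)
    return -op.back(G)                                     # 2 back


def _exact_jacobian(cache: DCCache) -> np.ndarray:
    """Full analytic Jacobian d DC_(i,x) / d c_(i',x'), dense.

    Derived from DC_i = -(1/Z_i) (log b~_i - log b^_i) with
    dq_j(y,E)/dc_i'(x') = -q mu_i'(E) h(x',y); includes the cross-energy
    terms through M_i,j(y) = sum_E mu_i(E) q_j(y,E).
    """
    op, mu = cache.op, cache.basis.mu
    nvox = int(np.prod(cache.bhat.shape[1:]))
    if nvox > _EXACT_VOXEL_GUARD:
        raise ValueError(
            f"exact Jacobian guarded above {_EXACT_VOXEL_GUARD} voxels")
    H = op.dense(_EXACT_VOXEL_GUARD)                       # (n_rays, nvox)
    q, S, d = cache.q, cache.S, cache.d
    M = np.einsum("ie,jye->jiy", mu, q)                    # (2j, 2i, n_rays)
    W = np.einsum("ae,be,jye->jaby", mu, mu, q)            # (2j, 2a, 2b, n_rays)
    Wsum = W.sum(axis=0)                                   # (2, 2, n_rays)
    with np.errstate(divide="ignore", invalid="ignore"):
        dS2 = np.where(S > 0, d / S**2, 0.0)               # (2j, n_rays)
    # coefficient of h(x,y) h(x',y) in d b~ / d c
    coef_t = np.einsum("jy,jaby->aby",
                       dS2, np.einsum("jay,jby->jaby", M, M) - S[:, None, None, :] * W)
    J = np.zeros((2, nvox, 2, nvox))
    sup = cache.supported.reshape(2, nvox)
    Zf = cache.Z.reshape(2, nvox)
    bh = cache.bhat.reshape(2, nvox)
    bt = cache.btilde.reshape(2, nvox)
    for i in range(2):
        for ip in range(2):
            Bt = (H.T * coef_t[i, ip]) @ H
            Bh = -(H.T * Wsum[i, ip]) @ H
            rows = np.zeros((nvox, nvox))
            m = sup[i]
            rows[m] = (Bt[m] / bt[i, m, None] - Bh[m] / bh[i, m, None])
            rows[m] *= -1.0 / Zf[i, m, None]
            J[i, :, ip, :] = rows
    return J.reshape(2 * nvox, 2 * nvox)
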