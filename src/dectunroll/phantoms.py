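"""Synthetic ground truth and measurements.

Phantoms mimic a cylindrical acrylic-shell calibration phantom (215 mm full
scale) filled with water and carrying eight liquid-filled insert bottles
(ethanol, propanol, butanol, K2HPO4 solutions, water), plus a simple
head-like ellipse phantom.  Every region is filled with the least-squares
basis decomposition of its material's attenuation curve, so simulated
measurements are exactly consistent with the basis-vector forward model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

import math

from . import materials as mat
from .geometry import (ScanGeometry, SystemOperator, interior_rotations,
                       rotation_rays)
from .spectral import (BasisImage, EnergyGrid, MaterialBasis, ScatterTerm,
                       SinogramSet, SpectrumPair, polychromatic_forward)

__all__ = [
    "PhantomSpec",
    "SimSample",
    "decompose_material_to_basis",
    "make_phantom",
    "simulate_measurement",
    "make_dataset",
    "DEFAULT_INSERTS",
]

# Insert ring contents, full-scale layout.  Eight bottles as in the physical
# calibration phantom; K2HPO4 concentrations are 50-200 mg/ml plus a water
# reference bottle.
DEFAULT_INSERTS = (
    "ethanol", "propanol", "butanol", "water",
    "k2hpo4_050", "k2hpo4_100", "k2hpo4_150", "k2hpo4_200",
)

FIT_RANGE_KEV = (40.0, 140.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Layout of a synthetic phantom, full-scale dimensions in mm."""

    kind: str = "insert_cylinder"
    shell_diameter: float = 215.0
    shell_wall: float = 6.0
    insert_diameter: float = 31.0
    ring_radius: float = 65.0
    insert_materials: tuple[str, ...] = DEFAULT_INSERTS
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.kind not in ("insert_cylinder", "head_ellipse"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "insert_cylinder":
            if (self.ring_radius + self.insert_diameter / 2.0
                    > self.shell_diameter / 2.0 - self.shell_wall):
                raise ValueError("inserts do not fit inside the shell")
            n = len(self.insert_materials)
            if n > 1:
                gap = 2.0 * self.ring_radius * np.sin(np.pi / n)
                if gap < self.insert_diameter:
                    raise ValueError("inserts overlap on the ring")

    @property
    def scaled_shell_diameter(self) -> float:
        return self.shell_diameter * self.scale


def decompose_material_to_basis(mu_table: np.ndarray, basis: MaterialBasis,
                                grid: EnergyGrid,
                                weight: np.ndarray | str = "uniform",
                                fit_range=FIT_RANGE_KEV):
    """Least-squares basis weights for an attenuation curve.

    Fits mu(E) ~ c1 mu1(E) + c2 mu2(E) over ``fit_range`` (optionally
    fluence-weighted) and returns ((c1, c2), relative residual).
    """
    e = grid.energies
    sel = (e >= fit_range[0]) & (e <= fit_range[1])
    mu_target = mat.interp_loglog(e[sel], mu_table[:, 0], mu_table[:, 1]) \
        if mu_table.ndim == 2 else np.asarray(mu_table)[sel]
    A = basis.mu[:, sel].T
    if isinstance(weight, str):
        w = np.ones(sel.sum()) if weight == "uniform" else None
        if w is None:
            raise ValueError("weight must be 'uniform' or an array")
    else:
        w = np.asarray(weight, dtype=float)[sel]
    cond = np.linalg.cond(A)
    if cond > 1e8:
        raise np.linalg.LinAlgError("basis curves are nearly collinear on this grid")
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], mu_target * sw, rcond=None)
    resid = A @ coef - mu_target
    denom = np.linalg.norm(mu_target * sw)
    rel = float(np.linalg.norm(resid * sw) / denom) if denom > 0 else 0.0
    return (float(coef[0]), float(coef[1])), rel


def _material_weights(name: str | None, basis: MaterialBasis, grid: EnergyGrid):
    if name is None or name == "air":
        return (0.0, 0.0)
    (c1, c2), _ = decompose_material_to_basis(mat.tabulate_material(name),
                                              basis, grid)
    return (c1, c2)


def _k2hpo4_like(conc: float):
    """Register a jittered-concentration solution on the fly."""
    name = f"k2hpo4_{conc:.4f}"
    if name not in mat.MATERIALS:
        mat.MATERIALS[name] = mat._k2hpo4_solution(conc)
    return name


def make_phantom(spec: PhantomSpec, geom: ScanGeometry, basis: MaterialBasis,
                 grid: EnergyGrid, center_jitter: np.ndarray | None = None):
    """Voxelize a phantom; returns (BasisImage, integer label map, legend).

    Label 0 is air, 1 the water background, 2 the shell, 3.. the inserts in
    ``spec.insert_materials`` order.
    """
    nx, ny, nz = geom.voxel_grid
    dx, dy, _ = geom.voxel_spacing
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    label = np.zeros((nx, ny), dtype=int)
    legend = {0: "air", 1: "water", 2: "shell"}
    R2 = X**2 + Y**2

    if spec.kind == "insert_cylinder":
        r_out = spec.shell_diameter * spec.scale / 2.0
        r_in = r_out - spec.shell_wall * spec.scale
        label[R2 <= r_out**2] = 2
        label[R2 <= r_in**2] = 1
        n = len(spec.insert_materials)
        jit = np.zeros((n, 2)) if center_jitter is None else center_jitter
        for k, name in enumerate(spec.insert_materials):
            ang = 2.0 * np.pi * k / n
            cx = spec.ring_radius * spec.scale * np.cos(ang) + jit[k, 0]
            cy = spec.ring_radius * spec.scale * np.sin(ang) + jit[k, 1]
            rr = spec.insert_diameter * spec.scale / 2.0
            label[((X - cx)**2 + (Y - cy)**2) <= rr**2] = 3 + k
            legend[3 + k] = name
        region_mats = {1: "water", 2: "acrylic"}
        for k, name in enumerate(spec.insert_materials):
            region_mats[3 + k] = name
    else:  # head_ellipse: skull-like shell, brain-like interior, air pockets
        a = spec.shell_diameter * spec.scale / 2.0
        b = 0.78 * a
        ell = (X / a)**2 + (Y / b)**2
        ell_in = (X / (a - spec.shell_wall * spec.scale))**2 \
            + (Y / (b - spec.shell_wall * spec.scale))**2
        label[ell <= 1.0] = 2
        label[ell_in <= 1.0] = 1
        for k, (px, py, pr) in enumerate([(0.0, 0.45 * b, 0.12 * a),
                                          (-0.3 * a, -0.3 * b, 0.08 * a)]):
            label[((X - px)**2 + (Y - py)**2) <= pr**2] = 3 + k
            legend[3 + k] = "air"
        region_mats = {1: "water", 2: "cacl2_23pct", 3: None, 4: None}
        legend[2] = "skull"

    c = np.zeros((2, nx, ny, nz))
    for lab, name in region_mats.items():
        w = _material_weights(name, basis, grid)
        m = label == lab
        c[0][m] = w[0]
        c[1][m] = w[1]
    label3 = np.broadcast_to(label[:, :, None], (nx, ny, nz)).copy()
    return BasisImage(c), label3, legend


def simulate_measurement(phantom: BasisImage, op: SystemOperator,
                         spec: SpectrumPair, basis: MaterialBasis,
                         noise: str = "none", seed: int | None = None,
                         scatter: ScatterTerm | None = None) -> SinogramSet:
    """Mean polychromatic sinograms, optionally with Poisson counting noise."""
    g = polychromatic_forward(op, spec, basis, phantom, scatter=scatter)
    if noise == "none":
        return g
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        return SinogramSet(rng.poisson(g.d).astype(float))
    raise ValueError(f"unknown noise model {noise!r}")


@dataclass
class SimSample:
    """One training/evaluation unit: sinogram stack + target + initializer."""

    d: SinogramSet
    target: BasisImage
    init: BasisImage
    seed: int
    meta: dict = field(default_factory=dict)


def make_dataset(n_samples: int, spec: PhantomSpec, geom: ScanGeometry,
                 op: SystemOperator, spectrum: SpectrumPair,
                 basis: MaterialBasis, grid: EnergyGrid, seed: int = 0,
                 noise: str = "poisson", initializer=None) -> list[SimSample]:
    """Seeded collection of jittered phantom samples with measurements.

    Jitter policy per sample: insert diameters +-10%, K2HPO4 concentrations
    +-15%, insert centers +-1 voxel.  In fan2d mode one sample is one slice;
    in helical3d mode each simulated scan is cut into per-rotation sinogram
    stacks with matching slice stacks (padded by half a collimation width of
    real neighboring slices, as the margin effect requires), one sample per
    interior rotation.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    samples = []
    while len(samples) < n_samples:
        k = len(samples)
        sub = int(rng.integers(0, 2**31 - 1))
        srng = np.random.default_rng(sub)
        mats = []
        for name in spec.insert_materials:
            if name.startswith("k2hpo4"):
                conc = float(name.split("_")[1])
                conc *= 1.0 + srng.uniform(-0.15, 0.15)
                mats.append(_k2hpo4_like(conc))
            else:
                mats.append(name)
        jspec = replace(
            spec,
            insert_diameter=spec.insert_diameter * (1.0 + srng.uniform(-0.10, 0.10)),
            insert_materials=tuple(mats))
        jitter = srng.uniform(-1.0, 1.0, size=(len(mats), 2)) \
            * min(geom.voxel_spacing[:2])
        target, label, legend = make_phantom(jspec, geom, basis, grid,
                                             center_jitter=jitter)
        d = simulate_measurement(target, op, spectrum, basis, noise=noise,
                                 seed=sub)
        if initializer is not None:
            init = initializer(d)
        else:
            init = BasisImage(np.zeros_like(target.c))
        if geom.mode == "helical3d":
            dz = geom.voxel_spacing[2]
            n_pad = math.ceil((geom.collimation_width / 2.0) / dz - 1e-12)
            spr = geom.slices_per_rotation
            for r in interior_rotations(geom, n_pad):
                z0, z1 = r * spr, r * spr + spr
                samples.append(SimSample(
                    d=SinogramSet(d.d[:, rotation_rays(geom, r)]),
                    target=BasisImage(target.c[..., z0:z1].copy()),
                    init=BasisImage(init.c[..., z0:z1].copy()),
                    seed=sub,
                    meta={"legend": legend, "rotation": r, "n_pad": n_pad,
                          # padding with the volume's real neighboring slices
                          "init_padded": init.c[..., z0 - n_pad:z1 + n_pad].copy()}))
                if len(samples) >= n_samples:
                    break
        else:
            samples.append(SimSample(d=d, target=target, init=init, seed=sub,
                                     meta={"legend": legend}))
    return samples[:n_samples]
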