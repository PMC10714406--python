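"""Scan geometry, the system operator h(x,y), and helical view-support accounting.

The system operator is assembled once per geometry as a sparse matrix of
ray-voxel interaction lengths (mm), built by interpolating line integration:
each ray is sampled at half-voxel steps and the sample weight is spread onto
the surrounding voxels with trilinear interpolation.  Backprojection is the
exact transpose of the matrix, so the forward/adjoint pair is matched to
machine precision — a requirement for the gradient-oracle tests of the
data-consistency layer.

Two scan modes are supported:

``fan2d``
    A single-slice equiangular (curved detector) fan-beam geometry used for
    small-scale experiments.

``helical3d``
    A cone-beam geometry with the source on a helix; detector rows are spaced
    along z (row spacing quoted at the isocenter so that
    ``collimation_width = n_rows * row_spacing``).

Sinograms are stored flat with ray index ``(view, row, channel)`` in
C order; :meth:`SystemOperator.sino_shape` gives the 3-D layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ScanGeometry",
    "SystemOperator",
    "SliceSupport",
    "CropSpec",
    "build_system_operator",
    "apply_system_operator",
    "slice_view_support",
    "n_views_supporting_slice",
    "pad_stack",
    "desk_fan_geometry",
    "desk_helical_geometry",
    "clinical_geometry",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry for one scan.

    Distances are in mm, ``channel_spacing`` in radians.  ``row_spacing`` is
    quoted at the isocenter; in helical mode ``collimation_width`` must equal
    ``n_rows * row_spacing``.
    """

    mode: str
    n_rows: int
    n_channels: int
    row_spacing: float
    channel_spacing: float
    n_vpr: int
    z_feed: float
    collimation_width: float
    source_axis_dist: float
    source_detector_dist: float
    voxel_grid: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]
    n_rotations: int = 1

    def __post_init__(self):
        if self.mode not in ("fan2d", "helical3d"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if min(self.voxel_spacing) <= 0 or self.channel_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.n_vpr < 1 or self.n_channels < 1 or self.n_rows < 1:
            raise ValueError("counts must be >= 1")
        if self.source_axis_dist <= 0 or self.source_detector_dist <= self.source_axis_dist:
            raise ValueError("need 0 < source_axis_dist < source_detector_dist")
        if self.mode == "helical3d":
            if self.row_spacing <= 0 or self.z_feed <= 0:
                raise ValueError("helical mode needs positive row spacing and feed")
            if not math.isclose(self.collimation_width, self.n_rows * self.row_spacing,
                                rel_tol=1e-9):
                raise ValueError("collimation_width must equal n_rows * row_spacing")

    @property
    def n_views_total(self) -> int:
        return self.n_vpr * (self.n_rotations if self.mode == "helical3d" else 1)

    @property
    def effective_rows(self) -> int:
        return self.n_rows if self.mode == "helical3d" else 1

    @property
    def n_rays(self) -> int:
        return self.n_views_total * self.effective_rows * self.n_channels

    @property
    def slices_per_rotation(self) -> int:
        """Number of image slices the bed advances per gantry rotation."""
        return int(round(self.z_feed / self.voxel_spacing[2]))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "n_rows": self.n_rows, "n_channels": self.n_channels,
            "row_spacing": self.row_spacing, "channel_spacing": self.channel_spacing,
            "n_vpr": self.n_vpr, "z_feed": self.z_feed,
            "collimation_width": self.collimation_width,
            "source_axis_dist": self.source_axis_dist,
            "source_detector_dist": self.source_detector_dist,
            "voxel_grid": list(self.voxel_grid),
            "voxel_spacing": list(self.voxel_spacing),
            "n_rotations": self.n_rotations,
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScanGeometry":
        cfg = dict(cfg)
        cfg["voxel_grid"] = tuple(cfg["voxel_grid"])
        cfg["voxel_spacing"] = tuple(cfg["voxel_spacing"])
        return cls(**cfg)


def desk_fan_geometry(n=64, n_channels=95, n_views=120, pixel_mm=1.0) -> ScanGeometry:
    """Small 2D fan-beam geometry for desk-scale experiments."""
    return ScanGeometry(
        mode="fan2d", n_rows=1, n_channels=n_channels, row_spacing=1.0,
        channel_spacing=0.005, n_vpr=n_views, z_feed=1.0, collimation_width=1.0,
        source_axis_dist=200.0, source_detector_dist=400.0,
        voxel_grid=(n, n, 1), voxel_spacing=(pixel_mm, pixel_mm, 1.0),
    )


def desk_helical_geometry() -> ScanGeometry:
    """Small helical cone-beam geometry (8 slices per rotation)."""
    return ScanGeometry(
        mode="helical3d", n_rows=4, n_channels=24, row_spacing=3.0,
        channel_spacing=0.0099, n_vpr=60, z_feed=8.0, collimation_width=12.0,
        source_axis_dist=200.0, source_detector_dist=400.0,
        voxel_grid=(32, 32, 24), voxel_spacing=(1.0, 1.0, 1.0), n_rotations=3,
    )


def clinical_geometry() -> ScanGeometry:
    """The 16x816 helical geometry (1320 views/rotation, 8.304 mm feed).

    Used for geometry-level calculations (view support, padding, slices per
    rotation); its projection matrix is far too large to assemble here.
    """
    return ScanGeometry(
        mode="helical3d", n_rows=16, n_channels=816, row_spacing=0.75,
        channel_spacing=0.00118971, n_vpr=1320, z_feed=8.304,
        collimation_width=12.0, source_axis_dist=645.0,
        source_detector_dist=1118.0, voxel_grid=(610, 610, 340),
        voxel_spacing=(1.0, 1.0, 1.034), n_rotations=43,
    )


class _Counters:
    __slots__ = ("forward", "back")

    def __init__(self):
        self.forward = 0
        self.back = 0


class SystemOperator:
    """Linear map between the image grid and the sinogram, with exact adjoint.

    ``forward``/``back`` accept a single field or a stack of fields along a
    leading axis; the instrumentation counters advance by one per component
    field processed.  ``restricted`` returns a view over a subset of rays that
    shares the call counters (used by ordered subsets).
    """

    def __init__(self, H: sp.csr_matrix, image_shape: tuple[int, ...],
                 geometry: ScanGeometry | None = None,
                 counters: _Counters | None = None):
        self.H = H.tocsr()
        self.HT = self.H.T.tocsr()
        self.image_shape = tuple(image_shape)
        self.geometry = geometry
        self.counters = counters if counters is not None else _Counters()
        self.n_rays = H.shape[0]
        self.n_voxels = H.shape[1]
        self.dc_serial = 0  # bumped by dc_forward; guards stale caches

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_matrix(cls, H, image_shape) -> "SystemOperator":
        H = sp.csr_matrix(np.atleast_2d(np.asarray(H, dtype=float))) if not sp.issparse(H) else H
        return cls(H, image_shape)

    def restricted(self, ray_idx: np.ndarray) -> "SystemOperator":
        sub = SystemOperator(self.H[ray_idx], self.image_shape, self.geometry,
                             counters=self.counters)
        return sub

    # -- application ----------------------------------------------------------
    def _flatten_image(self, u):
        u = np.asarray(u, dtype=float)
        if u.shape == self.image_shape:
            return u.reshape(1, -1), True
        if u.ndim == len(self.image_shape) + 1 and u.shape[1:] == self.image_shape:
            return u.reshape(u.shape[0], -1), False
        raise ValueError(f"image field shape {u.shape} does not match {self.image_shape}")

    def forward(self, u):
        """Line-integral projection of an image field (mm-weighted)."""
        flat, single = self._flatten_image(u)
        out = self.H @ flat.T  # (n_rays, k)
        self.counters.forward += flat.shape[0]
        return out[:, 0] if single else out.T.copy()

    def back(self, s):
        """Adjoint (backprojection) of a sinogram field."""
        s = np.asarray(s, dtype=float)
        single = s.ndim == 1
        flat = s.reshape(1, -1) if single else s
        if flat.shape[1] != self.n_rays:
            raise ValueError(f"sinogram length {flat.shape[1]} != {self.n_rays}")
        out = self.HT @ flat.T  # (n_vox, k)
        self.counters.back += flat.shape[0]
        if single:
            return out[:, 0].reshape(self.image_shape)
        return out.T.reshape((flat.shape[0],) + self.image_shape)

    # -- introspection --------------------------------------------------------
    @property
    def sino_shape(self) -> tuple[int, int, int]:
        g = self.geometry
        if g is None:
            return (1, 1, self.n_rays)
        return (g.n_views_total, g.effective_rows, g.n_channels)

    def row_sums(self) -> np.ndarray:
        """Per-ray total path weight sum_x h(x, y) (mm)."""
        return np.asarray(self.H.sum(axis=1)).ravel()

    def dense(self, max_voxels: int = 10_000) -> np.ndarray:
        if self.n_voxels > max_voxels:
            raise ValueError(f"dense matrix guarded above {max_voxels} voxels")
        return self.H.toarray()


def apply_system_operator(op: SystemOperator, field, direction: str):
    """Apply the operator in the requested direction with shape checking."""
    if direction == "forward":
        return op.forward(field)
    if direction == "back":
        return op.back(field)
    raise ValueError(f"direction must be 'forward' or 'back', got {direction!r}")


# -- projector assembly -------------------------------------------------------

def _view_rays(geom: ScanGeometry, view: int):
    """Source position and unit directions for every ray of one view."""
    beta = 2.0 * math.pi * (view % geom.n_vpr) / geom.n_vpr
    if geom.mode == "helical3d":
        travel = geom.z_feed * geom.n_rotations
        z_src = -travel / 2.0 + geom.z_feed * view / geom.n_vpr
    else:
        z_src = 0.0
    src = np.array([geom.source_axis_dist * math.cos(beta),
                    geom.source_axis_dist * math.sin(beta), z_src])
    nr, nc = geom.effective_rows, geom.n_channels
    gammas = (np.arange(nc) - (nc - 1) / 2.0) * geom.channel_spacing
    z_iso = (np.arange(nr) - (nr - 1) / 2.0) * geom.row_spacing
    z_det = z_iso * geom.source_detector_dist / geom.source_axis_dist
    ang = beta + gammas
    u = np.stack([-np.cos(ang), -np.sin(ang), np.zeros_like(ang)], axis=-1)
    det = (src[None, None, :]
           + geom.source_detector_dist * u[None, :, :]
           + np.stack([np.zeros((nr, nc)), np.zeros((nr, nc)),
                       np.broadcast_to(z_det[:, None], (nr, nc))], axis=-1))
    dirs = det - src[None, None, :]
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return src, dirs.reshape(-1, 3)


def build_system_operator(geom: ScanGeometry) -> SystemOperator:
    """Assemble the sparse ray-voxel interaction matrix for a geometry."""
    n = np.array(geom.voxel_grid, dtype=int)
    d = np.array(geom.voxel_spacing, dtype=float)
    # clip rays half a voxel beyond the grid so the interpolation basis of
    # boundary voxels integrates over its full support
    ext = (n + 1) * d / 2.0
    step = 0.5 * float(d[:2].min() if n[2] == 1 else d.min())
    nvox = int(n.prod())
    rays_per_view = geom.effective_rows * geom.n_channels

    blocks = []
    for v in range(geom.n_views_total):
        src, dirs = _view_rays(geom, v)
        # slab clipping against the grid bounding box
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-ext[None, :] - src[None, :]) / dirs
            t2 = (ext[None, :] - src[None, :]) / dirs
        lo = np.where(np.abs(dirs) > 1e-12, np.minimum(t1, t2), -np.inf)
        hi = np.where(np.abs(dirs) > 1e-12, np.maximum(t1, t2), np.inf)
        parallel_miss = (np.abs(dirs) <= 1e-12) & (np.abs(src[None, :]) >= ext[None, :])
        tmin = lo.max(axis=1)
        tmax = hi.min(axis=1)
        tmax = np.where(parallel_miss.any(axis=1), tmin, tmax)
        span = np.clip(tmax - tmin, 0.0, None)
        nsmp = int(np.ceil(span.max() / step)) if span.max() > 0 else 0
        if nsmp == 0:
            continue
        t = tmin[:, None] + (np.arange(nsmp)[None, :] + 0.5) * step
        alive = t < tmax[:, None]
        pts = src[None, None, :] + t[:, :, None] * dirs[:, None, :]
        u = pts / d[None, None, :] + (n[None, None, :] - 1) / 2.0
        i0 = np.floor(u).astype(np.int64)
        f = u - i0
        ray_ids = np.broadcast_to(np.arange(rays_per_view)[:, None], t.shape)

        rows_l, cols_l, vals_l = [], [], []
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = i0 + off[None, None, :]
            w = np.prod(np.where(off[None, None, :] == 1, f, 1.0 - f), axis=-1)
            inb = np.all((idx >= 0) & (idx < n[None, None, :]), axis=-1)
            keep = alive & inb & (w > 0)
            if not keep.any():
                continue
            flat_vox = (idx[..., 0] * n[1] + idx[..., 1]) * n[2] + idx[..., 2]
            rows_l.append(ray_ids[keep])
            cols_l.append(flat_vox[keep])
            vals_l.append(w[keep] * step)
        if rows_l:
            rows = np.concatenate(rows_l) + v * rays_per_view
            cols = np.concatenate(cols_l)
            vals = np.concatenate(vals_l)
            blocks.append(sp.coo_matrix((vals, (rows, cols)),
                                        shape=(geom.n_rays, nvox)))
    if not blocks:
        raise ValueError("no ray intersects the image grid; check the geometry")
    H = sp.csr_matrix(sum(blocks[1:], start=blocks[0]))
    H.sum_duplicates()
    return SystemOperator(H, tuple(int(x) for x in n), geometry=geom)


# -- per-rotation stacks -------------------------------------------------------

def rotation_rays(geom: ScanGeometry, rotation: int) -> np.ndarray:
    """Flat ray indices of one gantry rotation."""
    if geom.mode != "helical3d":
        raise ValueError("rotations are defined for helical3d mode only")
    if not 0 <= rotation < geom.n_rotations:
        raise ValueError(f"rotation {rotation} out of range")
    rays_per_view = geom.effective_rows * geom.n_channels
    lo = rotation * geom.n_vpr * rays_per_view
    return np.arange(lo, lo + geom.n_vpr * rays_per_view)


def stack_operator(op: SystemOperator, n_pad: int,
                   rotation: int | None = None) -> SystemOperator:
    """Operator from one rotation's rays to its (padded) slice stack.

    The image domain is the ``slices_per_rotation + 2 * n_pad`` slices
    centered on the rotation's own stack; attenuation from slices further
    out is neglected, which is exactly what z-padding by half a collimation
    width makes negligible.  Because the helix is periodic (the feed equals
    one stack height), the matrix is identical for every interior rotation,
    so the returned operator serves all of them.
    """
    geom = op.geometry
    if geom is None or geom.mode != "helical3d":
        raise ValueError("stack_operator needs a helical3d operator")
    spr = geom.slices_per_rotation
    if rotation is None:
        rotation = geom.n_rotations // 2
    z0 = rotation * spr - n_pad
    z1 = rotation * spr + spr + n_pad
    nz = geom.voxel_grid[2]
    if z0 < 0 or z1 > nz:
        raise ValueError("padded stack exceeds the image grid; "
                         "use an interior rotation")
    nx, ny, _ = geom.voxel_grid
    zsel = np.arange(z0, z1)
    cols = ((np.arange(nx * ny)[:, None]) * nz + zsel[None, :]).ravel()
    H = op.H[rotation_rays(geom, rotation)][:, cols]
    sub = SystemOperator(H, (nx, ny, z1 - z0), geometry=None,
                         counters=op.counters)
    return sub


def interior_rotations(geom: ScanGeometry, n_pad: int) -> list[int]:
    """Rotations whose padded stack lies fully inside the image grid."""
    spr = geom.slices_per_rotation
    nz = geom.voxel_grid[2]
    return [r for r in range(geom.n_rotations)
            if r * spr - n_pad >= 0 and r * spr + spr + n_pad <= nz]


# -- helical view support (margin effect) -------------------------------------

@dataclass(frozen=True)
class SliceSupport:
    """Per-slice helical view support and the full-rotation slice window."""

    n_vps_per_slice: np.ndarray  # real-valued view counts, one per image slice
    full_range: tuple[float, float]  # slice-index bounds, rounded to 1 decimal
    geometry: ScanGeometry = field(repr=False, default=None)

    def n_vps(self, z_mm):
        g = self.geometry
        return n_views_supporting_slice(z_mm, g.n_vpr, g.z_feed, g.collimation_width)


def n_views_supporting_slice(z_mm, n_vpr: int, z_feed: float, z_d: float):
    """Real-valued number of gantry steps whose data involve a slice.

    ``z_mm`` is the distance between the centers of the first and the queried
    slice.  The formula is piecewise linear in z with a flat top equal to
    ``n_vpr``; it is evaluated in mm exactly as printed, including the unit
    offset of 1 mm in the descending branch.
    """
    z = np.asarray(z_mm, dtype=float)
    b1 = z_feed - z_d / 2.0
    b2 = z_d / 2.0 - 1.0
    rising = n_vpr * (z_d / (2.0 * z_feed) + z / z_feed)
    falling = n_vpr * (z_d / (2.0 * z_feed) + (z_feed - 1.0 - z) / z_feed)
    out = np.full_like(z, float(n_vpr))
    out = np.where(z < b1, rising, out)
    out = np.where(z > b2, falling, out)
    return np.clip(out, 0.0, float(n_vpr))[()]


def slice_view_support(geom: ScanGeometry) -> SliceSupport:
    """View support per slice and the full-rotation window in slice indices."""
    if geom.mode != "helical3d":
        raise ValueError("slice view support is defined for helical3d mode only")
    dz = geom.voxel_spacing[2]
    z = np.arange(geom.voxel_grid[2]) * dz
    counts = n_views_supporting_slice(z, geom.n_vpr, geom.z_feed,
                                      geom.collimation_width)
    lo_mm = geom.z_feed - geom.collimation_width / 2.0
    hi_mm = geom.collimation_width / 2.0 - 1.0
    full = (round(lo_mm / dz, 1), round(hi_mm / dz, 1))
    return SliceSupport(n_vps_per_slice=counts, full_range=full, geometry=geom)


# -- z padding for the margin effect ------------------------------------------

@dataclass(frozen=True)
class CropSpec:
    """Inverse of :func:`pad_stack` (number of padded slices per side)."""

    n_pad: int

    def apply(self, padded: np.ndarray) -> np.ndarray:
        if self.n_pad == 0:
            return padded
        return padded[..., self.n_pad:-self.n_pad]


def pad_stack(volume: np.ndarray, geom: ScanGeometry):
    """Pad a slice stack along z by ceil((Z_d/2)/dz) replicated edge slices.

    Rays of one rotation traverse half a collimation width beyond the stack on
    each side; padding with the nearest slice avoids artificial attenuation
    steps at the stack boundary.
    """
    if geom.mode != "helical3d":
        raise ValueError("pad_stack applies to helical3d mode only")
    dz = geom.voxel_spacing[2]
    n_pad = math.ceil((geom.collimation_width / 2.0) / dz - 1e-12)
    if geom.collimation_width <= dz:
        n_pad = 0
    if n_pad == 0:
        return volume, CropSpec(0)
    width = [(0, 0)] * (volume.ndim - 1) + [(n_pad, n_pad)]
    return np.pad(volume, width, mode="edge"), CropSpec(n_pad)
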