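"""Energy-resolved physics: basis decomposition, spectra, the polychromatic
forward model, and the q/p auxiliaries of the alternating-minimization update.

Units: energies keV, LAC mm^-1, lengths mm.  The LAC at voxel x and energy E
is modelled with the two-material basis vector model (BVM)

    mu(x, E) = mu_1(E) c_1(x) + mu_2(E) c_2(x),

where basis 1 is a 23% aqueous CaCl2 solution and basis 2 polystyrene, and
the dimensionless component weights c_i(x) are the reconstruction target.
The mean measured photon count along ray y for spectrum j in {L, H} is

    g_j(y) = sum_E I0_j(E) exp(-sum_i mu_i(E) [H c_i](y)) + xi_j(y),

with [H c](y) the line integral through the grid and xi an optional additive
scatter floor (zero by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import materials as mat

__all__ = [
    "EnergyGrid",
    "MaterialBasis",
    "SpectrumPair",
    "BasisImage",
    "ScatterTerm",
    "SinogramSet",
    "build_material_basis",
    "build_spectrum",
    "synthesize_vmi",
    "polychromatic_forward",
    "project_components",
    "compute_q",
    "compute_qp",
    "percent_error_map",
    "water_lac",
]

DEFAULT_ENERGY_RANGE = (20.0, 150.0)


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing photon energies in keV (default 20-150, 1 keV)."""

    energies: np.ndarray = field(
        default_factory=lambda: np.arange(DEFAULT_ENERGY_RANGE[0],
                                          DEFAULT_ENERGY_RANGE[1] + 0.5, 1.0))

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0) or e[0] <= 0:
            raise ValueError("energy grid must be >= 2 strictly increasing positive values")
        object.__setattr__(self, "energies", e)

    @property
    def n(self) -> int:
        return self.energies.size

    def index_of(self, e_kev: float) -> int:
        idx = np.searchsorted(self.energies, e_kev)
        if idx >= self.n or not np.isclose(self.energies[idx], e_kev):
            raise ValueError(f"{e_kev} keV is not on the energy grid")
        return int(idx)


@dataclass(frozen=True)
class MaterialBasis:
    """Basis-material LAC tables mu_i(E) (mm^-1) on a shared energy grid."""

    grid: EnergyGrid
    mu: np.ndarray  # (2, n_energies)
    names: tuple[str, str]

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (2, self.grid.n):
            raise ValueError("basis table shape must be (2, n_energies)")
        if np.any(mu <= 0):
            raise ValueError("basis LACs must be strictly positive")
        object.__setattr__(self, "mu", mu)

    def mu_at(self, e_kev: float) -> np.ndarray:
        return self.mu[:, self.grid.index_of(e_kev)]


@dataclass(frozen=True)
class SpectrumPair:
    """Mean fluence per energy bin for the low/high-kVp spectra."""

    grid: EnergyGrid
    I0: np.ndarray  # (2, n_energies); row 0 low kVp, row 1 high kVp

    def __post_init__(self):
        I0 = np.asarray(self.I0, dtype=float)
        if I0.shape != (2, self.grid.n):
            raise ValueError("spectrum shape must be (2, n_energies)")
        if np.any(I0 < 0) or np.any(I0.sum(axis=1) <= 0):
            raise ValueError("spectra must be non-negative with positive total flux")
        object.__setattr__(self, "I0", I0)

    @property
    def psi_L(self) -> np.ndarray:
        """Low-energy spectrum normalized to unit sum (loss weighting)."""
        return self.I0[0] / self.I0[0].sum()

    @property
    def flux(self) -> np.ndarray:
        return self.I0.sum(axis=1)

    @property
    def effective_energies(self) -> np.ndarray:
        w = self.I0 / self.I0.sum(axis=1, keepdims=True)
        return w @ self.grid.energies


@dataclass
class BasisImage:
    """Two component-weight fields on the voxel grid (the unknown image)."""

    c: np.ndarray  # (2, nx, ny, nz) or (2, nx, ny)

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim < 3 or self.c.shape[0] != 2:
            raise ValueError("BasisImage expects shape (2, *grid)")

    @property
    def c1(self) -> np.ndarray:
        return self.c[0]

    @property
    def c2(self) -> np.ndarray:
        return self.c[1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.c.shape[1:]

    def copy(self) -> "BasisImage":
        return BasisImage(self.c.copy())


@dataclass(frozen=True)
class ScatterTerm:
    """Additive mean scatter counts per sinogram bin (default zero)."""

    xi: np.ndarray | float = 0.0

    def __post_init__(self):
        if np.any(np.asarray(self.xi) < 0):
            raise ValueError("scatter must be non-negative")

    def per_ray(self, n_rays: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.xi, dtype=float),
                               (2, n_rays))


@dataclass
class SinogramSet:
    """Photon counts (measured or mean) for both spectra, flat ray layout."""

    d: np.ndarray  # (2, n_rays)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != 2:
            raise ValueError("SinogramSet expects shape (2, n_rays)")

    @property
    def n_rays(self) -> int:
        return self.d.shape[1]


# -- construction -------------------------------------------------------------

def build_material_basis(grid: EnergyGrid,
                         source: tuple | None = None) -> MaterialBasis:
    """Basis LAC tables, log-log interpolated onto the energy grid.

    ``source`` may name two materials (default: the CaCl2 solution and
    polystyrene) or provide two-column (keV, mm^-1) tables directly.
    """
    if source is None:
        source = ("cacl2_23pct", "polystyrene")
    mus, names = [], []
    for item in source:
        if isinstance(item, str):
            table = mat.tabulate_material(item)
            names.append(item)
        else:
            table = np.asarray(item, dtype=float)
            names.append("custom")
        mus.append(mat.interp_loglog(grid.energies, table[:, 0], table[:, 1]))
    return MaterialBasis(grid=grid, mu=np.stack(mus), names=tuple(names))


def build_spectrum(kvp_low: float, kvp_high: float, grid: EnergyGrid,
                   flux: float = 2e5,
                   filter_mm_al: tuple[float, float] = (2.0, 8.0)) -> SpectrumPair:
    """Synthetic filtered-bremsstrahlung spectrum pair.

    Kramers-rule photon counts ~ (kVp/E - 1) hardened by an aluminium filter,
    cut off above the tube voltage, and scaled to ``flux`` total counts per
    ray in the absence of the object.  The high-kVp beam carries heavier
    filtration by default, emulating the differential filtration of clinical
    dual-kVp protocols; this keeps the two effective energies well separated,
    which is what makes the two basis materials distinguishable.
    """
    if kvp_low >= kvp_high:
        raise ValueError("need kvp_low < kvp_high")
    if flux <= 0:
        raise ValueError("flux must be positive")
    e = grid.energies
    al = mat.interp_loglog(e, mat.ELEMENT_ENERGIES_KEV,
                           np.asarray(mat.MASS_ATTENUATION["Al"]))
    rows = []
    for kvp, filt in zip((kvp_low, kvp_high), filter_mm_al):
        shape = np.clip(kvp / e - 1.0, 0.0, None) \
            * np.exp(-2.699 * al * filt / 10.0)
        shape[e > kvp] = 0.0
        total = shape.sum()
        if total <= 0:
            raise ValueError("spectrum is empty on this energy grid")
        rows.append(shape * (flux / total))
    return SpectrumPair(grid=grid, I0=np.stack(rows))


def water_lac(e_kev, grid: EnergyGrid | None = None) -> np.ndarray:
    """Water LAC (mm^-1) used for HU conversion."""
    return mat.material_mu("water", np.asarray(e_kev, dtype=float))


# -- virtual monoenergetic synthesis ------------------------------------------

def synthesize_vmi(c: BasisImage, basis: MaterialBasis, e_kev: float,
                   unit: str = "lac") -> np.ndarray:
    """Virtual monoenergetic image mu(x, E) = sum_i mu_i(E) c_i(x).

    ``unit='hu'`` converts to Hounsfield units with the water LAC at E.
    """
    mu = basis.mu_at(e_kev)
    vmi = mu[0] * c.c1 + mu[1] * c.c2
    if unit == "lac":
        return vmi
    if unit == "hu":
        mu_w = float(water_lac(e_kev))
        return 1000.0 * (vmi - mu_w) / mu_w
    raise ValueError("unit must be 'lac' or 'hu'")


# -- polychromatic model ------------------------------------------------------

def project_components(op, c: BasisImage) -> np.ndarray:
    """Line integrals of both component fields: exactly 2 forward projections."""
    if np.any(~np.isfinite(c.c)):
        raise ValueError("component image contains non-finite values")
    return op.forward(c.c)  # (2, n_rays)


def _attenuation(lines: np.ndarray, basis: MaterialBasis) -> np.ndarray:
    """exp(-sum_i mu_i(E) l_i(y)) with shape (n_rays, n_E); shared by spectra."""
    expo = lines.T @ basis.mu  # (n_rays, n_E)
    # negative iterates can drive the exponent past the float range; the
    # clamp keeps transients finite (divergence is caught at the objective)
    return np.exp(-np.clip(expo, -700.0, 700.0))


def polychromatic_forward(op, spec: SpectrumPair, basis: MaterialBasis,
                          c: BasisImage, scatter: ScatterTerm | None = None,
                          lines: np.ndarray | None = None) -> SinogramSet:
    """Mean counts g_j(y) of the polychromatic forward model."""
    if lines is None:
        lines = project_components(op, c)
    atten = _attenuation(lines, basis)
    g = atten @ spec.I0.T  # (n_rays, 2)
    g = g.T
    if scatter is not None:
        g = g + scatter.per_ray(lines.shape[1])
    return SinogramSet(d=g)


def compute_q(op, spec: SpectrumPair, basis: MaterialBasis, c: BasisImage,
              lines: np.ndarray | None = None) -> np.ndarray:
    """q_j(y, E): modeled mean counts per spectrum, ray and energy bin."""
    if lines is None:
        lines = project_components(op, c)
    atten = _attenuation(lines, basis)
    return spec.I0[:, None, :] * atten[None, :, :]  # (2, n_rays, n_E)


def compute_qp(op, spec: SpectrumPair, basis: MaterialBasis, c: BasisImage,
               d: SinogramSet, lines: np.ndarray | None = None):
    """The q/p auxiliaries of the I-divergence surrogate.

    p redistributes the measured counts d_j(y) over energy proportionally to
    q, so that sum_E p_j(y, E) = d_j(y) holds exactly by construction.
    """
    if np.any(d.d < 0):
        raise ValueError("measured counts must be non-negative")
    q = compute_q(op, spec, basis, c, lines=lines)
    S = q.sum(axis=2)  # (2, n_rays)
    if np.any(S <= 0):
        raise FloatingPointError(
            "fully attenuated ray: sum_E q underflowed to zero")
    p = q * (d.d / S)[:, :, None]
    return q, p


# -- error metric -------------------------------------------------------------

def percent_error_map(est: BasisImage, gt: BasisImage, basis: MaterialBasis,
                      e_kev: float,
                      mask_range: tuple[float, float] = (0.01, 0.05),
                      mask_energy: float = 60.0):
    """Percentage VMI error on voxels inside the ground-truth LAC mask.

    The default mask keeps voxels with mu_GT(60 keV) in [0.01, 0.05] mm^-1
    (soft and bony tissue), excluding near-air voxels whose tiny denominators
    would dominate the statistic.  Returns (errors on masked voxels, mask).
    """
    if est.grid_shape != gt.grid_shape:
        raise ValueError("estimate and ground truth grids differ")
    mu_gt_mask = synthesize_vmi(gt, basis, mask_energy)
    mask = (mu_gt_mask >= mask_range[0]) & (mu_gt_mask <= mask_range[1])
    if not mask.any():
        warnings.warn("empty evaluation mask", RuntimeWarning)
        return np.empty(0), mask
    mu_est = synthesize_vmi(est, basis, e_kev)
    mu_gt = synthesize_vmi(gt, basis, e_kev)
    err = 100.0 * (mu_est[mask] - mu_gt[mask]) / mu_gt[mask]
    return err, mask
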