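"""Photon attenuation data for the materials used in dual-energy CT simulation.

Linear attenuation coefficients (LAC) are computed from an element-wise mass
attenuation compilation by the standard mixture rule

    mu(E) = rho * sum_el  w_el * (mu/rho)_el(E),

with mass fractions ``w_el`` and bulk density ``rho``.  All LACs produced by
this module are in mm^-1 and energies in keV; interpolation between tabulated
energies is linear in log-log space, which is accurate at the few-percent
level in the diagnostic range for these low-Z materials.

The two reconstruction basis materials are a 23% (by weight) aqueous CaCl2
solution and polystyrene; phantom inserts additionally use water, acrylic
(PMMA), three alcohols and K2HPO4 solutions at several concentrations.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

__all__ = [
    "ELEMENT_ENERGIES_KEV",
    "MASS_ATTENUATION",
    "MATERIALS",
    "material_mu",
    "tabulate_material",
    "load_table_csv",
    "save_table_csv",
    "bundled_table",
    "interp_loglog",
]

# Tabulated photon energies (keV) for the element compilation.
ELEMENT_ENERGIES_KEV = np.array(
    [15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0]
)

# Element mass attenuation coefficients (cm^2/g) at ELEMENT_ENERGIES_KEV.
# Approximate compilation of standard photon cross-section tables; adequate
# for polychromatic simulation in the 20-150 keV range.
MASS_ATTENUATION = {
    "H": [0.3764, 0.3695, 0.3570, 0.3458, 0.3355, 0.3260, 0.3091, 0.2944, 0.2651, 0.2429],
    "C": [0.8071, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610, 0.1514, 0.1347, 0.1229],
    "N": [1.1980, 0.5980, 0.2924, 0.2203, 0.1913, 0.1757, 0.1578, 0.1466, 0.1287, 0.1172],
    "O": [1.5450, 0.8651, 0.3779, 0.2585, 0.2132, 0.1907, 0.1678, 0.1551, 0.1361, 0.1237],
    "Al": [7.9550, 3.4410, 1.1280, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378, 0.1223],
    "P": [7.3000, 3.1400, 1.0200, 0.4920, 0.3100, 0.2290, 0.1683, 0.1432, 0.1223, 0.1150],
    "Cl": [10.500, 4.5200, 1.4500, 0.6770, 0.4030, 0.2810, 0.1920, 0.1564, 0.1261, 0.1170],
    "K": [15.700, 6.8000, 2.1600, 0.9900, 0.5650, 0.3780, 0.2350, 0.1824, 0.1415, 0.1270],
    "Ca": [19.300, 8.0000, 2.5100, 1.1300, 0.6370, 0.4160, 0.2570, 0.1940, 0.1441, 0.1282],
}

# Mass fractions within pure compounds.
_CACL2 = {"Ca": 0.3612, "Cl": 0.6388}
_K2HPO4 = {"K": 0.4490, "H": 0.0058, "P": 0.1778, "O": 0.3674}
_WATER = {"H": 0.1119, "O": 0.8881}


def _aqueous(solute: dict[str, float], frac: float) -> dict[str, float]:
    """Mass fractions of an aqueous solution with solute weight fraction frac."""
    out = {el: (1.0 - frac) * w for el, w in _WATER.items()}
    for el, w in solute.items():
        out[el] = out.get(el, 0.0) + frac * w
    return out


def _k2hpo4_solution(conc_mg_ml: float) -> tuple[dict[str, float], float]:
    """Composition and density of aqueous K2HPO4 at a given concentration."""
    rho = 1.0 + 7.7e-4 * conc_mg_ml  # g/cm^3, linear fit to solution densities
    frac = conc_mg_ml / (1000.0 * rho)
    return _aqueous(_K2HPO4, frac), rho


# name -> (mass fractions, density g/cm^3)
MATERIALS: dict[str, tuple[dict[str, float], float]] = {
    "water": (_WATER, 1.000),
    "cacl2_23pct": (_aqueous(_CACL2, 0.23), 1.210),
    "polystyrene": ({"C": 0.9226, "H": 0.0774}, 1.050),
    "acrylic": ({"C": 0.5998, "H": 0.0805, "O": 0.3196}, 1.190),
    "ethanol": ({"C": 0.5214, "H": 0.1313, "O": 0.3473}, 0.789),
    "propanol": ({"C": 0.5996, "H": 0.1341, "O": 0.2663}, 0.803),
    "butanol": ({"C": 0.6482, "H": 0.1360, "O": 0.2158}, 0.810),
}
for _c in (50, 100, 150, 200, 250):
    MATERIALS[f"k2hpo4_{_c:03d}"] = _k2hpo4_solution(float(_c))


def interp_loglog(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Log-log linear interpolation (positive data only)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < xp[0]) or np.any(x > xp[-1]):
        raise ValueError(
            f"energy outside tabulated range [{xp[0]}, {xp[-1]}] keV"
        )
    return np.exp(np.interp(np.log(x), np.log(xp), np.log(fp)))


def material_mu(name: str, energies_kev: np.ndarray) -> np.ndarray:
    """LAC of a named material (mm^-1) at the requested energies."""
    if name not in MATERIALS:
        raise KeyError(f"unknown material {name!r}; known: {sorted(MATERIALS)}")
    fractions, rho = MATERIALS[name]
    mu_rho = np.zeros_like(ELEMENT_ENERGIES_KEV)
    for el, w in fractions.items():
        mu_rho = mu_rho + w * np.asarray(MASS_ATTENUATION[el])
    mu_cm = rho * interp_loglog(energies_kev, ELEMENT_ENERGIES_KEV, mu_rho)
    return mu_cm / 10.0  # per-cm -> per-mm


def tabulate_material(name: str, energies_kev: np.ndarray | None = None):
    """Two-column (keV, mm^-1) table for a named material."""
    if energies_kev is None:
        energies_kev = ELEMENT_ENERGIES_KEV
    energies_kev = np.asarray(energies_kev, dtype=float)
    return np.column_stack([energies_kev, material_mu(name, energies_kev)])


def save_table_csv(path, table: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["energy_kev", "mu_per_mm"])
        for e, m in table:
            w.writerow([f"{e:g}", f"{m:.8g}"])


def load_table_csv(path) -> np.ndarray:
    """Read a two-column (keV, mu) attenuation CSV with a header row."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    data = [(float(r[0]), float(r[1])) for r in rows[1:]]
    table = np.asarray(data, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError(f"malformed attenuation table {path}")
    return table


def bundled_table(name: str) -> np.ndarray:
    """Load one of the attenuation tables shipped with the package."""
    ref = resources.files("dectunroll").joinpath(f"data/{name}.csv")
    with resources.as_file(ref) as path:
        return load_table_csv(path)
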