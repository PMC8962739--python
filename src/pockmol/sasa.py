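"""Solvent-accessible surface area by Shrake–Rupley sphere sampling.

Each atom is surrounded by a quasi-uniform shell of test points at
radius ``r_vdw + probe``; the accessible area is the fraction of points
not buried inside any neighbouring atom's probe-expanded sphere, times
the full sphere area 4π(r+p)². Defaults: 960 points per atom, 1.4 Å
water probe, Bondi van der Waals radii.
"""

from __future__ import annotations

import numpy as np

#: Bondi van der Waals radii (Å) for elements common in protein pockets.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.31,
    "MN": 2.00, "NA": 2.27, "K": 2.75,
}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4
N_POINTS = 960


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(coords: np.ndarray, elements: list[str],
                  probe: float = PROBE_RADIUS, n_points: int = N_POINTS,
                  radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom SASA in Å². Fully buried atoms score exactly 0."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a nonempty N×3 array")
    lookup = radii if radii is not None else VDW_RADII
    r = np.array([lookup.get(e.upper(), DEFAULT_RADIUS) for e in elements])
    unit = sphere_points(n_points)
    out = np.zeros(len(coords))
    expanded = r + probe
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        # neighbours whose probe-expanded sphere can reach the shell
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.where((d < expanded + expanded[i]) & (np.arange(len(coords)) != i))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in nb:
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
            if not accessible.any():
                break
        out[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out
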