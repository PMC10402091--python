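"""Solvent-accessible surface area and surface-atom classification.

Shrake–Rupley sphere sampling: each atom's van der Waals sphere is inflated
by the solvent probe radius and covered with a quasi-uniform (golden spiral)
point set; the accessible fraction is the fraction of points not inside any
neighbouring atom's inflated sphere. An atom is a surface atom when its SASA
exceeds a small area cutoff.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .types import StructureModel

__all__ = [
    "VDW_RADII",
    "sphere_points",
    "shrake_rupley_sasa",
    "detect_surface_atoms",
]

# Bondi-style van der Waals radii in Å
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92, "SE": 1.90,
}
DEFAULT_VDW = 1.70

PROBE_RADIUS = 1.4      # water probe, Å
N_SPHERE_POINTS = 960
SASA_CUTOFF = 0.1       # Å²; above this an atom counts as surface


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into a deterministic principal-axes frame.

    The sampled SASA estimate depends (weakly) on the orientation of the
    fixed sphere-point lattice relative to the structure; evaluating it in
    a canonical frame makes the estimate, and hence the surface
    classification, exactly invariant under rigid motion. Axes are sorted
    by decreasing variance with signs fixed by the third moment; the frame
    is then made right-handed.
    """
    centered = coords - coords.mean(axis=0)
    if len(centered) < 3:
        return centered
    _, v = np.linalg.eigh(centered.T @ centered)
    v = v[:, ::-1]
    for k in range(2):
        if np.sum((centered @ v[:, k]) ** 3) < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return centered @ v


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(elements, probe_radius: float = PROBE_RADIUS) -> np.ndarray:
    return np.array(
        [VDW_RADII.get(e.upper(), DEFAULT_VDW) + probe_radius for e in elements]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å²."""
    coords = _canonical_frame(np.asarray(coords, dtype=float))
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    radii = atom_radii(elements, probe_radius)
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    sasa = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        if neigh:
            nb = np.asarray(neigh)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            accessible = ~np.any(d2 < (radii[nb] ** 2)[None, :], axis=1)
        sasa[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return sasa


def detect_surface_atoms(
    s: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    sasa_cutoff: float = SASA_CUTOFF,
    n_points: int = N_SPHERE_POINTS,
) -> StructureModel:
    """Fill ``sasa`` and ``is_surface`` on the protein atoms, in place.

    Returns the same model for chaining. Ligand atoms do not occlude the
    protein surface (the apo surface is what the model scores).
    """
    coords = s.coords()
    elements = [a.element for a in s.protein_atoms]
    sasa = shrake_rupley_sasa(coords, elements, probe_radius, n_points)
    for a, area in zip(s.protein_atoms, sasa):
        a.sasa = float(area)
        a.is_surface = bool(area > sasa_cutoff)
    return s
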