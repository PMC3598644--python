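"""Center-of-mass geometry and solvent accessibility.

The general center of mass (GCM) is the mass-weighted mean position of all
heavy atoms of the chain, R = Σ_i M_i·R_i / Σ_i M_i; the per-residue
geometric feature is the Euclidean distance from each Cα to the GCM.

Solvent-accessible surface area is computed with a deterministic
Shrake–Rupley quadrature (golden-spiral sphere points) and converted to
relative accessibility (RSA, %) against an extended Gly-X-Gly reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import ProteinChain

#: Van der Waals radii (Å) by element; fallback used for rare elements.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
_DEFAULT_VDW = 1.70

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_SPHERE_POINTS = 960

#: Maximum accessible surface area (Å²) of residue X in an extended
#: Gly-X-Gly tripeptide (theoretical values of Tien et al. 2013).
MAX_ASA_GXG: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

RSA_REFERENCE_NAME = "tien2013-theoretical-gly-x-gly"


@dataclass
class AccessibilityRecord:
    """Absolute SASA (Å²) and relative accessibility (% of extended reference)."""

    area: float
    relative: float


def general_center_of_mass(chain: ProteinChain) -> np.ndarray:
    """Mass-weighted mean position of all heavy atoms of the chain (Å)."""
    atoms = chain.atoms()
    if not atoms:
        raise ValueError("chain has no heavy atoms")
    masses = np.array([a.mass for a in atoms])
    coords = np.array([a.coord for a in atoms])
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def distance_to_gcm(chain: ProteinChain, gcm: np.ndarray) -> np.ndarray:
    """Per-residue Euclidean Cα-to-GCM distance; NaN where the Cα is absent."""
    gcm = np.asarray(gcm, dtype=float)
    out = np.full(len(chain), np.nan)
    for i, res in enumerate(chain.residues):
        if res.has_ca:
            out[i] = float(np.linalg.norm(res.ca - gcm))
    return out


def sphere_points(n: int) -> np.ndarray:
    """*n* quasi-uniform unit-sphere points on a golden-spiral lattice."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def solvent_accessible_area(
    chain: ProteinChain,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Per-residue solvent-accessible surface area (Å²), Shrake–Rupley style.

    Each atom is expanded by the probe radius; the accessible fraction of
    its surface is the fraction of quadrature points not inside any
    neighboring atom's expanded sphere.  Deterministic for a fixed number
    of sphere points.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 100:
        raise ValueError("need at least 100 sphere points")
    atoms = chain.atoms()
    coords = np.array([a.coord for a in atoms])
    radii = np.array([VDW_RADII.get(a.element, _DEFAULT_VDW) for a in atoms]) + probe_radius
    owner = np.array([a.residue_index for a in atoms])
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(chain))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + max_r):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        frac = accessible.sum() / n_sphere_points
        areas[owner[i]] += frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def relative_accessibility(areas, types) -> list[AccessibilityRecord]:
    """RSA% = 100 · area / reference(type); may exceed 100 for termini."""
    if len(areas) != len(types):
        raise ValueError("areas and types must have equal length")
    out = []
    for area, aa in zip(areas, types):
        if aa not in MAX_ASA_GXG:
            raise ValueError(f"unknown residue type: {aa!r}")
        out.append(AccessibilityRecord(float(area), 100.0 * float(area) / MAX_ASA_GXG[aa]))
    return out


def read_naccess_rsa(text: str) -> list[AccessibilityRecord]:
    """Adapter for naccess ``.rsa`` output: all-atoms absolute and relative columns."""
    out = []
    for line in text.splitlines():
        if not line.startswith("RES"):
            continue
        parts = line.split()
        # RES <type> <chain> <num> <abs-all> <rel-all> ...
        out.append(AccessibilityRecord(float(parts[4]), float(parts[5])))
    return out
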