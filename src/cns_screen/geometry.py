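"""Conformer geometry: minimal projection area (MPA) and polarizability.

MPA is the smallest area of the molecule's van-der-Waals silhouette over
all projection directions, in A^2.  Compounds with MPA below about 60 A^2
are taken as small enough in cross-section for passive CNS entry.  The
silhouette area for a direction is the area of the union of disks obtained
by projecting every atomic sphere onto the plane normal to that direction;
it is computed by fixed-pitch rasterization (deterministic — Monte Carlo
is reserved for test oracles).  The direction search is a coarse Fibonacci
sphere followed by Nelder-Mead refinement in spherical coordinates.

Molecular polarizability (PL, A^3) uses Miller's additive atomic hybrid
polarizabilities (Miller, J. Am. Chem. Soc. 1990, 112, 8533-8542): the
molecular value is the sum of hybridization-dependent atomic terms, which
makes it exactly additive over disconnected fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize

from .registry import Compound

__all__ = [
    "VDW_RADII",
    "ConformerSet",
    "GeometryResult",
    "embed_conformers",
    "projection_area",
    "minimal_projection_area",
    "polarizability",
]

# Bondi-type van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

# Miller atomic hybrid polarizabilities tau(ahp), A^3, keyed by
# (element, hybridization class).
_MILLER_AHP: dict[tuple[str, str], float] = {
    ("H", "any"): 0.387,
    ("C", "sp3"): 1.061,
    ("C", "sp2"): 1.352,
    ("C", "aromatic_bridge"): 1.896,
    ("C", "sp"): 1.283,
    ("N", "sp3"): 0.964,
    ("N", "sp2"): 1.030,
    ("N", "aromatic"): 1.090,
    ("O", "sp3"): 0.637,
    ("O", "sp2"): 0.569,
    ("F", "any"): 0.296,
    ("Cl", "any"): 2.315,
    ("Br", "any"): 3.013,
    ("I", "any"): 5.415,
    ("S", "sp3"): 3.000,
    ("S", "sp2"): 3.729,
    ("P", "sp3"): 1.538,
}

DEFAULT_SEED = 17
DEFAULT_PITCH = 0.05  # rasterization pitch, Angstrom
DEFAULT_DIRECTIONS = 1536


@dataclass(frozen=True)
class ConformerSet:
    """Energy-sorted 3D conformers (coordinates in Angstrom, with H)."""

    compound_id: str
    coordinates: np.ndarray  # (n_conf, n_atoms, 3)
    energies: np.ndarray  # kcal/mol, non-decreasing
    elements: tuple[str, ...]
    seed: int


@dataclass(frozen=True)
class GeometryResult:
    mpa: float  # A^2
    mpa_direction: np.ndarray  # unit 3-vector
    polarizability: float | None  # A^3
    conformer_index: int


def embed_conformers(c: Compound, n: int = 50, seed: int = DEFAULT_SEED) -> ConformerSet:
    """Distance-geometry conformers, force-field minimized, energy-sorted.

    MMFF94 is used when parameterized for the molecule, UFF otherwise.
    Deterministic for a fixed seed.
    """
    mol = Chem.AddHs(c.mol())
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params))
    if not ids:
        # fall back to random coordinates before giving up
        params.useRandomCoords = True
        ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params))
    if not ids:
        raise RuntimeError(f"conformer embedding failed for {c.id}")
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = np.array([e for _, e in results], dtype=float)
    coords = np.stack([mol.GetConformer(i).GetPositions() for i in ids])
    order = np.argsort(energies, kind="stable")
    return ConformerSet(
        compound_id=c.id,
        coordinates=coords[order],
        energies=energies[order],
        elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
        seed=int(seed),
    )


def _orthonormal_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def projection_area(
    coords: np.ndarray,
    radii: np.ndarray,
    direction: np.ndarray,
    pitch: float = DEFAULT_PITCH,
) -> float:
    """Area (A^2) of the union of atom-sphere shadows along ``direction``.

    Each atom sphere projects to a disk of its vdW radius on the plane
    normal to ``direction``; the union area is counted on a square grid of
    the given pitch (bounding box padded by the largest radius).  Invariant
    to rigid rotation of coordinates and direction together, up to the
    grid discretization error which shrinks with the pitch.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / norm
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)

    u, v = _orthonormal_basis(direction)
    xy = np.column_stack([coords @ u, coords @ v])
    rmax = float(radii.max())
    lo = xy.min(axis=0) - rmax - pitch
    hi = xy.max(axis=0) + rmax + pitch
    nx = int(math.ceil((hi[0] - lo[0]) / pitch))
    ny = int(math.ceil((hi[1] - lo[1]) / pitch))
    grid = np.zeros((nx, ny), dtype=bool)
    # pixel centers
    for (cx, cy), r in zip(xy, radii):
        ix0 = max(int((cx - r - lo[0]) / pitch) - 1, 0)
        ix1 = min(int((cx + r - lo[0]) / pitch) + 2, nx)
        iy0 = max(int((cy - r - lo[1]) / pitch) - 1, 0)
        iy1 = min(int((cy + r - lo[1]) / pitch) + 2, ny)
        gx = lo[0] + (np.arange(ix0, ix1) + 0.5) * pitch
        gy = lo[1] + (np.arange(iy0, iy1) + 0.5) * pitch
        mask = ((gx[:, None] - cx) ** 2 + (gy[None, :] - cy) ** 2) <= r * r
        grid[ix0:ix1, iy0:iy1] |= mask
    return float(grid.sum()) * pitch * pitch


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper hemisphere (area is
    symmetric under direction negation)."""
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = (i + 0.5) / n  # hemisphere: z in (0, 1)
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z * z)
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _dir_from_angles(angles: np.ndarray) -> np.ndarray:
    th, ph = angles
    return np.array([
        math.sin(th) * math.cos(ph),
        math.sin(th) * math.sin(ph),
        math.cos(th),
    ])


def minimal_projection_area(
    cs: ConformerSet,
    n_directions: int = DEFAULT_DIRECTIONS,
    pitch: float = DEFAULT_PITCH,
    polarizability_value: float | None = None,
) -> GeometryResult:
    """Minimal projection area of the lowest-energy conformer.

    Minimizes :func:`projection_area` over a Fibonacci hemisphere grid of
    ``n_directions`` directions, then refines the best direction with
    Nelder-Mead on (theta, phi).  Ties on the grid break by first index.
    """
    coords = cs.coordinates[0]
    radii = np.array([VDW_RADII[el] for el in cs.elements])
    if len(radii) == 1:
        # one sphere: the silhouette is a disk from every direction
        return GeometryResult(
            mpa=float(math.pi * radii[0] ** 2),
            mpa_direction=np.array([0.0, 0.0, 1.0]),
            polarizability=polarizability_value,
            conformer_index=0,
        )
    dirs = _fibonacci_sphere(n_directions)
    areas = np.array([projection_area(coords, radii, d, pitch) for d in dirs])
    best = int(np.argmin(areas))
    d0 = dirs[best]
    theta0 = math.acos(np.clip(d0[2], -1, 1))
    phi0 = math.atan2(d0[1], d0[0])

    def objective(angles: np.ndarray) -> float:
        return projection_area(coords, radii, _dir_from_angles(angles), pitch)

    res = minimize(objective, x0=np.array([theta0, phi0]), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 200})
    if res.fun <= areas[best]:
        mpa = float(res.fun)
        direction = _dir_from_angles(res.x)
    else:
        mpa = float(areas[best])
        direction = d0
    return GeometryResult(
        mpa=mpa,
        mpa_direction=direction / np.linalg.norm(direction),
        polarizability=polarizability_value,
        conformer_index=0,
    )


def _miller_class(atom: Chem.Atom) -> tuple[str, str]:
    el = atom.GetSymbol()
    if el in ("H", "F", "Cl", "Br", "I"):
        return el, "any"
    hyb = atom.GetHybridization()
    if el == "C":
        if atom.GetIsAromatic():
            rings = atom.GetOwningMol().GetRingInfo().NumAtomRings(atom.GetIdx())
            return ("C", "aromatic_bridge") if rings > 1 else ("C", "sp2")
        if hyb == Chem.HybridizationType.SP3:
            return "C", "sp3"
        if hyb == Chem.HybridizationType.SP:
            return "C", "sp"
        return "C", "sp2"
    if el == "N":
        if atom.GetIsAromatic():
            return "N", "aromatic"
        return ("N", "sp3") if hyb == Chem.HybridizationType.SP3 else ("N", "sp2")
    if el == "O":
        return ("O", "sp2") if any(
            b.GetBondTypeAsDouble() == 2.0 for b in atom.GetBonds()
        ) else ("O", "sp3")
    if el == "S":
        return ("S", "sp2") if atom.GetIsAromatic() or any(
            b.GetBondTypeAsDouble() == 2.0 for b in atom.GetBonds()
        ) else ("S", "sp3")
    if el == "P":
        return "P", "sp3"
    return el, "any"


def polarizability(c: Compound) -> float:
    """Additive molecular polarizability (A^3) from Miller's hybrid table."""
    mol = Chem.AddHs(c.mol())
    total = 0.0
    for atom in mol.GetAtoms():
        key = _miller_class(atom)
        try:
            total += _MILLER_AHP[key]
        except KeyError:
            raise KeyError(
                f"no polarizability parameter for element/hybridization {key}"
            ) from None
    return total
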