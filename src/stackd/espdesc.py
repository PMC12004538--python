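"""Electrostatic-potential plane descriptors.

The descriptors characterise the ESP evaluated on a plane offset 3.25 Å
from a planar molecule, restricted to the projection of its van der Waals
volume onto that plane (the union of per-atom circles of vdW radius).
Simple statistics over the masked nodes — ESP_max, ESP_min, ESP_mean and
ESP_range = ESP_max − ESP_min — are the inputs to the maximum-stacking
model.  Two backends produce the planar field: a native point-charge
Coulomb sum, and trilinear sampling of an externally computed QM ESP grid
in Gaussian-cube format.  ESP values are stored in kcal/mol throughout;
cube files in atomic units are converted once at ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chemstruct import Molecule, heavy_atom_count
from .stackgeom import fit_plane

__all__ = [
    "PlanarField",
    "DescriptorSet",
    "MaskError",
    "CubeGrid",
    "COULOMB_KCAL",
    "HARTREE_KCAL",
    "BOHR_ANGSTROM",
    "DEFAULT_HEIGHT",
    "DEFAULT_SPACING",
    "NUCLEOBASE_DESCRIPTORS",
    "grid_for_molecule",
    "vdw_projection_mask",
    "esp_plane_point_charges",
    "read_cube",
    "esp_plane_from_cube",
    "descriptors",
]

COULOMB_KCAL = 332.0637     # kcal·Å/(mol·e²)
HARTREE_KCAL = 627.509
BOHR_ANGSTROM = 0.52917721067

DEFAULT_HEIGHT = 3.25       # Å above the molecular plane
DEFAULT_SPACING = 0.1       # Å grid spacing
GRID_PAD = 2.0              # Å padding of the mask bounding box

# Reference descriptor constants for the five natural nucleobases
# (ESP_range in kcal/mol from DFT-level ESPs; N_HA heavy-atom counts).
# Bundled so the predictive model never needs a QM engine.
NUCLEOBASE_DESCRIPTORS: dict[str, dict[str, float]] = {
    "A": {"esp_range": 13.1, "n_ha": 10},
    "G": {"esp_range": 24.3, "n_ha": 11},
    "C": {"esp_range": 22.8, "n_ha": 8},
    "T": {"esp_range": 16.1, "n_ha": 9},
    "U": {"esp_range": 17.7, "n_ha": 8},
}


class MaskError(ValueError):
    """The vdW projection mask selects no grid nodes."""


@dataclass
class PlanarField:
    """ESP sampled on a rectangular grid in a plane parallel to the molecule.

    ``origin`` is the (x, y) of node [0, 0] and ``height`` the signed plane
    offset along the molecular normal; ``values`` (kcal/mol) and ``mask``
    share shape (nx, ny).
    """

    origin: tuple[float, float]
    spacing: float
    height: float
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")

    def node_xy(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        xs = self.origin[0] + self.spacing * np.arange(nx)
        ys = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(xs, ys, indexing="ij")


@dataclass(frozen=True)
class DescriptorSet:
    """ESP plane statistics plus the heavy-atom count for one molecule face."""

    n_ha: int
    esp_max: float
    esp_min: float
    esp_mean: float
    esp_range: float
    face: int = 1
    backend: str = "point-charge"

    def __post_init__(self) -> None:
        if abs(self.esp_range - (self.esp_max - self.esp_min)) > 1e-9:
            raise ValueError("esp_range must equal esp_max - esp_min")
        if not (self.esp_min - 1e-9 <= self.esp_mean <= self.esp_max + 1e-9):
            raise ValueError("esp_mean outside [esp_min, esp_max]")


# ---------------------------------------------------------------------------
# grid + mask


def grid_for_molecule(mol: Molecule, spacing: float = DEFAULT_SPACING,
                      pad: float = GRID_PAD) -> tuple[tuple[float, float], int, int]:
    """Rectangular in-plane grid covering the vdW projection, padded.

    Assumes the molecule is in (or near) its canonical frame so the plane
    projection is simply (x, y).
    """
    if len(mol) == 0:
        raise ValueError("empty molecule")
    lo = (mol.coords[:, :2] - mol.vdw_radii[:, None]).min(axis=0) - pad
    hi = (mol.coords[:, :2] + mol.vdw_radii[:, None]).max(axis=0) + pad
    nx = int(np.ceil((hi[0] - lo[0]) / spacing)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / spacing)) + 1
    return (float(lo[0]), float(lo[1])), nx, ny


def vdw_projection_mask(mol: Molecule, origin: tuple[float, float],
                        spacing: float, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of grid nodes inside the projected vdW volume.

    A node is in iff its in-plane point lies within distance r_vdW(i) of the
    projected position of at least one atom — the union of circles.
    """
    if len(mol) == 0:
        raise ValueError("empty molecule")
    nx, ny = shape
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    mask = np.zeros(shape, bool)
    for (ax, ay, _z), r in zip(mol.coords, mol.vdw_radii):
        mask |= (gx - ax) ** 2 + (gy - ay) ** 2 <= r * r
    return mask


# ---------------------------------------------------------------------------
# point-charge backend


def esp_plane_point_charges(mol: Molecule, height: float = DEFAULT_HEIGHT,
                            spacing: float = DEFAULT_SPACING) -> PlanarField:
    """Coulomb ESP of the molecule's point charges on an offset plane.

    ESP(r) = 332.0637 · Σ_i q_i / |r − r_i| with q in e and r in Å, giving
    kcal/mol.  The molecule is expected in its canonical frame (plane ≈ z=0);
    the evaluation plane is z = height.
    """
    if height == 0:
        raise ValueError("height must be nonzero")
    origin, nx, ny = grid_for_molecule(mol, spacing)
    mask = vdw_projection_mask(mol, origin, spacing, (nx, ny))
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx, gy, np.full_like(gx, height)], axis=-1)  # (nx, ny, 3)
    diff = pts[:, :, None, :] - mol.coords[None, None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    if (dist < 1e-6).any():
        raise ZeroDivisionError("grid node coincident with an atom")
    values = COULOMB_KCAL * (mol.charges[None, None, :] / dist).sum(-1)
    return PlanarField(origin=origin, spacing=spacing, height=height,
                       values=values, mask=mask)


# ---------------------------------------------------------------------------
# Gaussian cube backend


@dataclass
class CubeGrid:
    """A volumetric scalar field from a Gaussian cube file (values in kcal/mol)."""

    origin: np.ndarray          # Å
    axes: np.ndarray            # (3, 3) voxel step vectors, Å (rows)
    shape: tuple[int, int, int]
    values: np.ndarray          # (n1, n2, n3), kcal/mol


def read_cube(path: str | Path, assume_atomic_units: bool = True) -> CubeGrid:
    """Parse a Gaussian cube file.

    Cube convention: two comment lines; a line with the atom count and grid
    origin; three lines of (npoints, step vector); atom lines; then values in
    z-fastest order.  Negative atom counts (Gaussian's marker for a trailing
    orbital-id line) are handled.  Lengths are Bohr when the axis point count
    is positive (the usual case) and Å when negative, per the format's sign
    convention; values are converted Hartree → kcal/mol when
    ``assume_atomic_units``.
    """
    tokens_lines = Path(path).read_text().splitlines()
    if len(tokens_lines) < 7:
        raise ValueError(f"{path}: malformed cube (too short)")
    try:
        hdr = tokens_lines[2].split()
        natoms = int(hdr[0])
        origin = np.array([float(x) for x in hdr[1:4]])
        counts, axes, unit_scale = [], [], []
        for k in range(3):
            parts = tokens_lines[3 + k].split()
            n = int(parts[0])
            counts.append(abs(n))
            scale = BOHR_ANGSTROM if n > 0 else 1.0
            unit_scale.append(scale)
            axes.append([float(x) * scale for x in parts[1:4]])
        origin = origin * (BOHR_ANGSTROM if counts and int(tokens_lines[3].split()[0]) > 0 else 1.0)
        nskip = 6 + abs(natoms) + (1 if natoms < 0 else 0)
        data = np.array(" ".join(tokens_lines[nskip:]).split(), dtype=float)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed cube header") from exc
    n1, n2, n3 = counts
    if data.size != n1 * n2 * n3:
        raise ValueError(
            f"{path}: expected {n1 * n2 * n3} values, found {data.size}"
        )
    values = data.reshape(n1, n2, n3)
    if assume_atomic_units:
        values = values * HARTREE_KCAL
    return CubeGrid(origin=origin, axes=np.array(axes), shape=(n1, n2, n3),
                    values=values)


def esp_plane_from_cube(cube: CubeGrid | str | Path, mol: Molecule,
                        height: float = DEFAULT_HEIGHT,
                        spacing: float = DEFAULT_SPACING) -> PlanarField:
    """Sample a volumetric ESP onto the offset plane by trilinear interpolation.

    Only axis-aligned (orthogonal) cubes are supported; the plane must lie
    inside the cube bounds or a bounds error is raised.
    """
    from scipy.interpolate import RegularGridInterpolator

    if not isinstance(cube, CubeGrid):
        cube = read_cube(cube)
    off = cube.axes - np.diag(np.diag(cube.axes))
    if np.abs(off).max() > 1e-9:
        raise ValueError("non-orthogonal cube axes are not supported")
    steps = np.diag(cube.axes)
    grids = [cube.origin[k] + steps[k] * np.arange(cube.shape[k]) for k in range(3)]
    interp = RegularGridInterpolator(grids, cube.values, method="linear",
                                     bounds_error=True)
    origin, nx, ny = grid_for_molecule(mol, spacing)
    mask = vdw_projection_mask(mol, origin, spacing, (nx, ny))
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, height)], axis=1)
    try:
        vals = interp(pts).reshape(nx, ny)
    except ValueError as exc:
        raise ValueError(f"requested plane extends outside cube bounds: {exc}") from exc
    return PlanarField(origin=origin, spacing=spacing, height=height,
                       values=vals, mask=mask)


# ---------------------------------------------------------------------------
# descriptors


def descriptors(field: PlanarField, mol: Molecule, face: int = 1,
                backend: str = "point-charge") -> DescriptorSet:
    """ESP statistics over the vdW-masked nodes plus the heavy-atom count."""
    vals = field.values[field.mask]
    if vals.size == 0:
        raise MaskError("vdW projection mask is empty")
    vmax, vmin = float(vals.max()), float(vals.min())
    return DescriptorSet(
        n_ha=heavy_atom_count(mol),
        esp_max=vmax,
        esp_min=vmin,
        esp_mean=float(vals.mean()),
        esp_range=vmax - vmin,
        face=face,
        backend=backend,
    )


def descriptors_both_faces(mol: Molecule, height: float = DEFAULT_HEIGHT,
                           spacing: float = DEFAULT_SPACING) -> tuple[DescriptorSet, DescriptorSet]:
    """Point-charge descriptors for the +z and −z faces.

    Returns (reported, other): the reported face is the one with the larger
    ESP_max; planar aromatics with mirror-symmetric charges give identical
    descriptors on both faces.
    """
    up = descriptors(esp_plane_point_charges(mol, height, spacing), mol, face=1)
    dn = descriptors(esp_plane_point_charges(mol, -height, spacing), mol, face=-1)
    return (up, dn) if up.esp_max >= dn.esp_max else (dn, up)
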