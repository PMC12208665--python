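"""Real-space density grids: synthesis from atoms, masking, scaling, CCP4 I/O.

The per-atom density model is a single isotropic Gaussian whose integral
equals the element's atomic number Z,

    rho_a(r) = Z * (4*pi / B_eff)^(3/2) * exp(-4*pi^2 r^2 / B_eff),

with B_eff = B_atom + B_blur and B_blur = 8 * d_min^2 (A^2).  The
resolution-dependent blur makes the atom peak width track the nominal map
resolution d_min; the constant is configurable through ``b_blur_factor``.
This is a deliberately simple, analytically checkable stand-in for a full
scattering-factor model: electron counts are conserved exactly and the map is
linear in conformer weights, which is all the occupancy solver relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "DensityGrid",
    "FootprintMask",
    "grid_for_conformers",
    "calc_density",
    "footprint_mask",
    "scale_calc_to_obs",
    "read_map",
    "write_map",
]

# B_blur = B_BLUR_FACTOR * d_min^2; peak FWHM then tracks d_min
B_BLUR_FACTOR = 8.0
# default footprint radius (A) around ensemble heavy atoms
DEFAULT_MASK_RADIUS = 1.5
# grid extent padding (A) and Nyquist-safe spacing rule for per-ligand grids
GRID_PADDING = 4.0
MAX_SPACING = 0.5
# atom density evaluated out to this many Gaussian sigmas (>= 99.9% of Z)
SIGMA_CUTOFF = 4.5


@dataclass(eq=False)
class DensityGrid:
    """3D voxel array with spacing, origin and nominal resolution.

    Voxel (i, j, k) is centered at ``origin + (i, j, k) * voxel_spacing``.
    Map statistics mu/sigma are computed on demand so they can never go stale
    after value mutation.
    """

    values: np.ndarray            # (nx, ny, nz)
    voxel_spacing: np.ndarray     # (3,) A per axis
    origin: np.ndarray            # (3,) A
    resolution: float             # nominal d_min, A

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_spacing = np.asarray(self.voxel_spacing, dtype=float).ravel()
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.voxel_spacing <= 0):
            raise ValueError("voxel spacing must be > 0 on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        """RMS deviation of the map about its mean."""
        return float(self.values.std())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def empty_like(self) -> "DensityGrid":
        return DensityGrid(np.zeros(self.shape), self.voxel_spacing.copy(),
                           self.origin.copy(), self.resolution)

    def congruent(self, other: "DensityGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_spacing, other.voxel_spacing)
                and np.allclose(self.origin, other.origin))

    def voxel_coords(self, idx: np.ndarray) -> np.ndarray:
        """Cartesian centers of voxels given integer index array (n, 3)."""
        return self.origin + np.asarray(idx, float) * self.voxel_spacing

    def index_box(self, center: np.ndarray, radius: float):
        """Integer index ranges of the voxel box covering a sphere (clipped)."""
        lo = np.floor((center - radius - self.origin) / self.voxel_spacing)
        hi = np.ceil((center + radius - self.origin) / self.voxel_spacing)
        lo = np.clip(lo, 0, np.array(self.shape) - 1).astype(int)
        hi = np.clip(hi, 0, np.array(self.shape) - 1).astype(int)
        return lo, hi


@dataclass(eq=False)
class FootprintMask:
    """Set of voxels of a DensityGrid within a radius of ensemble atoms."""

    mask: np.ndarray                      # boolean, grid shape
    radius: float = DEFAULT_MASK_RADIUS

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of the footprint."""
        return np.argwhere(self.mask)

    def extract(self, grid: DensityGrid) -> np.ndarray:
        return grid.values[self.mask]


def grid_for_conformers(conformers, resolution: float,
                        padding: float = GRID_PADDING,
                        max_spacing: float = MAX_SPACING) -> DensityGrid:
    """Empty grid covering the conformers' bounding box plus padding.

    Spacing is min(d_min / 4, 0.5 A): Nyquist-safe with bounded memory.
    """
    coords = np.vstack([c.coords for c in conformers])
    spacing = min(resolution / 4.0, max_spacing)
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    return DensityGrid(np.zeros(tuple(n)), np.full(3, spacing), lo, resolution)


def _add_atom_density(values: np.ndarray, grid: DensityGrid,
                      pos: np.ndarray, z: float, b_eff: float,
                      weight: float) -> None:
    sigma = np.sqrt(b_eff / (8.0 * np.pi**2))
    r_cut = SIGMA_CUTOFF * sigma
    lo, hi = grid.index_box(pos, r_cut)
    if np.any(lo > hi):
        return
    ax = [grid.origin[d] + np.arange(lo[d], hi[d] + 1) * grid.voxel_spacing[d]
          - pos[d] for d in range(3)]
    r2 = (ax[0][:, None, None]**2 + ax[1][None, :, None]**2
          + ax[2][None, None, :]**2)
    amp = weight * z * (4.0 * np.pi / b_eff) ** 1.5
    contrib = amp * np.exp(-4.0 * np.pi**2 * r2 / b_eff)
    contrib[r2 > r_cut**2] = 0.0      # spherical cutoff, same as point path
    values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += contrib


def calc_density(conformers, weights, grid: DensityGrid, resolution: float,
                 atomic_numbers=None,
                 b_blur_factor: float = B_BLUR_FACTOR) -> DensityGrid:
    """Calculated map: weighted sum of per-conformer Gaussian-atom maps.

    ``grid`` supplies geometry only; a fresh grid is returned.  Linear in the
    weights by construction.  ``atomic_numbers`` defaults to carbon for every
    atom if neither given nor attached to the conformers' topology.
    """
    conformers = list(conformers)
    if not conformers:
        raise ValueError("empty conformer list")
    weights = np.asarray(weights, dtype=float).ravel()
    if len(weights) != len(conformers):
        raise ValueError("one weight per conformer required")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    out = grid.empty_like()
    out.resolution = resolution
    b_blur = b_blur_factor * resolution**2
    for conf, w in zip(conformers, weights):
        if w == 0.0:
            continue
        if np.any(conf.b_factors <= 0):
            raise ValueError("zero/negative B-factor")
        if atomic_numbers is None:
            zs = np.full(conf.n_atoms, 6.0)
        else:
            zs = np.asarray(atomic_numbers, dtype=float)
        for pos, z, b in zip(conf.coords, zs, conf.b_factors):
            _add_atom_density(out.values, out, pos, z, b + b_blur, w)
    return out


def density_at_points(points: np.ndarray, conformer, resolution: float,
                      atomic_numbers=None,
                      b_blur_factor: float = B_BLUR_FACTOR) -> np.ndarray:
    """Single-conformer Gaussian-atom density evaluated at arbitrary points.

    Used to fill the occupancy-solver design matrix on a footprint mask
    without synthesizing full grids per candidate.
    """
    points = np.asarray(points, dtype=float)
    b_blur = b_blur_factor * resolution**2
    if atomic_numbers is None:
        zs = np.full(conformer.n_atoms, 6.0)
    else:
        zs = np.asarray(atomic_numbers, dtype=float)
    rho = np.zeros(points.shape[0])
    for pos, z, b in zip(conformer.coords, zs, conformer.b_factors):
        b_eff = b + b_blur
        r2 = np.sum((points - pos) ** 2, axis=1)
        cut2 = (SIGMA_CUTOFF**2 / (8.0 * np.pi**2)) * b_eff
        sel = r2 <= cut2
        rho[sel] += (z * (4.0 * np.pi / b_eff) ** 1.5
                     * np.exp(-4.0 * np.pi**2 * r2[sel] / b_eff))
    return rho


def footprint_mask(conformers, grid: DensityGrid,
                   radius: float = DEFAULT_MASK_RADIUS) -> FootprintMask:
    """All voxels whose center lies within ``radius`` of any heavy atom."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    mask = np.zeros(grid.shape, dtype=bool)
    for conf in conformers:
        for pos in conf.coords:
            lo, hi = grid.index_box(pos, radius)
            if np.any(lo > hi):
                continue
            ax = [grid.origin[d]
                  + np.arange(lo[d], hi[d] + 1) * grid.voxel_spacing[d]
                  - pos[d] for d in range(3)]
            r2 = (ax[0][:, None, None]**2 + ax[1][None, :, None]**2
                  + ax[2][None, None, :]**2)
            mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= (
                r2 <= radius**2)
    return FootprintMask(mask, radius)


def scale_calc_to_obs(calc: DensityGrid, obs: DensityGrid,
                      mask: FootprintMask) -> float:
    """Least-squares scale s minimizing ||s*calc - obs||^2 over the mask."""
    if not calc.congruent(obs):
        raise ValueError("grids are not congruent")
    c = mask.extract(calc)
    o = mask.extract(obs)
    denom = float(c @ c)
    if denom == 0.0:
        raise ValueError("calculated density is identically zero on the mask")
    return float(c @ o) / denom


# ---------------------------------------------------------------------------
# CCP4/MRC I/O (orthogonal cells; axis order canonicalized on read)

def write_map(grid: DensityGrid, path) -> None:
    """Write a grid as a CCP4 map (mode 2, orthogonal cell, ORIGIN header)."""
    nx, ny, nz = grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(gemmi.UnitCell(nx * grid.voxel_spacing[0],
                                   ny * grid.voxel_spacing[1],
                                   nz * grid.voxel_spacing[2],
                                   90.0, 90.0, 90.0))
    np.asarray(g.array)[:] = grid.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def read_map(path, resolution: float = float("nan")) -> DensityGrid:
    """Read a CCP4/MRC map into a DensityGrid (canonical X,Y,Z axis order).

    The nominal resolution is not stored in the format; pass it explicitly
    when known.  The origin is taken from the ORIGIN header words when set,
    else from the start indices.
    """
    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed CCP4/MRC map {path}: {exc}")
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError("only orthogonal map cells are supported")
    values = np.array(m.grid.array, dtype=float)
    spacing = np.array(m.grid.spacing, dtype=float)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        start = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
        axes = [m.header_i32(w) - 1 for w in (17, 18, 19)]  # MAPC/R/S
        xyz_start = np.empty(3)
        xyz_start[axes] = start
        origin = xyz_start * spacing
    return DensityGrid(values, spacing, origin, resolution)
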