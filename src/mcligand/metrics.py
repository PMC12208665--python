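"""Real-space model validation: RSCC, per-atom EDIA / combined EDIAm, RMSD.

RSCC is the Pearson correlation of observed vs calculated density over the
footprint mask.  EDIA estimates the density support for an individual atom by
summing, over grid points p in a sphere around atom a,

    EDIA(a) = sum_p w(p,a) o(p,a) z(p)  /  sum_{p: w(p,a)>0} w(p,a),

where z(p) = clamp((rho(p) - mu)/sigma, 0, zeta) with zeta = 1.2, w is a
distance-dependent weight (positive inside the atom radius r(a), negative in
the shell r(a) < d <= 2 r(a) to penalize unclaimed excess density), and the
ownership o(p,a) partitions each point among the atoms claiming it.  The atom
radius is where the Gaussian atom model falls to 10% of its peak, making it
element-, B-factor- and resolution-aware.  EDIAm combines per-atom scores
with a power mean of exponent -2, which punishes poorly supported atoms more
than an arithmetic mean would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import B_BLUR_FACTOR, DensityGrid, FootprintMask

__all__ = [
    "ValidationReport",
    "rscc",
    "edia_z",
    "edia_atom",
    "ediam",
    "rmsd",
    "closest_conformer_rmsd",
    "atom_radius",
]

# truncation point of the normalized density score z(p)
ZETA = 1.2
# atom radius = density falloff to this fraction of the peak
RADIUS_FALLOFF = 0.1
# per-atom EDIA floor used in the power-mean combination (avoids div-by-zero)
EDIA_FLOOR = 1e-3
# power-mean exponent for EDIAm; None selects the arithmetic mean
EDIAM_EXPONENT = -2.0
# total negative-lobe weight mass as a fraction of the positive mass; the
# outer shell has ~7x the volume of the atom sphere, so the raw lobe is
# renormalized per atom to keep the excess-density penalty bounded
NEG_WEIGHT_MASS = 0.5


@dataclass(eq=False)
class ValidationReport:
    rscc: float
    ediam: float
    edia_per_atom: np.ndarray
    rmsd_to_reference: float | None = None

    def to_dict(self) -> dict:
        d = {"rscc": float(self.rscc), "ediam": float(self.ediam),
             "edia_per_atom": [float(x) for x in self.edia_per_atom]}
        if self.rmsd_to_reference is not None:
            d["rmsd_to_reference"] = float(self.rmsd_to_reference)
        return d

    def to_tsv(self, path, atom_names=None) -> None:
        import pandas as pd
        names = atom_names or [f"atom{i}" for i in
                               range(len(self.edia_per_atom))]
        pd.DataFrame({"atom": names, "edia": self.edia_per_atom}).to_csv(
            path, sep="\t", index=False)


def rscc(obs: DensityGrid, calc: DensityGrid, mask: FootprintMask) -> float:
    """Pearson correlation of the two maps over the masked voxels."""
    if not obs.congruent(calc):
        raise ValueError("grids are not congruent")
    o = mask.extract(obs)
    c = mask.extract(calc)
    if o.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    so, sc = o.std(), c.std()
    if so == 0 or sc == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.corrcoef(o, c)[0, 1])


def edia_z(rho: float | np.ndarray, mu: float, sigma: float,
           zeta: float = ZETA):
    """Truncated normalized density score: clamp((rho-mu)/sigma, 0, zeta)."""
    return np.clip((np.asarray(rho, float) - mu) / sigma, 0.0, zeta)


def atom_radius(b_factor: float, resolution: float,
                b_blur_factor: float = B_BLUR_FACTOR) -> float:
    """Radius where the Gaussian atom density drops to 10% of its peak."""
    b_eff = b_factor + b_blur_factor * resolution**2
    return float(np.sqrt(b_eff * np.log(1.0 / RADIUS_FALLOFF))
                 / (2.0 * np.pi))


def _distance_weight(d: np.ndarray, r: float) -> np.ndarray:
    """Positive paraboloid inside r, negative lobe on (r, 2r], zero beyond.

    The negative lobe is renormalized so its total mass is NEG_WEIGHT_MASS
    times the positive mass, keeping the two regions commensurate despite
    the shell's much larger volume.
    """
    w = np.zeros_like(d)
    inside = d <= r
    w[inside] = 1.0 - (d[inside] / r) ** 2
    shell = (d > r) & (d <= 2.0 * r)
    h = (d[shell] - r) / r
    w[shell] = -h * (1.0 - h)
    pos_mass = w[inside].sum()
    neg_mass = -w[shell].sum()
    if neg_mass > 0 and pos_mass > 0:
        w[shell] *= NEG_WEIGHT_MASS * pos_mass / neg_mass
    return w


def edia_atom(position, element_b_factor: float, grid: DensityGrid,
              neighbors=(), resolution: float | None = None,
              zeta: float = ZETA) -> float:
    """Density support score of one atom.

    ``neighbors`` are (position, b_factor) pairs of the other atoms of the
    model; they claim shared grid points through the ownership term.  Raises
    when the atom sphere leaves the grid.
    """
    pos = np.asarray(position, float)
    res = grid.resolution if resolution is None else resolution
    if not np.isfinite(res):
        raise ValueError("resolution required for the atom radius")
    r = atom_radius(element_b_factor, res)
    lo, hi = grid.index_box(pos, 2.0 * r)
    span = np.asarray(grid.shape)
    flo = (pos - 2.0 * r - grid.origin) / grid.voxel_spacing
    fhi = (pos + 2.0 * r - grid.origin) / grid.voxel_spacing
    if np.any(flo < -1) or np.any(fhi > span):
        raise ValueError("atom sphere extends outside the density grid")
    idx = np.stack(np.meshgrid(*[np.arange(lo[d], hi[d] + 1)
                                 for d in range(3)], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    pts = grid.voxel_coords(idx)
    d_self = np.linalg.norm(pts - pos, axis=1)
    sel = d_self <= 2.0 * r
    idx, pts, d_self = idx[sel], pts[sel], d_self[sel]
    w = _distance_weight(d_self, r)

    # ownership: count atoms claiming each point positively (d <= r(atom))
    pos_claims = (d_self <= r).astype(float)
    neg_claims = ((d_self > r) & (d_self <= 2 * r)).astype(float)
    for npos, nb in neighbors:
        nr = atom_radius(nb, res)
        dn = np.linalg.norm(pts - np.asarray(npos, float), axis=1)
        pos_claims += dn <= nr
        neg_claims += (dn > nr) & (dn <= 2 * nr)
    o = np.zeros_like(w)
    own_pos = (w > 0)
    o[own_pos] = 1.0 / pos_claims[own_pos]
    own_neg = (w < 0) & (pos_claims == 0)
    o[own_neg] = 1.0 / neg_claims[own_neg]

    mu, sigma = grid.mean, grid.sigma
    if not np.isfinite(mu) or not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("grid statistics undefined")
    rho = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    z = edia_z(rho, mu, sigma, zeta)
    denom = w[w > 0].sum()
    if denom <= 0:
        raise ValueError("atom has no positively weighted grid points")
    return float(max((w * o * z).sum() / denom, 0.0))


def ediam(conformers, grid: DensityGrid, resolution: float | None = None,
          exponent: float | None = EDIAM_EXPONENT):
    """Combined EDIA over all atoms of a multiconformer ligand model.

    Returns (ediam, per_atom_scores).  Warns (but proceeds) beyond 2 A, where
    the spherical-atom assumption behind EDIA degrades.
    """
    import warnings

    conformers = list(conformers)
    if not conformers:
        raise ValueError("empty model")
    res = grid.resolution if resolution is None else resolution
    if np.isfinite(res) and res > 2.0:
        warnings.warn("EDIA assumes spherical atoms; unreliable beyond 2 A "
                      f"resolution (got {res:.2f} A)", stacklevel=2)
    # each conformer is an alternate of the same molecule, so its atoms are
    # scored in the context of that conformer only (alternate copies of one
    # atom must not split ownership of the same density), then combined with
    # occupancy weighting
    scores, weights = [], []
    for conf in conformers:
        atoms = [(p, float(b)) for p, b in zip(conf.coords, conf.b_factors)]
        occ = conf.occupancy if conf.occupancy > 0 else 1.0
        for i, (p, b) in enumerate(atoms):
            nbrs = [atoms[j] for j in range(len(atoms)) if j != i]
            scores.append(edia_atom(p, b, grid, neighbors=nbrs,
                                    resolution=res))
            weights.append(occ)
    scores = np.asarray(scores)
    weights = np.asarray(weights) / np.sum(weights)
    if exponent is None:
        return float(weights @ scores), scores
    clamped = np.maximum(scores, EDIA_FLOOR)
    combined = float((weights @ clamped ** exponent) ** (1.0 / exponent))
    return combined, scores


def rmsd(c1, c2) -> float:
    """In-place RMSD (no superposition) over a fixed atom order."""
    a = np.asarray(c1.coords if hasattr(c1, "coords") else c1, float)
    b = np.asarray(c2.coords if hasattr(c2, "coords") else c2, float)
    if a.shape != b.shape:
        raise ValueError("atom-count mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def closest_conformer_rmsd(conformers, reference) -> float:
    """Minimum RMSD from any model conformer to the reference conformer."""
    conformers = list(conformers)
    if not conformers:
        raise ValueError("empty model")
    return min(rmsd(c, reference) for c in conformers)
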