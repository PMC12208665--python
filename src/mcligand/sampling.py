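"""Biased conformer generation over a constrained distance-geometry engine.

Six search strategies drive RDKit's experimental-torsion knowledge distance
geometry (ETKDG) generator followed by MMFF94 relaxation:

* ``unconstrained`` -- toolkit defaults only;
* ``fixed_terminal`` -- hard distance constraints between every pair of
  terminal heavy atoms (degree 1 in the heavy-atom graph), preserving the
  overall molecular envelope while the interior moves;
* ``blob`` -- conformers confined to the sphere around the seed centroid
  whose radius is the seed's own maximal centroid-to-atom distance;
* ``branch`` -- core (non-side-chain) atoms locked to the seed coordinates,
  side chains free (side chains of >= 4 heavy atoms);
* ``long_chain`` -- the opposite: side chains of > 30 atoms locked, core
  free;
* ``flip`` -- 180-degree flips about the principal axes with fine rotations
  (explicit user opt-in).

Every emitted conformer is rigid-body aligned into the seed's map frame and
must preserve the template connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdDistGeom, rdMolAlign
from rdkit.Geometry import Point3D

from .ligand import (Conformer, LigandTopology, classify_topology,
                     validate_connectivity)

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "SamplingPlan",
    "build_plan",
    "sample",
    "flip_sample",
    "deduplicate",
    "principal_axes",
]

# default conformer budgets by ligand size
SMALL_LIGAND_BUDGET = 5000
LARGE_LIGAND_BUDGET = 7000
SMALL_LIGAND_MAX_HEAVY = 25          # "< 25 heavy atoms" gets the small budget
# redundant-pair RMSD threshold (A)
DEDUP_RMSD = 0.2
# per-conformer tolerance on hard coordinate/distance constraints (A)
CONSTRAINT_TOL = 0.1
# each strategy may attempt up to this multiple of its allocation
RETRY_FACTOR = 3
# fine flip rotations: +/-2..10 degrees in 2-degree steps about the flip axis
FLIP_FINE_DEGREES = tuple(d for d in range(-10, 11, 2) if d != 0)

BASE_STRATEGIES = ("unconstrained", "fixed_terminal", "blob")


@dataclass
class SamplingPlan:
    """Strategy set, budget split, and seed for one sampling run."""

    strategies: tuple[str, ...]
    allocations: dict[str, int]
    n_total: int
    seed: int
    flip: bool = False

    def __post_init__(self):
        if sum(self.allocations.values()) != self.n_total:
            raise ValueError("allocations must sum to the total budget")


def build_plan(topology: LigandTopology, n_override: int | None = None,
               flip: bool = False, seed: int = 0) -> SamplingPlan:
    """Budget 5000 (< 25 heavy atoms) or 7000, split evenly over strategies.

    The flip search is user-opt-in and costs a fixed 33 conformers on top of
    the stochastic budget, so it does not enter the even split.
    """
    if n_override is not None and n_override <= 0:
        raise ValueError("n_override must be positive")
    flags = classify_topology(topology)
    strategies = list(BASE_STRATEGIES)
    if flags.branch_search:
        strategies.append("branch")
    if flags.long_chain_search:
        strategies.append("long_chain")
    if n_override is not None:
        n = int(n_override)
    elif topology.heavy_atom_count < SMALL_LIGAND_MAX_HEAVY:
        n = SMALL_LIGAND_BUDGET
    else:
        n = LARGE_LIGAND_BUDGET
    k = len(strategies)
    per, rem = divmod(n, k)
    alloc = {s: per for s in strategies}
    alloc["unconstrained"] += rem
    return SamplingPlan(tuple(strategies), alloc, n, int(seed), flip)


# ---------------------------------------------------------------------------
# geometry helpers

def principal_axes(coords: np.ndarray) -> np.ndarray:
    """Principal axes (rows, descending moment) of a centered point cloud.

    Raises on degenerate (collinear) geometry where the axes are undefined.
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 3:
        raise ValueError("principal axes need at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-8 * max(evals[2], 1e-300):
        raise ValueError("degenerate (collinear) geometry")
    axes = evecs[:, ::-1].T
    # deterministic sign convention
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def rotate_about_centroid(coords: np.ndarray, axis: np.ndarray,
                          angle_deg: float) -> np.ndarray:
    cen = coords.mean(axis=0)
    rot = _rotation_about_axis(axis, angle_deg)
    return (coords - cen) @ rot.T + cen


def flip_sample(seed_conformer: Conformer) -> list[Conformer]:
    """180-degree flips about the three principal axes plus fine rotations.

    Per axis: the base flip and rotations of that flip by +/-2..10 degrees in
    2-degree steps about the same axis (33 conformers total).  All outputs
    share the seed centroid.
    """
    coords = seed_conformer.coords
    axes = principal_axes(coords)
    out = []
    for ax_i, axis in enumerate(axes):
        base = rotate_about_centroid(coords, axis, 180.0)
        out.append(seed_conformer.with_coords(base, source=f"flip{ax_i}"))
        for deg in FLIP_FINE_DEGREES:
            fine = rotate_about_centroid(base, axis, float(deg))
            out.append(seed_conformer.with_coords(
                fine, source=f"flip{ax_i}{deg:+d}"))
    return out


def rmsd_matrix(coord_sets: np.ndarray) -> np.ndarray:
    """In-place pairwise RMSD matrix for (n, atoms, 3) coordinate stacks."""
    n, a, _ = coord_sets.shape
    flat = coord_sets.reshape(n, -1)
    sq = np.einsum("ij,ij->i", flat, flat)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T) / a
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


def deduplicate(conformers, threshold: float = DEDUP_RMSD, seed: int = 0,
                protected: int | None = None) -> list[Conformer]:
    """Remove one member of every conformer pair with in-place RMSD < threshold.

    The choice within a pair is uniform-random under the seed; a ``protected``
    index (the injected input conformer) is never removed.  Deterministic for
    a given seed; idempotent.
    """
    conformers = list(conformers)
    n = len(conformers)
    if n <= 1:
        return conformers
    rng = np.random.default_rng(seed)
    coords = np.stack([c.coords for c in conformers])
    alive = np.ones(n, dtype=bool)
    # chunk rows to bound the pairwise matrix memory
    chunk = max(1, int(2e7) // max(n, 1))
    flat = coords.reshape(n, -1)
    sq = np.einsum("ij,ij->i", flat, flat)
    a = coords.shape[1]
    thr2 = threshold**2 * a
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d2 = (sq[start:stop, None] + sq[None, :]
              - 2.0 * flat[start:stop] @ flat.T)
        for ii in range(start, stop):
            if not alive[ii]:
                continue
            close = np.nonzero(d2[ii - start] < thr2)[0]
            for jj in close:
                if jj <= ii or not alive[jj] or not alive[ii]:
                    continue
                if ii == protected:
                    alive[jj] = False
                elif jj == protected:
                    alive[ii] = False
                elif rng.random() < 0.5:
                    alive[ii] = False
                else:
                    alive[jj] = False
    return [c for c, keep in zip(conformers, alive) if keep]


# ---------------------------------------------------------------------------
# the constrained embedding engine

def _embed_params(seed: int, bounds=None):
    p = rdDistGeom.ETKDGv3()
    p.randomSeed = int(seed) % (2**31 - 1)
    p.numThreads = 1
    if bounds is not None:
        p.SetBoundsMat(bounds)
        p.useRandomCoords = True
    return p


def _heavy_indices(molH: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in molH.GetAtoms() if a.GetAtomicNum() > 1]


def _mmff_relax(molH, conf_ids, fixed=None, dist_constraints=None):
    props = AllChem.MMFFGetMoleculeProperties(molH)
    if props is None:
        return
    for cid in conf_ids:
        ff = AllChem.MMFFGetMoleculeForceField(molH, props, confId=cid)
        if ff is None:
            continue
        for idx in fixed or ():
            ff.AddFixedPoint(int(idx))
        for i, j, d in dist_constraints or ():
            ff.MMFFAddDistanceConstraint(int(i), int(j), False,
                                         d - 0.02, d + 0.02, 1000.0)
        ff.Minimize(maxIts=500)


def _align_to_seed(molH, conf_ids, seed_coords, heavy):
    ref = Chem.Mol(molH)
    ref_conf = ref.GetConformer(conf_ids[0])
    for h, xyz in zip(heavy, seed_coords):
        ref_conf.SetAtomPosition(h, Point3D(*xyz))
    amap = [(h, h) for h in heavy]
    for cid in conf_ids:
        rdMolAlign.AlignMol(molH, ref, prbCid=cid,
                            refCid=conf_ids[0], atomMap=amap)


class _Generator:
    """Shared state for one sampling run (template mol with explicit Hs)."""

    def __init__(self, topology: LigandTopology, seed_conformer: Conformer):
        if topology.template_mol is None:
            raise ValueError("topology lacks a template mol")
        self.topology = topology
        self.seed_conf = seed_conformer
        mol = Chem.Mol(topology.template_mol)
        mol.RemoveAllConformers()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(seed_conformer.coords):
            conf.SetAtomPosition(i, Point3D(*xyz))
        mol.AddConformer(conf)
        self.molH = Chem.AddHs(mol, addCoords=True)
        self.heavy = _heavy_indices(self.molH)
        self.molH.RemoveAllConformers()

    def _extract(self, molH, conf_ids, source):
        out = []
        for cid in conf_ids:
            pos = molH.GetConformer(cid).GetPositions()[self.heavy]
            out.append(self.seed_conf.with_coords(pos, source=source))
        return out

    def _embed(self, n, seed, params=None, coord_map=None):
        molH = Chem.Mol(self.molH)
        if coord_map is not None:
            cids = AllChem.EmbedMultipleConfs(
                molH, numConfs=n, randomSeed=int(seed) % (2**31 - 1),
                coordMap=coord_map, useRandomCoords=True, numThreads=1)
        else:
            cids = rdDistGeom.EmbedMultipleConfs(
                molH, n, params or _embed_params(seed))
        return molH, list(cids)

    def unconstrained(self, n, seed):
        molH, cids = self._embed(n, seed)
        _mmff_relax(molH, cids)
        _align_to_seed(molH, cids, self.seed_conf.coords, self.heavy)
        return self._extract(molH, cids, "unconstrained")

    def blob(self, n, seed):
        """Unconstrained draws recentered on the seed, kept only when every
        atom stays inside the seed's bounding sphere."""
        cen = self.seed_conf.centroid()
        radius = float(np.max(np.linalg.norm(self.seed_conf.coords - cen,
                                             axis=1)))
        kept: list[Conformer] = []
        attempt, budget = 0, RETRY_FACTOR * n
        while len(kept) < n and attempt < budget:
            take = min(n - len(kept), budget - attempt)
            molH, cids = self._embed(take, seed + 101 * attempt + 1)
            attempt += take
            _mmff_relax(molH, cids)
            _align_to_seed(molH, cids, self.seed_conf.coords, self.heavy)
            for c in self._extract(molH, cids, "blob"):
                shifted = c.coords - c.centroid() + cen
                if np.max(np.linalg.norm(shifted - cen, axis=1)) <= radius:
                    kept.append(c.with_coords(shifted))
        return kept

    def fixed_terminal(self, n, seed):
        terminals = self.topology.terminal_atoms()
        pairs = [(terminals[i], terminals[j])
                 for i in range(len(terminals))
                 for j in range(i + 1, len(terminals))]
        dists = {(i, j): float(np.linalg.norm(
            self.seed_conf.coords[i] - self.seed_conf.coords[j]))
            for i, j in pairs}
        bm = rdDistGeom.GetMoleculeBoundsMatrix(self.molH)
        for (i, j), d in dists.items():
            bm[min(i, j)][max(i, j)] = d + 0.01   # upper bound
            bm[max(i, j)][min(i, j)] = max(d - 0.01, 0.0)
        from rdkit import DistanceGeometry
        DistanceGeometry.DoTriangleSmoothing(bm)
        kept: list[Conformer] = []
        attempt, budget = 0, RETRY_FACTOR * n
        while len(kept) < n and attempt < budget:
            take = min(n - len(kept), budget - attempt)
            molH, cids = self._embed(
                take, 0, params=_embed_params(seed + 211 * attempt + 3, bm))
            attempt += take
            _mmff_relax(molH, cids,
                        dist_constraints=[(i, j, d)
                                          for (i, j), d in dists.items()])
            _align_to_seed(molH, cids, self.seed_conf.coords, self.heavy)
            for c in self._extract(molH, cids, "fixed_terminal"):
                ok = all(abs(np.linalg.norm(c.coords[i] - c.coords[j]) - d)
                         <= CONSTRAINT_TOL for (i, j), d in dists.items())
                if ok:
                    kept.append(c)
        return kept

    def _locked(self, n, seed, locked_atoms, source):
        coord_map = {int(i): Point3D(*self.seed_conf.coords[i])
                     for i in locked_atoms}
        kept: list[Conformer] = []
        attempt, budget = 0, RETRY_FACTOR * n
        while len(kept) < n and attempt < budget:
            take = min(n - len(kept), budget - attempt)
            molH, cids = self._embed(take, seed + 307 * attempt + 7,
                                     coord_map=coord_map)
            attempt += take
            _mmff_relax(molH, cids, fixed=locked_atoms)
            for c in self._extract(molH, cids, source):
                dev = np.linalg.norm(
                    c.coords[list(locked_atoms)]
                    - self.seed_conf.coords[list(locked_atoms)], axis=1)
                if np.all(dev <= CONSTRAINT_TOL):
                    kept.append(c)
        return kept

    def branch(self, n, seed):
        side = set().union(*(m for _, m in self.topology.side_chains
                             if len(m) >= 4)) if self.topology.side_chains \
            else set()
        core = sorted(set(range(self.topology.heavy_atom_count)) - side)
        return self._locked(n, seed, core, "branch")

    def long_chain(self, n, seed):
        chains = [m for _, m in self.topology.side_chains if len(m) > 30]
        locked = sorted(set().union(*chains)) if chains else []
        return self._locked(n, seed, locked, "long_chain")


def sample(plan: SamplingPlan, topology: LigandTopology,
           seed_conformer: Conformer, check_connectivity: bool = True,
           cores: int = 1) -> list[Conformer]:
    """Run every strategy in the plan; return the pooled conformers.

    Strategies run concurrently on up to five workers; each strategy has its
    own derived seed and results are assembled in plan order, so the worker
    count never changes the output.  Conformers that fail the
    template-connectivity check are dropped.  A shortfall (constrained
    embeddings can fail) is tolerated up to the retry budget; total failure
    of a strategy raises.
    """
    from concurrent.futures import ThreadPoolExecutor

    gen = _Generator(topology, seed_conformer)
    jobs = []
    for k, strat in enumerate(plan.strategies):
        n = plan.allocations[strat]
        if n:
            strat_seed = (plan.seed * 7919 + 104729 * (k + 1)) % (2**31 - 1)
            jobs.append((strat, n, strat_seed))
    workers = max(1, min(int(cores), 5, len(jobs)))
    if workers == 1:
        results = [getattr(gen, s)(n, sd) for s, n, sd in jobs]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futures = [pool.submit(getattr(gen, s), n, sd)
                       for s, n, sd in jobs]
            results = [f.result() for f in futures]
    out: list[Conformer] = []
    for (strat, _, _), confs in zip(jobs, results):
        if not confs:
            raise RuntimeError(f"strategy '{strat}' produced no conformers")
        if check_connectivity:
            confs = [c for c in confs if validate_connectivity(c, topology)]
        out.extend(confs)
    if plan.flip:
        out.extend(flip_sample(seed_conformer))
    return out
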