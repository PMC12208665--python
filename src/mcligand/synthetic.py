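"""Synthetic two-conformer benchmark: ground-truth models plus density maps.

Four programmatically constructed ligand archetypes cover the canonical
classes of ligand disorder:

* ``ring_flip``      -- an asymmetric aromatic ring flipped 180 degrees about
                        its attachment bond (localized ring flip);
* ``linear_shift``   -- a linear alcohol displaced rigidly as a whole
                        (non-localized displacement);
* ``torsion_shift``  -- a short chain with a single 120-degree torsional
                        change (localized torsional disorder);
* ``macrocycle``     -- a 14-membered ring with an exocyclic branch whose
                        torsions differ between conformers (branch plus
                        terminal-end heterogeneity).

For each archetype, truth maps are synthesized over occupancy splits
0.50/0.50 ... 0.90/0.10 and resolutions 0.8-2.5 A in 0.1 A steps
(4 x 5 x 18 = 360 cases).  B-factors inflate linearly with d_min and
i.i.d. Gaussian noise is added with standard deviation proportional to
d_min times the clean-map rms, emulating the loss of signal at lower
resolution.  All constants are explicit and recorded in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolTransforms

from .density import DensityGrid, calc_density, grid_for_conformers, write_map
from .ligand import (Conformer, LigandTopology, topology_from_smiles,
                     validate_connectivity, write_ligand_pdb)
from .metrics import rmsd
from .sampling import rotate_about_centroid

__all__ = [
    "FixtureLigand",
    "BenchmarkCase",
    "fixture_ligands",
    "build_truth_map",
    "generate_benchmark",
    "benchmark_cases",
    "occupancy_recovery",
    "OCCUPANCY_SPLITS",
    "RESOLUTIONS",
]

# occupancy of the 'A' conformer; 'B' carries the remainder
OCCUPANCY_SPLITS = (0.50, 0.60, 0.70, 0.80, 0.90)
RESOLUTIONS = tuple(np.round(np.arange(0.8, 2.51, 0.1), 1))

# B-factor inflation schedule: B = B0 + B_SLOPE * (d_min - 0.8)  [A^2]
B0 = 15.0
B_SLOPE = 20.0
# noise sd = NOISE_ALPHA * d_min * rms(clean map)
NOISE_ALPHA = 0.05

_ARCHETYPE_SMILES = {
    "ring_flip": "CCc1ccccn1",
    "linear_shift": "CCCCCCCO",
    "torsion_shift": "OCCCc1ccccc1",
    "macrocycle": "OCCCC1CCCCCCCCCCCCC1",
}


@dataclass
class FixtureLigand:
    archetype: str
    topology: LigandTopology
    conformer_a: Conformer
    conformer_b: Conformer


@dataclass
class BenchmarkCase:
    archetype: str
    topology: LigandTopology
    conformer_a: Conformer
    conformer_b: Conformer
    q_a: float
    q_b: float
    resolution: float
    noise_seed: int

    def __post_init__(self):
        if abs(self.q_a + self.q_b - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")


def _set_dihedral_delta(topo: LigandTopology, conf: Conformer,
                        quad: tuple[int, int, int, int],
                        delta_deg: float) -> Conformer:
    mol = Chem.Mol(topo.template_mol)
    mol.RemoveAllConformers()
    rconf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(conf.coords):
        rconf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*xyz))
    mol.AddConformer(rconf)
    c = mol.GetConformer()
    cur = rdMolTransforms.GetDihedralDeg(c, *quad)
    rdMolTransforms.SetDihedralDeg(c, *quad, cur + delta_deg)
    return conf.with_coords(c.GetPositions())


def _make_ring_flip(seed: int) -> FixtureLigand:
    topo, a = topology_from_smiles(_ARCHETYPE_SMILES["ring_flip"], seed=seed)
    # flip the pyridine ring 180 degrees about the exocyclic C-C bond axis
    ring = max(topo.ring_systems, key=len)
    exo = next((i, j) for i, j, _ in topo.bonds if (i in ring) != (j in ring))
    p_out = a.coords[exo[0] if exo[0] not in ring else exo[1]]
    p_in = a.coords[exo[0] if exo[0] in ring else exo[1]]
    axis = p_in - p_out
    axis /= np.linalg.norm(axis)
    coords = a.coords.copy()
    for idx in ring:
        v = coords[idx] - p_in
        rot = _rodrigues(axis, np.pi)
        coords[idx] = p_in + rot @ v
    b = a.with_coords(coords)
    return FixtureLigand("ring_flip", topo, a, b)


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _make_linear_shift(seed: int) -> FixtureLigand:
    topo, a = topology_from_smiles(_ARCHETYPE_SMILES["linear_shift"],
                                   seed=seed)
    b = a.with_coords(a.coords + np.array([0.5, 0.5, 0.3]))
    return FixtureLigand("linear_shift", topo, a, b)


def _make_torsion_shift(seed: int) -> FixtureLigand:
    # hydroxypropyl side chain (4 heavy atoms) on a phenyl core: localized
    # torsional disorder of the chain while the ring stays put
    topo, a = topology_from_smiles(_ARCHETYPE_SMILES["torsion_shift"],
                                   seed=seed)
    ring = max(topo.ring_systems, key=len)
    nbrs = [j if i == 3 else i for i, j, _ in topo.bonds if 3 in (i, j)]
    ring_att = min(n for n in nbrs if n in ring)
    b = _set_dihedral_delta(topo, a, (ring_att, 3, 2, 1), 120.0)
    return FixtureLigand("torsion_shift", topo, a, b)


def _make_macrocycle(seed: int) -> FixtureLigand:
    # 14-membered ring with a 4-atom exocyclic branch: branch rotation at the
    # ring attachment plus terminal hydroxyl rotation
    topo, a = topology_from_smiles(_ARCHETYPE_SMILES["macrocycle"], seed=seed)
    ring = max(topo.ring_systems, key=len)
    nbrs4 = [j if i == 4 else i for i, j, _ in topo.bonds if 4 in (i, j)]
    ring_nbr = min(n for n in nbrs4 if n in ring)
    b = _set_dihedral_delta(topo, a, (ring_nbr, 4, 3, 2), 120.0)
    b = _set_dihedral_delta(topo, b, (3, 2, 1, 0), -120.0)
    return FixtureLigand("macrocycle", topo, a, b)


def fixture_ligands(seed: int = 20) -> list[FixtureLigand]:
    """The four benchmark archetypes, constructed deterministically.

    Each A/B pair shares a topology, preserves template connectivity, and
    differs by at least 0.5 A in-place RMSD.
    """
    makers = (_make_ring_flip, _make_linear_shift, _make_torsion_shift,
              _make_macrocycle)
    out = []
    for make in makers:
        for attempt in range(8):
            fix = make(seed + 1000 * attempt)
            ok = (rmsd(fix.conformer_a, fix.conformer_b) >= 0.5
                  and validate_connectivity(fix.conformer_b, fix.topology))
            if ok:
                out.append(fix)
                break
        else:
            raise RuntimeError(f"could not construct archetype via {make}")
    return out


def _case_b_factor(resolution: float) -> float:
    return B0 + B_SLOPE * (resolution - 0.8)


def build_truth_map(case: BenchmarkCase, alpha: float = NOISE_ALPHA,
                    with_noise: bool = True) -> DensityGrid:
    """Simulated observed map for one benchmark case.

    Weighted two-conformer density with resolution-inflated B-factors plus
    seeded Gaussian noise of sd = alpha * d_min * rms(clean map).
    """
    d = case.resolution
    bval = _case_b_factor(d)
    a = replace(case.conformer_a, b_factors=np.full(
        case.conformer_a.n_atoms, bval))
    b = replace(case.conformer_b, b_factors=np.full(
        case.conformer_b.n_atoms, bval))
    grid = grid_for_conformers([a, b], d)
    out = calc_density([a, b], [case.q_a, case.q_b], grid, d,
                       atomic_numbers=case.topology.atomic_numbers)
    if with_noise and alpha > 0:
        rng = np.random.default_rng(case.noise_seed)
        sd = alpha * d * out.values.std()
        out.values = out.values + rng.normal(0.0, sd, out.shape)
    return out


def _case_seed(base: int, i: int) -> int:
    return (base * 1000003 + 7919 * i + 1) % (2**31 - 1)


def benchmark_cases(seed: int = 0, archetypes=None, splits=OCCUPANCY_SPLITS,
                    resolutions=RESOLUTIONS) -> list[BenchmarkCase]:
    """Enumerate benchmark cases (archetype x split x resolution)."""
    fixtures = archetypes if archetypes is not None else fixture_ligands()
    cases = []
    i = 0
    for fix in fixtures:
        for q_a in splits:
            for d in resolutions:
                cases.append(BenchmarkCase(
                    fix.archetype, fix.topology, fix.conformer_a,
                    fix.conformer_b, float(q_a), float(round(1.0 - q_a, 10)),
                    float(d), _case_seed(seed, i)))
                i += 1
    return cases


def generate_benchmark(outdir, seed: int = 0, archetypes=None,
                       splits=OCCUPANCY_SPLITS, resolutions=RESOLUTIONS,
                       alpha: float = NOISE_ALPHA) -> pd.DataFrame:
    """Emit (truth model, input model, map) files for every benchmark case.

    The truth model is the two-conformer ligand with altlocs A/B at the case
    occupancies; the input model holds only the 'A' conformer at occupancy
    1.0 (what the fitting pipeline receives).  Returns and writes a TSV
    manifest with one row per (map, model) pair.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in benchmark_cases(seed, archetypes, splits, resolutions):
        tag = f"{case.archetype}_a{case.q_a:.2f}_d{case.resolution:.1f}"
        bval = _case_b_factor(case.resolution)
        a = replace(case.conformer_a, occupancy=case.q_a, altloc="A",
                    b_factors=np.full(case.conformer_a.n_atoms, bval))
        b = replace(case.conformer_b, occupancy=case.q_b, altloc="B",
                    b_factors=np.full(case.conformer_b.n_atoms, bval))
        truth_pdb = outdir / f"{tag}_truth.pdb"
        input_pdb = outdir / f"{tag}_input.pdb"
        map_file = outdir / f"{tag}.ccp4"
        write_ligand_pdb(case.topology, [a, b], truth_pdb)
        write_ligand_pdb(case.topology,
                         [replace(a, occupancy=1.0, altloc="")], input_pdb)
        grid = build_truth_map(case, alpha=alpha)
        write_map(grid, map_file)
        rows.append({
            "archetype": case.archetype, "q_a": case.q_a, "q_b": case.q_b,
            "resolution": case.resolution, "b_factor": bval,
            "noise_alpha": alpha, "noise_seed": case.noise_seed,
            "smiles": case.topology.smiles,
            "truth_model": truth_pdb.name, "input_model": input_pdb.name,
            "map": map_file.name,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def occupancy_recovery(model_conformers, occupancies, truth_a: Conformer,
                       truth_b: Conformer) -> tuple[float, float]:
    """Partition fitted occupancy between the two truth conformers.

    Each model conformer's occupancy is credited to whichever truth conformer
    it is closer to (in-place RMSD).  Returns (q_a_recovered, q_b_recovered).
    """
    qa = qb = 0.0
    for conf, occ in zip(model_conformers, occupancies):
        if rmsd(conf, truth_a) <= rmsd(conf, truth_b):
            qa += occ
        else:
            qb += occ
    return qa, qb
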