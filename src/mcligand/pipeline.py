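"""End-to-end multiconformer ligand fitting.

Stages: load -> plan -> sample -> deduplicate -> QP screen -> rigid
perturbation -> global QP -> cardinality-constrained MIQP -> low-occupancy
cull -> altloc relabeling -> embedding into the untouched parent structure.

Modes: ``xray`` (cardinality 3), ``event`` (PanDDA event maps; final
occupancies scaled by (1 - BDC) before embedding), ``cryoem``
(cardinality 2).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from . import density, metrics, sampling, solver
from .ligand import Conformer, LigandTopology, load_ligand, write_ligand_pdb
from .perturb import perturb

__all__ = [
    "RunConfig",
    "MultiConformerModel",
    "fit_ligand",
    "run",
    "cull_low_occupancy",
]

log = logging.getLogger("mcligand")

MODES = ("xray", "event", "cryoem")
DEFAULT_T_MIN = 0.20
OCCUPANCY_FLOOR = 0.1
CARDINALITY = {"xray": 3, "event": 3, "cryoem": 2}


@dataclass
class RunConfig:
    """User-facing knobs of one fitting run."""

    mode: str = "xray"
    resolution: float = float("nan")
    smiles: str = ""
    selection: str = ""
    n_conformers: int | None = None      # budget override (-nc)
    seed: int = 0
    flip: bool = False
    bdc: float | None = None             # event mode only, in [0, 1)
    cores: int = 1
    t_min: float = DEFAULT_T_MIN
    cardinality: int | None = None       # default by mode
    mask_radius: float = density.DEFAULT_MASK_RADIUS
    occupancy_floor: float = OCCUPANCY_FLOOR

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.bdc is not None and not 0.0 <= self.bdc < 1.0:
            raise ValueError("BDC must lie in [0, 1)")

    @property
    def effective_cardinality(self) -> int:
        return self.cardinality if self.cardinality is not None \
            else CARDINALITY[self.mode]


@dataclass
class MultiConformerModel:
    """Final 1-3 conformers with altlocs and occupancies summing to <= 1."""

    conformers: list[Conformer]
    objective: float = float("nan")
    provenance: list[str] = field(default_factory=list)
    report: metrics.ValidationReport | None = None

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([c.occupancy for c in self.conformers])

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("model must contain at least one conformer")
        if self.occupancies.sum() > 1.0 + 1e-9:
            raise ValueError("occupancies must sum to <= 1")


def cull_low_occupancy(model: MultiConformerModel,
                       floor: float = OCCUPANCY_FLOOR) -> MultiConformerModel:
    """Drop conformers below the occupancy floor (never emit an empty model).

    Remaining occupancies are unchanged; any redistribution happens in
    external refinement, outside this tool's scope.
    """
    idx = [i for i, c in enumerate(model.conformers) if c.occupancy >= floor]
    if not idx:
        warnings.warn("all conformers below the occupancy floor; keeping the "
                      "highest-occupancy one", stacklevel=2)
        idx = [int(np.argmax([c.occupancy for c in model.conformers]))]
    prov = model.provenance or [""] * len(model.conformers)
    return MultiConformerModel([model.conformers[i] for i in idx],
                               model.objective, [prov[i] for i in idx],
                               model.report)


def _relabel(conformers, provenance):
    order = np.argsort([-c.occupancy for c in conformers], kind="stable")
    out, prov = [], []
    for rank, i in enumerate(order):
        out.append(replace(conformers[i], altloc=chr(ord("A") + rank)))
        prov.append(provenance[i])
    return out, prov


def fit_ligand(topology: LigandTopology, seed_conformer: Conformer,
               obs: density.DensityGrid, config: RunConfig,
               ) -> MultiConformerModel:
    """Core fitting loop on in-memory objects (no file I/O)."""
    t0 = time.time()
    res = config.resolution if np.isfinite(config.resolution) \
        else obs.resolution
    if not np.isfinite(res):
        raise ValueError("a nominal map resolution is required")
    zs = topology.atomic_numbers

    plan = sampling.build_plan(topology, n_override=config.n_conformers,
                               flip=config.flip, seed=config.seed)
    candidates = [replace(seed_conformer, source="input")]
    candidates += sampling.sample(plan, topology, seed_conformer,
                                  cores=config.cores)
    log.info("sampled %d candidates (%.1fs)", len(candidates),
             time.time() - t0)

    candidates = sampling.deduplicate(candidates, seed=config.seed,
                                      protected=0)
    log.info("%d candidates after dedup", len(candidates))

    mask = density.footprint_mask(candidates, obs, radius=config.mask_radius)
    survivors, _, _ = solver.qp_screen(candidates, obs, mask,
                                       resolution=res, atomic_numbers=zs)
    log.info("%d QP-screen survivors", len(survivors))

    enriched = perturb(survivors)
    design = solver.build_design_matrix(enriched, obs, mask, resolution=res,
                                        atomic_numbers=zs)
    qp_sol = solver.solve_qp(design)
    pool_idx = qp_sol.selected
    if pool_idx.size == 0:
        pool_idx = np.array([0])
    pool = [enriched[i] for i in pool_idx]
    log.info("%d conformers enter model selection", len(pool))

    final_design = solver.build_design_matrix(pool, obs, mask,
                                              resolution=res,
                                              atomic_numbers=zs)
    miqp = solver.solve_miqp(final_design,
                             cardinality=min(config.effective_cardinality,
                                             len(pool)),
                             t_min=config.t_min)
    sel = miqp.selected
    if sel.size == 0:
        # density does not support any conformer at t_min; fall back to the
        # input conformer so the model is never empty
        warnings.warn("MIQP selected no conformer; emitting the input "
                      "conformer at its QP weight", stacklevel=2)
        sel = np.array([int(np.argmax(qp_sol.weights[pool_idx]))])
        weights = np.array([max(float(qp_sol.weights[pool_idx][sel[0]]),
                                config.t_min)])
    else:
        weights = miqp.weights[sel]

    chosen = [replace(pool[i], occupancy=float(w))
              for i, w in zip(sel, weights)]
    prov = [pool[i].source for i in sel]
    chosen, prov = _relabel(chosen, prov)
    model = MultiConformerModel(chosen, miqp.objective, prov)
    model = cull_low_occupancy(model, config.occupancy_floor)

    if config.mode == "event" and config.bdc is not None:
        scaled = [replace(c, occupancy=c.occupancy * (1.0 - config.bdc))
                  for c in model.conformers]
        model = MultiConformerModel(scaled, model.objective, model.provenance)

    calc = density.calc_density(model.conformers, model.occupancies,
                                obs, res, atomic_numbers=zs)
    s = density.scale_calc_to_obs(calc, obs, mask)
    calc.values *= s
    em, per_atom = metrics.ediam(model.conformers, obs, resolution=res)
    model.report = metrics.ValidationReport(
        rscc=metrics.rscc(obs, calc, mask), ediam=em, edia_per_atom=per_atom)
    log.info("done in %.1fs: %d conformer(s), occupancies %s, RSCC %.3f",
             time.time() - t0, len(model.conformers),
             np.round(model.occupancies, 3), model.report.rscc)
    return model


def _embed_model(structure_path, selection: str, topology: LigandTopology,
                 model: MultiConformerModel, out_path) -> None:
    """Replace the selected residue with the multiconformer ligand; keep
    everything else untouched."""
    from .ligand import _find_residue, _parse_selection

    st = gemmi.read_structure(str(structure_path))
    chain_name, resnum = _parse_selection(selection)
    res = _find_residue(st, chain_name, resnum)
    single = len(model.conformers) == 1
    while len(res) > 0:
        del res[0]
    for conf in model.conformers:
        for name, el, xyz, b in zip(topology.atom_names, topology.elements,
                                    conf.coords, conf.b_factors):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*xyz)
            atom.b_iso = float(b)
            atom.occ = float(conf.occupancy)
            if not single:
                atom.altloc = conf.altloc
            res.add_atom(atom)
    st.write_pdb(str(out_path))


def run(structure_path, map_path, config: RunConfig, outdir=".",
        ) -> MultiConformerModel:
    """File-level entry point.

    Reads the structure and CCP4/MRC map, fits the ligand named by
    ``config.selection`` with the SMILES template ``config.smiles``, and
    writes ``multiconformer_ligand.pdb`` (ligand only),
    ``multiconformer_model.pdb`` (embedded) and ``report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topology, seed_conf = load_ligand(structure_path, config.selection,
                                      config.smiles)
    obs = density.read_map(map_path, resolution=config.resolution)
    model = fit_ligand(topology, seed_conf, obs, config)

    write_ligand_pdb(topology, model.conformers,
                     outdir / "multiconformer_ligand.pdb")
    _embed_model(structure_path, config.selection, topology, model,
                 outdir / "multiconformer_model.pdb")
    report = {
        "mode": config.mode,
        "resolution": float(config.resolution) if
        np.isfinite(config.resolution) else obs.resolution,
        "n_conformers": len(model.conformers),
        "occupancies": [float(o) for o in model.occupancies],
        "altlocs": [c.altloc for c in model.conformers],
        "provenance": model.provenance,
        "objective": float(model.objective),
        "validation": model.report.to_dict() if model.report else None,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return model
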