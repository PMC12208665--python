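"""Ligand loading, topology classification, and connectivity validation.

A ligand is represented by a :class:`LigandTopology` (the element/bond graph
with bond orders taken from a SMILES template) plus one or more
:class:`Conformer` objects (heavy-atom coordinate sets in the map frame).

Bond orders in PDB files are unreliable, so they are always assigned from a
user-supplied SMILES template.  Hydrogens are dropped at load time: their
density contribution is negligible at typical map resolutions and all scoring
masks on heavy atoms.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdDetermineBonds
from rdkit.Geometry import Point3D

__all__ = [
    "Conformer",
    "LigandTopology",
    "SelectionError",
    "CompositionError",
    "load_ligand",
    "validate_connectivity",
    "classify_topology",
    "topology_from_smiles",
    "write_ligand_pdb",
]

# macrocycle = ring of at least this many atoms
MACROCYCLE_RING_SIZE = 12
# side chains at least this long trigger the branch search
BRANCH_MIN_ATOMS = 4
# side chains longer than this trigger the long-chain search
LONG_CHAIN_ATOMS = 30


class SelectionError(ValueError):
    """The chain/residue selection did not match exactly one residue."""


class CompositionError(ValueError):
    """SMILES template and coordinates disagree on heavy-atom composition."""


@dataclass(eq=False)
class Conformer:
    """One heavy-atom coordinate set of a ligand, in the map frame."""

    coords: np.ndarray          # (n_atoms, 3) Angstrom
    b_factors: np.ndarray       # (n_atoms,) Angstrom^2, all > 0
    occupancy: float = 1.0
    altloc: str = ""
    source: str = ""            # provenance tag (sampling strategy etc.)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.b_factors = np.asarray(self.b_factors, dtype=float).ravel()
        if self.coords.shape[0] != self.b_factors.shape[0]:
            raise ValueError("coords and b_factors length mismatch")
        if np.any(self.b_factors <= 0):
            raise ValueError("all B-factors must be > 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, source: str | None = None) -> "Conformer":
        return replace(self, coords=np.asarray(coords, float),
                       source=self.source if source is None else source)


@dataclass
class StrategyFlags:
    """Which specialized sampling searches apply to a topology."""

    branch_search: bool = False
    long_chain_search: bool = False
    macrocycle: bool = False


@dataclass
class LigandTopology:
    """Element/bond graph of a ligand with template bond orders."""

    elements: list[str]
    atom_names: list[str]
    bonds: list[tuple[int, int, float]]       # (i, j, order)
    ring_systems: list[frozenset[int]] = field(default_factory=list)
    side_chains: list[tuple[int, frozenset[int]]] = field(default_factory=list)
    is_macrocycle: bool = False
    template_mol: Chem.Mol | None = None      # heavy-atom RDKit mol, template orders
    smiles: str = ""

    @property
    def heavy_atom_count(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([gemmi.Element(e).atomic_number for e in self.elements])

    def bond_set(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j, _ in self.bonds}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.heavy_atom_count))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def terminal_atoms(self) -> list[int]:
        """Heavy atoms with exactly one heavy-atom neighbour."""
        deg = Counter()
        for i, j, _ in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return [a for a in range(self.heavy_atom_count) if deg[a] == 1]


def _mol_from_coords(elements, coords) -> Chem.Mol:
    """Bare RDKit mol (no bonds) from element symbols and positions."""
    rw = Chem.RWMol()
    for e in elements:
        a = Chem.Atom(e)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    conf = Chem.Conformer(len(elements))
    for i, p in enumerate(np.asarray(coords, float)):
        conf.SetAtomPosition(i, Point3D(*p))
    rw.AddConformer(conf)
    return rw.GetMol()


def _perceive_bonds(elements, coords) -> set[tuple[int, int]] | None:
    """Geometry-derived connectivity (covalent-radius perception).

    Returns None when perception itself fails (overlapping atoms etc.).
    """
    mol = _mol_from_coords(elements, coords)
    try:
        rdDetermineBonds.DetermineConnectivity(mol)
    except Exception:
        return None
    return {tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
            for b in mol.GetBonds()}


def _heavy_template(smiles: str) -> Chem.Mol:
    tmpl = Chem.MolFromSmiles(smiles)
    if tmpl is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.RemoveHs(tmpl)


def _assign_bond_orders(elements, coords, smiles: str) -> Chem.Mol:
    """Perceive connectivity from geometry and stamp template bond orders.

    Raises on composition mismatch or failed assignment.
    """
    tmpl = _heavy_template(smiles)
    want = Counter(a.GetSymbol() for a in tmpl.GetAtoms())
    have = Counter(elements)
    if want != have:
        raise CompositionError(
            f"SMILES heavy-atom composition {dict(want)} does not match "
            f"coordinates {dict(have)}")
    mol = _mol_from_coords(elements, coords)
    rdDetermineBonds.DetermineConnectivity(mol)
    lvl = RDLogger.logger()
    lvl.setLevel(RDLogger.CRITICAL)
    try:
        out = AllChem.AssignBondOrdersFromTemplate(tmpl, mol)
    finally:
        lvl.setLevel(RDLogger.ERROR)
    # restore implicit-H accounting (perception ran with NoImplicit set) and
    # carry formal charges over from the template via the substructure match
    for atom in out.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    match = out.GetSubstructMatch(tmpl)
    if match:
        for t_i, o_i in enumerate(match):
            out.GetAtomWithIdx(o_i).SetFormalCharge(
                tmpl.GetAtomWithIdx(t_i).GetFormalCharge())
    Chem.SanitizeMol(out)
    return out


def _ring_systems(mol: Chem.Mol) -> tuple[list[frozenset[int]], bool]:
    rings = [frozenset(r) for r in mol.GetRingInfo().AtomRings()]
    macro = any(len(r) >= MACROCYCLE_RING_SIZE for r in rings)
    # merge fused/spiro rings into ring systems
    systems: list[set[int]] = []
    for r in rings:
        merged = set(r)
        keep = []
        for s in systems:
            if s & merged:
                merged |= s
            else:
                keep.append(s)
        keep.append(merged)
        systems = keep
    return [frozenset(s) for s in systems], macro


def _side_chains(g: nx.Graph, ring_systems) -> list[tuple[int, frozenset[int]]]:
    """Maximal connected acyclic heavy-atom subgraphs hanging off the rings.

    For acyclic ligands the branches are taken relative to a graph-center atom.
    """
    ring_atoms = set().union(*ring_systems) if ring_systems else set()
    if ring_atoms:
        anchors = ring_atoms
    else:
        if g.number_of_nodes() <= 1:
            return []
        anchors = {min(nx.center(g))}
    rest = g.subgraph(n for n in g if n not in anchors)
    chains = []
    for comp in nx.connected_components(rest):
        attach = sorted(a for a in anchors
                        if any(g.has_edge(a, m) for m in comp))
        chains.append((attach[0], frozenset(comp)))
    return sorted(chains)


def topology_from_mol(mol: Chem.Mol, atom_names=None, smiles: str = "") -> LigandTopology:
    """Build a LigandTopology from a sanitized heavy-atom RDKit mol."""
    mol = Chem.RemoveHs(mol)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    if atom_names is None:
        counts: Counter = Counter()
        atom_names = []
        for e in elements:
            counts[e] += 1
            atom_names.append(f"{e}{counts[e]}")
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    systems, macro = _ring_systems(mol)
    topo = LigandTopology(elements=elements, atom_names=list(atom_names),
                          bonds=bonds, ring_systems=systems,
                          is_macrocycle=macro, template_mol=mol, smiles=smiles)
    topo.side_chains = _side_chains(topo.graph(), systems)
    if not nx.is_connected(topo.graph()):
        raise ValueError("ligand bond graph is not connected")
    return topo


def topology_from_smiles(smiles: str, seed: int = 0,
                         b_factor: float = 15.0) -> tuple[LigandTopology, Conformer]:
    """Construct a topology plus an embedded, relaxed conformer from SMILES.

    Used by the synthetic benchmark; the conformer is MMFF94-relaxed and
    centered at the origin.
    """
    tmpl = Chem.MolFromSmiles(smiles)
    if tmpl is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    molH = Chem.AddHs(tmpl)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(molH, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(molH)
    mol = Chem.RemoveHs(molH)
    topo = topology_from_mol(mol, smiles=smiles)
    coords = mol.GetConformer().GetPositions()
    coords = coords - coords.mean(axis=0)
    conf = Conformer(coords=coords,
                     b_factors=np.full(len(topo.elements), b_factor))
    return topo, conf


def classify_topology(topology: LigandTopology) -> StrategyFlags:
    """Decide which specialized sampling searches apply.

    Branch search for side chains of >= 4 heavy atoms, long-chain search for
    side chains of > 30, macrocycle handling for rings of >= 12 atoms.
    """
    sizes = [len(m) for _, m in topology.side_chains]
    return StrategyFlags(
        branch_search=any(s >= BRANCH_MIN_ATOMS for s in sizes),
        long_chain_search=any(s > LONG_CHAIN_ATOMS for s in sizes),
        macrocycle=topology.is_macrocycle,
    )


def validate_connectivity(conformer: Conformer, topology: LigandTopology,
                          smiles: str | None = None) -> bool:
    """True iff the conformer's geometry still encodes the template chemistry.

    Bond connectivity is re-perceived from interatomic distances and compared
    against the template bond graph; the SMILES bond-order assignment is then
    re-attempted as a proxy for chemical integrity.  Returns False (never
    raises) on any failure, signalling a corrupted geometry.
    """
    perceived = _perceive_bonds(topology.elements, conformer.coords)
    if perceived is None or perceived != topology.bond_set():
        return False
    try:
        _assign_bond_orders(topology.elements, conformer.coords,
                            smiles or topology.smiles)
    except Exception:
        return False
    return True


def _parse_selection(selection: str) -> tuple[str, int]:
    try:
        chain, resnum = selection.split(",")
        return chain.strip(), int(resnum)
    except Exception as exc:
        raise SelectionError(
            f"selection must be 'CHAIN,RESNUM', got {selection!r}") from exc


def _find_residue(structure: gemmi.Structure, chain_name: str, resnum: int):
    model = structure[0]
    for chain in model:
        if chain.name != chain_name:
            continue
        for res in chain:
            if res.seqid.num == resnum:
                return res
    raise SelectionError(
        f"selection '{chain_name},{resnum}' not found in structure")


def load_ligand(structure_file, selection: str,
                smiles: str) -> tuple[LigandTopology, Conformer]:
    """Load a ligand residue from a PDB/mmCIF file.

    ``selection`` is ``"CHAIN,RESNUM"``.  Heavy atoms only; if the residue has
    alternate locations, altloc 'A' is kept (with a warning).  Bond orders come
    from the SMILES template.
    """
    try:
        structure = gemmi.read_structure(str(structure_file))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable structure file {structure_file}: {exc}")
    chain_name, resnum = _parse_selection(selection)
    res = _find_residue(structure, chain_name, resnum)

    def _alt(a):  # gemmi encodes "no altloc" as NUL
        return a.altloc if a.altloc not in ("", "\x00") else ""

    altlocs = {_alt(a) for a in res if _alt(a)}
    if altlocs:
        warnings.warn(
            f"residue {selection} has alternate locations {sorted(altlocs)}; "
            "keeping 'A'", stacklevel=2)
    elements, names, coords, bvals, occs = [], [], [], [], []
    for atom in res:
        if atom.is_hydrogen():
            continue
        if _alt(atom) and _alt(atom) != "A":
            continue
        elements.append(atom.element.name)
        names.append(atom.name)
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        bvals.append(atom.b_iso)
        occs.append(atom.occ)
    if not elements:
        raise SelectionError(f"residue {selection} has no heavy atoms")

    mol = _assign_bond_orders(elements, np.array(coords), smiles)
    topo = topology_from_mol(mol, atom_names=names, smiles=smiles)
    conf = Conformer(coords=np.array(coords),
                     b_factors=np.maximum(np.array(bvals), 1e-3),
                     occupancy=float(np.clip(np.mean(occs), 0.0, 1.0)),
                     altloc="A" if altlocs else "")
    return topo, conf


def write_ligand_pdb(topology: LigandTopology, conformers, path,
                     resname: str = "LIG", chain: str = "A",
                     resnum: int = 1) -> None:
    """Write one or more conformers of a ligand as a (multiconformer) PDB.

    A single conformer is written without altloc; several conformers get
    altlocs from their ``altloc`` field (or A, B, C... by position).
    """
    conformers = list(conformers)
    st = gemmi.Structure()
    st.name = resname
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(resnum, " ")
    res.het_flag = "H"
    for k, conf in enumerate(conformers):
        alt = conf.altloc or (chr(ord("A") + k) if len(conformers) > 1 else "")
        for name, el, xyz, b in zip(topology.atom_names, topology.elements,
                                    conf.coords, conf.b_factors):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*xyz)
            atom.b_iso = float(b)
            atom.occ = float(conf.occupancy)
            if alt:
                atom.altloc = alt
            res.add_atom(atom)
    ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
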