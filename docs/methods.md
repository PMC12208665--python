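# Methods

This note documents the models, numerical choices, and limitations behind
`mcligand`. Everything stated here is computed by the package's own tests or
scripts; nothing is quoted from external runs.

## Problem statement

Experimental density at a ligand site is an occupancy-weighted average over
the conformations present in the sample. Given a single-conformer placement,
the task is to find a small set of conformers {c₁…c_k} and occupancies ω
(ωᵢ ≥ 0, Σω ≤ 1) minimizing the real-space residual ‖Σ ωᵢ ρᶜ(cᵢ) − ρᵒ‖² over
a footprint mask, with k ≤ 3 for X-ray / event maps and k ≤ 2 for cryo-EM,
and every retained occupancy ≥ t_min = 0.20.

## Density model

Each heavy atom contributes a single isotropic Gaussian normalized to its
electron count:

    ρ_a(r) = Z · (4π / B_eff)^{3/2} · exp(−4π² r² / B_eff),
    B_eff  = B_atom + 8 · d_min²  [Å²].

The resolution blur `8·d_min²` makes the peak width track the nominal
resolution; the constant is exposed as `density.B_BLUR_FACTOR`. Hydrogens
are dropped at load time — their density contribution is negligible at the
resolutions where multiconformer modeling is meaningful, and all metrics
mask on heavy atoms. This single-Gaussian model is a stated approximation,
not a reconstruction of any particular scattering-factor library: it
conserves electrons exactly (verified to 1% on padded grids in the tests),
is linear in occupancy, and is analytically checkable, which is what the
solver and the synthetic benchmark rely on. Atom densities are truncated at
4.5 Gaussian sigmas (≥ 99.9% of the integral), identically in the full-grid
and masked-point evaluation paths.

Per-ligand grids cover the conformer bounding box padded by 4 Å at spacing
min(d_min/4, 0.5 Å) — Nyquist-safe with bounded memory. Observed maps are
accepted as CCP4/MRC with orthogonal cells; axes are reordered to canonical
X, Y, Z on read and the origin is taken from the ORIGIN header words (start
indices otherwise). Structure-factor inputs (MTZ) are not parsed; convert
to a real-space map externally. Map σ is computed as the rms deviation
about the map mean: for the crystallographic difference maps this tool
expects, the mean is ≈ 0 and this coincides with the plain rms, while for
the ligand-box synthetic maps it keeps the normalized density score
well-defined.

## Sampling

Conformers come from RDKit's ETKDGv3 distance-geometry embedding with
explicit hydrogens, followed by MMFF94 minimization, driven through four
constraint mechanisms:

- **fixed_terminal** — distance-bounds entries for every pair of degree-1
  heavy atoms pinned to the seed distance (±0.01 Å), re-enforced during
  MMFF94 with harmonic distance constraints; conformers violating the
  0.1 Å contract are rejected and re-drawn.
- **branch / long_chain** — coordinate locks (embedding coordinate map plus
  MMFF94 fixed points) on the core atoms / on side chains of > 30 atoms.
  Side chains are maximal connected acyclic heavy-atom subgraphs attached
  to a ring system (or to the graph-center atom of an acyclic ligand).
- **blob** — unconstrained draws recentered on the seed centroid and
  rejected unless every atom lies within the seed's maximal
  centroid-to-atom radius (a per-atom reading of the spherical confinement;
  stricter than constraining the centroid, and directly testable).
- **unconstrained** — toolkit defaults.

Unconstrained, fixed-terminal and blob draws are rigid-body aligned onto
the seed (all-heavy-atom Kabsch fit) so candidates are posed in the map
frame. Budgets are 5000 conformers below 25 heavy atoms and 7000 otherwise,
split evenly across the active strategies (remainder to the unconstrained
search); each constrained strategy may attempt up to 3× its allocation
before accepting a shortfall. The input conformer is always injected into
the candidate pool (tagged `input`), so a single-conformer fallback always
exists. Strategies run concurrently on up to five workers with per-strategy
derived seeds and order-stabilized assembly: the worker count can never
change the output. Every emitted conformer must re-derive the template
connectivity from its geometry (covalent-radius bond perception plus SMILES
bond-order assignment); failures are discarded.

Deduplication removes one member of every pair with in-place heavy-atom
RMSD < 0.2 Å — no superposition, since position in the map is meaningful.
The removal choice is uniform-random under the run seed, except that the
injected input conformer is protected. The optional flip search emits 3
base flips (180° about each principal axis through the centroid) plus
rotations of each base flip about its own axis by ±2…±10° in 2° steps (33
conformers); it is off by default because it is only appropriate when this
specific disorder is suspected.

## Occupancy solving

The relaxed QP `min ‖Aᵀω − b‖²  s.t. ω ≥ 0, Σω ≤ 1` is solved exactly:
without the sum constraint it is nonnegative least squares (Lawson–Hanson);
when the NNLS solution exceeds unit total weight, the simplex face is
active and the equality Σω = 1 is imposed through a heavily weighted
penalty row, sharpened geometrically until the KKT conditions of the
original problem hold to 1e-8. Non-convergence raises. Weights below 1e-4
are zeroed. Observed densities are rescaled by a least-squares factor
against the candidate mean density first, so residuals compare like with
like regardless of map units; the solution is invariant under joint
rescaling of map and candidates (tested).

Large pools are screened in batches of 300 candidates; batch survivors
(nonzero weight) are pooled and re-solved globally, restoring optimality
among survivors while keeping the Gram matrix bounded. Screen survivors
are enriched 25× by one-at-a-time rigid perturbations ({±5, ±10, ±15}°
about each principal axis, ±0.3 Å along each map axis). The enumeration is
deliberately one-at-a-time — no rotation×translation products — keeping the
expansion factor small; both grids are configurable.

Model selection solves the cardinality-constrained problem (ωᵢ ∈ {0} ∪
[t_min, 1], ≤ k nonzero) by exhaustive enumeration over all supports of
size ≤ k, each reduced to a ≤ k-variable QP solved exactly by active-set
enumeration (every variable free / at t_min / at 1, sum constraint active
or not, with primal and dual feasibility checked). With post-screen pools
and k ≤ 3 this is a few thousand tiny solves — well under a minute — and is
globally optimal by construction, which removes any need for an MIQP solver
dependency and lets the test suite compare it against an independent
SLSQP-based enumeration. Ties between supports break to the
lexicographically smallest index set, enumerated smallest-size first, for
determinism.

After selection: conformers below 0.1 occupancy are culled (never emptying
the model — redistribution of culled occupancy belongs to external
refinement, which is out of scope); altlocs A, B, C are assigned by
descending occupancy; in event-map mode occupancies are multiplied by
(1 − BDC) before writing, since an event map describes the bound fraction
only. Total occupancy may remain < 1 and is reported as-is.

## Validation metrics

**RSCC** is the Pearson correlation of observed and calculated density over
the footprint mask (all voxels within 1.5 Å of any ensemble heavy atom —
the first density shell; radius configurable).

**EDIA** for atom a sums over grid points p within 2r(a):

    EDIA(a) = Σ_p w(p,a) · o(p,a) · z(p)  /  Σ_{p: w>0} w(p,a),
    z(p)    = clamp((ρ(p) − μ)/σ, 0, ζ),   ζ = 1.2.

The truncation ζ and the zero floor are the defining features; the weight
and ownership forms are this package's own documented choices: r(a) is the
radius where the atom's Gaussian falls to 10% of its peak (element-, B- and
resolution-aware); w is a positive paraboloid 1 − (d/r)² inside r and a
negative lobe on (r, 2r] whose total mass is renormalized to 0.5× the
positive mass (the shell has ~7× the volume, so without renormalization the
excess-density penalty would swamp the support term); ownership splits a
positively claimed point equally among claiming atoms, and negative-shell
points count only where no atom claims them positively. Alternate
conformers of one ligand are scored each in its own conformer's context —
overlapping altloc copies of an atom must not split ownership of the same
density — and **EDIAm** combines all per-atom scores with an
occupancy-weighted power mean of exponent −2 (floor 1e-3 avoids the pole),
which punishes poorly supported atoms harder than an arithmetic mean; the
arithmetic mean is available via `exponent=None`. EDIA assumes spherical
atoms; beyond 2 Å resolution the package warns but proceeds.

**RMSD** is the plain in-place root-mean-square coordinate deviation over
the fixed atom order, without superposition.

## Synthetic benchmark

Four archetypes cover the canonical ligand-disorder classes: an asymmetric
aromatic ring flipped 180° about its attachment bond (2-ethylpyridine); a
linear alcohol displaced rigidly by ~0.8 Å; a phenyl ligand whose 4-atom
hydroxypropyl side chain shifts by a 120° torsion (sized so the branch
search applies, as intended for this class); and a 14-membered macrocycle
with a 4-atom branch whose attachment and terminal torsions both change.
Each A/B pair shares one topology, preserves template connectivity, and
differs by ≥ 0.5 Å RMSD (asserted at construction).

Truth maps are the occupancy-weighted two-conformer density with B-factors
inflated linearly with resolution, B = 15 + 20·(d_min − 0.8) Å², plus
i.i.d. Gaussian noise of standard deviation 0.05 · d_min · rms(clean map).
The linear B schedule and the noise constant emulate the loss of order and
signal at lower resolution; neither has a canonical literature value, so
both are explicit, configurable, and recorded in the manifest. Maps are
synthesized directly in real space — no structure-factor round trip and no
bulk-solvent term, which is irrelevant for the ligand-local footprint. The
full grid is 4 archetypes × 5 occupancy splits (0.50/0.50 … 0.90/0.10) ×
18 resolutions (0.8–2.5 Å in 0.1 Å steps) = 360 map/model pairs, each with
the two-conformer truth PDB and the A-only input PDB at occupancy 1.0.

What the generator does **not** emulate: a protein environment and its
density overlap with the ligand, bulk solvent, map-phase error and
series-termination effects, anisotropy, and crystallographic symmetry.
Passing the recovery tests therefore demonstrates the correctness of the
sampling/solving machinery under the stated density model, not performance
on experimental maps.

## Problem sizes in the test suite

The acceptance tests run the full pipeline on one archetype (the
torsion-shift ligand) at the 0.50/0.50 and 0.90/0.10 splits, d_min = 1.0 Å,
with a sampling budget of 400 conformers — ample for a 10-heavy-atom ligand
with three torsions, and the same machinery exercised by the full default
budget. Recovery at the even split lands within ±0.03 of the true
occupancies with the closest conformer ≈ 0.2 Å from the held-out truth; at
0.90/0.10 the alternate conformer falls below the t_min/cull thresholds and
is (correctly) not modeled, reproducing the detection-limit trend. Solver
equivalence is checked on 500 random instances against an independent
exhaustive oracle.

## Known limitations

- Single-Gaussian atoms: no explicit multi-Gaussian scattering factors or
  anisotropic B; absolute density scales are handled by least-squares
  rescaling rather than proper map scaling.
- Poses far from the input (full rebinding events) are outside the reach of
  the input-anchored searches; the perturbation stage only explores ±0.3 Å
  and ±15°.
- Occupancy refinement, real/reciprocal-space model refinement, and
  composite-omit/event-map generation are external to this tool.
- Covalent, multi-residue, and peptide ligands are unsupported; charged or
  tautomeric SMILES/structure mismatches raise rather than guess.
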