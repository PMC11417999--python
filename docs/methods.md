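# Methods

This note documents the models, conventions and numerical choices behind
sorbdock, in the spirit of the methods sections of simulation and analysis
packages: what each stage computes, which knobs matter, and what the
synthetic fixtures do and do not establish about real systems.

## Scope and data model

The pipeline covers the desk-side portion of designing a protein-amended
sorbent: building idealized material surfaces, docking a rigid protein
dimer onto them, refining externally predicted metal-ion sites, and mining
simulation trajectories for persistent metal-binding pockets.  Force-field
parametrization, explicit-solvent molecular dynamics, and ion-site
*prediction* are out of scope: trajectories and scored site lists are
inputs, read from multi-model PDB and tab-separated text respectively.

Coordinates are Ångström everywhere; energies are kcal/mol; the Coulomb
constant is 332.0636 kcal·Å/(mol·e²); 1 kcal = 4.184 kJ and 1 nm² = 100 Å²
in unit conversions.  A `Structure` is a column-wise atom table (id, name,
element, residue, chain, position, partial charge); hydrogens are carried
but every contact criterion operates on heavy atoms only.

## Material models are geometric stand-ins

The builders reproduce the geometric and compositional features the
docking and contact analyses depend on, not mineral crystallography:

* **Clay slab** — three sublayers (basal O/OH, octahedral Al/Mg, basal
  O/OH) on a square grid (default 3 Å pitch), with
  `round(mg_fraction · n_sites)` seeded Mg-for-Al substitutions
  (default 0.33, the Al₁.₆₇Mg₀.₃₃ octahedral composition).  Perimeter
  sites carry edge hydroxyls.  The pH 7 variant removes the edge protons
  and every other edge hydroxyl group, so it always has strictly fewer
  edge H and OH atoms than the pH 3 variant — the deprotonated-edge
  chemistry the pipeline needs, without titration modelling.  The Mg/Al
  atoms are recorded as the fixed (restrained) subset; the reference
  restraint strength, 0.956 kcal mol⁻¹ Å⁻² (= 400 kJ mol⁻¹ nm⁻²), is the
  worked example of the unit converter.  Partial charges are configurable
  per-element constants (O negative, Mg/Al positive); the docking score
  only needs a consistent electrostatic field.
* **Carbon sheet** — a hexagonal ring lattice (C–C bond 1.42 Å) in which
  `round(defect_fraction · n_rings)` rings (half-up rounding, so 1 % of
  350 rings gives 4 defects) are drawn at seeded random positions and
  redrawn as 5- or 7-membered rings inscribed in the same footprint with
  the bond length preserved along the new ring.  Defect polygons do not
  share vertices with their neighbours; ring identity is kept as explicit
  metadata, so the hexagonal/non-hexagonal census is exact by
  construction and bonded degrees (from ring edges) stay in {2, 3}.  The
  pronounced curvature of highly defective carbon is available as an
  optional sinusoidal out-of-plane displacement (default amplitude 0);
  fullerene-fragment reconstruction is deliberately not attempted.

## Docking

Each round: center the protein over the material's x–y centre at height
`z_offset` (default: material half-thickness + protein bounding radius
+ 5 Å, and an error below that sum, where the bodies could overlap),
rotate it 90° about a uniformly random unit axis (normalised Gaussian
triple) around its own centre, then settle.  The order — translate, then
rotate about the protein's centre — is fixed; for a centered protein it
does not change the pose distribution.

**Settling** replaces constrained energy minimization with exact
rigid-body translation-only descent: the analytic gradient of the
interaction energy with respect to a whole-body translation is followed
with backtracking (step halved on any energy increase or non-finite
value, stop below 10⁻³ Å; accepted steps grow 1.2× up to twice the
initial step, default 0.5 Å, capped at `max_steps` iterations).  Because
the protein moves only as a whole, internal geometry is preserved to
machine precision — the purpose a "best-fit" integrity restraint serves
in a force-field minimizer — and the final energy can never exceed the
initial one.  Small-angle rotational refinement is intentionally left
out of the default path to keep the descent's guarantees trivial to
state; the pose archive stores the full transform so external refiners
can be applied downstream.

**Scoring.**  The interaction energy is the pairwise inter-entity sum of
12-6 Lennard-Jones (Lorentz–Berthelot combination over per-element ε/σ
tables; the shipped table is generic and configurable) and Coulomb terms
within a 12 Å cutoff, with no intra-entity contributions — hence additive
over sub-entities and symmetric in its arguments.  The second scorer is a
distance-binned heavy-atom pair potential (weights per distance bin,
zero outside the binned range) standing in the consensus where a
knowledge-based potential would sit; the shipped default table is a
shallow attractive well peaking in the 3–4 Å bin and both edges and
weights are user-replaceable.

**Consensus.**  The k = 5 lowest poses by each scorer are ranked 1..k
(competition ranks — tied scores share a rank, so fully degenerate
energies delegate the choice to the other scorer); a pose in both lists
scores the sum of its ranks, a pose in one list takes a k + 1 penalty for
the missing list, and the lowest total wins with ties broken by lower
interaction energy, then lower round index.  The k + 1 penalty for
single-list poses is a convention choice; it keeps a pose that one scorer
loves and the other merely misses competitive with mid-rank consensus
poses.  Campaigns derive every round's seed from one master seed
(`numpy.random.SeedSequence`), making the whole campaign bit-reproducible.

## Ion sites

The greedy exclusion filter visits sites in descending score order (ties
broken by input order and logged) and keeps a site iff it lies ≥ 6.5 Å
from every *already-kept* site — the reading of pairwise exclusion that
maximises the kept set, and provably the fixpoint of "drop any site with
a higher-scored kept neighbour in range" (the test suite checks this
equivalence exhaustively on small sets).  Harmonization adds a Pb site
(carrying the Cd score, origin `harmonized`) at every Cd position with no
Pb site within the match radius (default: the 6.5 Å exclusion radius, as
no separate value is established); it is idempotent and can only grow
the Pb set, guaranteeing equal coverage of Cd-only pockets.  Random
placement is rejection sampling with a default 3.0 Å minimum gap from
the existing complex and between ions.

## Trajectory analysis

All analyses drop the first `equilibration_frames` frames (default 30 of
100, i.e. a 30 ns extra equilibration at 1 frame/ns) and use the
inclusive heavy-atom contact criterion: two entities interact in a frame
iff some heavy-atom pair is ≤ 5.0 Å apart ("within" is read as
inclusive; the boundary case is asserted in the tests).  Minimum-image
distances are used only when a periodic box is supplied (100 Å cubic is
the conventional default in the CLI's scope).

* **Contact probability** — per-residue contact indicators, aggregated as
  100 × events / (residues × analyzed frames); per-chain mean bound
  residue counts are always emitted alongside because the aggregate can
  mask chain asymmetry.  The residue-type decomposition (positive R/H/K,
  negative D/E, polar T/S/Q/N, other) is normalized to sum to 100 % over
  contact events.
* **RMSD** — protein backbone (N, Cα, C).  Mode 1 superposes each frame
  optimally (Kabsch, proper rotation enforced) onto the initial frame;
  mode 2 uses no protein alignment (for materials that move freely a
  material-atom fit is applied to the whole frame first; restrained clay
  needs none); mode 3 is mode 2 against the unaligned arithmetic mean of
  the analyzed backbone frames (the natural definition where none is
  established).  Mode 1 ≤ mode 2 frame-by-frame is asserted as an
  invariant, and mode 1 is verified against an independent closed-form
  superposition oracle to 10⁻⁶ Å.
* **Trajectory selection** — competition ranks ascending in mean RMSD and
  descending in contact percent, lowest summed rank wins (ties: lower
  RMSD, then lower index).
* **Binding modes** — per ion per frame, exactly one of
  protein-and-material, protein-only, material-only, unbound; the four
  percentages over ions × frames sum to 100.
* **Pocket mining** — pocket identity is per ion (the evolving residue
  neighbourhood of one ion), not per residue set.  A frame is
  pocket-present iff ≥ 1 protein residue is in contact with the ion;
  ion–material contact neither qualifies nor disqualifies a frame, since
  the bridging binding mode explicitly combines both.  A pocket is
  reported iff occupancy ≥ 0.60 (inclusive) *and* the last analyzed frame
  is pocket-present; member residues need ≥ 0.50 (inclusive) membership
  over pocket-present frames.  Residue sets may span both chains.  Fewer
  than 10 analyzed frames triggers a warning, not an error.
* **Cross-system report** — rows are minimal observed residue sets;
  pockets whose sets are supersets of a row's core join that row with the
  extra residues shown in parentheses (in the row label as the union, and
  attributed per system in the cell), which reproduces the
  core-plus-parenthetical table convention.

## Synthetic fixtures and what passing tests show

The generator builds coarse chains (N, Cα, C plus a side-chain centroid,
Cα pitch 3.8 Å on a loose helix; defaults 2 chains × 162 residues,
matching the dimer the pipeline targets, with residue names overridable
per index so specific pockets like D129/D130/E131 can be planted at the
right positions).  Pocket residues are relocated onto a 3 Å sphere around
a per-ion anchor far from the rest of the system; the ion sits at the
anchor in a seeded random ⌈occupancy × analyzed frames⌉ subset of frames
(the last frame forced or forbidden by flag) and is parked ≥ 40 Å away
otherwise.  The margins — contacts planted at cutoff − 1 ≈ 3–4 Å,
non-contacts at ≥ cutoff + 2 Å — make each planted condition robust to
Gaussian coordinate noise up to σ ≈ 0.5 Å with per-condition flip
probability well under 1 %; at σ = 0 round-trips are exact.

These fixtures validate the *statistics*: thresholds, normalizations,
rank rules, frame bookkeeping.  They say nothing about force-field
realism, solvent effects, or whether a real trajectory exhibits the
planted behaviour — conclusions about a real system still require real
simulations, for which this package is only the analysis layer.

## Problem sizes and numerical conventions

Default campaign size is 1,000 rounds; the verification suite runs the
full campaign on a ~500-atom dimer against a 40-ring sheet (descent step
1 Å, ≤ 40 steps), which keeps a double campaign — run twice to prove
bit-reproducibility — around a minute on one core.  Pocket-recovery
checks use 100 trajectories of 100 frames (30 equilibration) over
occupancies {0.55, 0.65, 0.80} and both last-frame flags; oracle
agreement checks use 1,000 random site sets (≤ 12 sites) and 1,000
random score tables.  Protonation uses strict `pH < pKa` (deprotonated at
equality) against a textbook default table (ASP 3.9, GLU 4.1, HIS 6.0)
with per-residue overrides for site-specific shifts; empirical pKa
calculation is out of scope, so the default table is a stand-in, not a
reconstruction of any particular protein's shifted values.

## Known limitations

* Material builders are not INTERFACE-FF/crystallographic models; AC
  defect patches do not share bonds with neighbouring rings, and clay
  tetrahedral silicon sheets are not represented explicitly.
* The docking energy is a generic LJ/Coulomb field intended for *ranking*
  poses, not for energetics; no periodic electrostatics, no flexibility.
* The second scorer is a configurable binned potential, not a published
  knowledge-based potential; the consensus architecture, not the table,
  is the tested contract.
* Trajectory reading is multi-model PDB out of the box; binary formats
  plug in through the `TRAJECTORY_READERS` registry but none is bundled.
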