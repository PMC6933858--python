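# Methods

## The analysis model

A druggability simulation surrounds the target protein with drug-fragment
probes at roughly one probe per twenty waters. Two statistics of probe
binding matter for druggability: the *strength* of interactions at a locus
(enthalpic, captured by occupancy enrichment and inverse-square contact
scores) and the *recurrence* of interactions over time (entropic, captured
by frequency of occurrence). `probesite` computes both on a frame-by-frame
basis after rigidly superposing every frame onto a reference structure
(least-squares Cα fit; the rotation is solved with
`scipy.spatial.transform.Rotation.align_vectors` and verified in the tests
against an independent Horn-quaternion oracle). All distance criteria use
heavy atoms, with one deliberate exception noted below.

## Grid occupancy and hot spots

Space is discretised on a cubic lattice of edge 0.5 Å anchored at the
origin of the reference frame, so voxel addressing is reproducible across
runs. Per frame, a probe copy counts as protein-associated iff at least one
of its heavy atoms is within 2.5 Å of a protein heavy atom; its heavy-atom
centroid then increments one voxel of its probe type's grid. The grid is
sparse and unbounded — a centroid outside the initial region simply extends
the bounding box.

Counts become free energies by inverse Boltzmann:

    ΔG(v) = −RT ln( count(v) / expected_count ),   RT = 0.596 kcal/mol at 300 K.

`expected_count` is the uniform-background expectation: the probe type's
total protein-associated visits divided by the number of accessible voxels
(bounding box minus voxels containing a protein heavy atom in any frame).
Using the union over frames for the protein-excluded region slightly
enlarges it relative to a single-frame definition, which is conservative
for enrichment.

**Count floor.** At 0.5 Å voxel size the expected count per voxel is far
below one for any realistic trajectory length, so a voxel visited *once*
already carries a nominal enrichment of 10²–10³ and would pass any
reasonable energy cutoff while carrying no statistical weight. Candidate
voxels therefore must satisfy both ΔG ≤ `hotspot_energy_cutoff`
(−1.0 kcal/mol default) *and* `count ≥ min_voxel_count` (default 3, a
Poisson-noise floor). Without the floor, every stray bulk-probe contact
becomes a hot spot and hot-spot maps of noise-only trajectories percolate
into spurious sites.

Candidate voxels are merged greedily in descending occupancy (ties broken
by lexicographic voxel index, for determinism): each joins the nearest
existing hot spot of its probe type closer than 5.5 Å, else seeds a new
one. Hot-spot centers are occupancy-weighted centroids; ΔG is recomputed
from the summed count. The same 5.5 Å figure is used by default for
hot-spot → site linkage, but the two are independently configurable
(`merge_distance`, `site_link_distance`) because merging and clustering are
distinct operations and a user may legitimately want them decoupled.

## Druggable sites and the site score

Hot spots of all probe types are pooled and single-linkage clustered
(pairwise distance strictly below the linkage cutoff); clusters of at least
six hot spots become druggable sites, smaller clusters are discarded. Sites
are ranked by ascending site score (most negative first).

The site score is this package's own convention: the sum of ΔG over the
best (most negative) *connected* subset of at most `max_combination_size`
hot spots (default 7, roughly the number of fragment-sized groups a
drug-like molecule can present), where connectivity means consecutive
hot spots within the linkage distance. The cap keeps scores comparable
across sites of very different sizes, mimicking what a single drug-like
molecule could actually engage. For sites of ≤25 hot spots the optimum is
found by exhaustive enumeration of connected induced subsets; larger sites
fall back to a deterministic greedy best-first expansion from every seed
hot spot. Both paths are deterministic given the site.

## Residue binding scores

For probe type *p* and residue *i*,

    s(p, i) = Σ_frames Σ_pairs 1/d²   [Å⁻²],

summing every heavy-atom pair (residue atom, probe atom) within 4 Å —
all qualifying pairs in a snapshot count, so a probe wedged against a
residue scores more than one grazing it. Backbone atoms are included.
Profiles are computed per chain and never pooled across chains of a
multimer. The high-affinity threshold is 500 Å⁻², applied *strictly*
("above 500"), and is calibrated for 10,000-frame (40 ns at 4 ps) runs; the
score scales linearly with frame count, so shorter trajectories need a
proportionally lower threshold (exposed as a flag, never rescaled
automatically).

Site residues are the high-affinity residues with at least one heavy atom
(in the *reference* coordinates — site geometry is defined in the reference
frame) within 8.0 Å (inclusive) of at least one same-probe hot-spot center
of the analyzed site.

## Interaction frequency

A frame counts toward a (residue, probe-type) interaction iff some probe
copy of that type satisfies both criteria: (a) a heavy atom within 4 Å of a
residue heavy atom, and (b) *any* atom — hydrogens included — within 1.5 Å
of a hot-spot center of that probe type at the site. The heavy-atom /
all-atom asymmetry is intentional: contacts are a heavy-atom notion, while
hot-spot occupancy asks whether the probe's envelope covers the locus. A
frame counts at most once per pair regardless of how many copies qualify
(snapshots are counted, not instances). Frequencies are counts over all
frames; the top set keeps pairs at or above the 10% cutoff (inclusive).
Ordering is deterministic: frequency descending, then binding score
descending, then (chain, residue number, probe name).

## Snapshots and pharmacophore models

Co-occurrence frames are the intersection of the top-set records'
qualifying-frame sets. Conformer similarity is the mean pairwise Cα RMSD
over those frames *without* per-pair refitting — the conformers already
share the reference frame by construction, and refitting would understate
the spread relevant to screening. One pharmacophore model is emitted per
snapshot (users are encouraged to compare them all), each feature a 1 Å
sphere at its anchor: a named heavy atom (donors/acceptors, ionic nitrogen)
or the centroid of a named heavy-atom subset (hydrophobic and aromatic
groups, carboxylate). Built-in templates: isopropanol → donor(O) +
hydrophobic(C centroid); acetamide → donor(N) + acceptor(O); isobutane →
hydrophobic(C centroid); imidazole → aromatic(ring centroid) + donor(N1) +
acceptor(N3); acetate → negative-ion(carboxylate centroid) + one acceptor
per carboxylate oxygen (both oxygens are chemically equivalent acceptors);
isopropylamine → positive-ion(N) + donor(N). Hydrophobic/aromatic anchors
use the centroid rather than a specific carbon — for quasi-symmetric
fragments the centroid is the orientation-robust choice. Directional
(vector) features are not emitted; the Pharmit export uses point features
only, as a `{"points": [...]}` session JSON with the fixed kind → name map
(hbond_donor → HydrogenDonor, etc.). Parsing the JSON back reproduces the
model exactly. `pec50_from_ec50` (−log₁₀ of a molar EC50) is provided for
annotating screening hit tables.

## Synthetic fixtures

The generator emulates only the statistical structure the analysis relies
on, not physics: a rigid two-helix poly-alanine fold (ideal helix, 5 heavy
atoms per residue) with small Gaussian backbone jitter (σ = 0.1 Å default)
and an optional random rigid motion per frame that superposition must undo;
planted binding events placed by seeded rejection sampling inside distance
windows (protein contact 1.75–2.45 Å, target-residue contact ≤ 3.8 Å, one
atom within 1.0 Å of the planted center) so that a bound frame *provably*
registers in the occupancy grid, the binding-score profile and the hot-spot
assignment; and bulk probes re-placed uniformly every frame (no dynamics —
only occupancy statistics matter downstream). A planted druggable site is a
ring of six events, one per probe chemotype, 2.2 Å apart: per-type voxel
merging then yields one hot spot per chemotype and pooled clustering yields
one ≥6-member site. Multiple sites are kept >16.5 Å (three merge
distances) apart. Everything recoverable is recorded in a manifest whose
expected values (bound-frame sets, contact frames, per-residue scores) are
computed by direct loop-level code independent of the analysis modules, so
manifest-vs-pipeline comparisons are genuine oracle tests. Fixture probes
carry heavy atoms only; the hydrogen-sensitive criterion (b) is exercised
by hand-built ensembles in the unit tests.

What passing on fixtures does **not** show: real trajectories have
correlated frames, conformational change, periodic-boundary effects (input
is assumed pre-wrapped and whole-molecule; no unwrapping is performed),
partial occupancies across rotameric states, and probe–probe competition.
The fixtures validate the bookkeeping and the statistics, not force-field
realism.

## Problem sizes and numerical conventions

The test suite and the acceptance script use 300-frame fixtures for
hot-spot recovery (20 seeds, 1–3 sites), 2,000 frames for the
frequency-estimation check (planted f = 0.3, binomial 3σ band), 1,000
frames where binding scores must clear the 500 Å⁻² threshold, and a
50-frame, ~500-protein-atom, 30-probe random fixture for brute-force oracle
equivalence (1e-9 relative). Distance cutoffs are inclusive (≤) except the
score threshold (strictly >) and the two linkage distances (strictly <,
"within a distance less than"). Boundary cases at 500 Å⁻², 10%, 8.0 Å and
1.5 Å are pinned by constructed just-inside/just-outside tests. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (config, seed) pairs give
byte-identical fixture files and pipeline outputs (tables iterate in sorted
order, floats are formatted at fixed precision, provenance records contain
no timestamps).

## Known limitations

- The druggable-site score is a stand-in convention (connected ΔG sum,
  capped); it ranks sites sensibly but its absolute scale is only
  "comparable to" a binding energy.
- No probe–probe correlation, residence-time, or enthalpy/entropy
  decomposition.
- Trajectory formats: DCD (with PSF or PDB topology) and multi-model PDB
  only; frames must be pre-imaged.
- The 500 Å⁻² threshold is length-calibrated; the package does not rescale
  it automatically for shorter runs.
- Virtual screening itself (Pharmit submission, docking minimization) is
  out of scope: the package emits the Pharmit input and annotates results.
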