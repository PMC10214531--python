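# Methods

`xlmodel` implements the computational chain that turns chemical
cross-linking mass spectrometry (CLMS) identifications into a
coarse-grained conformational ensemble of a multi-chain protein complex,
together with the structural analytics used to interrogate such an
ensemble. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic test systems do and do not show.

## Cross-link restraints

A cross-linking reagent covalently tethers two reactive residues. An
identified residue pair therefore bounds the Cα–Cα distance of the pair
by the reagent's maximal spacer length plus a tolerance (default 10 Å)
that absorbs side-chain lengths and backbone-position uncertainty:

    threshold(linker) = spacer_length + tolerance

A link whose Cα–Cα distance in a structure exceeds this threshold is
*violated* by that structure; a distance exactly at the threshold counts
as satisfied (the violation condition is a strict inequality). Five
reagent chemistries are shipped as editable configuration
(`xlmodel/linkers.yaml`): amine-reactive BS3 (spacer 11.4 Å) and DSG
(7.7 Å), zero-length EDC (amine–carboxyl), KArGO (lysine/N-terminus to
arginine) and PDH (carboxyl–carboxyl). Reactivities and linker/mono
masses follow standard search-engine settings; spacer lengths for KArGO
and PDH are working defaults, clearly configuration rather than ground
truth, and every field can be overridden from a user YAML. N-terminus
reactivity is modelled as a pseudo-site on residue 1 of each chain.

Peptide-level identifications (pLink-style tables) are collapsed to
nonredundant residue pairs. A pair is retained iff records passing the
score filters (E-value < 0.001; an FDR column, when present, ≤ 5%) exist
in at least two distinct experimental replicates. Collapse is idempotent
and canonicalises unordered pairs by (chain, residue number).

Theoretical enumeration lists every residue pair a reagent could capture
on a given structure: one side α-reactive, the other β-reactive (either
orientation), Cα–Cα distance within the threshold. Overlap between two
reagents' link sets is reported union-based (|A∩B|/|A∪B|, so shared and
unique fractions sum to 1) with per-set fractions alongside, since both
conventions appear in practice.

## Representation and scoring

The complex is coarse-grained at one bead per residue, positioned at the
Cα. Residues named in the body specification form rigid bodies whose
internal coordinates are frozen from the input structure; all remaining
residues (loops, linkers, unresolved segments) are independent flexible
beads. A residue without a Cα is placed by linear interpolation between
its flanking anchors and flagged. Optionally, helix/sheet runs of ≥3
residues outside the named bodies are promoted to rigid bodies, unless
freezing the run would violate a cross-link internal to it.

A configuration (rigid transform per body plus free bead positions) is
scored by a sum of four non-negative flat-bottom harmonic terms:

* **cross-link**: Σ max(0, d − threshold)² / σ² over links (σ = 1 Å);
* **connectivity**: Σ max(0, d − d₀)² over consecutive-residue pairs not
  frozen inside one body, d₀ = 3.8 Å (the Cα virtual bond). Only stretch
  is penalised;
* **excluded volume**: Σ max(0, rᵢ + rⱼ − d)² over non-bonded pairs not
  frozen inside one body. Bead radii come in three side-chain volume
  classes: 2.3 Å (G/A/S/C), 2.8 Å (default), 3.2 Å (bulky);
* **membrane**: squared out-of-slab displacement of designated
  transmembrane residues for a flat slab normal to z with half-thickness
  15 Å (all slab parameters configurable).

The flat-bottom forms are a design choice: the terms are named by the
scoring model but their functional forms were open, and flat-bottom
harmonics make the native basin exactly zero-penalty, which keeps the
planted-recovery oracles interpretable. Scoring is invariant under global
rigid motion except for the membrane term, which defines the absolute
frame when present.

## Sampling

Single-temperature Metropolis Monte Carlo (optional temperature
schedule as (fraction-of-run, T) breakpoints). Moves are gaussian body
translations (σ = 2 Å), body rotations about a random axis (σ = 10°),
and bead translations (σ = 1 Å). Bodies and beads each receive half of
the proposed moves regardless of their counts, because bead counts
usually dwarf body counts and would otherwise starve pose sampling. The
starting configuration is randomized (uniform body orientations,
gaussian displacements) unless a start is supplied. If a calibration
window passes with no acceptance, move sizes are halved with a logged
warning. Trajectories are bit-reproducible per seed; after a burn-in
fraction of the run (default 20%) every k-th configuration is recorded
with its score breakdown, and the best-scoring configuration is
appended last.

Ensembles are clustered by single linkage on pairwise superposed bead
RMSD at a distance threshold; this equals connected components of the
"RMSD ≤ t" graph, which the tests exploit as an independent oracle.
Cluster precision is the mean RMSD of members to the cluster centroid
(the member minimising summed RMSD), mirroring the centroid rule used
for atomic model ensembles (heavy-atom scope there, bead scope here).

Convergence of two independent-seed runs is assessed by (i) a two-sample
KS test on total scores, (ii) a chi-square contingency test on
joint-cluster populations, and (iii) the sampling precision: the
smallest clustering threshold at which the two runs' cluster populations
are statistically indistinguishable (p > 0.05). Runs are flagged
converged when both tests pass.

## Ensemble analytics

* **PCA over rigid-body mass centers.** Models are aligned to the first
  model on an anchor selection (for a receptor–G-protein system, the
  transmembrane bundle); the feature vector concatenates the mass
  centers of designated bodies (unit residue masses — a deliberate
  simplification; atomic masses change little at one bead per residue).
  K-means with a fixed seed labels the PC-space clusters (3 by default).
  The "PCA centroid" is the model nearest the ensemble mean in PC1–PC2
  (a cluster-medoid alternative is exposed); the "ensemble centroid"
  minimises the summed pairwise RMSD.
* **Per-component RMSD** against a reference structure after a single
  anchor superposition per model (no per-component refit), summarised as
  median and IQR.
* **Helix rotation angle**: after anchor superposition, the helix axis
  is the first principal axis of the helix Cα cloud, oriented N→C to
  avoid 180° aliasing; the reported angle is the arccos of the axis dot
  product, in [0°, 180°].
* **Satisfaction percentages** per linker type and model, with
  min–max–mean across the ensemble; range endpoints are attained by
  actual models.

## Interface contacts

A cross-interface residue pair is a contact when it could form at least
one of: hydrogen bond (min N/O/S heavy-atom distance ≤ 3.5 Å), salt
bridge (min charged-group distance ≤ 4.0 Å between K/R/H and D/E, with
group atoms K:NZ, R:NH1/NH2/NE, H:ND1/NE2, D:OD1/OD2, E:OE1/OE2),
hydrophobic (min apolar side-chain carbon distance ≤ 4.0 Å between
A/V/L/I/P/F/M/W, or any heavy atom within 4.0 Å of an aromatic ring
centroid of F/Y/W/H). All criteria are purely distance-based — no
hydrogens or angle terms — matching how such census criteria are used on
heavy-atom models. Histidine counts as positively charged. Main-chain
atoms participate by default; a side-chain-only scope supports
comparisons against mutagenesis, which probes side chains. Because the
question "how many contacts" admits three different tallies, the census
reports all three: unique residue pairs, unique (pair, type)
combinations, and (model, pair) incidences.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral point set (no RNG; 960
points and a 1.4 Å probe by default), element-keyed heavy-atom radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å …), hydrogens ignored, waters and
heteroatoms excluded by default. Buried surface area of a binary
interface is SASA(A) + SASA(B) − SASA(A∪B); half of it is the PISA-style
interface area, and both figures are always reported because published
values use either convention. Region-restricted interface areas sum the
per-residue side-A SASA loss over a region (e.g. an intracellular loop),
and disjoint regions add exactly to the side-A total. A point exactly on
a neighbour sphere is credited to the lowest-index atom, which makes the
degenerate coincident-atom case resolve to a single sphere's area.

## Synthetic test systems

The toy generator builds rigid bodies as ideal α-helices (1.5 Å rise,
100°/residue, 2.3 Å radius) placed compactly — two bodies at the spacing
distance, three on an equilateral triangle, four on a tetrahedron, more
on a ring — with seeded random orientations redrawn until all bodies
clear each other, emulating the packed subunits of a real complex.
Flexible linkers between consecutive bodies of a chain are relaxed by
L-BFGS under the same functional forms the sampler scores (bond stretch
plus clearance), so a generated complex is a low-energy configuration of
its own restraint set rather than an accidentally clashing one.
Sequences are drawn from a configurable residue-type mix rich in
reactive residues. An optional side-chain mode adds a CB atom and a
simplified terminal polar/charged atom per residue so contact and SASA
analyses have chemistry to work with.

Simulated cross-link sets draw true links uniformly from the feasible
(within-threshold) reactive pairs and false positives from
reactivity-compatible pairs beyond the threshold, so chemistry filters
cannot remove them trivially; truth labels are returned for calibration
checks, and satisfied fractions land inside exact binomial confidence
intervals of 1 − fpr by construction.

What the toys do not emulate: real side-chain packing and rotamers,
irregular secondary structure, atomic detail of interfaces, peptide
detectability biases in CLMS (real link maps are depleted at membrane
spans), and density-derived restraints. Passing the planted-recovery
tests therefore shows the estimator and sampler are correct and
calibrated on well-posed inputs; it does not certify accuracy on real
complexes, where restraint sparsity dominates the error budget.

## Problem sizes in the tests and acceptance script

The planted-recovery experiments use 2- and 3-body complexes of 10
residues per body at 12 Å body spacing with a reactivity-rich sequence
mix, giving roughly 150–200 zero-noise links pooled over all five
chemistries; with bodies small relative to the cross-link thresholds,
most feasible pairs span bodies and the pose is well determined (large
bodies bury most links inside a body, where they carry no pose
information, and recovery degrades accordingly — the sparse-restraint
regime real data live in). Two independent 50,000-step chains are run
per experiment under a 3 → 1 → 0.3 cool-down, only the cold phase
(final 35%) is recorded, and the two runs are pooled before clustering
at a 10 Å threshold, mirroring the standard two-run analysis protocol
of integrative modeling pipelines.
Calibration uses a 4-body, 160-residue complex and 200 BS3 links at
false-positive rates {0, 0.1, 0.5, 1}. SASA checks run at 960 sphere
points against closed-form sphere and spherical-cap areas. These sizes
were chosen so each oracle remains exactly computable; the pipeline
itself has no intrinsic size limits beyond O(n²) pairwise stages.

## Known limitations

* Upper-bound-only restraints leave a zero-score basin whose breadth —
  not sampling error — bounds how close a cluster centroid can sit to
  the planted truth; recovery precision degrades gracefully as links
  become slack or sparse (the same effect that limits real integrative
  models to tens of Å precision).
* The Monte Carlo engine is a single chain without replica exchange;
  multimodal restraint sets should be run with several seeds and checked
  with the convergence report.
* pLink report parsing expects a normalised tabular layout (documented
  in `parse_crosslink_report`); exotic report dialects need reshaping.
* FDR is treated as a per-record gate when a column is present; no decoy
  re-estimation is done.
* The contact rules are census criteria, not an energy model; they
  over-count relative to hydrogen-bond geometry checks that use angles.
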