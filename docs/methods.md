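# Methods

This note records the models, conventions, parameter choices and known
limitations behind the package, in the order a user meets them.

## Table format and validation

A table row is one curated measurement: complex (`<pdb>_<side1>_<side2>`),
mutation list (`<wtAA><chain><resnum><icode?><mutAA>`, comma-separated,
PDB numbering; an optional parallel list in cleaned numbering), wild-type
and mutant dissociation constants in molar, temperature in kelvin, the
experimental-method category, citation key, and optional kinetic
(k<sub>on</sub> M⁻¹s⁻¹, k<sub>off</sub> s⁻¹) and calorimetric
(ΔH kcal·mol⁻¹, ΔS cal·mol⁻¹·K⁻¹) observables. The delimiter (comma or
semicolon) is sniffed from the header and honoured on write; unknown
columns pass through untouched. Affinity cells accept scientific
notation, a leading `>`/`<` when only a limit could be measured, and a
non-binding marker (`n.b.` and variants), optionally with a detection
limit in parentheses. The wild-type column always describes the protein
in the PDB file, even when that protein is itself a mutant form.

Validation distinguishes recoverable anomalies (warnings: malformed
optional numerics, missing temperature, KD outside a configurable
(0, 10) M sanity window, fully duplicated rows) from row-fatal problems
(unparseable complex id, mutation string or mandatory affinity), which
drop the row *with* a reported issue — rows are never silently lost or
reordered. A missing mandatory column is a fatal configuration error.
Missing temperatures default to 298 K with a warning; annotation suffixes
like `298(assumed)` are preserved verbatim for round-tripping. The
"unique entry" key is (PDB id, unordered side partition, canonicalized
mutation set) — replicate measurements of the same state collapse onto
one key.

## Thermodynamics

ΔG = RT ln K<sub>D</sub> with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ (the value
matters only at the third decimal of ΔG); ΔΔG = ΔG(mut) − ΔG(wt), so
destabilizing mutations are positive. Entropy stays in cal·mol⁻¹·K⁻¹
exactly as tabulated; the single /1000 conversion lives in
`dg_from_enthalpy_entropy`. Per-entry completion derives K<sub>D</sub>
from k<sub>off</sub>/k<sub>on</sub> when the affinity column is not
exact, never overwrites a reported value, and flags disagreement between
independent routes beyond 0.2 kcal·mol⁻¹ (configurable; the scale of a
typical reported experimental error, ~0.25 kcal·mol⁻¹).

Qualified affinities are treated as K<sub>D</sub> intervals — exact
[k, k], `>` [k, ∞), `<` (0, k], non-binding [detection limit, ∞) — and
the ΔΔG interval endpoints that are finite become explicit bounds with
directions. When both sides are qualified in compatible directions a
bound is still emitted; incompatible directions yield none. This is the
deliberate answer to an open convention question: no derivable bound is
suppressed.

## Replicate aggregation and mutant cycles

Replicates (identical mutation key) are averaged in ΔΔG *before* cycle
construction — equivalently, the geometric mean of the K<sub>D</sub>
ratios. A state is quantified if at least one replicate is exact;
inequality/non-binding-only states are kept (ΔΔG absent) so cycles
containing them can be counted. Aggregation-before-enumeration is a
convention choice: published cycle counts on the real dataset do not
state theirs, so censuses can differ by a few cycles under alternatives
(per-entry vertices, median aggregation, same-temperature restriction);
the convention is isolated in `aggregate_ddg` so alternatives are a
one-line change.

A double cycle exists for every background S (|S| ≤ 1 by default),
mutation pair {A, B}, with states S, S∪{A}, S∪{B}, S∪{A,B} all present;
vertex energies are re-referenced to the background. ΔΔG<sub>int</sub> is
stored as ΔΔG(AB) − ΔΔG(A) − ΔΔG(B); the two path formulations
(ΔΔG<sub>aB→AB</sub> − ΔΔG<sub>ab→Ab</sub> and
ΔΔG<sub>Ab→AB</sub> − ΔΔG<sub>ab→aB</sub>) are algebraically identical
and agree to ~10⁻¹⁵ in floating point (association order differs).
Cycles mixing measurement temperatures are allowed but flagged.

Classification thresholds (configurable, defaults): additive
|ΔΔG<sub>int</sub>| < 0.5 kcal·mol⁻¹; a single mutation counts as
stabilizing below −0.2 and destabilizing above +0.2; a sign flip requires
both context energies beyond ±0.2, a ≥ 0.4 difference between them, and
an actual sign change. Positive epistasis sub-classes: synergistic (both
singles stabilizing), antagonistic (both destabilizing), otherwise mixed
— the mixed class is explicit rather than dropped, because the taxonomy's
pure classes do not partition the non-additive cycles. Negative epistasis
mirrors this. When both mutations flip, the flips necessarily share a
direction (the two mixed-direction systems of inequalities are
infeasible), giving the two reciprocal classes. "Same reference" means
all vertices share at least one citation.

Higher-order couplings use the inclusion–exclusion alternating sum
Σ<sub>T⊆M</sub> (−1)^(|M|−|T|) ΔΔG(T), which equals the recursive
with/without-background difference and is permutation-symmetric; the test
suite checks the equality against an independently written recursive
oracle for orders 2–4.

## Duplicate concordance

Pairs estimate systematic inter-laboratory error: two entries with the
same mutation key qualify when they differ in citation OR method
category (configurable to AND) — same-source repeats estimate precision,
not bias, and are excluded. Concordance thresholds: 1 kcal·mol⁻¹ on
δΔΔG, 0.5 on δΔlog₁₀k<sub>on</sub> and δΔlog₁₀k<sub>off</sub>, 3
kcal·mol⁻¹ on δΔΔH, 10 cal·mol⁻¹·K⁻¹ on δΔΔS, each over pairs where
both quantities exist. The report always prints the published
full-dataset percentages (84% of 1741; 80% of 704; 83% of 702; 61%/58%
of 62) beside the computed fractions: the published pair-eligibility
rule is ambiguous, so these are reproduction goals, not gates. Whether
multi-point mutation keys are paired is likewise unstated; this
implementation pairs any identical mutation set.

## Structures

Cleaning keeps the two chain groups of interest, renumbers their polymer
residues consecutively from 1 per chain (insertion codes and negative
numbers removed, with a bijective numbering map both ways), and retains
any water/heteroatom with a heavy atom within 5 Å of a chain of
interest, appended after the polymer residues of the chain they follow.
Alternate locations collapse to the highest-occupancy conformer (ties:
first encountered); hydrogens are ignored throughout. Cleaning is
idempotent. Interfaces use the symmetric 10 Å heavy-atom criterion.

SASA is Shrake–Rupley (probe 1.4 Å, 960 points/atom, Bio.PDB radii,
heavy atoms only); rASA divides by the Tien et al. (2013) theoretical
Gly-X-Gly maxima (unknown residue types use the table mean and are
flagged). Burial classes with threshold rASA = 0.25 (configurable):
ΔrASA ≤ ε → interior if rASA<sub>monomer</sub> < 0.25 else surface;
ΔrASA > ε → support if rASA<sub>monomer</sub> < 0.25, core if only
rASA<sub>complex</sub> < 0.25, rim otherwise. The suite program used to
produce the original annotations is not reproduced; classification
depends only on these coarse thresholds, so exact per-residue agreement
with distributed annotations is not guaranteed, only class-scheme
fidelity.

Numerical resolution: a fixed 960-point sphere sampling is not exactly
rotation-invariant. Measured on the toy slab structures, random rigid
rotations move total SASA by < 1% and per-residue rASA by < 0.01 on
average, with worst-case per-residue deviations of ~0.012–0.015 (a few
sphere points of one atom). Tests therefore assert the 1% total and
0.01 mean bounds plus a 0.03 per-residue cap; sub-quantization
per-residue agreement is not claimed. Residues with missing atoms are
classified from the atoms present and flagged.

## Homology

Alignment is global Needleman–Wunsch with affine gaps (BLOSUM62, open
10, extend 0.5) via Bio.Align.PairwiseAligner; ties break
deterministically by the engine's first optimum. Percent identity is
computed over aligned non-gap columns — note that this quantity exceeds
30% for many unrelated random pairs (gapped alignments align only the
similar stretches), which is precisely why the homology call is the
conjunction score > 50 AND identity ≥ 30%. The score threshold is a
calibration tied to this scoring scheme, not a portable constant: the
program that produced the original "> 50" is not reproduced, and raw
alignment scores do not transfer across substitution matrices and gap
penalties. Shared binding sites map one partner's interface positions
through the alignment; the overlap denominator is the smaller interface
set (configurable). Interaction clustering is the transitive closure
(single linkage, union-find) of the pairwise relation and is independent
of input order; cluster category labels are carried from manual
assignment only, never computed.

## Synthetic data

The generator emulates the gross statistics of curated mutation tables:
true ΔΔG ~ N(1.5, 2.0) kcal·mol⁻¹ (≈98% of draws inside the typical
[−3, 7] window, satisfying the ≥80% design target), clipped at ±9 so
mutant K<sub>D</sub> stays physically sane given wild-type K<sub>D</sub>
log-uniform between 10 pM and 100 nM; measurement noise N(0, 0.25)
applied in energy space (replicate scatter is quoted in kcal·mol⁻¹, so
noise belongs on the energy scale, not the K<sub>D</sub> scale); ~72%
single-point mutations, ~55% of them to alanine; kinetics emitted on 26%
of entries and calorimetry on 6% (both exactly consistent with the
entry's noisy K<sub>D</sub>); 3% inequality and 3% non-binding entries;
replicate counts 1/2/3 with probabilities 0.7/0.2/0.1 (non-binding
entries are not replicated — an identical contentless row would be
flagged as a duplicate); 15% of mutations re-measured by a second
laboratory (different citation and method) to create concordance pairs;
everything at 298 K; default seed 17, fully deterministic per seed.

Planted cycles draw (ΔΔG_A, ΔΔG_B, ΔΔG_AB) satisfying every inequality
of the requested epistasis class with a requested margin to spare
(default 0.1 kcal·mol⁻¹), verify themselves against the classifier, and
are emitted noiselessly so the margin guarantee survives into the table.
The feasible margin is capped per class (0.5/0.4 bounds for additive,
0.2 for classes needing a near-neutral single).

Toy complexes are two lattice slabs of planar five-atom alanine-like
residues (spacing 5.6 Å, chosen so a fully exposed lattice face exceeds
the 0.25 burial threshold while body-centred filler residues keep the
block interior probe-inaccessible). Chain A is an n×n four-layer block;
chain B a 3×3 two-layer block across a plane-to-plane gap (default 4 Å,
within the ~6.2 Å occlusion range of carbon + probe radii). The centre
residue of A's facing layer is recessed by 2 Å: mostly shaded by its
raised neighbours when unbound, sealed by B's central residue on binding
— a geometry-forced support residue. Bottom-layer residues are surface,
deep central residues interior, B-covered facing residues core, and the
edge-centre facing residues rim. Only residues whose class the geometry
forces carry ground-truth labels; with gaps beyond occlusion range the
facing layer's truth degrades gracefully to surface/interior. Realism is
not a goal — label-forcing geometry is; the toys have no side chains,
secondary structure, or chemical diversity, so passing label-recovery
tests demonstrates the classification logic, not performance on real
interfaces.

Homolog families mutate a per-family ancestral receptor (15% per-site
mutation rate → ~77% pairwise identity within a family, far above the
call thresholds) and keep a fixed 80% core of the ancestral interface
positions so pairwise overlap lands near 0.8, above the 0.7 clustering
threshold; ligands and cross-family receptors are independent random
sequences whose alignment scores fall far below 50.

## What the synthetic results do and do not show

Passing tests demonstrate: the record grammar round-trips; the unit
conversions and their algebraic identities hold; cycle enumeration finds
exactly the complete vertex sets; classification implements the stated
rule table (verified against an independent transcription on a 50³
grid); aggregation and concordance match their sampling-theory closed
forms; the geometric and alignment machinery matches brute-force
oracles. They do not show that real curated data will reproduce any
published census exactly — that depends on the real table (see the two
dataset-gated acceptance checks) and on unstated conventions documented
above as configuration.

## Problem sizes

Default test and acceptance runs use tables of ~300–2000 entries,
toy structures of ~1500 atoms, 100-seed planting sweeps, 50³
classification grids, 200 exhaustive-alignment pairs (lengths ≤ 8) and
2000-pair concordance samples — sizes chosen so the full suite completes
in well under a minute of compute per module while keeping every
statistical check at ≥3σ resolution.
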