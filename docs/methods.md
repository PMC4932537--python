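# Methods

## The model

The package operationalizes a general Ser/Thr-kinase pharmacophore as a
4-point, near-planar "rhomb": two hydrophobic (HYD) features on opposite
corners, one aromatic (ARO) feature on a third corner and one H-bond
donor or acceptor projection (PROJ) on the fourth, with the four sides
(HYD_a–ARO, ARO–HYD_b, HYD_b–PROJ, PROJ–HYD_a) constrained to 4.0–5.0 Å
in the default model and the two diagonals (HYD–HYD, ARO–PROJ) left
free.  A model is a set of four typed slots, six pairwise distance
ranges, a per-distance clustering tolerance τ and a planarity cap
(maximum RMS distance of the four matched points to their least-squares
plane).  "More or less planar" is operationalized as a 0.75 Å RMS cap;
it is configurable.  Matching is purely distance-based, so scores are
invariant under rigid motion and reflection; the chirality of a 4-point
arrangement is deliberately not distinguished.

## Compound fixtures and mass arithmetic

The 16-compound aminothiazole/aminopyrazole inhibitor series is shipped
as hand-transcribed SMILES stored beside the published IUPAC name, the
printed HRMS formula text and the printed calcd [M+H]⁺ value.  Masses
are always computed from the structure: monoisotopic masses use an
embedded isotope table (≥7 decimals per element), and
[M+H]⁺ = M + m(H) − mₑ, which reproduces every printed calcd value to
±0.0005 Da.  The printed formulas mix two conventions (neutral molecule
for the amide-series entries, [M+H]⁺ cation for the screening-series
entries) and two entries carry printed-formula typos whose printed
masses nonetheless match the named structures; the fixture table flags
those two entries and the structure is treated as ground truth.

## Conformer ensembles

Geometry comes from RDKit: one seeded ETKDGv3 distance-geometry embed
per molecule supplies bond lengths, angles and a single ring pucker.
Diversity is generated by a deterministic torsion grid (default 60°
steps) over the acyclic rotatable bonds, enumerated exhaustively when
the full grid fits within the trial cap (`iteration_limit`, default
1000) and otherwise sampled from the grid with a seeded generator
capped at that limit.  The grid is laid relative to the embedded
dihedrals so staggered minima are preserved.  Candidates with any
heavy-atom pair more than three bonds apart closer than 1.8 Å are
discarded; survivors are deduplicated keep-first (clash score, then
enumeration index) by best-fit heavy-atom RMSD (Kabsch superposition)
at the 0.25 Å limit and capped at `conformation_limit` (default 500).
Kept conformers are then relaxed with MMFF94 (UFF fallback) under the
configured force tolerance (`rms_gradient`, default 0.005) and
iteration cap (`mm_iteration_limit`, default 500), and re-deduplicated,
since minimization can collapse neighbouring grid points onto the same
minimum.  Everything is deterministic given the seed; ensembles are
byte-identical across reruns.

Limitations: ring puckers are not enumerated (one embedded pucker per
molecule), there is no conformer energy ranking beyond the clash score,
and macrocycles are out of scope.

## Feature perception

Fixed rules, applied in order on each conformer (hydrogens explicit):

* ARO: centroid of every aromatic SSSR ring.
* HYD: centroid of every saturated ring (all ring bonds single) with at
  most one heteroatom; centroid of every aromatic five-membered ring
  containing sulfur — thiazoles act as hydrophobes in this model and
  therefore carry both an ARO and a HYD feature at the same centroid;
  centroid of every acyclic sp³-carbon component that includes a
  terminal carbon and spans ≥ 2 carbons (so n-propyl and isopropyl count
  once, a lone methyl does not).
* DON_PROJ: a point exactly 2.0 Å beyond each N–H/O–H hydrogen along
  the X–H vector.
* ACC_PROJ: a point 2.0 Å from each acceptor atom along the idealized
  lone-pair bisector (the negated mean of its unit bond vectors).
  Acceptors are two-coordinate aromatic N (pyridine-type), trivalent
  non-aromatic N whose lone pair is not delocalized (anilines and
  amide/amidine N are excluded — this keeps, e.g., 2-aminothiazole's
  acceptor on the ring N only), carbonyl O and dialkyl ether O.
  Degenerate (near-linear) environments produce no projection.

The projection distance of 2.0 Å sits inside the canonical 1.8–2.2 Å
H-bond range and is configurable.  Halogens carry no feature.  Features
of identical type closer than 0.5 Å are merged at their centroid to
avoid fused-ring double counting.  Feature counts are invariant under
atom reindexing and rigid motion; positions transform covariantly.

## Elucidation

All quads — combinations of two distinct HYD, one ARO and one
projection feature, canonically ordered so d(HYD_a, ARO) ≤ d(HYD_b, ARO)
with ties broken by the PROJ distances — are encoded as 6-distance
signatures in the fixed pair order (ab, aA, aP, bA, bP, AP).  Quads
whose planarity RMS exceeds the cap are dropped, as are quads with any
two corners closer than 1.0 Å: a thiazole contributes coincident HYD
and ARO centroids, and a "rhomb" with two corners at the same point is
a 3-point model in disguise.

Signatures are leader-clustered in the fixed (molecule, conformer,
quad) enumeration order: a quad joins the first existing cluster whose
leader it matches within τ (default 1.0 Å) on every component, else it
founds a new cluster.  The winning cluster maximizes the number of
distinct molecules covered, with ties resolved toward the smaller mean
per-component spread and then the earlier leader; its per-component
[min, max] over members become the model's distance ranges.  Coverage
below `min_coverage` (default 0.7 — a general model should cover most
but not necessarily all actives) raises a no-consensus error that
reports the best coverage found.  Greedy leader clustering was chosen
over k-means-style alternatives because it is deterministic,
order-stable under the fixed enumeration, and trivially auditable.

A known behaviour of this coverage-then-spread selection on a
*congeneric* active set: many clusters tie at maximal coverage, and the
tie-break favours the most rigid scaffold-core quad, which can place
the PROJ corner adjacent to one hydrophobe (a kite) rather than
opposite the aromatic corner (the rhomb).  With a structurally diverse
active set, scaffold-specific rigid clusters cannot reach high coverage
and the truly common arrangement wins; with a single chemical series
the elucidated ranges describe that series' core geometry instead.  The
fixture-series run in `scripts/acceptance.py` reports both the winning
cluster's side bounds and, as a diagnostic, the best coverage reachable
by any strictly rhomb-shaped (all side upper bounds ≤ 5 Å) cluster.

## Screening and enrichment

Matching a conformer's features to a model enumerates type-compatible
slot assignments with branch-and-bound pruning on partial deviations
(deviation = maximum distance outside a range; 0 inside), returning the
minimal-deviation assignment with lexicographic feature-index
tie-break.  An independent pure-exhaustive implementation
(`match_bruteforce`) serves as the oracle in tests.  A hit has
deviation ≤ 1e-9 and planarity within the cap.  Libraries are ranked
hits-first by ascending deviation with molecule-id tie-break;
assignment-free molecules rank last.  Enrichment factors use
EF(f) = (actives in top ⌈fN⌉ / ⌈fN⌉) / (A/N).

## Synthetic libraries

`planted_geometry_library` builds labelled feature-point libraries
directly in feature space: actives place the four typed points at the
corners of a planar square rhomb of side s (default 4.5 Å, the middle
of the model window), add i.i.d. Gaussian positional noise σ per
coordinate, and apply a random rigid motion; decoys either drop one
required corner or pull the projection corner out until two sides reach
s + 3 Å.  Everything is driven by one seed.  Note the noise convention:
per-corner noise σ makes each pairwise *distance* fluctuate with
standard deviation σ√2, so e.g. at σ = 0.3 the closed-form probability
that a noisy active still fits the 4–5 Å box is only
(2Φ(0.5/(σ√2)) − 1)⁴ ≈ 0.34 — the tests assert this closed form rather
than a high hit rate.  Planted-recovery checks read the model's side
estimate as the midpoint of the recovered range; the endpoints are
extreme order statistics whose spread grows with the number of actives
and are only required to bracket the planted value.

What the generator does not emulate: real conformational flexibility
(each synthetic molecule has one feature set), feature-perception noise,
correlated noise between corners, and decoys that are chemically
similar but geometrically subtly wrong.  Passing the planted-recovery
and enrichment suites therefore demonstrates the correctness of the
elucidation/matching machinery, not screening performance on real
libraries.

## Problem sizes and numerical choices

The fixture-series elucidation protocol uses 50-conformer ensembles per
molecule (all other sampling settings at their defaults), which keeps a
full 16-compound elucidation under two minutes on one core while leaving
the cluster landscape stable across seeds.  Distances are float64
throughout; Kabsch residuals below 1e-12 are clamped to zero; the
three-point-collinear planarity case returns zero with a degeneracy
flag.  Seeds derived for per-molecule embedding are reduced modulo
2³¹ − 1 (RDKit's seed width).
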