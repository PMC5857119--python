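# Methods

## Scope and data model

`iondist` analyzes monoatomic ions in protein structures supplied as
PDB-format text. Parsing (via gemmi) keeps, per file, the first model
only; hydrogens and deuteriums are dropped; alternate locations are
resolved to the highest-occupancy conformer with ties broken by the
lexicographically smallest altLoc indicator; waters and polyatomic
hetero groups are excluded; residues with non-canonical names (MSE and
the like) are skipped with a log entry. Ions are single-atom HETATM
groups whose chemical-component name appears in a curated table
(alkali and alkaline-earth metals, first-row transition metals, Cd,
Hg, and the halides); ferrous and ferric iron are pooled into one
label `Fe2+/3+` because the oxidation state is rarely assignable from
a crystal structure. Unknown monoatomic species are logged and
excluded. The calcium component `CA` cannot collide with alpha-carbon
atoms because ions are recognized by residue name on single-atom
hetero groups, never by atom name.

These parsing rules (model 1 only, altLoc policy, exclusion of
modified residues) are this package's own choices where the field has
no single convention; each is deterministic and logged so a user can
audit what was skipped.

## Local frame

For each residue: origin = geometry center (GC, unweighted mean of all
heavy atoms, including O and OXT when present); x̂ = unit vector from
GC to the backbone nitrogen; ŷ = unit vector of y = c − (x̂·c)x̂ where
c points from GC to the carboxyl carbon; ẑ = x̂ × ŷ. A residue
missing N or C raises `FrameUndefined`; ‖y‖ below 1e-6 Å raises
`FrameDegenerate`; both are skipped upstream with a log entry rather
than silently. φ uses the two-argument arctangent (the naive tan⁻¹(y/x)
is quadrant-ambiguous and would scramble the octant statistics), and a
query at the exact origin maps to (0, 0, 0) with a flag. Octants are
indexed 4·[x<0] + 2·[y<0] + [z<0], with zero counting as non-negative
so boundary points are assigned deterministically.

Local coordinates are invariant under any proper rigid motion applied
to residue and ion together; the test suite checks this to 1e-9 Å over
1000 random transforms, which is the property that justifies pooling
pairs across structures.

## Pair statistics

A pair is (residue, ion) with GC distance ≤ cutoff (default 6 Å,
boundary inclusive). The statistics database (StatsDB) accumulates:
residue counts N(aa) over *all* parsed residues (not only paired
ones), ion counts N(ion), pair counts N(aa, ion), octant-resolved
counts N(aa, ion, octant), radial histograms (0.1 Å bins over
[0, cutoff]), angular histograms (18 θ × 36 φ bins), a pooled 3-D
density grid per amino acid (12³ voxels over [−cutoff, cutoff]³), and
side-chain/backbone counts. StatsDBs merge additively, and merging
equals accumulating the concatenated input. Serialization is a single
JSON document.

Side-chain preference: backbone atoms are {N, CA, C, O, OXT}, side
chain the rest. R = N_s/(N_s + N_c) counts ions within
r_a = cutoff − max(r_c, r_s) of the side-chain and backbone centers,
where r_c, r_s are the distances from those centers to the whole-
residue GC; an ion within r_a of both centers increments both counts.
R is undefined for glycine and flagged (not zeroed) when no ion is in
range.

Probabilities for scoring derive from the count tables with add-α
smoothing (α = 1 by default, exposed): the joint over the full
(20 × ions) or (20 × ions × 8) grid is (N + α)/Σ(N + α), and p(aa),
p(ion) are marginals of the smoothed pair joint — making the ratio
p(aa, ion)/(p(aa)p(ion)) a pointwise-mutual-information-style
quantity and guaranteeing no candidate is annihilated by a single
unseen combination.

## Ion-type prediction

The environment of a query position is the set of residues with
buildable frames whose GC lies within the cutoff. Pair mode scores a
candidate ion by Σ over neighbors of log p(aa, ion) − log p(aa) −
log p(ion); octant mode replaces p(aa, ion) by p(aa, ion, o) where o
is the octant of the query in that neighbor's frame. The octant joint
carries the ion index even though the motivating formula is often
written without it — without the ion index the quantity cannot
discriminate candidates. p(ion) is applied once per neighbor, matching
the product form; this shifts scores by an ion-dependent constant
proportional to the neighbor count, which can affect rankings between
sites of different coordination number and is therefore documented
here as a modeling choice. An empty context scores every candidate 0
(prediction degenerates to a tie at the prior). Ranking is by
descending score with average ranks for ties; the uniform-random
baseline over 11 candidates is rank 6.

Evaluation consumes labelled sites (structure with the ion removed,
ion position, true label) and reports per-ion mean rank, population
standard deviation, and the cumulative rank distribution.

## Amino-acid clustering

Each amino acid's pooled (all ion types — pooling per-ion first is
possible but not the default) 3-D density is normalized over the
voxels whose centers lie inside the cutoff ball. Similarity between
two amino acids is the maximum Pearson correlation between one density
and rotated copies of the other over a deduplicated 15°-step zyz Euler
grid (~6.4k rotations; configurable). Rotation of a voxel map is
nearest-neighbor pullback of bin centers: exact for the 24 cube-group
rotations (which the grid always contains), accurate to voxel
resolution otherwise. A constant or empty map correlates at 0 by
convention. The 20×20 similarity matrix is clustered by
complete-linkage on distance 1 − similarity via
`scipy.cluster.hierarchy.linkage`; merge heights are the quantity of
record (they match a naive O(n³) agglomeration exactly in the tests),
and the tie-break among equal-height merges is scipy's internal
deterministic order. Dendrograms export to Newick with ultrametric
branch lengths (node height = merge height / 2).

This explicit rotation search replaces FFT-based rotation functions
used for the same quantity at archive scale; at 12³ voxels the direct
search is transparent, testable and fast enough (the full 20×20 matrix
takes well under a minute on one core).

## Synthetic fixtures

Templates supply the correct heavy-atom inventory (standard PDB atom
names and elements) for all 20 amino acids. Backbone N, CA, C, O use
standard bond lengths and angles (N–CA 1.458 Å, CA–C 1.524 Å, C=O
1.231 Å, N–CA–C 110°, CA–C–O 121°); side chains are *schematic* —
a planar zig-zag with 1.53 Å steps in name order, not real rotamers or
closed rings. This is deliberate: every frame-based quantity depends
only on the GC and the N and C atoms, so schematic side chains change
nothing the package measures while keeping templates short and exact.
The carbonyl-O geometry matters for glycine, whose GC is built from
four atoms only: the standard in-plane anti placement keeps the
orthogonalized y vector at ~0.46 Å, conditioning the frame well enough
that PDB coordinate quantization (±0.0005 Å) propagates to sub-1e-3
errors in recovered (r, θ, φ).

Fixtures place template residues under arbitrary proper rigid
transforms and plant ions at chosen (r, θ, φ) in a chosen residue's
frame (or at absolute positions). Random fixtures sample r ∈
[2.5, 5.5] Å, |cos θ| ≤ 0.9, and can enforce a margin from octant
boundary planes when the octant itself is the ground truth being
recovered through 3-decimal PDB text. Generation is deterministic
given a seed; fixture specs round-trip through JSON.

What the fixtures emulate: rigid-body placement and exact local-frame
geometry. What they do not: realistic conformational variation,
crystallographic noise beyond coordinate quantization, occupancy or
disorder, or realistic ion-site chemistry. Passing the closure tests
therefore demonstrates correctness of the coordinate pipeline, not
biological fidelity of any learned preference.

## Planted-model simulation

`PlantedIonModel` defines the study conditions for parameter-recovery
experiments. Each of the 11 default candidate ions prefers one amino
acid (probability 0.7; remaining mass uniform over the other 19) and
one octant (probability 0.8; remaining mass uniform over the other 7);
radii are uniform on [2.5, 5.5] Å and directions uniform within the
sampled octant with a 0.15 margin on the unit-vector components.
Consecutive ions *share* their preferred amino acid but differ in
preferred octant, so composition-only (pair-mode) scoring saturates
near rank 1.5 on the shared partners while octant mode can reach
rank 1 — the simulation separates the contribution of angular
resolution from raw signal strength by construction. Training uses
isolated residue–ion pairs on a 30 Å grid (500 per class in the
acceptance experiment); held-out sites have 4 neighbors arranged so
the query position carries the planted local coordinates in every
neighbor's frame. These values were fixed as the simulation's design;
they are not tuned per run.

## Numerical and formatting choices

Degeneracy tolerance for frame axes 1e-6 Å; probability tables
strictly positive for α > 0; log-domain scoring (monotone, underflow-
free); TSV output at six significant digits for byte-stable reruns;
radial histogram's last bin absorbs r = cutoff exactly. Group-summary
means use the arithmetic mean over group members, skipping undefined
entries (glycine's R). The published survey tables bundled in
`reference_data` are inputs for the grouping summaries; one printed
group average (the polar-uncharged pair-count column) is not the
arithmetic mean of its printed cells under any grouping of the 20
amino acids, so the summaries reproduce only the three pair-count
means and four percentage means that are arithmetically consistent.

## Known limitations

mmCIF input, assembly/symmetry expansion and hydrogen placement are
out of scope; non-redundant subsets are consumed as precomputed ID
lists, not computed; whole-archive statistics (absolute abundances,
archive-scale prediction ranks) require the full PDB and are not
reproduced here; ion *location* prediction (as opposed to type) is not
attempted; nucleic-acid statistics are excluded.
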