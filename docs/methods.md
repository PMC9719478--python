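# Methods

This note documents the models, conventions, numerical choices and
limitations behind capsidkit. It is the reference for anyone auditing
why a quantity is computed the way it is.

## Icosahedral group and axis setting

The 60 proper rotations of the 532 point group are generated from one
five-fold generator (through the vertex (0, 1, φ)/‖·‖, φ the golden
ratio) and the two-fold rotation about *z*, and closed by breadth-first
multiplication. Generation-by-closure is self-verifying: the
construction fails loudly unless exactly 60 operators emerge, and the
test suite checks all 3600 pairwise products, inverses and determinants.

The axis setting places icosahedron vertices at the cyclic permutations
of (0, ±1, ±φ), i.e. **two-fold axes on x, y and z** — the common
cryo-EM "I" convention. Nothing downstream depends on the setting; the
operator file export and `RotationGroup.convention_tag` document it, and
any other setting is obtained by conjugating with the inter-setting
rotation.

Axes are recovered from the operators themselves (rotation angle from
the trace, axis from the dominant eigenvector of the symmetric part),
deduplicated over antipodes; the census must be 6 five-fold, 10
three-fold, 15 two-fold or an error is raised. Orbits deduplicate
images at relative tolerance 1e−6 — far below any physical spacing,
safely above double-precision noise — and enforce
|orbit| × stabilizer = 60.

## Caspar–Klug lattice construction

The planar hexagonal lattice uses basis a₁ = (1, 0),
a₂ = (1/2, √3/2) (unit capsomer spacing). The face triangle has corners
0, h·a₁ + k·a₂ and its 60° rotation; lattice points with barycentric
coordinates in [0, 1] are mapped through the barycentric frame of an
icosahedron face and projected to the unit sphere, then orbit-expanded
and deduplicated to the full capsid. The census — 12 pentamers (corner
points) and 10(T−1) hexamers — is asserted, not assumed.

Axis-coincidence tests (`hexagon_on_axis`) are geometric: a hexamer
counts as "on" a two-/three-fold axis when its centre direction is
within 1e−6 of the axis (exact lattice points land on axes to machine
precision). The suite verifies the geometric tests agree with the
arithmetic rules (two-fold ⇔ even T; three-fold ⇔ 3 | T) for every
canonical lattice with T ≤ 148.

Handedness follows the convention h > k > 0 ⇒ *dextro*; canonical
enumeration emits h ≥ k (the dextro representative), with *laevo*
lattices available by mirroring. Class, axis flags and hexamer
complexity are mirror-invariant (tested).

## Hexamer complexity C^h

Each hexamer is the Voronoi hexagon of its lattice point (circumradius
1/√3, corners at 30° + 60°k). On the folded capsid a hexagon may be
crossed by icosahedron edges; each crossing is a **bend chord**. Chords
are found by developing the surface isometrically around the hexagon
(no cone point can fall inside it, as vertices sit a full lattice
spacing away) and unfolding neighbor triangles across every crossed
edge; chord–hexagon intersections use exact polygon clipping with a
minimum chord length of 1e−3 lattice units, so exact tangencies (e.g.
the T = 3 hexamer, whose hexagon edges lie on the fold lines) do not
register as bends.

A hexamer's **shape signature** classifies its chord set:

* folds *anchored at a hexagon corner* — a triple point of the tiling,
  where the fold line is pinned to a lattice-symmetric feature — are
  recorded combinatorially: `B` (fold along a hexagon edge), `CC`
  (corner-to-corner, tagged with the corner separation), `CE`
  (corner-to-edge);
* folds crossing only *edge interiors*, whose geometry varies
  continuously with (h, k), are recorded metrically: endpoint
  coordinates canonicalized over the hexagon's 12 planar symmetries and
  rounded to 4 decimals.

C^h is the number of distinct signatures over the capsid (every hexamer
orbit has a representative in one closed face triangle, which is what
is enumerated).

This operationalization is **calibrated**: the literature quantity it
reproduces is defined in a source whose exact formula is not available
here, so the anchor values are the ground truth — C^h(3,3) = 4 exactly,
C^h ≤ 2 for T ∈ {3, 7, 9, 13, 21, 25} and C^h > 2 for
T ∈ {12, 19, 27}. The corner-anchored/edge-interior distinction is the
geometric discriminator that satisfies all anchors simultaneously: in
the (4,1) lattice both bent trimer positions (types 1 and 2, at edge
offsets s and 2s with s = √3/(2√T)) are corner-anchored and collapse
into one shape class, whereas the two bent classes of (3,2) cross edge
interiors at different offsets and remain distinct. Purely metric or
purely combinatorial classifications provably cannot satisfy both
anchors (both lattices present the same flat/bent@s/bent@2s pattern).
C^h values outside the anchor sets (e.g. C^h(2,2) = 4) follow from the
rule and are reported as computed, not tuned.

## Architecture atlas and the size model

`allowed_for_trimeric_mcp` rejects a lattice with reasons
`hexagon-on-two-fold` (trimer on a two-fold position) and/or
`complexity` (C^h above the threshold, default 2). T = 1 is rejected
with `no-hexamers`: an all-pentamer shell offers no trimer position at
all, so the allowed series starts at T = 3.

Relative size uses the only parameter-free scaling: surface area ∝ T,
hence D_rel = √(T/T_ref) and V_rel = D_rel³ (T_ref = 21 by default).
Under this law V(13)/V(21) = (13/21)^{3/2} ≈ 0.49. Volume models that
account for shell thickness or interior packing give larger ratios; no
such model is adopted because each would introduce an arbitrary
parameter. The atlas reports the sqrt-law values only.

## pT = 21 bookkeeping

Trimer types for (4,1): type 3 is the 20-copy orbit on the three-fold
axes; of the three 60-copy orbits, type 1 is the orbit closest (angular
distance) to the five-fold axes, type 2 the closest to the two-fold
axes among the rest, type 4 the remainder. Distances are rounded at
1e−9 before comparison and ties break by orbit id — (4,1) has no true
ties, but the contract stays total. The asymmetric-unit census follows
from counting: (T−1)/2 MCP monomers, T−1 β-sandwiches, one penton
domain, T building blocks; even T raises (the arithmetic twin of the
two-fold exclusion).

## Sub-particle geometry

Euler angles (rot, tilt, psi) are intrinsic ZYZ in degrees;
R = R_z(rot)·R_y(tilt)·R_z(psi) maps capsid-frame to laboratory
coordinates (z the imaging axis). The local alignment A is the minimal
rotation taking the site direction to +z (180° about x for the
antipodal direction — a documented tie-break); it fixes two of three
degrees of freedom, and the in-plane angle is whatever the minimal
rotation yields, deterministically. Sub-particle orientation is
R·G·Aᵀ; offsets are the in-plane projection of R·G·(r·v) in pixels plus
the parent origin; z_shift is the out-of-plane component in Å.

Special positions deduplicate by 3D position (tolerance 1e−6 × radius),
*not* operator index, which is what yields 20 sub-particles per capsid
on three-folds and 12 on five-folds against 60 at general positions.

Defocus adjustment: by default a positive z_shift (toward the electron
source) *decreases* both defocus values; a flag flips the convention,
since metadata dialects disagree. Over a complete orbit the adjustments
sum to zero because the orbit centroid is the capsid centre.

Symmetry relaxation (`relax_candidates`) composes an orientation with
in-plane rotations 360k/n about the local axis; candidate sets are
closed under the Cn generator and identical (as sets) for orientations
differing by a Cn rotation.

Composite stitching maps each component's local-frame points back
through the inverse alignment, translates to the site, replicates over
the site orbit, and resolves overlaps by mask precedence: points of an
earlier component inside the spherical mask (diameter in pixels ×
pixel size) of a *later* component are dropped. Listing penton before
spike therefore carves the spike-mask region out of the penton, the
same effect as subtracting the spike mask from the penton mask when
compositing maps. The extract→stitch round trip is exact to < 1e−6 Å.

## Prophage scanning

Locus calling consumes homology hit tables (TSV/HitRecord); it never
runs a search. A locus is a rep-initiator hit followed — in reading
orientation, so right-to-left on the minus strand — by an MCP hit on
the same strand within `max_gap` (default 10 kb). Competing pairings
resolve greedily by smallest gap then leftmost coordinate
(deterministic, input-order independent). Boundaries start as hit
extents; loci outside the expected size range (default 5–10 kb, after
the observed 6.0–8.4 kb prophage sizes) are flagged, never dropped.

Dif detection scans both flanks for windows of the configured geometry
(default 11-nt XerC arm + 6-nt central hexanucleotide + 11-nt XerD arm
= 28 nt; configurable, since reported sites differ in how flanking
bases are attributed) whose palindrome score — fraction of non-spacer
positions base-pairing with their mirror — reaches `min_score`
(default 0.8). Upstream/downstream candidates pair only at sequence
identity ≥ `min_pair_identity`; the best pair maximizes summed
palindrome score, ties broken by tightest bracketing.
`attach_dif_sites` widens the scan flank so the pair can bracket a
prophage of up to 10 kb around the hit extents (hits cover only two
genes, not the element), and snaps locus boundaries to the inner dif
edges. Circular genomes are handled by linearization at a chosen
origin; coordinates are 1-based inclusive on the linearized sequence,
0-based only inside the code.

Conservation: per-column sum-of-pairs identity over non-gap residue
pairs, z-normalized across columns (zero-variance alignments map to
all-zero scores). The exact formula behind published conservation
colorings is not reproducible from available sources; z-scoring matches
their signed ranges, and score ranges on real data remain
data-dependent. The column map drops columns gapped in the reference
row. Structure mapping writes scores into the PDB B-factor column
(sentinel −9.99 for unmapped residues, stated in a REMARK), exact to
the format's 0.01 precision. Logo matrices report per-column base
frequencies and information content 2 − H bits, without small-sample
correction.

## Synthetic data

All generators draw from a single `numpy.random.default_rng(seed)`
stream and are bit-reproducible. Defaults are the study conditions:
particle defoci uniform in 0.1–2.2 µm at 1.24 Å/pixel with orientations
uniform over rotations (normalized Gaussian quaternions); host genomes
i.i.d. at the requested GC; the implanted cassette is 7642 nt at 30.5%
GC with rep-initiator → MCP → spike ORFs (rep near the start, MCP close
behind, spike near the end, mirroring the family's synteny) and one
28-nt perfect-palindrome dif copy immediately outside each cassette
end. Synthetic ORFs are coordinate-marked random sequence, not
codon-realistic — ORF prediction is out of scope and hits are supplied
as truth tables. Families mutate a cassette with uniform substitutions
(optionally gamma-distributed per-site weights, mean 1, emulating
site-specific conservation) and geometric indels (mean 3 nt), with the
truth alignment maintained by edit bookkeeping.

What the generators do **not** emulate: micrograph images, noise and
CTFs; realistic codon structure or regulatory signals; evolutionary
models beyond substitutions and indels; compositional heterogeneity of
real bacterial genomes. Passing tests therefore demonstrate the
geometry/bookkeeping and detection logic, not detection power on real
genomes, where repeat content and diverged elements will matter.

## Problem sizes and test design

The suite verifies group closure by brute force (3600 products), the
axis-rule equivalence for all T ≤ 148, orbit–stabilizer for 1000 random
directions, sub-particle count laws at full study scale (6501- and
2351-particle tables), caller precision/recall on 20 noise-free
genomes of 40 kb, the dif empirical null on 20 random 20-kb genomes,
and conservation recovery on a 60-member, 200-column family (Spearman
≥ 0.9 against the generating weights; 60 members gives the column
statistics enough power that the bound holds across seeds). These sizes
keep the whole suite under ~20 s while exercising every count law at
the scale the quantities are defined at.

## Known limitations

* C^h is a calibrated operationalization (above); values outside the
  anchor sets carry the rule's, not a published, authority.
* The point models are pseudo-atom site models; they do not reproduce
  capsid faceting ratios (face-to-face vs vertex-to-vertex distances)
  or atomic structure, and the membrane shell is a sampling of a
  spherical slab, not a bilayer model.
* No image-domain operations whatsoever: no extraction, CTF handling,
  signal subtraction on pixels, refinement, FSC or B-factors.
* The prophage caller requires both a rep and an MCP hit; elements with
  a missing or diverged copy of either gene are invisible to it, so no
  census of real genomes should be read off the synthetic recall.
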