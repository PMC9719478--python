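# capsidkit

Tools for the geometry and comparative genomics of small icosahedral
virus capsids built from **pseudo-hexameric trimers** of double
jelly-roll (DJR) major capsid proteins — the architecture of
lipid-containing phages such as PM2, FLiP and their ssDNA relatives.

It is aimed at structural virologists and phage genomicists who want to

* enumerate and classify Caspar–Klug capsid architectures and test which
  ones a trimeric building block can actually realize,
* derive localized-reconstruction sub-particle tables (orientations,
  offsets, defocus gradients, symmetry relaxation, composite stitching)
  from cryo-EM particle metadata, and
* find integrated prophages of this virus family in bacterial genomes,
  together with their flanking *dif* (XerC/XerD) recombination sites, and
  map sequence conservation onto capsid protein structures.

Everything runs on synthetic, seeded inputs generated by the package
itself; no micrograph or database access is needed.

## The model in brief

A Caspar–Klug lattice is indexed by integers *(h, k)* with triangulation
number *T = h² + hk + k²*; the shell has 12 pentamers on the five-fold
vertices and *N = 60(T−1)/6 = 10(T−1)* hexamer positions. Lattices fall
into class 1 (*k = 0*), class 3 (*h = k*) and the handed class 2
(*h ≠ k*, *h > k > 0* taken as *dextro*).

When the hexamer positions are occupied by **trimers** (each monomer
contributing two jelly rolls, so a trimer is pseudo-hexameric), two
constraints prune the list of feasible architectures:

1. **Two-fold exclusion** — a three-fold object cannot sit on an
   icosahedral two-fold axis. Geometrically this strikes every even *T*
   (4, 12, 16, 28, …).
2. **Hexamer complexity *C*ʰ** — the number of distinct hexamer
   *shapes* (classified by how the icosahedron's fold edges cross each
   hexagon; see `docs/methods.md`). Architectures needing more than two
   shapes (T = 12, 19, 27, …) are disfavored.

The surviving series starts *T* = 3, 7, 9, 13, 21, 25 — with *pT* = 21
*dextro* the smallest architecture observed for DJR capsids with an
internal membrane. For *pT* = 21 the asymmetric unit holds 10 MCP
monomers (20 β-sandwiches) in four trimer types (peripentonal type 1,
two-fold-adjacent type 2, type 3 on the three-fold, type 4 between)
plus one penton domain: 21 quasi-equivalent building blocks.

For localized reconstruction, a capsomer site **v** (unit vector, radius
*r* Å) expands under the 60 icosahedral rotations *G* into sub-particles
with orientation *R·G·Aᵀ* (particle orientation *R*, minimal rotation
*A* putting the local symmetry axis on *z*), in-plane offsets from the
projected site position, and defocus shifted by the out-of-plane
component. Sites on three-/five-fold axes deduplicate to 20/12
sub-particles per capsid.

## Worked example

Architecture atlas up to *T* = 28 (`capsidkit atlas --tmax 28 --out atlas.tsv`):

```
h  k  T   class  handedness  n_hexagons  hex_on_2fold  hex_on_3fold  Ch  allowed  reasons              D_rel   V_rel
1  0  1   1      achiral     0           False         False         0   False    no-hexamers          0.2182  0.0104
1  1  3   3      achiral     20          False         True          1   True                          0.3780  0.0540
2  0  4   1      achiral     30          True          False         1   False    hexagon-on-two-fold  0.4364  0.0831
2  1  7   2      dextro      60          False         False         1   True                          0.5774  0.1925
3  0  9   1      achiral     80          False         True          2   True                          0.6547  0.2806
...
4  1  21  2      dextro      200         False         True          2   True                          1.0000  1.0000
```

Reading the *T* = 21 row: the (4,1) lattice is class 2 *dextro*, has 200
hexamer (trimer) positions, a hexamer on the three-fold axis (hence a
trimer type with shared symmetry), needs only *C*ʰ = 2 hexamer shapes,
and passes both trimer-placement constraints. `D_rel`/`V_rel` are the
diameter and volume relative to the *T* = 21 shell under the
parameter-free surface-area scaling *D* = √(T/T_ref), *V* = D³.

Sub-particle expansion of a synthetic 6501-particle table at the
three-fold trimer site:

```sh
$ capsidkit simulate particles --n 6501 --seed 1 --out particles
INFO particles n=6501 out=particles.star
$ capsidkit subparticles --star particles.star --site trimer3 --radius 315 --out trimer3_subs.star
INFO subparticles n=130020 site=trimer3 out=trimer3_subs.star
```

130,020 = 6501 × 20: a site on a three-fold axis keeps 20 of the 60
symmetry copies after special-position deduplication (a generic trimer
site gives 390,060 = 6501 × 60; a five-fold vertex 78,012 = 6501 × 12).

Five-fold symmetry relaxation candidates for one sub-particle
orientation (`capsidkit relax --rot 10 --tilt 20 --psi 30 --n 5`):

```
0   10.0000  20.0000  30.0000
1   10.0000  20.0000  102.0000
2   10.0000  20.0000  174.0000
3   10.0000  20.0000  -114.0000
4   10.0000  20.0000  -42.0000
```

The prophage side: `capsidkit simulate genome --length 30000 --seed 4
--out sim` writes a host genome with an implanted, *dif*-flanked 7642-nt
cassette plus its truth hit table, and `capsidkit scan-prophage --genome
sim.fasta --hits sim.hits.tsv --out loci.gff3` recovers the element with
its two 28-nt palindromic dif sites as GFF3 features.

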