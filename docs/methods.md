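# Methods

`dnanma` builds procedural three-dimensional models of finite-size DNA tile
assemblies — 12-tile rings and the 60-tile three-point-star (3PS) buckyball
— reduces them to a mass-weighted chemical elastic network (MWCENM), solves
for vibrational normal modes either directly or through a
symmetry-constrained reduction (SCENM), and classifies the low-frequency
mode shapes into a ring / cage / tile motion taxonomy.  This note records
the model, its assumptions, the parameters that matter, and the design
choices made where the published descriptions leave the geometry open.

## Structure construction

**B-form geometry.**  Duplexes are generated slot by slot on an ideal
B-form lattice: rise 0.34 nm/bp, nominal twist 34.3°/bp (10.5 bp/turn),
C1'–C1' separation 1.05 nm across a pair.  Each nucleotide is a stylized
heavy-atom template (backbone P/OP1/OP2/O5'/C5'/C4'/O4'/C3'/O3'/C2'/C1'
plus the base ring) with hydrogen masses folded into their parent heavy
atoms, so template masses sum exactly to the standard residue compositions
(internal dT = 304.20 amu).  Watson–Crick edge sites of the two bases face
each other at 0.29 nm.  Base atoms carry small (±0.015–0.08 nm)
propeller-like out-of-plane offsets: a perfectly coplanar stylized base
admits exact inextensional mechanisms (zero-frequency flexes of dangling
sticky-end bases) that real, three-dimensional bases do not have.

**Rings (R1/R2).**  A ring is 12 congruent tiles: an inner and an outer
duplex circle built as true arcs (per-bp frames rotated about the ring
axis) joined by radial bridge duplexes.  Arc bp counts follow from the
designed diameters: R1 inner 10 bp/tile (13 nm), outer 21 bp/tile (29 nm
including the duplex envelope); R2 inner 31 bp/tile (40 nm), outer
41 bp/tile (55 nm).  Within a tile window the helical twist is rounded to a
whole number of turns (e.g. 36°/bp over a 10-bp window) so both the arc and
the helix phase close seamlessly at tile boundaries.  Tiles hybridize
through 4-nt sticky overhangs on both arcs (the complementary strand is
offset by the overhang length, so four base pairs per arc form across every
interface).  Open-form rings carry the 8-nt single-stranded domain in the
outer arc.  R2 rings are 12 composite tiles (unit + connector segments, two
bridges per tile at ±7.5°).

**Bridge–arc junctions.**  The published schematics do not resolve the
crossover geometry, and the junction model controls the softest ring modes.
Each bridge strand end is anchored by covalent springs to the arc
nucleotides at angular offsets −2/0/+2, with bead pairs chosen nearest the
ring plane.  The anchors spread along the arc tangent, so in-plane swing of
a bridge stretches them (stiff, as crossovers hold helices together in the
tile plane) while out-of-plane rocking about the tangent line is
second-order (a compliant hinge).  This is the only junction variant, of
roughly a dozen examined, that leaves exactly six zero modes while keeping
tile-plane rigidity; looser anchoring reintroduces zero-frequency pivot
mechanisms or low-lying bridge rattles.

**Three-point-star tile and cages.**  The 3PS tile is three 19-bp duplex
arms from a 1.3 nm hub, tethered by 5-nt single-stranded T-loops, each arm
ending in a palindromic 4-nt sticky overhang (purine-terminal, e.g. TGCA,
so the dangling 3' base is a four-bead, three-dimensional cluster).  The
hub radius puts adjacent arm ends in van der Waals contact: without that
contact the in-plane tweezer pair falls below out-of-plane bending,
inverting the tile taxonomy.  The buckyball places 60 tiles at
truncated-icosahedron vertices (edge length 16.2 nm, cage diameter ≈86 nm,
matching the reported ~80 nm scale); a vertex there joins two hexagons and
one pentagon and has no threefold site symmetry, so assembly arms aim at
the actual neighbor-edge midpoints rather than exact 120° directions.
Overhang helical phases are chosen analytically so that the two
single-stranded tips meeting at an edge midpoint form an exact duplex; with
all 60 tiles identical, palindromic overhangs are forced by the symmetry.
A tetrahedral 12-tile "mini ball" (truncated tetrahedron, V−E+F = 2 with 4
triangles + 4 hexagons) serves as a desk-scale topology fixture.

**Validation.**  Every built model is checked as the structures are checked
during construction: all Watson–Crick H-bond site distances must lie in
0.25–0.35 nm, sticky-end pairing counts per interface must equal the
overhang design, and no non-bonded atom pair may come closer than 0.25 nm.
Pairs within two covalent bonds through the duplex ladder or a designed
junction are bonded environment and excluded from the clash scan.

## Coarse graining (MWCENM)

Each nucleotide is represented by P, C4' and C1' on the backbone plus three
(pyrimidine) or four (purine) base atoms on the glycosidic/Watson–Crick
edge — A: N9/N1/N6/C2, G: N9/N1/O6/N2, C: N1/N3/N4, T: N1/N3/O4 (a
configurable table).  5'-terminal nucleotides are synthesized without a
phosphate by default and contribute no P bead.  Every remaining atom's mass
is lumped onto the nearest representative within its own nucleotide; the
assignment is computed once per template in local coordinates, so it is
identical for every copy regardless of placement and conserves mass
exactly.

Springs are typed by chemical bond with constants in the 1:10:100 ratio:
van der Waals 7 N/m for all bead pairs within the 0.8 nm cutoff, hydrogen
70 N/m between the two matched Watson–Crick site pairs of every base pair
(including hybridized sticky ends), covalent 700 N/m along the backbone
chain (P–C4'–C1'–glycosidic N, inter-nucleotide C4'(i)–P(i+1)), between all
base-bead pairs of one base (the base ring is a rigid covalent unit), and
at designed junction linkages.  Ion (70) and disulfide (700) types exist in
the table but are unused for DNA.  Where a pair qualifies for several
types, the strongest bond wins — one spring per pair, rest length equal to
the built distance.

## Normal mode analysis

The pair potential ½Σk(‖x_i−x_j‖−L_ij)² linearized at the built geometry
gives the anisotropic-network Hessian: each spring contributes k·êêᵀ
blocks.  An independent finite-difference oracle of the pair potential pins
this form in the tests.  With the diagonal lumped-mass matrix, modes solve
K v = ω²M v.  Units: k in N/m, masses in amu, 1 N/m = 602.214 amu/ps², so ω
emerges in rad/ps (cm⁻¹ provided for reporting).

Below matrix order 3000 the problem is diagonalized densely; above it,
ARPACK shift-invert around σ slightly below zero with a pre-factorized LU,
a generous Krylov subspace (symmetric assemblies have heavily degenerate
spectra) and a seeded start vector, which makes runs bit-reproducible.
Eigenvectors are mass-orthonormalized with a deterministic sign convention.
Rigid-body eigenvalues compute to ~10⁻¹² of the spectral scale while the
softest elastic ring modes sit near 10⁻⁸ of it; the zero threshold is
10⁻¹¹ × a Gershgorin bound (configurable).  A connected free structure has
exactly six zero modes; more raises a disconnected-network warning.  Mode
numbering in all reports starts after the rigid modes.

## Symmetry-constrained reduction (SCENM)

For q identical subunits placed by a rotation group, constraining every
copy to repeat subunit 1's motion in its own frame (Δ_i = R_iΔ_1) reduces
the eigenproblem to K_red = K₁₁ + Σ_i K₁ᵢR_i of order 3N/q with the
subunit-1 mass block.  Coupling blocks are assembled directly from
subunit-1 and interface springs without materializing the full stiffness (a
full-matrix extraction path exists and must agree entrywise — both are
tested).  K_red is symmetrized before solving and the asymmetry residual
reported; it vanishes (≈10⁻¹⁵) for group-consistent networks.  Expanded
modes are mass-normalized on the full assembly and verified against the
full eigen-equation through the block-row residual.  The reduction spans
only the totally symmetric representation: on C3/C4/C6 toys every reduced
eigenvalue matches the dense full spectrum to ~10⁻¹², but degenerate
non-symmetric families (e.g. the ring seesaw pair) require the full
problem, so rings are solved by full NMA and SCENM is used for the
buckyball, where the analysis targets the breathing family.  Symmetric
rigid motions survive as reduced zero modes (two for a C_q ring — axial
translation and rotation; none for the icosahedral cage).

## Mode classification

Every score is a ratio of quadratic forms in the mode vector, normalized to
[0,1] by total displacement energy, hence invariant to sign and scale;
degenerate groups (relative eigenvalue gap < 10⁻⁵) are scored jointly by
summing the quadratic forms over the group, making labels stable under
solver-arbitrary remixing.  Rings: O-T = coherent uniform z-displacement of
inner-circle beads; O-R = projection of the inner z-field on the k = 1
angular harmonics (seesaw); I-T = coherent in-plane inner displacement;
zigzag = outer-circle z-power at angular wavenumber ≥ 2 (harmonics
orthogonalized by QR against k ≤ 1); spiderlike = same-direction bridge
lift; mixed spiderlike = per-bridge-coherent but cross-bridge alternating
lift.  Ball: O_B = uniform-radial coherence; L_B = non-uniform radial
energy weighted by a participation-ratio localization complement;
torsional = per-tile coherent rotation about the tile's own radial axis.
Tile: bending = out-of-plane arm energy; tweezer = opposing per-arm
rotations about the hub (azimuthal projection weighted by the lever arm,
whole-tile rotation projected out); sticky-end bending and twisting are
restricted to overhang beads.  The top-scoring category labels the mode
unless the margin to the runner-up is below 0.15, in which case the mode is
`mixed`.  These formulas are this package's own quantitative realization of
a verbal taxonomy; the margin and all thresholds are configurable.

## What the defaults reproduce, and what they do not

With the default geometry and spring parameters the package reproduces the
designed ring diameters (29/13 and 55/40 nm to the nearest nm), the
buckyball tile graph (60 vertices, 90 edges, 12 pentagons + 20 hexagons),
exact six-zero-mode rigidity of every assembly, machine-precision agreement
between the symmetry-reduced and dense spectra, and the tile taxonomy
(mode 1 out-of-plane bending, tweezer pair at modes 2–3, sticky-end motions
above).  For the assembled structures the classifier identifies all the
taxonomy families, but their frequency ordering differs from the reference
behaviour in one systematic way: the outer circle of a ring modeled as a
single B-form duplex hoop has k ≥ 2 out-of-plane bending (zigzag) softer
than the inner-circle suspension modes (O-T appears at mode 3 for R1, mode
5 for R2, instead of first), and the buckyball's overall breathing sits at
mode 3 behind two softer cage-shear/tile-flex modes.  Within the stated
7/70/700 N/m rules this ordering is controlled by structural details — the
tile cross-section and exact sequences — that the available design
descriptions do not fix; the acceptance tests assert the reference ordering
as stated and the mismatching entries fail openly rather than being tuned
away.

## Numerical choices and limitations

Lengths are nm internally (Å only in PDB output); outputs are byte-stable
for a given configuration and stamped with a configuration hash.  Problem
sizes at the defaults: R1 rings ≈6.6k beads, R2 ≈15k (sparse solver);
buckyball 52,560 beads = 60 × 876, solved through the order-2628 reduced
problem; the published full-scale count (≈103k coarse-grained atoms)
depends on the exact sequences, so the pipeline logs its own counts and the
tests assert the 60× subunit scaling instead.  The generator produces ideal
unstrained geometry — no thermal disorder, no sequence-dependent structure,
no electrostatics or solvent, and arcs are unstrained at their built
curvature (no bending prestress).  Passing tests therefore demonstrate the
method's internal correctness and the qualitative mode families of the
idealized architecture, not thermodynamic properties of the real
assemblies.  Absolute frequencies are model-scale quantities: the stylized
duplex is stiffer in bending than B-DNA's 50 nm persistence length by
roughly 5× in ω, a known property of uniform-constant elastic networks at
this bead density.
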