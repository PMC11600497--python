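# Methods

This note documents the models, conventions and numerical choices behind
`stericzip`, in the order the pipeline applies them.

## Coordinate conventions and input handling

All geometry downstream of symmetry expansion lives in orthonormal
Ångström coordinates; fractional coordinates are used only inside the
expansion itself. The canonical amyloid frame follows the field's usage:
the β-sheet stacking (fibril) axis is *y*, the strand (chain) direction is
*z*, and the inter-sheet packing direction is *x*. For real crystals these
axes are fitted per sheet from the strand centroids and CA traces, so no
assumption is made about how a deposited structure is oriented.

Structures are parsed with gemmi. A missing unit cell or space-group
record is a hard error — symmetry expansion is meaningless without them.
Sanitization removes hydrogens and, per altloc group, keeps the
highest-occupancy conformer (ties: alphabetically first identifier);
solvent residues are retained but routed past the peptide machinery and
used only for wetness classification. Unknown elements keep their atoms
and receive a fallback radius of 1.80 Å with a warning.

Van der Waals radii follow the CCP4 AREAIMOL defaults (C 1.90, N 1.70,
O 1.40, S 1.80 Å, …). Absolute buried areas shift by a few Å² under a
different radii table; all thresholds in this package are interpreted
with this table.

Symmetry expansion enumerates every space-group operator combined with
lattice translations −2…+2 along each cell axis and keeps chain copies
with any atom within the expansion radius of the asymmetric unit
(duplicates on special positions dropped; configurable copy cap of 2000
as a runaway guard). The default radius is 20 Å: the slab standardization
below needs each contacted sheet to carry at least three repeating units,
i.e. roughly ±10 Å of sheet beyond the contact, which an 8 Å contact
shell would not supply. The sheet–sheet *contact* criterion itself is the
conventional one (any interatomic distance below the vdW sum plus two
probe radii).

## Sheets, H-bonds and the two antiparallel flavors

Backbone H-bonds are detected geometrically: N···O ≤ 3.5 Å with a
C=O···N angle ≥ 120°, between distinct chain copies only. No cutoffs are
published for this analysis family; these are standard values and both
are configurable. Strands sharing at least two H-bonds are sheet
neighbors; sheets are the connected components of that graph, ordered
along the fitted stacking axis.

Two facts about ideal hexapeptide sheets anchor the whole geometry and
are enforced by tests: an interior chain of an in-register parallel sheet
participates in exactly 10 backbone H-bonds, its antiparallel counterpart
in 12. The builder reproduces both without special-casing — the counts
emerge from end effects of the bonding pattern.

Antiparallel sheets come in two geometrically distinct flavors, and
recognizing this resolves several observations at once:

* **equifacial** sheets relate adjacent strands by a 2-fold rotation about
  the H-bond axis (*y*). Narrow-ring H-bond pairs satisfy
  i + j = L + 1, which is realizable in register for even-length chains
  (hexapeptides). Each face shows residues of both parities — every
  residue type appears on both faces, hence the name.
* **antifacial** sheets relate adjacent strands by a 2-fold about the
  sheet normal (*x*). Their faces are residue-parity pure (an
  alternating sequence gives an all-odd face and an all-even face), but
  the narrow-ring registry demands an even residue-number sum — possible
  in register only for odd-length chains. Even-length antifacial sheets
  are forced one residue out of register, which is exactly the observed
  association between out-of-register structures and parity-pure-face
  antiparallel packings.

## Topology classes

A contacting sheet pair is classified by three attributes:

* arrangement (parallel / antiparallel) from within-sheet strand
  directions;
* which face of each sheet forms the contact — faces are identified by
  the residue parity of the side chains pointing at the partner (side
  chain direction = CB−CA; glycine uses the backbone bisector surrogate);
* relative orientation — for parallel pairs the sign of the mean
  strand-direction dot product; for equifacial antiparallel pairs the
  orientation of y-aligned facing strands.

Parallel sheets (always antifacial): same face + same direction → 1,
other face + same direction → 2, same face + opposite → 3, other face +
opposite → 4. Antifacial antiparallel sheets: face-to-face → 5,
face-to-back → 6. Equifacial antiparallel sheets: facing strands parallel
→ 7, antiparallel → 8. Classes 1, 3 and 5 pair each face with its own
kind and therefore produce two distinct interfaces per crystal; the
classifier and the fixture builder share this convention and round-trip
all eight classes. Classes 9/10 (equifacial parallel) have no observed
representative; the fixture generator refuses to build them and the
classifier would report such geometry as unassigned.

Out-of-register detection uses the H-bond registry for antiparallel
sheets (modal narrow-ring sum vs L + 1) and the inter-strand displacement
along the strand direction, in units of the residue rise, for parallel
sheets. The associated strand tilt away from perpendicularity to the
stacking axis is reported as a diagnostic, not used as a criterion — it
is a consequence of the shift. A chain is flagged kinked (LARKS-like)
when an interior residue lies more than 30° (wrap-aware Euclidean
distance in φ/ψ space) outside the allowed β region; the margin is
configurable and the flag never overrides the class, which is then
reported as a pseudoclass.

## Interface admission and deduplication

The four admission criteria use the published constants: per-chain buried
area ≥ 50 Å²; every strand contributes an involved side chain; mean
involved side chains per chain ≥ 1.5; involvement = side-chain burial
≥ 10 Å² (glycine: CA burial ≥ 5 Å²). Two interpretive choices, echoed in
the report metadata: the 50 Å² size limit is read as the per-chain
buried-area value of the equation above (the same symbol is used for
both), and the 1.5 average is taken jointly over the middle-unit chains
of both sheets. Rejections always carry the first failed criterion.

Observations with identical involved-side-chain sets and the same class
are symmetry copies of one interface; their descriptors are arithmetic
means and the multiplicity is recorded. An interface is partially wet
when a solvent center falls inside the convex hull of the two slabs and
within the footprint extent along the strand direction — the paper gives
no numeric rule, so the hull test is this package's construction. Fully
solvent-covered faces never reach wetness classification: they fail the
admission criteria first.

## Descriptors

**Slab standardization.** All descriptors are computed on the central
three repeating units of each sheet (units: 1 chain parallel, 2 chains
antiparallel), centered on the closest-approach region, so the values do
not depend on how much lattice the expansion happened to produce.

**SASA.** Deterministic Shrake–Rupley: each atom's sphere (vdW + probe,
probe 1.4 Å) is sampled with a Fibonacci point set (960 points/atom by
default — bit-stable, no RNG) and points are tested against neighbor
spheres. Accuracy against the analytic one- and two-sphere formulas is
well within 1% at the default sampling; tests that compare against a
closed form to 0.1 Å² raise the sampling to 8000 points. The engine is
cross-checked against an independent implementation (biotite) in the
suite.

**Ab.** `(SASA_A + SASA_B − SASA_U)/N` with the middle-unit areas
computed inside their own 3-unit slab (flanking strands present, partner
sheet absent/present). Keeping the flanks in both terms cancels
intra-sheet burial — the historical ambiguity in reported buried areas —
and makes Ab a pure inter-sheet quantity. N = 2 (parallel) or 4
(antiparallel). The same per-atom decomposition yields the side-chain
burial table used by the admission criteria.

**Sc.** Molecular (solvent-excluded) surfaces are extracted per slab from
a Euclidean distance transform of the probe-forbidden volume on a 0.35 Å
grid, via marching cubes (the SES is the set of points at least one probe
radius from the probe-accessible region; marching-cubes vertices and
gradient normals give a surface sampling finer than the grid). Buried
points are those within 1 Å of the partner surface; each pairs with its
nearest partner point and scores −(n_a·n_b)·exp(−w·d²) with w = 0.5 Å⁻²
(the Lawrence–Colman weight). Sc is the median of the pooled scores of
both directions. Rigid-motion invariance is asserted to ±0.03, the grid
discretization scale.

**Footprint and SDi.** The footprint width is the repeating-unit extent
along the stacking axis (strand spacing × strands per unit). For the
length, the slab is projected along the stacking axis; atoms become disks
of their vdW radius, and a 1.4 Å probe disk is brought into the groove
from each open end until it is simultaneously tangent to disks of both
sheets (implemented as a 1D root-find on the probe clearance maximized
across the groove; a brute-force 2D grid oracle backs it in the tests).
Each endpoint is the innermost point of the tangent probe circle.
SDi = Ab × (chains per repeating unit) / (length × width): the one-sided
buried area of one repeating unit over its flat footprint. This
numerator convention is inferred — the source description does not fix
the side/unit normalization — and is the one that makes SDi independent
of peptide length (hexa- vs octapeptide fixtures agree to < 0.05) and
lands flat fixtures near 1 and interdigitated ones well above.

## Quaternary networks

Admitted interface observations form a graph over sheet instances in the
expanded lattice. Dimensionality is read from the central sheets (those
containing asymmetric-unit chains; rim sheets have truncated contact
counts): one contact → 1D isolated sandwiches; two contacts on opposite
faces → 2D catemer layers; more than two → 3D. Degrees deliberately count
lattice contacts rather than symmetry-unique interface types: in a
brick-wall packing a sheet touches two z-shifted partners through
symmetry-equivalent interfaces, and collapsing them by type would
misclassify the network as 2D. Patterns follow the lateral shift along
the strand direction relative to the chain length: straight < 15%,
brick > 35%, tilted between, fishbone when shifts alternate sign. The
thresholds are package choices (the source material is qualitative) and
are echoed in every report.

## The fixture generator

Strands are built by NeRF chain extension with ideal bond lengths/angles
(trans peptide, CB at the L-configuration improper of +122.6°) at any
requested (φ,ψ); side chains beyond CB come from a small fixed-rotamer
template table (A, G, S, V, L, I, N, Q, Y, W). Default β geometry:
φ = −119°, ψ = +113°, strand spacing 4.8 Å — canonical parallel-β values.
Sheet assembly optimizes only the alignment degrees of freedom that the
uniform-strand construction leaves free (the inter-strand displacement
along the strand direction, and for antiparallel sheets the pair-repeat
shear), by minimizing a smooth H-bond objective over a deterministic
grid + refinement; a register shift re-centers that search window, so
out-of-register sheets are built at their best geometry rather than by
naive translation.

Zippers place a second, rigidly transformed sheet at a closest-approach
gap of 3.8 Å (carbon vdW contact) with a lateral stagger that interleaves
the side-chain ladders of the two faces — one residue rise for
parity-pure faces, half a rise for equifacial antiparallel faces, whose
knobs repeat every residue. These defaults produce hexapeptide fixtures
with Ab ≈ 85–120 Å² and SDi ≈ 1.2–1.6, the scale seen in real zippers.
The crystal is emitted as a P1 cell whose b vector is the exact sheet
translation (the lattice continues the sheets), with the a vector closing
the catemer along the packing direction, and an optional explicit c
length for brick-like 3D packings; a final rigid rotation puts the cell
in the PDB orthogonalization convention so written files re-expand
identically.

What the generator does **not** emulate: side-chain rotamer relaxation
(rotamers are fixed ideal ones, so synthetic Sc values sit below those of
real, mutually adapted zipper surfaces), thermal/positional disorder,
charged termini and their H-bond networks, bound ions, and non-P1
symmetry. Passing tests therefore demonstrate the correctness of the
measurement machinery on known ground truth, not the distributional
properties of real crystal structures; absolute descriptor values for
real depositions additionally depend on the radii table above.

## Problem sizes and runtime

The shipped analyses use 3-strand parallel and 6-strand antiparallel
asymmetric units (hexa- to decapeptides), 20 Å expansion, 960-point SASA
sampling and a 0.35 Å surface grid; one full structure report takes a
few seconds and the complete test suite runs in about a minute.

## Known limitations

* Topology class numbering follows the standard attribute scheme
  (arrangement, face pairing, orientation); the assignment of the two
  equifacial-antiparallel combinations to the labels 7 vs 8 is a
  convention pinned by the builder/classifier pair.
* Trigonal/hexagonal nanopore packings are out of scope and surface as
  unclassified geometry, mirroring their exclusion from this analysis
  family.
* Sc depends mildly on the surface grid spacing (±0.02–0.03 at 0.35 Å);
  comparisons should use a fixed configuration.
* The wetness slab test uses atom centers; a solvent molecule grazing the
  footprint rim may be classified either way within ~1 Å.
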