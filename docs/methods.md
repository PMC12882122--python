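# Methods

## Scope and model

`ringconf` analyses monocyclic, all-carbon 5- and 6-membered rings in
ligand residues of crystallographic structure models.  Three questions
are answered per ring: what is its conformation (chair, half-chair,
boat, twist-boat, envelope, flat), is that conformation a low-energy
form for the unsubstituted ring, and do the experimental data (map
coverage plus resolution) actually support the modelled shape.  The
pipeline is deterministic end to end: identical inputs give
byte-identical reports.

## Ring extraction

Connectivity is taken from a CCD-style component dictionary, which is
treated as authoritative; no bond perception from interatomic distances
is attempted, and a component that is misannotated in the dictionary
will be misanalysed the same way downstream tools relying on that
dictionary would be.  Ring candidates are the chordless cycles of length
5 or 6 in the component bond graph (enumerated with networkx; a
brute-force permutation oracle cross-checks the enumeration in the test
suite), restricted to members the structure reports as carbon.  Fused
systems return each six-ring separately.

Type classification looks only at ring-internal bonds: exocyclic double
bonds (cyclohexanone) do not disqualify a saturated ring.  Two modes
exist for aromatic rings.  The default trusts the dictionary's
per-bond aromatic flag, so fused aromatics (naphthalene, anthracene)
count as benzene rings.  `paper_replication` mode instead rejects a
six-ring as benzene when any of its atoms has an aromatic bond leaving
the ring — reproducing the behaviour of order-based filters that read
the Kekulé single/double alternation and mistake fused benzenes for
cyclohexadienes.  The mode exists so results can be compared against
analyses with that known limitation.

Alternate locations: by default atoms with blank altloc or altloc "A"
are analysed, giving one conformer per ring; a flag selects another
altloc.  Occupancy is carried through but not used in any decision.
Hydrogens are ignored throughout: every geometric quantity is defined on
the 5–6 ring carbons.

## Atom ordering (C1/C2 selection)

Flap angles require a start atom and traversal direction; heterocycles
get these from the heteroatom, homocycles need a geometric rule.  The
best-fit plane is computed by orthogonal least squares (smallest
principal axis of the centred coordinates via SVD).  "Total distance" is
thus read as the sum of squared perpendicular distances: the unique,
smooth, standard choice; an absolute-distance objective is non-smooth
and has no closed form.  The plane normal's sign is fixed by making the
first nonzero signed distance positive — the downstream statistics use
absolute differences, so any deterministic convention gives identical
results (tested explicitly).

From the signed distances SD the neighbour deviations
SDdev(x, x+1) = |SD(x) − SD(x+1)| and the per-atom sums
SDsum(x) = SDdev(x−1, x) + SDdev(x, x+1) are formed cyclically.  C1 is
the argmax of SDsum, C2 the neighbour of C1 with the larger SDdev.
Near-ties (within 1e−9 Å, e.g. a perfect chair where all six SDsum are
equal) are broken by lowest file serial.  The tie-break never changes
the outcome: for symmetric rings all tied choices give the same flap
angles and classification, which the suite verifies by exhausting all
twelve rotations/reflections of an ideal chair.

## Flap angles and classification

The ordered ring is decomposed into a central reference triangle and
N − 3 corner flaps.  The assignment used is: 6-rings — reference plane
through C2, C4, C6, flaps (C2,C3,C4), (C4,C5,C6), (C6,C1,C2) with apices
C3, C5, C1; 5-rings — reference plane through C1, C2, C4, flaps
(C2,C3,C4) and (C4,C5,C1) with apices C3, C5.  Each θ is the signed
dihedral about the flap's hinge (both hinge endpoints lie in the
reference plane, so the two plane normals are perpendicular to the hinge
and the dihedral is well defined), computed with atan2 for numerical
stability; a flap apex on the positive side of the oriented reference
normal gives a positive angle.

The decomposition convention was the one genuinely open design choice.
It was fixed by calibration against the reference angle table: all
twelve candidate assignments for 6-rings (two reference-atom choices ×
flap orderings) and ten for 5-rings were scored by how well
low-dimensional ideal conformer shapes could reproduce the published
reference vectors; the assignment above reproduces the chair exactly and
every other row to within a few degrees with one- or two-parameter
shapes, while every alternative leaves residuals of tens of degrees.

Mirror-inverted rings give sign-flipped θ vectors.  Enantiomers are
deliberately not distinguished, so vectors are normalized by negating
all components when the last one is negative; normalization is
idempotent, and mirror pairs classify identically.

Classification assigns the reference conformer nearest in Euclidean
θ-distance.  Candidate sets: cyclohexane {chair, half-chair, boat,
twist-boat, flat}; cyclopentane {half-chair, envelope, flat}; benzene
{flat} plus the four cyclohexane shapes, so that physically distorted
"benzenes" get a descriptive label instead of a forced "flat".  Ties
break by table row order.  The reference table ships as package data
(columnar CSV) and can be overridden by a user-supplied file with the
same layout, e.g. to extend the method to other ring types.  The
cyclohexane "flat" row is (0.1, −0.0, 0.4) — the published constants
derive from quantum-chemically optimised structures and are used
verbatim rather than idealised to zeros.

Energetic favourability is a fixed label per (ring type, conformation):
cyclohexane — chair only; cyclopentane — half-chair and envelope;
benzene — flat.  Twist-boat cyclohexane, although a local minimum, is
counted as unfavourable, matching the reporting convention this package
follows.

## Density coverage

Maps are read with gemmi, reordered to canonical X,Y,Z axis order, and
expanded to the full unit cell; regions a box-shaped map does not cover
become NaN and the map is flagged non-periodic.  σ scaling uses the mean
and RMS-about-mean of the full (finite) grid — the common convention of
molecular viewers; whether a downloaded map was already σ-scaled is
irrelevant because the scaling is idempotent up to the affine transform,
and coverage decisions are invariant under affine value transforms
(tested).

Interpolation is the trilinear blend of the eight surrounding nodes,
implemented directly (and checked in the tests against an independently
coded weight-by-weight oracle and against exact trilinear polynomial
fields).  Periodic maps wrap positions by unit-cell translations;
positions touching uncovered regions of a box map raise an out-of-bounds
error, which `ring_coverage` converts (unless strict mode) into "atom
not covered" plus a log message.

An atom is covered iff its σ value is strictly greater than the
threshold; default 1.5 σ, with 1.2 σ a common alternative.  Coverage is
monotone in the threshold (covered@1.5 ⊆ covered@1.2), which the suite
asserts on random maps.  The choice of map type (2Fo−Fc vs other) is
the caller's; any CCP4/MRC map is treated uniformly.  Difference-map
blob detection and real-space correlation scores are out of scope.

## Support rule and reporting

A ring is supported by experimental data iff resolution ≤ 2.0 Å
(inclusive — "2 Å or better") and all ring atoms are covered.
Resolutions come from a local two-column CSV (entry id → Å) or are
passed per structure; duplicate entry ids in the table are an error, and
a missing entry marks the row unsupported with a missing-metadata flag.

Summary tables count conformations per ring type with percentages
relative to the ring-type total, also for the supported subset (so the
supported percentage is directly comparable to the overall one), plus
favourable/unfavourable subtotals.  Percentages round half-up to two
decimals (decimal arithmetic, not binary-float rounding).  Per-ring CSV
output uses a fixed column order with full-precision floats, so
write → read round-trips exactly and repeated runs are byte-identical.

## Synthetic data

The fixture generator emulates all three input kinds without any
external downloads:

- **Conformers** are regular N-gons (bond length 1.54 Å saturated,
  1.39 Å aromatic) with out-of-plane z displacements.  Per conformation
  the displacement vector was calibrated once, by minimising the
  distance between the pipeline's computed θ and the reference vector
  over the full N-dimensional z space (Nelder-Mead, small ridge
  penalty), and frozen as constants; residuals are below 1e−3°.
  Textbook symmetric patterns (alternating chair, prow-up boat, lifted
  envelope) are kept separately for symmetry-based tests.  An
  `amplitude` multiplier scales the calibrated vector (0 gives an exactly
  planar ring); poses are seeded uniform rotations plus translations,
  and coordinate noise is seeded isotropic Gaussian.
- **Dictionaries** provide single-bond tables for the saturated rings, a
  Kekulé-alternating aromatic benzene, and a fused naphthalene-like
  component (10 atoms, 11 bonds) for the fused-aromatic tests.
- **Maps** are sums of isotropic Gaussians (default width 0.9 Å on a
  0.5 Å grid) at atom centres, plus seeded background noise at 0.1×
  the peak scale so the σ statistic is stable.  The peak height is
  iterated so the smallest interpolated σ value over kept atoms reaches
  the target (default 3 σ), and the generator reports the map's own
  interpolated σ at every atom so coverage expectations are exact, not
  estimated.  Maps are periodic P1 boxes with a 5 Å margin.

What the fixtures do *not* emulate: real bond-angle relaxation (the
calibrated shapes match the references in θ-space, not in Cartesian
detail), crystallographic symmetry beyond P1, solvent/neighbour density,
series-termination noise, or partial-occupancy disorder.  Passing tests
therefore demonstrate the correctness of the geometry, classification
and coverage machinery under controlled conditions, not the field
behaviour of any particular deposited structure.

## Numerical choices and degenerate inputs

- Plane fit requires non-collinear input; collinear or coincident rings
  raise a degenerate-geometry error, as do collinear flap triangles.
- Tie tolerance for argmax selections: 1e−9 Å.
- θ invariance under rigid motion and uniform scaling holds to 1e−6°
  (tested over 100 random poses); interpolation matches its oracle to
  1e−9.
- Angles are kept at full precision internally and rounded only at
  presentation time.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
inputs: 9 reference conformers, bundles of 9 entries, 25–50 random poses
per conformer for recovery rates, maps of ≤ 32³ voxels, and 100–200
random interpolation points.  These sizes keep full runs under a few
seconds while exercising every stage; all rates quoted anywhere are
computed at run time at these sizes.

## Known limitations

- Dictionary-trusting extraction inherits dictionary annotation errors.
- Only monocyclic all-carbon 5/6-rings are analysed; heterocycles and
  larger rings would need their own reference vectors and (for
  heterocycles) the heteroatom-based ordering rule.
- No enantiomer discrimination (by design, via sign normalization).
- Whole-archive scale analysis (downloading and scanning the PDB) is out
  of scope; the package analyses local files.
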