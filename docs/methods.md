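# Methods

## The geometric model

A building block is a rigid body with an internal Cn rotation symmetry
(axis + center fitted by least squares from chain-to-next-chain Kabsch
superposition on Cα atoms) and a set of *bond sites*: right-handed
orthonormal frames at which one polarity of a heterodimeric bonding module
is presented.  Two sites of the same module type and opposite polarity mate
when one site's presented frame equals the *complement* of the other's.

**Mating convention.**  The complement of a frame F is F composed with a
180° rotation about its local x axis (the interface normal is local z).
This operation is an involution, so "A mates A′" is symmetric.  The atomic
coordinates of real heterodimer interfaces are not modelled; the convention
is shared by the fixture generator and the scoring code, which is all the
geometry layer requires.

**Placement.**  A slot assigns a block to a symmetry-axis line of the target
group.  The placement transform is: translate the fitted center to the
origin, rotate the fitted axis onto the group axis (minimal rotation),
rotate by the phase ψ about that axis, translate by the offset r along it.
The full assembly is the orbit of the placed block under the group, with
orbit elements that differ only by one of the block's own internal rotations
merged — hence |G|/n instances for a Cn block on a group axis, |G| for a
block at a general position (used for docked symmetry-broken heterotrimers,
which carry a single bonding module).  Canonical axis choice when several
group axes share an order: largest z component, then lexicographic; the
orbit generates the rest, so the choice is a convention, not a restriction.

**Closure score.**  For each required bond pairing, the nearest
complementary site instance (by frame-origin distance; ties broken by
smaller rotational deviation) is compared with the complement of the
presented frame: translational deviation Δt (Å), rotational deviation Δθ
(degrees), blended as

    combined = sqrt(Δt² + (L · Δθ_rad)²)

with lever arm L = 20 Å by default — the displacement a rotational error
produces at the far end of a bonding-module-sized object.  The default
acceptance threshold on the combined score is 0.1.  This mirrors the
permitted terminal-segment deviation used by fusion-based backbone samplers;
the units of that published tolerance are not stated, so it is stored here
as a threshold on the blended score and both the threshold and the lever are
configurable per architecture spec.

**Clashes.**  Inter-instance atom pairs closer than 2.4 Å (pseudo-Cα
carbon), counted with a k-d tree and verified against an all-pairs oracle in
the tests.  Pairs in which both atoms lie within 5 Å of an *engaged* site
origin are excluded — mated bonding modules are expected to touch.  A site
counts as engaged when some complementary site origin lies within 1 Å of its
own (mated frames have coincident origins under the convention above).

## Periodic architectures

**P3 layer.**  Component A (C3) at the (0,0) 3-fold site, component B at
fractional (1/3, 2/3) — the (2/3, 1/3) setting is lattice-equivalent and
selectable — with free parameters (a, z_off, φ).  Only the asymmetric pair
is placed; the slab is its orbit under the lattice translations.  Closure is
evaluated against the infinite lattice by minimum image (neighbour cells up
to a configurable reach), which makes per-bond scores independent of the
materialized slab size.

**F432 crystal.**  O-symmetric cages on the four FCC nodes per cell (4-fold
axes on the cell axes, pinned by the node's 432 site symmetry), C3 linkers
at the eight tetrahedral holes.  Every hole has a cage on the [111] line
through it, so all linker axes are placed along [111]; the per-cell linker
decoration is the orbit of the base placement under the F432 operators whose
rotation part preserves that line.  This is a deliberate convention: the
hole's site symmetry (order 12) does not single out one body diagonal, so a
one-linker-per-hole crystal of *oriented* linkers cannot be invariant under
all of F432 — it is invariant under the [111]-preserving subgroup, while
cage positions and the hole positions remain invariant under the full group.
Under this convention each linker's three arms reach the three off-axis
cages of its hole, and the local complex around any hole contains exactly
four cages (a regular tetrahedron of edge a/√2) and four bonded linkers —
the hole's own linker bonding three of the four cages and three neighbouring
linkers bonding two each.

**Free-DOF accounting.**  An architecture's continuous parameters are
counted from a declarative spec: an axis-locked Cn block keeps (ψ, r); a
general position keeps 6; a fully pinned site (cage on an FCC node) keeps 0;
free cell lengths count 1 each.  Components marked *reference* (held fixed
as the given input model, e.g. the pre-validated trimer at the P3 origin)
and *designed-to-fit* connectors (crystal linkers generated to match their
neighbours) contribute nothing.  The analytic count is cross-checked
numerically as the null-space dimension of the constraint Jacobian
(central differences, SVD rank) at a feasible configuration.  Shipped specs:
two-component cage → 4 (ψ_a, r_a, ψ_b, r_b); P3 layer → 3 (a, z_off, φ);
F432 crystal → 1 (a).

## Synthetic fixtures

The generator builds ideal Cn oligomers from a rigid pseudo-Cα helical arc
(100° twist, 1.5 Å rise, 2.3 Å helix radius, default 24 atoms at 12–14 Å
from the symmetry axis — typical dimensions of small designed oligomers),
element carbon.  It does **not** emulate side chains, sequence, interface
energetics or solvent; passing tests therefore demonstrate the correctness
of the geometry, scoring and sampling machinery, not the designability of
any real protein.

Mated fixtures are constructed by placing undecorated blocks at planted DOF
values, choosing a bond frame on the segment between the two nearest placed
components (origin at the midpoint, displaced 3 Å perpendicular so symmetry
replicas are distinct; z along the center-to-center direction), and pulling
that frame back into each block's local coordinates — one side receiving the
frame, the other its complement.  Closure at the planted DOFs is then zero
by construction and rises monotonically under small perturbations, giving
planted-truth recovery tests for the cage scanner, the layer builder and the
crystal builder.  Block radii grow automatically (×1.3 per attempt) if the
initial geometry clashes.  Site-frame perturbations for tolerance testing
are Gaussian in translation and axis-uniform with |N(0, σ)| angles in
rotation.

## SAXS simulation

Amplitudes default to atomic numbers (point-atom approximation,
q-independent; overridable per element).  The Monte-Carlo estimator draws
uniform ordered pairs (i ≠ j; default 10⁷, matching the published
simulation protocol), bins distances into 2048 bins up to the structure
diameter, weights each sample by fᵢfⱼ, and inverts with

    I(q) = Σᵢ fᵢ² + W · Σ_b w_b · sinc(q r_b),

where r_b is the bin midpoint and W scales the sampled weight to the full
ordered-pair total (Σf)² − Σf², so I(0) = (Σf)² exactly.  The estimator is
unbiased up to binning; tests verify agreement with the exact O(N²) sum
within Monte-Carlo error, the two-atom closed form, the Rayleigh sphere form
factor for a uniform point cloud, and the 1/a scaling of the first
Bragg-like peak of a finite hexagonal net.  Solvent exclusion, q-dependent
form factors and instrument smearing are out of scope.

## Design filters

Externally predicted metrics (pLDDT, pTM, ddG, shape complementarity, SAP,
unsatisfied H-bonds) are ingested from tables only — recomputing them
requires the external predictors that produced them.  Comparator strictness
follows the published cut-offs symbol for symbol (≤ 5 methionines is
inclusive; > 0.6 shape complementarity and < 30 SAP are exclusive).  Missing
metrics fail a design by default; a skip policy is available.  Cα RMSD uses
Kabsch superposition (both cut-offs, 1.5 and 2.0 Å, appear in practice; the
engine stores the threshold per filter spec, default 2.0).  SASA uses
Shrake–Rupley sphere sampling (960 points default, Fibonacci distribution,
probe 1.4 Å) with an explicit element → van-der-Waals-radius table.

## Numerical choices and limitations

* Group-membership and frame-comparison tolerance 1e-6 on matrix elements;
  assembly G-invariance holds to better than 1e-6 Å RMSD.
* The icosahedral group is generated in the setting with 2-fold axes on the
  coordinate axes (one 2-fold on z, 3-folds on body diagonals, 5-folds
  through (0, 1, φ)-type vertices); no standard setting is imposed by the
  design problem, and this one contains the tetrahedral group in the same
  frame.
* Dihedral specs place the Cn principal axis on z and 2-folds
  perpendicular, so the 90° Cn–C2 intersection is derived from the operator
  set, never tabulated; the same holds for all polyhedral angles.
* Two slots may share an axis line (e.g. both components of a T33 cage on a
  body diagonal, one at negative offset); placements are rejected only if
  they coincide exactly.
* Problem sizes in the tests (fixtures of tens of atoms per chain, 10⁶-pair
  MC runs, 2×2×2-cell crystals, 3-point-per-DOF recovery grids) were chosen
  as the smallest sizes at which every property is sharply testable; all
  engine code paths are size-independent.
* Assembly thermodynamics and kinetics (cage↔layer exchange, capping-driven
  nucleation dynamics, crystalline domain growth) are deliberately not
  modelled: the site balance is stoichiometric only.
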