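# bondforge

Bond-centric modular design of symmetric protein assemblies.

Designed protein nanomaterials can be built the way chemistry builds
molecules: from a small set of rigid building blocks carrying directional
"bonds".  A building block is a cyclic (Cn) oligomeric *structural module*
decorated with *bonding modules* — reversible heterodimeric interfaces (LHD
pairs) whose two polarities (A / A′) mate specifically and directionally.  A
target architecture (a polyhedral cage, a 2D array or a 3D crystal) is then a
purely geometric statement: place each block on a rotation axis of the target
symmetry group so that every presented bonding module coincides with the
complement frame of a partner's module.

`bondforge` implements that geometric engine for people designing such
materials:

* **symgroups** — chiral point groups C1…Cn, D2…Dn, T (12), O (24), I (60)
  generated by closure over canonical generators, plus the periodic groups
  P3 (2D) and F432 (face-centred-cubic 3D); axis enumeration and
  inter-axis angles.  The geometric requirement for a two-component cage is
  that the component axes intersect at the group's axis angle, e.g. 45° for
  the C2 and C4 axes of the octahedron.
* **blocks** — building-block data model, PDB/mmCIF I/O (via gemmi), cyclic
  symmetry-axis fitting, the bond-site mating convention, and the
  `[sym]ab-c` design nomenclature (`O42-24` = octahedral cage of a C4 and a
  C2 component, design 24).
* **fixtures** — synthetic generator producing ideal Cn oligomers and
  pre-solved architectures whose bond sites mate with *exactly zero* closure
  error at planted degrees of freedom: the ground truth used throughout the
  test suite.
* **architect** — placement of components on group axes, orbit expansion
  with merging of copies related by a block's own internal symmetry,
  closure scoring (translational Δt, rotational Δθ, blended with a lever
  arm: `sqrt(Δt² + (L·Δθ)²)`), DOF grid scans, clash counting and
  junction-gap export for downstream generative backbone design.
* **lattice** — the two-component P3 layer (free DOFs: lattice spacing a,
  axial offset z_off, trimer rotation φ) and the F432 crystal of O-symmetric
  cage secondary building units bridged by C3 linkers (one free DOF: the
  cell parameter / translation of the cages along their diagonal 3-fold
  axes); local tetrahedral-cluster extraction and free-DOF accounting with a
  numeric constraint-Jacobian cross-check.
* **bondgraph** — interaction-network topology (line / star / ring), shared
  components and reconfigurability between bounded and unbounded
  architectures, and stoichiometric site balance with capping ligands.
* **saxs** — Monte-Carlo Debye simulator: the orientation-averaged
  intensity I(q) = Σᵢⱼ fᵢfⱼ sin(q·rᵢⱼ)/(q·rᵢⱼ) estimated by random pair
  sampling into an amplitude-weighted distance histogram (default 10⁷
  pairs), with the exact O(N²) sum as oracle.
* **filters** — threshold engine for the in-silico design screens
  (pLDDT > 90, pTM > 0.80, Cα RMSD < 1.5/2.0 Å; methionine ≤ 5, shape
  complementarity > 0.6, ddG < −20, SASA < 1600, clashes ≤ 2, unsatisfied
  H-bonds ≤ 2, SAP < 30), plus internally computed Cα RMSD, Shrake–Rupley
  SASA and methionine counts.

## Worked example

```python
from bondforge.symgroups import generate_point_group, min_axis_angle
from bondforge.fixtures import make_mated_pair
from bondforge.architect import place_components, closure_error, clash_count

O = generate_point_group("O")
print(f"|O| = {len(O)} operators")
print(f"C2-C4 axis angle: {min_axis_angle(O, 2, 4):.1f} degrees")

spec, dofs = make_mated_pair("O42")          # octahedral C4 + C2 cage fixture
model = place_components(spec, dofs)
print(f"instances: {model.instance_count(0)} tetramers, {model.instance_count(1)} dimers")
report = closure_error(model)
print(f"worst closure: {report.worst:.2e}  (tolerance {spec.tolerance})")
print(f"clashes: {clash_count(model)}")
```

prints

```
|O| = 24 operators
C2-C4 axis angle: 45.0 degrees
instances: 6 tetramers, 12 dimers
worst closure: 3.58e-15  (tolerance 0.1)
clashes: 0
```

The 45° angle is the closure condition for an octahedral two-component cage;
6 = |O|/4 tetramer and 12 = |O|/2 dimer placements tile the cage; the
closure score is zero at the fixture's planted DOFs because its bond sites
were constructed to mate exactly, and rises monotonically as any DOF is
perturbed — which is what `scan_dofs` exploits to recover design parameters.

A command-line wrapper exposes the same machinery
(`bondforge group O --angle 2 4`, `bondforge fixture --arch O42 --out dir/`,
`bondforge saxs model.pdb --pairs 10000000`, `bondforge filter metrics.csv`).

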