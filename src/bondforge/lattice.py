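"""Periodic architectures: the P3 two-component layer and the F432 crystal.

The 2D layer places two C3 trimers on the 3-fold sites of plane group P3
(component A at fractional (0,0), component B at (1/3,2/3)) with three free
parameters: the lattice spacing a, the axial offset z_off of B from the
lattice plane, and the rotation phi of B about its own 3-fold axis.

The 3D crystal places an O-symmetric cage (a secondary building unit
displaying 24 outward bonding modules) on the face-centred-cubic nodes of
space group F432 and C3 linkers at the eight (1/4,1/4,1/4)-type interstitial
sites, 3-fold axes along the body diagonal.  Four cages around an
interstitial site form a regular tetrahedron (edge a/sqrt(2)) tied together
by four linkers.  Linker orientation convention: the 8c site symmetry (order
12) does not single out one diagonal, so all linker axes are placed on the
[111] line -- every hole has a cage on that line through it -- which keeps
the linker decoration invariant under the subgroup of F432 preserving [111]
while cage positions remain invariant under the full group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .architect import AssemblyModel, DEFAULT_CLOSURE_TOLERANCE, DEFAULT_LEVER_ARM
from .blocks import BondSite, BuildingBlock, complement_frame
from .geometry import RigidTransform, rotation_angle_between
from .symgroups import Cell, SymmetryGroup, lattice_group

__all__ = [
    "LatticeModel",
    "Cluster",
    "build_p3_layer",
    "build_f432_crystal",
    "lattice_closure",
    "count_bonded_partners",
    "local_cluster",
    "SlotDof",
    "DofSpec",
    "free_dof_count",
    "constraint_nullity",
    "two_component_cage_dofs",
    "p3_layer_dofs",
    "f432_crystal_dofs",
]

_U111 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)

#: fractional positions of the FCC tetrahedral holes in one cell
_HOLE_FRACS = np.array(list(itertools.product([0.25, 0.75], repeat=3)))

_FCC_NODES = np.array(
    [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
)


@dataclass(frozen=True)
class LatticeModel:
    """Periodic model: per-cell units replicated over n_cells."""

    group: SymmetryGroup
    units: tuple[tuple[str, BuildingBlock, RigidTransform], ...]
    n_cells: tuple[int, ...]

    @property
    def cell(self) -> Cell:
        return self.group.cell

    @property
    def dim(self) -> int:
        return len(self.n_cells)

    @property
    def lattice_vectors(self) -> np.ndarray:
        orth = self.cell.orth
        return orth.T[: self.dim]  # rows are the cell vectors

    def cell_shifts(self) -> list[tuple[int, ...]]:
        return list(itertools.product(*[range(n) for n in self.n_cells]))

    def instances(self):
        """(label, block, transform, cell index) over the materialized slab."""
        vecs = self.lattice_vectors
        out = []
        for shift in self.cell_shifts():
            t = RigidTransform.from_translation(np.asarray(shift, dtype=float) @ vecs)
            for label, block, base in self.units:
                out.append((label, block, t @ base, shift))
        return out

    def site_instances(self, label: str | None = None):
        out = []
        for lab, block, tf, shift in self.instances():
            if label is not None and lab != label:
                continue
            for j, site in enumerate(block.bond_sites):
                out.append((lab, shift, j, tf @ site.frame, site))
        return out

    def atoms(self):
        coords, inst, elements = [], [], []
        for k, (_, block, tf, _) in enumerate(self.instances()):
            xyz = tf.apply(block.all_coords())
            coords.append(xyz)
            inst.append(np.full(len(xyz), k))
            elements.extend(block.elements())
        return np.vstack(coords), np.concatenate(inst), elements

    def neighbor_images(self, reach: int = 2) -> np.ndarray:
        """Lattice translations within ``reach`` cells, for minimum-image
        closure on the infinite lattice."""
        vecs = self.lattice_vectors
        shifts = np.array(
            list(itertools.product(range(-reach, reach + 1), repeat=self.dim)),
            dtype=float,
        )
        return shifts @ vecs


# ---------------------------------------------------------------------------
# P3 layer


def build_p3_layer(
    block_a: BuildingBlock,
    block_b: BuildingBlock,
    a: float,
    z_off: float,
    phi: float,
    n_cells: int = 1,
    c: float = 60.0,
    site_b: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> LatticeModel:
    """Two-component P3 layer: A at the origin 3-fold site, B at ``site_b``
    ((1/3,2/3) canonically; (2/3,1/3) selects the lattice-equivalent setting)
    with axial offset ``z_off`` and own-axis rotation ``phi``.

    Only the asymmetric pair is placed explicitly; the slab is its orbit
    under the lattice translations.
    """
    for blk in (block_a, block_b):
        if blk.cyclic_order != 3:
            raise ValueError("P3 layer components must be trimeric (C3)")
    cell = Cell(a, a, c, 90.0, 90.0, 120.0)
    group = lattice_group("P3", cell)
    p_a = _axis_placement(block_a, np.zeros(3), 0.0)
    s_cart = cell.orth @ np.array([site_b[0], site_b[1], 0.0])
    p_b = _axis_placement(block_b, s_cart + np.array([0.0, 0.0, z_off]), phi)
    units = (("A", block_a, p_a), ("B", block_b, p_b))
    return LatticeModel(group=group, units=units, n_cells=(n_cells, n_cells))


def _axis_placement(block: BuildingBlock, position: np.ndarray, phi: float) -> RigidTransform:
    from .architect import _align_rotation

    align = RigidTransform.from_rotation(_align_rotation(block.axis, [0, 0, 1])) @ \
        RigidTransform.from_translation(-block.center)
    return (
        RigidTransform.from_translation(position)
        @ RigidTransform.from_axis_angle([0, 0, 1], phi)
        @ align
    )


# ---------------------------------------------------------------------------
# F432 crystal


def build_f432_crystal(
    cage: BuildingBlock | AssemblyModel,
    linker: BuildingBlock,
    a: float,
    n_cells: int = 1,
    check_symmetry: bool = True,
) -> LatticeModel:
    """F432 crystal of O-symmetric cages bridged by C3 linkers.

    Cages sit on the four FCC nodes of the cell (4-fold axes on the cell
    axes); linkers at the eight tetrahedral holes with their 3-fold along
    [111].  The linker decoration per cell is the orbit of the base placement
    (hole (3/4,1/4,1/4)) under the F432 operators whose rotation part
    preserves the [111] line.
    """
    if isinstance(cage, AssemblyModel):
        cage = cage.as_block("cage")
    if linker.cyclic_order != 3:
        raise ValueError("crystal linker must be trimeric (C3)")
    if check_symmetry and not _is_o_invariant(cage):
        raise ValueError("cage is not octahedrally symmetric within tolerance")
    cell = Cell(a, a, a)
    group = lattice_group("F432", cell)
    units: list[tuple[str, BuildingBlock, RigidTransform]] = []
    for node in _FCC_NODES:
        units.append(("cage", cage, RigidTransform.from_translation(cell.orth @ node)))
    base_hole = cell.orth @ np.array([0.75, 0.25, 0.25])
    l_base = _diagonal_placement(linker, base_hole)
    frac = cell.frac
    seen: list[np.ndarray] = []
    for op in group.ops:
        if not _preserves_line(op.rotation, _U111):
            continue
        g = RigidTransform(op.rotation, op.translation)
        cand = g @ l_base
        pos = np.mod(np.round(frac @ cand.origin, 9), 1.0)
        pos[np.isclose(pos, 1.0, atol=1e-9)] = 0.0
        if any(np.allclose(pos, s, atol=1e-6) for s in seen):
            continue
        seen.append(pos)
        # reduce the placement into the home cell by a pure lattice translation
        delta = cell.orth @ (pos - frac @ cand.origin)
        shifted = RigidTransform.from_translation(delta) @ cand
        units.append(("linker", linker, shifted))
    if sum(1 for lab, _, _ in units if lab == "linker") != 8:
        raise RuntimeError("expected 8 linker sites per cell")
    return LatticeModel(group=group, units=tuple(units), n_cells=(n_cells,) * 3)


def _diagonal_placement(block: BuildingBlock, position: np.ndarray) -> RigidTransform:
    from .architect import _align_rotation

    align = RigidTransform.from_rotation(_align_rotation(block.axis, _U111)) @ \
        RigidTransform.from_translation(-block.center)
    return RigidTransform.from_translation(position) @ align


def _preserves_line(rotation: np.ndarray, u: np.ndarray) -> bool:
    return bool(abs(abs(float(u @ rotation @ u)) - 1.0) < 1e-8)


def _is_o_invariant(cage: BuildingBlock, tol: float = 1e-3) -> bool:
    from scipy.spatial import cKDTree

    from .symgroups import generate_point_group

    coords = cage.all_coords(ca_only=True)
    tree = cKDTree(coords)
    for op in generate_point_group("O").ops:
        d, _ = tree.query(coords @ op.rotation.T)
        if float(np.sqrt(np.mean(d**2))) > tol:
            return False
    return True


# ---------------------------------------------------------------------------
# periodic closure and bonding


@dataclass(frozen=True)
class LatticeBond:
    unit_label: str
    site_index: int
    partner_label: str
    partner_shift: tuple
    dt: float
    dtheta: float
    combined: float


def lattice_closure(
    model: LatticeModel,
    tolerance: float = DEFAULT_CLOSURE_TOLERANCE,
    lever_arm: float = DEFAULT_LEVER_ARM,
    reach: int = 2,
) -> list[LatticeBond]:
    """Closure of every bond site of the base-cell units against the infinite
    lattice (minimum image over ``reach`` neighbour cells).

    Results are independent of the materialized slab size by construction.
    """
    images = model.neighbor_images(reach)
    zero_img = int(np.argmin(np.linalg.norm(images, axis=1)))
    partners = []
    for lab, block, base in model.units:
        for j, site in enumerate(block.bond_sites):
            partners.append((lab, j, base @ site.frame, site))
    bonds = []
    for lab, block, base in model.units:
        for j, site in enumerate(block.bond_sites):
            presented = base @ site.frame
            target = complement_frame(presented)
            # minimum-image origin distance per partner; the rotational term
            # is image-independent and only needed to break origin ties
            cands = []
            for plab, pj, pframe, psite in partners:
                if not psite.complements(site):
                    continue
                dts = np.linalg.norm(pframe.origin - presented.origin + images, axis=1)
                if plab == lab and pj == j:
                    dts[zero_img] = np.inf  # the presented site itself
                k = int(np.argmin(dts))
                cands.append((float(dts[k]), plab, pframe, images[k]))
            if not cands:
                continue
            dt_min = min(c[0] for c in cands)
            tied = [c for c in cands if c[0] <= dt_min + 1e-9]
            dt, plab, pframe, img = min(
                tied,
                key=lambda c: rotation_angle_between(c[2].rotation, target.rotation),
            )
            dth = rotation_angle_between(pframe.rotation, target.rotation)
            combined = float(np.hypot(dt, lever_arm * np.deg2rad(dth)))
            bonds.append(
                LatticeBond(
                    unit_label=lab, site_index=j, partner_label=plab,
                    partner_shift=tuple(np.round(img, 6)),
                    dt=dt, dtheta=dth, combined=combined,
                )
            )
    return bonds


def count_bonded_partners(
    model: LatticeModel,
    label: str,
    tolerance: float = DEFAULT_CLOSURE_TOLERANCE,
    lever_arm: float = DEFAULT_LEVER_ARM,
    reach: int = 2,
) -> int:
    """Distinct partner components fully bonded to the base-cell unit
    ``label`` (e.g. each trimer at a P3 3-fold site touches 3 partners)."""
    images = model.neighbor_images(reach)
    unit = next((u for u in model.units if u[0] == label), None)
    if unit is None:
        raise ValueError(f"no unit labelled {label!r}")
    _, block, base = unit
    partners = set()
    for j, site in enumerate(block.bond_sites):
        presented = base @ site.frame
        target = complement_frame(presented)
        for plab, pblock, pbase in model.units:
            for pj, psite in enumerate(pblock.bond_sites):
                if not psite.complements(site):
                    continue
                pframe = pbase @ psite.frame
                dts = np.linalg.norm(pframe.origin - presented.origin + images, axis=1)
                hits = np.nonzero(dts <= tolerance)[0]
                if len(hits) == 0:
                    continue
                dth = rotation_angle_between(pframe.rotation, target.rotation)
                for k in hits:
                    if np.hypot(dts[k], lever_arm * np.deg2rad(dth)) <= tolerance:
                        partners.add((plab, tuple(np.round(images[k], 3))))
    return len(partners)


# ---------------------------------------------------------------------------
# local cluster extraction


@dataclass(frozen=True)
class Cluster:
    cage_instances: tuple[int, ...]
    linker_instances: tuple[int, ...]
    centroid: np.ndarray
    cage_centers: np.ndarray


def local_cluster(
    crystal: LatticeModel,
    site: tuple[float, float, float] = (0.25, 0.25, 0.25),
    bond_tolerance: float = DEFAULT_CLOSURE_TOLERANCE,
    lever_arm: float = DEFAULT_LEVER_ARM,
) -> Cluster:
    """Cages and linkers of the local tetrahedral complex at an interstitial
    site (fractional coordinates of (1/4,1/4,1/4) type).

    Returns the four nearest cages and the linkers bonded to at least two of
    them.  Bonds are detected by exact site mating (combined closure below
    ``bond_tolerance``); the cage members form a regular tetrahedron of edge
    a/sqrt(2).
    """
    frac = np.asarray(site, dtype=float)
    if not np.all(np.isin(np.round(np.mod(frac, 1.0), 6), [0.25, 0.75])):
        raise ValueError("site is not an interstitial (tetrahedral-hole) center")
    center = crystal.cell.orth @ frac
    instances = crystal.instances()
    cages = [
        (k, tf.apply(block.all_coords().mean(axis=0)))
        for k, (lab, block, tf, _) in enumerate(instances)
        if lab == "cage"
    ]
    if len(cages) < 4:
        raise ValueError("crystal slab too small for cluster extraction")
    cages.sort(key=lambda kc: (round(float(np.linalg.norm(kc[1] - center)), 6), kc[0]))
    members = cages[:4]
    member_ids = tuple(k for k, _ in members)
    centers = np.array([c for _, c in members])

    # all cage site frames of the member cages
    member_sites = []
    for k, (lab, block, tf, _) in enumerate(instances):
        if k not in member_ids:
            continue
        for site_obj in block.bond_sites:
            member_sites.append((k, tf @ site_obj.frame, site_obj))

    linker_ids = []
    for k, (lab, block, tf, _) in enumerate(instances):
        if lab != "linker":
            continue
        bonded = set()
        for j, site_obj in enumerate(block.bond_sites):
            presented = tf @ site_obj.frame
            target = complement_frame(presented)
            for ck, cframe, csite in member_sites:
                if not csite.complements(site_obj):
                    continue
                dt = float(np.linalg.norm(cframe.origin - presented.origin))
                if dt > bond_tolerance:
                    continue
                dth = rotation_angle_between(cframe.rotation, target.rotation)
                if np.hypot(dt, lever_arm * np.deg2rad(dth)) <= bond_tolerance:
                    bonded.add(ck)
        if len(bonded) >= 2:
            linker_ids.append(k)
    return Cluster(
        cage_instances=member_ids,
        linker_instances=tuple(linker_ids),
        centroid=center,
        cage_centers=centers,
    )


# ---------------------------------------------------------------------------
# free-DOF accounting


@dataclass(frozen=True)
class SlotDof:
    """DOF declaration for one component of an architecture.

    ``site``: ``"axis"`` (block's Cn axis locked to a symmetry axis line;
    phase and axial offset remain), ``"general"`` (free rigid body) or
    ``"full"`` (site symmetry pins the whole placement, e.g. an O cage on an
    FCC node).  ``reference`` marks the component held fixed as the given
    input model; ``designed_fit`` marks a connector whose geometry is
    generated to match its neighbours rather than sampled.
    """

    label: str
    site: str = "axis"
    reference: bool = False
    designed_fit: bool = False
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    site_point: tuple[float, float, float] = (0.0, 0.0, 0.0)  # fractional if periodic
    stabilizer: str = "O"  # point group pinning a "full" slot


@dataclass(frozen=True)
class DofSpec:
    name: str
    slots: tuple[SlotDof, ...]
    periodic: str | None = None  # None | "P3" | "F432"
    cell_free: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(self.slots))


def free_dof_count(spec: DofSpec) -> tuple[int, list[str]]:
    """Continuous rigid-body parameters not fixed by symmetry constraints.

    Per slot: an axis-locked Cn block keeps (phase, axial offset); a general
    position keeps all 6; a fully pinned site keeps none.  Reference
    components (held fixed as given) and designed-to-fit connectors
    contribute nothing.  Free cell parameters are counted for periodic specs.
    The analytic count equals the numeric constraint-Jacobian nullity, see
    :func:`constraint_nullity`.
    """
    labels = [f"cell:{p}" for p in spec.cell_free]
    for slot in spec.slots:
        if slot.reference or slot.designed_fit:
            continue
        if slot.site == "axis":
            labels += [f"{slot.label}:psi", f"{slot.label}:r"]
        elif slot.site == "general":
            labels += [f"{slot.label}:{d}" for d in ("rx", "ry", "rz", "tx", "ty", "tz")]
        elif slot.site == "full":
            pass
        else:
            raise ValueError(f"unknown site kind {slot.site!r}")
    return len(labels), labels


def constraint_nullity(spec: DofSpec, h: float = 1e-6) -> int:
    """Numeric check of :func:`free_dof_count`: dimension of the null space
    of the symmetry-constraint Jacobian at a feasible configuration.

    Parameters are the free cell lengths plus a 6-vector (rotation vector,
    translation) per counted slot; constraints are axis-line coincidence
    (4 per axis slot) or full pinning (6 per "full" slot), evaluated by
    central differences.
    """
    from .symgroups import generate_point_group

    active = [s for s in spec.slots if not (s.reference or s.designed_fit)]
    n_cell = len(spec.cell_free)
    n_par = n_cell + 6 * len(active)
    if n_par == 0:
        return 0

    def cell_orth(params) -> np.ndarray:
        a = 100.0 * (1.0 + (params[0] if n_cell else 0.0))
        if spec.periodic == "P3":
            return Cell(a, a, 60.0, 90.0, 90.0, 120.0).orth
        return Cell(a, a, a).orth

    def residuals(params: np.ndarray) -> np.ndarray:
        orth = cell_orth(params)
        out = []
        for i, slot in enumerate(active):
            w = params[n_cell + 6 * i : n_cell + 6 * i + 3]
            t = params[n_cell + 6 * i + 3 : n_cell + 6 * i + 6]
            # placement perturbation around the feasible identity
            from scipy.spatial.transform import Rotation as _R

            rot = _R.from_rotvec(w).as_matrix()
            if spec.periodic:
                point = orth @ np.asarray(slot.site_point, dtype=float)
            else:
                point = np.asarray(slot.site_point, dtype=float)
            u = np.asarray(slot.axis, dtype=float)
            u = u / np.linalg.norm(u)
            e1 = np.eye(3)[np.argmin(np.abs(u))]
            b1 = np.cross(u, e1)
            b1 /= np.linalg.norm(b1)
            b2 = np.cross(u, b1)
            if slot.site == "axis":
                d = rot @ u
                c = point + t  # feasible center rides at the site point
                out += [b1 @ d, b2 @ d]  # direction must stay on the line
                offset = c - point
                out += [b1 @ offset, b2 @ offset]
            elif slot.site == "full":
                out += list(w) + list((point + t) - point)
            elif slot.site == "general":
                pass
        return np.asarray(out, dtype=float)

    x0 = np.zeros(n_par)
    r0 = residuals(x0)
    if len(r0) == 0:
        return n_par
    jac = np.zeros((len(r0), n_par))
    for j in range(n_par):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        jac[:, j] = (residuals(xp) - residuals(xm)) / (2 * h)
    rank = np.linalg.matrix_rank(jac, tol=1e-9)
    return n_par - rank


def two_component_cage_dofs(order_a: int, order_b: int, name: str = "cage") -> DofSpec:
    return DofSpec(
        name=name,
        slots=(
            SlotDof(label=f"C{order_a}", site="axis", axis=(0, 0, 1)),
            SlotDof(label=f"C{order_b}", site="axis", axis=(0, 1, 1)),
        ),
    )


def p3_layer_dofs(name: str = "P3-layer") -> DofSpec:
    return DofSpec(
        name=name,
        periodic="P3",
        cell_free=("a",),
        slots=(
            SlotDof(label="A", site="axis", reference=True),
            SlotDof(label="B", site="axis", site_point=(1 / 3, 2 / 3, 0.0)),
        ),
    )


def f432_crystal_dofs(name: str = "F432-crystal") -> DofSpec:
    return DofSpec(
        name=name,
        periodic="F432",
        cell_free=("a",),
        slots=(
            SlotDof(label="cage", site="full", stabilizer="O"),
            SlotDof(
                label="linker", site="axis", designed_fit=True,
                axis=(1, 1, 1), site_point=(0.25, 0.25, 0.25),
            ),
        ),
    )
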