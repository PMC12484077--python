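"""Synthetic building-block and architecture fixtures.

Idealized Cn oligomers with exactly mating bond sites, so that every
downstream stage (placement, closure scoring, lattice building, SAXS) is
testable with no external structure files.  Monomers are rigid pseudo-C-alpha
helices (element carbon): the geometric layer being exercised is independent
of side-chain detail.

The central construction is :func:`make_mated_pair`: given a two-component
cage label such as ``O42`` or ``T33``, it builds two cyclic blocks whose bond
sites mate with *exactly zero* closure error at the returned (planted) DOF
values -- a ground truth for parameter-recovery and monotonicity tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .architect import (
    ArchitectureSpec,
    ComponentSlot,
    clash_count,
    place_components,
)
from .blocks import AtomRecord, BondSite, BuildingBlock, complement_frame
from .geometry import RigidTransform, rotation_about_axis

__all__ = [
    "FixtureSpec",
    "make_ideal_oligomer",
    "make_heterotrimer",
    "make_mated_pair",
    "make_coaxial_pair",
    "perturb_block",
    "attach_site",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one idealized cyclic oligomer."""

    n: int = 3
    monomer_atoms: int = 24
    radius: float = 14.0  # A from the symmetry axis, typical small-oligomer size
    seed: int = 0
    res_names: tuple[str, ...] | None = None  # per-residue names, cycled

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cyclic order must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.monomer_atoms < 1:
            raise ValueError("monomer must have at least one atom")


def _monomer_coords(spec: FixtureSpec) -> np.ndarray:
    """Pseudo-C-alpha alpha-helical arc: 100 deg twist, 1.5 A rise, 2.3 A
    radius, axis parallel to z at ``radius`` from the oligomer axis."""
    j = np.arange(spec.monomer_atoms)
    ang = np.deg2rad(100.0 * j)
    local = np.column_stack(
        [2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * j - 0.75 * (spec.monomer_atoms - 1)]
    )
    return local + np.array([spec.radius, 0.0, 0.0])


def make_ideal_oligomer(spec: FixtureSpec, block_id: str | None = None) -> BuildingBlock:
    """Exact Cn oligomer about +z centered on the origin (zero fit residual)."""
    base = _monomer_coords(spec)
    res_names = spec.res_names or ("ALA",)
    chains = []
    for c in range(spec.n):
        rot = rotation_about_axis([0, 0, 1], 360.0 * c / spec.n)
        xyz = base @ rot.T
        cid = _CHAIN_IDS[c % len(_CHAIN_IDS)]
        chains.append(
            tuple(
                AtomRecord(
                    element="C",
                    name="CA",
                    coords=xyz[i],
                    residue_index=i,
                    chain_id=cid,
                    is_ca=True,
                    res_name=res_names[i % len(res_names)],
                )
                for i in range(len(xyz))
            )
        )
    return BuildingBlock(
        id=block_id or f"C{spec.n}-fixture",
        chains=tuple(chains),
        cyclic_order=spec.n,
        axis=np.array([0.0, 0.0, 1.0]),
        center=np.zeros(3),
    )


def attach_site(
    block: BuildingBlock,
    frame: RigidTransform,
    module_type: str = "LHD101",
    polarity: str = "A",
    replicate: bool = True,
) -> BuildingBlock:
    """Attach a bond site (block-local frame, anchored at the first chain's
    last residue) and optionally replicate it over the block's internal Cn."""
    last = max(a.residue_index for a in block.chains[0])
    sites = list(block.bond_sites)
    reps = block.cyclic_order if replicate else 1
    for k in range(reps):
        cid = block.chains[k % len(block.chains)][0].chain_id
        sites.append(
            BondSite(
                frame=block.internal_op(k) @ frame,
                module_type=module_type,
                polarity=polarity,
                anchor=(cid, last),
            )
        )
    return block.with_sites(sites)


def make_heterotrimer(spec: FixtureSpec | None = None, block_id: str = "het3") -> BuildingBlock:
    """Pseudo-symmetric heterotrimer: C3 geometry, but treated as carrying a
    single bonding module on one chain only (symmetry deliberately broken, as
    when one subunit of a trimer is swapped for a variant bearing the site)."""
    spec = spec or FixtureSpec(n=3)
    block = make_ideal_oligomer(spec, block_id=block_id)
    return replace(block, heterotrimer_flag=True)


def _bond_frame(p_from: np.ndarray, p_to: np.ndarray, offset: float = 3.0) -> RigidTransform:
    """Deterministic mating frame between two component centers: origin at
    the midpoint (displaced ``offset`` A perpendicular so that symmetry
    replicas have distinct origins), z along the center-to-center direction."""
    z = p_to - p_from
    z = z / np.linalg.norm(z)
    ref = np.eye(3)[np.argmin(np.abs(z))]
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    origin = 0.5 * (p_from + p_to) + offset * x
    return RigidTransform(np.column_stack([x, y, z]), origin)


_DEFAULT_CAGE_DOFS = {"psi0": 15.0, "r0": 30.0, "psi1": -40.0, "r1": 26.0}


def make_mated_pair(
    design: str,
    dofs: dict | None = None,
    seed: int = 0,
    module_type: str = "LHD101",
    max_retries: int = 6,
) -> tuple[ArchitectureSpec, dict]:
    """Two-component cage fixture with exact closure at planted DOFs.

    ``design`` is a two-component label without the design index, e.g.
    ``"O42"``, ``"T33"``, ``"D32"``, ``"I32"``.  Returns the architecture
    spec (blocks decorated with exactly mating sites, one bond pairing) and
    the planted DOF values.  Block radii are grown automatically if the
    initial geometry clashes.
    """
    if len(design) != 3:
        raise ValueError("expected a [sym]ab label like 'O42'")
    sym, a, b = design[0], int(design[1]), int(design[2])
    group_name = f"D{a}" if sym == "D" else sym
    from .symgroups import generate_point_group

    group = generate_point_group(group_name)
    dof_values = dict(_DEFAULT_CAGE_DOFS)
    if sym in ("T",) and a == b:
        # both components share the canonical 3-fold line: plant B on the
        # opposite axis direction
        dof_values["r1"] = -dof_values["r1"]
    if dofs:
        dof_values.update(dofs)

    radius_a, radius_b = 12.0, 12.0
    for attempt in range(max_retries):
        block_a = make_ideal_oligomer(
            FixtureSpec(n=a, radius=radius_a, seed=seed), block_id=f"{design}-A"
        )
        block_b = make_ideal_oligomer(
            FixtureSpec(n=b, radius=radius_b, seed=seed), block_id=f"{design}-B"
        )
        bare = ArchitectureSpec(
            name=design,
            group=group,
            slots=(
                ComponentSlot(block_a, target_axis_order=a),
                ComponentSlot(block_b, target_axis_order=b),
            ),
        )
        model = place_components(bare, dof_values)
        p_a = model.slot_instances(0)[0][1]
        # nearest B instance by placement-origin distance (deterministic)
        cands = sorted(
            model.slot_instances(1),
            key=lambda kt: (round(float(np.linalg.norm(kt[1].origin - p_a.origin)), 6), kt[0]),
        )
        p_b = cands[0][1]
        mate = _bond_frame(p_a.origin, p_b.origin)
        site_a_local = p_a.inverse() @ mate
        site_b_local = p_b.inverse() @ complement_frame(mate)
        block_a = attach_site(block_a, site_a_local, module_type, "A")
        block_b = attach_site(block_b, site_b_local, module_type, "Aprime")
        spec = ArchitectureSpec(
            name=design,
            group=group,
            slots=(
                ComponentSlot(block_a, target_axis_order=a),
                ComponentSlot(block_b, target_axis_order=b),
            ),
            bond_pairings=((0, 0, 1, 0),),
        )
        full = place_components(spec, dof_values)
        if clash_count(full) == 0:
            return spec, dof_values
        radius_a *= 1.3
        radius_b *= 1.3
        dof_values = {k: v * 1.2 if k.startswith("r") else v for k, v in dof_values.items()}
    raise ValueError(f"could not find a clash-free geometry for {design}")


def make_coaxial_pair(
    n: int = 3,
    dz: float = 24.0,
    dphi: float = 25.0,
    seed: int = 0,
) -> tuple[ArchitectureSpec, dict]:
    """Stacked-ring fixture: two Cn oligomers on one axis, offset ``dz`` and
    rotated ``dphi``, bridged by a bispecific connector pair of sites (two
    module types, one presented by each ring)."""
    from .symgroups import generate_point_group

    group = generate_point_group(f"C{n}")
    block_a = make_ideal_oligomer(FixtureSpec(n=n, seed=seed), block_id=f"C{n}-base")
    block_b = make_ideal_oligomer(FixtureSpec(n=n, seed=seed), block_id=f"C{n}-top")
    dof_values = {"psi0": 0.0, "r0": 0.0, "psi1": dphi, "r1": dz}
    bare = ArchitectureSpec(
        name=f"C{n}-stack",
        group=group,
        slots=(
            ComponentSlot(block_a, target_axis_order=n),
            ComponentSlot(block_b, target_axis_order="coaxial"),
        ),
    )
    model = place_components(bare, dof_values)
    p_a = model.slot_instances(0)[0][1]
    p_b = model.slot_instances(1)[0][1]
    mate = _bond_frame(p_a.origin, p_b.origin, offset=10.0)
    block_a = attach_site(block_a, p_a.inverse() @ mate, "LHD206", "A")
    block_b = attach_site(block_b, p_b.inverse() @ complement_frame(mate), "LHD206", "Aprime")
    spec = ArchitectureSpec(
        name=f"C{n}-stack",
        group=group,
        slots=(
            ComponentSlot(block_a, target_axis_order=n),
            ComponentSlot(block_b, target_axis_order="coaxial"),
        ),
        bond_pairings=((0, 0, 1, 0),),
    )
    return spec, dof_values


def make_p3_blocks(
    a: float = 90.0,
    z_off: float = 12.0,
    phi: float = 20.0,
    seed: int = 0,
    c: float = 60.0,
) -> tuple[BuildingBlock, BuildingBlock, dict]:
    """Two C3 trimers whose sites mate exactly in a P3 layer at the planted
    (a, z_off, phi).  Returns (block_a, block_b, planted parameters)."""
    from .lattice import build_p3_layer
    from .symgroups import Cell

    block_a = make_ideal_oligomer(FixtureSpec(n=3, seed=seed), block_id="C3-A")
    block_b = make_ideal_oligomer(FixtureSpec(n=3, seed=seed), block_id="C3-B")
    layer = build_p3_layer(block_a, block_b, a, z_off, phi, n_cells=1, c=c)
    (_, _, p_a), (_, _, p_b) = layer.units
    # nearest B image to the A trimer at the origin
    images = layer.neighbor_images(1)
    shifts = sorted(
        images, key=lambda v: (round(float(np.linalg.norm(p_b.origin + v)), 6), *np.round(v, 6))
    )
    p_b_near = RigidTransform.from_translation(shifts[0]) @ p_b
    mate = _bond_frame(p_a.origin, p_b_near.origin)
    block_a = attach_site(block_a, p_a.inverse() @ mate, "LHD101", "A")
    block_b = attach_site(block_b, p_b_near.inverse() @ complement_frame(mate), "LHD101", "Aprime")
    return block_a, block_b, {"a": a, "z_off": z_off, "phi": phi}


def make_f432_fixture(
    a: float = 200.0,
    cage_radius: float = 35.0,
    seed: int = 0,
) -> tuple[BuildingBlock, BuildingBlock, dict]:
    """O-symmetric cage (8 C3 trimers on the body diagonals, 24 bonding
    modules) plus a C3 linker, with sites mating exactly in an F432 crystal
    of lattice constant ``a``.  Returns (cage block, linker block, planted
    parameters)."""
    from .symgroups import Cell, generate_point_group

    group = generate_point_group("O")
    trimer = make_ideal_oligomer(FixtureSpec(n=3, radius=12.0, seed=seed), block_id="cage-C3")
    cage_dofs = {"psi0": 0.0, "r0": cage_radius}
    bare = ArchitectureSpec(
        name="O3", group=group, slots=(ComponentSlot(trimer, target_axis_order=3),)
    )
    model = place_components(bare, cage_dofs)
    # generating bond: the trimer on the (-1,1,1) diagonal faces the
    # tetrahedral hole at fractional (-1/4,1/4,1/4)
    d0 = np.array([-1.0, 1.0, 1.0]) / np.sqrt(3.0)
    inst = min(
        model.slot_instances(0),
        key=lambda kt: float(np.linalg.norm(kt[1].origin - cage_radius * d0)),
    )[1]
    hole = a * np.array([-0.25, 0.25, 0.25])
    mate = _bond_frame(inst.origin, hole)
    trimer = attach_site(trimer, inst.inverse() @ mate, "LHD206", "A")
    spec = ArchitectureSpec(
        name="O3", group=group, slots=(ComponentSlot(trimer, target_axis_order=3),)
    )
    cage = place_components(spec, cage_dofs).as_block("O3-cage")

    linker = make_ideal_oligomer(FixtureSpec(n=3, radius=10.0, seed=seed), block_id="C3-linker")
    from .lattice import _diagonal_placement

    l0 = _diagonal_placement(linker, hole)
    linker = attach_site(linker, l0.inverse() @ complement_frame(mate), "LHD206", "Aprime")
    return cage, linker, {"a": a, "cage_radius": cage_radius}


def perturb_block(
    block: BuildingBlock, sigma_t: float, sigma_r: float, seed: int = 0
) -> BuildingBlock:
    """Rigidly perturb every bond-site frame (atoms untouched).

    Translations are isotropic Gaussian (sigma_t per axis, A); rotations have
    a uniformly random axis and angle |N(0, sigma_r)| degrees.  sigma = 0 is
    the identity; a fixed seed reproduces the perturbation bit-for-bit.
    """
    if sigma_t < 0 or sigma_r < 0:
        raise ValueError("perturbation widths must be non-negative")
    rng = np.random.default_rng(seed)
    sites = []
    for site in block.bond_sites:
        dt = rng.normal(0.0, sigma_t, size=3) if sigma_t > 0 else np.zeros(3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = abs(rng.normal(0.0, sigma_r)) if sigma_r > 0 else 0.0
        wobble = RigidTransform(rotation_about_axis(axis, ang), dt)
        sites.append(replace(site, frame=wobble @ site.frame))
    return block.with_sites(sites)
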