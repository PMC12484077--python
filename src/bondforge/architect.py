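"""Realize target architectures as coordinates.

A declarative :class:`ArchitectureSpec` names a symmetry group, assigns each
cyclic component to a group axis (or a coaxial/general position), and lists
which bond sites must mate.  :func:`place_components` turns DOF values
(phase about the axis, offset along it) into a symmetric
:class:`AssemblyModel`; :func:`closure_error` scores how well each required
bond mates; :func:`scan_dofs` grids over the DOFs; :func:`clash_count` and
:func:`junction_gaps` supply the geometric design filters and the export
needed by downstream generative backbone tools.

Only the asymmetric unit is explicitly specified -- the full assembly is the
orbit of each placed component under the group, with copies related by a
block's own internal Cn merged.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .blocks import AtomRecord, BondSite, BuildingBlock, complement_frame
from .geometry import RigidTransform, rotation_angle_between
from .symgroups import SymmetryGroup, generate_point_group, symmetry_axes

__all__ = [
    "ComponentSlot",
    "ArchitectureSpec",
    "AssemblyModel",
    "PairingClosure",
    "ClosureReport",
    "JunctionGap",
    "place_components",
    "closure_error",
    "scan_dofs",
    "clash_count",
    "junction_gaps",
    "DEFAULT_CLOSURE_TOLERANCE",
    "DEFAULT_LEVER_ARM",
]

#: Default threshold on the combined closure score.  Mirrors the WORMS-style
#: permitted deviation of a segment from its target position (0.1); the
#: original units are not published, so the value is stored as a threshold on
#: the blended translation+rotation score and is configurable per spec.
DEFAULT_CLOSURE_TOLERANCE = 0.1

#: Lever arm (Angstroms) converting rotational deviation into an equivalent
#: displacement at the far end of a bonding module.
DEFAULT_LEVER_ARM = 20.0


@dataclass(frozen=True)
class ComponentSlot:
    """One component of the asymmetric unit.

    ``target_axis_order``: order of the group axis the block sits on;
    ``"coaxial"`` stacks the block on slot 0's axis (two-DOF coaxial
    sampling); ``"general"`` places it at a general position given by
    ``base_transform`` (used e.g. for docked heterotrimers whose own 3-fold
    is not a group axis).
    """

    block: BuildingBlock
    target_axis_order: int | str = 1
    base_transform: RigidTransform | None = None

    def dof_names(self, index: int) -> list[str]:
        if self.target_axis_order == "general":
            return []
        return [f"psi{index}", f"r{index}"]


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    group: SymmetryGroup
    slots: tuple[ComponentSlot, ...]
    bond_pairings: tuple[tuple[int, int, int, int], ...] = ()  # (slot_i, site_i, slot_j, site_j)
    tolerance: float = DEFAULT_CLOSURE_TOLERANCE
    lever_arm: float = DEFAULT_LEVER_ARM
    clash_max: int = 2  # interface clash-check threshold

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(self.slots))
        object.__setattr__(self, "bond_pairings", tuple(self.bond_pairings))
        for si, site_i, sj, site_j in self.bond_pairings:
            a = self.slots[si].block.bond_sites[site_i]
            b = self.slots[sj].block.bond_sites[site_j]
            if not a.complements(b):
                raise ValueError(
                    f"pairing ({si},{site_i})-({sj},{site_j}) is not "
                    "polarity-complementary within one module type"
                )

    def dof_names(self) -> list[str]:
        names: list[str] = []
        for i, slot in enumerate(self.slots):
            names.extend(slot.dof_names(i))
        return names


@dataclass(frozen=True)
class AssemblyModel:
    """A realized symmetric assembly: placed instances of each slot."""

    spec: ArchitectureSpec
    dof_values: dict
    placements: tuple[RigidTransform, ...]  # asymmetric-unit placement per slot
    instances: tuple[tuple[int, int, RigidTransform], ...]  # (slot, op index, transform)

    def slot_instances(self, slot_index: int) -> list[tuple[int, RigidTransform]]:
        return [(k, tf) for k, (s, _, tf) in enumerate(self.instances) if s == slot_index]

    def instance_count(self, slot_index: int) -> int:
        return len(self.slot_instances(slot_index))

    def site_instances(self, slot_index: int | None = None):
        """All materialized bond sites: (slot, instance, site index, global frame, site)."""
        out = []
        for k, (s, _, tf) in enumerate(self.instances):
            if slot_index is not None and s != slot_index:
                continue
            for j, site in enumerate(self.spec.slots[s].block.bond_sites):
                out.append((s, k, j, tf @ site.frame, site))
        return out

    def atoms(self):
        """Materialize (coords, instance_index, element) arrays for the assembly."""
        coords, inst, elements = [], [], []
        for k, (s, _, tf) in enumerate(self.instances):
            block = self.spec.slots[s].block
            xyz = tf.apply(block.all_coords())
            coords.append(xyz)
            inst.append(np.full(len(xyz), k))
            elements.extend(block.elements())
        return np.vstack(coords), np.concatenate(inst), elements

    def ca_coords(self) -> np.ndarray:
        out = []
        for s, _, tf in self.instances:
            out.append(tf.apply(self.spec.slots[s].block.all_coords(ca_only=True)))
        return np.vstack(out)

    def as_block(self, block_id: str) -> BuildingBlock:
        """Flatten the assembly into a rigid BuildingBlock (one chain per
        placed chain), carrying all materialized bond sites.  Used when an
        assembly serves as a secondary building unit, e.g. a polyhedral cage
        placed into a crystal."""
        chains = []
        sites = []
        for k, (s, _, tf) in enumerate(self.instances):
            block = self.spec.slots[s].block
            for ci, chain in enumerate(block.chains):
                cid = f"{k}:{chain[0].chain_id}"
                chains.append(
                    tuple(
                        replace(a, coords=tf.apply(a.coords), chain_id=cid)
                        for a in chain
                    )
                )
        for s, k, j, frame, site in self.site_instances():
            sites.append(
                BondSite(
                    frame=frame,
                    module_type=site.module_type,
                    polarity=site.polarity,
                    anchor=(f"{k}:{site.anchor[0]}", site.anchor[1]),
                )
            )
        return BuildingBlock(id=block_id, chains=tuple(chains), cyclic_order=1,
                             bond_sites=tuple(sites))


# ---------------------------------------------------------------------------
# placement


def _canonical_axis(group: SymmetryGroup, order: int) -> np.ndarray:
    """Canonical group axis of a given order: highest z-component wins, then
    lexicographically smallest (axes are undirected; stored sign-canonical)."""
    candidates = [ax for o, ax in symmetry_axes(group) if o == order]
    if not candidates:
        raise ValueError(f"group {group.name} has no axis of order {order}")
    return sorted(candidates, key=lambda a: (-round(a[2], 9), *np.round(a, 9)))[0]


def _align_rotation(from_vec: np.ndarray, to_vec: np.ndarray) -> np.ndarray:
    """Minimal rotation taking one unit vector onto another."""
    f = np.asarray(from_vec, dtype=float)
    t = np.asarray(to_vec, dtype=float)
    f, t = f / np.linalg.norm(f), t / np.linalg.norm(t)
    v = np.cross(f, t)
    c = float(np.dot(f, t))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 about any perpendicular
        perp = np.cross(f, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(f, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        from .geometry import rotation_about_axis

        return rotation_about_axis(perp, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _slot_placement(spec: ArchitectureSpec, index: int, dof_values: dict) -> RigidTransform:
    slot = spec.slots[index]
    block = slot.block
    if slot.target_axis_order == "general":
        if slot.base_transform is None:
            raise ValueError("general-position slot needs a base_transform")
        return slot.base_transform
    if slot.target_axis_order == "coaxial":
        axis = _resolved_axis(spec, 0)
    else:
        axis = _resolved_axis(spec, index)
    psi = float(dof_values.get(f"psi{index}", 0.0))
    r = float(dof_values.get(f"r{index}", 0.0))
    align = RigidTransform.from_rotation(_align_rotation(block.axis, axis)) @ \
        RigidTransform.from_translation(-block.center)
    twist = RigidTransform.from_axis_angle(axis, psi)
    shift = RigidTransform.from_translation(r * axis)
    return shift @ twist @ align


def _resolved_axis(spec: ArchitectureSpec, index: int) -> np.ndarray:
    slot = spec.slots[index]
    order = slot.target_axis_order
    if order == "coaxial":
        return _resolved_axis(spec, 0)
    if not isinstance(order, int) or order < 1:
        raise ValueError(f"invalid target_axis_order {order!r}")
    if order == 1:
        return np.array([0.0, 0.0, 1.0])
    return _canonical_axis(spec.group, order)


def place_components(spec: ArchitectureSpec, dof_values: dict | None = None) -> AssemblyModel:
    """Place every slot and expand by the group orbit.

    Instances related by a block's own internal cyclic rotation are merged,
    so each slot contributes |G| / n instances for a Cn block whose axis is a
    group axis (|G| instances at a general position).
    """
    dof_values = dict(dof_values or {})
    placements = [_slot_placement(spec, i, dof_values) for i in range(len(spec.slots))]
    instances: list[tuple[int, int, RigidTransform]] = []
    for i, (slot, pl) in enumerate(zip(spec.slots, placements)):
        block = slot.block
        # two orbit elements are the same physical copy when they differ by
        # one of the block's own internal rotations (applied in block frame)
        internal = [block.internal_op(k) for k in range(block.cyclic_order)]
        kept: list[tuple[int, RigidTransform]] = []
        for oi, op in enumerate(spec.group.ops):
            g = RigidTransform(op.rotation, op.translation)
            cand = g @ pl
            dup = any(
                cand.is_close(prev @ intr, atol=1e-6)
                for _, prev in kept
                for intr in internal
            )
            if not dup:
                kept.append((oi, cand))
        instances.extend((i, oi, tf) for oi, tf in kept)
    return AssemblyModel(
        spec=spec, dof_values=dof_values,
        placements=tuple(placements), instances=tuple(instances),
    )


# ---------------------------------------------------------------------------
# closure scoring


@dataclass(frozen=True)
class PairingClosure:
    pairing: tuple[int, int, int, int]
    dt: float  # translational deviation, Angstroms
    dtheta: float  # rotational deviation, degrees
    combined: float
    partner_instance: int
    passed: bool


@dataclass(frozen=True)
class ClosureReport:
    pairings: tuple[PairingClosure, ...]
    tolerance: float

    @property
    def passed(self) -> bool:
        return all(p.passed for p in self.pairings)

    @property
    def worst(self) -> float:
        return max((p.combined for p in self.pairings), default=0.0)


def closure_error(
    model: AssemblyModel,
    spec: ArchitectureSpec | None = None,
    extra_images: np.ndarray | None = None,
) -> ClosureReport:
    """Score each required bond pairing of the asymmetric unit.

    For the pairing's site on slot i (first instance), the nearest
    complementary site instance on slot j is found by frame-origin distance
    (ties broken by smaller rotational deviation).  Deviations: dt = distance
    between the presented origins, dtheta = rotation angle between the
    partner frame and the complement of the presented frame, combined =
    sqrt(dt^2 + (lever_arm * dtheta_rad)^2).  ``extra_images`` adds candidate
    lattice translations for periodic models (minimum-image convention).
    """
    spec = spec or model.spec
    images = np.zeros((1, 3)) if extra_images is None else np.asarray(extra_images)
    results = []
    for pairing in spec.bond_pairings:
        si, site_i, sj, site_j = pairing
        inst_i = model.slot_instances(si)
        if not inst_i:
            raise ValueError(f"slot {si} has no instances in the model")
        tf_i = inst_i[0][1]
        presented = tf_i @ spec.slots[si].block.bond_sites[site_i].frame
        target = complement_frame(presented)
        ref_site = spec.slots[si].block.bond_sites[site_i]
        best = None
        for s, k, j, frame, site in model.site_instances(sj):
            if not site.complements(ref_site):
                continue
            if s == si and frame.is_close(presented, atol=1e-9):
                continue  # the presented site itself
            for img in images:
                shifted = RigidTransform(frame.rotation, frame.translation + img)
                dt = float(np.linalg.norm(shifted.origin - presented.origin))
                dtheta = rotation_angle_between(shifted.rotation, target.rotation)
                key = (dt, dtheta)
                if best is None or key < best[0]:
                    best = (key, k)
        if best is None:
            raise ValueError(f"no complementary site instance for pairing {pairing}")
        (dt, dtheta), partner = best
        combined = float(np.hypot(dt, spec.lever_arm * np.deg2rad(dtheta)))
        results.append(
            PairingClosure(
                pairing=pairing, dt=dt, dtheta=dtheta, combined=combined,
                partner_instance=partner, passed=combined <= spec.tolerance,
            )
        )
    return ClosureReport(pairings=tuple(results), tolerance=spec.tolerance)


# ---------------------------------------------------------------------------
# clash counting


def clash_count(
    model: AssemblyModel,
    cutoff: float = 2.4,
    exclusion_shell: float = 5.0,
    extra_coords: np.ndarray | None = None,
) -> int:
    """Number of inter-instance atom pairs closer than ``cutoff``.

    Atom pairs in which both atoms lie within ``exclusion_shell`` of an
    engaged bond-site origin are excluded: mated bonding modules are expected
    to be in contact at their interface.  A site instance counts as engaged
    when a complementary site instance's origin lies within 1 A of its own
    (mated frames have coincident origins).  Uses a k-d tree; equal to the
    brute-force all-pairs count by construction.
    """
    coords, inst, _ = model.atoms()
    if extra_coords is not None:
        coords = np.vstack([coords, extra_coords])
        inst = np.concatenate([inst, np.full(len(extra_coords), inst.max() + 1 if len(inst) else 0)])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    mask = inst[pairs[:, 0]] != inst[pairs[:, 1]]
    pairs = pairs[mask]
    if len(pairs) == 0:
        return 0
    engaged = _engaged_site_origins(model)
    if len(engaged):
        site_tree = cKDTree(engaged)
        near = site_tree.query(coords, distance_upper_bound=exclusion_shell)[0] < np.inf
        both_near = near[pairs[:, 0]] & near[pairs[:, 1]]
        pairs = pairs[~both_near]
    return int(len(pairs))


def _engaged_site_origins(model: AssemblyModel, mate_tol: float = 1.0) -> np.ndarray:
    sites = model.site_instances()
    origins = np.array([frame.origin for _, _, _, frame, _ in sites]).reshape(-1, 3)
    out = []
    for a in range(len(sites)):
        sa, ka, _, fa, site_a = sites[a]
        for b in range(len(sites)):
            if a == b:
                continue
            sb, kb, _, fb, site_b = sites[b]
            if not site_a.complements(site_b):
                continue
            if np.linalg.norm(origins[a] - origins[b]) <= mate_tol:
                out.append(origins[a])
                break
    return np.array(out).reshape(-1, 3)


# ---------------------------------------------------------------------------
# DOF scanning


def scan_dofs(
    spec: ArchitectureSpec,
    grid: dict,
    compute_clash: bool = True,
    clash_cutoff: float = 2.4,
) -> tuple[pd.DataFrame, int]:
    """Exhaustive grid scan over named DOFs.

    ``grid`` maps DOF names (``psi0``, ``r0``, ...) to 1-D value arrays.
    Returns a DataFrame with one deterministic row per grid point (closure =
    worst combined score over pairings, clash count, accepted flag) and the
    index of the global closure minimum.
    """
    names = list(grid.keys())
    values = [np.atleast_1d(np.asarray(grid[n], dtype=float)) for n in names]
    if any(len(v) == 0 for v in values) or not names:
        raise ValueError("empty DOF grid")
    rows = []
    for combo in itertools.product(*values):
        dof_values = dict(zip(names, combo))
        model = place_components(spec, dof_values)
        report = closure_error(model, spec)
        clashes = clash_count(model, cutoff=clash_cutoff) if compute_clash else 0
        accepted = report.worst <= spec.tolerance and clashes <= spec.clash_max
        rows.append((*combo, report.worst, clashes, accepted))
    df = pd.DataFrame(rows, columns=[*names, "closure", "clashes", "accepted"])
    best = int(df["closure"].idxmin())
    return df, best


# ---------------------------------------------------------------------------
# junction-gap export


@dataclass(frozen=True)
class JunctionGap:
    """Gap between a structural-module terminus and its bonding-module frame,
    exported for downstream generative backbone design."""

    slot_index: int
    site_index: int
    anchor: tuple[str, int]
    terminus_frame: RigidTransform  # C-alpha frame at the attachment terminus
    site_frame: RigidTransform  # bonding-module docking frame (block-local)
    gap_distance: float  # Angstroms between the two frame origins


def junction_gaps(model: AssemblyModel) -> list[JunctionGap]:
    """One gap per unique junction in the asymmetric unit.

    Unique junctions are the bond sites anchored on each block's first chain
    (the asymmetric chain); symmetric replicas are generated by the group and
    need no separate backbone design.
    """
    gaps = []
    for si, slot in enumerate(model.spec.slots):
        block = slot.block
        first_chain = block.chains[0][0].chain_id
        for j, site in enumerate(block.bond_sites):
            chain_id, res_idx = site.anchor
            if chain_id != first_chain:
                continue
            chain = next(c for c in block.chains if c[0].chain_id == chain_id)
            ca = next(
                (a for a in chain if a.residue_index == res_idx and a.is_ca), None
            )
            if ca is None:
                raise ValueError(
                    f"slot {si} site {j}: no C-alpha at anchor {site.anchor}"
                )
            z = ca.coords - block.center
            nz = np.linalg.norm(z)
            z = z / nz if nz > 1e-9 else np.array([0.0, 0.0, 1.0])
            x = np.cross([0.0, 0.0, 1.0], z)
            if np.linalg.norm(x) < 1e-6:
                x = np.array([1.0, 0.0, 0.0])
            x = x / np.linalg.norm(x)
            y = np.cross(z, x)
            terminus = RigidTransform(np.column_stack([x, y, z]), ca.coords)
            gap = float(np.linalg.norm(site.frame.origin - ca.coords))
            gaps.append(
                JunctionGap(
                    slot_index=si, site_index=j, anchor=site.anchor,
                    terminus_frame=terminus, site_frame=site.frame,
                    gap_distance=gap,
                )
            )
    return gaps


def export_junction_gaps(gaps: list[JunctionGap], path) -> None:
    """Write junction gaps as JSON for external backbone generators."""
    payload = []
    for g in gaps:
        payload.append(
            {
                "slot": g.slot_index,
                "site": g.site_index,
                "anchor_chain": g.anchor[0],
                "anchor_residue": g.anchor[1],
                "terminus_rotation": g.terminus_frame.rotation.tolist(),
                "terminus_origin": g.terminus_frame.origin.tolist(),
                "site_rotation": g.site_frame.rotation.tolist(),
                "site_origin": g.site_frame.origin.tolist(),
                "gap_distance": g.gap_distance,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
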