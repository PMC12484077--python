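"""Chiral symmetry groups used as design targets.

Point groups Cn, Dn, T, O and I (proper rotations only; designed proteins are
chiral, so mirror/inversion groups are excluded), plus the two periodic groups
used for open architectures: the plane group P3 and the face-centred-cubic
space group F432.

Canonical orientations:

* Cn / Dn -- principal axis on +z; the first 2-fold of Dn on +x.
* T       -- 2-fold axes on the coordinate axes, 3-folds on the body diagonals.
* O       -- 4-fold axes on the coordinate axes.
* I       -- 2-fold axes on the coordinate axes (so one 2-fold on z), 3-folds
             on the body diagonals; 5-folds through (0, 1, phi)-type directions
             with phi the golden ratio.  The paper-level geometry never fixes
             an icosahedral setting; this one contains T as an aligned
             subgroup, which keeps all chiral point groups in one frame.

Periodic operators are stored with Cartesian rotation parts and translations
in Angstroms; fractional forms are available through the group's cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geometry import axis_angle_of, rotation_about_axis

__all__ = [
    "SymOp",
    "SymmetryGroup",
    "Cell",
    "generate_point_group",
    "symmetry_axes",
    "min_axis_angle",
    "lattice_group",
    "rotation_fixed_points",
    "POINT_GROUP_ORDERS",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

#: |G| for the named polyhedral groups (forced analytically).
POINT_GROUP_ORDERS = {"T": 12, "O": 24, "I": 60}

_MATCH_TOL = 1e-6  # group-membership tolerance on matrix elements


@dataclass(frozen=True)
class SymOp:
    """One proper symmetry operation ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray
    axis: np.ndarray
    angle: float  # degrees, in (0, 360]; identity reported as 360
    order: int  # smallest k with rotation^k = I

    @classmethod
    def from_matrix(cls, rotation, translation=None) -> "SymOp":
        rotation = np.asarray(rotation, dtype=float)
        if translation is None:
            translation = np.zeros(3)
        translation = np.asarray(translation, dtype=float)
        det = np.linalg.det(rotation)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"operator is not a proper rotation (det={det:.6f})")
        if not np.allclose(rotation.T @ rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation part is not orthonormal")
        axis, angle = axis_angle_of(rotation)
        return cls(rotation, translation, axis, angle, _rotation_order(rotation))

    @property
    def is_identity(self) -> bool:
        return self.order == 1 and np.allclose(self.translation, 0.0, atol=1e-9)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def _rotation_order(rotation: np.ndarray, max_order: int = 60) -> int:
    power = np.eye(3)
    for k in range(1, max_order + 1):
        power = power @ rotation
        if np.allclose(power, np.eye(3), atol=1e-8):
            return k
    raise ValueError("rotation order exceeds supported maximum")


@dataclass(frozen=True)
class Cell:
    """Unit-cell parameters (a, b, c in Angstroms; angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    @property
    def orth(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (columns are the cell vectors)."""
        al, be, ga = np.deg2rad([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos([al, be, ga])
        sg = np.sin(ga)
        v = np.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def frac(self) -> np.ndarray:
        return np.linalg.inv(self.orth)


@dataclass(frozen=True)
class SymmetryGroup:
    """A finite rotation group or a periodic (plane/space) group.

    For periodic kinds ``ops`` holds one representative per coset of the
    lattice-translation subgroup (|P3| = 3 per cell, |F432| = 96 per cell);
    composition closes modulo lattice translations.
    """

    name: str
    kind: str  # "point" | "plane" | "space"
    ops: tuple[SymOp, ...]
    cell: Cell | None = None

    def __len__(self) -> int:
        return len(self.ops)

    @property
    def is_point(self) -> bool:
        return self.kind == "point"

    def frac_op(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(rotation, translation) of op ``i`` in fractional coordinates."""
        if self.cell is None:
            raise ValueError("point groups have no fractional form")
        m, minv = self.cell.orth, self.cell.frac
        op = self.ops[i]
        return minv @ op.rotation @ m, minv @ op.translation


# ---------------------------------------------------------------------------
# point groups

_POINT_RE = re.compile(r"^(?:C(?P<cn>\d+)|D(?P<dn>\d+)|(?P<poly>[TOI]))$")


def _generators(name: str) -> list[np.ndarray]:
    m = _POINT_RE.match(name)
    if not m:
        raise ValueError(f"unrecognized point-group label {name!r}")
    if m.group("cn"):
        n = int(m.group("cn"))
        if n < 1:
            raise ValueError("cyclic order must be >= 1")
        return [rotation_about_axis([0, 0, 1], 360.0 / n)]
    if m.group("dn"):
        n = int(m.group("dn"))
        if n < 2:
            raise ValueError("dihedral order must be >= 2")
        return [
            rotation_about_axis([0, 0, 1], 360.0 / n),
            rotation_about_axis([1, 0, 0], 180.0),
        ]
    poly = m.group("poly")
    if poly == "T":
        return [
            rotation_about_axis([0, 0, 1], 180.0),
            rotation_about_axis([1, 1, 1], 120.0),
        ]
    if poly == "O":
        return [
            rotation_about_axis([0, 0, 1], 90.0),
            rotation_about_axis([1, 0, 0], 90.0),
        ]
    # I: 2-fold on z plus a 5-fold through an icosahedron vertex (0, 1, phi)
    return [
        rotation_about_axis([0, 0, 1], 180.0),
        rotation_about_axis([0, 1, _GOLDEN], 72.0),
    ]


def _closure(generators: list[np.ndarray], max_size: int = 120) -> list[np.ndarray]:
    mats: list[np.ndarray] = [np.eye(3)]
    frontier = [np.eye(3)]
    while frontier:
        new: list[np.ndarray] = []
        for m in frontier:
            for g in generators:
                cand = g @ m
                if not any(np.allclose(cand, x, atol=_MATCH_TOL) for x in mats):
                    mats.append(cand)
                    new.append(cand)
                    if len(mats) > max_size:
                        raise RuntimeError("group closure did not terminate")
        frontier = new
    return mats


def generate_point_group(name: str) -> SymmetryGroup:
    """Generate a chiral point group (Cn, Dn, T, O or I) by generator closure."""
    mats = _closure(_generators(name))
    ops = sorted(
        (SymOp.from_matrix(m) for m in mats),
        key=lambda op: (op.angle % 360.0, *np.round(op.axis, 9)),
    )
    return SymmetryGroup(name=name, kind="point", ops=tuple(ops))


def symmetry_axes(group: SymmetryGroup) -> list[tuple[int, np.ndarray]]:
    """Distinct rotation-axis lines of a point group.

    Antipodal axes are merged; each line is reported with the highest rotation
    order present on it, ordered by descending order then lexicographic axis.
    """
    if not group.is_point:
        raise ValueError("symmetry_axes is defined for point groups only")
    found: list[tuple[int, np.ndarray]] = []
    for op in group.ops:
        if op.order == 1:
            continue
        for i, (order, axis) in enumerate(found):
            if abs(abs(np.dot(axis, op.axis)) - 1.0) < 1e-8:
                if op.order > order:
                    found[i] = (op.order, axis)
                break
        else:
            found.append((op.order, op.axis))
    return sorted(found, key=lambda t: (-t[0], *np.round(t[1], 9)))


def min_axis_angle(group: SymmetryGroup, n1: int, n2: int) -> float:
    """Minimum intersection angle (degrees, folded to [0, 90]) between an
    order-``n1`` and an order-``n2`` rotation axis of a point group.

    For n1 == n2 only distinct axis lines are compared.  This is the quantity
    that fixes two-component cage geometry, e.g. 45 degrees between the 2- and
    4-fold axes of the octahedral group.
    """
    axes = symmetry_axes(group)
    a1 = [ax for order, ax in axes if order == n1]
    a2 = [ax for order, ax in axes if order == n2]
    if not a1 or not a2:
        raise ValueError(f"group {group.name} lacks an axis of order {n1 if not a1 else n2}")
    best = None
    for x in a1:
        for y in a2:
            cosang = abs(np.clip(np.dot(x, y), -1.0, 1.0))
            if n1 == n2 and cosang > 1.0 - 1e-8:
                continue  # same line
            ang = float(np.rad2deg(np.arccos(cosang)))
            if best is None or ang < best:
                best = ang
    if best is None:
        raise ValueError("no distinct axis pair with the requested orders")
    return best


# ---------------------------------------------------------------------------
# periodic groups

_FCC_CENTERINGS = np.array(
    [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
)


def lattice_group(name: str, cell: Cell) -> SymmetryGroup:
    """Build the plane group P3 or the space group F432 on a given cell.

    P3 requires a hexagonal cell (a = b, gamma = 120); its three rotations per
    cell fix in-cell points at fractional (0,0), (1/3,2/3) and (2/3,1/3).
    F432 requires a cubic cell; its 96 per-cell operators are the 24 rotations
    of O composed with the four face-centering translations.
    """
    if name == "P3":
        if abs(cell.a - cell.b) > 1e-6 or abs(cell.gamma - 120.0) > 1e-6:
            raise ValueError("P3 requires a hexagonal cell (a=b, gamma=120)")
        ops = [
            SymOp.from_matrix(rotation_about_axis([0, 0, 1], 120.0 * k))
            for k in range(3)
        ]
        return SymmetryGroup(name="P3", kind="plane", ops=tuple(ops), cell=cell)
    if name == "F432":
        if (
            abs(cell.a - cell.b) > 1e-6
            or abs(cell.a - cell.c) > 1e-6
            or any(abs(x - 90.0) > 1e-6 for x in (cell.alpha, cell.beta, cell.gamma))
        ):
            raise ValueError("F432 requires a cubic cell")
        point = generate_point_group("O")
        orth = cell.orth
        ops = [
            SymOp.from_matrix(op.rotation, orth @ t)
            for t in _FCC_CENTERINGS
            for op in point.ops
        ]
        return SymmetryGroup(name="F432", kind="space", ops=tuple(ops), cell=cell)
    raise ValueError(f"unsupported periodic group {name!r}")


def rotation_fixed_points(group: SymmetryGroup) -> list[tuple[int, np.ndarray]]:
    """In-cell fractional fixed points of the rotational operators.

    Solves ``op . x = x (mod lattice)`` for every non-identity operator over
    neighbouring lattice translations and returns the distinct (order,
    fractional point) site classes.  For P3 the z coordinate is free and
    reported as 0.
    """
    if group.cell is None:
        raise ValueError("fixed-point analysis applies to periodic groups")
    sites: list[tuple[int, np.ndarray]] = []
    planar = group.kind == "plane"
    dim = 2 if planar else 3
    shifts = np.array(
        np.meshgrid(*([[-1, 0, 1]] * dim), indexing="ij")
    ).reshape(dim, -1).T
    for i, op in enumerate(group.ops):
        if op.order == 1:
            continue
        rf, tf = group.frac_op(i)
        a = np.eye(dim) - rf[:dim, :dim]
        if abs(np.linalg.det(a)) < 1e-9:
            continue  # axis parallel to a free direction; handled as line, not point
        for n in shifts:
            x = np.linalg.solve(a, tf[:dim] + n)
            x = np.mod(np.round(x, 9), 1.0)
            if np.all(x < 1.0 - 1e-9):
                full = np.zeros(3)
                full[:dim] = x
                for order, seen in sites:
                    if np.allclose(seen, full, atol=1e-6) and order >= op.order:
                        break
                else:
                    sites = [
                        (o, s) for o, s in sites if not np.allclose(s, full, atol=1e-6)
                    ]
                    sites.append((op.order, full))
    return sorted(sites, key=lambda t: (-t[0], *np.round(t[1], 9)))


def parse_group(name: str, cell: Cell | None = None) -> SymmetryGroup:
    """Dispatch: point-group label, or P3/F432 with a cell."""
    if name in ("P3", "F432"):
        if cell is None:
            raise ValueError(f"{name} requires unit-cell parameters")
        return lattice_group(name, cell)
    return generate_point_group(name)
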