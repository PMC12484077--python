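"""Rigid-body transforms and small rotation utilities.

Everything downstream (bond-site frames, component placements, symmetry
operators) is expressed as a proper rigid transform ``x -> R x + t`` with
``det(R) = +1``.  Units are Angstroms for translations and degrees for angles
unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "rotation_about_axis",
    "axis_angle_of",
    "rotation_angle_between",
    "random_rotation",
]


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """3x3 matrix for a right-handed rotation of ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    return Rotation.from_rotvec(axis / n * np.deg2rad(angle_deg)).as_matrix()


def axis_angle_of(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit vector) and angle in degrees of a proper rotation matrix.

    The identity is reported as axis +z, angle 360 so that angles live in
    (0, 360].  The axis sign is canonicalized so its first component with
    magnitude > 1e-8 is positive (rotation axes are undirected lines).
    """
    rotvec = Rotation.from_matrix(matrix).as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rotvec)))
    if angle < 1e-9:
        return np.array([0.0, 0.0, 1.0]), 360.0
    axis = rotvec / np.linalg.norm(rotvec)
    for c in axis:
        if abs(c) > 1e-8:
            if c < 0:
                axis = -axis
            break
    return axis, angle


def rotation_angle_between(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotation matrices."""
    _, ang = axis_angle_of(r1.T @ r2)
    return 0.0 if ang == 360.0 else ang


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotation(cls, rotation) -> "RigidTransform":
        return cls(np.asarray(rotation, dtype=float), np.zeros(3))

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(translation, dtype=float))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg, center=None) -> "RigidTransform":
        """Rotation about an axis line through ``center`` (origin by default)."""
        rot = rotation_about_axis(axis, angle_deg)
        if center is None:
            return cls(rot, np.zeros(3))
        center = np.asarray(center, dtype=float)
        return cls(rot, center - rot @ center)

    @classmethod
    def from_euler_zyz(cls, angles_deg, origin) -> "RigidTransform":
        rot = Rotation.from_euler("ZYZ", angles_deg, degrees=True).as_matrix()
        return cls(rot, np.asarray(origin, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    @property
    def origin(self) -> np.ndarray:
        """Image of the local origin (frame position)."""
        return self.translation

    def is_close(self, other: "RigidTransform", atol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    def distance(self, other: "RigidTransform") -> tuple[float, float]:
        """(translational distance in A, rotational distance in degrees)."""
        dt = float(np.linalg.norm(self.translation - other.translation))
        dr = rotation_angle_between(self.rotation, other.rotation)
        return dt, dr
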