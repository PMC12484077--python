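"""Cyclic building blocks and their bonding-module attachment sites.

A building block is a cyclic (Cn) protein oligomer decorated with oriented
bond sites.  Each site carries the docking frame at which a reversible
heterodimeric bonding module (an LHD-style interface) is presented; the two
polarities of a module type ("A" and "Aprime") mate when one site's presented
frame coincides with the complement of the other's.

The mating convention used throughout the package: the complementary frame is
the site frame rotated 180 degrees about its local x axis, with the interface
normal along local z.  Published LHD interface coordinates are not available,
so site frames always come from user configuration or from the synthetic
fixture generator, which shares this convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .geometry import RigidTransform, axis_angle_of, rotation_about_axis

__all__ = [
    "AtomRecord",
    "BondSite",
    "BuildingBlock",
    "read_structure",
    "write_structure",
    "fit_cyclic_axis",
    "complement_frame",
    "parse_design_name",
    "COMPLEMENT_FLIP",
]

#: Local 180-degree flip about x relating a site frame to its mate's frame.
COMPLEMENT_FLIP = RigidTransform.from_rotation(rotation_about_axis([1, 0, 0], 180.0))


@dataclass(frozen=True)
class AtomRecord:
    element: str
    name: str
    coords: np.ndarray
    residue_index: int  # 0-based internally; converted to 1-based on write
    chain_id: str
    is_ca: bool = True
    res_name: str = "ALA"

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")


@dataclass(frozen=True)
class BondSite:
    """Oriented docking frame of one bonding-module polarity."""

    frame: RigidTransform
    module_type: str  # e.g. "LHD101", "LHD206", "LHD29", "LHD202"
    polarity: str  # "A" | "Aprime"
    anchor: tuple[str, int]  # (chain_id, residue_index) of the attachment terminus

    def __post_init__(self):
        if self.polarity not in ("A", "Aprime"):
            raise ValueError("polarity must be 'A' or 'Aprime'")

    def complements(self, other: "BondSite") -> bool:
        return self.module_type == other.module_type and self.polarity != other.polarity


def complement_frame(site: BondSite | RigidTransform) -> RigidTransform:
    """Frame at which the complementary polarity partner must sit to mate.

    An involution: ``complement(complement(f)) == f``.
    """
    frame = site.frame if isinstance(site, BondSite) else site
    return frame @ COMPLEMENT_FLIP


@dataclass(frozen=True)
class BuildingBlock:
    """A cyclic oligomer with a fitted symmetry frame and bond sites."""

    id: str
    chains: tuple[tuple[AtomRecord, ...], ...]
    cyclic_order: int = 1
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bond_sites: tuple[BondSite, ...] = ()
    heterotrimer_flag: bool = False

    def __post_init__(self):
        object.__setattr__(self, "chains", tuple(tuple(c) for c in self.chains))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.cyclic_order < 1:
            raise ValueError("cyclic_order must be >= 1")
        if self.chains and len(self.chains) % self.cyclic_order != 0:
            raise ValueError("chain count must be a multiple of cyclic_order")

    @property
    def chain_ids(self) -> list[str]:
        return [c[0].chain_id for c in self.chains]

    @property
    def n_atoms(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain_coords(self, i: int, ca_only: bool = False) -> np.ndarray:
        atoms = self.chains[i]
        if ca_only:
            atoms = [a for a in atoms if a.is_ca]
        return np.array([a.coords for a in atoms])

    def all_coords(self, ca_only: bool = False) -> np.ndarray:
        return np.vstack([self.chain_coords(i, ca_only) for i in range(len(self.chains))])

    def elements(self) -> list[str]:
        return [a.element for chain in self.chains for a in chain]

    def with_sites(self, sites) -> "BuildingBlock":
        return replace(self, bond_sites=tuple(sites))

    def internal_op(self, k: int) -> RigidTransform:
        """k-th internal cyclic rotation about the block's own symmetry axis."""
        return RigidTransform.from_axis_angle(
            self.axis, 360.0 * k / self.cyclic_order, center=self.center
        )


# ---------------------------------------------------------------------------
# file I/O (delegated to gemmi)


def read_structure(path, dialect: str | None = None, block_id: str | None = None) -> BuildingBlock:
    """Read a PDB or mmCIF file into a raw BuildingBlock (no fitted symmetry).

    Residue indices are converted to 0-based sequential positions per chain.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chains = []
    for chain in model:
        atoms = []
        for ridx, residue in enumerate(chain):
            for atom in residue:
                atoms.append(
                    AtomRecord(
                        element=atom.element.name,
                        name=atom.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_index=ridx,
                        chain_id=chain.name,
                        is_ca=atom.name == "CA",
                        res_name=residue.name,
                    )
                )
        if atoms:
            chains.append(tuple(atoms))
    if not chains:
        raise ValueError(f"no atoms in {path}")
    return BuildingBlock(id=block_id or st.name or "block", chains=tuple(chains))


def write_structure(block: BuildingBlock, path, dialect: str | None = None) -> None:
    """Write a block as PDB or mmCIF (chosen by extension unless given)."""
    path = str(path)
    if dialect is None:
        dialect = "mmCIF" if path.endswith((".cif", ".mmcif")) else "PDB"
    st = gemmi.Structure()
    st.name = block.id
    model = gemmi.Model("1")
    for chain_atoms in block.chains:
        chain = gemmi.Chain(chain_atoms[0].chain_id)
        current = None
        for a in chain_atoms:
            if current is None or current.seqid.num != a.residue_index + 1:
                current = gemmi.Residue()
                current.name = a.res_name
                current.seqid = gemmi.SeqId(a.residue_index + 1, " ")
                chain.add_residue(current)
                current = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            current.add_atom(atom)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if dialect.upper() == "PDB":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


# ---------------------------------------------------------------------------
# cyclic-symmetry fitting


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``."""
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, fc - rot @ mc)


def fit_cyclic_axis(block: BuildingBlock, n: int):
    """Fit the Cn symmetry axis of a block by chain-to-next-chain superposition.

    Returns ``(fitted_block, residual_rmsd)`` where the fitted block carries
    the least-squares axis/center and ``cyclic_order = n``.  Chains are
    compared on C-alpha atoms only; chain i is mapped onto chain i + m/n
    (cyclically) for m chains.
    """
    m = len(block.chains)
    if n < 1 or m % n != 0:
        raise ValueError(f"cyclic order {n} does not divide chain count {m}")
    lengths = {len([a for a in c if a.is_ca]) for c in block.chains}
    if len(lengths) != 1:
        raise ValueError("chains must have equal C-alpha counts for symmetry fitting")
    if n == 1:
        fitted = BuildingBlock(
            id=block.id, chains=block.chains, cyclic_order=1,
            axis=np.array([0.0, 0.0, 1.0]), center=block.all_coords().mean(axis=0),
            bond_sites=block.bond_sites, heterotrimer_flag=block.heterotrimer_flag,
        )
        return fitted, 0.0
    step = m // n
    moving = np.vstack([block.chain_coords(i, ca_only=True) for i in range(m)])
    fixed = np.vstack([block.chain_coords((i + step) % m, ca_only=True) for i in range(m)])
    tf = _kabsch(moving, fixed)
    # rotvec angle lies in (0, 180], which covers 360/n for every n >= 2 and
    # orients the axis with the positive rotation sense chain i -> chain i+1
    from scipy.spatial.transform import Rotation as _R

    rv = _R.from_matrix(tf.rotation).as_rotvec()
    norm = np.linalg.norm(rv)
    axis = rv / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    # axis point closest to the origin: min-norm solution of (I - R) c = t
    center = np.linalg.pinv(np.eye(3) - tf.rotation) @ tf.translation
    # shift the center along the axis to the structure's axial midpoint
    proj = float(np.dot(block.all_coords(ca_only=True).mean(axis=0) - center, axis))
    center = center + proj * np.asarray(axis)
    residual = float(np.sqrt(np.mean(np.sum((tf.apply(moving) - fixed) ** 2, axis=1))))
    fitted = BuildingBlock(
        id=block.id, chains=block.chains, cyclic_order=n,
        axis=np.asarray(axis, dtype=float), center=center,
        bond_sites=block.bond_sites, heterotrimer_flag=block.heterotrimer_flag,
    )
    return fitted, residual


# ---------------------------------------------------------------------------
# design-name nomenclature: [sym]ab-c, e.g. "O42-24"

_NAME_RE = re.compile(r"^([DTOI])(\d)(\d)-(\d+)$")


def parse_design_name(name: str) -> tuple[str, int, int, int]:
    """Parse the [sym]ab-c architecture nomenclature (e.g. O42-24).

    ``sym`` is the target point group family, ``a`` and ``b`` the rotational
    orders of the two components, ``c`` the design identifier.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"design name {name!r} does not match [D|T|O|I]ab-c")
    sym, a, b, c = m.groups()
    return sym, int(a), int(b), int(c)
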