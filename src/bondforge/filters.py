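"""In-silico design-filter pipeline.

Threshold engine over metric tables (externally predicted metrics such as
pLDDT, pTM, ddG, shape complementarity or SAP are ingested from CSV, never
recomputed here) plus the internally computed structural metrics: C-alpha
RMSD, solvent-accessible surface area and methionine count.  Comparator
strictness follows the published cut-offs exactly (e.g. methionine count
<= 5 inclusive, shape complementarity > 0.6 exclusive, SAP < 30 exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import BuildingBlock

__all__ = [
    "FilterSpec",
    "FilterCriterion",
    "apply_filters",
    "ca_rmsd",
    "sasa",
    "methionine_count",
    "AF2_DEFAULT",
    "RPX_INTERFACE",
    "VDW_RADII",
]

_COMPARATORS = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
}


@dataclass(frozen=True)
class FilterCriterion:
    metric: str
    comparator: str  # "<" | "<=" | ">" | ">="
    threshold: float
    source: str = "external"  # "external" | "internal"

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unsupported comparator {self.comparator!r}")

    def check(self, value: float) -> bool:
        return bool(_COMPARATORS[self.comparator](value, self.threshold))


@dataclass(frozen=True)
class FilterSpec:
    name: str
    criteria: tuple[FilterCriterion, ...]

    def __post_init__(self):
        names = [c.metric for c in self.criteria]
        if len(names) != len(set(names)):
            raise ValueError("metric names must be unique within a spec")


#: structure-prediction screen: confident fold and assembly prediction plus
#: closeness to the design model
AF2_DEFAULT = FilterSpec(
    "af2_default",
    (
        FilterCriterion("plddt", ">", 90.0),
        FilterCriterion("ptm", ">", 0.80),
        FilterCriterion("ca_rmsd", "<", 2.0),
    ),
)

#: interface-quality screen applied after docking/sequence design
RPX_INTERFACE = FilterSpec(
    "rpx_interface",
    (
        FilterCriterion("methionine_count", "<=", 5.0),
        FilterCriterion("shape_complementarity", ">", 0.6),
        FilterCriterion("ddg", "<", -20.0),
        FilterCriterion("sasa", "<", 1600.0),
        FilterCriterion("clash_check", "<=", 2.0),
        FilterCriterion("unsat_hbonds", "<=", 2.0),
        FilterCriterion("sap_delta", "<", 30.0),
    ),
)


def apply_filters(
    table: pd.DataFrame,
    spec: FilterSpec,
    missing_policy: str = "fail",
) -> tuple[pd.DataFrame, list[str]]:
    """Evaluate a filter spec over a wide metric table.

    ``table``: one row per design id (index), one column per metric.  A
    design passes iff every criterion holds; a missing metric fails the
    design (default) or is skipped under ``missing_policy="skip"``.
    Returns (per-design boolean frame with a ``pass`` column, survivor ids
    in index order).
    """
    if missing_policy not in ("fail", "skip"):
        raise ValueError("missing_policy must be 'fail' or 'skip'")
    results = {}
    for crit in spec.criteria:
        if crit.metric in table.columns:
            col = pd.to_numeric(table[crit.metric], errors="raise")
            ok = col.map(lambda v: bool(crit.check(v)) if np.isfinite(v) else missing_policy == "skip")
        else:
            ok = pd.Series(missing_policy == "skip", index=table.index)
        results[crit.metric] = ok
    frame = pd.DataFrame(results, index=table.index)
    frame["pass"] = frame.all(axis=1) if len(frame.columns) else True
    survivors = list(frame.index[frame["pass"]])
    return frame, survivors


def ca_rmsd(coords_a: np.ndarray, coords_b: np.ndarray, superpose: bool = True) -> float:
    """C-alpha RMSD between equally long, consistently ordered coordinate
    sets, optionally after optimal (Kabsch) rigid superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-shape (N, 3)")
    if superpose:
        ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
        h = ac.T @ bc
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        a = ac @ rot.T
        b = bc
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


#: element van der Waals radii (A) used for surface-area calculation
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


def sasa(
    coords: np.ndarray,
    elements,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict | None = None,
) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area by Shrake-Rupley sphere sampling.

    Deterministic for a fixed point count (Fibonacci sphere).  Returns
    (total, per-atom) in A^2.  Delegates the sphere-point accounting to
    biotite's implementation with an explicit per-atom radius array.
    """
    import biotite.structure as struc

    coords = np.asarray(coords, dtype=float)
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    try:
        radius_arr = np.array([table[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc}") from exc
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.asarray(elements, dtype="U2")
    arr.hetero = np.full(n, False)
    per_atom = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=n_sphere_points,
        vdw_radii=radius_arr,
    )
    per_atom = np.nan_to_num(per_atom)
    return float(per_atom.sum()), per_atom


def methionine_count(block: BuildingBlock, per_chain: bool = True) -> int:
    """MET residues in the asymmetric chain (or whole block).

    Low surface methionine counts are favoured to limit oxidation-prone,
    sticky interfaces in designed assemblies.
    """
    chains = block.chains[:1] if per_chain else block.chains
    if not chains or not chains[0]:
        raise ValueError("block has no residue information")
    count = 0
    for chain in chains:
        seen = set()
        for atom in chain:
            if atom.res_name is None:
                raise ValueError("residue identities unavailable for this block")
            if atom.residue_index not in seen:
                seen.add(atom.residue_index)
                if atom.res_name.upper() == "MET":
                    count += 1
    return count
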