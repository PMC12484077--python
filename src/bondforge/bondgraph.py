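"""Protein-protein interaction networks of building blocks and bonding modules.

Nodes are designed oligomers with typed, polarized bond sites; edges are the
architectures two nodes can co-assemble into through one complementary
module pair.  Shared bonding modules let one block participate in several
architectures (line, star and ring network topologies), and a block shared
between a bounded cage and an unbounded lattice is dynamically
reconfigurable.

Site bookkeeping is purely stoichiometric: site concentration equals node
concentration times valence, capping ligands consume complementary sites
1:1, and assembly yields are limited by the scarcer side.  No equilibrium
constants enter -- the designed interfaces span a wide affinity range but no
assembly free energies are available, so equilibrium partitioning is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "ComponentNode",
    "InteractionEdge",
    "BondNetwork",
    "PoolState",
    "classify_topology",
    "shared_components",
    "site_balance",
    "UNBOUNDED_GROUPS",
]

#: architecture labels counted as unbounded (periodic) rather than cages
UNBOUNDED_GROUPS = ("P3", "F432", "P6", "P4")


@dataclass(frozen=True)
class ComponentNode:
    """One designed oligomer: its bond sites per oligomer copy."""

    block_id: str
    site_types: tuple[tuple[str, str], ...]  # (module_type, polarity) per site

    @property
    def valence(self) -> int:
        return len(self.site_types)


@dataclass(frozen=True)
class InteractionEdge:
    node_a: str
    node_b: str
    site_a: tuple[str, str]
    site_b: tuple[str, str]
    architecture: str  # produced architecture label, e.g. "O43-36" or "P3-23"

    def __post_init__(self):
        if self.site_a[0] != self.site_b[0] or self.site_a[1] == self.site_b[1]:
            raise ValueError(
                f"edge {self.node_a}-{self.node_b}: sites must share a module "
                "type with opposite polarity"
            )

    @property
    def is_unbounded(self) -> bool:
        return self.architecture.split("-")[0] in UNBOUNDED_GROUPS


@dataclass(frozen=True)
class BondNetwork:
    nodes: tuple[ComponentNode, ...]
    edges: tuple[InteractionEdge, ...]

    def __post_init__(self):
        ids = {n.block_id for n in self.nodes}
        for e in self.edges:
            if e.node_a not in ids or e.node_b not in ids:
                raise ValueError(f"edge references unknown node: {e}")

    def node(self, block_id: str) -> ComponentNode:
        return next(n for n in self.nodes if n.block_id == block_id)

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(n.block_id for n in self.nodes)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, architecture=e.architecture)
        return g


def classify_topology(network: BondNetwork) -> str:
    """Classify a connected interaction network as line, star, ring or other.

    star: one hub of degree >= 3, all other nodes degree 1;
    line: a simple path; ring: a single cycle covering all nodes.
    Disconnected networks raise, reporting the components.
    """
    g = nx.Graph(network.graph())
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"network is disconnected; components: {comps}")
    degrees = sorted(d for _, d in g.degree())
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 1:
        return "other"
    if m == n and all(d == 2 for d in degrees):
        return "ring"
    if m == n - 1 and degrees[-1] <= 2:
        return "line"
    if m == n - 1 and degrees[-1] >= 3 and all(d == 1 for d in degrees[:-1]):
        return "star"
    return "other"


def shared_components(network: BondNetwork) -> list[dict]:
    """Nodes participating in two or more architectures.

    A node shared between a bounded (point-group) and an unbounded (lattice)
    architecture is flagged reconfigurable: adding the alternative partner
    can drive exchange between the two assemblies.  Deterministic ordering by
    node id.
    """
    out = []
    for node in sorted(network.nodes, key=lambda n: n.block_id):
        archs = [
            e.architecture
            for e in network.edges
            if node.block_id in (e.node_a, e.node_b)
        ]
        if len(archs) < 2:
            continue
        kinds = {
            "unbounded" if a.split("-")[0] in UNBOUNDED_GROUPS else "bounded"
            for a in archs
        }
        out.append(
            {
                "node": node.block_id,
                "architectures": sorted(archs),
                "reconfigurable": kinds == {"bounded", "unbounded"},
            }
        )
    return out


@dataclass(frozen=True)
class PoolState:
    """Concentrations on the oligomer basis (uM) plus capping ligands.

    Caps are monovalent binders given as {module_type: (polarity, uM)}: a cap
    of polarity "Aprime" occupies "A" sites of that module type.
    """

    concentrations: dict
    caps: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.concentrations.items():
            if v < 0:
                raise ValueError(f"negative concentration for {k}")
        for k, (_, v) in self.caps.items():
            if v < 0:
                raise ValueError(f"negative cap concentration for {k}")


def site_balance(pool: PoolState, network: BondNetwork) -> dict:
    """Stoichiometric site bookkeeping.

    For every (module_type, polarity) class: supply = sum over nodes of
    concentration x (sites of that class per oligomer).  Caps consume
    complementary sites 1:1 (up to availability).  Each edge's maximum
    assembly yield is the scarcer of its two site-class supplies after
    capping, expressed in site equivalents (uM).  Site conservation holds
    per class: total = paired + capped + free.
    """
    supply: dict[tuple[str, str], float] = {}
    for node in network.nodes:
        conc = float(pool.concentrations.get(node.block_id, 0.0))
        for st in node.site_types:
            supply[st] = supply.get(st, 0.0) + conc
    total = dict(supply)
    capped: dict[tuple[str, str], float] = {k: 0.0 for k in supply}
    for module_type, (polarity, conc) in pool.caps.items():
        target = (module_type, "A" if polarity == "Aprime" else "Aprime")
        if target in supply:
            used = min(float(conc), supply[target])
            supply[target] -= used
            capped[target] = capped.get(target, 0.0) + used
    per_edge = {}
    paired: dict[tuple[str, str], float] = {k: 0.0 for k in supply}
    for e in network.edges:
        avail_a = supply.get(e.site_a, 0.0) - paired.get(e.site_a, 0.0)
        avail_b = supply.get(e.site_b, 0.0) - paired.get(e.site_b, 0.0)
        y = max(0.0, min(avail_a, avail_b))
        per_edge[(e.node_a, e.node_b, e.architecture)] = y
        paired[e.site_a] = paired.get(e.site_a, 0.0) + y
        paired[e.site_b] = paired.get(e.site_b, 0.0) + y
    free = {k: supply[k] - paired.get(k, 0.0) for k in supply}
    return {
        "per_edge_yield": per_edge,
        "total_sites": total,
        "paired": paired,
        "capped": capped,
        "free": free,
    }
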