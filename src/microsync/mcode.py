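"""MCODE complex detection and cross-stage module tracing.

MCODE (molecular complex detection) scores each vertex by the density of
the highest k-core of its closed neighborhood, then grows complexes
greedily from high-weight seeds: a neighbor joins if its weight is within
a vertex-weight-percentage (vwp) of the seed's. Complexes without a
2-core are discarded and, optionally, degree-1 members are trimmed
(haircut) or dense neighbors added (fluff).

Modules found in one stage's network are traced into the other stages by
projecting their member set and counting the edges that survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .table import TaxonomyMap

__all__ = [
    "Module",
    "ModuleTrace",
    "vertex_weights",
    "find_complexes",
    "trace_modules",
    "module_taxonomy",
]


class McodeError(ValueError):
    pass


@dataclass
class Module:
    members: tuple[str, ...]     # sorted member OTU ids
    seed: str
    score: float                 # MCODE native score: density x size
    avg_degree: float            # within-module mean degree (ranking key)
    rank: int
    stage: str | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModuleTrace:
    module_rank: int
    target_stage: str
    retained_members: tuple[str, ...]
    induced_edges: int
    edge_retention: float        # induced edges / source-module edges
    first_neighbors: tuple[str, ...] = field(default_factory=tuple)


def _core_weight(sub: nx.Graph) -> float:
    """k_max x density of the highest k-core of ``sub``."""
    if sub.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(sub)
    k_max = max(cores.values())
    core_nodes = [v for v, c in cores.items() if c >= k_max]
    core = sub.subgraph(core_nodes)
    n = core.number_of_nodes()
    density = 2.0 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    return k_max * density


def vertex_weights(net: nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: core-clustering coefficient of the closed
    neighborhood (highest-k-core order times that core's density)."""
    weights = {}
    for v in net.nodes:
        nbrs = list(net.neighbors(v))
        sub = net.subgraph([v, *nbrs])
        weights[v] = _core_weight(sub)
    return weights


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively strip members whose induced degree falls below 2."""
    members = set(members)
    changed = True
    while changed and len(members) > 1:
        sub = g.subgraph(members)
        trim = {v for v in members if sub.degree(v) < 2}
        changed = bool(trim)
        members -= trim
    return members


def find_complexes(
    net: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.2,
    min_core: int = 2,
) -> list[Module]:
    """Greedy seeded MCODE complex prediction.

    Seeds are taken in descending vertex-weight order; expansion does a
    breadth-first walk over unvisited neighbors whose weight is at least
    ``seed_weight * (1 - vwp)``. Predicted complexes must contain a
    ``min_core``-core; haircut trims degree-1 members, fluff optionally
    adds dense outside neighbors (without unmarking them for later seeds).
    Modules are ranked by average within-module degree (descending), ties
    by size then seed id.
    """
    if not (0 <= vwp < 1):
        raise McodeError("vwp must be in [0, 1)")
    weights = vertex_weights(net)
    visited: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in sorted(net.nodes, key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0:
            continue
        cutoff = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            nxt = []
            for u in frontier:
                for w in net.neighbors(u):
                    if w in visited or weights[w] < cutoff:
                        continue
                    visited.add(w)
                    members.add(w)
                    nxt.append(w)
            frontier = nxt
        raw.append((seed, members))

    modules = []
    for seed, members in raw:
        sub = net.subgraph(members)
        cores = nx.core_number(sub) if sub.number_of_edges() else {}
        if not cores or max(cores.values()) < min_core:
            continue
        if haircut:
            members = _haircut(net.subgraph(members).copy(), members)
            if not members:
                continue
        if fluff:
            extra = set()
            for v in members:
                for w in net.neighbors(v):
                    if w in members or w in extra:
                        continue
                    nbrs = list(net.neighbors(w))
                    sub_w = net.subgraph([w, *nbrs])
                    n = sub_w.number_of_nodes()
                    dens = (
                        2.0 * sub_w.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
                    )
                    if dens > fluff_density:
                        extra.add(w)
            members = set(members) | extra
        sub = net.subgraph(members)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
        modules.append(
            Module(
                members=tuple(sorted(members)),
                seed=seed,
                score=density * n,
                avg_degree=2.0 * e / n if n else 0.0,
                rank=0,
                stage=net.graph.get("stage"),
            )
        )
    modules.sort(key=lambda m: (-m.avg_degree, -len(m), m.seed))
    for i, m in enumerate(modules, start=1):
        m.rank = i
    return modules


def trace_modules(
    modules: list[Module],
    nets: dict[str, nx.Graph],
    source_stage: str,
) -> list[ModuleTrace]:
    """Project each module's member set into every stage's network.

    Reports the retained members, the number of induced edges, the edge
    retention ratio relative to the module's edges in its source network,
    and the first neighbors (nodes adjacent to any retained member).
    """
    if source_stage not in nets:
        raise McodeError(f"source stage {source_stage!r} not among networks")
    source = nets[source_stage]
    traces = []
    for module in modules:
        src_edges = source.subgraph(module.members).number_of_edges()
        for stage, net in nets.items():
            retained = tuple(sorted(set(module.members) & set(net.nodes)))
            induced = net.subgraph(retained).number_of_edges()
            ratio = induced / src_edges if src_edges else 0.0
            neighbors: set[str] = set()
            for v in retained:
                neighbors.update(net.neighbors(v))
            neighbors -= set(retained)
            traces.append(
                ModuleTrace(
                    module_rank=module.rank,
                    target_stage=stage,
                    retained_members=retained,
                    induced_edges=induced,
                    edge_retention=ratio,
                    first_neighbors=tuple(sorted(neighbors)),
                )
            )
    return traces


def module_taxonomy(module: Module, tax: TaxonomyMap) -> list[tuple[str, int]]:
    """Family-level composition: (family label, member count), descending.

    Members unassigned at family aggregate under their most specific
    assigned prefix (``unclassified <name>``); fully unassigned members
    fall into a single ``unclassified`` row.
    """
    counts: dict[str, int] = {}
    for otu in module.members:
        label = tax.label_at(otu, "family") if otu in tax else "unclassified"
        counts[label] = counts.get(label, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
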