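"""Topological data model of a polyarc cell sheet.

A :class:`Mesh` is the single source of topology for force inference: nodes
(junction and intermediate point positions), edges (ordered point chains
between junctions, each carrying one unknown tension), cells (the pressure
unknowns) and junctions (where force-balance equations are written).

Conventions
-----------
* Coordinates are mathematical (x right, y up); image readers flip the row
  axis before building a mesh.
* ``Edge.side_cells = (cell_i, cell_j)`` with cell *i* on the **left** when
  the chain is traversed in stored order.  A side may be :data:`MEDIUM`
  (the surrounding medium, encoded as cell id 0) or ``None`` (outside the
  modelled domain, e.g. beyond a pinned boundary).
* A *stub* edge has exactly one endpoint at a junction; its other end is a
  free chain terminus produced by truncation at the region-of-interest
  boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

#: Cell id reserved for the surrounding medium.
MEDIUM = 0


class MeshError(ValueError):
    """Raised when mesh construction or validation fails."""


@dataclass
class Node:
    id: int
    position: np.ndarray  # shape (2,)


@dataclass
class Edge:
    id: int
    chain: list[int]                      # ordered node ids, >= 2
    side_cells: tuple[int | None, int | None]
    endpoint_junctions: tuple[int | None, int | None] = (None, None)
    is_stub: bool = False


@dataclass
class Cell:
    id: int
    edge_ids: list[int]
    is_partial: bool = False
    is_medium: bool = False


@dataclass
class Junction:
    id: int
    node_id: int
    incident_edge_ids: list[int]

    @property
    def order(self) -> int:
        return len(self.incident_edge_ids)


@dataclass
class Mesh:
    nodes: dict[int, Node]
    edges: dict[int, Edge]
    cells: dict[int, Cell]
    junctions: dict[int, Junction]
    length_scale: float = 1.0

    def node_xy(self, node_id: int) -> np.ndarray:
        return self.nodes[node_id].position

    def chain_points(self, edge_id: int) -> np.ndarray:
        """Return the (n, 2) coordinate array of an edge's chain."""
        e = self.edges[edge_id]
        return np.array([self.nodes[n].position for n in e.chain], dtype=float)

    def junction_at_node(self, node_id: int) -> Junction | None:
        return self._junction_by_node.get(node_id)

    @property
    def _junction_by_node(self) -> dict[int, Junction]:
        if not hasattr(self, "_jbn_cache"):
            self._jbn_cache = {j.node_id: j for j in self.junctions.values()}
        return self._jbn_cache

    def edge_end_junctions(self, edge_id: int) -> tuple[int | None, int | None]:
        return self.edges[edge_id].endpoint_junctions


@dataclass
class MeshCounts:
    """Equation/unknown tallies for a mesh and an exclusion set.

    All counts are computed by direct enumeration on the pre-removal
    topology.  ``n_tension_eqns`` counts two force balances (x, y) per
    retained junction; ``n_pressures`` counts complete plus partial cells
    with the medium as a single partial cell.
    """

    n_junctions: int
    n_junctions_removed: int
    n_tensions: int
    n_tension_eqns: int
    n_complete_cells: int
    n_partial_cells: int
    n_excess_edges: int
    n_removed_edges: int
    n_double_junctions: int
    n_stubs: int
    n_pressure_eqns: int
    n_pressures: int


def _is_cellish(side: int | None) -> bool:
    return side is not None


def build_mesh(
    nodes: list[Node],
    edges: list[Edge],
    cells: list[Cell],
    length_scale: float = 1.0,
) -> Mesh:
    """Assemble and validate a mesh; derive junctions and stub flags.

    Junctions are nodes where at least two edge endpoints meet.  An edge with
    exactly one endpoint at a junction is a stub; an edge with no junction
    endpoint is invalid (dangling).

    Raises
    ------
    MeshError
        On dangling edge endpoints, unclosed non-partial cell loops or
        inconsistent edge-cell sidedness.
    """
    node_map = {n.id: n for n in nodes}
    if len(node_map) != len(nodes):
        raise MeshError("duplicate node ids")
    edge_map = {e.id: e for e in edges}
    cell_map = {c.id: c for c in cells}

    # validate references and chains
    for e in edges:
        if len(e.chain) < 2:
            raise MeshError(f"edge {e.id}: chain must have >= 2 nodes")
        for nid in e.chain:
            if nid not in node_map:
                raise MeshError(f"edge {e.id} references missing node {nid}")
        a, b = e.side_cells
        if a == b:
            raise MeshError(f"edge {e.id}: side cells must be distinct")
        for s in e.side_cells:
            if s is not None and s != MEDIUM and s not in cell_map:
                raise MeshError(f"edge {e.id} references missing cell {s}")

    medium_cells = [c for c in cells if c.is_medium]
    if len(medium_cells) > 1:
        raise MeshError("at most one medium cell per mesh")

    # derive junctions: nodes where >= 2 edge endpoints meet
    incidence: dict[int, list[int]] = {}
    for e in edges:
        ends = (e.chain[0], e.chain[-1])
        for nid in set(ends) if ends[0] == ends[1] else ends:
            incidence.setdefault(nid, []).append(e.id)
    # closed-loop edge: same node twice counts as two endpoint incidences
    for e in edges:
        if e.chain[0] == e.chain[-1]:
            incidence[e.chain[0]].append(e.id)

    junctions: dict[int, Junction] = {}
    jid = 0
    for nid, eids in incidence.items():
        if len(eids) >= 2:
            junctions[jid] = Junction(jid, nid, sorted(set(eids), key=eids.index))
            jid += 1
    jbn = {j.node_id: j.id for j in junctions.values()}

    for e in edges:
        ja = jbn.get(e.chain[0])
        jb = jbn.get(e.chain[-1])
        e.endpoint_junctions = (ja, jb)
        n_j = (ja is not None) + (jb is not None)
        if e.chain[0] == e.chain[-1]:
            n_j = 2 if ja is not None else 0
        if n_j == 0:
            raise MeshError(f"edge {e.id}: dangling (no junction endpoint)")
        e.is_stub = n_j == 1

    mesh = Mesh(node_map, edge_map, cell_map, junctions, length_scale)

    # sidedness: every edge naming cell c must be listed by c, and vice versa
    for c in cells:
        if c.is_medium:
            continue
        for eid in c.edge_ids:
            if eid not in edge_map:
                raise MeshError(f"cell {c.id} references missing edge {eid}")
            if c.id not in edge_map[eid].side_cells:
                raise MeshError(
                    f"inconsistent sidedness: edge {eid} does not border cell {c.id}"
                )
        if not c.is_partial:
            if cell_node_loop(mesh, c.id) is None:
                raise MeshError(f"cell {c.id}: boundary loop not closed")
    return mesh


def cell_node_loop(mesh: Mesh, cell_id: int) -> list[int] | None:
    """Ordered (counter-clockwise) node loop of a cell, or None if open.

    Each boundary edge is traversed with the cell on its left; successive
    chains are stitched head-to-tail.  Returns node ids with the start node
    not repeated at the end.
    """
    cell = mesh.cells[cell_id]
    directed: dict[int, tuple[int, bool]] = {}  # start node -> (edge, forward)
    for eid in cell.edge_ids:
        e = mesh.edges[eid]
        if e.side_cells[0] == cell_id:
            directed[e.chain[0]] = (eid, True)
        elif e.side_cells[1] == cell_id:
            directed[e.chain[-1]] = (eid, False)
    if not directed:
        return None
    start = next(iter(directed))
    loop: list[int] = []
    node = start
    for _ in range(len(directed) + 1):
        if node not in directed:
            return None
        eid, fwd = directed.pop(node)
        chain = mesh.edges[eid].chain
        seq = chain if fwd else chain[::-1]
        loop.extend(seq[:-1])
        node = seq[-1]
        if node == start:
            break
    else:
        return None
    if directed:  # unused edges remain: not a single closed loop
        return None
    return loop


def cell_polygon(mesh: Mesh, cell_id: int) -> np.ndarray | None:
    loop = cell_node_loop(mesh, cell_id)
    if loop is None:
        return None
    return np.array([mesh.nodes[n].position for n in loop], dtype=float)


def polygon_area(points: np.ndarray) -> float:
    """Signed (shoelace) area of a closed polygon given without repeat."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def cell_area(mesh: Mesh, cell_id: int) -> float | None:
    poly = cell_polygon(mesh, cell_id)
    if poly is None:
        return None
    return abs(polygon_area(poly))


def tally_counts(mesh: Mesh, excluded_edge_ids: set[int] = frozenset()) -> MeshCounts:
    """Enumerate equation/unknown counts on the pre-removal topology.

    ``excluded_edge_ids`` are edges removed from the analysis; junctions
    incident to any excluded edge lose both of their force balances.
    """
    excluded = set(excluded_edge_ids)
    for eid in excluded:
        if eid not in mesh.edges:
            raise MeshError(f"excluded edge {eid} not in mesh")

    junctions = list(mesh.junctions.values())
    removed_j = [j for j in junctions if excluded & set(j.incident_edge_ids)]
    n_js = len(junctions)
    n_jrem = len(removed_j)
    n_tensions = len(mesh.edges) - len(excluded)
    n_excess = sum(max(j.order - 3, 0) for j in junctions)
    n_djs = sum(1 for j in junctions if j.order == 2)
    n_stubs = sum(1 for e in mesh.edges.values() if e.is_stub)
    cells = [c for c in mesh.cells.values()]
    n_complete = sum(1 for c in cells if not c.is_partial and not c.is_medium)
    n_partial = sum(1 for c in cells if c.is_partial or c.is_medium)
    n_pressure_eqns = sum(
        1
        for e in mesh.edges.values()
        if e.id not in excluded
        and not e.is_stub
        and all(_is_cellish(s) for s in e.side_cells)
    )
    return MeshCounts(
        n_junctions=n_js,
        n_junctions_removed=n_jrem,
        n_tensions=n_tensions,
        n_tension_eqns=2 * (n_js - n_jrem),
        n_complete_cells=n_complete,
        n_partial_cells=n_partial,
        n_excess_edges=n_excess,
        n_removed_edges=len(excluded),
        n_double_junctions=n_djs,
        n_stubs=n_stubs,
        n_pressure_eqns=n_pressure_eqns,
        n_pressures=n_complete + n_partial,
    )


def retained_junctions(mesh: Mesh, excluded_edge_ids: set[int] = frozenset()) -> list[int]:
    """Junction ids that keep their force balances under an exclusion set."""
    excluded = set(excluded_edge_ids)
    return [
        j.id
        for j in mesh.junctions.values()
        if not (excluded & set(j.incident_edge_ids))
    ]


def tension_components(
    mesh: Mesh, excluded_edge_ids: set[int] = frozenset()
) -> list[set[int]]:
    """Partition retained junctions into edge-connected components.

    Each component supports an independent tension system; relative tensions
    cannot be compared across components.
    """
    excluded = set(excluded_edge_ids)
    retained = set(retained_junctions(mesh, excluded))
    g = nx.Graph()
    g.add_nodes_from(retained)
    for e in mesh.edges.values():
        if e.id in excluded:
            continue
        ja, jb = e.endpoint_junctions
        if ja in retained and jb in retained and ja != jb:
            g.add_edge(ja, jb)
    return [set(c) for c in nx.connected_components(g)]


def pressure_components(mesh: Mesh, usable_edge_ids: set[int]) -> list[set[int]]:
    """Partition cells (including the medium) by adjacency through usable edges."""
    g = nx.Graph()
    g.add_nodes_from(
        c.id for c in mesh.cells.values()
    )
    for eid in usable_edge_ids:
        a, b = mesh.edges[eid].side_cells
        if _is_cellish(a) and _is_cellish(b):
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def contract_short_edges(mesh: Mesh, max_len: float) -> Mesh:
    """Contract 2-node junction-to-junction edges not longer than ``max_len``.

    Used on pixel meshes where a single quad junction can be extracted as two
    order-3 corners one pixel apart.  The two endpoint junctions merge at
    their midpoint, producing a quad/rosette junction.  Returns a new mesh.
    """
    nodes = {k: Node(n.id, n.position.copy()) for k, n in mesh.nodes.items()}
    edges = {
        k: Edge(e.id, list(e.chain), tuple(e.side_cells)) for k, e in mesh.edges.items()
    }
    cells = {k: Cell(c.id, list(c.edge_ids), c.is_partial, c.is_medium)
             for k, c in mesh.cells.items()}

    parent: dict[int, int] = {}

    def find(n: int) -> int:
        while parent.get(n, n) != n:
            n = parent[n]
        return n

    for e in list(edges.values()):
        if len(e.chain) != 2:
            continue
        a, b = find(e.chain[0]), find(e.chain[1])
        if a == b:
            continue
        ja = mesh.junction_at_node(mesh.edges[e.id].chain[0])
        jb = mesh.junction_at_node(mesh.edges[e.id].chain[-1])
        if ja is None or jb is None:
            continue
        d = float(np.linalg.norm(nodes[a].position - nodes[b].position))
        if d > max_len:
            continue
        mid = 0.5 * (nodes[a].position + nodes[b].position)
        nodes[a].position = mid
        parent[b] = a
        del edges[e.id]
        for c in cells.values():
            if e.id in c.edge_ids:
                c.edge_ids.remove(e.id)

    if not parent:
        return mesh
    for e in edges.values():
        e.chain = [find(n) for n in e.chain]
        # collapse consecutive duplicates introduced by merging
        chain = [e.chain[0]]
        for n in e.chain[1:]:
            if n != chain[-1]:
                chain.append(n)
        e.chain = chain if len(chain) >= 2 else e.chain[:1] * 2
    used = {n for e in edges.values() for n in e.chain}
    nodes = {k: v for k, v in nodes.items() if k in used}
    return build_mesh(list(nodes.values()), list(edges.values()), list(cells.values()),
                      mesh.length_scale)
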