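"""Readers and writers: mesh JSON, labelled segmentation images, results.

Mesh JSON schema
----------------
``{"length_scale": float,
   "nodes":  [{"id", "x", "y"}, ...],
   "edges":  [{"id", "junctions": [a, b], "chain": [node ids],
               "cells": [i, j], "stub": bool}, ...],
   "cells":  [{"id", "edges": [...], "partial": bool, "medium": bool}, ...]}``

The medium is encoded as cell id 0; an absent side (outside the modelled
domain) as ``null``.

Label images
------------
Integer-labelled 2-D images (TIFF or PNG), one label per cell, 0 = medium.
Boundaries are extracted on the inter-pixel corner lattice: regions are
4-connected, boundary chains 8-connected along pixel corners, junctions are
corners where three or more labels meet in the 2x2 pixel neighbourhood.
Coordinates are flipped to mathematical y-up; one pixel = one length unit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import MEDIUM, Cell, Edge, Mesh, MeshError, Node, build_mesh


class SchemaError(ValueError):
    """Mesh JSON does not match the expected schema."""


# ---------------------------------------------------------------------------
# Mesh JSON
# ---------------------------------------------------------------------------

def mesh_to_dict(mesh: Mesh) -> dict:
    return {
        "length_scale": mesh.length_scale,
        "nodes": [
            {"id": int(n.id), "x": float(n.position[0]), "y": float(n.position[1])}
            for n in sorted(mesh.nodes.values(), key=lambda n: n.id)
        ],
        "edges": [
            {
                "id": int(e.id),
                "junctions": [None if j is None else int(j)
                              for j in e.endpoint_junctions],
                "chain": [int(n) for n in e.chain],
                "cells": [None if s is None else int(s) for s in e.side_cells],
                "stub": bool(e.is_stub),
            }
            for e in sorted(mesh.edges.values(), key=lambda e: e.id)
        ],
        "cells": [
            {
                "id": int(c.id),
                "edges": [int(i) for i in c.edge_ids],
                "partial": bool(c.is_partial),
                "medium": bool(c.is_medium),
            }
            for c in sorted(mesh.cells.values(), key=lambda c: c.id)
        ],
    }


def write_mesh_json(mesh: Mesh, path) -> None:
    Path(path).write_text(json.dumps(mesh_to_dict(mesh)))


def mesh_from_dict(data: dict) -> Mesh:
    for key in ("nodes", "edges", "cells"):
        if key not in data:
            raise SchemaError(f"missing key: '{key}'")
    try:
        nodes = [Node(int(n["id"]), np.array([float(n["x"]), float(n["y"])]))
                 for n in data["nodes"]]
    except (KeyError, TypeError) as err:
        raise SchemaError(f"nodes: bad entry ({err})") from err
    try:
        edges = [
            Edge(int(e["id"]), [int(i) for i in e["chain"]],
                 tuple(None if s is None else int(s) for s in e["cells"]))
            for e in data["edges"]
        ]
    except (KeyError, TypeError) as err:
        raise SchemaError(f"edges: bad entry ({err})") from err
    try:
        cells = [
            Cell(int(c["id"]), [int(i) for i in c["edges"]],
                 bool(c.get("partial", False)), bool(c.get("medium", False)))
            for c in data["cells"]
        ]
    except (KeyError, TypeError) as err:
        raise SchemaError(f"cells: bad entry ({err})") from err
    return build_mesh(nodes, edges, cells,
                      float(data.get("length_scale", 1.0)))


def read_mesh_json(path) -> Mesh:
    data = json.loads(Path(path).read_text())
    return mesh_from_dict(data)


# ---------------------------------------------------------------------------
# Label images
# ---------------------------------------------------------------------------

def read_label_image(path, contract_pixel_junctions: bool = True) -> Mesh:
    """Build a mesh from an integer-labelled segmentation image file."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        labels = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        labels = iio.imread(p)
    return mesh_from_labels(np.asarray(labels), contract_pixel_junctions)


def write_label_image(labels: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def _smooth_chains(mesh: Mesh, window: int = 5) -> Mesh:
    """Moving-average smoothing of chain interiors (junctions stay fixed);
    tames the half-pixel staircase noise of corner-lattice boundaries."""
    half = window // 2
    for eid, e in mesh.edges.items():
        n = len(e.chain)
        if n < 4:
            continue
        pts = mesh.chain_points(eid)
        out = pts.copy()
        for i in range(1, n - 1):
            k = min(half, i, n - 1 - i)
            out[i] = pts[i - k:i + k + 1].mean(axis=0)
        for i, nid in enumerate(e.chain):
            if 0 < i < n - 1:
                mesh.nodes[nid].position = out[i]
    return mesh


def mesh_from_labels(labels: np.ndarray,
                     contract_pixel_junctions: bool = True,
                     smooth_window: int = 5) -> Mesh:
    """Extract a polyarc mesh from an integer label array (0 = medium).

    Boundary chains live on the pixel-corner lattice at integer coordinates;
    junctions are corners of degree >= 3 in the boundary graph.  With
    ``contract_pixel_junctions``, 2-node boundary chains no longer than one
    pixel diagonal between two junction corners are contracted, recovering
    quad junctions that rasterisation splits into adjacent triple corners.
    ``smooth_window`` applies a moving average along chain interiors to
    suppress pixel staircase noise (0 disables).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise MeshError("label image must be 2-D")
    if not np.issubdtype(labels.dtype, np.integer):
        if np.issubdtype(labels.dtype, np.floating) and np.allclose(
                labels, np.round(labels)):
            labels = labels.astype(np.int64)
        else:
            raise MeshError("label image must be integer-valued")
    present = np.unique(labels)
    if len(present[present != 0]) < 2:
        raise MeshError("need at least two cell labels")

    L = np.pad(labels.astype(np.int64), 1)  # frame of medium around the image
    H, W = L.shape

    # boundary segments between corner (r,c) and its +x / +y neighbours
    horiz = L[:-1, :] != L[1:, :]   # segment right of corner (r+?,c)..: shape (H-1, W)
    # horiz[r, c]: vertical pixel boundary? define carefully below
    # corners: (r, c), r in 0..H, c in 0..W  (pixel (i,j) spans corners
    # (i,j)-(i+1,j+1)).  Horizontal segment from corner (r,c) to (r,c+1)
    # separates pixels (r-1, c) and (r, c).
    hseg = np.zeros((H + 1, W), dtype=bool)
    hseg[1:H, :] = L[:-1, :] != L[1:, :]
    # vertical segment from corner (r,c) to (r+1,c) separates pixels
    # (r, c-1) and (r, c)
    vseg = np.zeros((H, W + 1), dtype=bool)
    vseg[:, 1:W] = L[:, :-1] != L[:, 1:]

    def corner_degree(r: int, c: int) -> int:
        d = 0
        if c < W and hseg[r, c]:
            d += 1
        if c > 0 and hseg[r, c - 1]:
            d += 1
        if r < H and vseg[r, c]:
            d += 1
        if r > 0 and vseg[r - 1, c]:
            d += 1
        return d

    deg = np.zeros((H + 1, W + 1), dtype=np.int8)
    deg[:, :-1] += hseg
    deg[:, 1:] += hseg
    deg[:-1, :] += vseg
    deg[1:, :] += vseg
    junction_corners = {tuple(rc) for rc in np.argwhere(deg >= 3)}

    def neighbours(r: int, c: int):
        if c < W and hseg[r, c]:
            yield (r, c + 1), ("h", r, c)
        if c > 0 and hseg[r, c - 1]:
            yield (r, c - 1), ("h", r, c - 1)
        if r < H and vseg[r, c]:
            yield (r + 1, c), ("v", r, c)
        if r > 0 and vseg[r - 1, c]:
            yield (r - 1, c), ("v", r - 1, c)

    visited: set[tuple] = set()

    def trace(start, first):
        """Follow a chain of boundary segments from a junction corner."""
        path = [start]
        corner, seg = first
        visited.add(seg)
        path.append(corner)
        while corner not in junction_corners:
            nxt = [(nc, ns) for nc, ns in neighbours(*corner) if ns not in visited]
            if not nxt:
                break
            (corner, seg) = nxt[0]
            visited.add(seg)
            path.append(corner)
        return path

    chains = []
    for rc in sorted(junction_corners):
        for nc, ns in neighbours(*rc):
            if ns in visited:
                continue
            chains.append(trace(rc, (nc, ns)))
    # closed loops without junctions (enclave cells)
    for (kind, r, c) in [("h", r, c) for r, c in np.argwhere(hseg)] + [
            ("v", r, c) for r, c in np.argwhere(vseg)]:
        if (kind, r, c) in visited:
            continue
        start = (r, c)
        chains.append(trace(start, ((r, c + 1) if kind == "h" else (r + 1, c),
                                    (kind, r, c))))

    # side labels for a chain from its first segment (image row/col space)
    def side_labels(path):
        (r0, c0), (r1, c1) = path[0], path[1]
        if r0 == r1:  # horizontal move
            c = min(c0, c1)
            up, down = L[r0 - 1, c], L[r0, c]
            if c1 > c0:   # moving +c: up pixel is on the left in y-up coords
                return int(up), int(down)
            return int(down), int(up)
        r = min(r0, r1)
        left_pix, right_pix = L[r, c0 - 1], L[r, c0]
        if r1 > r0:   # moving +r (downward in image, -y): left is right_pix
            return int(right_pix), int(left_pix)
        return int(left_pix), int(right_pix)

    node_id_of: dict[tuple, int] = {}
    nodes: list[Node] = []

    def node_for(rc) -> int:
        if rc not in node_id_of:
            nid = len(nodes)
            node_id_of[rc] = nid
            r, c = rc
            nodes.append(Node(nid, np.array([float(c - 1),
                                             float((H - 1) - (r - 1))])))
        return node_id_of[rc]

    def on_frame(rc) -> bool:
        r, c = rc
        return r in (1, H - 1) or c in (1, W - 1)

    edges: list[Edge] = []
    cell_edges: dict[int, list[int]] = {}
    for path in chains:
        if len(path) < 2:
            continue
        a, b = side_labels(path)
        # chains running along the image frame are crop lines, not physical
        # membranes: dropping them turns edges cut by the frame into stubs
        if MEDIUM in (a, b) and all(on_frame(rc) for rc in path):
            continue
        chain_ids = [node_for(rc) for rc in path]
        eid = len(edges)
        edges.append(Edge(eid, chain_ids, (a, b)))
        for s in (a, b):
            cell_edges.setdefault(s, []).append(eid)

    cells: list[Cell] = []
    frame_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])))
    for label, eids in sorted(cell_edges.items()):
        if label == MEDIUM:
            cells.append(Cell(MEDIUM, eids, is_partial=True, is_medium=True))
        else:
            cells.append(Cell(label, eids,
                              is_partial=label in frame_labels))
    # drop chains cut free at both ends (border arcs with both junctions on
    # dropped frame lines): they can enter no junction equation
    for _ in range(3):
        ends: dict[int, int] = {}
        for e in edges:
            for nid in (e.chain[0], e.chain[-1]):
                ends[nid] = ends.get(nid, 0) + 1
        keep = [e for e in edges
                if ends[e.chain[0]] >= 2 or ends[e.chain[-1]] >= 2]
        if len(keep) == len(edges):
            break
        kept_ids = {e.id for e in keep}
        edges = keep
        for c in cells:
            c.edge_ids = [i for i in c.edge_ids if i in kept_ids]
    cells = [c for c in cells if c.edge_ids]
    used_nodes = {n for e in edges for n in e.chain}
    nodes = [n for n in nodes if n.id in used_nodes]

    mesh = build_mesh(nodes, edges, cells)
    if contract_pixel_junctions:
        from .mesh import contract_short_edges

        mesh = contract_short_edges(mesh, float(np.sqrt(2.0)))
    if smooth_window:
        mesh = _smooth_chains(mesh, smooth_window)
    return mesh
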