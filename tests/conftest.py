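"""Shared fixtures: small hand-built meshes and annealed synthetic patches.

Annealed patches are expensive, so they are session-scoped and shared by
the geometry, inference, diagnostics and acceptance tests.
"""

import warnings

import numpy as np
import pytest

from arcforce.mesh import Cell, Edge, Node, build_mesh
from arcforce.synthetic import synthetic_patch

warnings.filterwarnings("ignore", message=".*negative inferred tensions.*")


def single_junction_mesh(angles_deg, stub_length=1.0, n_nodes=2):
    """Star of stub edges radiating from one central junction."""
    nodes = [Node(0, np.array([0.0, 0.0]))]
    edges = []
    nid = 1
    for k, a in enumerate(angles_deg):
        d = np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))])
        chain = [0]
        for s in range(1, n_nodes):
            nodes.append(Node(nid, d * stub_length * s / (n_nodes - 1)))
            chain.append(nid)
            nid += 1
        edges.append(Edge(k, chain, (k + 1, (k % len(angles_deg)) + 2)))
    # sides are placeholders (distinct per edge); cells declared partial
    cells = {}
    for e in edges:
        for s in e.side_cells:
            cells.setdefault(s, []).append(e.id)
    cell_objs = [Cell(cid, eids, is_partial=True) for cid, eids in cells.items()]
    return build_mesh(nodes, edges, cell_objs)


@pytest.fixture(scope="session")
def tj_star():
    """Symmetric triple junction: stubs at 0, 120, 240 degrees."""
    return single_junction_mesh([0, 120, 240])


@pytest.fixture(scope="session")
def two_cell_mesh():
    """Two square-ish cells sharing one curved interior edge.

    The shared edge (id 0) bulges into cell 2 with radius 2, the outer
    boundary is a rectangle of straight chains; the mesh is used for
    pressure-assembly examples where only the shared edge carries a row.
    """
    r = 2.0
    # shared edge from (0,1) down to (0,-1), bulging into x<0 (cell 2's
    # side, i.e. convex into cell j with cell 1 on the left of the chain)
    cx = np.sqrt(r**2 - 1.0)
    th = np.linspace(np.deg2rad(150.0), np.deg2rad(210.0), 9)
    arc = np.column_stack([cx + r * np.cos(th), r * np.sin(th)])
    arc[0] = (0.0, 1.0)
    arc[-1] = (0.0, -1.0)
    nodes = [Node(i, p) for i, p in enumerate(arc)]
    n0, n1 = 0, len(arc) - 1
    nid = len(arc)
    left = [np.array([-2.0, 1.0]), np.array([-2.0, -1.0])]
    right = [np.array([2.0, 1.0]), np.array([2.0, -1.0])]
    lids = [n0]
    for p in left:
        nodes.append(Node(nid, p))
        lids.append(nid)
        nid += 1
    lids.append(n1)
    rids = [n0]
    for p in right:
        nodes.append(Node(nid, p))
        rids.append(nid)
        nid += 1
    rids.append(n1)
    edges = [
        Edge(0, list(range(len(arc))), (1, 2)),  # cell 1 left of chain
        Edge(1, lids, (2, None)),                # outer boundary of cell 2
        Edge(2, rids, (None, 1)),                # outer boundary of cell 1
    ]
    cells = [Cell(1, [0, 2]), Cell(2, [0, 1])]
    return build_mesh(nodes, edges, cells)


@pytest.fixture(scope="session")
def annealed_region():
    """One annealed ~50-complete-cell frayed region with ground truth."""
    return synthetic_patch(150, 50, seed=11)


@pytest.fixture(scope="session")
def annealed_small():
    """A smaller annealed patch (for cheaper tests)."""
    return synthetic_patch(60, 20, seed=5)


@pytest.fixture(scope="session")
def patch_ensemble():
    """Full annealed patches (with ground truth) shared across tests."""
    from arcforce.synthetic import annealed_patch

    return [annealed_patch(150, seed=s) for s in range(1, 11)]


@pytest.fixture(scope="session")
def region_ensemble(patch_ensemble):
    """Frayed ~50-complete-cell regions extracted from the patch ensemble."""
    from arcforce.synthetic import extract_region, frayed_window

    out = []
    for mesh, truth in patch_ensemble:
        out.append(extract_region(mesh, truth, frayed_window(mesh, 50)))
    return out
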