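"""Circular-arc geometry of cell edges.

Each cell-cell interface is modelled as a circular arc.  From the fitted arc
we obtain the two *limiting tangents* (the directions in which the edge pulls
on its endpoint junctions, pointing away from the junction), the signed
curvature used by the Laplace pressure relation, and the chord length.

Sign convention: curvature is positive when the i-j edge is convex into cell
*j*, i.e. when the arc centre lies on cell *i*'s side (cell *i* is on the
left of the stored chain).  With tension gamma this gives the pressure jump
``p_i - p_j = gamma * curvature``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Edge, Mesh

#: Default sagitta/chord threshold below which an edge is treated as straight.
STRAIGHTNESS_TOL = 1e-3

ANGLE_METHODS = ("polyarc", "closest_segment", "minimal_polygon")


@dataclass
class ArcFit:
    """A circle fitted to an edge chain (or a straight-edge marker)."""

    center: np.ndarray | None   # None when straight
    radius: float               # inf when straight
    is_straight: bool
    fit_rms: float

    @property
    def curvature_magnitude(self) -> float:
        return 0.0 if self.is_straight else 1.0 / self.radius


@dataclass
class EdgeGeometry:
    """Fitted geometric quantities of one edge."""

    arc: ArcFit
    tangent_at_first: np.ndarray
    tangent_at_second: np.ndarray
    curvature_signed: float
    chord_length: float
    curvature_reliable: bool = True  # False for 2-node chains (no intermediate nodes)


def _kasa_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit: linear least squares on x^2+y^2."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    return np.array([cx, cy]), float(np.sqrt(max(r2, 0.0)))


def _geometric_refine(points: np.ndarray, center: np.ndarray, radius: float,
                      max_iter: int = 30) -> tuple[np.ndarray, float]:
    """Gauss-Newton refinement of the geometric distance objective."""
    for _ in range(max_iter):
        d = points - center
        dist = np.linalg.norm(d, axis=1)
        if np.any(dist < 1e-12) or radius <= 0:
            break
        f = dist - radius
        J = np.column_stack([-d[:, 0] / dist, -d[:, 1] / dist,
                             -np.ones_like(dist)])
        step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        center = center + step[:2]
        radius = radius + float(step[2])
        if np.linalg.norm(step) < 1e-12 * max(radius, 1.0):
            break
    return center, radius


def fit_circular_arc(points: np.ndarray, straightness_tol: float = STRAIGHTNESS_TOL
                     ) -> ArcFit:
    """Fit a circular arc to an ordered point chain.

    A Kasa algebraic fit refined by one geometric Gauss-Newton pass.  The
    edge is declared straight when it has only two points, when the points
    are collinear within tolerance, or when the fitted sagitta-to-chord
    ratio falls below ``straightness_tol``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("need at least 2 points")
    chord_vec = points[-1] - points[0]
    chord = float(np.linalg.norm(chord_vec))
    if len(points) == 2:
        return ArcFit(None, np.inf, True, 0.0)
    # max perpendicular deviation from the chord line
    if chord > 0:
        n = np.array([-chord_vec[1], chord_vec[0]]) / chord
        dev = np.abs((points - points[0]) @ n)
        if dev.max() / chord < straightness_tol:
            rms = float(np.sqrt(np.mean(dev**2)))
            return ArcFit(None, np.inf, True, rms)
    center, radius = _kasa_fit(points)
    center, radius = _geometric_refine(points, center, radius)
    if not np.isfinite(radius) or radius <= 0:
        return ArcFit(None, np.inf, True, 0.0)
    if chord > 0:
        n = np.array([-chord_vec[1], chord_vec[0]]) / chord
        dev = np.abs((points - points[0]) @ n)
        half = chord / 2.0
        sagitta = (radius - np.sqrt(radius**2 - half**2) if radius > half
                   else radius)
        # straightness by fitted sagitta/chord ratio
        if sagitta / chord < straightness_tol:
            return ArcFit(None, np.inf, True, float(np.sqrt(np.mean(dev**2))))
        # consistency guard: jagged, nearly straight chains (pixelated
        # boundaries) can collapse the algebraic fit onto a small circle
        # whose implied bulge far exceeds what the points show
        if sagitta > 2.5 * dev.max() + 1e-12:
            return ArcFit(None, np.inf, True, float(np.sqrt(np.mean(dev**2))))
    rms = float(np.sqrt(np.mean((np.linalg.norm(points - center, axis=1) - radius) ** 2)))
    return ArcFit(center, radius, False, rms)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def limiting_tangent(arc: ArcFit, chain: np.ndarray, at_end: str) -> np.ndarray:
    """Unit tangent at the junction end of an edge, pointing away from it.

    For arcs, the tangent of the fitted circle at its closest point to the
    junction; for straight edges, the chord direction.  ``at_end`` is
    ``"first"`` or ``"second"``.
    """
    chain = np.asarray(chain, dtype=float)
    if at_end not in ("first", "second"):
        raise ValueError("at_end must be 'first' or 'second'")
    if at_end == "first":
        junction, interior = chain[0], chain[1]
    else:
        junction, interior = chain[-1], chain[-2]
    if arc.is_straight:
        if at_end == "first":
            return _unit(chain[-1] - chain[0])
        return _unit(chain[0] - chain[-1])
    radial = junction - arc.center
    if np.linalg.norm(radial) == 0:
        raise ValueError("junction coincides with arc centre")
    radial = _unit(radial)
    tangent = np.array([-radial[1], radial[0]])
    if float(tangent @ (interior - junction)) < 0:
        tangent = -tangent
    return tangent


def angle_variant_tangent(edge: Edge, mesh: Mesh, method: str, at_end: str,
                          arc: ArcFit | None = None,
                          straightness_tol: float = STRAIGHTNESS_TOL) -> np.ndarray:
    """Limiting tangent under one of the three angle-determination methods.

    ``polyarc`` uses the fitted arc; ``closest_segment`` the chain segment
    adjacent to the junction; ``minimal_polygon`` the straight chord between
    the endpoint junctions.
    """
    pts = mesh.chain_points(edge.id)
    if method == "polyarc":
        if arc is None:
            arc = fit_circular_arc(pts, straightness_tol)
        return limiting_tangent(arc, pts, at_end)
    if method == "closest_segment":
        if at_end == "first":
            return _unit(pts[1] - pts[0])
        return _unit(pts[-2] - pts[-1])
    if method == "minimal_polygon":
        if at_end == "first":
            return _unit(pts[-1] - pts[0])
        return _unit(pts[0] - pts[-1])
    raise ValueError(f"unknown angle method {method!r}")


def signed_curvature(arc: ArcFit, edge: Edge, chain: np.ndarray) -> float:
    """Signed curvature of an edge: positive when convex into cell j.

    Cell *i* (``side_cells[0]``) lies on the left of the chain, so the edge
    bulges into cell *j* exactly when the arc centre is on the left side.
    """
    if edge.side_cells is None or len(edge.side_cells) != 2:
        raise ValueError(f"edge {edge.id}: sides undeclared")
    if arc.is_straight:
        return 0.0
    chain = np.asarray(chain, dtype=float)
    chord = chain[-1] - chain[0]
    # bulge side from the chain point of largest chord deviation (robust for
    # arcs subtending more than a half-circle, where the centre side flips)
    rel = chain - chain[0]
    cross = chord[0] * rel[:, 1] - chord[1] * rel[:, 0]
    bulge = cross[np.argmax(np.abs(cross))]
    if bulge == 0.0:  # chain indistinguishable from its chord
        return 0.0
    # bulge to the left (cell i side) means convex into cell i: negative
    sign = -1.0 if bulge > 0 else 1.0
    return sign / arc.radius


def edge_geometry(mesh: Mesh, edge_id: int, method: str = "polyarc",
                  straightness_tol: float = STRAIGHTNESS_TOL) -> EdgeGeometry:
    """Fit the arc and derive tangents, curvature and chord for one edge."""
    edge = mesh.edges[edge_id]
    pts = mesh.chain_points(edge_id)
    arc = fit_circular_arc(pts, straightness_tol)
    t1 = angle_variant_tangent(edge, mesh, method, "first", arc, straightness_tol)
    t2 = angle_variant_tangent(edge, mesh, method, "second", arc, straightness_tol)
    kappa = signed_curvature(arc, edge, pts)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    return EdgeGeometry(
        arc=arc,
        tangent_at_first=t1,
        tangent_at_second=t2,
        curvature_signed=kappa,
        chord_length=chord,
        curvature_reliable=len(pts) >= 3,
    )


def mesh_geometry(mesh: Mesh, method: str = "polyarc",
                  straightness_tol: float = STRAIGHTNESS_TOL
                  ) -> dict[int, EdgeGeometry]:
    """Edge geometry for every edge of a mesh."""
    return {eid: edge_geometry(mesh, eid, method, straightness_tol)
            for eid in mesh.edges}
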