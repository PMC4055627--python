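"""Rasterise a mesh to a label image and re-extract it (re-digitisation).

Emulates the pixelation round trip of real image analysis in four steps:
(1) draw every cell-cell boundary as a smooth curve onto a pixel grid;
(2) label the enclosed regions (watershed-style flood fill of the
non-boundary pixels, then expansion of the labels across the 1-px boundary
lines); (3) re-label the regions so they match the original cells by
maximal area overlap; (4) run the contour/junction extraction on the
relabelled image to produce a new mesh.

The re-extracted mesh carries pixel coordinates; its ``length_scale``
records the original length units per pixel so pressures can be converted
back to the original units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import mesh as mesh_mod
from .io import mesh_from_labels
from .mesh import MEDIUM, Mesh


@dataclass
class RedigitizedMesh:
    """Result of a rasterise/re-digitise round trip."""

    mesh: Mesh                    # pixel-coordinate mesh, labels = cell ids
    labels: np.ndarray            # relabelled image (0 = background/unmatched)
    cell_map: dict[int, int]      # region label -> original cell id
    scale: float                  # pixels per original length unit
    dropped_cells: list[int]      # original complete cells lost at this resolution


def _smooth_chain(pts: np.ndarray, samples_per_px: float, scale: float
                  ) -> np.ndarray:
    """Densely sample an edge chain with a spline (falls back to the
    polyline for very short chains)."""
    from scipy.interpolate import splev, splprep

    n = len(pts)
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    n_out = max(2, int(np.ceil(length * scale * samples_per_px)))
    if n < 4:
        t = np.linspace(0, 1, n_out)
        seg = np.linspace(0, 1, n)
        return np.column_stack([np.interp(t, seg, pts[:, 0]),
                                np.interp(t, seg, pts[:, 1])])
    tck, _ = splprep([pts[:, 0], pts[:, 1]], s=0, k=min(3, n - 1))
    u = np.linspace(0, 1, n_out)
    x, y = splev(u, tck)
    return np.column_stack([x, y])


def rasterize_boundaries(mesh: Mesh, image_width: int,
                         scale: float | None = None
                         ) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Draw all edge chains as 1-px lines; returns (boundary mask, scale,
    (x0, y1)) where scale is px per length unit and (x0, y1) the top-left
    anchor of the pixel grid in mesh coordinates.  The canvas covers the
    whole mesh; pass ``scale`` to fix the resolution independently of
    ``image_width``."""
    from skimage.draw import line

    pts_all = np.array([n.position for n in mesh.nodes.values()])
    x0, y0 = pts_all.min(axis=0) - 1e-6
    x1, y1 = pts_all.max(axis=0) + 1e-6
    if scale is None:
        scale = image_width / (x1 - x0)
    width = int(np.ceil((x1 - x0) * scale))
    height = int(np.ceil((y1 - y0) * scale))
    mask = np.zeros((height, width), dtype=bool)
    image_width = width

    def to_px(p):
        c = (p[:, 0] - x0) * scale
        r = (y1 - p[:, 1]) * scale
        return np.clip(np.round(r).astype(int), 0, height - 1), \
            np.clip(np.round(c).astype(int), 0, image_width - 1)

    span = max(x1 - x0, y1 - y0)

    def draw(pts: np.ndarray) -> None:
        rr, cc = to_px(pts)
        for i in range(len(rr) - 1):
            lr, lc = line(rr[i], cc[i], rr[i + 1], cc[i + 1])
            mask[lr, lc] = True

    def inside_canvas(p) -> bool:
        return (x0 - 2 / scale <= p[0] <= x1 + 2 / scale
                and y0 - 2 / scale <= p[1] <= y1 + 2 / scale)

    def extension(pts: np.ndarray, at_start: bool) -> np.ndarray:
        """Continue a truncated edge beyond its free end along its own
        fitted arc (straight if the edge is straight), so the regions on
        either side of the cut stay separated without a kink."""
        from .geometry import fit_circular_arc

        tip = pts[0] if at_start else pts[-1]
        prev = pts[1] if at_start else pts[-2]
        arc = fit_circular_arc(pts) if len(pts) >= 3 else None
        out = [tip]
        step = 1.0 / scale
        if arc is None or arc.is_straight:
            d = tip - prev
            d = d / np.linalg.norm(d)
            p = tip.copy()
            for _ in range(int(0.6 * span * scale)):
                p = p + d * step
                out.append(p.copy())
                if not inside_canvas(p):
                    break
        else:
            theta = np.arctan2(tip[1] - arc.center[1], tip[0] - arc.center[0])
            prev_theta = np.arctan2(prev[1] - arc.center[1],
                                    prev[0] - arc.center[0])
            dth = (theta - prev_theta + np.pi) % (2 * np.pi) - np.pi
            sign = 1.0 if dth > 0 else -1.0
            dstep = sign * step / arc.radius
            # cap the sweep so a tight arc cannot curl back into the tissue,
            # then continue straight along the final tangent
            max_sweep = np.deg2rad(60.0)
            k_arc = min(int(0.6 * span * scale),
                        max(1, int(max_sweep / abs(dstep))))
            p = tip
            for k in range(1, k_arc + 1):
                a = theta + k * dstep
                p = arc.center + arc.radius * np.array([np.cos(a), np.sin(a)])
                out.append(p)
                if not inside_canvas(p):
                    break
            else:
                a_end = theta + k_arc * dstep
                d = sign * np.array([-np.sin(a_end), np.cos(a_end)])
                q = p.copy()
                for _ in range(int(0.6 * span * scale)):
                    q = q + d * step
                    out.append(q.copy())
                    if not inside_canvas(q):
                        break
        return np.array(out)

    for eid in mesh.edges:
        pts = mesh.chain_points(eid)
        draw(_smooth_chain(pts, 2.0, scale))
        e = mesh.edges[eid]
        if e.is_stub:
            ja, jb = e.endpoint_junctions
            if ja is None:
                draw(extension(pts, at_start=True))
            if jb is None:
                draw(extension(pts, at_start=False))
    return mask, scale, (x0, y1)


def _reference_labels(mesh: Mesh, shape: tuple[int, int], scale: float,
                      anchor: tuple[float, float]) -> np.ndarray:
    """Rasterise the original cell polygons into a label image."""
    from skimage.draw import polygon

    x0, y1 = anchor
    out = np.zeros(shape, dtype=np.int32)
    for cid, cell in mesh.cells.items():
        if cell.is_medium:
            continue
        poly = mesh_mod.cell_polygon(mesh, cid)
        if poly is None:
            continue
        rr = (y1 - poly[:, 1]) * scale
        cc = (poly[:, 0] - x0) * scale
        r, c = polygon(rr, cc, shape=shape)
        out[r, c] = cid
    return out


def rasterize_redigitize(
    mesh: Mesh,
    image_width: int = 675,
    window: tuple[float, float, float, float] | None = None,
) -> RedigitizedMesh:
    """Full four-step round trip: draw, label, match, re-extract.

    With a ``window``, the mesh is drawn at the resolution implied by
    ``image_width`` over the window and the image is cropped to it, so
    cells crossing the window edge are cut by the frame.  Regions are
    matched to original complete cells by maximal pixel overlap and adopt
    their ids; remaining regions (cut cells without a reference polygon)
    receive fresh labels so the junction topology survives.  Cells that
    vanish at the given resolution are reported in ``dropped_cells``.
    """
    if image_width < 100:
        raise ValueError("image_size must be at least 100 px")
    from skimage.segmentation import expand_labels

    px_scale = None
    if window is not None:
        px_scale = image_width / (window[1] - window[0])
    boundary, scale, anchor = rasterize_boundaries(mesh, image_width, px_scale)
    ref = _reference_labels(mesh, boundary.shape, scale, anchor)
    if window is not None:
        x0w, x1w, y0w, y1w = window
        c0 = int(round((x0w - anchor[0]) * scale))
        r0 = int(round((anchor[1] - y1w) * scale))
        h = int(round((y1w - y0w) * scale))
        w = int(round((x1w - x0w) * scale))
        c0, r0 = max(c0, 0), max(r0, 0)
        boundary = boundary[r0:r0 + h, c0:c0 + w]
        ref = ref[r0:r0 + h, c0:c0 + w]
        anchor = (anchor[0] + c0 / scale, anchor[1] - r0 / scale)
    regions, _ = ndimage.label(~boundary)

    # overlap matching region -> original cell
    flat = regions.ravel()
    refflat = ref.ravel()
    keep = (flat > 0) & (refflat > 0)
    pairs = np.stack([flat[keep], refflat[keep]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    best: dict[int, tuple[int, int]] = {}
    for (reg, cid), n in zip(uniq.T, counts):
        if reg not in best or n > best[reg][1]:
            best[int(reg)] = (int(cid), int(n))

    complete = {c.id for c in mesh.cells.values()
                if not c.is_partial and not c.is_medium}
    # complete cells adopt their original ids via best overlap; partial
    # cells have open outlines (no reference polygon), so their regions --
    # and any other sizable unmatched region -- keep their identity under a
    # fresh label: the rim junction topology survives even though those
    # labels carry no ground-truth correspondence
    cell_map = {reg: cid for reg, (cid, _) in best.items() if cid in complete}
    sizes = np.bincount(regions.ravel())
    min_area = 25  # px; smaller regions are slivers absorbed by neighbours
    fresh = (max(complete) if complete else 0) + 1
    relabel = np.zeros(regions.max() + 1, dtype=np.int32)
    for reg, cid in cell_map.items():
        relabel[reg] = cid
    for reg in range(1, regions.max() + 1):
        if relabel[reg] == 0 and sizes[reg] >= min_area:
            relabel[reg] = fresh
            fresh += 1
    labels = relabel[regions]
    labels = expand_labels(labels, distance=3)

    dropped = sorted(complete - {cid for cid, _ in best.values()})
    new_mesh = mesh_from_labels(labels)
    new_mesh.length_scale = 1.0 / scale
    return RedigitizedMesh(
        mesh=new_mesh,
        labels=labels,
        cell_map={reg: cid for reg, cid in cell_map.items()},
        scale=scale,
        dropped_cells=dropped,
    )


def match_edges(original: Mesh, redigitized: Mesh) -> dict[int, int]:
    """Map re-extracted edge ids to original edge ids by shared cell pair.

    Only edges between two matched (non-medium) cells are mappable; when
    several re-extracted chains share a cell pair the longest is used.
    """
    by_pair: dict[frozenset, int] = {}
    for eid, e in original.edges.items():
        a, b = e.side_cells
        if a in (None, MEDIUM) or b in (None, MEDIUM):
            continue
        by_pair[frozenset((a, b))] = eid

    out: dict[int, int] = {}
    claimed: dict[int, float] = {}
    for eid, e in redigitized.edges.items():
        a, b = e.side_cells
        if a in (None, MEDIUM) or b in (None, MEDIUM):
            continue
        pair = frozenset((a, b))
        if pair not in by_pair:
            continue
        length = float(np.linalg.norm(
            np.diff(redigitized.chain_points(eid), axis=0), axis=1).sum())
        orig = by_pair[pair]
        if orig in claimed and claimed[orig] >= length:
            continue
        # drop a previously matched shorter duplicate
        for k, v in list(out.items()):
            if v == orig:
                del out[k]
        out[eid] = orig
        claimed[orig] = length
    return out
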