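"""Assembly and solution of the tension and pressure systems.

Tensions: each retained junction contributes an x and a y force balance,
``sum_e gamma_e * u_e = 0`` over its incident edges, where ``u_e`` is the
unit limiting tangent of edge *e* pointing away from the junction.  The
stacked homogeneous system ``G_gamma @ gamma = 0`` is solved in the
least-squares sense under the normalisation ``mean(gamma) = 1`` via a KKT
(Lagrange multiplier) block system, yielding the *Standard Tensions*.

Pressures: each usable edge contributes one Laplace row
``p_i - p_j = gamma_ij * kappa_ij`` (signed curvature kappa); the system is
solved under ``mean(p) = 0``, yielding the *Standard Pressures*.  The
General Solution is ``gamma = alpha * gamma_star``,
``p = alpha * p_star + beta`` for an external tension scale alpha and
pressure offset beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import mesh as mesh_mod
from .geometry import EdgeGeometry
from .mesh import Mesh

#: KKT condition number beyond which the SVD-based reduced solver is used.
KKT_COND_LIMIT = 1e12


class SingularSystemError(np.linalg.LinAlgError):
    """Raised when a constrained system is numerically singular."""

    def __init__(self, message: str, condition_number: float):
        super().__init__(f"{message} (condition number {condition_number:.3e})")
        self.condition_number = condition_number


@dataclass
class TensionSystem:
    """Assembled junction-equilibrium system ``G_gamma @ gamma ~ 0``."""

    matrix_G: np.ndarray               # (n_eqns, n_tensions)
    constraint_vector: np.ndarray      # (n_tensions,), entries 1/n
    row_index: list[tuple[int, str]]   # row -> (junction id, 'x'|'y')
    col_index: list[int]               # column -> edge id


@dataclass
class PressureSystem:
    """Assembled Laplace system ``G_p @ p ~ q``."""

    matrix_G: np.ndarray               # (n_eqns, n_pressures)
    rhs_q: np.ndarray                  # (n_eqns,)
    constraint_vector: np.ndarray      # (n_pressures,), entries 1/n
    row_index: list[int]               # row -> edge id
    col_index: list[int]               # column -> cell id


@dataclass
class Solution:
    """Standard tensions/pressures with the General-Solution scale slots."""

    standard_tensions: dict[int, float]
    standard_pressures: dict[int, float]
    alpha: float | None = None
    beta: float | None = None
    lagrange_tension: float | None = None
    lagrange_pressure: float | None = None


TangentMap = dict[tuple[int, str], np.ndarray]


def tangent_map(geometry: dict[int, EdgeGeometry]) -> TangentMap:
    """Per-edge-end unit tangents from fitted edge geometry."""
    out: TangentMap = {}
    for eid, g in geometry.items():
        out[(eid, "first")] = g.tangent_at_first
        out[(eid, "second")] = g.tangent_at_second
    return out


def curvature_map(geometry: dict[int, EdgeGeometry]) -> dict[int, float]:
    return {eid: g.curvature_signed for eid, g in geometry.items()}


def _tangent_at(mesh: Mesh, tangents: TangentMap, eid: int, jid: int
                ) -> np.ndarray | None:
    e = mesh.edges[eid]
    if e.endpoint_junctions[0] == jid:
        return tangents.get((eid, "first"))
    if e.endpoint_junctions[1] == jid:
        return tangents.get((eid, "second"))
    return None


def assemble_tension_system(
    mesh: Mesh,
    tangents: TangentMap,
    excluded_edge_ids: set[int] = frozenset(),
    junction_ids: set[int] | None = None,
) -> TensionSystem:
    """Build the junction-equilibrium matrix for one connected component.

    Junctions incident to excluded edges contribute no rows; excluded edges
    contribute no columns.  ``junction_ids`` restricts assembly to one
    tension component (default: all retained junctions).  Junctions left
    with fewer than two retained incident edges are dropped with a warning,
    and edges that end up with no equations are dropped from the columns.
    """
    excluded = set(excluded_edge_ids)
    retained = mesh_mod.retained_junctions(mesh, excluded)
    if junction_ids is not None:
        retained = [j for j in retained if j in junction_ids]

    # well-posedness guard: a junction whose equations are the only ones an
    # edge enters ("exclusive" edges, e.g. stubs) is locally underdetermined
    # when it has three or more of them (2 equations cannot fix 3 unknowns
    # that appear nowhere else), adding a spurious null mode to the
    # homogeneous system.  Such junctions are dropped together with their
    # exclusive edges — the same remedy as the manual exclusion of poorly
    # defined edges — unless the junction is the entire system, where the
    # mean constraint itself closes the count.
    retained_set = set(retained)
    dropped_exclusive: set[int] = set()
    while len(retained_set) > 1:
        eqn_count: dict[int, int] = {}
        for jid in retained_set:
            for eid in mesh.junctions[jid].incident_edge_ids:
                if eid not in excluded and eid not in dropped_exclusive:
                    eqn_count[eid] = eqn_count.get(eid, 0) + 1
        bad = []
        for jid in retained_set:
            exclusive = [
                eid for eid in mesh.junctions[jid].incident_edge_ids
                if eid not in excluded and eid not in dropped_exclusive
                and eqn_count.get(eid, 0) == 1
            ]
            if len(exclusive) >= 3:
                bad.append((jid, exclusive))
                continue
            if len(exclusive) == 2:
                # two single-equation edges with nearly parallel pull
                # directions: only one combination of their tensions is
                # constrained, the orthogonal one is a near-null mode
                e1, e2 = exclusive
                t1 = _tangent_at(mesh, tangents, e1, jid)
                t2 = _tangent_at(mesh, tangents, e2, jid)
                if t1 is not None and t2 is not None and \
                        abs(t1[0] * t2[1] - t1[1] * t2[0]) < 0.2:
                    warnings.warn(
                        f"junction {jid}: near-collinear poorly determined "
                        f"edges {e1}, {e2}; junction dropped",
                        stacklevel=2,
                    )
                    bad.append((jid, [e1, e2]))
        if not bad:
            break
        for jid, exclusive in bad:
            warnings.warn(
                f"junction {jid}: {len(exclusive)} edges appear in no other "
                "equation; junction dropped as underdetermined",
                stacklevel=2,
            )
            retained_set.discard(jid)
            dropped_exclusive.update(exclusive)
    retained = [j for j in retained if j in retained_set]
    excluded = excluded | dropped_exclusive

    rows_j = []
    for jid in retained:
        j = mesh.junctions[jid]
        live = [e for e in j.incident_edge_ids if e not in excluded]
        if len(live) < 2:
            warnings.warn(
                f"junction {jid} has fewer than 2 retained edges; dropped",
                stacklevel=2,
            )
            continue
        if len(live) == 2:
            # a genuine double junction separates the same two regions with
            # both edges; mismatched side pairs indicate a point contact of
            # four cells (e.g. an annihilated two-sided cell), where a
            # two-edge balance would wrongly equate unrelated tensions
            sa = frozenset(mesh.edges[live[0]].side_cells)
            sb = frozenset(mesh.edges[live[1]].side_cells)
            if sa != sb:
                warnings.warn(
                    f"junction {jid}: point-contact double junction, no equations",
                    stacklevel=2,
                )
                continue
        rows_j.append(jid)

    # columns: non-excluded edges incident to at least one retained junction
    used_edges: list[int] = []
    seen = set()
    for jid in rows_j:
        for eid in mesh.junctions[jid].incident_edge_ids:
            if eid not in excluded and eid not in seen:
                seen.add(eid)
                used_edges.append(eid)
    used_edges.sort()
    col_of = {eid: k for k, eid in enumerate(used_edges)}

    G = np.zeros((2 * len(rows_j), len(used_edges)))
    row_index: list[tuple[int, str]] = []
    for r, jid in enumerate(rows_j):
        j = mesh.junctions[jid]
        for eid in j.incident_edge_ids:
            if eid in excluded:
                continue
            e = mesh.edges[eid]
            ja, jb = e.endpoint_junctions
            ends = []
            if ja == jid:
                ends.append("first")
            if jb == jid:
                ends.append("second")
            for end in ends:
                t = tangents[(eid, end)]
                G[2 * r, col_of[eid]] += t[0]
                G[2 * r + 1, col_of[eid]] += t[1]
        row_index.append((jid, "x"))
        row_index.append((jid, "y"))
    row_index_flat = [(jid, ax) for jid in rows_j for ax in ("x", "y")]
    n = max(len(used_edges), 1)
    return TensionSystem(
        matrix_G=G,
        constraint_vector=np.full(len(used_edges), 1.0 / n),
        row_index=row_index_flat,
        col_index=used_edges,
    )


def _solve_kkt(GtG: np.ndarray, c: np.ndarray, rhs_top: np.ndarray,
               rhs_bottom: float) -> tuple[np.ndarray, float, float]:
    n = len(c)
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = 2.0 * GtG
    K[:n, n] = c
    K[n, :n] = c
    K[n, n] = 0.0
    cond = np.linalg.cond(K)
    rhs = np.concatenate([rhs_top, [rhs_bottom]])
    if not np.isfinite(cond) or cond > KKT_COND_LIMIT:
        raise SingularSystemError("KKT system numerically singular", cond)
    sol = np.linalg.solve(K, rhs)
    return sol[:n], float(sol[n]), cond


def _solve_reduced(G: np.ndarray, q: np.ndarray, target_mean: float
                   ) -> np.ndarray:
    """SVD fallback: eliminate the mean constraint by substitution."""
    n = G.shape[1]
    ones = np.ones(n) / np.sqrt(n)
    # orthonormal basis of the mean-zero subspace
    Z = np.linalg.svd(np.eye(n) - np.outer(ones, ones))[0][:, : n - 1]
    x0 = np.full(n, target_mean)
    u, *_ = np.linalg.lstsq(G @ Z, q - G @ x0, rcond=None)
    return x0 + Z @ u


def solve_tensions(system: TensionSystem) -> tuple[dict[int, float], float]:
    """Standard Tensions: minimise ||G gamma||^2 subject to mean(gamma)=1.

    Returns the per-edge tensions and the Lagrange multiplier.  Falls back
    to an SVD substitution solve when the KKT block is ill-conditioned.
    Negative tensions are reported with a warning, never clipped.
    """
    G = system.matrix_G
    if G.shape[0] < 1:
        raise ValueError("tension system has no equations")
    c = system.constraint_vector
    GtG = G.T @ G
    try:
        gamma, lam, _ = _solve_kkt(GtG, c, np.zeros(G.shape[1]), 1.0)
    except SingularSystemError:
        gamma = _solve_reduced(G, np.zeros(G.shape[0]), 1.0)
        lam = float(-len(c) * np.mean(2.0 * GtG @ gamma))
    if np.any(gamma < 0):
        warnings.warn(
            f"{int(np.sum(gamma < 0))} negative inferred tensions (reported, not clipped)",
            stacklevel=2,
        )
    return dict(zip(system.col_index, gamma)), lam


def solve_tension_field(
    mesh: Mesh,
    tangents: TangentMap,
    excluded_edge_ids: set[int] = frozenset(),
    cond_limit: float = 1e3,
    max_auto_exclusions: int | None = None,
) -> tuple[dict[int, float], list[TensionSystem], set[int], float | None]:
    """Solve Standard Tensions over all connected components of a mesh.

    A high condition number of the constraint-augmented matrix signals a
    near-null mode (typically a pair of nearly collinear truncated stubs
    whose tension sum no equation fixes).  The edges dominating the
    near-null right singular vector are then excluded — the automated
    version of inspecting the near-zero singular vectors and removing
    poorly determined edges — and the component is re-solved.

    Returns ``(gamma, systems, effective_excluded, lambda1)``.
    """
    excluded = set(excluded_edge_ids)
    if max_auto_exclusions is None:
        max_auto_exclusions = max(5, len(mesh.edges) // 20)
    gamma: dict[int, float] = {}
    systems: list[TensionSystem] = []
    lam1: float | None = None

    for _ in range(max_auto_exclusions + 1):
        comps = sorted(mesh_mod.tension_components(mesh, excluded),
                       key=len, reverse=True)
        gamma.clear()
        systems.clear()
        worst: tuple[float, int] | None = None
        for comp in comps:
            tsys = assemble_tension_system(mesh, tangents, excluded, comp)
            if tsys.matrix_G.size == 0:
                continue
            A = np.vstack([tsys.matrix_G, tsys.constraint_vector[None, :]])
            s_vals, Vt = np.linalg.svd(A)[1:]
            cond = np.inf if s_vals[-1] == 0 else s_vals[0] / s_vals[-1]
            g = lam = None
            wild = False
            if cond <= cond_limit or len(tsys.col_index) <= 3:
                g, lam = solve_tensions(tsys)
                vals = np.array(list(g.values()))
                # a near-null mode excited by equation errors shows up as a
                # wildly oscillating solution even at a moderate condition
                # number: many negative tensions or huge outliers
                wild = len(vals) > 10 and (
                    np.mean(vals < 0) > 0.2 or np.max(np.abs(vals)) > 25.0)
            if (cond > cond_limit or wild) and len(tsys.col_index) > 3:
                v = np.abs(Vt[-1])
                # prefer excluding stubs / no-intermediate-node edges
                order = np.argsort(-v)
                pick = None
                for idx in order:
                    eid = tsys.col_index[idx]
                    e = mesh.edges[eid]
                    if v[idx] < 0.3 * v.max():
                        break
                    if e.is_stub or len(e.chain) == 2:
                        pick = eid
                        break
                if pick is None:
                    pick = tsys.col_index[int(order[0])]
                if worst is None or cond > worst[0]:
                    worst = (cond, pick)
                continue
            gamma.update(g)
            systems.append(tsys)
            if lam1 is None:
                lam1 = lam
        if worst is None:
            break
        warnings.warn(
            f"ill-conditioned tension system (cond {worst[0]:.3g}); "
            f"excluding edge {worst[1]} implicated by the near-null mode",
            stacklevel=2,
        )
        excluded.add(worst[1])
    return gamma, systems, excluded, lam1


def pressure_usable_edges(
    mesh: Mesh,
    geometry: dict[int, EdgeGeometry],
    excluded_edge_ids: set[int] = frozenset(),
    include_unreliable_curvature: bool = True,
) -> list[int]:
    """Edges that contribute Laplace rows.

    Non-stub, non-excluded edges bounded by two declared cells (a cell or
    the medium on both sides).  Two-node chains carry no curvature
    information; by default they enter as straight edges (rhs 0), and the
    short-edges-removed protocol drops them via
    ``include_unreliable_curvature=False``.
    """
    excluded = set(excluded_edge_ids)
    out = []
    for eid, e in mesh.edges.items():
        if eid in excluded or e.is_stub:
            continue
        if not all(s is not None for s in e.side_cells):
            continue
        if not include_unreliable_curvature and not geometry[eid].curvature_reliable:
            continue
        out.append(eid)
    return sorted(out)


def assemble_pressure_system(
    mesh: Mesh,
    gamma: dict[int, float],
    curvatures: dict[int, float],
    usable_edge_ids: list[int],
    cell_ids: set[int] | None = None,
) -> PressureSystem:
    """Build the Laplace system: one row per usable edge.

    Row for edge (i, j): ``+1`` at cell i, ``-1`` at cell j, right-hand side
    ``gamma_ij * kappa_ij`` (zero for straight edges).  ``cell_ids``
    restricts assembly to one pressure component.
    """
    rows = []
    for eid in usable_edge_ids:
        a, b = mesh.edges[eid].side_cells
        if cell_ids is not None and (a not in cell_ids or b not in cell_ids):
            continue
        if eid not in gamma:
            raise ValueError(f"edge {eid} has no tension")
        rows.append((eid, a, b))
    cells = sorted({c for _, a, b in rows for c in (a, b)})
    if cell_ids is not None:
        cells = sorted(cell_ids)
    col_of = {cid: k for k, cid in enumerate(cells)}
    G = np.zeros((len(rows), len(cells)))
    q = np.zeros(len(rows))
    row_index = []
    for r, (eid, a, b) in enumerate(rows):
        G[r, col_of[a]] = 1.0
        G[r, col_of[b]] = -1.0
        q[r] = gamma[eid] * curvatures[eid]
        row_index.append(eid)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite pressure right-hand side")
    n = max(len(cells), 1)
    return PressureSystem(
        matrix_G=G,
        rhs_q=q,
        constraint_vector=np.full(len(cells), 1.0 / n),
        row_index=row_index,
        col_index=cells,
    )


def solve_pressures(system: PressureSystem) -> tuple[dict[int, float], float]:
    """Standard Pressures: minimise ||G p - q||^2 subject to mean(p)=0."""
    G, q = system.matrix_G, system.rhs_q
    if G.shape[0] < 1:
        raise ValueError("pressure system has no equations")
    c = system.constraint_vector
    GtG = G.T @ G
    try:
        p, lam, _ = _solve_kkt(GtG, c, 2.0 * G.T @ q, 0.0)
    except SingularSystemError:
        p = _solve_reduced(G, q, 0.0)
        lam = 0.0
    return dict(zip(system.col_index, p)), lam


def general_solution(
    gamma_star: dict[int, float],
    p_star: dict[int, float],
    alpha: float,
    beta: float,
) -> tuple[dict[int, float], dict[int, float]]:
    """Scale a standard solution to physical units: gamma = alpha*gamma*,
    p = alpha*p* + beta."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    gamma = {k: alpha * v for k, v in gamma_star.items()}
    p = {k: alpha * v + beta for k, v in p_star.items()}
    return gamma, p


def standardize(
    gamma: dict[int, float] | np.ndarray,
    p: dict[int, float] | np.ndarray,
) -> tuple:
    """Invert the General Solution: recover (gamma*, p*, alpha, beta).

    alpha is the mean tension, beta the mean pressure; works on dicts or
    plain arrays.
    """
    if isinstance(gamma, dict):
        gkeys, gvals = list(gamma), np.array(list(gamma.values()), dtype=float)
        pkeys, pvals = list(p), np.array(list(p.values()), dtype=float)
    else:
        gkeys = pkeys = None
        gvals = np.asarray(gamma, dtype=float)
        pvals = np.asarray(p, dtype=float)
    alpha = float(np.mean(gvals))
    if alpha <= 0:
        raise ValueError("mean tension must be positive")
    beta = float(np.mean(pvals)) if len(pvals) else 0.0
    gs = gvals / alpha
    ps = (pvals - beta) / alpha
    if gkeys is not None:
        return dict(zip(gkeys, gs)), dict(zip(pkeys, ps)), alpha, beta
    return gs, ps, alpha, beta
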