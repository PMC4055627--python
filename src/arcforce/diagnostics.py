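"""Solution-quality diagnostics: condition numbers, residuals, standard errors.

The condition number of each system is the ratio of largest to smallest
singular values of the constraint-augmented matrix ``[G; c^T]`` — the
mean-tension/mean-pressure constraint removes the intrinsic rank deficiency
of the force-inference problem, so a finite, modest condition number
certifies a well-posed inversion.

Tension residuals are the per-junction out-of-balance force vectors
``r = G_gamma @ gamma`` grouped as (x, y) pairs and reported normalised by
the mean tension.  Pressure residuals ``r = G_p @ p - q`` are converted to
forces by multiplying by the chord length of the edge they act on, then
normalised by the mean tension.  Standard errors come from the usual
linear-model covariance after eliminating the mean constraint by reduced
parametrisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mesh as mesh_mod
from .inference import PressureSystem, TensionSystem
from .mesh import Mesh


@dataclass
class DiagnosticsReport:
    cond_tension: float
    cond_pressure: float | None
    tension_residuals: dict[int, np.ndarray]          # junction id -> (x, y)
    tension_residuals_normalized: dict[int, float]    # junction id -> |r|/mean(gamma)
    pressure_residuals: dict[int, float]              # edge id -> raw residual
    pressure_residuals_normalized: dict[int, float]   # edge id -> |r|*L/mean(gamma)
    standard_errors_tension: dict[int, float]
    standard_errors_pressure: dict[int, float]
    mean_cell_radius: float | None = None
    mean_tension: float = 1.0
    ill_posed: bool = False


def condition_number(matrix_G: np.ndarray,
                     constraint_vector: np.ndarray | None = None) -> float:
    """sigma_max / sigma_min of the constraint-augmented matrix [G; c^T].

    Returns ``inf`` when the smallest singular value is zero (ill-posed).
    """
    A = matrix_G
    if constraint_vector is not None:
        A = np.vstack([matrix_G, constraint_vector[None, :]])
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] <= s[0] * np.finfo(float).eps * max(A.shape):
        return np.inf
    return float(s[0] / s[-1])


def system_condition_number(system: TensionSystem | PressureSystem) -> float:
    return condition_number(system.matrix_G, system.constraint_vector)


def tension_residuals(system: TensionSystem, gamma: dict[int, float]
                      ) -> tuple[dict[int, np.ndarray], dict[int, float]]:
    """Per-junction residual force vectors and mean-tension-normalised norms."""
    g = np.array([gamma[eid] for eid in system.col_index])
    r = system.matrix_G @ g
    mean_gamma = float(np.mean(g))
    vectors: dict[int, np.ndarray] = {}
    for k in range(0, len(r), 2):
        jid, _ = system.row_index[k]
        vectors[jid] = np.array([r[k], r[k + 1]])
    normalized = {jid: float(np.linalg.norm(v)) / mean_gamma
                  for jid, v in vectors.items()}
    return vectors, normalized


def pressure_residuals(system: PressureSystem, p: dict[int, float],
                       chord_lengths: dict[int, float],
                       mean_tension: float = 1.0
                       ) -> tuple[dict[int, float], dict[int, float]]:
    """Per-edge Laplace residuals, raw and chord-weighted force-normalised."""
    pv = np.array([p[cid] for cid in system.col_index])
    r = system.matrix_G @ pv - system.rhs_q
    raw = dict(zip(system.row_index, r))
    normalized = {eid: abs(val) * chord_lengths[eid] / mean_tension
                  for eid, val in raw.items()}
    return raw, normalized


def _reduced_covariance(A: np.ndarray, resid: np.ndarray, n_full: int,
                        Z: np.ndarray) -> np.ndarray | None:
    m = A.shape[0]
    dof = m - (n_full - 1)
    if dof <= 0:
        return None
    sigma2 = float(resid @ resid) / dof
    AtA = A.T @ A
    try:
        cov_u = sigma2 * np.linalg.inv(AtA)
    except np.linalg.LinAlgError:
        cov_u = sigma2 * np.linalg.pinv(AtA)
    return Z @ cov_u @ Z.T


def _mean_zero_basis(n: int) -> np.ndarray:
    ones = np.ones(n) / np.sqrt(n)
    return np.linalg.svd(np.eye(n) - np.outer(ones, ones))[0][:, : n - 1]


def standard_errors(matrix_G: np.ndarray, rhs: np.ndarray,
                    solution: np.ndarray) -> np.ndarray | None:
    """Covariance standard errors of a mean-constrained least-squares fit.

    The mean constraint is eliminated by parametrising the solution over an
    orthonormal basis Z of the mean-zero subspace; the residual variance
    uses m - (n - 1) degrees of freedom.  Returns None (flagged undefined)
    when the system is not overdetermined.
    """
    m, n = matrix_G.shape
    Z = _mean_zero_basis(n)
    A = matrix_G @ Z
    resid = matrix_G @ solution - rhs
    cov = _reduced_covariance(A, resid, n, Z)
    if cov is None:
        return None
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def mean_cell_radius(mesh: Mesh) -> float | None:
    """Mean over complete cells of sqrt(area / pi)."""
    radii = []
    for c in mesh.cells.values():
        if c.is_partial or c.is_medium:
            continue
        a = mesh_mod.cell_area(mesh, c.id)
        if a is not None:
            radii.append(np.sqrt(a / np.pi))
    return float(np.mean(radii)) if radii else None


def diagnostics_report(
    mesh: Mesh,
    tension_system: TensionSystem,
    gamma: dict[int, float],
    pressure_system: PressureSystem | None = None,
    pressures: dict[int, float] | None = None,
    chord_lengths: dict[int, float] | None = None,
) -> DiagnosticsReport:
    """Assemble the full quality report for a solved mesh."""
    cond_t = system_condition_number(tension_system)
    g = np.array([gamma[eid] for eid in tension_system.col_index])
    mean_gamma = float(np.mean(g))
    tr_vec, tr_norm = tension_residuals(tension_system, gamma)
    se_t = standard_errors(tension_system.matrix_G,
                           np.zeros(tension_system.matrix_G.shape[0]), g)
    se_t_map = (dict(zip(tension_system.col_index, se_t))
                if se_t is not None else {})

    cond_p = None
    pr_raw: dict[int, float] = {}
    pr_norm: dict[int, float] = {}
    se_p_map: dict[int, float] = {}
    if pressure_system is not None and pressures is not None:
        cond_p = system_condition_number(pressure_system)
        chords = chord_lengths or {}
        pr_raw, pr_norm = pressure_residuals(
            pressure_system, pressures,
            {eid: chords.get(eid, 1.0) for eid in pressure_system.row_index},
            mean_gamma,
        )
        pv = np.array([pressures[cid] for cid in pressure_system.col_index])
        se_p = standard_errors(pressure_system.matrix_G, pressure_system.rhs_q, pv)
        if se_p is not None:
            se_p_map = dict(zip(pressure_system.col_index, se_p))

    return DiagnosticsReport(
        cond_tension=cond_t,
        cond_pressure=cond_p,
        tension_residuals=tr_vec,
        tension_residuals_normalized=tr_norm,
        pressure_residuals=pr_raw,
        pressure_residuals_normalized=pr_norm,
        standard_errors_tension=se_t_map,
        standard_errors_pressure=se_p_map,
        mean_cell_radius=mean_cell_radius(mesh),
        mean_tension=mean_gamma,
        ill_posed=not np.isfinite(cond_t)
        or (cond_p is not None and not np.isfinite(cond_p)),
    )
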