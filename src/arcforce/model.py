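"""Model/Results interface for curvilinear force inference.

:class:`ForceInferenceModel` is built from a :class:`~arcforce.mesh.Mesh`
(or a mesh JSON file / labelled segmentation image) plus the analysis
choices (angle-determination method, excluded edges).  ``fit()`` assembles
and solves the junction-equilibrium and Laplace systems per connected
component and returns a :class:`ForceInferenceResults` carrying the Standard
Tensions (mean 1), Standard Pressures (mean 0), their standard errors,
quality diagnostics and a ``summary()`` table.

Example
-------
>>> from arcforce.synthetic import synthetic_patch
>>> from arcforce.model import ForceInferenceModel
>>> mesh, truth = synthetic_patch(seed=0)
>>> res = ForceInferenceModel(mesh).fit()
>>> res.tensions.head()
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import geometry as geom
from . import inference as inf
from . import mesh as mesh_mod
from .mesh import Mesh


class ForceInferenceModel:
    """Force-inference model for a polyarc cell sheet.

    Parameters
    ----------
    mesh
        Validated mesh (the single source of topology and geometry).
    angle_method
        How limiting angles at junctions are determined: ``"polyarc"``
        (tangent of the fitted circular arc, the standard method),
        ``"closest_segment"`` (first chain segment) or ``"minimal_polygon"``
        (straight chord between junctions).
    straightness_tol
        Sagitta/chord ratio below which an edge is treated as straight.
    excluded_edges
        Edge ids removed from the analysis; the force balances of their
        endpoint junctions are dropped as well.
    include_two_node_edges
        Whether edges without intermediate nodes (no curvature information)
        contribute Laplace rows as straight edges.  Set ``False`` for the
        short-edges-removed protocol (they are then also excluded from the
        tension equations).
    """

    def __init__(
        self,
        mesh: Mesh,
        angle_method: str = "polyarc",
        straightness_tol: float = geom.STRAIGHTNESS_TOL,
        excluded_edges: set[int] = frozenset(),
        include_two_node_edges: bool = True,
    ):
        if angle_method not in geom.ANGLE_METHODS:
            raise ValueError(f"unknown angle method {angle_method!r}")
        self.mesh = mesh
        self.angle_method = angle_method
        self.straightness_tol = straightness_tol
        self.excluded_edges = set(excluded_edges)
        self.include_two_node_edges = include_two_node_edges
        if not include_two_node_edges:
            self.excluded_edges |= {
                eid for eid, e in mesh.edges.items() if len(e.chain) == 2
            }
        self.geometry = geom.mesh_geometry(mesh, angle_method, straightness_tol)
        self._tangents: inf.TangentMap | None = None
        self._curvatures: dict[int, float] | None = None

    @classmethod
    def from_mesh_json(cls, path, **kwargs) -> "ForceInferenceModel":
        from .io import read_mesh_json

        return cls(read_mesh_json(path), **kwargs)

    @classmethod
    def from_label_image(cls, path, **kwargs) -> "ForceInferenceModel":
        from .io import read_label_image

        return cls(read_label_image(path), **kwargs)

    # measurement override hook (used for noise studies)
    def set_measurements(self, tangents: inf.TangentMap,
                         curvatures: dict[int, float]) -> "ForceInferenceModel":
        """Replace fitted tangents/curvatures with external measurements."""
        self._tangents = tangents
        self._curvatures = curvatures
        return self

    @property
    def tangents(self) -> inf.TangentMap:
        return self._tangents or inf.tangent_map(self.geometry)

    @property
    def curvatures(self) -> dict[int, float]:
        return self._curvatures or inf.curvature_map(self.geometry)

    def fit(self, tensions_only: bool = False) -> "ForceInferenceResults":
        """Solve the constrained least-squares systems.

        Tensions first (per edge-connected junction component, normalised to
        mean 1 within each component), then — unless ``tensions_only`` —
        pressures (per cell component, mean 0 within each component).
        """
        mesh = self.mesh
        excluded = self.excluded_edges
        tangents = self.tangents
        curvatures = self.curvatures

        gamma, tension_systems, effective_excluded, lam1 = \
            inf.solve_tension_field(mesh, tangents, excluded)
        excluded = effective_excluded
        self.effective_excluded_edges = effective_excluded
        if not gamma:
            raise ValueError("no solvable tension component")

        pressures = None
        pressure_systems = []
        lam2 = None
        if not tensions_only:
            usable = inf.pressure_usable_edges(
                mesh, self.geometry, excluded, self.include_two_node_edges)
            usable = [e for e in usable if e in gamma]
            pressures = {}
            pcomps = sorted(mesh_mod.pressure_components(mesh, set(usable)),
                            key=len, reverse=True)
            for comp in pcomps:
                psys = inf.assemble_pressure_system(
                    mesh, gamma, curvatures, usable, comp)
                if psys.matrix_G.size == 0 or psys.matrix_G.shape[0] == 0:
                    continue
                p, lam = inf.solve_pressures(psys)
                pressures.update(p)
                pressure_systems.append(psys)
                if lam2 is None:
                    lam2 = lam

        chords = {eid: g.chord_length for eid, g in self.geometry.items()}
        report = diag.diagnostics_report(
            mesh,
            tension_systems[0],
            gamma,
            pressure_systems[0] if pressure_systems else None,
            pressures,
            chords,
        )
        # merge residuals/SEs of secondary components into the report
        for tsys in tension_systems[1:]:
            vec, norm = diag.tension_residuals(tsys, gamma)
            report.tension_residuals.update(vec)
            report.tension_residuals_normalized.update(norm)
        for psys in pressure_systems[1:]:
            raw, norm = diag.pressure_residuals(
                psys, pressures, {e: chords.get(e, 1.0) for e in psys.row_index},
                report.mean_tension)
            report.pressure_residuals.update(raw)
            report.pressure_residuals_normalized.update(norm)

        counts = mesh_mod.tally_counts(mesh, excluded)
        return ForceInferenceResults(
            model=self,
            tensions=pd.Series(gamma, name="gamma_star").sort_index(),
            pressures=(pd.Series(pressures, name="p_star").sort_index()
                       if pressures is not None else None),
            diagnostics=report,
            counts=counts,
            tension_systems=tension_systems,
            pressure_systems=pressure_systems,
            lagrange_tension=lam1,
            lagrange_pressure=lam2,
        )


class ForceInferenceResults:
    """Standard Tensions/Pressures with uncertainties and diagnostics.

    The tensions are relative (mean 1 per component) and the pressures are
    gauge pressures (mean 0 per component); physical units require the
    external scale alpha (mean edge tension) and offset beta (mean
    intracellular pressure) via :meth:`general_solution`.
    """

    def __init__(self, model, tensions, pressures, diagnostics, counts,
                 tension_systems, pressure_systems,
                 lagrange_tension=None, lagrange_pressure=None,
                 alpha=None, beta=None):
        self.model = model
        self.tensions = tensions
        self.pressures = pressures
        self.diagnostics = diagnostics
        self.counts = counts
        self.tension_systems = tension_systems
        self.pressure_systems = pressure_systems
        self.lagrange_tension = lagrange_tension
        self.lagrange_pressure = lagrange_pressure
        self.alpha = alpha
        self.beta = beta

    @property
    def tension_se(self) -> pd.Series:
        return pd.Series(self.diagnostics.standard_errors_tension,
                         name="se", dtype=float).reindex(self.tensions.index)

    @property
    def pressure_se(self) -> pd.Series | None:
        if self.pressures is None:
            return None
        return pd.Series(self.diagnostics.standard_errors_pressure,
                         name="se", dtype=float).reindex(self.pressures.index)

    def general_solution(self, alpha: float, beta: float = 0.0):
        """Physical tensions/pressures: gamma = alpha*gamma*, p = alpha*p* + beta."""
        from .inference import general_solution as gs

        g, p = gs(self.tensions.to_dict(),
                  (self.pressures.to_dict() if self.pressures is not None else {}),
                  alpha, beta)
        return (pd.Series(g, name="gamma").sort_index(),
                pd.Series(p, name="p").sort_index())

    def edge_table(self) -> pd.DataFrame:
        """Per-edge geometry and solution table."""
        rows = []
        for eid, g in sorted(self.model.geometry.items()):
            rows.append({
                "edge_id": eid,
                "gamma_star": self.tensions.get(eid, np.nan),
                "se": self.tension_se.get(eid, np.nan),
                "radius": g.arc.radius,
                "curvature_signed": g.curvature_signed,
                "chord_length": g.chord_length,
                "fit_rms": g.arc.fit_rms,
                "tangent_angle_first_deg": float(np.degrees(
                    np.arctan2(g.tangent_at_first[1], g.tangent_at_first[0]))),
                "tangent_angle_second_deg": float(np.degrees(
                    np.arctan2(g.tangent_at_second[1], g.tangent_at_second[0]))),
                "is_stub": self.model.mesh.edges[eid].is_stub,
                "excluded": eid in self.model.excluded_edges,
            })
        return pd.DataFrame(rows).set_index("edge_id")

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        d = self.diagnostics
        c = self.counts
        lines = [
            "Curvilinear force inference results",
            "=" * 54,
            f"angle method:          {self.model.angle_method}",
            f"junctions (removed):   {c.n_junctions} ({c.n_junctions_removed})",
            f"tension eqns/unknowns: {c.n_tension_eqns} / {c.n_tensions}",
            f"pressure eqns/unknowns:{c.n_pressure_eqns} / {c.n_pressures}",
            f"stub edges:            {c.n_stubs}",
            f"excess edge count:     {c.n_excess_edges}",
            f"cond(tension system):  {d.cond_tension:.3g}",
        ]
        if d.cond_pressure is not None:
            lines.append(f"cond(pressure system): {d.cond_pressure:.3g}")
        t = self.tensions
        lines += [
            "-" * 54,
            f"standard tensions:  n={len(t)}  mean={t.mean():.4f}  "
            f"min={t.min():.4f}  max={t.max():.4f}",
        ]
        if len(d.tension_residuals_normalized):
            r = np.array(list(d.tension_residuals_normalized.values()))
            lines.append(
                f"junction residuals (|r|/mean gamma): median={np.median(r):.2e} "
                f"max={r.max():.2e}")
        if self.pressures is not None and len(self.pressures):
            p = self.pressures
            lines.append(
                f"standard pressures: n={len(p)}  mean={p.mean():.2e}  "
                f"rms={np.sqrt((p**2).mean()):.4f}")
        if d.ill_posed:
            lines.append("WARNING: system flagged ill-posed (infinite condition number)")
        return "\n".join(lines)

    def to_csv(self, outdir) -> None:
        """Write tensions.csv, pressures.csv and diagnostics.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        et = pd.DataFrame({
            "gamma_star": self.tensions,
            "se": self.tension_se,
        })
        et.to_csv(outdir / "tensions.csv", index_label="edge_id")
        if self.pressures is not None:
            pt = pd.DataFrame({"p_star": self.pressures, "se": self.pressure_se})
            pt.to_csv(outdir / "pressures.csv", index_label="cell_id")
        d = self.diagnostics
        payload = {
            "cond_tension": d.cond_tension,
            "cond_pressure": d.cond_pressure,
            "mean_tension": d.mean_tension,
            "mean_cell_radius": d.mean_cell_radius,
            "ill_posed": d.ill_posed,
            "alpha": self.alpha,
            "beta": self.beta,
            "lagrange_tension": self.lagrange_tension,
            "lagrange_pressure": self.lagrange_pressure,
            "counts": self.counts.__dict__,
            "tension_residuals": {
                str(j): [float(v[0]), float(v[1]),
                         d.tension_residuals_normalized[j]]
                for j, v in d.tension_residuals.items()
            },
            "pressure_residuals_normalized": {
                str(e): v for e, v in d.pressure_residuals_normalized.items()
            },
        }
        (outdir / "diagnostics.json").write_text(
            json.dumps(payload, indent=1, default=float))

    def plot(self, ax=None, linewidth: float = 1.5):
        """Draw edges coloured by standard tension (requires matplotlib)."""
        import matplotlib.pyplot as plt
        from matplotlib.collections import LineCollection

        if ax is None:
            _, ax = plt.subplots()
        segs, vals = [], []
        for eid in self.tensions.index:
            pts = self.model.mesh.chain_points(eid)
            segs.extend(np.stack([pts[:-1], pts[1:]], axis=1))
            vals.extend([self.tensions[eid]] * (len(pts) - 1))
        lc = LineCollection(segs, array=np.array(vals), cmap="viridis",
                            linewidths=linewidth)
        ax.add_collection(lc)
        ax.autoscale()
        ax.set_aspect("equal")
        plt.colorbar(lc, ax=ax, label="standard tension")
        return ax
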