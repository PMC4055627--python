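# Methods

## The inverse problem

A planar cell sheet is modelled as a network of membrane-like interfaces:
each cell-cell edge carries a uniform line tension γ_ij (actomyosin
contraction plus membrane tension minus adhesion), and each cell an
effective isotropic pressure p_i.  Under the quasi-static assumption the
observable cell shapes are fully determined by these forces, and two sets
of linear relations tie forces to geometry:

* **Junction equilibrium.**  At every junction the incident edges pull
  along their limiting tangents û (unit vectors tangent to the edge where
  it approaches the junction, pointing away from it):
  Σ_e γ_e û_e = 0, two scalar equations (x, y) per junction.
* **Laplace relation.**  Across every edge the pressure jump balances
  tension times curvature: p_i − p_j = γ_ij κ_ij, with κ_ij the signed
  curvature of the fitted circular arc, positive when the edge is convex
  into cell j (cell i lies on the left of the stored chain).

Stacked over a connected patch these give the homogeneous tension system
G_γ γ ≈ 0 and the inhomogeneous pressure system G_p p ≈ q with
q = (γ_ij κ_ij).  Both are rank deficient by one — only tension ratios and
pressure differences are observable — so they are solved as constrained
least squares with Lagrange multipliers enforcing mean(γ) = 1 and
mean(p) = 0.  The results are the *Standard Tensions* γ\* and *Standard
Pressures* p\*; every physically admissible solution is γ = αγ\*,
p = αp\* + β where the tension scale α (mean edge tension) and pressure
offset β (mean intracellular pressure) require information external to the
image.

The tension system is solved first and feeds the pressure system; the two
are never solved jointly (a coupled solve shows no advantage and mixes
units).  The primary solver is a dense KKT block solve; if the KKT matrix
is numerically singular (condition number above 1e12) an SVD-based
substitution solve over the mean-constrained subspace is used instead.
Negative inferred tensions are reported with a warning, never clipped —
clipping would bias the residual diagnostics.

### Well-posedness guards

Three degeneracy classes arise in frayed or pixelated meshes and are
handled automatically, mirroring the practice of excluding poorly defined
edges (exclusion of an edge always removes the two force balances of its
endpoint junctions):

1. a junction where three or more incident edges appear in no other
   equation (e.g. three truncated stubs) is locally underdetermined and is
   dropped with those edges — unless it is the entire system, where the
   mean constraint itself closes the count (a single triple junction *is*
   solvable up to scale);
2. a junction with exactly two such single-equation edges whose pull
   directions are nearly parallel (|sin| < 0.2) constrains only their
   difference; the junction is dropped;
3. if the constraint-augmented matrix is ill-conditioned (σ_max/σ_min
   above 1e3) or the solution oscillates wildly (over 20% negative
   tensions, or magnitudes above 25 in mean-1 units), the edge dominating
   the near-null right singular vector is excluded and the component is
   re-solved (bounded number of exclusions).

Point-contact double junctions — order-2 nodes whose two edges separate
*different* cell pairs, left behind when a two-sided cell is annihilated —
get no equations: a two-edge balance there would wrongly equate unrelated
tensions.

## Geometry extraction

Each edge chain is fitted with a circle: Kåsa algebraic fit refined by
Gauss–Newton iterations on the geometric distance (iterated to
convergence rather than a single pass — one pass is not enough to undo the
algebraic fit's small-circle bias on short pixelated chains; a consistency
guard additionally rejects fits whose implied sagitta exceeds 2.5× the
observed chord deviation, falling back to a straight edge).  An edge is
straight when it has two points, is collinear within tolerance, or has
fitted sagitta/chord below 1e-3 (`straightness_tol`, exposed in the API).
The limiting tangent is the tangent of the fitted circle at its closest
point to the junction, oriented away from the junction (sign fixed by the
dot product with the chain's interior direction).  Three angle methods are
supported: `polyarc` (the standard), `closest_segment` (direction of the
chain segment adjacent to the junction) and `minimal_polygon` (straight
chord between junctions).  Edges with no intermediate nodes cannot carry
curvature; they enter the pressure system as straight edges (zero
right-hand side) by default and are removed entirely under the
short-edges-removed protocol.

## Diagnostics

Condition numbers are σ_max/σ_min of the constraint-augmented matrix
[G; cᵀ] (one constraint row) — the augmentation removes the gauge rank
deficiency, so finite moderate values certify well-posedness.  Tension
residuals are reported per junction as (x, y) vectors normalised by the
mean tension; pressure residuals per edge are converted to forces by the
chord length and normalised the same way.  The display scale for residual
plots is the mean complete-cell radius √(A/π).  Standard errors use the
conventional linear-model covariance after eliminating the mean constraint
by an orthonormal reduced parametrisation, with m − (n − 1) degrees of
freedom (one parameter is fixed by the constraint; validated against a KKT
pseudo-inverse oracle).

## The synthetic forward model

The validation harness regenerates everything it tests against:

* **Tessellation.** n = 150 seed points, uniform in a square of side √n
  (unit mean cell area), two Lloyd iterations, bounded by four-mirror
  reflection.  Voronoi edges shorter than 8% of the mean edge length are
  contracted into quad/rosette junctions.
* **Discretisation.** Intermediate nodes are placed per edge in proportion
  to length (target segment length = mean edge length / 5, giving a mean
  of ≈4 intermediate nodes per edge); edges shorter than 8% of the mean
  stay two-node chains — they are physically unable to curve, which is
  exactly the "short edge" population whose inclusion degrades the
  pressure solution.
* **Ground truth.** Cell types i.i.d. uniform on {1,2,3}; interface class
  = unordered type pair mapped to tensions {11:5, 12:6, 13:7, 22:10,
  23:11, 33:12} (the sorted-pair reading of the 5:6:7:10:11:12 ratio
  table; boundary edges take the homotypic value of their one cell).
* **Annealing.** The mesh relaxes to static equilibrium by minimising
  E = Σ_e γ_e L_e + Σ_c (k/2)(A_c − A0_c)²/A0_c with analytic gradients
  (L-BFGS), the outer box pinned, target areas fixed at the initial cell
  areas, and k = 50 (in units of mean tension per unit area; chosen once
  to give ~10% area strains and visibly curved edges).  Pressures emerge
  as p_c = k(A0_c − A_c)/A0_c.  Between relaxation rounds, edges driven
  below 5% of the mean length are contracted (T1-frustrated edges and
  T2-annihilated two-sided cells cannot reach equilibrium otherwise), and
  chains are re-subdivided so segment counts track the evolving edge
  lengths.  Convergence requires the largest residual nodal force to fall
  below 1e-3 of the mean tension; chains are finally resampled to uniform
  spacing along their fitted arcs.
* **Extraction.** A centred window sized for ≈50 complete cells keeps all
  junctions inside it; edges crossing the window are truncated *at chain
  nodes* (a synthetic clip point would sit off the edge's arc and bias the
  stub's tangent) keeping at least three nodes so stubs still support an
  arc fit.  Cells are complete if untruncated, partial otherwise; no
  medium cell exists in a frayed region.
* **Noise.** Level x adds Gaussian angle noise of x degrees RMS per edge
  end and multiplicative Gaussian curvature noise of x% RMS per edge,
  reproducibly from a seed — noise enters the measurements, never the node
  coordinates.
* **Error metrics.** Both solutions are standardised over the compared
  sets; tension error = RMS(γ̂\*−γ\*)/mean(γ\*) and pressure error =
  RMS(p̂\*−p\*)/RMS(p\*), reported in percent.

### What the discrete equilibrium can and cannot certify

At the discrete equilibrium each interior chain settles uniformly onto a
circle, and the *fitted-arc* tangent rotation from the chord (half the
subtended angle) exactly matches the rotation of the true transmitted
force — so polyarc inference on the resampled mesh is accurate to second
order in (segment length)/(Laplace radius).  The *analytic* limiting
tangents exported for consistency checks are the per-edge junction force
directions (chord plus the edge's pressure-load share); with them the true
tensions balance to O((sΔp/2γ)²) — typically ~1e-3 of the mean tension,
but up to ~2e-2 at the most strongly curved edges (Δp up to ~25 at k=50).
The consistency property test therefore asserts the median scale and a
per-junction quadratic bound rather than a uniform 1e-3, which this
discretisation cannot honestly meet.

An analytically exact equilibrium — the asymmetric double bubble, where
the force triangle at the two junctions and the Laplace closure hold in
closed form for any admissible tension triple — carries the
machine-precision recovery tests instead.

### What passing synthetic tests does not show

The generator emulates the *geometry* of an epithelium under heterogeneous
interfacial tension; it does not emulate segmentation failures, intensity
noise, out-of-plane curvature, viscous or traction forces, or temporal
correlation between frames.  Accuracy numbers on synthetic patches
therefore bound the method error of the inference itself, not the
end-to-end error on real microscopy data.

## Rasterisation / re-digitisation

The pixelation experiment images a window of the annealed patch at 675 px
width: every boundary is drawn as a smooth spline 1 px wide, interior
regions are labelled by flood fill and the labels expanded across the
boundary lines (watershed-line convention), regions are re-labelled by
maximal pixel overlap with the original cells, and the label image is
re-extracted through the corner-lattice contour tracer (4-connected
regions, 8-connected chains, junctions at ≥3-label corners, 2-node chains
between adjacent junction corners contracted to recover quad junctions,
and a 5-point moving average on chain interiors to tame staircase noise).
Chains running along the image frame are crop lines, not membranes, and
are dropped — which turns cut edges into stubs, the pixel-space analogue
of the frayed boundary.  In the error experiment, boundaries hugging the
frame (within 6 px) and boundaries whose region pair corresponds to no
original adjacency (relabelling artefacts of sliver absorption) are
excluded with their junction equations; the comparison runs over the
window-interior complete cells.  The Laplace stage additionally requires
at least 20 px of chain per edge — below that the arc sagitta of a
typically curved edge (Laplace radius of order 100–300 px at this
resolution) falls under the half-pixel staircase noise, making the fitted
curvature pure noise whose inclusion dominates the pressure error through
a handful of small cells.  Pressures come out in px⁻¹ units and are
converted back through the recorded length scale.

## Problem sizes and defaults

Validation ensembles use 10 patches of 150 cells with ~50-complete-cell
windows; the noise protocol runs 100 seeded draws at each level on one
regenerated region; the re-digitisation experiment averages a few patches
at 675 px.  All randomness fans out from a single master seed through
`numpy` seed sequences, making every reported number reproducible.

## Known limitations

* Tensions are assumed uniform along each edge; shear-carrying straight
  edges and viscous or traction forces are out of scope.
* Multiple tension components are normalised to mean 1 independently;
  relative scale across components is not identifiable from the image.
* Pressure solutions on sparsely connected partial cells at the fray can
  be weakly determined; their standard errors reflect this.
* The annealer is a quasi-static energy minimiser: it reproduces
  equilibrium states, not dynamics, and resolves topological frustration
  by discrete contraction events rather than by resolving true T1 dynamics.
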