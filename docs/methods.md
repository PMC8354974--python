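# Methods

This note documents the models, conventions and numerical choices behind
`aneusep`, and what the synthetic phantoms do and do not establish about
real data.

## Coordinates, units, conventions

All coordinates are millimetres; velocities mm/s; wall shear stress Pa;
flows are integrated in mm³/s and reported in mL/s (÷1000); sac areas in
cm² (÷100 from mm²). Vertex and triangle indices are 0-based everywhere,
including the JSON curve exchange format. Meshes are validated on
construction (in-range distinct indices, positive areas, every edge in at
most two triangles, consistent winding) and rejected rather than repaired:
silent repair would alter the edge graph and therefore every geodesic
computed on it.

The curve JSON schema (`case_id`, `annotator_id`,
`group ∈ {clinical, nonclinical, unknown}`, `vertex_indices`, `points`) is
this package's own design; it captures exactly the annotator metadata the
variability analysis needs.

## Neck curves on the edge graph

Shortest paths run along mesh edges only — the natural reading of "the
surface mesh as a bidirectional graph" — not across faces. A\* uses the
straight-line distance to the target as heuristic; with Euclidean edge
weights this is admissible and consistent, so A\* cost equals Dijkstra
cost (asserted against `scipy.sparse.csgraph.dijkstra` as an independent
oracle). Determinism conventions, chosen because a batch tool must be
reproducible: nearest-vertex ties snap to the lowest index; equal-cost
paths (within 1e-12 mm) prefer the lexicographically smaller vertex
sequence; the loop is always closed last→first (a neck curve is by
definition a loop, so closing is not conditional on pick proximity).
Junction cleanup removes consecutive duplicates and immediate backtracks;
a pinch vertex (visited twice with four distinct incident loop edges) is
allowed, since the loop still separates the surface; a repeated *edge* is
an error, not repaired.

Edge-bound paths inherit the segmentation's triangle size. The remedy is
local refinement: every triangle with a vertex within radius *r* of the
curve polyline is 4-to-1 midpoint-split, with red–green closure (a face
acquiring ≥ 2 split edges is promoted to red, a face with exactly one gets
a conforming 1-to-2 split) so no T-junctions remain. All new vertices are
original-edge midpoints: the polyhedral surface, and hence the total area,
is unchanged exactly, which the tests assert at 1e-9 relative. Default
radius is 10 × the median edge length — wide enough to decouple the path
from triangle size, narrow enough to stay local. When a radius is given,
the CLI subdivides around a provisional curve first and rebuilds on the
finer mesh.

## Ostium reconstruction

The cap is seeded on the least-squares plane of the curve (SVD; normal =
smallest principal axis with a deterministic sign). The projected polygon
must be simple; otherwise a projection error is raised and the caller may
refine or pre-smooth — never silent repair. Interior Steiner points sit on
a triangular lattice at the target edge length (default: median boundary
edge length), triangulated by Delaunay and filtered to the polygon; the
result is verified to be a topological disc whose boundary equals the
input polygon exactly, with an ear-clipping fallback (boundary-only) for
polygons where filtered Delaunay fails. Whether the original interactive
tool seeded its cap in-plane or via 3-D hole filling is unknown; the
planar seed followed by smoothing is this package's reconstruction and
reproduces a "smooth, realistic initial ostium".

Smoothing is the simple uniform (umbrella) Laplacian,
`x ← x + λ(mean(neighbours) − x)` on interior vertices only, with
λ = 0.5, tol = 1e-4 mm, max 500 iterations by default; the boundary stays
bit-wise fixed. Note the fixed point is the *discrete-harmonic* state
(every interior vertex at its neighbour centroid), so even a planar seed
drifts tangentially within its plane before converging — planarity itself
is preserved, and a planar-boundary patch with off-plane interior
converges onto the boundary plane (discrete maximum principle); both are
tested. Dragging a vertex moves its interior neighbours by
`exp(−d²/2σ²)` of the displacement with σ = falloff_radius/2 — a Gaussian
reading of "reduced movement of its neighbours"; curvature-aware
(cotangent) smoothing is deliberately out of scope.

## Sac extraction and morphometry

The sac is the face component of a flood fill over face adjacency that
never crosses a neck-curve edge; a curve that fails to disconnect the
surface is an error. Without a dome seed, the component reaching farthest
from the ostium plane is taken (the dome sticks out; the vessel hugs the
plane) — a heuristic that can misfire on exotic geometry, so a seed is
preferred when known.

Table-style descriptors: D_max is the maximum pairwise distance among sac
vertices (convex-hull accelerated, brute-force verified). The neck curve
is resampled to 2k = 100 uniform arc-length points; N_max is the maximum
pairwise distance among them and N_avg the mean of the k opposite-point
chords ‖p_i − p_{i+k}‖. "Average neck diameter" has no published formula;
the opposite-chord mean is exact for circles and the equivalent-circle
diameter (perimeter/π) is emitted alongside (`N_eq`) for comparison.
H_max is the maximum unsigned distance of sac vertices from the ostium
plane, and AR = H_max/N_avg, the height-over-neck-width convention of
neck-aware morphometry; published per-case values are not rederivable
from printed tables, so AR is verified by closed forms (hemisphere:
AR = 0.5) and dimensional analysis, not against any specific case. A_a
counts wall triangles only, never the ostium cap.

## Variability statistics

D′ and D follow the definitions above, evaluated on the stored polyline
points verbatim — point-to-point, not point-to-segment, because the
statistic is defined over the points q_j. D is a symmetric premetric
(non-negative, zero diagonal, symmetric); the triangle inequality is
*not* claimed and not tested — it fails in general for this statistic.
Because D′ grows with point count, an optional uniform arc-length
resampling at 0.1 mm is offered, off by default for fidelity to the
submitted annotations. Percent differences of min/max vs median solutions
are rounded to one decimal, half-away-from-zero — the convention that
matches the checkable entries of published min/median/max tables. When
the median value is zero the relative difference is defined as 0 only if
min and max are also zero (nothing differs), and an error otherwise.

The bundled published five-case table (`aneusep.datasets`) pins this
arithmetic to real numbers. Recomputing the bracketed percentages from
the printed absolutes reproduces most entries at printed precision; a
handful (e.g. case 1 Q_in min, case 2 A_a, case 4 A_a) differ in the last
digit because the study evidently computed them from unrounded upstream
values. The same applies to the across-case aggregate for the min-area
solution: the printed absolutes give 11.2 ± 7.9 % (mean ± population SD)
against a published 11.4 ± 7.9 %; the max-area aggregate (10.6 ± 4.9 %)
reproduces exactly. The acceptance suite asserts exactly the reproducible
set and reports the computed values.

## Hemodynamic summaries

CFD solving (meshing, boundary conditions, solver settings) is upstream
and out of scope; the package post-processes supplied field series.
Per-element OSI = ½(1 − ‖∫τ dt‖/∫‖τ‖ dt) with trapezoidal time
quadrature over one cardiac period, defined as 0 where ∫‖τ‖dt = 0, and
clipped to [0, 0.5] against round-off. AWSS̄ is the area-weighted sac mean
of the per-element cycle-averaged magnitude; vertex-valued series are
averaged onto faces first. Mean OSI is area-weighted to match; the plain
unweighted mean is emitted alongside since either reading of a "mean OSI"
is defensible. Q_in integrates only inward flux max(0, v·n̂) per face
(midpoint rule) — an *inflow* rate is directional — with the signed net
flux exposed as a secondary output; the ostium patch must be oriented
toward the sac (`OstiumPatch.oriented`).

## Phantoms and simulated annotators

A phantom is the implicit union (min of signed distances; optional
smooth-min blend β) of a vessel capsule along the x-axis, a sac sphere of
radius r_a centred h mm above the axis, and optional extra tubes,
iso-surfaced by `skimage.measure.marching_cubes` at voxel size Δ with the
largest component kept. For β = 0 the true neck curve is the sphere ∩
cylinder intersection — a closed quartic space curve (planar only in the
limit of a flat vessel wall), returned as a dense polyline; a voxel size
that cannot resolve the neck (half-width < 3Δ) is rejected. In the
bifurcation preset the sac sits on the straight parent segment *near* the
apex rather than on it, and the generator verifies no secondary tube
approaches the analytic curve: this keeps the ground truth exact at the
cost of some geometric idealisation. Smooth blends (β > 0) displace the
true neck and are flagged as approximate ground truth.

Simulated annotators pick k = 8 arc-length-uniform points on the true
curve (one shared random phase, so zero noise means identical
submissions), perturb them in the local tangent plane with Gaussian
σ = 1 voxel — the scale of segmentation uncertainty — and snap/close them
into curves; a configurable fraction (default 10 %, i.e. one of ten
users) slides its picks 5 mm up the sac toward the dome, emulating the
clearly outlying submissions seen in multi-reader studies. Groups
alternate clinical/non-clinical. All randomness flows from one seeded
`numpy` generator; the seed is embedded in the case id of every output.

Synthetic fields emulate the qualitative CFD picture: WSS magnitude =
2 Pa baseline + 10 Pa Gaussian band (σ = 1 mm) at the neck, tangential
direction, pulsatile waveform 1 + 0.5 sin(2πt/T) over T = 1 s with 33
samples; dome faces get a zero-mean alternating tangential component
(purely oscillatory on request, which drives OSI to exactly 0.5). Ostium
velocity is a paraboloid profile scaled so the discrete net inflow equals
the prescribed Q₀ (default 1 mL/s) exactly under the same quadrature the
metrics use.

**What the phantoms do not show.** They are smooth, noise-free, exactly
manifold and topologically simple; real segmentations have bumpy walls,
touching vessels, variable triangle quality and no analytic neck. Passing
recovery tests demonstrates the correctness of the algorithms and the
internal consistency of the pipeline, not clinical accuracy on patient
geometry; the published-table statistics are the only contact with real
study data and exercise the reporting arithmetic, not the geometry chain.

## Problem sizes and tolerances in the test suite

The suites run phantoms at Δ = 0.3–0.4 mm (≈ 6–12 k triangles) for graph
and variability tests, one Δ = 0.15 mm pipeline-closure run, and a
Δ = 0.15 mm wide-vessel phantom (r_v = 12, r_a = 2, h = 13) for the
spherical-cap area check — the wide wall makes the cap formula 2πr·h
(h = r_a + h_offset − r_v) a faithful closed form, and the extracted sac
area matches it to well under the 3 % bound. The 100-seed median-recovery
study uses 10 users per seed at 1-voxel noise. Closed-form assertions use
the tolerance the discretisation supports: 1 % for resampled hemisphere
morphometry, 1e-3 for OSI limits at ≥ 129 time samples, 1e-9 mm for
A\*/Dijkstra cost equality and exact equality where arithmetic is exact
(area conservation ratios, Q_in on flat patches, boundary immutability).

## Known limitations

Edge-bound geodesics (no MMP/heat-method true geodesics) — mitigated, not
eliminated, by subdivision; planar-seeded caps can fail to project for
extremely folded necks (raised, not repaired); the no-seed sac rule is a
heuristic; the uniform Laplacian shrinks membranes (acceptable for a cap
pinned at its boundary); D grows with polyline density unless resampling
is enabled; phantom realism as discussed above.
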