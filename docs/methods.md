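# Methods

## The model

`puzzlecell` simulates the emergence of puzzle-shaped (pavement) cells in
a growing plant epidermis as the consequence of a single feedback rule:
cells restrict growth across any span that would otherwise open an
unsupported wall area larger than a target size, and they do so
anisotropically, sparing convex wall regions.  Wide spans of turgor-loaded
wall carry high stress — for a thin-walled cylinder the hoop stress is
`sigma = P * r / t` — so the radius of the largest empty circle (LEC)
inside a cell outline is a geometric proxy for the peak wall stress the
cell must carry.  The simulation shows that locally enforcing a bound on
that proxy, under imposed isotropic tissue growth, produces
interdigitating lobed cells; under anisotropic growth it produces plain
elongated cells.

### Tissue representation

A tissue is a shared-node polygonal complex: cells are closed
counter-clockwise loops of wall nodes; interior walls are shared by
exactly two cells.  Three element types give the wall network its
mechanics:

* **Wall stretching.**  Each wall segment is a linear spring with energy
  `1/2 * k_s * (l - l0)^2 / l0`.  The strain normalization (`1/l0`)
  makes the energy invariant to subdivision: splitting a wall into
  shorter segments does not change its stiffness.  An extension-based
  variant (no normalization) is switchable via
  `SimulationParams.strain_normalized` for sensitivity checks.
* **Bending.**  Every non-junction wall node carries a hinge with energy
  `1/2 * k_b * (theta - theta0)^2` on the interior angle between its two
  segments; `theta0 = pi` for nodes created by subdivision (straight at
  creation) and the initial polygon angle for original template
  vertices.  This penalizes sharp kinks, which are not seen in real
  walls, and sets the wavelength of wall buckling.  Junction nodes
  (shared by three cells) carry one hinge *per owning cell*, with the
  initial corner angle as rest angle: without them the two walls meeting
  at a junction can scissor through each other, which we observed as the
  dominant failure mode of junction-free corners.
* **Transversal springs.**  The growth restrictions: tension-only
  springs spanning a cell interior, standing in for microtubule-guided
  cellulose reinforcement that responds to stress.  A spring exerts
  force `k_m * (l - l_ref)` only when stretched beyond its reference
  length and nothing when shorter.  `l_ref = max(d, min_micro)` at
  placement (`d` the chord length), so a spring starts to pull only once
  the span it guards exceeds the target LEC span `min_micro`; growth
  never updates `l_ref`.

### Connection placement

At every `reset_period` steps all springs are discarded and rebuilt from
the current cell shapes: each wall node connects to the *closest* node of
the same cell whose chord (i) points within `theta_micro` of the inward
normals of both endpoints, (ii) is at least `s_min` positions away along
the contour, and (iii) lies entirely inside the cell polygon.  Nodes on
locally convex wall — smoothed turning angle above `kappa_convex`,
averaged over a window of +-`convex_window` nodes to suppress
discretization noise — neither initiate nor accept connections.  This
convexity inhibition is the lobe-forming ingredient: an incipient bulge
sheds its restrictions and keeps growing, while the matching indentation
in the neighbour accumulates them, a geometric stand-in for the
ROP2/ROP6 partitioning of the real cortex.  The *spk1* variant turns the
inhibition off.  Normals at a node are the normalized bisector of the two
incident segment normals (isolated in `geometry.node_normal`, so an
alternative definition can be swapped in).  Ties in the closest-partner
choice are broken deterministically by contour position; one physical
spring is kept per unordered node pair.

### The growth loop

One step = **connect** (periodically) -> **grow** -> **equilibrate**:

1. **Grow.**  Node positions map `(x, y) -> (g_x x, g_y y)`.  For
   gradient scenarios the factors are functions of the frozen material
   coordinate (template x), which keeps the displacement field continuous
   across the tissue.  *Stretched* wall segments then have their rest
   lengths raised to the post-growth actual lengths — the wall yields to
   growth — while compressed (buckled) segments keep their rest length
   and push back toward straight, so transient wrinkles are not ratcheted
   into the wall.  Transversal reference lengths are untouched, so growth
   progressively loads active springs.
   Walls longer than `max_segment` are subdivided (and again mid-step if
   relaxation stretches a segment past ~4/3 `max_segment`, so the
   discretization tracks the deformation).
2. **Equilibrate.**  Free nodes relax until the largest per-node force is
   below `solver_tol`; the tissue outline is pinned at its post-growth
   position, because tissue-scale growth is imposed and unopposed
   contracting springs would otherwise shrink the domain.  Metrics are
   computed per cell after equilibration; boundary cells are clamped and
   artefactual, so summary statistics use interior cells only.

### Numerics

* The default solver is L-BFGS-B on the free coordinates with an exact
  analytic gradient, polished by a displacement-capped FIRE relaxation
  when the per-node force residual is still above tolerance.  A plain
  monotone damped-descent solver (`solver="descent"`) is kept both as a
  reference (its accepted steps are strictly energy-decreasing) and as
  the documented fallback semantics.  Non-convergence within `max_iter`
  is reported with the residual via `ConvergenceWarning`, never silently
  accepted.
* **Self-contact.**  Nothing in the element energies prevents a wall from
  passing through another wall of the same cell, and in strongly
  restricted regimes (the *spk1* variant especially) opposing flanks of a
  narrowing neck do meet.  A short-range node-to-segment repulsion
  (`1/2 * k_c (r_c - d)^2` for `d < r_c`, with `d` the node-to-segment
  distance, `r_c = 0.8 * max_segment`, `k_c = 20 * k_s`, same cell,
  contour separation >= 2) gives the wall an effective thickness.
  Contact candidates are detected from the configuration at the start of
  each solve and the solve is repeated (up to 4 rounds) until the
  candidate list is stable; solver effort is additionally cut short once
  the residual stops improving, so frustrated contact clusters cannot
  consume the whole iteration budget (the residual is still reported).
* **Anti-tunnelling guard.**  A quasi-Newton line search can step across
  the thin contact barrier and settle in a self-intersecting minimum.
  After each equilibration the cell outlines are validity-checked; if a
  cell has newly gone non-simple the solve is redone from the pre-solve
  state with displacement-capped FIRE, which must climb the barrier and
  therefore cannot cross it.
* The hinge angle is measured in `(0, 2*pi)`; gradients of all element
  energies are analytic and verified against central finite differences
  (relative error < 1e-5 in the test suite).  The node-segment contact
  gradient treats the closest-point parameter as locally constant, which
  is exact by the envelope theorem.

### Parameters

| name | default | meaning |
| --- | --- | --- |
| `k_s` | 1.0 | wall stretching stiffness (per unit strain) |
| `k_b` | 0.2 | bending stiffness; sets buckling wavelength |
| `k_m` | 0.3 | transversal spring stiffness |
| `min_micro` | 20 µm | target LEC span (chord scale ~ LEC diameter) |
| `theta_micro` | 0.35 rad | half-angle of the normal cone for pairing |
| `kappa_convex` | 0.05 rad | smoothed-turning-angle convexity threshold |
| `convex_window` | 2 | smoothing window (+- nodes) |
| `s_min` | 5 | minimum contour separation (nodes) for a chord |
| `reset_period` | 1 | steps between connection reassignment |
| `g_x`, `g_y` | 1.04 | per-step growth factors |
| `max_segment` | 2 µm | wall subdivision length |
| `solver_tol` | 1e-3 | force residual at equilibrium |
| `n_steps` | 30 | growth steps (cumulative linear growth ~3.2x, area ~10x) |

These defaults are **calibrated**, not measured: they were chosen once so
that the five scenario presets reproduce the qualitative regimes the
model family is known for (lobed
cells under isotropic growth with regulated LEC; smooth elongated cells
under anisotropic growth; a left-right shape gradient under an isotropy
gradient; reduced lobeyness with comparable LEC in the *spk1* variant;
affine shapes with restrictions off).  Two calibration choices deserve
note: `min_micro` sits at the scale of the initial cell *diameter* (the
chord across a cell spans roughly the LEC diameter), which is what makes
anisotropically growing cells stay smooth — their fixed transverse span
never exceeds the target; and `k_m < k_s` keeps the restriction forces
from overwhelming the wall in tug-of-war regions where two cells pull a
shared wall in opposite directions.

### Scenario presets

* `isotropic` — defaults; puzzle cells emerge, interior mean lobeyness
  rises monotonically and the LEC distribution saturates near
  `min_micro / 2`.
* `anisotropic` — `g_y = 1`; elongated smooth cells (lobeyness stays
  ~1, aspect ratio grows with cumulative anisotropy).
* `gradient` — `g_y` interpolates linearly (in material x) from 1 at the
  left edge to `g_x` at the right; cell shape grades from elongated to
  lobed.
* `spk1` — convexity inhibition off, springs x2, wall stretching x4,
  bending x50, resets every 2 steps: worm-like interdigitation with mean
  lobeyness below wild type but a comparable final LEC.  The stiff-wall,
  slow-reset variant emulates the loss of ROP-mediated cytoskeletal
  rearrangement; the large bending factor is what keeps the mutant
  outlines smooth — with lobe tips no longer shedding their restrictions,
  every shared wall is pulled from both sides, and at wild-type bending
  stiffness that tug-of-war wrinkles the wall so much that lobeyness
  *exceeds* wild type.
* `no_restriction` — `k_m = 0` control: cells remain affine images of
  the template; the LEC simply scales with cumulative growth.

## Shape statistics

* **Lobeyness** = perimeter / convex-hull perimeter; 1 exactly for convex
  shapes, invariant to rigid motion and scale.
* **Circularity** = perimeter / sqrt(area); minimal (2 sqrt(pi)) for a
  disc but inflated by elongation — kept for comparison, not used as a
  lobation readout.
* **Hull solidity** = hull area / cell area; large for bent
  boomerang/worm shapes that lobeyness scores as nearly convex.
* **LEC** via Delaunay triangulation of the (resampled) contour: the
  largest circumcircle whose center lies inside the polygon.  Resampling
  to 1/100 of the bounding-box diagonal bounds the discretization error;
  candidates whose best empty point sits on the boundary are ignored, as
  appropriate for densely sampled outlines.  "Triangle within the cell"
  is implemented as *circumcenter inside the polygon*, which is the
  condition that actually guarantees an empty circle inside the region.
  The test suite checks the result against a brute-force oracle (max over
  an interior lattice of distance-to-contour) to 2% on 50 random
  polygons.
* **Growth anisotropy** = ratio of the singular values of the centered
  least-squares linear map between corresponded contour points at two
  time points; computed per cell.  Rotations cancel by construction.
* **Aspect ratio** = sqrt of the contour-point covariance eigenvalue
  ratio, on a uniform arc-length resampling (256 points).
* **Stress proxy** = `P r / t` with `r` the LEC radius — a closed-form
  thin-wall estimate, deliberately not a finite-element computation.
* 3D contours are projected on the PCA plane orthogonal to the direction
  of least variance before any 2D metric.
* The LEC-vs-area summary keeps the largest 20% of cells per time group
  (excluding, in real data, the small stomatal-lineage cells) and
  reports mean cell area against mean LEC area next to the
  `LEC area = cell area` line of a perfectly circular cell.

## The synthetic generator

`generate_tissue` emulates a meristematic epidermis: a jittered lattice
of seed points, Voronoi-tessellated with mirrored seeds so the
tessellation is clipped exactly to the rectangle with fully shared wall
topology, then Lloyd-relaxed (2 iterations by default — enough for a
near-isodiametric look without perfect hexagons) and resampled to the
wall discretization length.  It reproduces the convex, roughly
isodiametric polygonal geometry of young tissue, but none of real
tissue's cell-size heterogeneity, stomatal lineages, division, or 3D
curvature — so passing scenario tests demonstrates the model's internal
logic on idealized templates, not quantitative agreement with any real
epidermis.  `generate_lobed_disc` (disc with Gaussian radial bumps) and
`fixture_shapes` (square, 5x1 rectangle, plus-cross, boomerang, worm)
provide analytic test shapes; the plus-cross has closed-form lobeyness
`12 / (4 + 4 sqrt 2)` and hull solidity `1.4`.

## Problem sizes

Scenario runs in the test suite use 25-cell templates of 90 x 90 µm (32
cells at 150 x 75 µm for the gradient, to span six columns; a shared
20-cell 80 x 80 µm template for the wild-type/mutant comparison), 30
growth steps of 4%, ~600 nodes growing to a few thousand — enough for
the emergent regimes to separate cleanly while a full run stays in the
minutes range on one core.  Larger tissues and longer runs are a matter
of the same parameters scaled up.

## Known limitations

* No cell division, neighbor exchange, or 3D shell geometry; topology is
  fixed for a run.
* Boundary cells are clamped to the imposed growth and excluded from
  statistics.
* The *spk1* regime is mechanically frustrated (every wall is pulled
  from both sides); with the contact barrier and the anti-tunnelling
  guard its outlines stay simple, but equilibration can hit the
  iteration budget there, which is then reported as a
  `ConvergenceWarning` with the residual.
* The stress proxy is a scalar magnitude estimate; no stress
  *directions* are computed anywhere.
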