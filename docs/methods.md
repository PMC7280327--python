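# Methods

`myodecomp` turns a segmented muscle surface mesh into a set of polyline
fibres, animates the fibres across ball-and-socket joint poses, and computes
per-fibre moment arms by the tendon-excursion method. This note documents
the model, the numerical choices, and what the synthetic test fixtures do
and do not demonstrate.

## Mesh pre-processing

Segmented anatomical surfaces commonly carry three defect classes:
duplicated vertices, degenerate triangles, and non-manifold edges.
`clean_mesh` repairs exactly these — vertices closer than the weld tolerance
(default 1e-6 m, below scan resolution but well above double-precision
noise) are merged by union-find, zero-area and repeated-index faces are
dropped, and any face incident to an edge shared by more than two faces is
removed. The operation is idempotent. Smoothing is Taubin's shrink/inflate
pair (default λ = 0.5, μ = −0.53) with uniform (umbrella) weights and
boundary vertices pinned; it was chosen over plain Laplacian smoothing to
limit volume shrinkage. Any gentle feature-preserving smoother would serve;
nothing downstream depends on the choice.

Joint centres are estimated by an algebraic (linearised) least-squares
sphere fit to e.g. femoral-head vertices: solving
|p|² = 2c·p + (r² − |c|²) is linear in (c, r² − |c|²), deterministic, exact
on noiseless data, and translation-equivariant. An iterative geometric fit
would gain nothing at the accuracy scale that matters here.

## Scalar field and contours

Removing the two projected attachment regions leaves an open surface with
two boundary loops. A piece-wise linear scalar field is computed by discrete
harmonic interpolation: the cotangent-weighted Laplace equation with
Dirichlet values 0 on the origin loop and 1 on the insertion loop, solved
directly as a sparse SPD system. Negative cotangent weights (obtuse
triangles) are clamped to zero; this sacrifices a little accuracy on poor
meshes but guarantees the discrete maximum principle, so field values always
lie in [0, 1] and every isoline is a closed curve separating the two
attachments. On a straight cylinder the field reproduces the axial
coordinate to solver precision (≈ 4e-15 in the shipped fixture).

Isolines are extracted by marching triangles; vertices whose value equals
the level exactly are perturbed by 1e-12 so all crossings are interior to
edges. When a level yields several loops (branching cross-sections), the
largest-perimeter loop is kept — branching anatomies are out of scope.
Orientation is normalised counter-clockwise about the mean field gradient.
Each contour is resampled to 64 arc-length-uniform points; the first
contour's starting sample is anchored at the minimum angular coordinate
about the origin→insertion centroid axis, and each subsequent contour is
cyclically shifted to minimise total squared distance to its predecessor.
This index correspondence is what prevents twist along the stack (measured
< 5° between consecutive cylinder contours).

## Template mapping

Fibre architecture is described in a unit cube: each fibre is a Bezier
curve from the origin face (z = 0) to the insertion face (z = 1). The
shipped `parallel` template seeds vertical fibres on a ⌈√n⌉ × ⌈√n⌉ interior
grid at ((i+0.5)/m, (j+0.5)/m), truncated row-major — the seed layout inside
the cross-section is a package convention, chosen for even coverage. The
type admits curved control polygons, so pennate or fanned templates are an
extension hook rather than a redesign.

Slicing the template at a level gives one 2D point per fibre inside the
unit square. Each point's **mean-value coordinates** with respect to the
square outline (sampled at the same 64-point count as the contours) are
then applied to the corresponding mesh-contour samples. Mean-value
coordinates were selected as the generalized barycentric variant because
they are well defined on arbitrary simple polygons, smooth, and have linear
precision — affine images of the outline are reproduced exactly, which is
the property the transfer relies on. Partition of unity and affine
reproduction are verified to 1e-12/1e-9 over a thousand random star-shaped
polygons in the test suite.

### Point count convention

A fibre with `n_segments` straight segments has `n_segments + 1` points: 2
attachment endpoints plus `n_segments − 1` interior points from contours at
uniform levels k/n_segments, k = 1..n_segments−1. The attachment endpoints
are produced by the same barycentric machinery: template end-face seeds
mapped onto the attachment landmark outline (resampled to 64 points, with
cyclic shift and orientation chosen to best align with the adjacent interior
ring). Appending endpoints — rather than displacing the outermost contour
points — keeps the endpoint distribution consistent with the template and
the interior spacing uniform.

## Fibre smoothing

The final quadratic smoothing minimises, per fibre and coordinate,
Σ‖p−q‖² + λ Σ‖q_{k−1} − 2q_k + q_{k+1}‖² with both endpoints fixed
(default λ = 1). The normal equations form a small pentadiagonal SPD system
solved densely (fibres have ~16 points). λ = 0 is the identity, already
straight fibres are unchanged, and the solution matches an independent
dense least-squares formulation of the same programme to 1e-10.

## Kinematics

A ball-and-socket joint (3 rotational DoF) connects a fixed parent bone to
a child bone. Rotations compose body-fixed Z (flexion) → X (adduction) → Y
(internal rotation) about the joint centre; this mirrors common hip-model
convention, and the translation is chosen so the centre is a fixed point.
Angles are degrees at every interface and radians internally.

Each fibre point i is bound to its two nearest bones (rest-pose
point-to-surface distance, exact point-to-triangle projection) and posed as

    V'_i = Σ_j w_ij (R_j V_i + T_j),  w_i1 + w_i2 = 1,

with the origin-side weight following the quadratic profile
w_i1 = f(t) = a·t² − (a+1)·t + 1 at t = (i−1)/(n−1). The boundary
conditions f(0) = 1, f(1) = 0 hold exactly in floating point for the
shipped parameters, so fibre endpoints move rigidly with their attachment
bones at every pose. `a` controls how quickly a bone's influence fades;
defaults ship for the four hip muscles the method was developed on
(psoas −0.042, iliacus −0.024, gluteus maximus −0.042, gluteus medius 0.0).
There is no objective function for `a` — it was originally tuned visually
against bone penetration — so it remains a per-muscle configuration value.
The blended update is evaluated in the affine form V₁ + w₂(V₂ − V₁), which
is exact when both bone images coincide (identity pose) and keeps every
posed point on the segment between its two rigid images.

## Moment arms

For a single-coordinate sweep (defaults: flexion −10..60°, ad/abduction
−40..40°, internal/external rotation −30..30°, step 2°, other coordinates
held at zero) each fibre's polyline length is sampled per pose, fitted with
a least-squares 4th-order polynomial in radians, and the moment arm taken
as the analytic derivative of the fit (tendon excursion, r = ∂l/∂θ).

**Sign convention.** The raw derivative is positive for a muscle that
lengthens as the coordinate grows — i.e. one that opposes the motion. The
default `sign = −1` therefore reports moment-generating moment arms (a
flexor has a positive flexion moment arm); the switch is explicit in
`excursion_moment_arms`.

Fan summaries report per-pose envelopes plus global min/max/mean/sd in cm
over **all fibre × pose samples** (one defensible choice among several; the
averaging set is configurable in spirit by summarising any fibre subset).
The range-agreement metric counts the percentage of poses at which a
reference curve lies inside the fan's inclusive [min, max] envelope,
rounded half-up to an integer percent.

The straight-lines comparison model (`pathlines`) supports conditional via
points active on a closed angle interval. Its moment arms use the geometric
cross-product form r = â·((D−c)×û) on the joint-spanning segment, which
stays exact where condition toggles make the length non-smooth — the reason
this model does not use tendon excursion. Both routes agree to ~3e-7 m on
smooth paths (see below).

## Synthetic fixtures and what they show

The `synthetic` module generates everything the pipeline consumes, at
anatomy-like scales so tolerances transfer: watertight straight/bent/
fusiform tube muscles with landmark rings on their cap perimeters
(parallel-transported cross-section frames, so the surface itself carries
no twist), a two-box skeleton with a ball joint, and the planar hinge toy
whose length and moment arm have closed forms (l = √(a²+b²−2ab·cos φ),
|r| = ab·sin φ/l). All generators are deterministic under a fixed seed.

Validation scenarios and the problem sizes used:

- hinge toy a = b = 0.1 m, rest angle 90°, 36-pose flexion sweep: quartic
  excursion vs closed form, max relative error ≈ 0.02 %;
- excursion vs geometric on a smooth 2-point path over a ±15° sweep
  (16 poses): max difference ≈ 3e-7 m. The window is chosen where a quartic
  represents the sinusoidal length curve far below the comparison scale; on
  the full 70° sweep quartic truncation alone contributes ~5e-6 m;
- straight cylinder H = 0.2 m, r = 0.03 m (48 × 30 mesh, ≈ 3k faces), 100
  fibres × 15 segments: fibre lengths exact to ~1e-14 relative, harmonic
  field exact to ~4e-15, total runtime well under a second;
- 90°-bent tube: fibre lengths match the offset-curve closed form
  L + d·π/2 within 5 % stratified by radial position.

These fixtures exercise the full pipeline but are idealised: real muscle
surfaces are not surfaces of revolution, attachment outlines are not planar
rings, and real cross-sections are neither convex nor centred. Passing
these tests demonstrates correctness of the machinery (field, mapping,
kinematics, calculus), not anatomical fidelity of any particular muscle;
reproducing published hip moment-arm tables additionally requires the
original cadaveric meshes and attachment digitisations, which are external
data.

## Degenerate inputs and tie-breaks

- Levels colliding with vertex values: ε = 1e-12 perturbation.
- Several isoline loops at one level: largest perimeter wins.
- Outline alignment: cyclic shift (and orientation flip for attachment
  outlines) minimising summed squared distance; ties resolved by the first
  minimal shift, so runs are bit-reproducible.
- Removal that disconnects the surface (e.g. annular regions) is rejected
  rather than guessed at; multi-headed muscles with more than two
  attachment areas are out of scope.
- `contour_stack` accepts a single contour (needed for 2-segment fibres)
  even though typical use requests many.

## Known limitations

- Fibre points remain bound to their two bones throughout motion; at
  extreme poses this produces an "adhesion"-like pull toward the nearer
  bone and can admit bone penetration. Contact handling (e.g.
  position-based dynamics) is future work.
- No wrapping surfaces; the straight-lines model uses via points only.
- One ball-and-socket joint per skeleton; paths crossing several joints are
  unsupported.
- The harmonic-field approach assumes the muscle is topologically a tube
  between its two attachments.
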