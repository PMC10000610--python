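# Methods

## Problem and approach

Surface lumpiness of a poured powder heap (e.g. instant milk powder) is a
quality attribute that is normally graded by trained human panels. A poured
heap is close to a right circular cone, so lumpiness shows up as deviations
of its horizontal cross-sections from circularity. The package quantifies
that observable:

1. **Slicing.** The cone mesh is cut by horizontal planes at 40 equally
   spaced interior altitudes, `z_i = z_min + i (z_max − z_min)/41`. The base
   and apex planes are excluded because they give degenerate cuts. Each cut
   yields one segment per crossing triangle; segments are chained into closed
   loops through shared mesh edges and the largest-area loop is kept,
   oriented counterclockwise.
2. **Circle fit.** Each contour gets an algebraic (Kåsa) least-squares
   circle: the linear system for `x² + y² + Dx + Ey + F = 0` is solved in the
   least-squares sense. The fit is closed-form, deterministic, and exact on
   noiseless circular data; its radius is the reference `R`.
3. **Unwrapping.** Contour points are expressed as `(θ, r)` about the fitted
   centre, sorted by angle (duplicate angles averaged), and linearly
   interpolated with periodic wraparound onto `M = 512` uniform angles. The
   deviation profile is `e(θ) = R − r(θ)`, mean-centred.
4. **Spectrum.** The one-sided magnitude spectrum `|FFT(e)|` is taken at
   harmonics `k = 1..M/2`. Harmonic `k` corresponds to spatial wavelength
   `λ_k = P/k` along the perimeter `P = 2πR` (spatial frequency `β = 1/λ`).
   The transform is unnormalised and no one-sided doubling is applied at any
   bin, including DC (≈0 after centring) and Nyquist. Any fixed convention
   works here because Q enters the classifier only relatively.
5. **Roughness energy.** `Q = ∫|FFT(e)| dλ`, a trapezoidal integral over the
   non-uniform wavelength grid restricted to a band. The default band
   `[2P/M, P/2]` drops only the `k = 1` fundamental, which mostly reflects
   residual centre offset (an ellipse-like drift), not lumpiness.
6. **Grading.** Each sample's 40-layer Q vector feeds a second-order
   polynomial-kernel SVM (one-vs-one multiclass, features standardised to
   zero mean/unit variance on the training folds only), evaluated by
   stratified four-fold cross-validation pooled into a 4×4 confusion matrix.

## Synthetic samples

No reference meshes are available, so the study conditions are emulated by a
seeded generator. The lateral cone surface is built on a regular `(θ, z)`
grid (`n_theta = 192` vertices per ring, `n_z = 96` rings, base radius 50,
height 100 distance units) and perturbed radially by Gaussian bumps:

    r(θ, z) = R0 (1 − z/H) + Σ_m a_m exp(−Δθ_m²/(2σθ_m²) − (z − z_m)²/(2σz_m²))

Four grade presets control the bump population:

| grade | main lumps | amplitude (units) |
|-------|-----------|-------------------|
| 0     | 0–2       | 0.02–0.06         |
| 1     | 5–7       | 0.4–0.6           |
| 2     | 10–14     | 0.8–1.2           |
| 3     | 18–22     | 1.5–2.1           |

Main-lump altitudes are drawn as `H·Beta(1, 3)` fractions (lumps roll down
the heap, so they concentrate near the base), and the angular width is set
so a lump subtends an arc of about 10 distance units at its own altitude
(`σθ = 10/(4 r(z_c))`, i.e. ±2σ spans the arc). Grades 1–3 additionally
carry 40 small "texture" bumps (amplitude 0.03/0.06/0.12, arc ≈ 5 units)
spread uniformly over the full height: moisture roughens the whole surface,
while only the large lumps are gravity-sorted. Without this population the
upper layers of even a grade-3 cone would be geometrically perfect, which
neither matches the physical samples being emulated nor the per-layer
contrast the grading relies on. Grade-0 amplitudes are capped so that even
two coincident lumps stay below a 0.15-unit deviation.

A secondary generator, `make_uniform_density_cone`, builds a cone with ring
vertex counts proportional to circumference (two-pointer stitching between
rings of unequal counts). It emulates the uniform triangle density of
photogrammetric meshes, where contours near the base cross more triangles
than contours near the apex — a property the regular grid deliberately does
not have (its rings all carry `n_theta` vertices).

### What the generator does not emulate

Real reconstructed meshes carry photogrammetric noise, non-Gaussian lump
shapes, overhangs, holes, and an irregular triangulation of ~500k faces.
Passing tests therefore demonstrate that the measurement chain recovers
known ground truth planted in clean geometry and that the grades are
separable under the stated presets; they do not certify accuracy on scanned
powder heaps.

## Parameters that matter

- `n_layers = 40` — layer count; configurable, chosen so layers are a few
  lump heights apart on the default geometry.
- `M = 512` — angular resampling grid (power of two). One traversal of the
  contour at fixed M: sampling more densely would re-traverse the closed
  contour rather than add information.
- `lam_min, lam_max` — Q integration band, default `[2P/M, P/2]`. When the
  lump scale is known a priori the band should be abridged to that region
  (e.g. 2–20 units for ~10-unit lumps); see below.
- SVM: degree 2, `C = 10`, `coef0 = 1`, `gamma="scale"`, standardised
  features. With 24 samples of 40 standardised features, `C = 1` underfits
  visibly (grade-0/1 confusion); `C = 10` is the smallest decade that
  removes it, and results are insensitive to `C` in 10–1000.
- Cross-validation: stratified 4-fold with seeded shuffling — the only
  scheme that guarantees balanced 25% folds at n = 24 with 6 per class.

## Numerical choices

- Vertices exactly on a slicing plane: the plane is nudged upward by
  `1e−9·(z_max − z_min)`, which is geometrically negligible.
- Intersection points are computed once per unique mesh edge (sorted vertex
  index pair), so loop chaining matches endpoints exactly and is independent
  of face winding.
- Multiple loops at one altitude: largest absolute signed area wins.
- Multi-valued `r(θ)` (non-star-shaped contours): duplicate angles are
  averaged after sorting.
- STL input is welded by snapping vertices to a `1e−8`-unit grid, because
  STL stores three independent vertices per facet and chaining needs shared
  edges.
- Absent layers (no closed loop, or fewer than 16 contour points) are
  imputed with Q = 0 — the perfect-smoothness null — and flagged; feature
  extraction fails if more than half the layers are absent.
- Degenerate metric denominators (empty confusion row/column) yield NaN,
  never 0.

## Peak-wavelength locator

A single mean-centred Gaussian lump is a low-pass feature: its magnitude
spectrum decreases monotonically with harmonic number, so the in-band argmax
always sits at the long-wavelength band edge. The locator
`peak_wavelength` is therefore only meaningful after the wavelength axis is
abridged to the expected lump-size region, which is how the underlying
method is used in practice (the lump scale is known a priori). With the
band abridged to 2–20 units, single ~10-unit lumps peak at 18–20 units,
within a factor of two of the generating arc length.

## Terminology

The grading literature this package follows tabulates the
diagonal-over-column ratio of the confusion matrix under the name
"specificity". That quantity is the positive predictive value; the metrics
report it as `ppv_as_paper_specificity` and additionally report the
textbook specificity `TN/(TN+FP)`.

## Known limitations

- The slicer assumes an essentially star-shaped, single-boundary cross
  section; arbitrary topologies (handles, disconnected shells) are out of
  scope.
- The Kåsa fit biases the radius slightly low on strongly non-circular
  contours; since every layer is treated identically, the bias cancels in
  relative Q comparisons.
- Classifier results are for the synthetic presets; no claim is made about
  transfer to real scanned heaps without re-training.
- Problem sizes used throughout (192×96 grids, M = 512, 10-seed grading
  experiments) were chosen as the smallest that leave a comfortable margin
  between tessellation noise and the grade-0 signal.
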