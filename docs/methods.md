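# Methods

`microcrack3d` quantifies microdamage in grey-level micro-CT volumes of
trabecular bone: it enhances and segments micrometre-thin planar voids
(microcracks), separates them from osteocyte lacunae, and measures each
porosity and the whole specimen in 3D, together with simulated
histology-style 2D measurements. This note records the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Image model and conventions

Volumes are cubic-voxel scalar fields in `(z, y, x)` order, slice 0 at the
bottom; a voxel's physical centre is `(index + 0.5) * voxel_size_um`. The
nominal acquisition this is built for uses a 1.4 µm isotropic voxel, two
vertically adjacent scans merged with a ~280 µm overlap (the merge blends
the overlap with a linear ramp; a `take-lower` mode is available), bright
mineralised bone, dark marrow, and two nuisance signals: concentric ring
artifacts from non-uniform detector response and slowly varying intensity
bias.

## Pre-processing

**Ring removal** works per slice in polar coordinates about the rotation
axis (default: slice centre). Pixels are binned by integer radius; the
angular median per radius is a robust radial profile in which rings live at
high radial frequency and genuine anatomy at low frequency, so the
subtracted ring estimate is the median profile minus its radial Gaussian
low-pass (default smoothing 28 µm). Because the estimator is not an exact
projection (interpolation leaves a small radially coherent residue), the
estimate/subtract step is iterated three times, making the operation
idempotent in practice; the slice mean is preserved.

**Intensity normalisation** estimates a bias field by heavy Gaussian
smoothing (default window 200 µm; optionally restricted to bone-phase
voxels by normalised convolution) and subtracts its zero-mean part
(division mode available). Near the volume boundary the estimate is
one-sided and necessarily less accurate; tests therefore assess the
correction on interior regions.

## Segmentation chain

1. **Bone threshold** — global thresholding at the inter-class-variance
   (Otsu) optimum. The histogram must be bimodal: auto-thresholding
   refuses when the between-class variance explains < 75% of the total
   (a unimodal Gaussian reaches ~64% at its optimal split).
2. **Envelope** — morphological closing with a ball (default radius 14 µm,
   above the thickest expected crack) followed by filling of enclosed
   cavities. Closing is computed via two Euclidean distance transforms on
   a padded grid so the structuring ball is never clipped at the volume
   boundary.
3. **Planarity field** — the Hessian of the Gaussian-smoothed volume at
   scale σ (default 2.1 µm = 1.5 voxels; scale-normalised by σ²) is
   eigendecomposed per voxel with a closed-form symmetric-3×3 solver.
   With eigenvalues ordered |h1| ≥ |h2| ≥ |h3|, a dark sheet on bright
   bone has h1 large and positive across the sheet and |h2|, |h3| small,
   so the raw sheetness is
   `h1 · exp(−(h2² + h3²) / (2 (γ h1)²))` for h1 > 0 (γ = 0.5), zero
   otherwise; scores are normalised to [0, 1] by the volume maximum and
   evaluated only on envelope voxels. The local plane normal is h1's
   eigenvector.
4. **Planarity-guided filter** — a bilateral-type filter whose weight is
   the product of a spatial Gaussian (radius default 2.8 µm, σ = radius/2),
   a Gaussian in planarity-score difference (bandwidth 0.25) and a
   Gaussian in grey difference (bandwidth 0.3 × the robust grey spread).
   Voxels on the same sheet share planarity and grey level and are
   averaged together, raising crack contrast-to-noise without bleeding
   bone into the crack. Weights are normalised, so constants are
   preserved exactly, and with both range bandwidths → ∞ the filter
   degenerates to truncated Gaussian smoothing.
5. **Porosity response and hysteresis** — the filtered image is inverted
   into `R = (T − I) / (T − I_floor)` (T the bone threshold, I_floor the
   1st percentile of envelope grey); voxels whose raw grey is below T are
   additionally credited with their planarity score (`max(R, score)`),
   which recovers partial-volume crack voxels. Hysteresis keeps every
   voxel with `R ≥ low` 26-connected to a seed with `R ≥ high`. The
   defaults low = 0.25, high = 0.5 were calibrated on phantoms: they are
   the least permissive pair that still seeds one-voxel-thick cracks
   (whose blurred response never reaches ~0.6) while noise-induced false
   seeds in bone remain ≳4σ events at 10% noise.
6. **Rim filter** — morphological closing seals marrow fillets at concave
   trabecular junctions into the envelope; these surface-hugging dark
   components are ambient marrow, not intra-trabecular porosity. A
   component is dropped when at least 5% of its voxels lie in the
   envelope's outermost one-voxel layer: fillets lie along the boundary
   and far exceed that, while a genuine crack at worst grazes it with a
   clipped tip. Disable `exclude_rim_connected` to keep surface-breaking
   voids.
7. **Labelling** — deterministic scan-order 3D connected components;
   26-connectivity for porosities (thin tilted sheets fall apart under
   6-connectivity).

The exposed tuning profile is intentionally small: bone threshold (auto),
planarity scale, the hysteresis pair, and the guided-filter spatial radius.
Everything else is derived or fixed.

## Per-porosity morphometry

* **Volume** `Cr.V = N_C · voxel³` by counting.
* **Length/width** from the equal-moment ellipsoid: the centred
  second-moment matrix of the voxel set is eigendecomposed and the
  semi-axes of the uniform solid ellipsoid with the same moments are
  `a_i = sqrt(5 λ_i)`; `Cr.Le = 2 a1`, `Cr.W = 2 a2`. Voxels are treated
  as solid unit cubes, i.e. the per-voxel moment `voxel²/12 · I` is added;
  this removes the half-voxel surface bias that otherwise pushes thin
  digitised objects a few percent low (a single voxel is reported as zero
  extent by convention). Eigenvector signs are fixed by making the
  largest-magnitude component positive. Note that for a thin *slab* the
  equal-moment relation gives `a1 = (√5/2) × slab semi-length ≈ 1.118×`;
  lengths are comparable across objects measured the same way, which is
  how both truth and recovered cracks are compared in the tests.
* **Thickness** `Cr.Th` is the mean of the direct thickness map: at each
  voxel, the diameter of the largest inscribed sphere covering it. The
  inscribed radius at a candidate centre is `EDT − 0.5` voxels (so a
  3-voxel slab reads 3.0 and a 21-voxel ball 21). Propagation processes
  distinct radii in descending order, marking each radius group's coverage
  with one distance transform; a `coarse` mode quantises radii (0.5-voxel
  steps, widening to r/8 above 16 voxels) for whole-specimen envelopes,
  trading ≤ ~12% underestimate on very thick trabeculae for an order of
  magnitude fewer passes. Per-object maps are computed on padded
  bounding-box crops, which is exact.
* **Surface** `Cr.S = Cr.V / Cr.Th`: crack thickness is so close to the
  voxel size (and crack sheets so twisted) that a mesh-based area would be
  dominated by discretisation; volume over mean thickness is the stable
  estimator for sheet-like objects.
* **Classification**: microcrack iff `Cr.V > 500 µm³` and
  `Cr.Th / Cr.W < 1/3`; lacuna if only the volume cut passes; `other`
  below it (sub-resolution porosity and noise specks). Zero width is
  classified `other`.

## Specimen metrics

`BV` is the bone-phase volume (envelope minus segmented porosities), `TV`
the full analysed grid; densities `Cr.Dn`, `La.Dn` divide 3D object counts
by `BV` (a crack spanning many slices counts once). Crack statistics use
the population SD. **SMI** = `6·BV·S′/S²` is evaluated on a level set of
the half-voxel-corrected signed distance field: `S` is the marching-cubes
area of the zero level and `S′` the central difference of the areas at
±1 voxel. Structures that extend through the volume boundary are left open
there, so boundary faces do not count (plates and rods are idealised as
unbounded, giving the reference values 0/3/4 for plate/rod/sphere within
±0.5 on digitised test bodies).

**Local trabecular thickness** `Tb.Th.lo` is the mean envelope thickness
over envelope voxels within a ball of radius `max(Cr.W, 50 µm)` around the
crack centroid (the "site window"; the 50 µm floor keeps the window
meaningful for small cracks). **Trabecular shape** at the site is a
heuristic: a substantive curve-like skeleton (≥ 10 voxels, median
neighbour count ≤ 3) containing a branch voxel marks a junction; otherwise
moment semi-axis ratios decide (elongated ⇒ rod, else plate). Convex plate
windows whose skeleton collapses to a point are handled by the moment
branch. Reports flag the shape column as heuristic.

## 2D virtual sections

Thick sections emulate histology: section k is the mean of
`slices_averaged` consecutive slices starting at `z0 + k·spacing` (defaults
5 slices = 7 µm every 128 slices = 180 µm, eight sections). Bone and traces
are measured per section with the 2D analogue of the 3D chain (automated
counting; classically this was manual). A trace counts as a crack when it
is ≥ 20 µm long and its minor/major axis ratio is < 1/3 (the 2D analogue of
the thickness/width rule). `Cr.N 2D` sums traces over sections, so one 3D
crack crossing k sections counts k times and a crack between sections
counts zero — the two sampling biases the 3D analysis removes.
`Cr.Dn 2D` divides the trace count by the pooled 2D bone area; applying
this convention to reference 2D counts and bone fractions over eight
2.8 × 2.8 mm² sections reproduces reported 2D densities within 10%,
supporting the convention. `BV/TV 2D` is pooled bone pixels over section
pixels; on stationary phantoms it is an unbiased estimate of the 3D bone
fraction.

## Synthetic phantom

No public image data exists at this scale, so validation runs on phantoms
with voxel-level ground truth. The generator emulates what the analysis is
sensitive to:

* **Architecture** — a union of finite plate patches (discs ~42–58 µm
  thick, patch radius 0.30–0.40 of the grid extent) and rod segments
  (radius 28–48 µm), their boundaries perturbed by a smoothed random field
  (σ = 10 voxels, amplitude 1.5 voxels) for organic waviness. Primitives
  are added until the target BV/TV (default 0.20) is reached; only the
  last one is resized by bisection, so trabecular thicknesses stay
  realistic for crack hosting. Achieved fraction is within ±0.01 of
  target. Plates at desk scale are thinner than real femoral-head
  trabeculae (which reach 150–300 µm); a 256³ grid at 1.4 µm is only
  ~0.36 mm across, so everything is proportionally scaled down.
* **Cracks** — darkened elliptical slabs (default grey = marrow, i.e.
  void-filled), lengths 88–150 µm, widths ~0.4–0.7 of length, thicknesses
  1.4–5.6 µm, hosted in the mid-plane of a plate (or a plane containing a
  rod axis) with a small orientation jitter; types: linear, twisted
  (normal rotates along the major axis), parallel pairs, and cross-hatch
  pairs crossing at 35–55° (one connected object). In crowded volumes
  late placement attempts shrink the sampled footprint and finally fall
  back to a flat slab so the requested count is always realised. All truth
  objects keep a two-voxel clearance from each other, so they remain
  separable as connected components even after the blur and the guided
  filter widen their detected footprints.
* **Lacunae** — darkened ellipsoids (semi-axes 9–13 × 4.5–6 × 3.2–4.8 µm,
  random orientation) fully inside bone; the default 120 per 256³ grid
  gives a lacunar density of order 10⁴ mm⁻³ of bone, the physiological
  scale. Default sizes sit above the 500 µm³ volume cut and above the 1/3
  aspect cut, so the classifier must label them lacunae.
* **Degradation** — low-frequency mineralisation bands on bone (amplitude
  8 grey levels), a few one-voxel cement-line sheets (−12 grey), a 0.5
  voxel Gaussian blur as partial-volume surrogate, a concentric sinusoidal
  ring pattern (amplitude 4, six rings), and additive Gaussian noise
  (default σ = 7 ≈ 5% of the 140 bone–marrow contrast).

What phantom results do **not** show: performance on real tissue with
continuous mineralisation gradients, canaliculi, diffuse (sub-voxel)
damage, reconstruction artifacts beyond sinusoidal rings, or cracks
touching the trabecular surface (the generator keeps cracks interior, which
is also why the rim filter can be left on during validation).

## Validation summary (what the tests compute)

* Geometric operators are checked against independent brute-force oracles:
  explicit moment summation (1e-9 agreement), exhaustive
  maximal-inscribed-sphere search (≤ 1 voxel), BFS flood fill for
  hysteresis (exact), plus digitised ellipsoids/balls/slabs with analytic
  expectations.
* The full chain on a 256³ phantom with 20 cracks recovers ≥ 90% of the
  cracks at zero noise and ≥ 80% at 10% noise (50% voxel-overlap match),
  with median length error ≤ 10% and median thickness error ≤ 1 voxel.
  Problem sizes were chosen so a full desk run (generation, segmentation,
  quantification) completes in a few minutes per phantom.
* SMI reference bodies and the 2D over/under-counting mechanisms are
  asserted directly.

## Known limitations

* The trabecular-shape classifier is a simplified local-topology stand-in,
  not a full topological classification.
* `coarse` thickness maps bias thick-structure values down by up to ~12%.
* The 2D trace classifier's 20 µm length floor and 1/3 aspect rule are
  pragmatic analogues of manual counting, not a validated replica.
* Ring removal assumes rings are centred on the given (or default) axis;
  off-centre reconstructions need `center_xy`.
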