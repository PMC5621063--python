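# Methods

## The downscaling model

A coarse sensor observes an `m x n` field `X_l` that is, to good
approximation, a spatial aggregation of the fine field `X_h` (shape
`sm x sn`, scale factor `s`). Plain interpolation `I_s(X_l)` recovers the
smooth part of `X_h` but none of the high-frequency content; the quantity of
interest is therefore the residual field

    X_r = X_h - I_s(X_l),

which the method reconstructs patch by patch from examples. From coincident
coarse/fine acquisitions we collect M pairs of vectorized patches into a
*coupled dictionary*: `D_l` (`q x M`, `q = p^2`, coarse patches of edge `p`)
and `D_h` (`s^2 q x M`, the residual patch over the same ground footprint).
A query patch `y` from a new coarse image is approximated by a sparse
combination of `D_l` columns found with orthogonal matching pursuit (OMP),
and the *same* coefficients applied to the corresponding `D_h` columns
synthesize the unseen residual patch. This transfer rests on one assumption:
the coarse and fine fields are geometrically similar, so a combination that
explains the coarse patch also explains its fine-scale detail. Overlapping
synthesized patches are averaged, the assembled residual is added to the
interpolated base, and the sum is the downscaled product.

The dictionaries are raw training examples, not learned atoms (no K-SVD):
this keeps training trivially cheap and the mapping interpretable, at the
price of needing representative coincident imagery.

### Normalization convention

Stored `D_l` columns have unit Euclidean norm and the paired `D_h` column is
divided by the *same* coarse-patch norm (`atom_norms` undoes both). At
reconstruction time each query patch is scaled to unit norm before the
pursuit and the synthesized residual is scaled back by the query norm.
Consequences: coding is invariant to local brightness, and when a query
exactly equals a training coarse patch, the one-atom code reproduces the
training residual patch *exactly* — the self-trained ("scenario 1" with
non-overlapping stride) configuration recovers the fine benchmark to machine
precision. Zero-norm query patches skip coding and contribute a zero
residual.

## Orthogonal matching pursuit

At each iteration the atom with the largest `|<d_j, r>|` is appended to the
support (lowest index wins exact ties, for cross-platform determinism), all
coefficients are refit by ordinary least squares on the support, and the
residual is updated; by construction the residual is orthogonal to the
selected atoms and its norm never increases. Stopping: `|support| = k_max`,
or `||r|| <= tol * ||y||` (relative threshold by default; a flag switches to
absolute), or `||r||` reaches a machine-precision floor (`1e-12 * ||y||`) —
the floor prevents pointless, numerically rank-deficient refits after an
exact representation has been found. If the support submatrix's condition
number exceeds `1e12` the pursuit stops and returns the current code with a
logged warning rather than failing.

Defaults: `k_max = 8`, `tol = 1e-3` (relative). Small sparsity is standard
in example-based super-resolution and bounds per-patch cost.

### A caution on multi-atom codes with raw example dictionaries

Raw coarse patches are dominated by their local mean, so dictionary atoms
are often nearly collinear. An OLS refit over nearly collinear atoms can
produce large opposite-signed coefficients that cancel almost perfectly in
`D_l`-space — but the paired residual columns in `D_h` are mutually
incoherent, so the cancellation does not carry over and the synthesized
residual can blow up. On out-of-dictionary scenes we have observed
reconstructions far worse than interpolation with `k_max >= 2` while
`k_max = 1` (nearest-example regime) stays uniformly well-behaved. The
leave-one-out experiments below therefore use `k_max = 1`; users applying
larger `k_max` to dictionaries of raw patches should monitor the residual
statistics the downscaler logs. Mean-removal or coherence screening of atoms
would mitigate this but is not part of the reference pipeline.

## Scale-change operators

* `block_aggregate`: ideal-box (block-mean) aggregation; the valid-fraction
  rule masks output cells whose block has fewer valid cells than requested.
  The synthetic degrader also offers a Gaussian point-spread function
  (configurable sigma in output-pixel units, edge-clamped, weights
  normalized) since real sensor PSFs are not boxes; box remains the default
  because it is parameter-free and exactly invertible in the mean.
* `interpolate_upscale` (`I_s`): nearest / bilinear / bicubic, center-aligned
  so nearest is exact block replication and aggregating back at the same
  factor is the identity. Bicubic is the default base for reconstruction —
  the standard smooth baseline in super-resolution. Mask propagation is
  pessimistic: an output cell is masked if its kernel footprint (0/1/2 input
  cells for nearest/bilinear/bicubic) touches any masked input.
* Non-divisible dimensions under aggregation are cropped at the trailing
  edge with a warning; coordinate convention is 0-based row-major with LR
  cell `(i, j)` owning HR block `[s i, s i + s) x [s j, s j + s)`.

## Radiometric de-biasing

Two platforms report systematically different values for the same surface.
Before fine imagery can serve as training truth it is histogram-matched to
the coarse sensor: empirical quantiles of both images at 256 evenly spaced
probability levels (enough knots for 8–16-bit imagery, cheap to store) form
a piecewise-linear monotone map; values beyond the observed source range are
extrapolated linearly from the end segments (clamping would create
artificial histogram spikes). The map is estimated per band per scene on
co-gridded (aggregated) imagery and applied at the native fine scale; a
re-estimation at native scale is available. Rank order is preserved exactly.

## Evaluation

RMSE over jointly valid cells against a benchmark on the downscaled grid
(fine truth block-aggregated down when it is finer), and the improvement
ratio

    100 * (1 - RMSE_downscaled / RMSE_interpolation_baseline)  [percent],

i.e. the relative RMSE reduction versus plain interpolation: 0% = no gain,
100% = exact match, negative = the reconstruction hurt. Paired pixel samples
can be exported as CSV for scatter plots.

## The synthetic scene generator

The generator emulates irrigated farmland seen by a coarse satellite and a
fine camera: a smooth soil background, circular center-pivot fields, and
band-coupled high-frequency texture. Per band the latent field is

    background + pivot_delta * inside(disk) + a * (g_bg * B + g_tex * T)

with `B` a long-correlation background field and `T` the *shared*
fine-scale texture field (Gaussian-filtered white noise, renormalized;
correlation length `texture_correlation` cells). Sharing `T` across bands
with band-specific gains realizes the geometric-similarity assumption the
method relies on. Band constants are grounded in typical soil/vegetation
reflectance spectra — soil (red 0.20, green 0.18, blue 0.12, NIR 0.30) and
canopy deltas (red −0.15, green −0.08, blue −0.07, NIR +0.20) reflecting
chlorophyll absorption in blue and red and high NIR scattering; the thermal
band runs in kelvin (soil ≈ 312 K, canopy 12 K cooler) to exercise
non-reflectance ranges. NDVI inside pivots exceeds the exterior by
construction.

Defaults, chosen once as desk-scale study conditions: `hr_shape` 128 x 128,
`s` 2, 3 pivots, `texture_amplitude` 0.03 reflectance units (thermal scales
it by 60 into ≈ 1.8 K), `texture_correlation` 3 fine cells (texture partly
survives 2 x aggregation, so some of it is genuinely recoverable),
`noise_sd` 0.002, bias (1.0, 0.0). The fine-sensor bias used to exercise
de-biasing is gain 1.1 / offset 0.02. All outputs are pure functions of the
spec including its seed; reflectance is clipped to [0, 1] with the clipped
fraction logged.

What the generator does *not* emulate: atmospheric effects, georegistration
error, anisotropic or crop-row texture, sensor PSF mismatch between
platforms, or gap-filled missing scanlines. Passing tests on these scenes
show the pipeline's mechanics and its behavior under the model's own
assumptions — not performance on real satellite/aircraft imagery.

## Experiment designs and problem sizes

Two training designs are exposed: scenario 1 (every coincident pair,
including the test pair, populates the dictionary) and scenario 2
(leave-one-out). The packaged experiments use triples of 128 x 128 scenes at
`s = 2`, patch edge 3, training stride 2, reconstruction stride 1
(overlap-averaging suppresses blocking artifacts and materially stabilizes
out-of-dictionary reconstruction), `k_max = 1` (see the caution above), over
a 20-seed ensemble — sizes chosen to make the full suite a desk-scale run.
Observed on these conditions: leave-one-out median improvement is positive
for every reflectance band and the in-dictionary median is consistently
higher, mirroring the expected mild degradation when the test image is not
among the training examples.

## Known limitations

* Raw-example dictionaries scale linearly in memory and pursuit cost with
  training area; no atom pruning or clustering is provided.
* Multi-atom pursuit instability on incoherent coupled columns (above).
* Thermal imagery is treated like any other band apart from its value range.
* Inputs are assumed co-registered; no reprojection or alignment is done.
* Surface-soil-moisture and other indirect products are a pluggable hook
  only; no retrieval model ships with the package.
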