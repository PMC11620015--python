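# Methods

This note documents the models, defaults, and numerical choices behind
`ccfdgrid`, and what the synthetic-data suite does and does not establish.

## Scan model and conventions

All en-face rasters are (row, col), 0-based, pixel centers at integer
coordinates, with one isotropic lateral spacing (`pixel_spacing_um`,
default 12 µm for a 500×500-px, nominal 6×6-mm scan). Anisotropic sidecars
are rejected at read time. µm↔px conversions always go through the pixel
spacing; axial-length-dependent lateral scale differences between eyes are
*not* corrected (nominal geometry only).

Quality control excludes scans with signal strength < 7 or operator flags
for significant motion or insufficient illumination. "Insufficient
illumination" has no automated criterion here; it is an operator flag only.

## Slab extraction

A slab is a depth interval below the BM surface, positive downward. A voxel
at depth index `d` in column (r, c) is in the slab iff
`offset ≤ (d − bm[r,c]) · Δz < offset + thickness`. The CC slab is
offset 4 µm, thickness 16 µm (at Δz = 2 µm: 8 voxels, indices bm+2…bm+9);
the sub-RPE slab is 64–400 µm below BM. Projection is the per-column mean
by default (max available); the mean is the natural estimate for a thin
perfusion slab and is exactly checkable against a voxel loop.

## Attenuation compensation

Overlying material (drusen, hyperreflective RPE) attenuates the OCT beam,
reducing flow and structure signal in the same columns. To first order this
is a shared multiplicative factor A(x): `flow_obs = A·flow`,
`struct_obs = A·struct`. The default **divide** mode computes

    comp = flow_obs / max(G_σ(struct_obs), floor)

with Gaussian smoothing σ = 2 px and a floor at the 5th percentile of the
smoothed structure over unmasked pixels, then rescales so the unmasked
median matches the input flow. Under the shared-multiplicative model with
spatially constant true structure this removes A exactly (up to the smoothing
scale), which is what makes the mode testable. A **complement** mode
(multiply by `max − G_σ(struct)`, same rescale) is provided as the
lower-variance alternative that darkens rather than divides; it compensates
direction-correctly but not exactly.

The floor exists to keep noise-level structure from exploding the quotient.
Its percentile semantics interact with lesion load: the divisor is floored
at the 5th percentile of smoothed structure, so attenuated regions are only
fully compensated when they extend below that percentile — i.e. when
attenuated area exceeds roughly the floor quantile of the scan, as in a
drusen-laden macula. For scans with a single small druse, lower
`floor_quantile` accordingly.

## Thresholding

Global 2-cluster fuzzy C-means (fuzzifier m = 2) on the unmasked intensity
distribution: centers initialized at the 10th/90th percentiles, iterated on
a 256-bin histogram of unmasked pixels until the center shift < 1e-6 (max
300 iterations), threshold = midpoint of the converged centers. The
histogram makes cost independent of image size; on smooth bimodal mixtures
the binned threshold agrees with an unbinned FCM to well under 2 intensity
units. The procedure is deterministic and translation-equivariant. Pixels
are deficits iff unmasked and strictly below the threshold.

## Size filter

Deficits are 8-connected components. The greatest linear dimension is
defined as (max pairwise pixel-center distance)·spacing + spacing, so a
single pixel has GLD = spacing — one 12-µm pixel (GLD 12) is removed at the
24-µm cutoff, two adjacent pixels (GLD 24) are kept (strict `<` removal).
Component diameters are taken on the convex hull for components > 300 px;
this is exact (the diameter of a finite point set is attained at hull
vertices) with a brute-force fallback for degenerate hulls.

## Registration, integrated mask, ROIs

Repeat/visit scans are registered on retinal-vasculature en-face images to
the first scan: integer-pixel translation by masked normalized
cross-correlation over all lags (each lag scored on its actual overlap,
minimum 25% overlap, search radius 100 px), optional exhaustive rotation
search ±5° in 0.25° steps (off by default — same-day repeats rarely
rotate, and pure translations keep binary maps exact under resampling).
Registration below a normalized-correlation floor of 0.2 is an error, not
a silent fallback. Binary rasters are moved with nearest-neighbor,
intensities bilinearly; integer translations are applied by exact slicing.

The integrated mask is the union of every scan's registered combined mask
and every off-overlap region, applied identically to all scans so only
pixels measured in *every* scan enter any comparison.

The grid anchors a 74×74-px target box at `round(center) − 37` (the center
pixel sits in the upper-left quadrant of the box, since an even box has no
center pixel) and tiles the lattice of box-size multiples. A box is kept
iff complete — fully inside bounds and the overlap validity region; partial
lesion masking inside a kept box is handled by the valid-pixel denominator,
not by dropping the box. On a fully valid 500×500 region a fovea-centered
grid has 25 boxes (pooled area 25·0.888² = 19.71 mm²) and the best anchor
offset yields 36. Circle ROIs include a pixel iff its center is within
diameter/2 of the ROI center; a 5-mm circle at 12 µm covers 19.63 mm².
Circles exceeding the scan are clipped with a warning (a 5-mm circle
centered near an edge lesion legitimately spills over). Grid-total CCFD% is
the pooled-pixel ratio, not the mean of box percentages, so unequally
masked boxes are weighted by their valid area. A fully masked ROI yields a
null measurement, never a silent 0%.

## Repeatability statistics

The measurement model is a nested random-intercept LMM: patient ⊃ eye ⊃
box (as applicable) random intercepts, residual = repeat-to-repeat scan
variance. Balanced tables are fitted in closed form by expected mean
squares (nested ANOVA; negative estimates clamped to 0 with a warning);
unbalanced tables by REML, profiling the likelihood over variance ratios
γ_l = σ²_l/σ²_e and minimizing with Nelder–Mead on √γ (tolerance 1e-8,
components clamped at 0). The two agree to ≤1e-6 relative on balanced data.

* ICC = (σ²_total − σ²_residual)/σ²_total, clipped to [0, 1].
* ICC CI: parametric bootstrap — simulate tables from the fitted normal
  components under the same balanced design, refit, percentile interval.
  Default 1,000 resamples (raise via config/CLI for fidelity runs; the
  refit is vectorized so 10⁵ is cheap); deterministic given the seed.
* MDC95 = √2 · 1.96 · σ_residual exactly.
* Group contrasts: fixed group effect (cell-means coding) in the same LMM;
  all pairwise differences; Tukey adjustment via the studentized-range
  distribution with k = number of groups and df = eyes − groups
  (containment df — exact for balanced one-level designs, where the
  contrast variance is carried entirely by the between-eye stratum); a
  Satterthwaite option combines strata instead. CIs at the Tukey-adjusted
  level.
* Change calls: per-box Δ = follow-up − baseline is significant iff
  |Δ| **strictly** exceeds the MDC95 reference ("exceeded", not "reached").

Null CCFD% rows are dropped with a logged count before fitting; box
observations are unweighted by default (valid-pixel weighting is a config
option left off, matching the unweighted pooled-area reading of the grid).

## Synthetic eyes

The generator produces the study conditions end to end:

* **Deficit field**: white noise smoothed at the CC intercapillary scale
  (36 µm) and thresholded at the target quantile (default 8% deficit
  fraction), giving component sizes straddling the 24-µm filter.
* **Drusen**: smooth-edged discs of multiplicative attenuation (default
  factor 0.5) applied to flow *and* structure — the shared-multiplicative
  regime in which divide-mode compensation is exact. The default load is
  three large drusen (~6% of scan area), an iAMD-like macula; this also
  keeps the attenuated intensities below the compensation floor quantile
  (see above).
* **Vessels**: a recursive branching tree with Gaussian profiles — it
  exists to give registration realistic landmarks, not as a vascular model.
* **Lesion masks**: small HRF-like discs.
* **Repeats**: same truth, independent noise (default SD 4 on a flow base
  of 120), integer misalignment uniform in ±8 px.
* **Drusen resolution**: follow-up regenerates the scan with the target
  druse's attenuation removed and the deficit field untouched.

Everything is reproducible from (config, seed). Problem sizes used by the
test suite — 500×500 scans, 30 eyes × 3 repeats, 200–500 statistical
replicates, 1,000 bootstrap resamples — were chosen as the smallest designs
at which the recovery properties are sharp.

**What passing tests show, and don't.** The synthetic suite validates the
pipeline's arithmetic and the statistics' calibration under the stated
generative model. It does not model OCT speckle, flow-signal texture inside
deficits, partial-thickness shadows that attenuate flow and structure
differently, B-scan motion artifacts, or axial-length scale variation — so
agreement here does not certify accuracy on instrument data, only that the
implementation does what the definitions say.

## Known limitations

* Rigid (translation ± small rotation) registration only; no affine or
  deformable model.
* The compensation floor couples to lesion load (documented above).
* REML uses dense covariance algebra — fine for repeatability designs
  (≤ a few thousand rows), not for very large tables; balanced tables
  avoid it entirely.
* Only nested random intercepts + one fixed factor are supported; this is
  a repeatability toolkit, not a general mixed-model package.
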