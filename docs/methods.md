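# Methods

## Scope and data model

`orthopheno` covers the desk side of a UAS phenotyping campaign over a
replicated field trial: field-map construction, raster I/O with camera
pose, preflight calibration, plot-level trait extraction and mixed-model
analysis. Photogrammetry itself (structure-from-motion, orthorectification)
is out of scope; the package consumes already-orthorectified GeoTIFFs, and
its simulator produces them directly.

Rasters are north-up, axis-aligned GeoTIFFs with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA); band
roles, image id, CRS tag and camera pose travel in a JSON ImageDescription
tag, with a `.pose.json` sidecar honoured as an override. Pixel indices
are 0-based with half-open windows; world coordinates are evaluated at
pixel centres. Geographic coordinates are converted internally to a local
equirectangular metric frame (east = Δlon·cos(lat̄)·R, north = Δlat·R,
R = 6 371 008.8 m); at sub-kilometre field scale the error is below a
centimetre. ESRI Shapefile layers are not read or written — field maps are
GeoJSON, with property-name aliases accepted for shapefile-born spellings.

## Field maps

The four surveyed field corners (order NW, NE, SE, SW; must be convex) are
bilinearly interpolated into an n_rows × n_cols grid. Each grid cell spans
the full planting pitch; the plot polygon is the cell shrunk about its
centre to the sown plot length × width (lengths measured on the ground, so
geographic corners work too). Row index grows NW→SW, column index NW→NE;
rings are counter-clockwise. Alley widths are therefore implied by
pitch − plot size and must come from the user's configuration; nothing in
the imagery constrains them.

## Plot containment and cropping

A plot is extracted from a raster only when it is *completely included*:
every polygon vertex inside the raster extent and no nodata pixel whose
centre falls inside the polygon. This strict rule avoids the non-effective
fringe pixels that orthorectification leaves at image borders; a
`max_nodata_frac` parameter relaxes it when partial plots are acceptable.
Pixel-in-polygon tests use pixel centres, the standard convention for
zonal statistics; cropping is idempotent and monotone in the nodata mask.

## Trait definitions

* **Canopy temperature.** Thermal digital numbers are centikelvin:
  T = K·DN + T₀ with defaults K = 0.04 °C/DN and T₀ = −273.15 °C, so
  DN = 0 is absolute zero. (Some published statements of this conversion
  print the offset with the opposite sign, which would put DN = 0 at
  +273.15 °C; the physical convention is implemented.) The plot value is
  the mode of non-zero DN inside the polygon, converted to °C.
* **NDVI** = (NIR − Red)/(NIR + Red), with 0/0 mapped to nodata. The plot
  value is the histogram mode over fixed bins aligned at multiples of the
  bin width (default 0.01), reported at the bin midpoint; ties break to
  the lower bin for determinism.
* **Ground cover.** RGB → HSV; a pixel is canopy iff hue ∈ [60°, 180°],
  saturation ≥ 0.15 and value ≥ 0.10 (all configurable — the intended
  workflow tunes them once on a reference date and freezes them). The plot
  value is canopy pixels / valid pixels in the polygon.

Exact zero is treated as the background/nodata sentinel in the mode
summaries, so a true NDVI of exactly 0 is excluded — a documented
limitation of the non-zero rule. The mode (rather than the mean) makes the
plot value robust to residual soil pixels.

* **Camera azimuth.** For each orthorectified observation, θ is the angle
  of the vector from the plot centre to the camera ground position,
  measured counter-clockwise from true east, in [0°, 360°). Altitude is
  ignored (it is unreliable in flight logs). θ enters Model IV as a single
  linear covariate in degrees; no periodic basis is used, so the model
  captures a monotone trend in view direction, not a full BRDF.

## Preflight

Capture sets are grouped from filenames (`<capture>_<band 1..5>`, bands
blue/green/red/nir/rededge); captures with fewer than five bands are
dropped. Ground and air captures are split at the midpoint of the altitude
range (min + range/2) unless an explicit threshold is given. The
calibration panel and GCP markers share one detector: global Otsu
threshold, connected components, then filters for size fraction, bbox
aspect ∈ [0.8, 1.25] and coefficient of variation < 5%, tie-broken by
area then centroid. Panel means are taken over the region eroded by 20%
of its linear size to avoid edge mixing. Radiometric calibration is the
linear factor F_b = ρ_b/M_b per band — no vignetting or exposure terms,
which is exact for the simulator's linear DN and an approximation for real
sensors. GCP matching is pose-based: the surveyed marker nearest the
camera position wins if it is within the matching radius (default 20 m,
matching the minimum marker spacing); two markers within the radius make
the image ambiguous and it is skipped. Thermal imagery is refused for
automatic GCP detection (markers are not reliably resolvable at thermal
resolution; they are picked manually downstream).

## The REML engine

All five models are Gaussian mixed models
y = Xβ + Σ_u Z_u u_u + e with u_u ~ N(0, σ²_u I) and e ~ N(0, σ²_e I).
Estimation maximises the restricted likelihood via the mixed-model
equations: for each parameter vector the coefficient matrix
C = W′W/σ²_e + diag(0_p, I/σ²_u) (W = [X | Z₁ … Z_U]) is Cholesky-factored
once, giving the restricted log-likelihood

−2·l_R = n·ln σ²_e + Σ_u q_u·ln σ²_u + ln|C| + y′Py + (n−p)·ln 2π,

exact first derivatives (from the block traces of C⁻¹ and the BLUPs) and
the average-information matrix (from solves against the working vectors).
Updates are AI steps with step-halving; when an AI step cannot improve the
restricted likelihood the engine falls back to a damped EM step, and when
neither direction improves it the constrained optimum has been reached.
The trace of accepted log-likelihoods is therefore non-decreasing.
Numerical choices:

* start values: every component at var(y)/(U+1) — no randomness anywhere,
  so fits are bitwise reproducible;
* convergence: |Δl_R| < 1e-8 and max relative parameter change < 1e-6,
  cap 200 iterations (`ConvergenceError` carries the trace);
* lower bound: components are clamped at 1e-10·var(y); a component pinned
  there re-enters if its score turns positive;
* boundary reporting: at convergence, components below 0.1% of the
  phenotypic variance are flagged as boundary (the restricted likelihood
  is flat near zero, so strictly-at-bound classification misses
  effectively-null components); flagged terms are excluded from the BIC
  parameter count;
* degenerate data: factorisations retry with growing jitter; a response
  with an exactly perfect fit (zero residual variance) has an unbounded
  restricted likelihood and correctly raises.

The MME-based likelihood was verified against a direct dense-V evaluation,
and full fits against R's lme4 (components and restricted log-likelihood
agree to ~7 digits) and against closed-form balanced ANOVA. Fitting is
dense linear algebra in the MME dimension (p + Σq_u); the desk-scale
problems here (hundreds of levels) fit in milliseconds, and the design
scales to tens of thousands of observations with a few thousand levels.

Heritability uses r = number of blocks (the "plots per entry" of a
design with one plot per entry per block; per-entry replicate counts of
check varieties are deliberately ignored) and n = harmonic-mean
observations per plot. BIC uses residual degrees of freedom
ν = n_obs − rank(X) and counts only freely estimated variance parameters;
because additive likelihood constants differ across software, BIC values
are comparable within this package only, and only across models II/III/IV
(which share a response). Model Ib's plot mean is unweighted; weighting by
pixel count is available but not default.

## The simulator

`synthfield` emulates the structure of a deposited campaign: plot truth
follows value = μ + entry + block + row(block) + col(block) + plot with
independent normal effects; a serpentine flight renders one image per
camera trigger as a footprint-sized window of the field plus an image
offset I_n ~ N(0, σ²_I), cumulative drift·n, optional per-plot azimuth
shift β·θ and iid pixel noise; flight lines extend one pass beyond every
field edge (as real missions overfly the margins), which with 80% overlap
guarantees each plot is fully contained in at least three images. Mosaics
are blended as the per-pixel mean of valid overlapping images, or
first-wins. Thermal rendering quantises to uint16 centikelvin DN with 0
reserved as nodata; multispectral rendering encodes the plot value as NDVI
against a fixed red reflectance; RGB rendering paints an exact fraction of
each plot's pixels canopy-green for ground cover. One root seed fans out
into named child streams (effects, poses, noise) so any stage regenerates
identically.

Default parameters describe midday canopy temperature in a wheat nursery,
in °C²: σ²_entry = 0.5 (entry sd ≈ 0.7 °C), σ²_block = 0.2,
σ²_row = σ²_col = 0.1, σ²_plot = 0.5, σ²_image = 2.0 (flat-field steps
plus short-term ambient variation, sd ≈ 1.4 °C — image artifacts
genuinely dominate genetic signal for thermal sensing), pixel noise
sd 0.2 °C, drift 0.015 °C per capture (≈ 2–3 °C over a desk-scale
flight). The simulator does not attempt photorealism: no perspective
distortion, BRDF, lens model or canopy texture. Consequently, passing
tests demonstrate the pipeline's statistical behaviour under the stated
additive error structure, not robustness to real optical effects.

## Replication studies

Two canned studies (`orthopheno.experiments`) define the protocols used by
the test suite and the acceptance script.

**Recovery.** 200 entries × 2 blocks × 4–8 subsamples per plot, truth
(σ²_G, σ²_B, σ²_plot, σ²_ε) = (1, 0.2, 0.5, 1), 20 replicates: mean
estimates recover entry/plot/residual components within a few percent and
mean Ĥ² tracks the design-implied truth within ~0.01. The block component
is estimated from two levels (one degree of freedom): its single-replicate
sd is ≈ 0.235 at truth 0.2, so even the 20-replicate mean has a standard
error of ≈ 0.05 — any apparent bias smaller than that is sampling noise,
and checks on this component are intrinsically weak at this design size.

**Mosaic vs orthorectified.** 64 entries × 2 blocks, thermal flights with
σ²_I = 2.0 ≥ σ²_G = 0.5 and a per-flight drift total of 6 °C (the emulated
campaign is a multi-hour midday measurement window; the total is divided
by the capture count so the condition does not depend on desk-scale flight
geometry), row/column variance set to zero, 50 replicates. Row/column
effects are excluded by design: Model Ia models them explicitly while
Model III absorbs them into its plot term, so leaving them on confounds
the image-artifact mechanism the study isolates. Outcome at the default
seed: mean Ĥ² = 0.652 from Model III on orthorectified extraction versus
0.634 from Model Ia on the mean-blend mosaic.

The margin deserves honesty. Mean blending averages every covering image
(~10–25 at 80% overlap), shrinking iid image offsets in the mosaic by that
factor; and serpentine drift maps to a nearly row-separable spatial field
that Model Ia's row effects largely absorb. Under mean blending the
orthorectified advantage is therefore systematic but small (≈ +0.02 mean
H² here, growing with drift and offset magnitude); the large losses seen
in practice are driven by selection-style ("mosaic mode") blending, which
keeps single-image offsets patchwise intact — emulated here by the
first-wins blend. At σ²_I ≈ σ²_G the two pipelines are statistically
indistinguishable in this simulator.

## Known limitations

* Radiometric model omits vignetting/exposure compensation.
* The non-zero sentinel excludes true zero values of CT DN and NDVI.
* Azimuth is a linear covariate, not periodic; a full view-angle model
  would need a BRDF basis.
* No spatial correlation structures (e.g. AR1×AR1) or genomic
  relationship matrices — all random factors are iid.
* Shapefile I/O, CRS reprojection beyond the local metric frame, and the
  photogrammetric steps themselves are out of scope.
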