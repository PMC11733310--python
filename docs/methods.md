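# Methods

This note documents the models implemented in `batscape`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Activity surfaces

A radar "scene" is one scan's binary bat presence/absence on a regular
grid of 70 m pixels (0.49 ha each). Presence is density-based — a group
of bats large enough to register — not a count of individuals. Seasonal
aggregation sums scenes per pixel: a pixel detected in five scans of one
evening contributes five occurrences. Counts are stored as integers;
the standardized rate

    rate = count / (pixel_area_ha × n_nights)

is double precision, in occurrences·ha⁻¹·night⁻¹. Normalization is per
*night*, not per scan; the scenes-per-night average (~126 at full
season) is kept as bookkeeping only. Masked pixels (urban clutter,
terrain blockage — a user-supplied mask) propagate as missing, never as
zero: zeros would bias every area-weighted statistic downstream. An
all-masked raster is an error, not an empty mean.

## Roost commute correction

Counts near roosts are inflated by departing/returning bats. The
correction multiplies each pixel by

    f(d) = 1 / (1 + A · exp(−d / λ)),

with `d` the Euclidean distance from the pixel center to the nearest
roost. `f` is 1/(1+A) at a roost, strictly increasing, and →1 with
distance, so far-field values are untouched and no pixel is ever
amplified. Defaults: `A = 1` (halve the value at a roost), `λ = 5000 m`
(the order of a nightly commute radius). Both are configuration, fixed
a priori — the package deliberately does not estimate them from the
data being corrected, since the commute artifact and genuine roost-area
foraging are confounded in a single season. A sensitivity variant pools
the plume over all roosts, `1/(1 + A·Σⱼ exp(−dⱼ/λ))`; it attenuates
strictly more wherever several roosts are within a few λ. The
functional form is isolated in one function (`correction_factor`) so an
alternative correction can be swapped in without touching the pipeline.

## Land-cover statistics

Raw labels from a natural-vegetation layer and a crop-parcel layer are
regrouped through an editable TSV table into 13 classes nested in 4
types (agricultural, natural, urban/other, water). Where the layers
overlap, crop labels win: the crop layer is field-validated for the
study year. Natural-layer "agriculture" left uncovered becomes
"miscellaneous" — field margins and fallowed ground. Any unmapped label
is a hard error rather than a silent drop.

Zonal statistics assign each pixel to the parcel containing its center
(deterministic and order-independent; exact-overlap weighting is not
implemented). A parcel's mean rate averages its unmasked pixels; fully
masked parcels are recorded missing and excluded. Class summaries are
area-weighted parcel means, Σmᵢaᵢ/Σaᵢ. The 95% CIs come from a seeded
percentile bootstrap (default 1000 resamples) resampling *parcels* with
replacement — parcels, not pixels, are the independent management
units; pixel-level resampling would ignore within-field correlation and
produce far-too-narrow intervals. Verified calibration: on synthetic
landscapes with a known class mean the CIs cover truth ≈94% of the time
(the acceptance suite checks 93–97% over 500 replicates). Classes with
fewer than two parcels report a mean with undefined CI. Rankings break
ties alphabetically, and ratios are computed from unrounded means.

## Mosquito-abundance prey proxy

Flying-insect prey density is proxied by a relative mosquito-abundance
index built from thermal performance curves: Briere
`cT(T−Tmin)√(Tmax−T)` and concave quadratic `c(T−Tmin)(Tmax−T)`, both
exactly zero outside [Tmin, Tmax]; adult mortality is the reciprocal of
a quadratic lifespan ("inverted-quadratic"). The composition is

    M(T) = EFD(T) · pEA(T) · MDR(T) / max(μ(T), floor)²

(eggs·female⁻¹·day⁻¹ × egg-to-adult survival × development rate over
squared adult mortality), the standard temperature-dependent abundance
term of trait-based vector models, isolated behind one function so an
alternative composition (e.g. a full R₀) can be substituted. The
mortality floor (default 0.01 day⁻¹, i.e. a 100-day lifespan cap) keeps
M finite where the lifespan curve collapses at its thermal edges.

The shipped trait parameters are representative temperate-*Culex*-style
values — approximate, not authoritative transcriptions: unimodal curves
with limits near 3–40 °C and a composite peak in the low-to-mid 20s °C.
M is unitless and used only through a smooth term downstream, so any
monotone rescaling (hence the exact `c` constants) is immaterial; only
the curve shapes and limits matter. Users with fitted trait posteriors
should supply their own YAML. Seasonal abundance is the per-pixel mean
of M over the temperature stack; a pixel missing at any time step is
missing in the output, because a partial-season mean is not comparable
across pixels.

## Association model

All layers are block-averaged to coarse cells before modeling because
mosquitos disperse about a kilometer a day — finer proxy variation is
not meaningful. The default cell is 980 m = 14 × 70 m pixels (1000 m is
not an integer multiple of the base pixel). Cells need ≥50% valid area;
the dominant class is modal by area with alphabetical tie-breaks.

The model is a Gaussian-identity GAM,

    activity ~ s(mosquito) + lights + irrigated + C(landcover) + s(lat) + s(lon)

fit with statsmodels' penalized B-splines. Design choices:

* **Spatial term.** Implemented as additive penalized cubic smooths of
  latitude and longitude rather than an isotropic bivariate smoother.
  This captures broad-scale trend; a sharply anisotropic interaction
  field would be under-absorbed, which is the main known limitation.
  The reported "Lat./Long." p-value is a Bonferroni combination of the
  two axis tests.
* **Basis dimensions** default to k=10 (mosquito) and k=8 per spatial
  axis — sized for desk-scale landscapes of a few hundred cells; raise
  `k_space` for study-scale grids with tens of thousands of cells.
* **Penalty weights** are fixed (α=1) rather than data-selected, so
  refits are deterministic and permutation-invariant to 1e−8. With
  these defaults the penalty-adjusted Wald test of the mosquito smooth
  is well calibrated: ≤10% null rejections at α=0.05 across 50 seeds
  (acceptance suite), measured ≈4–6%.
* **Reference class** defaults to "miscellaneous" and is always named
  in the report; classes with fewer than 2 records are dropped with a
  warning to avoid rank deficiency.
* Adjusted R² uses the effective degrees of freedom (hat-matrix trace).

## Synthetic-data generator

The generator defines the conditions under which the pipeline is
demonstrated: per-scan presence probability

    p = clip( r · w_class · (1 + A_sim·e^{−d/λ_sim}) · prey(x), 0, 1 )

with defaults r=0.06 per scan (chosen so a typical pixel accumulates
≈16 occ·ha⁻¹·night⁻¹ over a 152-night, 126-scan season — the realistic
magnitude for this system), rice weight 2× grassland, A_sim=1,
λ_sim=5000 m, 8 roosts, and a linear prey coupling (strength 0.5) to
the temperature-driven abundance surface so a genuine monotone
bat–insect association exists in the data. Land cover is a Voronoi
patch tessellation (default 150 patches on a 224×224 grid) so parcels
are contiguous fields and the parcel-extraction path is exercised; the
per-patch pixel boxes are dissolved into polygons, making the vector
and raster representations exactly consistent. Covariates: temperature
= seasonal sinusoid + west–east gradient + noise, clipped to
[10, 35] °C; lights elevated over urban; irrigated fraction high over
rice and other crops.

Two sampling paths exist: `simulate_scenes` streams per-scan Bernoulli
scenes (used wherever scene-level behavior matters), and
`simulate_activity` draws seasonal counts directly as
Binomial(n_scenes, p) — distributionally identical because scans are
iid, and far cheaper at full-season sizes. All randomness derives from
one seed via per-stage child streams; identical config + seed gives
bit-identical outputs, which the pipeline manifest verifies by SHA-256.

What the generator does **not** emulate: radar beam geometry and range
bias, spatially correlated detection noise, night-to-night weather
suppression, non-stationary season phenology, and urban clutter false
positives. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to radar
artifacts; the masking interface is the extension point for the latter.

## Problem sizes

Defaults are desk-scale by design: the demonstration landscape is
224×224 pixels (≈2,460 ha) with 256 GAM cells, versus a real study box
two orders of magnitude larger. Test simulations use smaller grids
(20–56 px) and shortened seasons; the bootstrap-coverage check runs 500
replicates of 100 parcels at 400 resamples; the GAM null calibration
uses 50 seeds at n=600. These sizes are stated here as the package's
reporting conditions; all thresholds they are checked against
(|t|<2, r>0.9, 93–97% coverage, ≤10% rejections) are independent of
scale.

## Known limitations

* The roost correction's functional form is a documented modeling
  choice, not an estimate; mis-specified (A, λ) under- or over-corrects
  and there is no in-package diagnostic to detect it in real data.
* Additive (not isotropic) spatial smoothing, noted above.
* Pixel-center parcel assignment slightly misattributes boundary pixels
  of small or sliver parcels.
* Whole-season aggregation only; nightly/weekly temporal resolution is
  out of scope.
* The trait defaults are representative, not fitted posteriors; use
  your own trait YAML for inference about a specific vector species.
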