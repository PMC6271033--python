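# Methods

## Scope and data model

The package models a pushbroom SWIR imaging experiment: a scene is a
hypercube `A[y, x, λ]` with two spatial axes and 256 wavelength bands on a
uniform 920–2514 nm grid (~6.25 nm spacing). Memory order is fixed to
(line, sample, band); BIL/BIP/BSQ interleaves exist only at the ENVI I/O
boundary. Raw counts are calibrated per band against dark/white references
averaged over their spatial extent (a per-band vector; averaging suppresses
reference noise), clipped to reflectance `[1e-6, 1.5]` — the floor prevents
infinities from dead pixels in the log, the ceiling tolerates specular
pixels — and converted to pseudo-absorbance `A = log₁₀(1/R)`, the scale on
which constituent mixing is approximately linear.

## Masking

Interactive score-plot pixel selection is replaced by a deterministic rule:

* **dead pixels** — band-wise variance `< 1e-10` or any non-finite value;
* **background** — one mean-centered NIPALS component over all pixels
  (the dominant variance direction of a whole scene is sample-vs-stage
  contrast), then an Otsu threshold on the PC1 score histogram; of the two
  groups, the one with lower mean absorbance is the stage (`background=low`;
  configurable to `high` for dark-sample scenes). A degenerate histogram
  falls back to a score-sign split, and a spatially uniform image is an
  error;
* **edge effects** — 4-connected binary erosion of the kept set, default 1
  iteration (removes mixed boundary pixels with minimal area loss).

Dead pixels are excluded before the Otsu step, which makes the dead/
background composition order-insensitive. A mask keeping fewer than 1% of
pixels is rejected as a configuration error.

## Pretreatment

Fixed order: crop → scatter correction (SNV or MSC) → optional
Savitzky–Golay derivative → mean centering. Centering is a model step, so
SNV runs before it; the plan stores its fitted state (MSC reference
spectrum, column means, crop threshold) and replays it identically on
prediction pixels. Cropping keeps bands with λ strictly greater than the
threshold (default 996 nm — the short-wavelength end is detector-noise
dominated). SNV uses the sample (n−1) standard deviation; rows with SD
below 1e-12 are zero-filled and flagged. MSC fits `x ≈ a + b·ref` by least
squares and returns `(x − a)/b`, passing rows with `|b| < 1e-12` through
unchanged. Derivatives are taken per band index (the grid is near-uniform,
so the per-nm factor is a constant the bilinear models absorb); defaults
window 11, polynomial order 2 are a documented choice, exposed in the plan.
Choosing among candidate plans is a config decision supported by a reported
separation metric (silhouette of PCA scores), not an automatic optimizer.

## NIPALS PCA

Components are extracted one at a time by alternating least squares with
deflation; convergence when the score vector changes by less than `tol`
(default 1e-9 relative, max 500 iterations; non-convergence warns and
accepts the current vector). `R²X` per component is `tᵀt / SS(X_centered)`.
Extraction stops early if the residual drops below working precision
(rank exhaustion). Sign convention: each loading's largest-magnitude element
is made positive, so repeated runs are comparable. A truncated SVD is the
test oracle, never the implementation.

Component-count selection uses random row segments, but held-out rows are
*not* scored by plain projection — projecting a row onto any basis always
lowers its residual, which would flatter pure noise. Instead every element
of a held-out row is predicted from the row's other bands via the exact
least-squares leave-one-out identity (leverage `h_j = Σ_a P_ja²`,
`e_loo = e/(1−h)`), so a component only reduces PRESS when its loading
structure generalizes. Components are accepted while the marginal
`Q²X_cum` gain is ≥ 0.01 (floor: one component).

The most-discriminating wavelength window reported with a loadings plot is
the contiguous span (default width 300 nm) maximizing mean |loading| —
located by exhaustive search over window starts.

## PLS-DA

Class membership is one-hot encoded (alphabetical class order). NIPALS PLS2
deflates both blocks; regression coefficients for `a` factors are
`B = W (PᵀW)⁻¹ Qᵀ`, predictions `Ŷ = (X − x̄)B + ȳ`. Cross-validation uses 7
random segments drawn once, stratified by class so no fold loses a class;
`Q²Y_cum(a) = 1 − PRESS(a)/SS(Y_centered)` with PRESS pooled over segments
and Y columns. Factors are added while each raises `Q²Y_cum` by at least
0.01 (exposed in config; floor one factor). `Q²Y_cum ≤ R²Y_cum` is asserted
as a model invariant.

Pixel classification: candidate classes are those with `0.5 ≤ Ŷ_c ≤ 1.5`;
a single candidate wins; several candidates resolve by argmax of Ŷ (first
index on exact ties); none means *no class* — material unlike anything
calibrated. With the cut-offs pushed to ±∞ the rule degenerates to pure
argmax, which is asserted as a property.

Composition reports give per-region percentages of each class plus
no-class over **kept (non-background) pixels** — that denominator makes
rows sum to 100 and matches how a prediction table is read off a masked
image. Regions with a claimed class get a verdict: `match` if the dominant
class appears in the claim, `no_authentic_material` if no-class dominates,
else `mismatch`; zero-pixel regions are `unevaluable`.

## Synthetic scenes

The generator exists so that every stage has exact ground truth. It
emulates: a 256 × 320 scene; 18 authentic wells (3 species × root/leaf × 3
replicates) randomly placed on a 3×6 grid; a second scene of 20 "products"
(pure species, asymmetric two-species blends, excipient-only extracts,
mostly-excipient formulations, one multi-herb) plus 4 authentic controls;
and known flat references (white 3000–3800 counts, dark 120).

Endmembers are Gaussian absorption bands on a sloping baseline. All plant
materials share vegetation bands (1450, 1935, 2100, 2310 nm); organs add
their own (root 1580; leaf 1680, 2270); species identity lives in 2–3
bands between 1937 and 2400 nm. Roots carry deeper species features
(depth scale 0.18) than leaves (0.13), and the leaves' extra organ bands
further dilute their species signal after SNV, so root separation exceeds
leaf separation without a second mechanism; *E. pallida* gets an extra
band and a depth boost, making it the most distinct species in both organs
(SNV angular distances: roots 24–37°, leaves 11–28°). The excipient is the
average of the six plant endmembers plus weak processing bands (1730,
1250 nm) — the profile of a concentrate or blended filler that retains
generic vegetation chemistry but no species signature; a calibrated model
therefore predicts it near the class-mean dummy values, below every
cut-off window. Keeping the species-band depth profile consistent across
organs (rather than an order of magnitude apart) is what lets two to three
PLS factors describe the class structure; models forced beyond that by
organ-specific amplitude structure extrapolate out-of-domain material
unpredictably, which is a genuine failure mode of dummy-Y regression, not
of the implementation. The stage is dark and spectrally flat.

Per pixel, absorbance is `a(λ) = m·Σᵢ wᵢ·eᵢ(λ) + offset + ε(λ)` with
`m ~ lognormal(0, 0.06)` (multiplicative scatter), `offset ~ N(0, 0.015)`
(baseline) and `ε ~ N(0, 0.004)` per band (white noise) — levels set so
SNV demonstrably improves separability while a small fraction of pixels
still misclassifies. Mixtures default to **segregated** rendering: each
pixel draws its component from the mixture weights, like a powder blend
whose particles exceed the pixel size, so well-level percentages recover
the weights; an **intimate** mode mixes spectra within every pixel (a
homogeneous 50/50 blend then predicts near (0.5, 0.5) and classifies as
no-class — chemically sensible, but not how granular blends behave).
All randomness flows from a single seed; identical seeds give
bit-identical scenes.

What the generator does **not** emulate: real *Echinacea* spectra (the
endmembers are stylized caricatures; no spectral realism is claimed),
particle-size physics, instrument line spread, pushbroom registration
artifacts, or spatially correlated illumination drift. Passing tests show
the pipeline recovers known structure under this noise model, not that the
specific species are separable on a given instrument.

## Pipeline defaults and problem sizes

Training draws at most 200 masked pixels per calibration region (seeded),
giving 1800 calibration pixels × 243 bands after the 996 nm crop; the
calibration/test split is a seeded 50/50 split of labelled wells,
stratified by class with root/leaf sub-groups contributing to both halves.
PCA selection caps at 10 components, PLS at 10 factors, both with gain
threshold 0.01. The test suite exercises a scaled replica (96 × 128 pixels,
96 bands, 7-px wells) for unit-level checks and the full-size replica for
the end-to-end contract tests. Model archives use a purpose-built
deterministic format (JSON manifest + raw little-endian blocks) so that
rerun reproducibility is a byte comparison.

## Known limitations

* The dummy-Y cut-off rule has no outlier statistic (no SIMCA-style DModX);
  out-of-domain material is caught only when its prediction leaves the
  cut-off windows.
* Wavelength grids must match between model and scene; resampling across
  instruments is out of scope.
* Background orientation assumes a stage darker (lower absorbance) than the
  samples unless configured otherwise.
* Touching wells are not split (no watershed); the region layout is taken
  as given.
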