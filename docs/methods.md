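# Methods

This note documents the statistical procedures, the default parameters
and the deliberate design choices behind `smqc`, plus what the synthetic
data generator does and does not emulate.

## Data model and conventions

A peak table is a dense pixel × ion matrix with integer (x, y) grid
coordinates and a strictly increasing m/z axis. Missing cells are
canonicalized to 0 on read and "undetected" means intensity ≤ 0
throughout: peak tables conflate non-detection with zero, and keeping a
single convention makes the per-pixel and per-ion missingness views obey
an exact double-counting identity (mean missing-pixel ratio = mean
missing-ion ratio = overall zero fraction; computed from integer zero
counts so the identity is bit-exact rather than exact only up to float
summation order). Non-integer coordinates are mapped to ranks along each
axis (and the mapping logged) because quadrat gridding and image export
need a lattice. Ion identity is the exact decimal literal of the column
header; values are never re-rounded between stages.

Filtering stages always return flagged result tables over the *input*
rows: a removed pixel appears in `pixel_info.csv` with `kept=false`, a
removed ion in `peak_info.csv` with `is_noise=true`.

## Regions and background consistency

Regions are polygons rasterized onto the pixel grid (a pixel belongs to a
region when its center is covered by the polygon, boundary included;
self-intersecting polygons are rejected, so the winding rule coincides
with the even-odd rule) or explicit pixel lists. The representative
spectrum of a region is the per-ion median over its pixels, with the
even-count median defined as the mean of the two central order
statistics.

Background consistency is the pairwise Pearson correlation of the
background median spectra over all ions, on the raw intensity scale by
default. Correlating raw medians weights high-abundance channels most,
which is what instrument-drift detection needs; a `log10(x+1)` option
exists for data whose background is dominated by a handful of channels.
The summary is the *minimum* off-diagonal coefficient — the strictest
reading of "consistently high" — flagged consistent above 0.9.
Sub-clustering uses average linkage on distance 1 − r (the linkage is not
dictated by the problem; average linkage is the least committal for
correlation matrices of a handful of regions), with regions pre-sorted by
name so ties break deterministically.

## Tissue enrichment and pixel segmentation

Per ion, tissue pixels are compared to background pixels with a
one-sided Wilcoxon rank-sum test (tissue > background; one-sided because
enrichment is a directional claim). The test uses the exact null
distribution for tie-free samples with n+m ≤ 16 and otherwise the normal
approximation with tie-corrected variance and continuity correction. The
exact and approximate tails agree within 0.01 whenever both groups have
at least 5 observations (verified exhaustively over rank configurations);
for smaller groups the worst-case discrepancy grows to ~0.06 at n = 1,
which the exact mode avoids.

Fold change is mean-based — (mean tissue + ε)/(mean background + ε) with
ε equal to half the smallest positive intensity in the table — because
means, unlike medians, respond to the sub-region-localized signals that
MSI tissue markers often are, and the pseudo-count keeps the ratio finite
for ions absent from the background. An ion is enriched when FC > 1
(strict) and p < 0.05 (strict); p-values are deliberately *not* adjusted
for multiple testing by default (a Benjamini–Hochberg option exists):
the enriched percentage is a QC descriptor, not an inferential claim.
Note the direct consequence: truly flat ions are flagged at the nominal
~5% rate, so the false-positive rate among null ions hovers at, not
below, 5%.

Segmentation thresholds the per-pixel total intensity over the enriched
ions; pixels with total ≥ threshold are kept (a total exactly at the
threshold is tissue). The threshold is user-set; when unset, Otsu's
between-class-variance optimum on log10(total + 1) is suggested. On a
cleanly bimodal total distribution any threshold in the empty valley is
equivalent; Otsu lands there deterministically. Enrichment itself is
always computed on the original, unsegmented table using only the
delineated regions' pixels.

## Noise scoring

An ion is noise when its spatial pattern is indistinguishable from
complete spatial randomness (CSR) over the retained pixels. Two choices
matter:

**Image → point pattern.** Default: the ⌈k/2⌉ highest-intensity pixels
among the k detected ones (`top_fraction`, f = 0.5; ties at the cutoff
break by pixel order). Detection-only patterns saturate once an ion is
detected almost everywhere — every dense ion then looks perfectly
uniform — while intensity-rank selection keeps discrimination between
spatially structured and flat ions. A `detected` mode (all positive
pixels) is available for sparse data.

**The test.** The support bounding box is cut into a 5×5 grid; quadrats
containing no retained pixel are dropped and expected counts are
proportional to the number of support pixels per quadrat, so irregular
tissue masks introduce no bias. The statistic is the upper-tail
chi-square (clustering alternative only: a "too regular" lower tail would
misclassify uniform ions as structured) with df = used quadrats − 1. The
p-value is computed in log space; beyond the point where the survival
function underflows double precision (score ≈ 308) an asymptotic
upper-incomplete-gamma expansion takes over, so the noise score
−log₁₀ p is finite and exact at any magnitude.

Ions with fewer than 20 points are flagged as noise outright (a
chi-square on fewer points is unreliable, and ultra-sparse channels are
uninformative). The removal threshold defaults to 60; a score exactly at
the threshold is retained. Under simulated CSR (200 points on a 200×200
rectangle, 1000 replicates) the rejection rate at α = 0.05 is ~0.04–0.05
and the p-values are near-uniform (KS distance ~0.03). One caveat is
inherent to lattice data: a point pattern that covers a large fraction of
the support is a finite-population sample, whose quadrat counts are
under-dispersed relative to CSR; the test is then conservative. This is
why the calibration (and the generator's noise ions) use small sampling
fractions.

For threshold tuning the package exports borderline-ion images
(|score − threshold| ≤ window) for visual inspection, and
`suggest_noise_threshold` provides a scripted alternative: Otsu's optimum
on log10(score + 1), which on a bimodal score distribution lands between
the CSR-like and structured modes.

## Isotopologue and adduct annotation

Isotope search: anchors are swept in ascending m/z; for each order
k ≤ max_order (default 1), heavier ions within
|Δm − k·1.0035| ≤ ppm_tol·m_heavier/10⁶ (ppm_tol default 5, anchored at
the heavier member since the error scale is set by the heavier mass) are
candidates, confirmed when the Pearson correlation of the two images over
all retained pixels reaches corr_min (default 0.7, a conventional
co-localization cutoff). The spacing default is 1.0035 Da; the precise
¹³C spacing 1.003355 is available as `C13_SPACING`. A confirmed isotope
peak cannot itself anchor a pair; an ion matching several anchors keeps
all pair records, with its status listing anchors by increasing ppm
error. Correlations use all retained pixels (zeros included) — restricting
to co-detected pixels would bias r upward for sparse channels.

Adduct search runs on the monoisotopic remainder against configurable
(label, offset) lists for the positive and negative modes (seven common
forms each by default). A pair is a candidate when its mass difference
matches the difference of two offsets within the ppm window. Some default
offset differences coincide exactly — (M+Na)−(M+H) equals
(M+2Na−H)−(M+Na) — so each unordered ion pair is recorded once, under the
smallest-|ppm| interpretation with ties broken by list order; otherwise
every such pair would be double-reported.

The isotope rate is the percentage of ions flagged as isotope peaks; the
adduct rate is the percentage of monoisotopic ions in ≥ 1 confirmed
adduct pair. Raw counts are reported alongside so either denominator
convention can be recovered. The windowed sorted-m/z search is verified
equal to an exhaustive all-pairs oracle in the test suite.

## Synthetic data

The generator plants ground truth for every stage on a rectangular grid
(default 60×60) with an elliptical tissue mask split into an inner
ellipse (~half the tissue area) and the surrounding annulus:

* **Structured ions** (default 100): per-ion log-normal base intensity
  (log-mean uniform over [ln 10³, ln 10⁵]; within-ion pixel σ = 0.2).
  Each ion is elevated inside the tissue with its elevation concentrated
  in one of the two sub-regions, scaled so the population tissue/
  background mean ratio equals the configured effect size (default 2.0)
  exactly, with the low side fixed at 1.1× background so one-sided
  enrichment holds tissue-wide. The concentrated half gives structured
  ions noise scores of ~80–100 on the demo — the regime where spatial
  patterns are visually unambiguous — while keeping the marginal effect a
  modest 2-fold.
* **Noise ions** (default 100): Bernoulli detection at p = 0.05 uniformly
  over all pixels. The probability is kept small deliberately: a dense
  subsample of the lattice is under-dispersed relative to CSR
  (hypergeometric variance deflation), whereas at a 5% sampling fraction
  the planted quadrat p-values are near-uniform.
* **Solvent/background ions** (default 10): present everywhere, on and
  off tissue alike.
* **Isotope companions** (default 20): partner image × 0.2 with
  multiplicative log-normal noise (σ = 0.15), at partner + 1.0035 Da
  jittered within half the ppm window. **Decoy pairs** (default 20) sit
  at the correct spacing but pair ions from opposite sub-regions, whose
  images anti-correlate over the tissue — they exercise the correlation
  gate. **Adduct companions** (default 15) are analogous at the default
  positive-mode offset differences (M+H paired with M+Na/M+K/M+NH₄).
* **Dropout** (default 5%): detection-limit censoring — each ion loses
  its lowest-intensity 5% of values. Uniform random zeroing is available
  (`dropout_mode="random"`) but not default: random zeros land on hot
  pixels and degrade planted companion correlations far below the
  intended r ≈ 0.95, which is not how MSI non-detection behaves.

Random m/z positions are rejection-sampled away from every isotopic and
adduct target difference (±0.02 Da), so the only annotation candidates
are planted ones and recovery tests are exact. The generator emits a
matching `regions.json` (a shrunken tissue ellipse polygon and three
background corner squares) and writes real files so the CLI is exercised
through its true I/O path.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: mass-resolution-dependent peak overlap,
intensity drift over acquisition time, spatially correlated noise
(striping), hot pixels, isotope intensity ratios constrained by elemental
composition, and tissue masks with holes or disconnected components.
The quadrat machinery handles non-elliptical supports by construction,
but the recovery rates quoted here are specific to the planted effect
sizes and noise levels.

## Problem sizes and determinism

The shipped demo runs 3600 pixels × 245 ions; the full pipeline completes
in a couple of seconds and the acceptance script (including the 1000-rep
CSR calibration and the exhaustive rank-sum check over all C(n+m, n)
assignments up to n+m = 12) in under ten. The pipeline contains no random
step: identical input, configuration and seed reproduce byte-identical
outputs, with wall-clock timings written to a separate `timings.json` so
the QC report itself is reproducible at the byte level.

## Known limitations

* The quadrat test's conservativeness for dense point patterns (above)
  means `detected` mode should not be used for ions detected in most
  pixels; `top_fraction` is the default for exactly this reason.
* Fold change and rank-sum sidedness follow a single convention
  (means, tissue > background); median-based FC is not offered.
* The flat-ion false-positive rate of the enrichment rule equals the
  nominal test level by construction (no multiplicity correction by
  default).
* Polygon rasterization treats pixels as points (their centers), not as
  unit squares; a polygon threading between pixel centers selects
  nothing.
* Annotation is mass-difference + co-localization only; it does not
  verify isotope intensity ratios against elemental composition, and it
  cannot distinguish an adduct pair from two co-localized isobars at the
  same mass offset.
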