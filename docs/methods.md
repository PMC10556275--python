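# Methods

This note records the model behind `tmathresh`, the numerical conventions
it fixes where the method description leaves room, the design of the
synthetic cohort generator, and what the tests do and do not demonstrate
about real data.

## Adaptive thresholds

The unit of analysis is one TMA spot at lattice position (i, j) of slide
s. Marker positivity is decided against a threshold that varies at two
scales:

* slide level: `T_ms = T_mR * I_ms / I_mR`, with the reference slide R
  chosen by the analyst (a slide free of artefacts) and `T_mR` set by
  review on that slide. `I_ms` is the slide's mean marker intensity —
  by convention the mean of per-cell mean intensities when nuclei are
  segmented, otherwise the mean of spot summaries.
* spot level: `T_ms,i,j = F_m * wmedian(I_ms,k,l, w_ms,k,l)` over the
  7×7 window `|k−i| ≤ 3, |l−j| ≤ 3`, where `I` is the spot's mean
  intensity over all pixels of the spot square and `w` the spot's valid
  tissue area in μm². The window half-width (default 3) is a parameter,
  supporting sensitivity analyses over neighbourhood size.

The weighted median rather than a weighted mean makes the local
background estimate insensitive to a minority of biologically bright
spots: smooth staining gradients move all window entries together and
are tracked, while sparse outliers cannot move the median. Because both
corrections are ratios of intensities, each threshold is degree-1
homogeneous in the slide's intensities — a property the tests assert
exactly (scaling a slide by c scales every threshold by c and leaves
every positivity call unchanged).

### Numerical conventions

* **Weighted median**: the *lower* weighted median — the smallest value
  whose cumulative weight reaches half of the total. Deterministic,
  standard, and preserves the outlier robustness above. Zero-weight
  entries are dropped before the computation and can never influence
  the result; a window whose total weight is zero has no support and
  triggers the slide-threshold fallback (logged), or an error when no
  slide threshold is available.
* **Positivity comparator**: `>=`. The boundary case must be fixed
  somewhere; ties at the threshold are counted positive.
* **Invalid spots** keep their records but contribute weight 0 to every
  neighbourhood and are never assigned thresholds or quantified.

### CD68-style extras

Macrophage markers are more threshold-sensitive, so two extra features
apply to markers configured with them:

* **Centre weighting**: the centre spot's weight is multiplied by the
  number of *other entries in its window*, giving it equal weight to
  all the others together, so spots with genuinely high signal raise
  their own threshold. The count includes virtual entries (below).
  This choice is load-bearing: virtual complement values are
  background *deviations* — exactly 0 on a flat intensity field — and
  near slide corners they can outnumber the real spots (up to 33 of
  49 entries). Counting only real neighbours would let those
  near-zero entries accumulate more than half of the window's weight
  and collapse the weighted median, and hence the threshold, to 0.
  With the full count the centre always balances the rest of the
  window, the virtual mass stays below half, and boundary thresholds
  remain positive on flat fields. Note that with the lower-median
  convention the centre's half-weight pulls the median exactly to the
  boundary between the neighbourhood value and the centre value, and
  the lower one is returned.
* **Virtual complement**: boundary spots lack a balanced
  neighbourhood, so every absent window position (missing, invalid,
  or outside the lattice) is filled with a virtual value: the
  intensity of the spot at the point reflection of the missing
  position through the centre, minus the mean intensity of the
  window's present spots, floored at 0 (intensities cannot be
  negative). When the opposite position is itself absent, the mean of
  the present spots stands in for its intensity, so the complement
  degenerates to 0. Virtual entries carry the mean tissue weight of
  the present entries, so they neither vanish nor dominate. The mean
  subtracted is the mean over the *window*, not the whole slide.
* As a final safeguard, a spot threshold that still degenerates to a
  non-positive value (pathological case: an isolated spot surrounded
  entirely by virtual entries) falls back to the slide threshold with
  a logged warning, keeping every valid spot's threshold positive.

## Quantification

* **Cell-based**: cells are taken from input nuclei label masks
  (segmentation is upstream). The cytoplasm of each cell is the ring of
  pixels within 1 μm of its nucleus that are closer to that nucleus
  than to any other — a Euclidean distance transform with nearest-label
  assignment, which realizes the half-distance split for nuclei closer
  than 2 μm. A cell is positive when the mean intensity of the marker's
  configured compartment (nucleus for nuclear markers, cytoplasm ring
  for membranous/cytoplasmic ones) reaches the threshold; the
  compartment mean (not max) matches the intensity summaries used
  elsewhere in the pipeline. Cells with an empty compartment are
  negative and logged. A cell belongs to the region (epithelium/stroma)
  holding the majority of its nucleus pixels.
* **Pixel-based**: every tissue pixel of the requested region is
  classified against the threshold; areas are pixel counts times the
  pixel area (default 0.4976 μm/pixel). Region "all" is the tissue mask
  regardless of region labels.
* **Aggregation**: case-level tables sum counts and areas over the
  case's spots and recompute densities from the sums — never averaging
  per-spot ratios — so a 10 cells/1 mm² spot and a 20 cells/1 mm² spot
  yield 15 cells/mm², and area totals are conserved exactly.
* Densities are reported per mm² (areas held in μm²; factor 10⁶ exact).
  Empty regions report zero areas and undefined (NaN) densities.

## Evaluation

`compare_adaptive_vs_global` scores four thresholding modes by the mean
absolute error (MAE) of the per-spot positive-area fraction against
ground truth: `global` (a single threshold fit *in hindsight* on a
512-point geometric candidate grid spanning the cohort's intensity
range — the strongest global competitor, not a strawman), `slide`,
`spot` (the weighted-median equation, which being in absolute intensity
units absorbs inter- and intra-slide variation at once), and
`slide+spot` (spot thresholds with the slide fallback — the combined
method as deployed). Spearman correlations use tie-corrected average
ranks (scipy), with an exact permutation p value for n ≤ 8 and the
large-sample approximation otherwise; constant inputs are reported as
undefined rather than 0.

## Synthetic cohort generator

The generator emulates the variation structure the method is built to
absorb, with known ground truth:

* Each spot is a circular tissue disc (tissue fraction 0.40–0.70 of the
  square) with an off-centre epithelial disc (the rest is stroma) and
  non-overlapping disc nuclei (radius 3 px) placed by dart throwing
  with a minimum-gap parameter. Spot images are rendered at 72×72 px —
  a deliberately scaled-down core (a real 1.0 mm core at 0.4976
  μm/pixel would be ~2,000 px across); nuclei realism is out of scope.
* Per marker, a cell is positive with a per-spot probability drawn from
  (0.02, 0.15), or (0.30, 0.60) on "outlier" spots (rate 0.05), and
  its configured compartment is rendered at the positive level 3.0;
  negative tissue sits at 0.4 and non-tissue background at 0.05
  (arbitrary units). The latent positivity threshold is the geometric
  mean √(0.4·3.0) ≈ 1.10.
* The latent image is multiplied by slide factor × gradient: factors
  default to geomspace(0.5, 2) over 5 slides, the gradient is a
  slide-wide geometric ramp of amplitude 3 normalised to mean 1. Noise
  adds per-pixel multiplicative jitter (CV 0.05) and additive
  background noise (σ 0.02), clipped at 0. Boundary spots are dropped
  with probability 0.25 (plus 0.02 anywhere); 2% of spots are invalid.
* Marker factors are calibrated once per cohort as F = latent threshold
  / median undistorted spot mean — the in-silico analogue of setting F
  by visual assessment; reference thresholds equal the latent threshold
  scaled by the reference slide's factor.

The levels were chosen so that (a) each spot's positive/negative gap is
wide enough that the spot equation lands inside it, making recovery
*exact* in the noiseless limit and giving the tests sharp oracles, and
(b) the cohort-wide distortion spread (~12×) exceeds the gap ratio
(7.5×), so no single global threshold can be correct everywhere. The
flip side is that moderate distortions (spread below the gap ratio) are
absorbed by *any* correctly centred threshold; mode-ordering tests
therefore inject spreads that exceed the gap ratio at the scale they
probe. A separate validation configuration (96 px spots, nucleus gap
4 px, positive fractions 0.05–0.40) provides the well-separated-cells,
wide-dynamic-range regime for the pixel-vs-cell correlation; with the
default low positive fractions the epithelial compartment holds so few
positive cells that the rank correlation degenerates — the same
small-number effect reported for CD20 in epithelium on real data.

### Known interaction: centre weighting vs biological outliers

CD68 centre weighting raises a bright spot's *own* threshold by design.
When the centre's tissue weight exceeds the window average, its boosted
weight crosses half the window total and the weighted median lands on
the centre's own (bright) mean. In the generator, outlier spots are
bright because of genuinely elevated positive fractions, so on some
seeds a single CD68 outlier spot's threshold can land above its
positive level and its positives are clipped — a per-cohort MAE
contribution below ~2×10⁻⁴. This is the faithful behaviour of the
centre-weighting rule meeting a cohort whose bright spots are biology
rather than background, and it is the reason centre weighting is
reserved for markers where high spot intensity usually reflects
background.

### What the synthetic tests do not show

The generator's distortions are exactly multiplicative, its noise never
approaches the positive/negative gap, and its segmentation is perfect.
Passing tests therefore demonstrate that the implementation inverts the
variation model it targets — not that the method handles spectral
bleed-through, autofluorescence, segmentation errors, continuous
expression spectra, or additive background comparable to signal. Region
masks, nuclei masks and spot validity flags are inputs throughout;
tissue classification and nuclei segmentation quality are upstream
concerns.

## Problem sizes

Test and acceptance runs use 5 slides × 10×10 grids (~440 valid spots)
for parameter recovery and the same scale for the validation cohort;
unit fixtures use 9×9 closed-form grids and two-nucleus geometry
images. The weighted-median oracle sweep uses 1,000 random instances of
sizes 1–49 (the window size).
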