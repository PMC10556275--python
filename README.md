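# tmathresh

Adaptive thresholding and marker quantification for multiplex
immunofluorescence (mIF) tissue-microarray (TMA) cohorts.

## The problem

Large clinical TMA cohorts are stained and imaged in batches, often with
tissue sourced from many institutions. The resulting multi-channel
fluorescence images show substantial *inter-slide* intensity variation
(different overall staining/imaging gain per slide) and *intra-slide*
variation (smooth staining gradients running across a slide), on top of
genuine biology — sparse spots with very high marker expression. A single
global positivity threshold applied to such a cohort misclassifies pixels
and cells wherever the local intensity scale drifts. `tmathresh`
implements adaptive, locally varying thresholds for TMA spot-grid
analysis, plus the pixel-based and cell-based marker quantification they
feed, the spot-to-case aggregation, and the cross-validation statistics
used to check the pipeline — together with a synthetic TMA cohort
generator with known ground truth for testing all of it end to end.

## The method

For marker *m*, slide *s* and a TMA spot at grid position *(i, j)*:

* **Slide-specific thresholds** correct inter-slide gain. A reference
  slide *R* gets a reviewed threshold *T<sub>mR</sub>*; every other
  slide's threshold is scaled by the ratio of slide mean intensities:

  *T<sub>ms</sub> = T<sub>mR</sub> · I<sub>ms</sub> / I<sub>mR</sub>*

* **Spot-specific thresholds** correct intra-slide gradients. The
  threshold of a spot is a marker-specific factor *F<sub>m</sub>* times
  the tissue-weighted median of the spot mean intensities over the 7×7
  grid window centred on it:

  *T<sub>ms,i,j</sub> = F<sub>m</sub> ·
  wmedian{ (I<sub>ms,k,l</sub>, w<sub>ms,k,l</sub>) :
  |k−i| ≤ 3, |l−j| ≤ 3 }*

  where *w* is the amount of valid tissue (μm²) in each spot. The median
  tracks smooth gradients while ignoring sparse biologically bright
  spots; invalid/empty spots carry weight 0. For threshold-sensitive
  markers (CD68-style) the centre spot's weight is multiplied by the
  number of neighbouring window entries (so it weighs as much as all
  others together) and boundary windows are completed with *virtual*
  intensities reflected through the centre (defaults *F*: CD20 = 10,
  CD8 = 6, FoxP3 = 8, CD68 = 2.5).

Classification then calls a pixel (or a cell compartment mean — nucleus
for nuclear markers, the 1 μm cytoplasm ring for membranous markers)
positive when its intensity is ≥ the local threshold. Spot-level counts
and areas aggregate to case level by summing, with densities recomputed
from the sums.

## Worked example

```python
from tmathresh import (CohortSpec, generate_cohort,
                       compare_adaptive_vs_global)

cohort = generate_cohort(CohortSpec(n_slides=3, n_rows=8, n_cols=8,
                                    seed=42))
table = compare_adaptive_vs_global(
    cohort.grids, cohort.truth.spots, cohort.marker_configs,
    cohort.imaging, cohort.reference_slide)
summary = (table[table.slide_id == "ALL"]
           .pivot(index="marker", columns="mode", values="mae"))
print(summary.round(4))
```

prints

```
mode    global  slide  slide+spot  spot
marker
CD20    0.0080    0.0         0.0   0.0
CD68    0.0073    0.0         0.0   0.0
CD8     0.0059    0.0         0.0   0.0
FoxP3   0.0051    0.0         0.0   0.0
```

Each number is the mean absolute error of the per-spot positive-area
fraction against the generator's ground truth. Even the *best
possible* single global threshold (fit in hindsight) misclassifies a
fraction of every spot's area because the cohort's slide gains (0.5–2×)
combined with the intra-slide gradient (3×) exceed the separation
between positive and negative signal; the adaptive modes invert the
multiplicative distortion and recover the truth exactly here.

The same pipeline is available from the shell:

```bash
tmathresh simulate --out cohort/ --seed 7
tmathresh thresholds --grid cohort/grid.csv --panel cohort/panel.yaml \
    --reference-slide S03 --mode both --out thresholds.csv
tmathresh quantify --grid cohort/grid.csv --panel cohort/panel.yaml \
    --thresholds thresholds.csv --out spots.csv
tmathresh validate-pixel-vs-cell --spots spots.csv --out corr.csv
tmathresh evaluate --cohort cohort/ --out report/
```

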