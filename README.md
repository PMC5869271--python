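# anthoquant

Noninvasive estimation of relative anthocyanin concentration in plant
tissues from calibrated digital images and reflectance spectra.

Anthocyanins — the flavonoid pigments behind most red, purple and blue
coloration in petals, stems, calyces and leaves — are traditionally
quantified by destructive extraction and spectrophotometry. Because they
absorb around 520–560 nm, their concentration also leaves a strong signature
in the *green* region of reflected light: pigment-rich tissue reflects less
green relative to red and blue. `anthoquant` turns that signature into a
calibrated, noninvasive assay:

1. **Image branch.** Photograph the sample with two gray standards of known
   reflectance in frame (defaults: ColorChecker Neutral 3.5 and Neutral 8,
   9.11% and 60.90% reflectance). A per-channel affine map anchored on the
   two standards converts linear sensor values to percent reflectance; mean
   R, G, B values are extracted from a region of interest.
2. **Spectral branch.** Alternatively, measure percent reflectance against a
   white standard over 300–800 nm.
3. **Color indices.** Fourteen indices are computed per branch. The
   anthocyanin-targeted ones compare the green signal *G* with the red/blue
   plateau: with channel means N (or reflectances R₄₅₀/R₅₅₀/R₆₅₀),

   - chroma difference  AC_CD = (N_blue + N_red)/2 − N_green
   - chroma ratio       AC_CR = N_green / ((N_blue + N_red)/2)
   - chroma basic       AC_CB = (N_blue + N_red) / N_green
   - strength of green  S_green = N_green / (N_red + N_green + N_blue)

   plus hue/lightness/saturation/brightness, chroma, red:green ratios and
   Endler-style segment-analysis hue and chroma for spectra. Degenerate
   cases (achromatic input, zero denominators) are flagged, never raised.
4. **Calibration statistics.** Each index is regressed against biochemical
   concentrations (absorbance units per cm² of tissue, with the chlorophyll
   correction A_max − 0.24·A₆₅₃ for photosynthetic tissue). Fits are ranked
   by r² under Holm ("sequential Bonferroni") family-wise error control;
   prediction error is the range-normalized RMSE; and fitted models are
   validated on independent samples by testing the observed-vs-predicted
   slope against 1.

A synthetic specimen generator (Beer–Lambert pigment optics, a Gaussian-band
camera model, and a renderer that draws gray standards plus uniform,
striped, spotted or veined tissue) makes the entire pipeline runnable and
testable without any field data.

## Worked example

Simulate a 30-sample petal campaign, calibrate each frame on its own gray
standards, rank the indices and validate the best one on an independent
batch of 28:

```python
import numpy as np, pandas as pd
from anthoquant import (generate_dataset, fit_two_point_calibration,
                        extract_roi_stats, compute_rgb_indices, rank_indices,
                        fit_index_regression, validate_model)
from anthoquant.imaging import apply_calibration

specimens = generate_dataset(n=30, conc_range=(0.04, 0.33), seed=42)
rows = {}
for sp in specimens:
    cal = fit_two_point_calibration(sp.image, sp.rois["dark_standard"],
                                    sp.rois["light_standard"])
    stats = extract_roi_stats(apply_calibration(sp.image, cal), sp.rois["tissue"])
    rows[sp.sample_id] = compute_rgb_indices(stats.triplet, max_value=100.0)

wide = pd.DataFrame({sid: dict(s) for sid, s in rows.items()}).T
conc = pd.Series({sp.sample_id: sp.true_concentration for sp in specimens})
ranking = rank_indices(wide, conc.loc[wide.index])
print(ranking[["index", "r2", "p_holm", "sig_code", "best"]].head(5))
```

```
  index       r2       p_holm sig_code  best
S_green 0.995009 1.247622e-32      ***  True
      C 0.994505 4.454112e-32      *** False
  R:G_R 0.992558 2.875264e-30      *** False
  AC_CB 0.992350 3.882070e-30      *** False
  S_red 0.992320 3.882070e-30      *** False
```

`S_green` wins the ranking (r² = 0.995 after Holm control), consistent with
anthocyanins absorbing green light. Fitting concentration on `S_green` and
validating against 28 independent specimens:

```
best index: S_green  slope=-1.9184  intercept=0.6405  r2=0.995
validation: slope=1.033  t=2.774 (df=26)  r2=0.997  NRMSE=2.2%
```

The negative calibration slope says pigment-rich tissue has a weaker green
share; the observed-vs-predicted slope of 1.03 with NRMSE 2.2% shows the
calibration transfers to new samples.

The same workflow is available from the shell:

```bash
anthoquant simulate --n 30 --seed 42 -o outdir/
anthoquant calibrate --image outdir/syn000.tif --dark-roi 2,2,60,20 \
    --light-roi 66,2,60,20 -o cal.json
anthoquant extract --image outdir/syn000.tif --cal cal.json \
    --roi tissue.json -o stats.csv
anthoquant fit --indices stats.indices.csv --conc conc.csv -o fits.csv
```

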