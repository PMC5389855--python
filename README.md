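# wormquant

Quantification pipeline for *C. elegans* microscopy and lifespan studies:

* **HyPer redox imaging** — autofluorescence unmixing of lifetime-gated
  confocal stacks and per-worm 488/405 ratiometric quantification of the
  genetically encoded H₂O₂ biosensor HyPer, plus the plate-reader variant of
  the assay;
* **mitochondrial morphometry** — thresholded %-area of mitochondrial signal
  per intestinal cell from 5-slice maximum-intensity projections, with an
  optional Richardson–Lucy deconvolution preprocessing step;
* **Oil Red O densitometry** — fat-stain quantification from RGB brightfield
  images: pseudo flat-field correction, green-channel thresholding, and the
  integrated density inside a 40-pixel-diameter circle over the anterior
  intestine;
* **cohort statistics** — relative-fluorescence normalization against
  per-experiment controls, Welch/pooled t-tests and one-way ANOVA with
  Bonferroni correction, the Wilcoxon rank-sum lifespan test, survival
  summaries and scored-proportion comparisons;
* **synthetic scenes** — generators for all of the above with known ground
  truth, so each stage's parameter recovery is testable end to end.

It is aimed at labs doing ratiometric biosensor imaging or histology
densitometry in worms (or other small animals) who want the bespoke
ImageJ-style measurement chain as reproducible, tested library code.

## The unmixing model

Gut autofluorescence (AF) bleeds into each sensor channel. A dedicated
lifetime-gated AF channel (405ex 450–470em, 7–11.5 ns) contains no HyPer
signal, so the bleed is a fixed proportion per channel:

```
R = F_AF-in-sensor-channel / F_AF-in-AF-channel
F_HyPer = F_raw − R · F_AF          (pixel-wise)
redox ratio = F_HyPer(488ex) / F_HyPer(405ex)
```

R is fit through the origin over pixels pooled from control
(non-transgenic) animals, separately per experimental group:
`R = Σ F_target·F_AF / Σ F_AF²`. The per-worm readout is the ratio of sums
over a hand-drawn head ROI at the focal plane with the greatest combined
in-ROI fluorescence. The 488ex channel shows negligible autofluorescence
after lifetime gating and is not corrected by default.

## Worked example

```python
import numpy as np
from wormquant import (HyperSceneParams, RatioFieldSpec, make_hyper_scene,
                       estimate_af_ratio, subtract_autofluorescence, quantify_worm)

params = HyperSceneParams(ratio_field_spec=RatioFieldSpec("constant", 1.8), seed=1)
scene, controls = make_hyper_scene(params)          # truth: R = 0.35, ratio = 1.8

pairs = [(c.raw_stacks["405"], c.raw_stacks["af"]) for c in controls]
model = estimate_af_ratio(pairs, "405")
print(f"R = {model.r['405']:.4f}")                  # R = 0.3489

c405 = subtract_autofluorescence(scene.raw_stacks["405"], scene.raw_stacks["af"],
                                 model.r["405"])
res = quantify_worm(c405, scene.raw_stacks["488"], scene.roi.rois[0])
print(f"z = {res.z_selected}, ratio = {res.roi_ratio:.4f}")   # z = 3, ratio = 1.8004
```

The fitted bleed ratio lands within 0.3% of the generating value 0.35 under
Poisson noise, and the recovered per-worm redox ratio is within 0.03% of the
true 1.8 — i.e. the unmixing removes the AF bias that would otherwise
deflate the 405 denominator.

The same stages are available from the shell:

```
wormquant simulate hyper --seed 5 --out scene/
wormquant hyper-fit --controls controls/ --channel 405 --out model.json
wormquant hyper-quant --model model.json --stacks worms/ --rois rois.json --out results.csv
wormquant mito-area --stacks stacks/ --masks cells.json --threshold 500 --out areas.csv
wormquant oro-quant --images imgs/ --centers centers.csv --threshold 50 --out oro.csv
wormquant stats wilcoxon --table cohort.csv --control-group EV --out pvals.csv
```

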