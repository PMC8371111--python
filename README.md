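# limbusvd

Quantitative analysis of limbal vessel density (VD) on en-face
anterior-segment OCT-angiography (AS-OCTA) images, for studies of acute
ocular chemical injury.

Clinical grading of limbal ischemia after a chemical burn — the loss of
the perilimbal vascular arcades that predicts limbal stem cell failure —
is subjective on slit-lamp examination.  AS-OCTA images the limbal
vasculature directly, and vessel density gives it a number.  `limbusvd`
implements the full quantification chain for researchers running such
studies:

1. **Segmentation** — speckle denoising (median + Gaussian), multi-scale
   Frangi vesselness, local adaptive thresholding, small-component
   cleanup under a manual exclusion mask.
2. **Quadrant metrics** — VD per limbal quadrant (superior/inferior ×
   nasal/temporal, laterality-aware), defined as
   `VD = 100 · (vessel pixels in ROI) / (ROI pixels)` over a perilimbal
   annulus sector.
3. **Ischemia grading** — the percent of the limbal circumference whose
   angular VD falls below half a baseline reference, mapped onto grades
   I (0%), II (>0–<25%), III (25–<50%), IV (50–<75%), V (75–<100%),
   VI (100%).
4. **Longitudinal statistics** — injured-vs-control Student t-tests per
   timepoint, within-group one-way ANOVA with Bonferroni-adjusted
   baseline contrasts, and OLS of the per-eye day-1 VD sum on the number
   of injured quadrants (with Pearson r and a 95% CI on the slope).
5. **A synthetic limbal phantom** — branching Bézier arcade vessels with
   exact pixel-level ground truth, Gamma-speckle noise, per-segment
   vessel dropout in injured sectors, month-1 neovascular ingrowth, and
   calibration of any quadrant to a target true VD.  Every stage above
   is validated against it.

See `docs/methods.md` for the model, parameter choices and limitations.

## Worked example

A right eye whose superior-nasal quadrant was burned, imaged one day
post-injury, segmented and graded:

```python
import limbusvd as lv
from limbusvd.roi_geometry import all_quadrant_rois
from limbusvd.vessel_segmentation import SegmentationConfig

params = lv.SceneParams(seed=7)
injury = lv.InjurySpec.from_quadrants(("SN",), "OD", phase="day1")
scene = lv.generate_scene(params, injury)

vmap = lv.segment(scene.image, SegmentationConfig(), scene.exclusion_mask)
rois = all_quadrant_rois(params.annotation, scene.image.shape,
                         params.pixel_spacing_mm, "OD", scene.exclusion_mask)
for q in ("SN", "ST", "IN", "IT"):
    vd = lv.vessel_density(vmap, rois[q])
    print(f"{q}: measured VD {vd:5.2f}%   (true {scene.true_vd_by_quadrant[q]:5.2f}%)")
```

prints

```
SN: measured VD  1.68%   (true  2.97%)
ST: measured VD  8.40%   (true  8.72%)
IN: measured VD  7.93%   (true  9.43%)
IT: measured VD  9.56%   (true  9.80%)
```

The burned SN quadrant reads ~2–3% against ~8–10% in the three control
quadrants.  Grading the same eye against its uninjured baseline
(30° angular bins, drop threshold 0.5) yields

```
ischemia extent 33.3% of circumference -> grade III
```

and the summary-statistics group comparison at day 1 (injured
3.3 ± 2.4%, n = 28 vs control 7.6 ± 2.3%, n = 20) gives

```
day-1 injured vs control: t = -6.23, df = 46, p = 1.33e-07
```

i.e. the acute VD drop in injured quadrants is highly significant.

## Command line

```
limbusvd simulate --seed 1 --outdir sim/        # synthetic study + truth table
limbusvd segment --image eye.tiff --mask iris.png --out vessels.png
limbusvd quantify --scene-dir sim/ --outdir out/
limbusvd grade --ischemia-pct 30
limbusvd stats --records out/vd_records.csv --out report.json
limbusvd run --seed 1 --outdir out/             # end-to-end on the 12-eye design
```

All CSV/JSON outputs embed a hash of the configuration that produced
them; reruns with the same design, config and seed are byte-identical.

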