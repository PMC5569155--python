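# swequant

Quantitative shear-wave elastography (SWE) from saved ultrasound screen
captures.

## The problem

SWE maps tissue stiffness (Young's modulus *E*, in kPa) as a pseudocolour
overlay on the greyscale B-mode image. On Aixplorer-class systems the
clinical reading — place a 2 mm circular ROI at the stiffest point in terms
of *E*<sub>mean</sub> and report *E*<sub>max</sub>, *E*<sub>mean</sub> and SD
— is only possible while the exam is still on the device; once images move
to PACS as DICOM or JPG screen captures, the numbers are gone and only the
colours remain. That blocks long-term and multi-centre studies.

`swequant` recovers the numbers from the colours. The display renders the
jet palette at opacity α = 0.5 over an unknown B-mode grey *g*:

```
observed = α · c(E) + (1 − α) · (g, g, g)
```

The grey underlay shifts all channels equally, so the chroma signature
**d** = (R − G, G − B) of an observed pixel equals α times the chroma of the
pure palette colour — independent of *g*. Inversion is a nearest-neighbour
lookup in chroma space: exact on lossless captures, robust to JPEG noise,
and pixels with no overlay (zero chroma) are flagged missing. The
elastogram is located automatically via the white frame the device draws
around it; values above the 180 kPa display ceiling are recovered as
180 kPa, exactly as the display truncates them.

On top of the recovered maps the package implements the clinical
measurement routine (exhaustive 2 mm-ROI search maximising *E*<sub>mean</sub>,
per-lesion averaging over four images) and the diagnostic statistics used
to validate such pipelines: Se/Sp/accuracy at the clinical thresholds
(*E*<sub>max</sub> 80 kPa, *E*<sub>mean</sub> 50 kPa, SD 7 kPa), ROC/AUC,
Youden-optimal cutoffs, ICC(2,1) agreement between quantification routes,
and chi-square comparisons. A synthetic module generates ground-truthed
phantom images (three 11 mm spherical inclusions) and lesion cohorts so
everything is testable end to end without clinical data.

## Worked example

```bash
python examples/invert_screenshot.py
```

renders the default three-inclusion phantom (background 20 kPa, inclusions
45/80/140 kPa) as a framed screenshot, then reads it back:

```
frame interior      : FrameBox(top=14, left=14, bottom=214, right=314)
stiffest 2 mm ROI at: row 85, col 239
E_mean =  139.8 kPa   (stiffest inclusion is 140 kPa)
E_max  =  139.8 kPa
SD     =   0.00 kPa  over 81 pixels
lossless inversion exact vs quantized truth: True
```

The ROI lands inside the stiffest inclusion; 139.8 kPa is the 140 kPa
truth quantized to the colour-map grid (one step = 180/255 ≈ 0.71 kPa), and
on a lossless capture the inversion is bit-exact against the quantized
ground truth. Other examples cover palette calibration from paired exports
(`calibrate_colourmap.py`), cohort-level diagnostic performance
(`diagnostic_performance.py`) and batch quantification through a manifest
(`quantify_manifest.py`).

The same pipeline is available from the shell:

```bash
swequant render-fixtures --out fixtures/ --seed 0
swequant quantify --manifest fixtures/manifest.csv --out results/
swequant evaluate --lesions results/results_lesions.csv --out report/
swequant calibrate-lut --pairs pairs.csv --out lut.csv
```

## Layout

- `src/swequant/colourmap.py` — palette model, chroma-space inversion, calibration
- `src/swequant/segmentation.py` — white-frame detection and cropping
- `src/swequant/quantification.py` — circular-ROI sweep, statistics, clamping, aggregation
- `src/swequant/diagnostics.py` — Se/Sp/DA, ROC/AUC, Youden, ICC, chi-square, route comparison
- `src/swequant/synthetic.py` — phantom fields, speckle, screenshot renderer, cohort simulator
- `src/swequant/io.py` — DICOM/JPG/PNG readers, the open QDE-style matrix dialect, pipeline driver
- `src/swequant/cli.py` — thin command-line interface
- `docs/methods.md` — models, assumptions, numerical choices and limitations
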