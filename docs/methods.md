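# Methods

## Rendering model and inversion

A saved SWE screen capture shows, per elastogram pixel, the alpha blend of
a palette colour with the B-mode grey underneath:

    observed = α · c(E) + (1 − α) · (g, g, g),    α = 0.5 by default.

`c(E)` is a jet-family lookup table (LUT) over the display range
(0–180 kPa, 256 entries by default). The underlay `g` is unknown and varies
per pixel, but it adds equally to all three channels, so the chroma
signature d = (R − G, G − B) of an observed pixel satisfies
d = α · (chroma of c(E)) regardless of `g`. Inversion finds the LUT entry
whose scaled chroma is nearest (Euclidean) to the observed one. The metric
lives in chroma space rather than RGB space precisely because that cancels
the underlay analytically; ties resolve to the lower stiffness (a
conservative, deterministic reading). Pixels whose chroma magnitude is at
most `chroma_tolerance` (default 3/255 — one 8-bit quantization step per
channel plus margin) are effectively greyscale, meaning no overlay was
rendered there; they are flagged missing, not given a value.

The default LUT is the classic piecewise-linear jet trajectory (dark blue →
blue → cyan → green → yellow → red → dark red; each channel a trapezoid of
ramp slope 4), evaluated in closed form and snapped to the 8-bit grid. The
closed form is used deliberately: some common library renderings of jet
contain a short flat plateau at pure blue, which would make several LUT
entries share a chroma signature and break invertibility. LUT validity is
enforced as an invariant: strictly increasing stiffness spanning the
display range, components in [0, 1], all chroma signatures pairwise
distinct and bounded away from zero.

Exactness on lossless captures is an arithmetic property of the whole
chain, not luck: with 8-bit LUT colours, α = 0.5, and round-half-up
quantization of the blend, the per-component chroma error introduced by the
8-bit screen grid is at most 0.5/255, while the minimum spacing between
adjacent blended chromas of the 256-entry jet LUT is 3/(2·255). The nearest
neighbour is therefore always the rendered entry, for every background
grey — which is what makes inversion bitwise independent of the B-mode
underlay and makes lossless round trips exact. Under ±1/255 per-channel
perturbation (worst-case 8-bit noise) the recovered entry can move by up to
4 LUT steps (≈ 2.8 kPa) near corners of the chroma path; JPEG compression
adds more, which the test suite bounds by regression on fixed fixtures.

Because the display cannot encode values above its ceiling, anything
stiffer than 180 kPa renders as — and is recovered as — exactly 180 kPa.
Inversion never extrapolates beyond the display range.

## Palette calibration

When pixel-aligned pairs of (screen capture, directly exported elasticity
matrix) are available, `calibrate_lut` derives a device-faithful palette
instead of assuming the default: truth pixels are binned to the stiffness
grid, each bin's map chroma is the per-component median of observed chromas
divided by α (the median is robust to compression noise and the underlay
cancels exactly), and unsupported bins are filled by linear interpolation.
A support gap wider than a configurable fraction of the range (default
0.25) aborts with an error naming the gap, since interpolating across it
would be guesswork.

Blended pixels constrain only the chroma of an entry, never its absolute
brightness — any grey offset added to a colour is invisible after blending.
The reconstruction therefore anchors each entry's grey level on the densely
sampled jet trajectory (nearest-chroma anchor) and imposes the measured
chroma exactly. Measured chroma is authoritative for inversion; the jet
anchor only supplies the physically unidentifiable brightness. Calibrated
LUTs accept a smaller chroma-separation margin than constructed ones,
because per-bin measurement noise can push adjacent entries closer together
without ever making them coincide.

## Frame segmentation

The device surrounds the elastogram with a thin white frame; segmentation
binarizes the capture at a whiteness threshold on the darkest channel,
labels white components, and looks for components enclosing a large
rectangular hole (fill-holes minus the component). The hole — the
elastogram interior, frame pixels excluded — must cover at least 5% of the
image and at least 95% of its own bounding box. When the dual display shows
a second framed B-mode panel below, the uppermost qualifying box wins (the
SWE panel is conventionally on top). Coordinates are 0-based, half-open,
everywhere.

The whiteness threshold defaults to 0.85 (217/255). The natural-seeming
235/255 fails in practice: under JPEG at quality 85 the innermost line of a
1–3 px frame dips to ≈222–230 and the ring breaks. At 0.85 a sweep of 240
synthetic cases (15 fields × quality 85/90 × thickness 1–4 × with/without
second panel) shows pixel-perfect recovery lossless and ≤1 px/edge error
under JPEG, with the threshold still comfortably above B-mode speckle
(generator ceiling 0.80). A 3×3 binary-closing fallback pass bridges
residual hairline breaks before giving up; manual `FrameBox` override
remains available for nonstandard layouts.

## ROI sweep and lesion statistics

The clinical routine is reproduced literally: a circular ROI of 2 mm
diameter (pixels whose centres lie within the radius of the centre pixel's
centre) is evaluated at every position where its full footprint fits inside
the map, and the position maximising E_mean wins. Full-footprint placement
mirrors how an operator drags a fixed circle; partial border ROIs are not
candidates. Missing pixels inside a candidate ROI are excluded from the
statistics rather than disqualifying it, but a candidate must retain at
least 50% valid pixels (configurable). Ties in E_mean break to the earliest
row-major centre, making runs bit-reproducible.

The implementation scans by exact discrete correlation and then recomputes
the statistics of near-maximal candidates pixel-by-pixel, so the returned
numbers are bit-identical to a naive per-centre evaluation (the test suite
asserts this against an independent brute-force oracle on 100 random maps).
SD uses the population divisor n by default; the device's convention is
unpublished, so the divisor is switchable (`sd_ddof`). Per-lesion values
are the arithmetic mean over up to four images; fewer than four triggers a
warning, more is an error. User-supplied exclusion masks support manual
artefact removal; automatic artefact/pectoral-muscle exclusion is out of
scope.

## Diagnostic statistics

A lesion is called positive when its parameter exceeds the threshold
(strictly greater by default; the comparator is switchable since cited
thresholds do not state it). Sensitivity, specificity and diagnostic
accuracy are reported in percent, with NaN rather than an exception for
empty denominators. ROC curves place thresholds at every distinct value;
the trapezoidal AUC then equals the tie-corrected Mann–Whitney concordance
(asserted against a brute-force pairwise oracle). Youden's J = Se + Sp − 1
is maximised over midpoints between adjacent distinct sorted values, ties
to the smallest cutoff.

Between-route agreement uses the two-way random-effects,
absolute-agreement, single-measure ICC — ICC(2,1) — computed from the
two-way ANOVA mean squares; this is the conventional method-comparison
form, and consistency/average-measure variants are available. Proportions
are compared with the plain Pearson chi-square (no continuity correction)
at the 5% level, significance inclusive at p = α; McNemar's test is
provided as an option, being the statistically preferable choice when the
two routes rate the same lesions.

When routes that saturate at the display ceiling are compared with routes
that do not, E_max and E_mean of *all* routes are clamped to the ceiling
first (`apply_display_adjustment`); SD receives no such adjustment — lost
within-ROI spread cannot be restored — which is exactly why SD agreement
and SD-based discrimination suffer on display-limited routes.

## Synthetic data: what it emulates, and what it does not

`make_elasticity_field` rasterizes circular inclusions (spherical
inclusions imaged through their centres) over a uniform background, with an
optional logistic edge profile and multiplicative heterogeneity. The
default scene mirrors a commercial breast elasticity phantom: three 11 mm
inclusions (45, 80, 140 kPa) in a 20 kPa background, 0.2 mm pixels.
Overlapping inclusions are rejected to keep the ground truth unambiguous.
`make_bmode` produces low-pass-filtered speckle in [0.05, 0.80].
`render_screenshot` quantizes the truth to the LUT grid, blends with the
speckle at the LUT opacity using round-half-up 8-bit quantization, draws
the white frame (and optionally the second framed B-mode panel below), and
can encode losslessly or as JPEG. JPEG uses 4:4:4 chroma sampling: the
generator models DCT quantization noise, not chroma subsampling, under
which a 1-px frame beside saturated colour is unrecoverable by any
detector.

`make_cohort` simulates a lesion cohort at the study scale (70 benign, 137
malignant; four image replicates per lesion with multiplicative
within-lesion noise, then averaged). Class distributions are log-normal —
elasticity values are positive and right-skewed — with medians chosen so
that the clinical thresholds (80/50/7 kPa) sit between the class centres
and a realistic fraction of malignant lesions exceeds the 180 kPa ceiling.
Each route applies a bias, additive noise, optional clamping at its
ceiling, and optional quantization to the colour-map step; the
screen-capture routes' biases (+2/+4 kPa DICOM, +6/+7 kPa JPG for
E_max/E_mean) follow phantom-measured offsets. Clamped routes additionally
shrink SD by (ceiling / true E_max)^κ for lesions whose true E_max exceeds
the ceiling, modelling the loss of within-ROI spread when the top of the
range is flattened; this, plus larger SD noise on compressed routes, is the
generator's mechanism for the empirically observed SD degradation.

What passing tests on this generator shows: the inversion, segmentation,
ROI and statistics machinery is correct under the stated rendering model.
What it does not show: robustness to real-device UI clutter (colour bars,
annotations), device-specific smoothing, chroma-subsampled JPEG, non-jet
palettes, or the clinical distributions themselves. Real captures with
unusual layouts are supported through the manual frame override and
per-device calibration, not guaranteed by these tests.

## Numerical choices and problem sizes

- Tie-breaks: LUT inversion → lower stiffness; ROI sweep → earliest
  row-major centre; Youden → smallest cutoff. All deterministic.
- Disc membership uses a 1e-9 tolerance on the radius comparison so pixels
  exactly on the circle are included, matching integer lattice counts
  (an 11 mm disc at 0.1 mm spacing contains 9477 pixels).
- The QDE-style matrix dialect (three header lines: rows, cols,
  pixel_spacing_mm; −1 as missing sentinel) is an open stand-in defined by
  this package; the vendor's research export format is proprietary and is
  not reverse-engineered.
- All generators and the pipeline are bit-reproducible given a seed;
  result CSVs embed a hash of the configuration that produced them.
- The test suite and acceptance script run on scaled inputs chosen for
  quick iteration — 40×40 maps for oracle equivalence (100 seeds), 50
  segmentation fixtures, a 207-lesion simulated cohort — sizes at which
  every oracle comparison is exhaustive.

## Known limitations

- The exact vendor LUT (entry count, endpoint colours) is unpublished; the
  jet default is a reconstruction, and device-faithful use requires
  `calibrate_lut` on paired exports.
- Agreement with any specific statistics package's ICC output depends on
  that package's chosen ICC form; only ICC(2,1) semantics are claimed.
- No colour management (ICC display profiles), no per-pixel opacity
  variation, no OCR of on-screen annotation, no cine loops (first frame
  only), no PACS networking, no DICOM writing.
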