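"""Derive a device-faithful colour map from paired exports.

When direct quantitative exports exist alongside saved screen captures,
the palette can be calibrated instead of assumed: pixels are binned by
true stiffness and each bin's chroma (R-G, G-B) is estimated robustly.
Here the pairs are synthesized from the default jet palette, so the
calibration should return it (within one 8-bit step per channel).
"""

import numpy as np

import swequant as sq

lut = sq.build_default_lut()
rng = np.random.default_rng(0)

pairs = []
for seed in range(2):
    vals = rng.uniform(0, 180, (120, 160))
    field = sq.ElasticityMap(vals, np.zeros_like(vals, bool), 0.2, 300.0)
    bmode = sq.make_bmode(field.shape, seed=seed)
    capture, truth = sq.render_screenshot(field, bmode)
    region = sq.crop(capture, truth.frame_box)
    pairs.append((region, truth.quantized_map))

calibrated = sq.calibrate_lut(pairs)
err = np.abs(calibrated.rgb - lut.rgb).max()
print(f"calibrated LUT: {calibrated.n_entries} entries over "
      f"[{calibrated.display_min:.0f}, {calibrated.display_max:.0f}] kPa")
print(f"max per-channel deviation from the generating palette: {err * 255:.2f}/255")

# the calibrated palette inverts a held-out render to the colour-map grid
vals = rng.uniform(0, 180, (80, 100))
field = sq.ElasticityMap(vals, np.zeros_like(vals, bool), 0.2, 300.0)
capture, truth = sq.render_screenshot(field, sq.make_bmode(field.shape, seed=9))
rec = sq.invert_image(sq.crop(capture, truth.frame_box), calibrated, pixel_spacing_mm=0.2)
mae = np.abs(rec.values - truth.quantized_map.values).mean()
print(f"held-out inversion mean abs error: {mae:.3f} kPa "
      f"(one colour-map step = {180 / 255:.3f} kPa)")
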