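"""Recover elasticity values from a rendered SWE screen capture.

Builds the default three-inclusion phantom, renders it as a framed
device-style screenshot (jet colours at 50% opacity over speckle),
then runs the offline reading: frame detection, colour-map inversion,
and the exhaustive 2 mm ROI search for the stiffest point.
"""

import numpy as np

import swequant as sq

scene = sq.PhantomScene()
field = sq.make_elasticity_field(scene, edge_width_mm=0.3)
bmode = sq.make_bmode(field.shape, seed=0)
capture, truth = sq.render_screenshot(field, bmode, second_panel=True)

box = sq.detect_frame(capture)
region = sq.crop(capture, box)
lut = sq.build_default_lut()
recovered = sq.invert_image(region, lut, pixel_spacing_mm=capture.pixel_spacing_mm)

roi = sq.sweep_roi(recovered, diameter_mm=2.0)
print(f"frame interior      : {box}")
print(f"stiffest 2 mm ROI at: row {roi.centre_rc[0]}, col {roi.centre_rc[1]}")
print(f"E_mean = {roi.e_mean:6.1f} kPa   (stiffest inclusion is 140 kPa)")
print(f"E_max  = {roi.e_max:6.1f} kPa")
print(f"SD     = {roi.sd:6.2f} kPa  over {roi.n_pixels} pixels")

exact = np.array_equal(
    recovered.values[~recovered.missing], truth.quantized_map.values[~truth.quantized_map.missing]
)
print(f"lossless inversion exact vs quantized truth: {exact}")
# The ROI lands inside the 140 kPa inclusion; E_mean sits at the truth value
# quantized to the 180/255 kPa colour-map grid.
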