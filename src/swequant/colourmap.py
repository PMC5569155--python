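"""Colour-map model and inversion for shear-wave-elastography screen captures.

The Aixplorer-class display encodes Young's modulus (kPa) through a jet-style
pseudocolour palette rendered at partial opacity over the greyscale B-mode
image.  A saved screen capture therefore contains, per pixel,

    observed = alpha * map_colour(E) + (1 - alpha) * (g, g, g)

with ``g`` the unknown B-mode grey underneath.  Because the grey underlay
shifts all three channels equally, the chroma signature

    d = (R - G, G - B)

of the observed pixel equals ``alpha`` times the chroma of the pure map
colour, independent of ``g``.  Inversion is therefore a nearest-neighbour
lookup in chroma space: exact for lossless captures, robust for lossy ones.
Pixels that carry no elasticity overlay are (near-)greyscale, have chroma
close to zero, and are flagged missing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .quantification import ElasticityMap

__all__ = [
    "ColourLUT",
    "CalibrationError",
    "DEFAULT_CHROMA_TOLERANCE",
    "jet_colours",
    "build_default_lut",
    "blend_pixel",
    "invert_pixel",
    "invert_image",
    "calibrate_lut",
]

#: Default chroma-magnitude cut below which a pixel is treated as greyscale
#: (no elasticity signal): one 8-bit quantization step per channel plus margin.
DEFAULT_CHROMA_TOLERANCE = 3.0 / 255.0

#: Minimum Euclidean separation required between the chroma signatures of any
#: two LUT entries for the palette to be considered invertible.
MIN_CHROMA_SEPARATION = 1.0 / 255.0


class CalibrationError(ValueError):
    """Raised when paired data cannot support a colour-map calibration."""


def jet_colours(x: np.ndarray) -> np.ndarray:
    """Evaluate the classic jet trajectory (dark blue -> blue -> cyan ->
    green -> yellow -> red -> dark red) at positions ``x`` in [0, 1].

    This is the piecewise-linear palette popularised by MATLAB: each channel
    is a trapezoid with ramp slope 4, the ramps meeting end-to-end so the
    colour (and its chroma) changes strictly monotonically along the path.
    Returns an ``(..., 3)`` float array of unit-scale RGB.
    """
    x = np.asarray(x, dtype=float)
    r = np.clip(np.minimum(4.0 * x - 1.5, -4.0 * x + 4.5), 0.0, 1.0)
    g = np.clip(np.minimum(4.0 * x - 0.5, -4.0 * x + 3.5), 0.0, 1.0)
    b = np.clip(np.minimum(4.0 * x + 0.5, -4.0 * x + 2.5), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


@dataclass
class ColourLUT:
    """Ordered stiffness -> RGB lookup table with a blending opacity.

    ``rgb`` holds the colour of the *fully opaque* palette at each stiffness;
    what appears on screen is that colour alpha-blended with the B-mode grey.

    Invariants (enforced by :meth:`validate`): stiffness strictly increasing
    and spanning the display range; RGB components in [0, 1]; the chroma
    signatures (R-G, G-B) of all entries pairwise distinct and bounded away
    from zero, which is what makes the palette invertible under blending.
    """

    stiffness: np.ndarray
    rgb: np.ndarray
    opacity: float = 0.5
    name: str = "jet-default"
    min_chroma_separation: float = MIN_CHROMA_SEPARATION

    def __post_init__(self) -> None:
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        self.rgb = np.asarray(self.rgb, dtype=float)
        self.validate()

    # -- derived views -----------------------------------------------------
    @property
    def n_entries(self) -> int:
        return int(self.stiffness.shape[0])

    @property
    def display_min(self) -> float:
        return float(self.stiffness[0])

    @property
    def display_max(self) -> float:
        return float(self.stiffness[-1])

    @property
    def chroma(self) -> np.ndarray:
        """(n_entries, 2) array of (R-G, G-B) signatures of the pure colours."""
        return np.stack(
            [self.rgb[:, 0] - self.rgb[:, 1], self.rgb[:, 1] - self.rgb[:, 2]],
            axis=1,
        )

    def validate(self) -> None:
        if self.stiffness.ndim != 1 or self.rgb.ndim != 2 or self.rgb.shape[1] != 3:
            raise ValueError("LUT must be 1-D stiffness with matching (n, 3) rgb")
        if self.stiffness.shape[0] != self.rgb.shape[0]:
            raise ValueError("stiffness and rgb lengths differ")
        if self.stiffness.shape[0] < 2:
            raise ValueError("LUT needs at least 2 entries")
        if not np.all(np.diff(self.stiffness) > 0):
            raise ValueError("stiffness must be strictly increasing")
        if np.any(self.rgb < 0) or np.any(self.rgb > 1):
            raise ValueError("rgb components must lie in [0, 1]")
        if not 0 < self.opacity <= 1:
            raise ValueError("opacity must be in (0, 1]")
        ch = self.chroma
        norms = np.linalg.norm(ch, axis=1)
        if np.any(norms <= self.min_chroma_separation):
            raise ValueError("LUT contains a (near-)greyscale entry; not invertible")
        # pairwise distinctness of chroma signatures
        diff = ch[:, None, :] - ch[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() < self.min_chroma_separation:
            raise ValueError(
                "LUT chroma signatures are not pairwise distinct; not invertible"
            )

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as CSV with header ``stiffness_kpa,r,g,b`` (unit floats)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stiffness_kpa", "r", "g", "b"])
            for s, (r, g, b) in zip(self.stiffness, self.rgb):
                writer.writerow([repr(float(s)), repr(float(r)), repr(float(g)), repr(float(b))])

    @classmethod
    def from_csv(cls, path, opacity: float = 0.5, name: str | None = None) -> "ColourLUT":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["stiffness_kpa", "r", "g", "b"]:
                raise ValueError(f"{path}: expected header 'stiffness_kpa,r,g,b'")
            rows = [[float(v) for v in row] for row in reader if row]
        arr = np.asarray(rows, dtype=float)
        return cls(
            stiffness=arr[:, 0],
            rgb=arr[:, 1:4],
            opacity=opacity,
            name=name or str(path),
        )


def build_default_lut(
    n_entries: int = 256,
    display_min: float = 0.0,
    display_max: float = 180.0,
    opacity: float = 0.5,
) -> ColourLUT:
    """Construct the default jet LUT over the display range.

    Colours are snapped to the 8-bit grid (multiples of 1/255), matching how
    a device palette is actually stored and making lossless round trips exact.
    """
    if n_entries < 2:
        raise ValueError("n_entries must be >= 2")
    if not display_min < display_max:
        raise ValueError("display_min must be < display_max")
    x = np.linspace(0.0, 1.0, n_entries)
    rgb = np.round(jet_colours(x) * 255.0) / 255.0
    stiffness = np.linspace(display_min, display_max, n_entries)
    return ColourLUT(stiffness=stiffness, rgb=rgb, opacity=opacity)


def blend_pixel(map_rgb, background_grey: float, alpha: float) -> np.ndarray:
    """Alpha-blend a palette colour over a grey underlay.

    Returns ``alpha * map_rgb + (1 - alpha) * (g, g, g)`` clipped to [0, 1].
    """
    c = np.asarray(map_rgb, dtype=float)
    if c.shape[-1] != 3:
        raise ValueError("map_rgb must have 3 components")
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("map_rgb components must lie in [0, 1]")
    if not 0 <= background_grey <= 1:
        raise ValueError("background_grey must lie in [0, 1]")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    out = alpha * c + (1.0 - alpha) * background_grey
    return np.clip(out, 0.0, 1.0)


def _observed_chroma(rgb: np.ndarray) -> np.ndarray:
    return np.stack([rgb[..., 0] - rgb[..., 1], rgb[..., 1] - rgb[..., 2]], axis=-1)

def invert_pixel(
    observed_rgb,
    lut: ColourLUT,
    chroma_tolerance: float = DEFAULT_CHROMA_TOLERANCE,
) -> float:
    """Recover the stiffness encoded by one observed screen pixel.

    Returns the stiffness (kPa) of the LUT entry whose blended chroma is
    nearest to the observed chroma, or ``nan`` if the pixel is effectively
    greyscale (chroma magnitude <= ``chroma_tolerance``), meaning no
    elasticity overlay was rendered there.  Ties go to the lower stiffness.
    """
    obs = np.asarray(observed_rgb, dtype=float)
    if obs.shape != (3,):
        raise ValueError("observed_rgb must be a single RGB triple")
    if np.any(obs < 0) or np.any(obs > 1):
        raise ValueError("observed_rgb components must lie in [0, 1]")
    if chroma_tolerance < 0:
        raise ValueError("chroma_tolerance must be non-negative")
    d = _observed_chroma(obs)
    if np.linalg.norm(d) <= chroma_tolerance:
        return float("nan")
    target = lut.opacity * lut.chroma
    dist2 = ((target - d) ** 2).sum(axis=1)
    # argmin returns the first minimum -> lower stiffness on exact ties
    return float(lut.stiffness[int(np.argmin(dist2))])


def invert_image(
    capture_region: np.ndarray,
    lut: ColourLUT,
    chroma_tolerance: float = DEFAULT_CHROMA_TOLERANCE,
    pixel_spacing_mm: float | None = None,
) -> ElasticityMap:
    """Invert a cropped elastogram region (H, W, 3) back to an elasticity map.

    ``capture_region`` may be 8-bit (0..255) or unit floats.  Pixels whose
    chroma magnitude is within ``chroma_tolerance`` are marked missing.
    """
    region = np.asarray(capture_region)
    if region.ndim != 3 or region.shape[-1] != 3 or region.size == 0:
        raise ValueError("capture_region must be a non-empty (H, W, 3) array")
    if region.dtype.kind in "ui":
        region = region.astype(float) / 255.0
    else:
        region = region.astype(float)
    if chroma_tolerance < 0:
        raise ValueError("chroma_tolerance must be non-negative")

    h, w, _ = region.shape
    d = _observed_chroma(region).reshape(-1, 2)
    target = lut.opacity * lut.chroma  # (n, 2)
    values = np.empty(h * w, dtype=float)
    missing = np.linalg.norm(d, axis=1) <= chroma_tolerance

    # chunked nearest-neighbour search keeps the distance matrix small
    chunk = 8192
    stiff = lut.stiffness
    for start in range(0, d.shape[0], chunk):
        block = d[start : start + chunk]
        dist2 = ((block[:, None, :] - target[None, :, :]) ** 2).sum(-1)
        values[start : start + chunk] = stiff[np.argmin(dist2, axis=1)]
    values[missing] = np.nan

    return ElasticityMap(
        values=values.reshape(h, w),
        missing=missing.reshape(h, w),
        pixel_spacing_mm=pixel_spacing_mm,
        value_ceiling=lut.display_max,
    )


def calibrate_lut(
    paired,
    n_entries: int = 256,
    opacity: float = 0.5,
    display_min: float = 0.0,
    display_max: float = 180.0,
    gap_fraction: float = 0.25,
) -> ColourLUT:
    """Derive a device-faithful LUT from pixel-aligned (capture, truth) pairs.

    This mirrors how an adjusted palette is obtained in practice: directly
    exported elasticity matrices are compared with the rendered captures.
    Truth pixels are binned to the ``n_entries`` stiffness grid; each bin's
    map chroma is the per-component median of observed chromas divided by
    ``opacity`` (the grey underlay cancels in the chroma, so no background
    model is needed).  Unsupported bins are filled by linear interpolation;
    a support gap wider than ``gap_fraction`` of the display range raises
    :class:`CalibrationError`.

    Blended pixels fix only the chroma of an entry, never its absolute
    brightness, so the grey level of each entry is anchored on the densely
    sampled jet trajectory (nearest-chroma anchor) while the measured chroma
    is imposed exactly.
    """
    if n_entries < 2:
        raise ValueError("n_entries must be >= 2")
    if not paired:
        raise CalibrationError("at least one (capture, truth) pair is required")

    stiffness = np.linspace(display_min, display_max, n_entries)
    step = (display_max - display_min) / (n_entries - 1)

    chroma_lists: list[list[np.ndarray]] = [[] for _ in range(n_entries)]
    for region, truth in paired:
        rgb = np.asarray(region)
        if rgb.dtype.kind in "ui":
            rgb = rgb.astype(float) / 255.0
        vals = np.asarray(truth.values, dtype=float)
        valid = ~np.asarray(truth.missing, dtype=bool)
        if rgb.shape[:2] != vals.shape:
            raise CalibrationError("capture region and truth map shapes differ")
        idx = np.clip(
            np.round((np.clip(vals, display_min, display_max) - display_min) / step),
            0,
            n_entries - 1,
        ).astype(int)
        d = _observed_chroma(rgb)
        for k in np.unique(idx[valid]):
            sel = valid & (idx == k)
            chroma_lists[k].append(d[sel])

    measured = np.full((n_entries, 2), np.nan)
    for k, chunks in enumerate(chroma_lists):
        if chunks:
            allc = np.concatenate(chunks, axis=0)
            measured[k] = np.median(allc, axis=0) / opacity

    supported = ~np.isnan(measured[:, 0])
    if not supported.any():
        raise CalibrationError("no bin received any supporting pixels")
    # gap rule: longest run of unsupported bins, in stiffness units
    run, longest, gap_at = 0, 0, 0
    for k, ok in enumerate(supported):
        run = 0 if ok else run + 1
        if run > longest:
            longest, gap_at = run, k - run + 1
    # unsupported ends count as gaps too
    if longest * step > gap_fraction * (display_max - display_min):
        lo = stiffness[gap_at]
        hi = stiffness[min(gap_at + longest - 1, n_entries - 1)]
        raise CalibrationError(
            f"insufficient coverage: no pixels between {lo:.1f} and {hi:.1f} kPa"
        )

    # fill unsupported bins by interpolation over stiffness (ends -> nearest)
    sup_idx = np.flatnonzero(supported)
    for comp in range(2):
        measured[:, comp] = np.interp(
            np.arange(n_entries), sup_idx, measured[sup_idx, comp]
        )

    # anchor brightness on the jet family, impose measured chroma exactly
    dense_x = np.linspace(0.0, 1.0, 4096)
    dense_rgb = jet_colours(dense_x)
    dense_ch = np.stack(
        [dense_rgb[:, 0] - dense_rgb[:, 1], dense_rgb[:, 1] - dense_rgb[:, 2]], axis=1
    )
    rgb = np.empty((n_entries, 3))
    for k in range(n_entries):
        a, b = measured[k]
        anchor = int(np.argmin(((dense_ch - measured[k]) ** 2).sum(1)))
        g0 = dense_rgb[anchor, 1]
        rgb[k] = np.clip([g0 + a, g0, g0 - b], 0.0, 1.0)

    # measurement noise can push adjacent measured chromas closer than the
    # default separation; entries stay strictly distinct and ties resolve
    # deterministically, so a relaxed separation is accepted for calibrated LUTs
    lut = ColourLUT(
        stiffness=stiffness,
        rgb=rgb,
        opacity=opacity,
        name="calibrated",
        min_chroma_separation=MIN_CHROMA_SEPARATION / 8.0,
    )
    return lut
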