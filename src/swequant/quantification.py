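"""Clinical measurement routine on recovered elasticity maps.

Implements the standard quantitative SWE reading: a fixed 2 mm circular
region of interest is swept exhaustively across the elastogram, the position
maximising the mean elasticity E_mean is retained, and E_max, E_mean and the
standard deviation SD are reported from that ROI.  Per-lesion values are the
arithmetic mean over up to four images (two orthogonal planes, two images
each).  Display-range clamping (values above 180 kPa are shown, and hence
recovered, as 180 kPa) is modelled explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ElasticityMap",
    "ROIResult",
    "LesionRecord",
    "UncomputableROIError",
    "circular_offsets",
    "roi_stats",
    "sweep_roi",
    "clamp_to_display",
    "aggregate_lesion",
    "render_roi_overlay",
]


class UncomputableROIError(ValueError):
    """Raised when a ROI contains no valid (non-missing, non-excluded) pixel."""


@dataclass
class ElasticityMap:
    """A 2-D elasticity field in kPa with a missing-data mask.

    ``value_ceiling`` records the largest value the source can encode:
    180 kPa for maps recovered from the colour display, 300 kPa for direct
    quantitative exports.  Missing cells (no SWE signal) hold NaN.
    """

    values: np.ndarray
    missing: np.ndarray | None = None
    pixel_spacing_mm: float | None = None
    value_ceiling: float = 180.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape must match values")
        if self.pixel_spacing_mm is not None and not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        ok = self.values[~self.missing]
        if ok.size and (np.nanmin(ok) < -1e-9 or np.nanmax(ok) > self.value_ceiling + 1e-9):
            raise ValueError("non-missing values must lie in [0, value_ceiling]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ROIResult:
    """Winning circular ROI and its elasticity statistics."""

    centre_rc: tuple[int, int]
    diameter_mm: float
    e_mean: float
    e_max: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (0 <= self.e_mean <= self.e_max + 1e-9):
            raise ValueError("need 0 <= e_mean <= e_max")


@dataclass
class LesionRecord:
    """Per-lesion aggregate over up to four per-image ROI results."""

    lesion_id: str
    pathology: str
    per_image: list
    e_max: float = field(init=False)
    e_mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.pathology not in ("benign", "malignant"):
            raise ValueError("pathology must be 'benign' or 'malignant'")
        if not self.per_image:
            raise ValueError("per_image must be non-empty")
        self.e_max = float(np.mean([r.e_max for r in self.per_image]))
        self.e_mean = float(np.mean([r.e_mean for r in self.per_image]))
        self.sd = float(np.mean([r.sd for r in self.per_image]))


def circular_offsets(diameter_mm: float, pixel_spacing_mm: float) -> np.ndarray:
    """Integer (dr, dc) offsets of pixels whose centres lie within the circle.

    A pixel belongs to the ROI when its centre is within ``diameter_mm / 2``
    of the centre pixel's centre.  Offsets are returned sorted row-major;
    (0, 0) is always included.  A spacing larger than the radius yields the
    single-pixel mask.
    """
    if diameter_mm <= 0 or pixel_spacing_mm <= 0:
        raise ValueError("diameter_mm and pixel_spacing_mm must be positive")
    r_px = (diameter_mm / 2.0) / pixel_spacing_mm
    rr = int(np.floor(r_px))
    dr, dc = np.mgrid[-rr : rr + 1, -rr : rr + 1]
    inside = dr * dr + dc * dc <= r_px * r_px + 1e-12
    return np.stack([dr[inside], dc[inside]], axis=1)


def _valid_mask(emap: ElasticityMap, exclusion: np.ndarray | None) -> np.ndarray:
    valid = ~emap.missing
    if exclusion is not None:
        excl = np.asarray(exclusion, dtype=bool)
        if excl.shape != emap.shape:
            raise ValueError("exclusion mask shape must match the map")
        valid &= ~excl
    return valid


def roi_stats(
    emap: ElasticityMap,
    centre_rc: tuple[int, int],
    offsets: np.ndarray,
    exclusion: np.ndarray | None = None,
    diameter_mm: float | None = None,
    sd_ddof: int = 0,
) -> ROIResult:
    """Elasticity statistics over one circular ROI.

    ``sd`` uses the population divisor n by default (``sd_ddof=0``); the
    device convention is unpublished, so the divisor is switchable.
    Missing or excluded pixels are dropped from the statistics.
    """
    r, c = centre_rc
    h, w = emap.shape
    rows = offsets[:, 0] + r
    cols = offsets[:, 1] + c
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise ValueError("ROI footprint extends outside the map")
    valid = _valid_mask(emap, exclusion)
    ok = valid[rows, cols]
    if not ok.any():
        raise UncomputableROIError(f"ROI at {centre_rc} has no valid pixel")
    vals = emap.values[rows[ok], cols[ok]]
    return ROIResult(
        centre_rc=(int(r), int(c)),
        diameter_mm=float(diameter_mm) if diameter_mm is not None else float("nan"),
        e_mean=float(np.mean(vals)),
        e_max=float(np.max(vals)),
        sd=float(np.std(vals, ddof=sd_ddof)),
        n_pixels=int(ok.sum()),
    )


def sweep_roi(
    emap: ElasticityMap,
    diameter_mm: float = 2.0,
    exclusion: np.ndarray | None = None,
    min_valid_fraction: float = 0.5,
    sd_ddof: int = 0,
) -> ROIResult:
    """Exhaustive search for the circular ROI maximising E_mean.

    Every centre whose full circular footprint lies inside the map is a
    candidate, provided at least ``min_valid_fraction`` of its pixels are
    valid.  Ties in E_mean are broken by the earliest row-major centre,
    making runs bit-reproducible.

    The scan uses an exact discrete correlation to locate the maximum, then
    recomputes the statistics of near-maximal candidates with
    :func:`roi_stats` so the returned numbers are bit-identical to a naive
    per-centre evaluation.
    """
    if emap.pixel_spacing_mm is None:
        raise ValueError("map has no pixel spacing; cannot size the ROI")
    offsets = circular_offsets(diameter_mm, emap.pixel_spacing_mm)
    h, w = emap.shape
    rr = int(np.abs(offsets).max()) if offsets.size else 0
    if h - 2 * rr <= 0 or w - 2 * rr <= 0:
        raise UncomputableROIError("map is smaller than the ROI footprint")

    valid = _valid_mask(emap, exclusion)
    kernel = np.zeros((2 * rr + 1, 2 * rr + 1))
    kernel[offsets[:, 0] + rr, offsets[:, 1] + rr] = 1.0
    vals = np.where(valid, emap.values, 0.0)
    counts = ndimage.correlate(valid.astype(float), kernel, mode="constant", cval=0.0)
    sums = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)

    n_off = offsets.shape[0]
    interior = np.zeros((h, w), dtype=bool)
    interior[rr : h - rr, rr : w - rr] = True
    candidate = interior & (counts >= min_valid_fraction * n_off - 1e-9) & (counts > 0)
    if not candidate.any():
        raise UncomputableROIError("no candidate ROI centre (too much missing data)")

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(candidate, sums / counts, -np.inf)
    m = mean.max()
    tol = 1e-9 * max(1.0, abs(m))
    near = np.argwhere(mean >= m - tol)  # row-major order from argwhere

    best: ROIResult | None = None
    for r, c in near:
        res = roi_stats(
            emap, (int(r), int(c)), offsets, exclusion=exclusion,
            diameter_mm=diameter_mm, sd_ddof=sd_ddof,
        )
        if best is None or res.e_mean > best.e_mean:
            best = res
    assert best is not None
    return best


def clamp_to_display(value, ceiling: float = 180.0):
    """Clamp elasticity values to the display ceiling (180 kPa by default).

    The colour display cannot encode values above the top of its range, so
    anything stiffer is shown — and therefore recovered — as the ceiling.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("elasticity values must be non-negative")
    out = np.minimum(arr, ceiling)
    if np.isscalar(value) or arr.ndim == 0:
        return float(out)
    return out


def aggregate_lesion(per_image, lesion_id: str, pathology: str) -> LesionRecord:
    """Average per-image ROI parameters into a single lesion record.

    The clinical protocol acquires four images per lesion; fewer are
    accepted with a warning, more than four are rejected.
    """
    if not per_image:
        raise ValueError("per_image must contain at least one ROIResult")
    if len(per_image) > 4:
        raise ValueError("at most 4 images per lesion are expected")
    if len(per_image) != 4:
        warnings.warn(
            f"lesion {lesion_id}: averaging over {len(per_image)} image(s) "
            "instead of the usual 4",
            stacklevel=2,
        )
    return LesionRecord(lesion_id=lesion_id, pathology=pathology, per_image=list(per_image))


def render_roi_overlay(emap: ElasticityMap, result: ROIResult, lut=None) -> np.ndarray:
    """Colour-mapped elastogram with the winning ROI circle drawn on top.

    Returns an (H, W, 3) uint8 image.  Missing pixels render mid-grey; the
    ROI perimeter is drawn in white so an operator can check the placement
    and, if needed, supply an exclusion mask for artefacts.
    """
    from skimage.draw import circle_perimeter

    h, w = emap.shape
    r, c = result.centre_rc
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("ROI centre lies outside the map")
    if lut is None:
        from .colourmap import build_default_lut

        lut = build_default_lut(display_max=max(emap.value_ceiling, 1.0))
    step = (lut.display_max - lut.display_min) / (lut.n_entries - 1)
    idx = np.clip(
        np.round((np.clip(np.nan_to_num(emap.values), lut.display_min, lut.display_max)
                  - lut.display_min) / step),
        0, lut.n_entries - 1,
    ).astype(int)
    img = (lut.rgb[idx] * 255).astype(np.uint8)
    img[emap.missing] = 128

    if emap.pixel_spacing_mm:
        radius_px = max(1, int(round((result.diameter_mm / 2) / emap.pixel_spacing_mm)))
    else:
        radius_px = 3
    rr_idx, cc_idx = circle_perimeter(r, c, radius_px, shape=(h, w))
    img[rr_idx, cc_idx] = 255
    return img
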