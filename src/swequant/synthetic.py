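"""Ground-truthed synthetic inputs: phantom fields, B-mode speckle,
rendered framed screenshots and diagnostic cohorts.

The generator emulates the structure of saved SWE captures — a jet-coloured
elastogram at 50% opacity over speckled greyscale, enclosed in a white
frame, optionally above a second framed B-mode panel — with full ground
truth, so the whole pipeline is testable without any real data.  The
default phantom mirrors a commercial breast elasticity phantom: spherical
inclusions of 11 mm diameter, imaged through their centres, i.e. rendered
as 2-D discs.  Visual realism is not the goal; the invertibility structure
of the rendering is.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .colourmap import ColourLUT, build_default_lut
from .diagnostics import Cohort
from .quantification import ElasticityMap
from .segmentation import FrameBox, ScreenCapture

__all__ = [
    "PhantomScene",
    "RouteModel",
    "CohortSpec",
    "RenderTruth",
    "make_elasticity_field",
    "make_bmode",
    "render_screenshot",
    "make_cohort",
    "default_cohort_spec",
    "write_synthetic_dicom",
]


@dataclass
class PhantomScene:
    """Geometry and stiffness of a breast-elasticity-phantom imaging plane.

    ``inclusions`` is a list of ``(centre_mm (row, col), diameter_mm,
    stiffness_kpa)``.  The defaults give three 11 mm spherical inclusions of
    increasing stiffness in a 20 kPa background, scanned through their
    centres.
    """

    field_size_mm: tuple[float, float] = (40.0, 60.0)
    background_kpa: float = 20.0
    inclusions: list = field(
        default_factory=lambda: [
            ((20.0, 12.0), 11.0, 45.0),
            ((20.0, 30.0), 11.0, 80.0),
            ((20.0, 48.0), 11.0, 140.0),
        ]
    )
    pixel_spacing_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_mm
        for (cr, cc), diam, stiff in self.inclusions:
            r = diam / 2.0
            if diam <= 0:
                raise ValueError("inclusion diameter must be positive")
            if not (0.0 <= stiff <= 300.0):
                raise ValueError("inclusion stiffness must lie in [0, 300] kPa")
            if not (r <= cr <= h - r and r <= cc <= w - r):
                raise ValueError("inclusion extends outside the field")
        # overlap keeps the ground truth ambiguous -> reject
        for i in range(len(self.inclusions)):
            for j in range(i + 1, len(self.inclusions)):
                (ci, di, _), (cj, dj, _) = self.inclusions[i], self.inclusions[j]
                dist = float(np.hypot(ci[0] - cj[0], ci[1] - cj[1]))
                if dist <= (di + dj) / 2.0:
                    raise ValueError(f"inclusions {i} and {j} overlap")


def make_elasticity_field(
    scene: PhantomScene,
    edge_width_mm: float = 0.0,
    heterogeneity: float = 0.0,
) -> ElasticityMap:
    """Rasterize the phantom scene into a ground-truth elasticity map.

    Pixel centres sit at ``(index + 0.5) * pixel_spacing_mm``.  With
    ``edge_width_mm == 0`` inclusions are hard discs (a pixel is stiff when
    its centre lies within the radius); otherwise the edge follows a
    logistic profile of that width.  ``heterogeneity`` adds smooth
    multiplicative log-normal texture of the given log-sd.
    """
    s = scene.pixel_spacing_mm
    h = int(round(scene.field_size_mm[0] / s))
    w = int(round(scene.field_size_mm[1] / s))
    rows = (np.arange(h) + 0.5) * s
    cols = (np.arange(w) + 0.5) * s
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    values = np.full((h, w), float(scene.background_kpa))
    for (cr, ccen), diam, stiff in scene.inclusions:
        dist = np.hypot(rr - cr, cc - ccen)
        radius = diam / 2.0
        if edge_width_mm <= 0:
            # tiny tolerance keeps pixels exactly on the circle inside,
            # matching integer lattice enumeration
            weight = (dist <= radius + 1e-9).astype(float)
        else:
            weight = 1.0 / (1.0 + np.exp((dist - radius) / edge_width_mm))
        values = values + (stiff - scene.background_kpa) * weight

    if heterogeneity > 0:
        rng = np.random.default_rng(scene.seed)
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
        noise /= max(noise.std(), 1e-12)
        values = values * np.exp(heterogeneity * noise)

    values = np.clip(values, 0.0, 300.0)
    return ElasticityMap(
        values=values,
        missing=np.zeros((h, w), dtype=bool),
        pixel_spacing_mm=s,
        value_ceiling=300.0,
    )


def make_bmode(
    shape: tuple[int, int],
    seed: int,
    smooth_px: float = 1.5,
    low: float = 0.05,
    high: float = 0.80,
) -> np.ndarray:
    """Speckle-like greyscale texture in [low, high], deterministic per seed.

    Low-pass-filtered white noise, min-max rescaled.  The ceiling of 0.80
    keeps speckle below the frame-whiteness threshold.
    """
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smooth_px)
    tmin, tmax = tex.min(), tex.max()
    if tmax > tmin:
        tex = (tex - tmin) / (tmax - tmin)
    else:
        tex = np.full(shape, 0.5)
    return low + (high - low) * tex


@dataclass
class RenderTruth:
    """Ground truth bundled with a rendered screenshot."""

    quantized_map: ElasticityMap
    frame_box: FrameBox
    lut: ColourLUT


def _quantize_to_lut(emap: ElasticityMap, lut: ColourLUT) -> tuple[np.ndarray, np.ndarray]:
    """Indices and stiffness of the nearest LUT entry after display clamping."""
    step = (lut.display_max - lut.display_min) / (lut.n_entries - 1)
    clamped = np.clip(np.nan_to_num(emap.values), lut.display_min, lut.display_max)
    idx = np.clip(np.round((clamped - lut.display_min) / step), 0, lut.n_entries - 1)
    idx = idx.astype(int)
    return idx, lut.stiffness[idx]


def render_screenshot(
    emap: ElasticityMap,
    bmode: np.ndarray,
    lut: ColourLUT | None = None,
    frame_px: int = 2,
    jpeg_quality: int | None = None,
    second_panel: bool = False,
    margin_px: int = 12,
) -> tuple[ScreenCapture, RenderTruth]:
    """Render an elasticity map as a device-style framed screen capture.

    Each elastogram pixel shows the LUT colour of the clamped, quantized
    truth alpha-blended with the B-mode grey (missing pixels show the grey
    alone); a white frame of ``frame_px`` surrounds the panel.  With
    ``second_panel`` a framed plain B-mode panel is placed below, mimicking
    the device's dual display.  ``jpeg_quality`` encodes the capture
    lossily.  Returns the capture plus the ground truth (clamped/quantized
    map and the interior FrameBox).
    """
    if lut is None:
        lut = build_default_lut()
    if frame_px < 1:
        raise ValueError("frame_px must be >= 1")
    bmode = np.asarray(bmode, dtype=float)
    if bmode.shape != emap.shape:
        raise ValueError("bmode shape must match the elasticity map")

    idx, quantized = _quantize_to_lut(emap, lut)
    c8 = np.round(lut.rgb * 255.0).astype(np.int64)[idx]  # (h, w, 3)
    g8 = np.round(np.clip(bmode, 0, 1) * 255.0).astype(np.int64)[..., None]
    alpha = lut.opacity
    # round-half-up quantization of the alpha blend
    panel = np.floor(alpha * c8 + (1.0 - alpha) * g8 + 0.5).astype(np.int64)
    panel = np.where(emap.missing[..., None], g8, panel)
    panel = np.clip(panel, 0, 255).astype(np.uint8)

    h, w = emap.shape
    fp, m = frame_px, margin_px
    total_h = m + fp + h + fp + m
    if second_panel:
        total_h += fp + h + fp + m
    total_w = m + fp + w + fp + m
    canvas = np.full((total_h, total_w, 3), 40, dtype=np.uint8)

    def draw_panel(top: int, content: np.ndarray) -> FrameBox:
        canvas[top : top + fp + h + fp, m : m + fp + w + fp] = 255
        canvas[top + fp : top + fp + h, m + fp : m + fp + w] = content
        return FrameBox(top + fp, m + fp, top + fp + h, m + fp + w)

    box = draw_panel(m, panel)
    if second_panel:
        grey = np.repeat(g8.astype(np.uint8), 3, axis=2)
        draw_panel(m + fp + h + fp + m, grey)

    source_format = "PNG"
    if jpeg_quality is not None:
        img = Image.fromarray(canvas)
        buf = _io.BytesIO()
        # 4:4:4 sampling: the generator models DCT quantization noise; with
        # 2x2 chroma subsampling a 1-px frame beside saturated colour is
        # unrecoverable by any detector, which is not the regime modelled.
        img.save(buf, format="JPEG", quality=int(jpeg_quality), subsampling=0)
        buf.seek(0)
        canvas = np.asarray(Image.open(buf).convert("RGB"))
        source_format = "JPG"

    capture = ScreenCapture(
        pixels=canvas,
        source_format=source_format,
        pixel_spacing_mm=emap.pixel_spacing_mm,
        metadata={"synthetic": "true"},
    )
    truth_map = ElasticityMap(
        values=np.where(emap.missing, np.nan, quantized),
        missing=emap.missing.copy(),
        pixel_spacing_mm=emap.pixel_spacing_mm,
        value_ceiling=lut.display_max,
    )
    return capture, RenderTruth(quantized_map=truth_map, frame_box=box, lut=lut)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class RouteModel:
    """How one quantification route perturbs the true lesion parameters.

    ``bias_kpa`` and ``noise_sd_kpa`` are per-parameter additive effects;
    ``clamp_ceiling_kpa`` truncates E_max/E_mean at the display ceiling;
    ``quantize_step_kpa`` snaps values to the colour-map grid; clamped
    routes additionally shrink SD for lesions whose true E_max exceeds the
    ceiling (flattening the top of the range removes within-ROI spread),
    with exponent ``sd_truncation_exponent``.
    """

    name: str
    bias_kpa: dict = field(default_factory=dict)
    noise_sd_kpa: dict = field(default_factory=dict)
    clamp_ceiling_kpa: float | None = None
    quantize_step_kpa: float | None = None
    sd_truncation_exponent: float = 1.0


@dataclass
class CohortSpec:
    """Statistical recipe for a synthetic benign/malignant lesion cohort.

    Class distributions are log-normal (elasticity is positive and
    right-skewed): ``class_params[label][parameter] = (median_kpa,
    sigma_log)``.  Four image-level replicates per lesion carry
    multiplicative within-lesion noise of log-sd ``within_lesion_sigma``
    before route effects and averaging.
    """

    n_benign: int = 70
    n_malignant: int = 137
    class_params: dict = field(
        default_factory=lambda: {
            "benign": {"e_max": (45.0, 0.55), "e_mean": (30.0, 0.55), "sd": (4.5, 0.40)},
            "malignant": {"e_max": (150.0, 0.55), "e_mean": (95.0, 0.55), "sd": (10.0, 0.45)},
        }
    )
    routes: list = field(default_factory=list)
    n_images_per_lesion: int = 4
    within_lesion_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("class counts must be >= 1")
        if not 1 <= self.n_images_per_lesion <= 4:
            raise ValueError("n_images_per_lesion must be 1..4")
        if self.within_lesion_sigma < 0:
            raise ValueError("within_lesion_sigma must be >= 0")
        for route in self.routes:
            for sd in route.noise_sd_kpa.values():
                if sd < 0:
                    raise ValueError("route noise sd must be >= 0")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Study-condition cohort: 70 benign / 137 malignant lesions and the
    five quantification routes, with route biases taken from the phantom
    offsets (DICOM ≈ +2/+4 kPa, JPG ≈ +6/+7 kPa for E_max/E_mean) and
    display clamping at 180 kPa for the screen-capture routes.
    """
    routes = [
        RouteModel("manual_A", noise_sd_kpa={"e_max": 2.0, "e_mean": 1.5, "sd": 0.6}),
        RouteModel("manual_B", noise_sd_kpa={"e_max": 2.5, "e_mean": 1.8, "sd": 0.7}),
        RouteModel("QDE", noise_sd_kpa={"e_max": 0.5, "e_mean": 0.4, "sd": 0.2}),
        RouteModel(
            "DICOM",
            bias_kpa={"e_max": 2.0, "e_mean": 4.0},
            noise_sd_kpa={"e_max": 1.0, "e_mean": 0.8, "sd": 1.5},
            clamp_ceiling_kpa=180.0,
            quantize_step_kpa=180.0 / 255.0,
        ),
        RouteModel(
            "JPG",
            bias_kpa={"e_max": 6.0, "e_mean": 7.0},
            noise_sd_kpa={"e_max": 2.0, "e_mean": 1.5, "sd": 3.0},
            clamp_ceiling_kpa=180.0,
            quantize_step_kpa=180.0 / 255.0,
        ),
    ]
    return CohortSpec(routes=routes, seed=seed)


def make_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort: true per-lesion parameters per class, per-route
    observed values via bias + noise + clamping + quantization, four
    image-level replicates averaged per lesion.  Bit-reproducible per seed.
    """
    if not spec.routes:
        raise ValueError("spec must define at least one route")
    rng = np.random.default_rng(spec.seed)
    params = ("e_max", "e_mean", "sd")

    labels, ids, true_vals = [], [], {p: [] for p in params}
    for label_name, label, count in (
        ("benign", 0, spec.n_benign),
        ("malignant", 1, spec.n_malignant),
    ):
        cp = spec.class_params[label_name]
        for i in range(count):
            ids.append(f"{label_name[0]}{i:03d}")
            labels.append(label)
            for p in params:
                median, sigma = cp[p]
                true_vals[p].append(median * np.exp(sigma * rng.standard_normal()))
    labels = np.asarray(labels)
    n = len(ids)

    values: dict = {}
    for route in spec.routes:
        route_vals = {p: np.empty(n) for p in params}
        for i in range(n):
            reps = {p: [] for p in params}
            for _ in range(spec.n_images_per_lesion):
                wobble = np.exp(spec.within_lesion_sigma * rng.standard_normal())
                emax_t = true_vals["e_max"][i] * wobble
                emean_t = true_vals["e_mean"][i] * wobble
                sd_t = true_vals["sd"][i] * wobble
                obs = {}
                for p, t in (("e_max", emax_t), ("e_mean", emean_t), ("sd", sd_t)):
                    v = t + route.bias_kpa.get(p, 0.0)
                    v += route.noise_sd_kpa.get(p, 0.0) * rng.standard_normal()
                    obs[p] = v
                ceiling = route.clamp_ceiling_kpa
                if ceiling is not None:
                    obs["e_max"] = min(obs["e_max"], ceiling)
                    obs["e_mean"] = min(obs["e_mean"], ceiling)
                    if emax_t > ceiling:
                        obs["sd"] *= (ceiling / emax_t) ** route.sd_truncation_exponent
                step = route.quantize_step_kpa
                if step:
                    obs["e_max"] = round(obs["e_max"] / step) * step
                    obs["e_mean"] = round(obs["e_mean"] / step) * step
                for p in params:
                    reps[p].append(max(obs[p], 0.0))
            for p in params:
                route_vals[p][i] = float(np.mean(reps[p]))
        values[route.name] = route_vals

    return Cohort(lesion_ids=ids, labels=labels, values=values)


def write_synthetic_dicom(capture: ScreenCapture, path) -> None:
    """Write a minimal synthetic RGB secondary-capture DICOM file.

    Exists only so the DICOM reading path is testable without real device
    output; the dataset is synthetic and carries no clinical metadata.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SYNTH000"
    ds.PhotometricInterpretation = "RGB"
    ds.SamplesPerPixel = 3
    ds.PlanarConfiguration = 0
    ds.Rows, ds.Columns = capture.pixels.shape[:2]
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    if capture.pixel_spacing_mm is not None:
        ds.PixelSpacing = [str(capture.pixel_spacing_mm), str(capture.pixel_spacing_mm)]
    ds.PixelData = np.ascontiguousarray(capture.pixels).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
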