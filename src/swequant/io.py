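"""Readers/writers for the touched formats and the pipeline driver.

Formats: DICOM screen captures (read, RGB), JPG/PNG captures (read), an
open plain-text matrix dialect standing in for the vendor's proprietary
quantitative data export (QDE), lesion manifests and result tables as CSV,
frame boxes and run metadata as JSON.  The pipeline driver runs
read -> frame detect -> invert -> ROI sweep -> per-lesion aggregation and,
when pathology labels allow, the route-comparison diagnostics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .colourmap import DEFAULT_CHROMA_TOLERANCE, ColourLUT, build_default_lut, invert_image
from .diagnostics import Cohort, compare_routes
from .quantification import ElasticityMap, sweep_roi
from .segmentation import FrameBox, ScreenCapture, crop, detect_frame

__all__ = [
    "RunConfig",
    "read_capture",
    "read_qde_matrix",
    "write_qde_matrix",
    "read_manifest",
    "run_pipeline",
    "PipelineResult",
]

MANIFEST_COLUMNS = ["lesion_id", "pathology", "image_path", "format", "pixel_spacing_mm"]


@dataclass
class RunConfig:
    """Every tunable of a quantification run, hashable for provenance.

    Defaults reproduce the standard clinical acquisition: 2 mm ROI,
    0–180 kPa display at 50% opacity, decision thresholds E_max 80 /
    E_mean 50 / SD 7 kPa, strictly-greater positive calls, population-SD
    divisor.
    """

    roi_diameter_mm: float = 2.0
    display_min_kpa: float = 0.0
    display_max_kpa: float = 180.0
    opacity: float = 0.5
    threshold_e_max_kpa: float = 80.0
    threshold_e_mean_kpa: float = 50.0
    threshold_sd_kpa: float = 7.0
    positive_if: str = "gt"
    sd_ddof: int = 0
    chroma_tolerance: float = DEFAULT_CHROMA_TOLERANCE
    min_valid_fraction: float = 0.5
    whiteness_threshold: float = 0.85
    seed: int = 0
    lut_path: str | None = None

    def __post_init__(self) -> None:
        if self.roi_diameter_mm <= 0:
            raise ValueError("roi_diameter_mm must be positive")
        if not self.display_min_kpa < self.display_max_kpa:
            raise ValueError("display range must be increasing")
        if not 0 < self.opacity <= 1:
            raise ValueError("opacity must be in (0, 1]")
        for thr in (self.threshold_e_max_kpa, self.threshold_e_mean_kpa, self.threshold_sd_kpa):
            if thr <= 0:
                raise ValueError("clinical thresholds must be positive")
        if self.positive_if not in ("gt", "ge"):
            raise ValueError("positive_if must be 'gt' or 'ge'")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 (population) or 1 (sample)")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @property
    def thresholds(self) -> dict:
        return {
            "e_max": self.threshold_e_max_kpa,
            "e_mean": self.threshold_e_mean_kpa,
            "sd": self.threshold_sd_kpa,
        }

    def lut(self) -> ColourLUT:
        if self.lut_path:
            return ColourLUT.from_csv(self.lut_path, opacity=self.opacity)
        return build_default_lut(
            display_min=self.display_min_kpa,
            display_max=self.display_max_kpa,
            opacity=self.opacity,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _spacing_from_dicom(ds) -> float | None:
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing:
        return float(spacing[0])
    spacing = getattr(ds, "ImagerPixelSpacing", None)
    if spacing:
        return float(spacing[0])
    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if regions:
        delta = getattr(regions[0], "PhysicalDeltaX", None)
        if delta:
            return abs(float(delta)) * 10.0  # cm/px -> mm/px
    return None


def read_capture(
    path,
    format_hint: str | None = None,
    pixel_spacing_mm: float | None = None,
) -> ScreenCapture:
    """Decode a DICOM/JPG/PNG screen capture to 8-bit RGB.

    Pixel spacing is harvested from DICOM attributes when present
    (standard spacing tags, then ultrasound calibration regions); for
    JPG/PNG it must come from ``pixel_spacing_mm`` (CLI flag or manifest).
    """
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).upper()
    if fmt in ("DCM", "DICOM"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        photometric = getattr(ds, "PhotometricInterpretation", "")
        if not photometric.startswith("RGB"):
            raise ValueError(
                f"{path}: DICOM is {photometric or 'unknown'}, not an RGB screen "
                "capture; greyscale-only exports carry no colour overlay to invert"
            )
        arr = np.asarray(ds.pixel_array)
        if arr.ndim == 4:  # multi-frame: first frame only
            arr = arr[0]
        spacing = pixel_spacing_mm if pixel_spacing_mm is not None else _spacing_from_dicom(ds)
        return ScreenCapture(
            pixels=arr.astype(np.uint8),
            source_format="DICOM",
            pixel_spacing_mm=spacing,
            metadata={"sop_instance_uid": str(getattr(ds, "SOPInstanceUID", ""))},
        )
    if fmt in ("JPG", "JPEG", "PNG"):
        arr = np.asarray(Image.open(path).convert("RGB"))
        return ScreenCapture(
            pixels=arr,
            source_format="JPG" if fmt.startswith("JP") else "PNG",
            pixel_spacing_mm=pixel_spacing_mm,
            metadata={},
        )
    raise ValueError(f"unsupported capture format: {fmt!r}")


def write_qde_matrix(emap: ElasticityMap, path) -> None:
    """Write the open QDE-style matrix dialect.

    Three header lines (rows, cols, pixel_spacing_mm) then the kPa matrix
    as CSV; missing cells are the sentinel -1.
    """
    h, w = emap.shape
    vals = np.where(emap.missing, -1.0, emap.values)
    with open(path, "w") as fh:
        fh.write(f"rows,{h}\n")
        fh.write(f"cols,{w}\n")
        fh.write(f"pixel_spacing_mm,{emap.pixel_spacing_mm}\n")
        for row in vals:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_qde_matrix(path, value_ceiling: float = 300.0) -> ElasticityMap:
    """Read the open QDE-style matrix dialect (see :func:`write_qde_matrix`)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()

    def header(idx: int, key: str) -> float:
        if idx >= len(lines):
            raise ValueError(f"{path}:{idx + 1}: missing header line '{key}'")
        parts = lines[idx].split(",")
        if len(parts) != 2 or parts[0].strip() != key:
            raise ValueError(f"{path}:{idx + 1}: expected '{key},<value>'")
        try:
            return float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{idx + 1}: non-numeric {key}") from exc

    rows = int(header(0, "rows"))
    cols = int(header(1, "cols"))
    spacing = header(2, "pixel_spacing_mm")
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != rows:
        raise ValueError(f"{path}:4: body has {len(body)} rows, header says {rows}")
    data = np.empty((rows, cols))
    for i, ln in enumerate(body):
        parts = ln.split(",")
        if len(parts) != cols:
            raise ValueError(f"{path}:{4 + i}: {len(parts)} columns, header says {cols}")
        data[i] = [float(v) for v in parts]
    missing = data < 0
    return ElasticityMap(
        values=np.where(missing, np.nan, data),
        missing=missing,
        pixel_spacing_mm=spacing if spacing > 0 else None,
        value_ceiling=value_ceiling,
    )


def read_manifest(path) -> pd.DataFrame:
    """Read a lesion manifest CSV, validating the required columns."""
    df = pd.read_csv(path, dtype={"lesion_id": str})
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    return df


@dataclass
class PipelineResult:
    image_results: pd.DataFrame
    lesion_results: pd.DataFrame
    report: object | None
    failures: list
    metadata: dict


def _frame_override(row) -> FrameBox | None:
    keys = ("frame_top", "frame_left", "frame_bottom", "frame_right")
    if all(k in row.index and pd.notna(row[k]) for k in keys):
        return FrameBox(*(int(row[k]) for k in keys))
    return None


def run_pipeline(manifest, config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full quantification pipeline over a lesion manifest.

    Per image: read -> frame detect (or manifest override columns
    frame_top/left/bottom/right) -> colour-map inversion -> ROI sweep.
    QDE-format rows are read directly as elasticity matrices.  Per lesion:
    arithmetic averaging of the per-image parameters.  When at least two
    lesions with both pathology classes are present per format route, the
    diagnostic route comparison is added.  Per-image failures are recorded
    and skipped; the run fails only if no image succeeds.  With ``out_dir``,
    results CSVs and a run-metadata JSON are written; identical inputs,
    config and seed produce byte-identical files.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    lut = config.lut()
    cfg_hash = config.config_hash()

    image_rows, failures = [], []
    for _, row in manifest.iterrows():
        try:
            fmt = str(row["format"]).upper()
            spacing = row.get("pixel_spacing_mm")
            spacing = float(spacing) if pd.notna(spacing) else None
            if fmt == "QDE":
                emap = read_qde_matrix(row["image_path"])
                if emap.pixel_spacing_mm is None and spacing is not None:
                    emap.pixel_spacing_mm = spacing
            else:
                capture = read_capture(row["image_path"], fmt, spacing)
                if capture.pixel_spacing_mm is None:
                    raise ValueError(
                        f"{row['image_path']}: no pixel spacing available; supply "
                        "pixel_spacing_mm in the manifest or via --pixel-spacing"
                    )
                box = _frame_override(row)
                if box is None:
                    box = detect_frame(capture, config.whiteness_threshold)
                region = crop(capture, box)
                emap = invert_image(
                    region, lut, config.chroma_tolerance, capture.pixel_spacing_mm
                )
            roi = sweep_roi(
                emap,
                diameter_mm=config.roi_diameter_mm,
                min_valid_fraction=config.min_valid_fraction,
                sd_ddof=config.sd_ddof,
            )
            image_rows.append(
                {
                    "lesion_id": str(row["lesion_id"]),
                    "pathology": str(row["pathology"]),
                    "route": fmt,
                    "image_path": str(row["image_path"]),
                    "centre_row": roi.centre_rc[0],
                    "centre_col": roi.centre_rc[1],
                    "e_max": roi.e_max,
                    "e_mean": roi.e_mean,
                    "sd": roi.sd,
                    "n_pixels": roi.n_pixels,
                    "config_hash": cfg_hash,
                }
            )
        except Exception as exc:  # per-image failures are data, not crashes
            failures.append({"image_path": str(row.get("image_path", "?")), "error": str(exc)})

    if not image_rows:
        raise RuntimeError(f"no image could be processed; failures: {failures}")

    images = pd.DataFrame(image_rows)
    lesion_rows = []
    for (lesion_id, route), grp in images.groupby(["lesion_id", "route"], sort=True):
        lesion_rows.append(
            {
                "lesion_id": lesion_id,
                "route": route,
                "pathology": grp["pathology"].iloc[0],
                "n_images": len(grp),
                "e_max": grp["e_max"].mean(),
                "e_mean": grp["e_mean"].mean(),
                "sd": grp["sd"].mean(),
                "config_hash": cfg_hash,
            }
        )
    lesions = pd.DataFrame(lesion_rows)

    report = None
    label_of = {"benign": 0, "malignant": 1}
    pivot = lesions.pivot_table(
        index="lesion_id", columns="route", values=["e_max", "e_mean", "sd"]
    )
    lesion_labels = lesions.drop_duplicates("lesion_id").set_index("lesion_id")["pathology"]
    complete = pivot.dropna()
    if len(complete) >= 2:
        labels = np.array([label_of[lesion_labels[i]] for i in complete.index])
        if len(np.unique(labels)) == 2:
            routes = sorted(lesions["route"].unique())
            values = {
                r: {p: complete[(p, r)].to_numpy() for p in ("e_max", "e_mean", "sd")}
                for r in routes
            }
            cohort = Cohort(lesion_ids=list(complete.index), labels=labels, values=values)
            report = compare_routes(
                cohort, thresholds=config.thresholds, positive_if=config.positive_if
            )

    metadata = {
        "config": asdict(config),
        "config_hash": cfg_hash,
        "lut_name": lut.name,
        "n_images_ok": len(images),
        "n_failures": len(failures),
        "failures": failures,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        images.to_csv(out / "results_images.csv", index=False, float_format="%.6f")
        lesions.to_csv(out / "results_lesions.csv", index=False, float_format="%.6f")
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
        if report is not None:
            report.to_csv(out)

    return PipelineResult(
        image_results=images,
        lesion_results=lesions,
        report=report,
        failures=failures,
        metadata=metadata,
    )
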