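"""End-to-end quantification runs.

`run_quantify` ties the modules together: read plate photographs, convert
to CIELAB, segment the blue band, detect rounded halos, convert pixel
counts to cm^2 with the calibration, organise per-clone areas into the
density matrix and summarise the screen.  Every parameter actually used is
logged, and numeric CSV output is formatted at fixed precision (4 decimals
for cm^2) so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibrate import CalibrationLine, CalibrationRecord, calibrate, region_area_cm2
from .color import load_rgb_image, srgb_to_lab
from .halo import (
    CircularMask,
    DetectionParams,
    SegmentationParams,
    blue_mask,
    detect_halos,
    pixel_count_in_circle,
)
from .screen import (
    GridLayout,
    HaloAreaRecord,
    build_density_matrix,
    condition_label,
    summarize_screen,
)

__all__ = ["PlateImage", "RunConfig", "run_quantify", "load_run_config"]

log = logging.getLogger(__name__)

AREA_DECIMALS = 4


@dataclass(frozen=True)
class PlateImage:
    """One photograph and the condition it was acquired under."""

    path: str
    temperature_c: float
    day: int


@dataclass
class RunConfig:
    """Configuration of a quantification run (see README for the JSON schema)."""

    images: list[PlateImage]
    layout: GridLayout
    calibration: CalibrationRecord
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    manual_masks: list[CircularMask] = field(default_factory=list)
    n_screened: int | None = None
    out_dir: str = "."


def _calibration_from_dict(d: dict) -> CalibrationRecord:
    if "mm_per_pixel" in d:
        return CalibrationRecord(mm_per_pixel=float(d["mm_per_pixel"]))
    return calibrate(
        CalibrationLine(
            pixel_length=float(d["pixel_length"]),
            physical_length_mm=float(d["physical_length_mm"]),
        )
    )


def load_run_config(path) -> RunConfig:
    """Load a run configuration from JSON.

    The layout may be inline (an object) or a path to a layout JSON file,
    resolved relative to the config file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    cfg = json.loads(path.read_text())
    layout_src = cfg["layout"]
    if isinstance(layout_src, str):
        layout_path = (path.parent / layout_src).resolve()
        if not layout_path.exists():
            raise FileNotFoundError(f"layout file not found: {layout_path}")
        layout = GridLayout.from_dict(json.loads(layout_path.read_text()))
    else:
        layout = GridLayout.from_dict(layout_src)
    images = [
        PlateImage(
            path=str((path.parent / img["path"]).resolve()),
            temperature_c=float(img["temperature_c"]),
            day=int(img["day"]),
        )
        for img in cfg["images"]
    ]
    manual = [
        CircularMask(center=(float(m["cx"]), float(m["cy"])), radius=float(m["r"]),
                     cell_id=m.get("cell_id"))
        for m in cfg.get("manual_masks", [])
    ]
    return RunConfig(
        images=images,
        layout=layout,
        calibration=_calibration_from_dict(cfg["calibration"]),
        segmentation=SegmentationParams(**cfg.get("segmentation", {})),
        detection=DetectionParams(**cfg.get("detection", {})),
        manual_masks=manual,
        n_screened=cfg.get("n_screened"),
        out_dir=cfg.get("out_dir", "."),
    )


def run_quantify(config: RunConfig) -> dict:
    """Quantify halo areas across all configured images and write results.

    Writes, under ``config.out_dir``: ``regions.csv`` (per detected
    region), ``halo_areas.csv`` (per clone and condition), and, when the
    layout labels clones, ``density_matrix.csv`` plus
    ``screen_summary.json``.  Returns a dict with the density matrix,
    summary and per-region table.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info(
        "quantify: %d image(s); segmentation=%s detection=%s mm/px=%.6g",
        len(config.images),
        config.segmentation,
        config.detection,
        config.calibration.mm_per_pixel,
    )

    region_rows = []
    records: list[HaloAreaRecord] = []
    conditions: list[tuple[float, int]] = []
    for plate in config.images:
        img_path = Path(plate.path)
        if not img_path.exists():
            raise FileNotFoundError(f"image not found: {img_path}")
        rgb = load_rgb_image(img_path)
        lab = srgb_to_lab(rgb)
        mask = blue_mask(lab, config.segmentation)
        regions = detect_halos(mask, config.layout, config.detection)
        detected_cells = {r.cell_id for r in regions if r.cell_id is not None}
        # manual fallback: operator-placed circles for cells the automatic
        # path did not resolve
        next_id = max((r.region_id for r in regions), default=0)
        for circ in config.manual_masks:
            if circ.cell_id is not None and circ.cell_id in detected_cells:
                continue
            count = pixel_count_in_circle(mask, circ)
            next_id += 1
            cell = circ.cell_id or config.layout.cell_at(*circ.center)
            from .halo import HaloRegion

            regions.append(
                HaloRegion(
                    region_id=next_id,
                    pixel_count=count,
                    centroid=circ.center,
                    equivalent_radius=circ.radius,
                    circularity=1.0,
                    cell_id=cell,
                )
            )
        cond = (plate.temperature_c, plate.day)
        if cond not in conditions:
            conditions.append(cond)
        for reg in regions:
            clone = (
                config.layout.clone_labels.get(reg.cell_id)
                if reg.cell_id is not None
                else None
            )
            area = region_area_cm2(reg.pixel_count, config.calibration)
            region_rows.append(
                {
                    "image": img_path.name,
                    "condition": condition_label(*cond),
                    "region_id": reg.region_id,
                    "cell_id": reg.cell_id or "",
                    "clone": clone or "",
                    "pixel_count": reg.pixel_count,
                    "centroid_x": round(reg.centroid[0], 2),
                    "centroid_y": round(reg.centroid[1], 2),
                    "circularity": round(reg.circularity, 4),
                    "area_cm2": round(area, AREA_DECIMALS),
                }
            )
            if clone is not None and reg.pixel_count > 0:
                records.append(
                    HaloAreaRecord(
                        clone=clone,
                        temperature_c=plate.temperature_c,
                        day=plate.day,
                        area_cm2=round(area, AREA_DECIMALS),
                    )
                )

    regions_df = pd.DataFrame(
        region_rows,
        columns=[
            "image", "condition", "region_id", "cell_id", "clone",
            "pixel_count", "centroid_x", "centroid_y", "circularity", "area_cm2",
        ],
    )
    regions_df.to_csv(out_dir / "regions.csv", index=False, float_format="%.4f")

    result: dict = {"regions": regions_df}
    clones = sorted(set(config.layout.clone_labels.values()))
    if clones:
        conditions_sorted = sorted(conditions)
        dm = build_density_matrix(records, clones, conditions_sorted)
        dm.round(AREA_DECIMALS).to_csv(
            out_dir / "density_matrix.csv", float_format="%.4f"
        )
        areas_df = pd.DataFrame(
            [
                {
                    "clone": r.clone,
                    "temperature_C": r.temperature_c,
                    "day": r.day,
                    "area_cm2": r.area_cm2,
                }
                for r in records
            ],
            columns=["clone", "temperature_C", "day", "area_cm2"],
        )
        areas_df.to_csv(out_dir / "halo_areas.csv", index=False, float_format="%.4f")
        positives = sorted(dm.index[(dm > 0).any(axis=1)])
        n_screened = config.n_screened if config.n_screened is not None else len(clones)
        summary = summarize_screen(n_screened, positives)
        (out_dir / "screen_summary.json").write_text(
            json.dumps(
                {
                    "n_screened": summary.n_screened,
                    "n_positive": len(summary.positive_clones),
                    "positive_clones": list(summary.positive_clones),
                    "hit_rate_percent": summary.hit_rate_percent,
                },
                indent=2,
            )
            + "\n"
        )
        result["density_matrix"] = dm
        result["summary"] = summary
    return result
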