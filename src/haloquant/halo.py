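"""Blue-halo segmentation and rounded-region detection.

Positive (enzymatically active) pixels are selected by a band on the CIELAB
b* channel: the released dye is blue, so b* is negative, and the default
band is the open interval -20 < b* < -5.  Rounded regions of high positive
density are then extracted as connected components passing a circularity
filter, with a manual circular-mask fallback for plates the automatic path
cannot handle.

Shape filtering happens *before* hole-filling on purpose: thin grid lines
drawn under the plate enclose the cells, and filling first would flood the
enclosed interiors into one plate-sized blob that a circularity test on the
filled shape would not reject.  On the unfilled component the line network
has a huge perimeter for almost no area and is discarded immediately; holes
are then filled only inside the surviving, already-roundish regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton
from skimage.morphology import closing as sk_closing
from skimage.morphology import disk

from .screen import GridLayout

__all__ = [
    "SegmentationParams",
    "DetectionParams",
    "HaloRegion",
    "CircularMask",
    "blue_mask",
    "detect_halos",
    "pixel_count_in_circle",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """b* band defining a positive (blue) pixel.

    Bounds are strict: positive iff ``b_lo < b* < b_hi``.  With
    ``extend_blue`` the lower bound is dropped (``b* < b_hi``), for assays
    where very saturated halos fall below the nominal band.
    """

    b_lo: float = -20.0
    b_hi: float = -5.0
    extend_blue: bool = False

    def __post_init__(self) -> None:
        if not self.b_lo < self.b_hi <= 0:
            raise ValueError(
                f"require b_lo < b_hi <= 0, got b_lo={self.b_lo}, b_hi={self.b_hi}"
            )


@dataclass(frozen=True)
class DetectionParams:
    """Rounded-region extraction parameters.

    circularity = 4*pi*area/perimeter^2 (1 for a perfect disk); regions
    below ``min_circularity`` or smaller than ``min_area_px`` are discarded.
    ``closing_radius_px`` is the radius of the morphological closing that
    bridges small gaps before labeling.
    """

    min_area_px: int = 50
    min_circularity: float = 0.6
    closing_radius_px: int = 2

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if not 0 < self.min_circularity <= 1:
            raise ValueError("min_circularity must be in (0, 1]")
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be >= 0")


@dataclass(frozen=True)
class HaloRegion:
    """One detected halo: pixel statistics plus its grid-cell assignment."""

    region_id: int
    pixel_count: int
    centroid: tuple[float, float]  # (x, y) in pixels
    equivalent_radius: float
    circularity: float
    cell_id: str | None = None


@dataclass(frozen=True)
class CircularMask:
    """A manually placed circular mask (center and radius in pixels)."""

    center: tuple[float, float]
    radius: float
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


def blue_mask(lab: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Boolean mask of blue-positive pixels from a CIELAB image.

    Parameters
    ----------
    lab : ndarray
        ``(H, W, 3)`` CIELAB image (see :func:`haloquant.color.srgb_to_lab`).
    params : SegmentationParams, optional
        The b* band; defaults to the open interval (-20, -5).
    """
    if params is None:
        params = SegmentationParams()
    lab = np.asarray(lab)
    if lab.ndim != 3 or lab.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) Lab image, got shape {lab.shape}")
    b = lab[..., 2]
    if params.extend_blue:
        return b < params.b_hi
    return (params.b_lo < b) & (b < params.b_hi)


def detect_halos(
    mask: np.ndarray,
    layout: GridLayout | None = None,
    params: DetectionParams | None = None,
) -> list[HaloRegion]:
    """Extract rounded halo regions from a binary positive mask.

    Pipeline: morphological closing (disk footprint), 8-connected component
    labeling, area + circularity filtering on the raw components, hole
    filling inside the survivors, then assignment of each region to the
    grid cell containing its centroid.  At most one region is kept per cell
    (largest pixel count wins; extras are logged).  Regions whose centroid
    falls in no cell keep ``cell_id=None``.
    """
    if params is None:
        params = DetectionParams()
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"expected 2-D binary mask, got shape {mask.shape}")
    if not mask.any():
        return []
    closed = (
        sk_closing(mask, disk(params.closing_radius_px)).astype(bool)
        if params.closing_radius_px > 0
        else mask
    )
    labels = sk_label(closed, connectivity=2)
    regions: list[HaloRegion] = []
    rid = 0
    for lbl in range(1, labels.max() + 1):
        comp = labels == lbl
        area = int(comp.sum())
        if area < params.min_area_px:
            continue
        perim = perimeter_crofton(comp, directions=4)
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
        if circ < params.min_circularity:
            continue
        filled = ndi.binary_fill_holes(comp)
        count = int(filled.sum())
        ys, xs = np.nonzero(filled)
        cx, cy = float(xs.mean()), float(ys.mean())
        rid += 1
        cell = layout.cell_at(cx, cy) if layout is not None else None
        regions.append(
            HaloRegion(
                region_id=rid,
                pixel_count=count,
                centroid=(cx, cy),
                equivalent_radius=float(np.sqrt(count / np.pi)),
                circularity=float(circ),
                cell_id=cell,
            )
        )
    # keep the largest region per assigned cell
    best: dict[str, HaloRegion] = {}
    unassigned: list[HaloRegion] = []
    for reg in regions:
        if reg.cell_id is None:
            unassigned.append(reg)
        elif reg.cell_id not in best or reg.pixel_count > best[reg.cell_id].pixel_count:
            if reg.cell_id in best:
                log.info(
                    "cell %s: dropping smaller extra region %d (%d px)",
                    reg.cell_id,
                    best[reg.cell_id].region_id,
                    best[reg.cell_id].pixel_count,
                )
            best[reg.cell_id] = reg
        else:
            log.info(
                "cell %s: dropping smaller extra region %d (%d px)",
                reg.cell_id,
                reg.region_id,
                reg.pixel_count,
            )
    kept = sorted(best.values(), key=lambda r: r.region_id) + unassigned
    return sorted(kept, key=lambda r: r.region_id)


def pixel_count_in_circle(mask: np.ndarray, circle: CircularMask) -> int:
    """Count positive pixels whose centers lie within a circular mask.

    The manual fallback: the circle is placed and sized by the operator and
    the positive pixels inside it are tallied.  Membership is by pixel
    center, distance <= radius.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"expected 2-D binary mask, got shape {mask.shape}")
    h, w = mask.shape
    cx, cy = circle.center
    # nearest point of the image rectangle to the circle center
    nearest_x = min(max(cx, 0.0), w - 1.0)
    nearest_y = min(max(cy, 0.0), h - 1.0)
    if (nearest_x - cx) ** 2 + (nearest_y - cy) ** 2 > circle.radius**2:
        raise ValueError("circular mask does not intersect the image")
    ys, xs = np.ogrid[:h, :w]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= circle.radius**2
    return int((mask & inside).sum())
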