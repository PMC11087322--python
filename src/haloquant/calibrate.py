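"""Pixel-to-physical calibration.

A line of known physical length (in practice, the distance between two
consecutive vertical grid lines drawn under the plate) fixes the size of a
pixel in millimetres; halo areas then follow from pixel counts.  A single
scalar scale is used: pixels are assumed square, and lens distortion is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CalibrationLine", "CalibrationRecord", "calibrate", "region_area_cm2"]


@dataclass(frozen=True)
class CalibrationLine:
    """A measured line: its length in pixels and in millimetres."""

    pixel_length: float
    physical_length_mm: float

    def __post_init__(self) -> None:
        if self.pixel_length <= 0:
            raise ValueError(f"pixel_length must be > 0, got {self.pixel_length}")
        if self.physical_length_mm <= 0:
            raise ValueError(
                f"physical_length_mm must be > 0, got {self.physical_length_mm}"
            )


@dataclass(frozen=True)
class CalibrationRecord:
    """Scale of one image: mm per pixel and mm^2 per pixel (its square)."""

    mm_per_pixel: float
    area_mm2_per_pixel: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        object.__setattr__(self, "area_mm2_per_pixel", self.mm_per_pixel**2)


def calibrate(line: CalibrationLine) -> CalibrationRecord:
    """Derive the per-pixel scale from a drawn line of known length."""
    return CalibrationRecord(mm_per_pixel=line.physical_length_mm / line.pixel_length)


def region_area_cm2(pixel_count: int, cal: CalibrationRecord) -> float:
    """Area of a region in cm^2 from its pixel count (100 mm^2 = 1 cm^2)."""
    if pixel_count < 0:
        raise ValueError(f"pixel_count must be >= 0, got {pixel_count}")
    return pixel_count * cal.area_mm2_per_pixel / 100.0
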