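"""Synthetic plate images with known ground truth.

The generator emulates the acquisition geometry of a back-lit Petri plate
photographed from above: a uniform agar background, thin blue grid lines at
known pixel (and physical) spacing dividing the plate into clone cells,
disk-shaped halos rendered from target CIELAB values, an optional linear
illumination ramp on L*, and additive Gaussian sensor noise applied in
sRGB space after encoding (where a phone camera's quantisation lives).
Ground truth — per-halo centers, radii, rasterised pixel counts, physical
areas and the pre-noise positive mask — is returned alongside the image so
the whole measurement pipeline can be validated without real photographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .color import lab_to_srgb
from .screen import GridLayout

__all__ = [
    "HaloSpec",
    "SyntheticPlateSpec",
    "GroundTruthHalo",
    "GroundTruth",
    "generate_plate",
    "default_plate_spec",
    "DEFAULT_CLONE_LABELS",
]


@dataclass(frozen=True)
class HaloSpec:
    """One simulated halo: a solid disk of blue dye in a given cell."""

    cell_id: str
    center: tuple[float, float]  # (x, y) pixels
    radius_px: float
    target_b: float = -12.0
    halo_l: float = 70.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError(f"radius_px must be > 0, got {self.radius_px}")


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Parametric description of a simulated plate photograph.

    Defaults describe the screening plates this package models: a 4 x 5
    grid of 13 mm cells at 100 px spacing, pale straw agar, saturated blue
    marker grid lines (far bluer than diffuse dye halos, hence outside the
    default segmentation band), and mild sensor noise (sigma = 2 on 8-bit
    channels).
    """

    image_size: tuple[int, int] = (500, 400)  # (width, height)
    n_rows: int = 4
    n_cols: int = 5
    background_lab: tuple[float, float, float] = (85.0, 0.0, 8.0)
    grid_spacing_px: int = 100
    grid_spacing_mm: float = 13.0
    grid_color_lab: tuple[float, float, float] = (40.0, 10.0, -45.0)
    grid_line_width_px: int = 2
    halos: tuple[HaloSpec, ...] = ()
    noise_sigma: float = 2.0
    gradient_amplitude: float = 0.0

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w < 1 or h < 1:
            raise ValueError("image must be at least 1x1")
        if self.grid_spacing_px < 2:
            raise ValueError("grid_spacing_px must be >= 2")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "halos", tuple(self.halos))
        layout = self.layout()
        for halo in self.halos:
            cx, cy = halo.center
            if not (0 <= cx - halo.radius_px and cx + halo.radius_px < w
                    and 0 <= cy - halo.radius_px and cy + halo.radius_px < h):
                raise ValueError(f"halo in cell {halo.cell_id!r} extends outside the image")
            if halo.cell_id not in layout.cell_bounds:
                raise ValueError(f"halo references unknown cell {halo.cell_id!r}")
            x0, y0, x1, y1 = layout.cell_bounds[halo.cell_id]
            if not (x0 <= cx < x1 and y0 <= cy < y1):
                raise ValueError(f"halo center {halo.center} not inside cell {halo.cell_id!r}")

    @property
    def mm_per_pixel(self) -> float:
        return self.grid_spacing_mm / self.grid_spacing_px

    def layout(self, clone_labels: dict[str, str] | None = None) -> GridLayout:
        """Grid layout implied by the cell grid and spacing."""
        return GridLayout.regular(
            self.n_rows, self.n_cols, self.grid_spacing_px, clone_labels=clone_labels
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["halos"] = [asdict(h) for h in self.halos]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticPlateSpec":
        d = json.loads(text)
        halos = tuple(
            HaloSpec(
                cell_id=h["cell_id"],
                center=tuple(h["center"]),
                radius_px=h["radius_px"],
                target_b=h.get("target_b", -12.0),
                halo_l=h.get("halo_l", 70.0),
            )
            for h in d.pop("halos", [])
        )
        d["image_size"] = tuple(d["image_size"])
        for key in ("background_lab", "grid_color_lab"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(halos=halos, **d)


@dataclass(frozen=True)
class GroundTruthHalo:
    cell_id: str
    center: tuple[float, float]
    radius_px: float
    pixel_count: int
    area_cm2: float


@dataclass(frozen=True)
class GroundTruth:
    """True halo geometry of a simulated plate (pre-noise)."""

    halos: tuple[GroundTruthHalo, ...]
    mask: np.ndarray  # (H, W) bool, union of halo disks
    mm_per_pixel: float

    def to_dict(self) -> dict:
        return {
            "mm_per_pixel": self.mm_per_pixel,
            "halos": [asdict(h) for h in self.halos],
        }


# Clone naming of the modelled screen: 12 positives (LP) and 8 negative
# controls (NG) on one 20-cell plate, row-major.
DEFAULT_CLONE_LABELS: dict[str, str] = {
    **{f"r{i // 5}c{i % 5}": f"LP{i + 1}" for i in range(12)},
    **{f"r{(i + 12) // 5}c{(i + 12) % 5}": f"NG{i + 1}" for i in range(8)},
}


def _disk_mask(h: int, w: int, center: tuple[float, float], radius: float) -> np.ndarray:
    ys, xs = np.ogrid[:h, :w]
    cx, cy = center
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2


def generate_plate(
    spec: SyntheticPlateSpec, seed: int
) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic plate photograph and its ground truth.

    Deterministic for a fixed (spec, seed); distinct seeds change only the
    sensor noise, never the geometry or the ground truth.

    Returns
    -------
    image : ndarray
        ``(H, W, 3)`` uint8 sRGB image.
    truth : GroundTruth
        True halo centers, radii, rasterised pixel counts, areas in cm^2
        (from the grid spacing calibration) and the pre-noise union mask.
    """
    w, h = spec.image_size
    lab = np.empty((h, w, 3), dtype=np.float64)
    lab[:] = spec.background_lab

    union = np.zeros((h, w), dtype=bool)
    gt_halos = []
    area_factor = spec.mm_per_pixel**2 / 100.0  # cm^2 per pixel
    for halo in spec.halos:
        dm = _disk_mask(h, w, halo.center, halo.radius_px)
        lab[dm] = (halo.halo_l, 0.0, halo.target_b)
        union |= dm
        count = int(dm.sum())
        gt_halos.append(
            GroundTruthHalo(
                cell_id=halo.cell_id,
                center=halo.center,
                radius_px=halo.radius_px,
                pixel_count=count,
                area_cm2=count * area_factor,
            )
        )

    # thin grid lines at the cell boundaries (drawn over the background;
    # halos sit inside their cells, so no overlap)
    lw = spec.grid_line_width_px
    if lw > 0:
        for k in range(1, (w - 1) // spec.grid_spacing_px + 1):
            x = k * spec.grid_spacing_px
            lab[:, max(0, x - lw // 2) : x + (lw + 1) // 2] = spec.grid_color_lab
        for k in range(1, (h - 1) // spec.grid_spacing_px + 1):
            y = k * spec.grid_spacing_px
            lab[max(0, y - lw // 2) : y + (lw + 1) // 2, :] = spec.grid_color_lab

    if spec.gradient_amplitude != 0.0 and w > 1:
        ramp = spec.gradient_amplitude * (np.arange(w) / (w - 1) - 0.5)
        lab[..., 0] = np.clip(lab[..., 0] + ramp[None, :], 0.0, 100.0)

    rgb, _ = lab_to_srgb(lab)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = rgb.astype(np.float64) + rng.normal(0.0, spec.noise_sigma, rgb.shape)
        rgb = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    truth = GroundTruth(halos=tuple(gt_halos), mask=union, mm_per_pixel=spec.mm_per_pixel)
    return rgb, truth


def default_plate_spec(
    halo_cells: dict[str, tuple[float, float]] | None = None,
    *,
    noise_sigma: float = 2.0,
    seed_geometry: int | None = None,
    rng: np.random.Generator | None = None,
    n_halos: int = 6,
    radius_range: tuple[float, float] = (10.0, 40.0),
    b_range: tuple[float, float] = (-19.0, -6.0),
) -> SyntheticPlateSpec:
    """A randomly populated standard screening plate.

    ``halo_cells`` maps cell ids to (radius_px, target_b); when omitted,
    ``n_halos`` distinct cells are drawn at random with radii and b* values
    in the given ranges, disks centered in their cells.
    """
    base = SyntheticPlateSpec(noise_sigma=noise_sigma)
    layout = base.layout()
    if rng is None:
        rng = np.random.default_rng(seed_geometry)
    halos = []
    if halo_cells is None:
        cells = list(layout.cell_bounds)
        chosen = rng.choice(len(cells), size=min(n_halos, len(cells)), replace=False)
        halo_cells = {
            cells[i]: (
                float(rng.uniform(*radius_range)),
                float(rng.uniform(*b_range)),
            )
            for i in chosen
        }
    for cell_id, (radius, target_b) in halo_cells.items():
        x0, y0, x1, y1 = layout.cell_bounds[cell_id]
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        halos.append(
            HaloSpec(cell_id=cell_id, center=(cx, cy), radius_px=radius, target_b=target_b)
        )
    return SyntheticPlateSpec(halos=tuple(halos), noise_sigma=noise_sigma)
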