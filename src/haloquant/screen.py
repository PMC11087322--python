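"""Plate layout, density matrix and clone ranking.

A plate is divided into a grid of equal cells, each inoculated with one
clone.  Per-cell halo areas measured under several (temperature, day)
conditions are organised into a clones x conditions "density matrix", from
which clones are ranked by breadth of temperature response and total halo
area, and the screen's hit rate is summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridLayout",
    "HaloAreaRecord",
    "ScreenSummary",
    "RankedClone",
    "build_density_matrix",
    "rank_clones",
    "summarize_screen",
    "condition_label",
]


class DataError(ValueError):
    """Inconsistent or duplicated screening data."""


def condition_label(temperature_c: float, day: int) -> str:
    """Column label for a (temperature, day) condition, e.g. ``T37_d1``."""
    t = int(temperature_c) if float(temperature_c).is_integer() else temperature_c
    return f"T{t}_d{day}"


@dataclass(frozen=True)
class GridLayout:
    """Rectangular division of a plate image into equal clone cells.

    ``cell_bounds`` maps a cell id to a half-open pixel rectangle
    ``(x0, y0, x1, y1)``; ``clone_labels`` maps cell ids to clone names
    (e.g. LP1..LP12 for positives, NG1..NG8 for negative controls).
    Cells are identified as ``"r{row}c{col}"`` with 0-based indices.
    """

    n_rows: int
    n_cols: int
    cell_bounds: dict[str, tuple[int, int, int, int]]
    clone_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        for cid in self.clone_labels:
            if cid not in self.cell_bounds:
                raise ValueError(f"labeled cell {cid!r} has no bounds")
        for cid, (x0, y0, x1, y1) in self.cell_bounds.items():
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"cell {cid!r} has empty bounds {x0, y0, x1, y1}")

    @classmethod
    def regular(
        cls,
        n_rows: int,
        n_cols: int,
        cell_size_px: int,
        origin: tuple[int, int] = (0, 0),
        clone_labels: dict[str, str] | None = None,
    ) -> "GridLayout":
        """Equal square cells of ``cell_size_px``, top-left at ``origin``."""
        ox, oy = origin
        bounds = {}
        for r in range(n_rows):
            for c in range(n_cols):
                bounds[f"r{r}c{c}"] = (
                    ox + c * cell_size_px,
                    oy + r * cell_size_px,
                    ox + (c + 1) * cell_size_px,
                    oy + (r + 1) * cell_size_px,
                )
        return cls(n_rows, n_cols, bounds, clone_labels or {})

    def cell_at(self, x: float, y: float) -> str | None:
        """Cell id containing pixel (x, y), or None outside every cell."""
        for cid, (x0, y0, x1, y1) in self.cell_bounds.items():
            if x0 <= x < x1 and y0 <= y < y1:
                return cid
        return None

    def clone_at(self, x: float, y: float) -> str | None:
        cid = self.cell_at(x, y)
        return self.clone_labels.get(cid) if cid is not None else None

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_bounds": {k: list(v) for k, v in self.cell_bounds.items()},
            "clone_labels": dict(self.clone_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridLayout":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cell_bounds={k: tuple(int(u) for u in v) for k, v in d["cell_bounds"].items()},
            clone_labels=dict(d.get("clone_labels", {})),
        )


@dataclass(frozen=True)
class HaloAreaRecord:
    """One measured halo area for one clone under one condition."""

    clone: str
    temperature_c: float
    day: int
    area_cm2: float

    def __post_init__(self) -> None:
        if self.area_cm2 < 0:
            raise ValueError(f"area_cm2 must be >= 0, got {self.area_cm2}")


@dataclass(frozen=True)
class ScreenSummary:
    """Hit-rate summary of a functional screen."""

    n_screened: int
    positive_clones: tuple[str, ...]
    hit_rate_percent: float


@dataclass(frozen=True)
class RankedClone:
    """A clone's rank in the selection: tier 1 clones responded at every
    requested temperature; within a tier, larger total halo area first."""

    clone: str
    tier: int
    total_area_cm2: float


def build_density_matrix(
    records: list[HaloAreaRecord],
    clones: list[str],
    conditions: list[tuple[float, int]],
) -> pd.DataFrame:
    """Assemble halo-area records into a clones x conditions table.

    Rows are clone labels in the given order; columns are (temperature, day)
    pairs labelled ``T{temp}_d{day}``.  Pairs with no detected halo are 0.
    Duplicate (clone, condition) records and records referencing undeclared
    clones or conditions raise :class:`DataError`.
    """
    cols = [condition_label(t, d) for t, d in conditions]
    if len(set(cols)) != len(cols):
        raise DataError("duplicate conditions")
    if len(set(clones)) != len(clones):
        raise DataError("duplicate clone labels")
    dm = pd.DataFrame(0.0, index=pd.Index(clones, name="clone"), columns=cols)
    seen: set[tuple[str, str]] = set()
    for rec in records:
        col = condition_label(rec.temperature_c, rec.day)
        if rec.clone not in dm.index:
            raise DataError(f"record for undeclared clone {rec.clone!r}")
        if col not in dm.columns:
            raise DataError(f"record for undeclared condition {col!r}")
        key = (rec.clone, col)
        if key in seen:
            raise DataError(f"duplicate record for {rec.clone!r} at {col}")
        seen.add(key)
        dm.loc[rec.clone, col] = rec.area_cm2
    return dm


def rank_clones(
    dm: pd.DataFrame,
    day: int,
    temperatures: set[float] | list[float],
) -> list[RankedClone]:
    """Rank clones by breadth and size of response on a given day.

    Tier 1: clones with a halo (area > 0) at *all* requested temperatures
    on that day — the fast, temperature-robust responders.  Tier 2: the
    rest.  Within a tier, descending total area over the requested
    conditions; ties break alphabetically, so the ordering is deterministic.
    """
    cols = [condition_label(t, day) for t in sorted(set(temperatures))]
    missing = [c for c in cols if c not in dm.columns]
    if missing:
        raise ValueError(f"conditions not in density matrix: {missing}")
    sub = dm[cols]
    all_positive = (sub > 0).all(axis=1)
    totals = sub.sum(axis=1)
    ranked = sorted(
        (
            RankedClone(
                clone=str(clone),
                tier=1 if all_positive[clone] else 2,
                total_area_cm2=float(totals[clone]),
            )
            for clone in dm.index
        ),
        key=lambda r: (r.tier, -r.total_area_cm2, r.clone),
    )
    return ranked


def summarize_screen(n_screened: int, positive_clones: list[str]) -> ScreenSummary:
    """Hit rate of a screen: percent positives, one decimal, half away from zero.

    Exact integer arithmetic avoids float rounding at the .x5 boundary:
    the rate in tenths of a percent is floor((2000 k + n) / (2 n)).
    """
    n_pos = len(positive_clones)
    if n_screened <= 0:
        raise ValueError(f"n_screened must be > 0, got {n_screened}")
    if n_pos > n_screened:
        raise ValueError(f"{n_pos} positives exceed {n_screened} screened")
    tenths = (2000 * n_pos + n_screened) // (2 * n_screened)
    return ScreenSummary(
        n_screened=n_screened,
        positive_clones=tuple(positive_clones),
        hit_rate_percent=tenths / 10.0,
    )
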