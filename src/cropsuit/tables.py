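"""Municipality tables, productivity, standardization and occurrence sets.

Tabular I/O is plain CSV (header row, UTF-8) through pandas. The municipality
table layout mirrors an agricultural-census extract: one row per municipality
with coordinates of the central town, per-year production (tons) and harvested
area (hectares), and named technology covariates. Both a yearly layout
(``production_<year>`` / ``area_<year>`` columns) and a pre-averaged layout
(a single ``productivity`` column) are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, snap_to_grid

__all__ = [
    "compute_productivity",
    "bin_productivity",
    "z_transform",
    "OccurrenceSet",
    "read_cell_table",
    "write_cell_table",
    "productivity_from_table",
    "TECH_VARIABLES",
]

#: The eleven agricultural-technology census covariates, in census order.
TECH_VARIABLES = [
    "workers",
    "machinery_family",
    "machinery_nonfamily",
    "electric_energy",
    "establishment_area",
    "pest_control",
    "water_resources",
    "fertilizers",
    "agrochemicals",
    "irrigated_area",
    "irrigation_use",
]


def compute_productivity(production_by_year, area_by_year) -> float:
    """Average productivity (tons/hectare) over producing years.

    Productivity is the per-year ratio production/area, averaged over the
    years with harvested area > 0; zero-area years are excluded from the mean
    (0/0 is undefined and such years did not produce).

    Raises
    ------
    ValueError
        If the series lengths differ or no year has positive area.
    """
    prod = np.asarray(production_by_year, dtype=float)
    area = np.asarray(area_by_year, dtype=float)
    if prod.shape != area.shape:
        raise ValueError("production and area series must have equal length")
    if np.any(prod < 0) or np.any(area < 0):
        raise ValueError("production and harvested area must be non-negative")
    producing = area > 0
    if not np.any(producing):
        raise ValueError("no producing years (all harvested areas are zero)")
    return float(np.mean(prod[producing] / area[producing]))


def bin_productivity(values, bin_width: float) -> pd.Series:
    """Histogram of municipality counts per half-open productivity bin.

    Bins are ``(lo, hi]`` multiples of ``bin_width`` starting at 0, so with
    width 0.5 a value of exactly 2.50 falls in the bin (2.0, 2.5] — the
    convention behind census-style bin labels like "2.01 to 2.50". Returns a
    Series indexed by a pandas IntervalIndex, covering only the span of the
    data; counts always sum to ``len(values)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return pd.Series(dtype=int)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("values must be finite and >= 0")
    # a value exactly 0 is placed in the first bin (0, width]
    n_bins = max(int(np.ceil(values.max() / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    cut = pd.cut(values, bins=edges, right=True, include_lowest=True)
    counts = pd.Series(cut).value_counts().sort_index()
    counts.index = pd.IntervalIndex.from_breaks(edges, closed="right")
    return counts


def z_transform(values) -> np.ndarray:
    """Standardize to mean 0 and sample (n-1 denominator) SD 1.

    Order-preserving and idempotent to numerical tolerance. Raises on fewer
    than two values or a constant vector.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance: cannot Z-transform a constant vector")
    return (x - x.mean()) / sd


@dataclass
class OccurrenceSet:
    """Presence (and sampled pseudo-absence) cells on a grid.

    ``presence_cells`` and ``pseudo_absence_cells`` are (n, 2) arrays of
    (row, col) indices; duplicate presences within one cell are collapsed.
    """

    grid: GridSpec
    presence_cells: np.ndarray
    pseudo_absence_cells: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )

    @classmethod
    def from_points(cls, lonlat, grid: GridSpec) -> "OccurrenceSet":
        """Snap presence points to the grid, collapsing cell duplicates."""
        return cls(grid=grid, presence_cells=snap_to_grid(lonlat, grid))

    @property
    def n_presences(self) -> int:
        return len(self.presence_cells)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, cells in (
            ("presence", self.presence_cells),
            ("pseudo_absence", self.pseudo_absence_cells),
        ):
            if len(cells):
                lon, lat = self.grid.cell_center(cells[:, 0], cells[:, 1])
                frames.append(
                    pd.DataFrame(
                        {"lon": lon, "lat": lat, "row": cells[:, 0], "col": cells[:, 1], "label": label}
                    )
                )
        if not frames:
            return pd.DataFrame(columns=["lon", "lat", "row", "col", "label"])
        return pd.concat(frames, ignore_index=True)


def write_cell_table(df: pd.DataFrame, path) -> None:
    """Write a table as comma-separated UTF-8 CSV with a header row."""
    df.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_cell_table`."""
    df = pd.read_csv(path)
    if df.columns.str.startswith("Unnamed").any():
        raise ValueError("malformed table: unnamed columns (missing header?)")
    return df


_PROD_RE = re.compile(r"^production_(\d{4})$")


def productivity_from_table(df: pd.DataFrame) -> pd.Series:
    """Per-municipality average productivity from either table layout.

    Yearly layout: matching ``production_<year>`` / ``area_<year>`` column
    pairs, averaged with :func:`compute_productivity`. Pre-averaged layout: a
    ``productivity`` column taken as-is. Yearly columns win when both exist.
    """
    years = sorted(int(m.group(1)) for c in df.columns if (m := _PROD_RE.match(c)))
    if years:
        missing = [y for y in years if f"area_{y}" not in df.columns]
        if missing:
            raise ValueError(f"area columns missing for years {missing}")
        prod = df[[f"production_{y}" for y in years]].to_numpy(dtype=float)
        area = df[[f"area_{y}" for y in years]].to_numpy(dtype=float)
        return pd.Series(
            [compute_productivity(p, a) for p, a in zip(prod, area)],
            index=df.index,
            name="productivity",
        )
    if "productivity" in df.columns:
        return df["productivity"].astype(float)
    raise ValueError("table has neither production_<year>/area_<year> pairs nor a productivity column")
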