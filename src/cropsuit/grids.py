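"""Gridded domain types and ESRI ASCII grid I/O.

Conventions used throughout the package (stated once, used everywhere):
coordinates are decimal degrees with longitude in [-180, 180]; grid cells are
indexed row-major with 0-based (row, col) from the north-west corner; a point
lying exactly on a cell edge belongs to the cell to its south-east.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "EnvStack",
    "snap_to_grid",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``origin_lon``/``origin_lat`` are the *north-west corner* of the grid
    (west edge longitude, north edge latitude). ``cell_size`` is in degrees.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row, col):
        """Lon/lat of cell centers for (arrays of) row/col indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat arrays of shape (n_rows, n_cols) for every cell center."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        east = self.origin_lon + self.n_cols * self.cell_size
        south = self.origin_lat - self.n_rows * self.cell_size
        return (lon >= self.origin_lon) & (lon < east) & (lat > south) & (lat <= self.origin_lat)


def snap_to_grid(
    points, grid: GridSpec, collapse_duplicates: bool = True
) -> np.ndarray:
    """Map (lon, lat) points to 0-based (row, col) cell indices.

    Edge convention: a point on a cell boundary belongs to the cell to its
    south-east, consistent with the row-major north-west origin.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        Columns are longitude, latitude in decimal degrees.
    collapse_duplicates : bool
        If True (default) duplicate cells are collapsed, preserving first-seen
        order.

    Raises
    ------
    ValueError
        If any point falls outside the grid extent; the message carries the
        offending coordinate.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lon, lat = pts[:, 0], pts[:, 1]
    inside = grid.contains(lon, lat)
    if not np.all(inside):
        bad = pts[~inside][0]
        raise ValueError(f"point outside grid extent: lon={bad[0]}, lat={bad[1]}")
    col = np.floor((lon - grid.origin_lon) / grid.cell_size).astype(int)
    row = np.floor((grid.origin_lat - lat) / grid.cell_size).astype(int)
    # lat exactly on the north edge maps to row 0 (south-east rule)
    row = np.clip(row, 0, grid.n_rows - 1)
    col = np.clip(col, 0, grid.n_cols - 1)
    cells = np.column_stack([row, col])
    if collapse_duplicates:
        _, idx = np.unique(cells, axis=0, return_index=True)
        cells = cells[np.sort(idx)]
    return cells


@dataclass
class EnvStack:
    """Named environmental layers on a common grid.

    ``layers`` maps variable name -> float array of shape ``grid.shape``;
    off-domain cells are NaN. Insertion order of ``layers`` is the variable
    order.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} does not match grid {self.grid.shape}"
                )
            self.layers[name] = arr

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_variables(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def valid_mask(self) -> np.ndarray:
        """Cells with complete (non-NaN) data across all variables."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask

    def as_matrix(self, cells: np.ndarray | None = None) -> np.ndarray:
        """Environmental matrix, one row per cell, one column per variable.

        With ``cells`` (an (n, 2) array of row/col indices) rows follow that
        order; otherwise all grid cells in row-major order.
        """
        if cells is None:
            return np.column_stack([a.ravel() for a in self.layers.values()])
        cells = np.asarray(cells)
        return np.column_stack([a[cells[:, 0], cells[:, 1]] for a in self.layers.values()])

    def subset(self, names) -> "EnvStack":
        return EnvStack(self.grid, {n: self.layers[n] for n in names})


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_ascii_grid(path, values: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (rows north to south)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon!r}\n")
        fh.write(f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; NODATA cells become NaN.

    Returns ``(values, grid)`` with values of shape ``grid.shape``.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if len(header) < 6 and key in _HEADER_KEYS:
                if len(tokens) != 2:
                    raise ValueError(f"malformed header line: {line.strip()!r}")
                header[key] = float(tokens[1])
            else:
                try:
                    rows.append([float(t) for t in tokens])
                except ValueError as exc:
                    raise ValueError(f"malformed data line: {line.strip()!r}") from exc
    missing = [k for k in _HEADER_KEYS if k != "nodata_value" and k not in header]
    if missing:
        raise ValueError(f"missing header keys: {missing}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    if len(rows) != n_rows or any(len(r) != n_cols for r in rows):
        raise ValueError("data block does not match nrows/ncols (ragged or truncated)")
    values = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    cell = header["cellsize"]
    grid = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return values, grid


def read_env_stack(paths: dict[str, str]) -> EnvStack:
    """Read named ASCII grids into an EnvStack, checking grid agreement."""
    layers = {}
    grid = None
    for name, path in paths.items():
        values, g = read_ascii_grid(path)
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"layer {name!r} grid differs from first layer")
        layers[name] = values
    if grid is None:
        raise ValueError("no layers given")
    return EnvStack(grid, layers)


def write_env_stack(env: EnvStack, directory, prefix: str = "") -> dict[str, str]:
    """Write every layer as ``<prefix><name>.asc``; returns name -> path."""
    import os

    paths = {}
    for name, arr in env.layers.items():
        path = os.path.join(str(directory), f"{prefix}{name}.asc")
        write_ascii_grid(path, arr, env.grid)
        paths[name] = path
    return paths
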