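"""Regular planar grids and ESRI ASCII raster I/O.

All grids live in a projected planar coordinate system in meters. A grid is
stored row-major with row 0 at the *top* (north), matching the ESRI ASCII
grid convention, with the origin given as the lower-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: lower-left origin, square cells."""

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def from_extent(
        cls, x0: float, y0: float, width: float, height: float, cell_size: float
    ) -> "GridSpec":
        if width <= 0 or height <= 0:
            raise ValueError("extent must be positive")
        if cell_size > width or cell_size > height:
            raise ValueError("cell size larger than extent")
        n_cols = int(np.ceil(width / cell_size))
        n_rows = int(np.ceil(height / cell_size))
        return cls(x0, y0, cell_size, n_cols, n_rows)

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) center coordinates, shape (n_rows, n_cols), row 0 north."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class Raster:
    """A single-band grid of values on a :class:`GridSpec`."""

    values: np.ndarray
    spec: GridSpec
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def cell_size(self) -> float:
        return self.spec.cell_size

    def mask_valid(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.values != self.nodata

    def aligned_with(self, other: "Raster") -> bool:
        return self.spec == other.spec


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    spec = raster.spec
    nodata = raster.nodata if raster.nodata is not None else -9999
    lines = [
        f"ncols {spec.n_cols}",
        f"nrows {spec.n_rows}",
        f"xllcorner {spec.x0:.6f}",
        f"yllcorner {spec.y0:.6f}",
        f"cellsize {spec.cell_size:.6f}",
        f"NODATA_value {nodata}",
    ]
    vals = raster.values
    if raster.nodata is None:
        vals = np.where(np.isfinite(vals), vals, nodata)
    body = "\n".join(" ".join(format(v, ".10g") for v in row) for row in vals)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_ascii_grid(path: str | Path, dtype=float) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(text[i:], dtype=dtype)
    values = np.atleast_2d(values)
    spec = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    nodata = header.get("nodata_value")
    if nodata is not None and dtype is not float:
        nodata = dtype(nodata)
    return Raster(values=values, spec=spec, nodata=nodata)
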