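"""Gridded environmental layers.

An :class:`EnvGrid` is a stack of named environmental layers (e.g. bioclimatic
and land-cover variables) on a common rectangular grid with a shared validity
mask. Coordinates are planar map units; cell ``(r, c)`` covers the half-open
square ``[origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s,
origin_y - r*s]`` with rows increasing southward, so snapping a point to a
cell is unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnvGrid", "read_ascii_grid", "write_ascii_grid", "resample_to"]

NODATA_DEFAULT = -9999.0


@dataclass
class EnvGrid:
    """Stack of environmental layers on a common grid.

    Parameters
    ----------
    layer_names : list of str
        One identifier per layer.
    values : ndarray of shape (n_layers, n_rows, n_cols)
        Per-layer cell values. Masked-out cells carry the no-data value and
        are excluded from every statistic.
    mask : ndarray of bool, shape (n_rows, n_cols)
        True where the cell is valid (land).
    origin_x, origin_y : float
        Map coordinates of the top-left corner of cell (0, 0).
    cell_size : float
        Cell edge length in map units (square cells).
    """

    layer_names: list[str]
    values: np.ndarray
    mask: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = field(default=NODATA_DEFAULT)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None, :, :]
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape[0] != len(self.layer_names):
            raise ValueError("number of layers does not match layer_names")
        if self.values.shape[1:] != self.mask.shape:
            raise ValueError("layer shape does not match mask shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer_names must be unique")
        self.values[:, ~self.mask] = self.nodata

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def same_geometry(self, other: "EnvGrid") -> bool:
        return (
            self.mask.shape == other.mask.shape
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_of(self, x, y):
        """Snap map coordinates to (row, col) indices (may be out of range)."""
        c = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        r = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        # points exactly on the top/left boundary belong to row/col 0 by the
        # half-open convention; the floor above already handles that.
        return r, c

    def in_grid(self, x, y):
        r, c = self.cell_of(x, y)
        return (r >= 0) & (r < self.n_rows) & (c >= 0) & (c < self.n_cols)

    def cell_center(self, r, c):
        x = self.origin_x + (np.asarray(c) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(r) + 0.5) * self.cell_size
        return x, y

    def valid_cell_centers(self) -> np.ndarray:
        """(n_valid, 2) array of x, y centres of valid cells, row-major order."""
        rr, cc = np.nonzero(self.mask)
        x, y = self.cell_center(rr, cc)
        return np.column_stack([x, y])

    # -- layers -------------------------------------------------------------
    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"no such layer: {name!r}") from None
        return self.values[i]

    def single(self, name: str) -> "EnvGrid":
        """A one-layer EnvGrid sharing geometry and mask."""
        return EnvGrid([name], self.layer(name).copy(), self.mask.copy(),
                       self.origin_x, self.origin_y, self.cell_size, self.nodata)

    def extract(self, x, y) -> np.ndarray:
        """Environmental values (n_points, n_layers) at map coordinates.

        Points outside the grid or on invalid cells yield NaN rows.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full((x.size, len(self.layer_names)), np.nan)
        inside = self.in_grid(x, y)
        r, c = self.cell_of(x[inside], y[inside])
        ok = self.mask[r, c]
        idx = np.nonzero(inside)[0][ok]
        out[idx] = self.values[:, r[ok], c[ok]].T
        return out

    @staticmethod
    def stack(layers: list["EnvGrid"]) -> "EnvGrid":
        """Stack single-layer grids sharing geometry; masks are intersected."""
        if not layers:
            raise ValueError("nothing to stack")
        first = layers[0]
        for g in layers[1:]:
            if not first.same_geometry(g):
                raise ValueError("cannot stack grids with different geometry")
        mask = np.logical_and.reduce([g.mask for g in layers])
        names: list[str] = []
        vals = []
        for g in layers:
            names.extend(g.layer_names)
            vals.append(g.values)
        return EnvGrid(names, np.concatenate(vals, axis=0), mask,
                       first.origin_x, first.origin_y, first.cell_size, first.nodata)


def read_ascii_grid(path, name: str | None = None) -> EnvGrid:
    """Read a single-band ESRI ASCII grid (.asc) into a one-layer EnvGrid.

    The header must provide ncols, nrows, xllcorner, yllcorner and cellsize;
    NODATA_value is optional (default -9999).
    """
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError as exc:
                    raise ValueError(f"malformed ASCII grid header line: {line!r}") from exc
                n_header += 1
            else:
                break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= header.keys():
        missing = sorted(required - header.keys())
        raise ValueError(f"ASCII grid header missing keys: {missing}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    data = np.loadtxt(path, skiprows=n_header, ndmin=2)
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"ASCII grid body shape {data.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    mask = ~np.isclose(data, nodata)
    origin_y = header["yllcorner"] + nrows * header["cellsize"]
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return EnvGrid([name], data, mask, header["xllcorner"], origin_y,
                   header["cellsize"], nodata)


def write_ascii_grid(grid: EnvGrid, path, layer: str | None = None) -> None:
    """Write one layer of an EnvGrid as an ESRI ASCII grid."""
    if layer is None:
        if len(grid.layer_names) != 1:
            raise ValueError("grid has several layers; specify which to write")
        layer = grid.layer_names[0]
    vals = grid.layer(layer).copy()
    vals[~grid.mask] = grid.nodata
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def resample_to(source: EnvGrid, template: EnvGrid) -> EnvGrid:
    """Nearest-neighbour resampling of ``source`` onto ``template`` geometry.

    Each template cell takes the value of the source cell containing its
    centre; template cells whose centre falls outside the source (or on a
    masked source cell) are masked.
    """
    sx0, sy0, sx1, sy1 = source.bounds()
    tx0, ty0, tx1, ty1 = template.bounds()
    if sx0 >= tx1 or tx0 >= sx1 or sy0 >= ty1 or ty0 >= sy1:
        raise ValueError("source and template grids do not overlap spatially")
    rr, cc = np.meshgrid(np.arange(template.n_rows), np.arange(template.n_cols),
                         indexing="ij")
    x, y = template.cell_center(rr, cc)
    sr, sc = source.cell_of(x, y)
    inside = (sr >= 0) & (sr < source.n_rows) & (sc >= 0) & (sc < source.n_cols)
    sr_c = np.clip(sr, 0, source.n_rows - 1)
    sc_c = np.clip(sc, 0, source.n_cols - 1)
    vals = source.values[:, sr_c, sc_c]
    mask = inside & source.mask[sr_c, sc_c] & template.mask
    vals = np.where(mask[None], vals, source.nodata)
    if not mask.any():
        warnings.warn("resampled grid has no valid cells")
    return EnvGrid(list(source.layer_names), vals, mask, template.origin_x,
                   template.origin_y, template.cell_size, source.nodata)
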