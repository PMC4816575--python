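"""Georeferenced raster containers shared by every pipeline stage.

A :class:`GeoGrid` is a 2-D field of values with a nodata mask and an
affine north-up georeferencing; a :class:`GridStack` is an ordered,
label-addressable collection of grids sharing one geometry (e.g. the 12
monthly layers of a climatology, or the daily layers of one sensor-month).

Convention: cell-centre registration, row 0 is the northernmost row, and
point-to-cell lookups use half-open cell intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np


class GridTransform(NamedTuple):
    """North-up affine georeferencing.

    ``(x_origin, y_origin)`` is the outer corner of the top-left cell;
    ``dx``/``dy`` are strictly positive cell sizes in degrees.  The centre
    of cell ``(row, col)`` sits at ``(x_origin + (col + 0.5) * dx,
    y_origin - (row + 0.5) * dy)``.
    """

    x_origin: float
    y_origin: float
    dx: float
    dy: float


@dataclass
class GeoGrid:
    """A single-band georeferenced raster with an explicit nodata mask."""

    values: np.ndarray
    mask: np.ndarray = None  # True where nodata
    transform: GridTransform = GridTransform(0.0, 0.0, 1.0, 1.0)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GeoGrid values must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        self.transform = GridTransform(*self.transform)
        if self.transform.dx <= 0 or self.transform.dy <= 0:
            raise ValueError("cell sizes must be strictly positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "GeoGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.transform, other.transform)
            and self.crs == other.crs
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude arrays of all cell centres (2-D each)."""
        t = self.transform
        nr, nc = self.shape
        lon = t.x_origin + (np.arange(nc) + 0.5) * t.dx
        lat = t.y_origin - (np.arange(nr) + 0.5) * t.dy
        return np.meshgrid(lon, lat)

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing a point; half-open intervals, row 0 north."""
        t = self.transform
        col = int(np.floor((lon - t.x_origin) / t.dx))
        row = int(np.floor((t.y_origin - lat) / t.dy))
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise IndexError(f"point ({lon}, {lat}) outside grid")
        return row, col

    # -- values -------------------------------------------------------
    def filled(self, fill=np.nan) -> np.ndarray:
        """Values with masked cells replaced by *fill*."""
        out = self.values.astype(float).copy()
        out[self.mask] = fill
        return out

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def copy_with(self, values=None, mask=None) -> "GeoGrid":
        return GeoGrid(
            values=self.values.copy() if values is None else np.asarray(values, float),
            mask=self.mask.copy() if mask is None else np.asarray(mask, bool),
            transform=self.transform,
            crs=self.crs,
        )


@dataclass
class GridStack:
    """Ordered grids on one shared geometry, addressable by unique label."""

    grids: list[GeoGrid] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.grids) != len(self.labels):
            raise ValueError("grids and labels must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        for g in self.grids[1:]:
            if not g.same_geometry(self.grids[0]):
                raise ValueError("all grids in a stack must share geometry")

    def __len__(self) -> int:
        return len(self.grids)

    def __getitem__(self, label: str) -> GeoGrid:
        return self.grids[self.labels.index(label)]

    def __iter__(self):
        return iter(zip(self.labels, self.grids))

    @property
    def transform(self) -> GridTransform:
        return self.grids[0].transform

    @property
    def crs(self) -> str:
        return self.grids[0].crs

    def as_array(self, fill=np.nan) -> np.ndarray:
        """(n_layers, rows, cols) array with masked cells set to *fill*."""
        return np.stack([g.filled(fill) for g in self.grids])

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        labels: Sequence[str],
        transform: GridTransform = GridTransform(0.0, 0.0, 1.0, 1.0),
        crs: str = "EPSG:4326",
        mask: np.ndarray | None = None,
    ) -> "GridStack":
        arr = np.asarray(arr, float)
        grids = []
        for i in range(arr.shape[0]):
            m = None if mask is None else (mask[i] if mask.ndim == 3 else mask)
            grids.append(GeoGrid(arr[i], mask=m, transform=transform, crs=crs))
        return cls(grids=grids, labels=list(labels))


MONTH_LABELS = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]
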