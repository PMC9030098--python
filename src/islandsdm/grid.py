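"""Gridded spatial containers.

Everything downstream of the landscape generator moves through two
containers: :class:`RasterGrid`, a single-band georeferenced grid on an
equirectangular lon/lat lattice with a stated cell size in km, and
:class:`LayerStack`, an ordered, geometry-checked mapping of named grids.

Conventions
-----------
* row 0 is the northern edge; columns increase eastward,
* nodata is ``NaN`` (sea cells are nodata in every derived product),
* distances are computed in projected km (equirectangular about a
  reference latitude) or great-circle km, never in degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

#: Authalic Earth radius, km.
EARTH_RADIUS_KM = 6371.0072
#: km spanned by one degree of latitude (and of longitude at the equator).
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class RasterGrid:
    """Single-band grid with geotransform implied by (west, north, cell_km).

    Parameters
    ----------
    data
        2-D float array, ``NaN`` = nodata. Boolean masks are stored as
        0/1 floats.
    west, north
        Longitude / latitude of the outer NW corner, degrees.
    cell_km
        Cell side length in km (cells are square in projected km, hence
        rectangular in degrees).
    ref_lat
        Latitude at which the lon->km scale is anchored.
    """

    data: np.ndarray
    west: float
    north: float
    cell_km: float = 1.0
    ref_lat: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")
        if self.ref_lat is None:
            self.ref_lat = self.north - 0.5 * self.data.shape[0] * self.dlat

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def dlat(self) -> float:
        """Cell height in degrees latitude."""
        return self.cell_km / KM_PER_DEG

    @property
    def dlon(self) -> float:
        """Cell width in degrees longitude (at ref_lat)."""
        lat = self.ref_lat if self.ref_lat is not None else self.north
        return self.cell_km / (KM_PER_DEG * np.cos(np.radians(lat)))

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.north, other.north)
            and np.isclose(self.cell_km, other.cell_km)
            and np.isclose(self.ref_lat, other.ref_lat)
        )

    def like(self, data: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's geometry."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError(f"shape {data.shape} != grid shape {self.shape}")
        return RasterGrid(data, self.west, self.north, self.cell_km, self.ref_lat)

    # -- coordinates ----------------------------------------------------
    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.shape[1]) + 0.5) * self.dlon

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.shape[0]) + 0.5) * self.dlat

    def cell_center(self, rows, cols):
        """(lon, lat) of cell centers for row/col index arrays."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        lon = self.west + (cols + 0.5) * self.dlon
        lat = self.north - (rows + 0.5) * self.dlat
        return lon, lat

    def index_of(self, lon, lat):
        """(row, col, inside) for lon/lat arrays; inside is a bool mask."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.dlon).astype(int)
        row = np.floor((self.north - lat) / self.dlat).astype(int)
        inside = (row >= 0) & (row < self.shape[0]) & (col >= 0) & (col < self.shape[1])
        return row, col, inside

    def xy_km(self, lon, lat):
        """Equirectangular projection to km (x east, y south of `north`)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = (lon - self.west) * KM_PER_DEG * np.cos(np.radians(self.ref_lat))
        y = (self.north - lat) * KM_PER_DEG
        return x, y

    # -- masks ----------------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.data)

    def valid_values(self) -> np.ndarray:
        return self.data[self.valid]

    # -- I/O -------------------------------------------------------------
    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        """Write as ESRI ASCII grid (projected-km coordinates) + JSON sidecar.

        The .asc carries the lattice in local km; the sidecar records the
        lon/lat georeference so :meth:`read_ascii` round-trips.
        """
        path = Path(path)
        nrows, ncols = self.shape
        header = (
            f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\n"
            f"yllcorner {-nrows * self.cell_km}\ncellsize {self.cell_km}\n"
            f"NODATA_value -9999\n"
        )
        body = np.where(self.valid, self.data, -9999.0)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt=fmt)
        sidecar = {"west": self.west, "north": self.north, "cell_km": self.cell_km, "ref_lat": self.ref_lat}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                k, v = fh.readline().split()
                hdr[k.lower()] = float(v)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        data[data == hdr.get("nodata_value", -9999.0)] = np.nan
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(data, meta["west"], meta["north"], meta["cell_km"], meta["ref_lat"])


class LayerStack(Mapping):
    """Named, geometry-checked collection of :class:`RasterGrid` layers."""

    def __init__(self, layers: Mapping[str, RasterGrid] | None = None, provenance: Mapping[str, str] | None = None):
        self._layers: dict[str, RasterGrid] = {}
        self.provenance: dict[str, str] = {}
        if layers:
            for name, grid in layers.items():
                note = (provenance or {}).get(name, "")
                self.add(name, grid, note)

    def add(self, name: str, grid: RasterGrid, note: str = "") -> None:
        if name in self._layers:
            raise KeyError(f"duplicate layer name {name!r}")
        if self._layers:
            ref = next(iter(self._layers.values()))
            if not ref.same_geometry(grid):
                raise ValueError(f"layer {name!r} does not share the stack geometry")
        self._layers[name] = grid
        self.provenance[name] = note

    # Mapping protocol
    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self._layers.values()))

    def subset(self, names) -> "LayerStack":
        out = LayerStack()
        for n in names:
            out.add(n, self._layers[n], self.provenance.get(n, ""))
        return out

    def common_valid(self) -> np.ndarray:
        """Boolean mask of cells valid in every layer."""
        mask = np.ones(self.template.shape, dtype=bool)
        for g in self._layers.values():
            mask &= g.valid
        return mask

    def to_matrix(self, rows=None, cols=None, names=None):
        """Sample layers into an (n, d) matrix.

        With no indices, returns (rows, cols, X) over the common valid mask;
        with indices, returns X at those cells.
        """
        names = list(names) if names is not None else self.names
        if rows is None:
            mask = self.common_valid()
            rows, cols = np.nonzero(mask)
            X = np.column_stack([self._layers[n].data[rows, cols] for n in names])
            return rows, cols, X
        return np.column_stack([self._layers[n].data[rows, cols] for n in names])

    def values_at(self, lon, lat, names=None):
        """Matrix of layer values at lon/lat points (NaN outside grid)."""
        names = list(names) if names is not None else self.names
        row, col, inside = self.template.index_of(lon, lat)
        row, col, inside = np.atleast_1d(row), np.atleast_1d(col), np.atleast_1d(inside)
        out = np.full((row.shape[0], len(names)), np.nan)
        for j, n in enumerate(names):
            out[inside, j] = self._layers[n].data[row[inside], col[inside]]
        return out

    # -- I/O -------------------------------------------------------------
    def write_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for name, grid in self._layers.items():
            fname = f"{name}.asc"
            grid.write_ascii(directory / fname)
            manifest[name] = {"file": fname, "derivation": self.provenance.get(name, "")}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def read_dir(cls, directory: str | Path) -> "LayerStack":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        out = cls()
        for name, entry in manifest.items():
            out.add(name, RasterGrid.read_ascii(directory / entry["file"]), entry.get("derivation", ""))
        return out
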