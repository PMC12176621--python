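"""Gridded bathymetry: reading, writing and nearest-cell seabed-depth lookup.

Grids follow the GEBCO convention: a regular lon/lat raster of elevation in
metres, negative below sea level.  Seabed depth is defined as ``-elevation``
and only where ``elevation < 0``; cells with elevation >= 0 (land, including
the shoreline at exactly 0) have no seabed depth.

Cells are half-open ``[lo, hi)`` on both axes, so a coordinate lying exactly
on a cell boundary belongs to the cell to the north-east.  Longitude 180
wraps to -180 before lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

__all__ = ["BathymetryGrid", "read_bathymetry", "write_bathymetry"]

#: tolerance on grid-spacing uniformity, degrees
_SPACING_TOL = 1e-9


class BathymetryError(ValueError):
    """Raised for malformed or unsupported bathymetry inputs."""


@dataclass(frozen=True)
class BathymetryGrid:
    """Regular lon/lat elevation grid.

    Parameters
    ----------
    lon_edges, lat_edges
        Strictly ascending cell-boundary coordinates (length ``n + 1`` for
        ``n`` cells along each axis), uniformly spaced.
    elevation_m
        Elevation per cell, shape ``(n_lat, n_lon)``, metres, negative below
        sea level.
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    elevation_m: np.ndarray
    _res: tuple[float, float] = field(init=False, repr=False, default=(0.0, 0.0))

    def __post_init__(self) -> None:
        lon = np.asarray(self.lon_edges, dtype=float)
        lat = np.asarray(self.lat_edges, dtype=float)
        elev = np.asarray(self.elevation_m, dtype=float)
        object.__setattr__(self, "lon_edges", lon)
        object.__setattr__(self, "lat_edges", lat)
        object.__setattr__(self, "elevation_m", elev)
        for name, edges in (("lon", lon), ("lat", lat)):
            if edges.ndim != 1 or edges.size < 2:
                raise BathymetryError(f"{name}_edges must be 1-D with >= 2 entries")
            steps = np.diff(edges)
            if np.any(steps <= 0):
                raise BathymetryError(f"{name}_edges must be strictly ascending")
            if np.ptp(steps) > _SPACING_TOL:
                raise BathymetryError(
                    f"non-regular grid: {name} spacing varies by {np.ptp(steps):.3g} deg "
                    f"(tolerance {_SPACING_TOL} deg)"
                )
        if elev.shape != (lat.size - 1, lon.size - 1):
            raise BathymetryError(
                f"elevation shape {elev.shape} does not match grid "
                f"({lat.size - 1}, {lon.size - 1})"
            )
        object.__setattr__(self, "_res", (float(np.mean(np.diff(lon))), float(np.mean(np.diff(lat)))))

    @property
    def resolution(self) -> tuple[float, float]:
        """(lon, lat) cell size in degrees."""
        return self._res

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation_m.shape

    def seabed_depth(self) -> np.ndarray:
        """Per-cell seabed depth in metres (positive down); NaN over land."""
        return np.where(self.elevation_m < 0, -self.elevation_m, np.nan)

    def locate(self, lons: np.ndarray, lats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to cell indices.

        Returns ``(iy, ix, inside)``; indices are only valid where ``inside``.
        Longitude 180 wraps to -180 when the grid starts at -180.
        """
        lons = np.asarray(lons, dtype=float).copy()
        lats = np.asarray(lats, dtype=float)
        res_lon, res_lat = self._res
        if np.isclose(self.lon_edges[0], -180.0):
            lons[lons == 180.0] = -180.0
        ix = np.floor((lons - self.lon_edges[0]) / res_lon).astype(np.int64)
        iy = np.floor((lats - self.lat_edges[0]) / res_lat).astype(np.int64)
        ny, nx = self.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        return iy, ix, inside

    def seabed_depth_at(self, lons: np.ndarray, lats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell seabed depth at each point.

        Returns ``(depth_m, status)`` where depth is NaN for any point not in
        an ocean cell and status is one of ``"ocean"``, ``"on land"``,
        ``"outside grid"`` per point.
        """
        iy, ix, inside = self.locate(lons, lats)
        n = iy.size
        depth = np.full(n, np.nan)
        status = np.full(n, "outside grid", dtype=object)
        if inside.any():
            elev = self.elevation_m[iy[inside], ix[inside]]
            d = np.where(elev < 0, -elev, np.nan)
            depth[inside] = d
            status[inside] = np.where(elev < 0, "ocean", "on land")
        return depth, status


_LON_NAMES = ("lon", "longitude", "x")
_LAT_NAMES = ("lat", "latitude", "y")
_ELEV_NAMES = ("elevation", "z", "Band1", "depth", "topo")


def read_bathymetry(path: str | Path) -> BathymetryGrid:
    """Read a single-variable regular lon/lat elevation grid from NetCDF.

    The file must contain 1-D longitude/latitude coordinates (cell centers,
    uniform spacing) and a 2-D elevation variable in metres with negative
    values below sea level.  GeoTIFF input is not supported; convert to
    NetCDF first.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raise BathymetryError(
            "GeoTIFF input is not supported; supply a NetCDF grid with "
            "lon/lat coordinates and elevation in metres (negative below sea level)"
        )
    try:
        ds = xr.open_dataset(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise BathymetryError(f"cannot open bathymetry file {path}: {exc}") from exc
    with ds:
        lon_name = next((n for n in _LON_NAMES if n in ds.coords or n in ds.variables), None)
        lat_name = next((n for n in _LAT_NAMES if n in ds.coords or n in ds.variables), None)
        if lon_name is None or lat_name is None:
            raise BathymetryError(
                f"no lon/lat coordinates found in {path} (looked for {_LON_NAMES}/{_LAT_NAMES})"
            )
        var_name = next(
            (n for n in _ELEV_NAMES if n in ds.data_vars),
            next((n for n, v in ds.data_vars.items() if v.ndim == 2), None),
        )
        if var_name is None:
            raise BathymetryError(f"no 2-D elevation variable found in {path}")
        da = ds[var_name]
        if da.dims != (lat_name, lon_name):
            da = da.transpose(lat_name, lon_name)
        lat_c = np.asarray(ds[lat_name], dtype=float)
        lon_c = np.asarray(ds[lon_name], dtype=float)
        elev = np.asarray(da, dtype=float)
    if lat_c.size > 1 and lat_c[1] < lat_c[0]:  # north-up rasters
        lat_c = lat_c[::-1]
        elev = elev[::-1, :]
    return BathymetryGrid(
        lon_edges=_centers_to_edges(lon_c, "lon"),
        lat_edges=_centers_to_edges(lat_c, "lat"),
        elevation_m=elev,
    )


def write_bathymetry(grid: BathymetryGrid, path: str | Path) -> None:
    """Write a grid as classic NetCDF (cell-center lon/lat, elevation in metres)."""
    ds = xr.Dataset(
        {"elevation": (("lat", "lon"), grid.elevation_m)},
        coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        attrs={"Conventions": "CF-1.8"},
    )
    ds["elevation"].attrs.update(units="m", positive="up")
    ds.to_netcdf(Path(path), engine="scipy")


def _centers_to_edges(centers: np.ndarray, name: str) -> np.ndarray:
    if centers.size < 2:
        raise BathymetryError(f"{name} axis needs >= 2 cells")
    steps = np.diff(centers)
    if np.any(steps <= 0) or np.ptp(steps) > _SPACING_TOL:
        raise BathymetryError(f"non-regular grid: {name} centers are not uniformly spaced")
    h = float(np.mean(steps))
    return np.concatenate([centers - h / 2, [centers[-1] + h / 2]])
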