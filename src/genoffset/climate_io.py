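"""Georeferenced climate grids, point extraction, ensembles, and scaling.

Rasters are plain numpy grids with a cell-center affine georeference
(row 0 = northernmost row, WGS84 lon/lat). NaN is the in-memory nodata
sentinel and is propagated, never imputed. Text I/O uses the ESRI
ASCII-grid format so raster artifacts stay human-readable.

The :class:`Scaler` captures the train-time standardization contract:
per-variable means and standard deviations are estimated once from the
sampled-tree (current period) climate table, and every later table or
raster — future scenarios included — is scaled with those same training
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Raster",
    "RasterSet",
    "ExtractionResult",
    "Scaler",
    "bilinear_extract",
    "ensemble_mean",
    "fit_scaler",
    "apply_scaler",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class Raster:
    """Single-band raster with cell-center registration.

    Parameters
    ----------
    data
        2-D float array, row 0 = north. NaN marks nodata.
    west, north
        Outer edge coordinates of the top-left cell (degrees).
    dx, dy
        Positive cell sizes in degrees (dy is the north-south extent of a
        cell; rows advance southward).
    crs
        Coordinate reference identifier; only stored and compared.
    """

    data: np.ndarray
    west: float
    north: float
    dx: float
    dy: float
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds."""
        nrows, ncols = self.shape
        return (
            self.west,
            self.north - nrows * self.dy,
            self.west + ncols * self.dx,
            self.north,
        )

    def x_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.shape[1]) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.shape[0]) + 0.5) * self.dy

    def grid_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (lon, lat) arrays of every cell center."""
        xx, yy = np.meshgrid(self.x_centers(), self.y_centers())
        return xx, yy

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.north, other.north)
            and np.isclose(self.dx, other.dx)
            and np.isclose(self.dy, other.dy)
            and self.crs == other.crs
        )

    def copy_with(self, data: np.ndarray) -> "Raster":
        if np.shape(data) != self.shape:
            raise ValueError("replacement data shape mismatch")
        return Raster(np.asarray(data, dtype=float), self.west, self.north,
                      self.dx, self.dy, self.crs)


@dataclass
class RasterSet:
    """Aligned single-band rasters keyed by variable name, plus a scenario tag."""

    rasters: dict[str, Raster]
    scenario: str = "current"

    def __post_init__(self) -> None:
        names = list(self.rasters)
        if names:
            ref = self.rasters[names[0]]
            for name in names[1:]:
                if not self.rasters[name].aligned_with(ref):
                    raise ValueError(
                        f"raster '{name}' is not aligned with '{names[0]}'"
                    )

    @property
    def variables(self) -> list[str]:
        return list(self.rasters)

    def __getitem__(self, name: str) -> Raster:
        return self.rasters[name]

    def template(self) -> Raster:
        return next(iter(self.rasters.values()))

    def map(self, fn) -> "RasterSet":
        return RasterSet(
            {k: r.copy_with(fn(k, r.data)) for k, r in self.rasters.items()},
            scenario=self.scenario,
        )


OK = "ok"
OUTSIDE = "outside"
NODATA = "nodata"


@dataclass
class ExtractionResult:
    """Per-point extraction values with explicit error records.

    ``flags`` holds one of ``"ok"``, ``"outside"`` (point outside raster
    bounds) or ``"nodata"`` (a bilinear neighbor carried nodata). Values
    at non-ok points are NaN, but the flag — not the NaN — is the error
    signal.
    """

    values: np.ndarray
    flags: np.ndarray

    @property
    def ok(self) -> np.ndarray:
        return self.flags == OK

    def errors(self) -> pd.DataFrame:
        bad = ~self.ok
        return pd.DataFrame(
            {"index": np.nonzero(bad)[0], "flag": self.flags[bad]}
        )


def bilinear_extract(raster: Raster, lons: Sequence[float],
                     lats: Sequence[float]) -> ExtractionResult:
    """Sample a raster at points by blending the four nearest cell centers.

    A point sitting exactly on a cell center reproduces that cell's stored
    value. Points in the outer half-cell margin (inside the bounds but
    beyond the outermost centers) degrade to edge interpolation by
    clamping the neighbor stencil. Points outside the raster bounds are
    flagged ``outside``; any NaN neighbor flags the point ``nodata``.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.shape != lats.shape:
        raise ValueError("lon/lat arrays must have the same length")
    n = lons.size
    values = np.full(n, np.nan)
    flags = np.full(n, OK, dtype=object)

    west, south, east, north = raster.bounds
    inside = (lons >= west) & (lons < east) & (lats > south) & (lats <= north)
    flags[~inside] = OUTSIDE

    nrows, ncols = raster.shape
    # fractional position in cell-center coordinates
    u = (lons - west) / raster.dx - 0.5
    v = (north - lats) / raster.dy - 0.5
    j0 = np.clip(np.floor(u).astype(int), 0, max(ncols - 2, 0))
    i0 = np.clip(np.floor(v).astype(int), 0, max(nrows - 2, 0))
    fx = np.clip(u - j0, 0.0, 1.0)
    fy = np.clip(v - i0, 0.0, 1.0)
    j1 = np.minimum(j0 + 1, ncols - 1)
    i1 = np.minimum(i0 + 1, nrows - 1)

    a = raster.data[i0, j0]
    b = raster.data[i0, j1]
    c = raster.data[i1, j0]
    d = raster.data[i1, j1]
    blend = ((1 - fy) * ((1 - fx) * a + fx * b)
             + fy * ((1 - fx) * c + fx * d))
    has_nodata = np.isnan(a) | np.isnan(b) | np.isnan(c) | np.isnan(d)
    flags[inside & has_nodata] = NODATA
    okmask = inside & ~has_nodata
    values[okmask] = blend[okmask]
    return ExtractionResult(values=values, flags=np.asarray(flags))


def extract_table(raster_set: RasterSet, lons, lats) -> pd.DataFrame:
    """Bilinear-extract every variable of a set at the given points."""
    out = {}
    for name in raster_set.variables:
        res = bilinear_extract(raster_set[name], lons, lats)
        out[name] = res.values
    return pd.DataFrame(out)


def ensemble_mean(rasters: Sequence[Raster]) -> Raster:
    """Cell-wise unweighted mean across aligned rasters.

    Mirrors the ensemble-mean step used to combine global circulation
    models: nodata in any member makes the output cell nodata.
    """
    rasters = list(rasters)
    if len(rasters) < 2:
        raise ValueError("ensemble mean needs at least 2 rasters")
    ref = rasters[0]
    for idx, r in enumerate(rasters[1:], start=1):
        if not r.aligned_with(ref):
            raise ValueError(f"raster #{idx} grid does not match raster #0")
    stack = np.stack([r.data for r in rasters])
    return ref.copy_with(stack.mean(axis=0))  # NaN propagates


@dataclass
class Scaler:
    """Train-time per-variable standardization (mean 0, sd 1, ddof=1).

    Also records the training min/max envelope per variable, used later
    to flag climatically novel cells during spatial projection.
    """

    means: dict[str, float]
    sds: dict[str, float]
    mins: dict[str, float] = field(default_factory=dict)
    maxs: dict[str, float] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.means)

    def transform_table(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for v in self.variables:
            if v not in table.columns:
                raise KeyError(f"variable '{v}' missing from table")
            out[v] = (table[v] - self.means[v]) / self.sds[v]
        return out

    def transform_rasters(self, rs: RasterSet) -> RasterSet:
        missing = [v for v in self.variables if v not in rs.variables]
        if missing:
            raise KeyError(f"variables missing from raster set: {missing}")
        return RasterSet(
            {v: rs[v].copy_with((rs[v].data - self.means[v]) / self.sds[v])
             for v in self.variables},
            scenario=rs.scenario,
        )

    def transform(self, data):
        if isinstance(data, RasterSet):
            return self.transform_rasters(data)
        return self.transform_table(data)

    def novelty(self, table: pd.DataFrame) -> np.ndarray:
        """True where any variable falls outside the training envelope."""
        flag = np.zeros(len(table), dtype=bool)
        for v in self.variables:
            flag |= (table[v].to_numpy() < self.mins[v]) | (
                table[v].to_numpy() > self.maxs[v])
        return flag

    def to_dict(self) -> dict:
        return {
            "means": self.means, "sds": self.sds,
            "mins": self.mins, "maxs": self.maxs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scaler":
        return cls(dict(d["means"]), dict(d["sds"]),
                   dict(d.get("mins", {})), dict(d.get("maxs", {})))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "Scaler":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_scaler(table: pd.DataFrame,
               variables: Iterable[str] | None = None) -> Scaler:
    """Estimate per-variable mean/sd (ddof=1) from the training table.

    Must be fit only on current-period sampled-tree values; downstream
    data — future tables and raster grids alike — reuse these statistics.
    """
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])]
    means, sds, mins, maxs = {}, {}, {}, {}
    for v in variables:
        col = table[v].to_numpy(dtype=float)
        sd = float(np.std(col, ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"variable '{v}' has zero variance; cannot scale")
        means[v] = float(np.mean(col))
        sds[v] = sd
        mins[v] = float(np.min(col))
        maxs[v] = float(np.max(col))
    return Scaler(means, sds, mins, maxs)


def apply_scaler(scaler: Scaler, data):
    """Apply a fitted scaler to a climate table or raster set."""
    return scaler.transform(data)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (text raster format; square cells)

NODATA_VALUE = -9999.0


def write_ascii_grid(raster: Raster, path) -> None:
    if not np.isclose(raster.dx, raster.dy, rtol=1e-9):
        raise ValueError("ASCII grid requires square cells (dx == dy)")
    nrows, ncols = raster.shape
    south = raster.north - nrows * raster.dy
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.west!r}\n"
        f"yllcorner {south!r}\n"
        f"cellsize {raster.dx!r}\n"
        f"NODATA_value {NODATA_VALUE}\n"
    )
    body = np.where(np.isnan(raster.data), NODATA_VALUE, raster.data)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.8g")


def read_ascii_grid(path, crs: str = "EPSG:4326") -> Raster:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = hdr.get("nodata_value", NODATA_VALUE)
    data[data == nodata] = np.nan
    cell = hdr["cellsize"]
    north = hdr["yllcorner"] + hdr["nrows"] * cell
    return Raster(data, west=hdr["xllcorner"], north=north,
                  dx=cell, dy=cell, crs=crs)


def write_raster_set(rs: RasterSet, outdir, prefix: str = "") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in rs.variables:
        p = outdir / f"{prefix}{name}_{rs.scenario}.asc"
        write_ascii_grid(rs[name], p)
        paths.append(p)
    return paths
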