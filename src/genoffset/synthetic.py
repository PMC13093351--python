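"""Synthetic study system: paired sites, climate fields, structured genotypes.

Emulates a montane tree species sampled along the southern Andes with a
paired-site design: 10 locations spread over ~15 degrees of latitude,
each contributing a locally-high and a locally-low elevation site a
kilometre or so apart. Five bioclimatic predictors (bio3 isothermality,
gst growing-season temperature, scd snow-cover days, bio12 annual
precipitation, bio15 precipitation seasonality) ride on two
quasi-orthogonal gradients — temperature along latitude/elevation,
precipitation along longitude — with enough independent noise to keep
pairwise correlations moderate. Genotypes carry K discrete ancestral
pools mixed along latitude (Balding–Nichols differentiation) plus a
minority of planted climate-adaptive loci whose site allele frequencies
are logit-linear in one driver variable.

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .climate_io import Raster, RasterSet, bilinear_extract
from .genotypes import GenotypeMatrix

__all__ = [
    "CLIMATE_VARS",
    "SamplingDesign",
    "VariableField",
    "Scenario",
    "ClimateConfig",
    "default_climate_config",
    "generate_design",
    "generate_climate",
    "generate_genotypes",
    "generate_future",
    "admixture_weights",
    "true_site_frequencies",
    "haversine_km",
    "InfeasibleDesignError",
]

CLIMATE_VARS = ("bio3", "gst", "scd", "bio12", "bio15")

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = 111.195

# within-pair separations: supports are the observed ranges, Beta shapes
# place the means at the observed averages (1.1 km, 230 m)
PAIR_DIST_RANGE_KM = (0.6, 2.2)
PAIR_DIST_BETA = (2.0, 4.4)        # mean 0.3125 -> 0.6 + 1.6*0.3125 = 1.1 km
PAIR_DELEV_RANGE_M = (150.0, 320.0)
PAIR_DELEV_BETA = (2.0, 2.25)      # mean 0.4706 -> 150 + 170*0.4706 = 230 m


class InfeasibleDesignError(ValueError):
    """Raised when pair-geometry constraints cannot be satisfied."""


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between WGS84 points."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class SamplingDesign:
    """Site table for a paired elevation-gradient design.

    ``sites`` columns: site_id (1..N, numbered north to south), pair_id
    (NaN for ungrouped sites), area_id, latitude (negative = south),
    longitude, elevation (m a.s.l.), elevation_class in
    {high, low, middle, ungrouped}.
    """

    sites: pd.DataFrame

    def validate(self) -> None:
        s = self.sites
        required = {"site_id", "pair_id", "area_id", "latitude", "longitude",
                    "elevation", "elevation_class"}
        missing = required - set(s.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        ordered = s.sort_values("site_id")
        lats = ordered["latitude"].to_numpy()
        if not np.all(np.diff(lats) < 0):
            raise ValueError("site latitudes must strictly decrease with site_id")
        for pid, grp in s.dropna(subset=["pair_id"]).groupby("pair_id"):
            if len(grp) != 2:
                raise ValueError(f"pair {pid} does not have exactly 2 sites")
            if set(grp["elevation_class"]) != {"high", "low"}:
                raise ValueError(f"pair {pid} classes must be {{high, low}}")
            d = float(haversine_km(grp["latitude"].iloc[0], grp["longitude"].iloc[0],
                                   grp["latitude"].iloc[1], grp["longitude"].iloc[1]))
            de = abs(float(grp["elevation"].iloc[0] - grp["elevation"].iloc[1]))
            if not (PAIR_DIST_RANGE_KM[0] <= d <= PAIR_DIST_RANGE_KM[1]):
                raise ValueError(f"pair {pid} distance {d:.3f} km out of range")
            if not (PAIR_DELEV_RANGE_M[0] <= de <= PAIR_DELEV_RANGE_M[1]):
                raise ValueError(f"pair {pid} |Δelev| {de:.1f} m out of range")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pair_distances_km(self) -> pd.Series:
        out = {}
        for pid, grp in self.sites.dropna(subset=["pair_id"]).groupby("pair_id"):
            out[pid] = float(haversine_km(
                grp["latitude"].iloc[0], grp["longitude"].iloc[0],
                grp["latitude"].iloc[1], grp["longitude"].iloc[1]))
        return pd.Series(out, name="distance_km")

    def pair_elevation_diffs_m(self) -> pd.Series:
        out = {}
        for pid, grp in self.sites.dropna(subset=["pair_id"]).groupby("pair_id"):
            out[pid] = abs(float(grp["elevation"].iloc[0]
                                 - grp["elevation"].iloc[1]))
        return pd.Series(out, name="delev_m")


def _base_elevation(lat: np.ndarray, lat_range: tuple[float, float]) -> np.ndarray:
    """Elevation–latitude coupling: treeline populations sit higher in the
    north (≈1500 m near the northern range edge) and near sea level in the
    far south."""
    south = min(lat_range)
    return 180.0 + 92.0 * (np.asarray(lat) - south)


def _andes_axis_lon(lat: np.ndarray) -> np.ndarray:
    """Approximate cordillera axis longitude as a function of latitude."""
    return -71.6 + 0.02 * (np.asarray(lat) + 47.5)


def generate_design(n_pairs: int = 10, n_ungrouped: int = 0,
                    latitude_range: tuple[float, float] = (-54.8, -40.1),
                    seed: int = 0,
                    elevation_latitude_coupling: bool = True) -> SamplingDesign:
    """Generate a paired elevation-gradient sampling design.

    Pair members are separated by a great-circle distance drawn on
    [0.6, 2.2] km (mean 1.1) and an elevation contrast on [150, 320] m
    (mean 230); exactly one member per pair is classed high, one low.
    Sites are numbered north to south. Raises
    :class:`InfeasibleDesignError` rather than silently clipping when the
    geometry cannot be honoured.
    """
    if n_pairs < 1:
        raise InfeasibleDesignError("need at least one pair")
    lo, hi = sorted(latitude_range)
    if lo < -56.0 or hi > -36.0:
        raise InfeasibleDesignError(
            f"latitude range {latitude_range} outside the feasible band [-56, -36]")
    span = hi - lo
    # pair centres must be separated far beyond the pair's own footprint
    if span / max(n_pairs, 1) < 0.05:
        raise InfeasibleDesignError(
            f"latitude span {span:.2f}° too small for {n_pairs} pairs")

    rng = np.random.default_rng(seed)
    centers = np.linspace(hi, lo, n_pairs)
    if n_pairs > 1:
        jitter_sd = min(0.15, span / (10.0 * n_pairs))
        centers = np.sort(centers + rng.normal(0, jitter_sd, n_pairs))[::-1]
    lon_noise = rng.normal(0, 0.35, n_pairs)
    if n_pairs > 2:
        # residualize the east-west scatter against latitude so the sampled
        # precipitation (longitude) gradient stays quasi-orthogonal to the
        # temperature (latitude) gradient — the stated point of the design
        c = centers - centers.mean()
        lon_noise = lon_noise - c * (lon_noise @ c) / (c @ c)
    lons = -71.6 + lon_noise

    if elevation_latitude_coupling:
        elev_noise = rng.normal(0, 110, n_pairs)
        if n_pairs > 2:
            c = centers - centers.mean()
            elev_noise = elev_noise - c * (elev_noise @ c) / (c @ c)
        base_elev = _base_elevation(centers, (lo, hi)) + elev_noise
    else:
        base_elev = rng.uniform(400, 1200, n_pairs)
    base_elev = np.maximum(base_elev, 200.0)

    dist_km = PAIR_DIST_RANGE_KM[0] + (
        PAIR_DIST_RANGE_KM[1] - PAIR_DIST_RANGE_KM[0]
    ) * rng.beta(*PAIR_DIST_BETA, size=n_pairs)
    delev = PAIR_DELEV_RANGE_M[0] + (
        PAIR_DELEV_RANGE_M[1] - PAIR_DELEV_RANGE_M[0]
    ) * rng.beta(*PAIR_DELEV_BETA, size=n_pairs)
    bearing = rng.uniform(0, 2 * np.pi, n_pairs)
    high_first = rng.random(n_pairs) < 0.5

    rows = []
    for k in range(n_pairs):
        dlat = dist_km[k] * math.cos(bearing[k]) / KM_PER_DEG_LAT
        dlon = dist_km[k] * math.sin(bearing[k]) / (
            KM_PER_DEG_LAT * math.cos(math.radians(centers[k])))
        lat_a, lon_a = centers[k] + dlat / 2, lons[k] + dlon / 2
        lat_b, lon_b = centers[k] - dlat / 2, lons[k] - dlon / 2
        # one Newton step so the measured great-circle distance matches the draw
        d_now = float(haversine_km(lat_a, lon_a, lat_b, lon_b))
        scale = dist_km[k] / d_now
        lat_a = centers[k] + scale * dlat / 2
        lat_b = centers[k] - scale * dlat / 2
        lon_a = lons[k] + scale * dlon / 2
        lon_b = lons[k] - scale * dlon / 2
        cls_a, cls_b = ("high", "low") if high_first[k] else ("low", "high")
        e_a = base_elev[k] + (delev[k] / 2 if cls_a == "high" else -delev[k] / 2)
        e_b = base_elev[k] + (delev[k] / 2 if cls_b == "high" else -delev[k] / 2)
        rows.append((k + 1, lat_a, lon_a, e_a, cls_a))
        rows.append((k + 1, lat_b, lon_b, e_b, cls_b))

    for u in range(n_ungrouped):
        lat_u = rng.uniform(lo, hi)
        lon_u = _andes_axis_lon(lat_u) + rng.normal(0, 0.35)
        e_u = max(200.0, (_base_elevation(np.array([lat_u]), (lo, hi))[0]
                          + rng.normal(0, 150)))
        rows.append((np.nan, lat_u, lon_u, e_u, "ungrouped"))

    df = pd.DataFrame(rows, columns=["pair_id", "latitude", "longitude",
                                     "elevation", "elevation_class"])
    df = df.sort_values("latitude", ascending=False).reset_index(drop=True)
    df.insert(0, "site_id", np.arange(1, len(df) + 1))
    # one sampling area per pair; ungrouped sites form their own areas
    pair_to_area = {pid: i + 1
                    for i, pid in enumerate(sorted(df["pair_id"].dropna().unique()))}
    next_area = len(pair_to_area) + 1
    areas = []
    for pid in df["pair_id"]:
        if pd.isna(pid):
            areas.append(next_area)
            next_area += 1
        else:
            areas.append(pair_to_area[pid])
    df.insert(2, "area_id", areas)
    design = SamplingDesign(df)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# climate


@dataclass
class VariableField:
    """Linear gradient model for one bioclimatic variable.

    value = baseline + lat_slope·(lat−lat0) + lon_slope·(lon−lon0)
            + elev_slope·elevation + smooth field noise(sd=noise_sd)
            [+ per-tree microclimate noise(sd=micro_sd), tree tables only]
    """

    baseline: float
    lat_slope: float = 0.0     # per degree northward
    lon_slope: float = 0.0     # per degree eastward
    elev_slope: float = 0.0    # per metre
    noise_sd: float = 0.0
    micro_sd: float = 0.0


@dataclass
class Scenario:
    """Additive future-climate shift with optional elevation-dependent warming.

    ``edw_coef`` adds ``edw_coef * elevation`` (°C per metre) to the gst
    shift, emulating faster warming at higher elevations; ``lat_coefs``
    add a per-degree-northward gradient to each variable's shift,
    emulating the spatial non-uniformity of circulation-model deltas
    (warming is stronger toward the northern trailing edge).
    """

    name: str
    period: str                      # "mid" | "late"
    shifts: dict[str, float]
    edw_coef: float = 0.0
    lat_coefs: dict[str, float] = field(default_factory=dict)
    severity: int = 0                # rank within a period (0 = mildest)

    @property
    def key(self) -> str:
        return f"{self.name}_{self.period}"


@dataclass
class ClimateConfig:
    fields: dict[str, VariableField]
    scenarios: list[Scenario] = field(default_factory=list)
    ref_lat: float = -47.5
    ref_lon: float = -71.6
    grid_rows: int = 120
    grid_margin_deg: float = 0.4

    def validate(self) -> None:
        if set(self.fields) != set(CLIMATE_VARS):
            raise ValueError(
                f"climate fields must be exactly {CLIMATE_VARS}, got "
                f"{sorted(self.fields)}")
        by_period: dict[str, list[Scenario]] = {}
        for sc in self.scenarios:
            unknown = set(sc.shifts) - set(CLIMATE_VARS)
            if unknown:
                raise ValueError(f"scenario {sc.key}: unknown variables {unknown}")
            by_period.setdefault(sc.period, []).append(sc)
        for period, scs in by_period.items():
            ordered = sorted(scs, key=lambda s: s.severity)
            mags = [abs(s.shifts.get("gst", 0.0)) for s in ordered]
            if any(b < a for a, b in zip(mags, mags[1:])):
                raise ValueError(
                    f"period '{period}': temperature-shift magnitude must be "
                    "monotone in scenario severity")

    def scenario(self, key: str) -> Scenario:
        for sc in self.scenarios:
            if sc.key == key or sc.name == key:
                return sc
        valid = [sc.key for sc in self.scenarios]
        raise KeyError(f"unknown scenario '{key}'; valid: {valid}")


#: base shift vector: one unit of warming severity. Scenario shifts are this
#: vector times a severity multiplier, so severities are exactly proportional.
_BASE_SHIFT = {"gst": 1.0, "scd": -9.0, "bio12": -28.0, "bio15": 1.6,
               "bio3": 0.35}
#: per-degree-northward gradients of the shifts (one severity unit);
#: ~±40% relative variation across the 15° study span
_BASE_LAT_COEF = {"gst": 0.07, "scd": -0.9, "bio12": -3.2, "bio15": 0.14,
                  "bio3": 0.03}
_SEVERITY_MULT = {
    # (scenario, period) -> multiplier; optimistic < moderate < pessimistic
    ("ssp126", "mid"): 1.0, ("ssp126", "late"): 1.15,
    ("ssp370", "mid"): 1.6, ("ssp370", "late"): 2.6,
    ("ssp585", "mid"): 2.1, ("ssp585", "late"): 3.6,
}
_SEVERITY_RANK = {"ssp126": 0, "ssp370": 1, "ssp585": 2}
_BASE_EDW = 0.0006  # °C per metre per severity unit (elevation-dependent warming)


def default_climate_config() -> ClimateConfig:
    """Five-variable gradient configuration for the study region.

    Temperature variables (gst, scd) respond to latitude and elevation,
    precipitation variables (bio12, bio15) to longitude (west wetter),
    and isothermality (bio3) weakly to latitude; noise levels keep the
    pairwise Pearson correlations among variables moderate (< 0.77).
    """
    fields = {
        "bio3": VariableField(baseline=46.0, lat_slope=0.45, noise_sd=0.5,
                              micro_sd=1.1),
        "gst": VariableField(baseline=9.0, lat_slope=0.70, elev_slope=-0.0055,
                             noise_sd=0.18, micro_sd=0.4),
        "scd": VariableField(baseline=95.0, lat_slope=-2.0, elev_slope=0.025,
                             noise_sd=4.0, micro_sd=9.0),
        "bio12": VariableField(baseline=900.0, lon_slope=-380.0, lat_slope=-5.0,
                               noise_sd=35.0, micro_sd=80.0),
        "bio15": VariableField(baseline=38.0, lon_slope=4.5, noise_sd=1.2,
                               micro_sd=3.0),
    }
    scenarios = [
        Scenario(name=name, period=period,
                 shifts={v: s * mult for v, s in _BASE_SHIFT.items()},
                 edw_coef=_BASE_EDW * mult,
                 lat_coefs={v: c * mult for v, c in _BASE_LAT_COEF.items()},
                 severity=_SEVERITY_RANK[name])
        for (name, period), mult in _SEVERITY_MULT.items()
    ]
    return ClimateConfig(fields=fields, scenarios=scenarios)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sm = gaussian_filter(white, sigma=1.2, mode="nearest")
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def design_grid(design: SamplingDesign, cfg: ClimateConfig) -> Raster:
    """Square-cell template raster covering the design with a margin."""
    s = design.sites
    m = cfg.grid_margin_deg
    south, north = s["latitude"].min() - m, s["latitude"].max() + m
    west, east = s["longitude"].min() - m, s["longitude"].max() + m
    cell = (north - south) / cfg.grid_rows
    ncols = int(np.ceil((east - west) / cell))
    return Raster(np.zeros((cfg.grid_rows, ncols)), west=float(west),
                  north=float(north), dx=cell, dy=cell)


def _dem(template: Raster, design: SamplingDesign,
         rng: np.random.Generator) -> Raster:
    lon, lat = template.grid_centers()
    lat_range = (design.sites["latitude"].min(), design.sites["latitude"].max())
    axis = _andes_axis_lon(lat)
    ridge = np.exp(-((lon - axis) / 1.3) ** 2)
    elev = _base_elevation(lat, lat_range) * (0.35 + 0.65 * ridge)
    elev = elev + _smooth_noise(rng, template.shape, 60.0)
    return template.copy_with(np.maximum(elev, 0.0))


def _field_values(fld: VariableField, cfg: ClimateConfig, lat, lon, elev,
                  noise=0.0):
    return (fld.baseline
            + fld.lat_slope * (np.asarray(lat) - cfg.ref_lat)
            + fld.lon_slope * (np.asarray(lon) - cfg.ref_lon)
            + fld.elev_slope * np.asarray(elev)
            + noise)


def generate_climate(design: SamplingDesign, cfg: ClimateConfig | None = None,
                     seed: int = 0, n_per_site: int = 25
                     ) -> tuple[pd.DataFrame, RasterSet, Raster]:
    """Generate per-tree climate and the current-period raster set.

    Returns ``(trees, raster_set, dem)``. Trees are placed with small
    positional jitter around their site; their climate is the bilinear
    raster extraction plus a lapse-rate correction for the difference
    between the tree's (site) elevation and the DEM surface — the same
    downscaling a practitioner applies when point elevations are better
    known than the terrain model.
    """
    cfg = cfg or default_climate_config()
    cfg.validate()
    rng = np.random.default_rng(seed)
    template = design_grid(design, cfg)
    dem = _dem(template, design, rng)
    lon_g, lat_g = template.grid_centers()

    rasters = {}
    for var in CLIMATE_VARS:
        fld = cfg.fields[var]
        noise = _smooth_noise(rng, template.shape, fld.noise_sd)
        rasters[var] = template.copy_with(
            _field_values(fld, cfg, lat_g, lon_g, dem.data, noise))
    rs = RasterSet(rasters, scenario="current")

    s = design.sites
    recs = []
    tid = 0
    for _, site in s.iterrows():
        for _ in range(n_per_site):
            tid += 1
            recs.append({
                "tree_id": f"t{tid:04d}",
                "site_id": int(site["site_id"]),
                "pair_id": site["pair_id"],
                "area_id": int(site["area_id"]),
                "elevation_class": site["elevation_class"],
                "latitude": site["latitude"] + rng.normal(0, 5e-4),
                "longitude": site["longitude"] + rng.normal(0, 5e-4),
                "elevation": site["elevation"] + rng.normal(0, 8.0),
            })
    trees = pd.DataFrame(recs)

    dem_at = bilinear_extract(dem, trees["longitude"], trees["latitude"]).values
    for var in CLIMATE_VARS:
        fld = cfg.fields[var]
        vals = bilinear_extract(rs[var], trees["longitude"],
                                trees["latitude"]).values
        micro = (rng.normal(0, fld.micro_sd, len(trees))
                 if fld.micro_sd > 0 else 0.0)
        trees[var] = (vals + fld.elev_slope
                      * (trees["elevation"].to_numpy() - dem_at) + micro)
    return trees, rs, dem


def generate_future(current, scenario: str, cfg: ClimateConfig,
                    elevation=None):
    """Apply a scenario's additive shifts to a climate table or raster set.

    ``elevation`` supplies the elevation surface for elevation-dependent
    warming: a column name / array for tables (defaults to the table's
    ``elevation`` column) or a DEM :class:`Raster` for raster sets.
    """
    sc = cfg.scenario(scenario)  # KeyError lists valid names
    if isinstance(current, RasterSet):
        if sc.edw_coef and elevation is None:
            raise ValueError("elevation DEM raster required for "
                             "elevation-dependent warming")
        template = current.template()
        _, lat_g = template.grid_centers()

        def shift(name, data):
            out = (data + sc.shifts.get(name, 0.0)
                   + sc.lat_coefs.get(name, 0.0) * (lat_g - cfg.ref_lat))
            if name == "gst" and sc.edw_coef:
                out = out + sc.edw_coef * elevation.data
            return out

        out = current.map(shift)
        out.scenario = sc.key
        return out

    table = current.copy()
    if elevation is None:
        elev = table["elevation"].to_numpy() if "elevation" in table else 0.0
    else:
        elev = np.asarray(elevation, dtype=float)
    lat = (table["latitude"].to_numpy() if "latitude" in table
           else cfg.ref_lat)
    for var in set(sc.shifts) | set(sc.lat_coefs):
        if var in table.columns:
            table[var] = (table[var] + sc.shifts.get(var, 0.0)
                          + sc.lat_coefs.get(var, 0.0) * (lat - cfg.ref_lat))
    if sc.edw_coef and "gst" in table.columns:
        table["gst"] = table["gst"] + sc.edw_coef * elev
    return table


# ---------------------------------------------------------------------------
# genotypes


def admixture_weights(lats: np.ndarray, k_pops: int,
                      lat_range: tuple[float, float]) -> np.ndarray:
    """Latitude-driven admixture proportions (rows sum to 1).

    Ancestral pools sit at evenly spaced latitude centres; membership
    decays as a Gaussian of distance, reproducing a predominantly
    latitude-oriented population structure.
    """
    lats = np.asarray(lats, dtype=float)
    lo, hi = sorted(lat_range)
    if k_pops == 1:
        return np.ones((lats.size, 1))
    centers = np.linspace(hi, lo, k_pops)
    bw = (hi - lo) / (1.6 * (k_pops - 1))
    w = np.exp(-0.5 * ((lats[:, None] - centers[None, :]) / bw) ** 2)
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class TruthTable:
    """Ground truth for planted loci and neutral differentiation.

    ``loci`` columns: locus_id, is_adaptive, driver_variable, beta,
    ancestral_frequency, driver_center, driver_scale, and pop_freq_k for
    each ancestral pool. β is a logit-scale slope per scaled driver unit
    and is 0 for every non-adaptive locus.
    """

    loci: pd.DataFrame
    k_pops: int
    lat_range: tuple[float, float]

    def validate(self) -> None:
        t = self.loci
        adaptive = t["is_adaptive"].to_numpy(dtype=bool)
        if np.any(t.loc[~adaptive, "beta"].to_numpy() != 0):
            raise ValueError("non-adaptive loci must have beta == 0")
        has_driver = t["driver_variable"].notna().to_numpy()
        if np.any(adaptive != has_driver):
            raise ValueError("driver_variable must be set iff is_adaptive")

    @property
    def adaptive_ids(self) -> list[str]:
        return list(self.loci.loc[self.loci["is_adaptive"], "locus_id"])


def generate_genotypes(design: SamplingDesign, climate: pd.DataFrame,
                       n_neutral: int = 1900, n_adaptive: int = 100,
                       beta_range: tuple[float, float] = (0.5, 1.5),
                       F_model: float = 0.10, K_pops: int = 3,
                       seed: int = 0, missing_rate: float = 0.0
                       ) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate dosage genotypes for the trees of a climate table.

    Neutral loci follow a Balding–Nichols differentiation model across
    ``K_pops`` ancestral pools mixed along latitude; adaptive loci have
    individual allele frequencies logit-linear in one (standardized)
    driver climate variable with slope drawn from ``beta_range`` and a
    random sign.
    """
    if n_neutral < 0 or n_adaptive < 0 or n_neutral + n_adaptive == 0:
        raise ValueError("need a positive total number of loci")
    if K_pops < 1:
        raise ValueError("K_pops must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(climate)
    lat_range = (design.sites["latitude"].min(), design.sites["latitude"].max())
    W = admixture_weights(climate["latitude"].to_numpy(), K_pops, lat_range)

    # neutral: Balding–Nichols pool frequencies around a common ancestor
    p_anc = rng.uniform(0.1, 0.9, n_neutral)
    shape = (1.0 - F_model) / F_model
    pool_freq = rng.beta(p_anc[:, None] * shape,
                         (1.0 - p_anc[:, None]) * shape,
                         size=(n_neutral, K_pops))
    ind_freq_neutral = W @ pool_freq.T          # n × n_neutral

    # adaptive: logit-linear response to one standardized driver variable
    drivers = rng.choice(CLIMATE_VARS, size=n_adaptive)
    betas = rng.uniform(*beta_range, size=n_adaptive)
    betas *= rng.choice([-1.0, 1.0], size=n_adaptive)
    p0 = rng.uniform(0.25, 0.75, n_adaptive)
    centers = {v: float(climate[v].mean()) for v in CLIMATE_VARS}
    scales = {v: float(climate[v].std(ddof=1)) for v in CLIMATE_VARS}
    ind_freq_adapt = np.empty((n, n_adaptive))
    for j in range(n_adaptive):
        v = drivers[j]
        z = (climate[v].to_numpy() - centers[v]) / scales[v]
        ind_freq_adapt[:, j] = expit(logit(p0[j]) + betas[j] * z)

    freq = np.concatenate([ind_freq_neutral, ind_freq_adapt], axis=1)
    dosages = rng.binomial(2, freq).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan

    locus_ids = ([f"n{j:05d}" for j in range(n_neutral)]
                 + [f"a{j:05d}" for j in range(n_adaptive)])
    G = GenotypeMatrix(
        dosages=dosages,
        individual_ids=list(climate["tree_id"]),
        locus_ids=locus_ids,
        site_ids=climate["site_id"].to_numpy(),
        area_ids=climate["area_id"].to_numpy(),
    )

    rows = []
    for j in range(n_neutral):
        rows.append({"locus_id": locus_ids[j], "is_adaptive": False,
                     "driver_variable": None, "beta": 0.0,
                     "ancestral_frequency": p_anc[j],
                     "driver_center": np.nan, "driver_scale": np.nan,
                     **{f"pop_freq_{k+1}": pool_freq[j, k]
                        for k in range(K_pops)}})
    for j in range(n_adaptive):
        rows.append({"locus_id": locus_ids[n_neutral + j], "is_adaptive": True,
                     "driver_variable": drivers[j], "beta": betas[j],
                     "ancestral_frequency": p0[j],
                     "driver_center": centers[drivers[j]],
                     "driver_scale": scales[drivers[j]],
                     **{f"pop_freq_{k+1}": np.nan for k in range(K_pops)}})
    truth = TruthTable(pd.DataFrame(rows), k_pops=K_pops, lat_range=lat_range)
    truth.validate()
    return G, truth


def true_individual_frequencies(truth: TruthTable,
                                climate: pd.DataFrame) -> pd.DataFrame:
    """Recompute each locus's expected allele frequency per individual."""
    W = admixture_weights(climate["latitude"].to_numpy(), truth.k_pops,
                          truth.lat_range)
    out = {}
    pf_cols = [f"pop_freq_{k+1}" for k in range(truth.k_pops)]
    for _, row in truth.loci.iterrows():
        if row["is_adaptive"]:
            z = ((climate[row["driver_variable"]].to_numpy()
                  - row["driver_center"]) / row["driver_scale"])
            out[row["locus_id"]] = expit(
                logit(row["ancestral_frequency"]) + row["beta"] * z)
        else:
            pf = row[pf_cols].to_numpy(dtype=float)
            out[row["locus_id"]] = W @ pf
    return pd.DataFrame(out, index=climate["tree_id"])


def true_site_frequencies(truth: TruthTable,
                          climate: pd.DataFrame) -> pd.DataFrame:
    """Expected per-site allele frequency (mean of individual expectations)."""
    ind = true_individual_frequencies(truth, climate)
    ind["site_id"] = climate["site_id"].to_numpy()
    return ind.groupby("site_id").mean()


def true_adaptive_mismatch(truth: TruthTable, climate_cur: pd.DataFrame,
                           climate_fut: pd.DataFrame) -> pd.Series:
    """Ground-truth maladaptation per tree under a future climate.

    Mean squared change, over planted adaptive loci, of the expected
    allele frequency between current and future climate — the quantity a
    genomic-offset statistic is supposed to track on this generator.
    """
    adaptive = truth.loci[truth.loci["is_adaptive"]]
    if adaptive.empty:
        return pd.Series(np.zeros(len(climate_cur)),
                         index=climate_cur["tree_id"])
    acc = np.zeros(len(climate_cur))
    for _, row in adaptive.iterrows():
        v = row["driver_variable"]
        zc = (climate_cur[v].to_numpy() - row["driver_center"]) / row["driver_scale"]
        zf = (climate_fut[v].to_numpy() - row["driver_center"]) / row["driver_scale"]
        fc = expit(logit(row["ancestral_frequency"]) + row["beta"] * zc)
        ff = expit(logit(row["ancestral_frequency"]) + row["beta"] * zf)
        acc += (ff - fc) ** 2
    return pd.Series(acc / len(adaptive), index=climate_cur["tree_id"])
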