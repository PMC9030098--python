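"""Synthetic archipelago generator.

Produces a self-contained island system with known ground truth for every
downstream stage: a DEM and land/sea mask with several disjoint islands, a
Mediterranean-regime monthly climate (winter rain, summer drought, lapse-rate
cooling with altitude), warming/drying future scenarios, virtual species with
known Gaussian niches, a distance-to-settlement sampling-bias surface, a
human-modification raster, and protected-area polygons covering a
configurable fraction of land.

All stochastic operations take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union
import shapely

from .grid import RasterGrid, LayerStack, haversine_km
from .scenario import ScenarioSpec, BASELINE

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity for island labelling


# ---------------------------------------------------------------------------
# random fields
# ---------------------------------------------------------------------------

def gaussian_random_field(shape, corr_cells, rng) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field.

    corr_cells sets the smoothing length (cells); 0 gives white noise.
    """
    z = rng.standard_normal(shape)
    if corr_cells > 0:
        z = ndimage.gaussian_filter(z, corr_cells, mode="wrap")
    sd = z.std()
    return z / sd if sd > 0 else z


# ---------------------------------------------------------------------------
# archipelago
# ---------------------------------------------------------------------------

@dataclass
class Archipelago:
    """DEM + sea mask + settlements, the spatial frame for everything else.

    ``land_mask`` is 1 exactly where ``dem.data > 0``; ``components`` labels
    islands 1..n by decreasing area (0 = sea).
    """

    dem: RasterGrid
    land_mask: RasterGrid
    settlements: list  # [(lon, lat), ...]
    seed: int
    components: np.ndarray = field(repr=False, default=None)

    @property
    def land(self) -> np.ndarray:
        return self.dem.data > 0

    @property
    def n_islands(self) -> int:
        return int(self.components.max())

    def nan_on_sea(self, values: np.ndarray) -> RasterGrid:
        out = np.where(self.land, values, np.nan)
        return self.dem.like(out)


def make_archipelago(
    seed: int,
    n_islands: int = 6,
    grid_shape: tuple[int, int] = (150, 150),
    cell_km: float = 1.0,
    smooth_cells: float | None = None,
    roughness: float = 0.35,
    max_elev_m: float = 1500.0,
    west: float = 24.0,
    north: float = 38.6,
    min_island_cells: int = 8,
) -> Archipelago:
    """Threshold a smoothed random field into ~n_islands land components.

    The threshold is scanned over field quantiles and the one whose
    component count (ignoring specks below ``min_island_cells``) is closest
    to ``n_islands`` wins; elevation rises linearly with field height above
    the threshold up to ``max_elev_m``.
    """
    if grid_shape[0] < 50 or grid_shape[1] < 50:
        raise ValueError("grid_shape must be at least 50x50")
    if n_islands < 1:
        raise ValueError("n_islands must be >= 1")
    rng = np.random.default_rng(seed)
    if smooth_cells is None:
        smooth_cells = min(grid_shape) / 12.0
    fld = gaussian_random_field(grid_shape, smooth_cells, rng)

    best = None
    for q in np.linspace(0.50, 0.95, 46):
        t = np.quantile(fld, q)
        land = fld > t
        labels, _ = ndimage.label(land, structure=_EIGHT)
        sizes = np.bincount(labels.ravel())[1:]
        count = int((sizes >= min_island_cells).sum())
        if count == 0:
            continue
        score = (abs(count - n_islands), -land.sum())
        if best is None or score < best[0]:
            best = (score, t)
    if best is None:
        raise ValueError("thresholding produced zero land cells; lower n_islands or smoothing")
    t = best[1]

    land = fld > t
    labels, _ = ndimage.label(land, structure=_EIGHT)
    sizes = np.bincount(labels.ravel())
    # erase speck components so land_mask <-> dem>0 matches the island count
    for lab in np.flatnonzero(sizes < min_island_cells):
        if lab == 0:
            continue
        land[labels == lab] = False
    if not land.any():
        raise ValueError("thresholding produced zero land cells")

    # multiplicative small-scale relief: keeps the land mask (dem > 0) intact
    # while decorrelating local topography (TPI/TRI) from absolute elevation
    dem_data = np.where(land, (fld - t) / max(fld.max() - t, 1e-9) * max_elev_m, 0.0)
    if roughness > 0:
        detail = gaussian_random_field(grid_shape, 1.5, rng)
        dem_data = np.where(land, dem_data * np.exp(roughness * detail), 0.0)
        dem_data = np.where(land, dem_data * (max_elev_m / max(dem_data.max(), 1e-9)), 0.0)
    dem = RasterGrid(dem_data, west=west, north=north, cell_km=cell_km)

    # relabel islands by decreasing area
    labels, n = ndimage.label(land, structure=_EIGHT)
    order = np.argsort(-np.bincount(labels.ravel())[1:]) + 1
    components = np.zeros_like(labels)
    for new, old in enumerate(order, start=1):
        components[labels == old] = new

    # settlements: one low-elevation (coastal) cell per island, plus a few
    # extra on the largest islands
    settlements = []
    for isl in range(1, n + 1):
        rows, cols = np.nonzero(components == isl)
        elev = dem_data[rows, cols]
        k = int(np.argmin(elev + rng.uniform(0, 1e-6, elev.size)))
        lon, lat = dem.cell_center(rows[k], cols[k])
        settlements.append((float(lon), float(lat)))
    extra_rows, extra_cols = np.nonzero(components == 1)
    for _ in range(2):
        k = int(rng.integers(extra_rows.size))
        lon, lat = dem.cell_center(extra_rows[k], extra_cols[k])
        settlements.append((float(lon), float(lat)))

    land_mask = dem.like(land.astype(float))
    return Archipelago(dem=dem, land_mask=land_mask, settlements=settlements, seed=seed, components=components)


def distance_to_settlements(arch: Archipelago) -> RasterGrid:
    """Great-circle distance (km) from every cell center to the nearest settlement."""
    g = arch.dem
    lon = np.repeat(g.lon_centers()[None, :], g.shape[0], axis=0)
    lat = np.repeat(g.lat_centers()[:, None], g.shape[1], axis=1)
    d = np.full(g.shape, np.inf)
    for slon, slat in arch.settlements:
        d = np.minimum(d, haversine_km(lon, lat, slon, slat))
    return g.like(d)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

#: Calendar month lengths (non-leap), used for PET and degree-day sums.
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: Months treated as the dry/summer half of a Mediterranean year (Apr-Sep).
SUMMER_MONTHS = np.array([3, 4, 5, 6, 7, 8])
WINTER_MONTHS = np.array([9, 10, 11, 0, 1, 2])  # Oct-Mar

# within-season monthly rainfall profile (relative weights)
_WINTER_PROFILE = np.array([1.0, 1.3, 1.5, 1.4, 1.2, 1.0])  # Oct..Mar
_SUMMER_PROFILE = np.array([0.8, 0.5, 0.25, 0.15, 0.3, 0.6])  # Apr..Sep


@dataclass
class ClimateSet:
    """12 monthly tmin/tmax/prec grids sharing the DEM geometry.

    Arrays are (12, rows, cols); NaN on sea. ``scenario`` is BASELINE for
    the reference climate.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray
    grid: RasterGrid
    scenario: ScenarioSpec = BASELINE

    @property
    def tavg(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    def month(self, which: str, m: int) -> RasterGrid:
        return self.grid.like(getattr(self, which)[m])


def make_monthly_climate(
    arch: Archipelago,
    lapse_rate: float = 6.5,
    seasonal_amp: float = 8.0,
    wet_season_share: float = 0.78,
    seed: int = 0,
    t_sea_level: float = 18.5,
    lat_gradient: float = 1.2,
    diurnal_range: float = 8.0,
    noise_sd: float = 0.5,
    month_noise_frac: float = 0.2,
    noise_corr_cells: float = 8.0,
    annual_prec_base: float = 480.0,
    orographic_mm_per_km: float = 220.0,
    prec_noise_sd: float = 90.0,
) -> ClimateSet:
    """Altitude/latitude-structured Mediterranean monthly climate.

    Monthly mean temperature = sea-level mean - lat_gradient x (lat - lat_s)
    + seasonal sinusoid (peak July) - lapse_rate x elevation(km) + correlated
    noise; precipitation concentrated in the six winter months
    (``wet_season_share`` of the annual total; 1.0 silences Apr-Sep).
    """
    if lapse_rate < 0:
        raise ValueError("lapse_rate must be >= 0")
    rng = np.random.default_rng(seed)
    g = arch.dem
    lat = np.repeat(g.lat_centers()[:, None], g.shape[1], axis=1)
    lat_s = g.lat_centers().min()
    elev_km = g.data / 1000.0

    base = t_sea_level - lat_gradient * (lat - lat_s) - lapse_rate * elev_km
    shared_anom = noise_sd * gaussian_random_field(g.shape, noise_corr_cells, rng) if noise_sd > 0 else 0.0

    months = np.arange(12)
    seasonal = seasonal_amp * np.cos(2 * np.pi * (months - 6) / 12.0)  # peak July (index 6)

    tavg = np.empty((12,) + g.shape)
    # spatial anomalies are mostly shared across months (warm places are warm
    # all year); only a small month-specific component is drawn independently
    for m in months:
        month_anom = month_noise_frac * noise_sd * gaussian_random_field(g.shape, noise_corr_cells, rng) if noise_sd > 0 else 0.0
        tavg[m] = base + seasonal[m] + shared_anom + month_anom

    dr = diurnal_range + (1.0 * gaussian_random_field(g.shape, noise_corr_cells, rng) if noise_sd > 0 else 0.0)
    dr = np.clip(dr, 4.0, None)
    tmin = tavg - dr / 2.0
    tmax = tavg + dr / 2.0

    annual = annual_prec_base + orographic_mm_per_km * elev_km
    if prec_noise_sd > 0:
        annual = annual + prec_noise_sd * gaussian_random_field(g.shape, noise_corr_cells, rng)
    annual = np.clip(annual, 30.0, None)

    share = np.zeros(12)
    share[WINTER_MONTHS] = wet_season_share * _WINTER_PROFILE / _WINTER_PROFILE.sum()
    share[SUMMER_MONTHS] = (1.0 - wet_season_share) * _SUMMER_PROFILE / _SUMMER_PROFILE.sum()
    prec = annual[None, :, :] * share[:, None, None]

    sea = ~arch.land
    for arr in (tmin, tmax, prec):
        arr[:, sea] = np.nan
    return ClimateSet(tmin=tmin, tmax=tmax, prec=prec, grid=g, scenario=BASELINE)


def apply_scenario(clim: ClimateSet, delta_t: float, prec_factor: float, spec: ScenarioSpec) -> ClimateSet:
    """Uniform warming/drying: +delta_t on every month, x prec_factor on rain."""
    if prec_factor <= 0:
        raise ValueError("prec_factor must be > 0")
    return ClimateSet(
        tmin=clim.tmin + delta_t,
        tmax=clim.tmax + delta_t,
        prec=clim.prec * prec_factor,
        grid=clim.grid,
        scenario=spec,
    )


# ---------------------------------------------------------------------------
# virtual species
# ---------------------------------------------------------------------------

@dataclass
class VirtualSpecies:
    """A species with a known Gaussian niche over named predictor layers.

    niche_params maps layer name -> (optimum, tolerance); suitability is the
    product of Gaussian responses, optionally restricted to one island
    (``island``, 1-based component label) for endemics.
    """

    name: str
    niche_params: dict
    prevalence: float = 0.15
    detectability_decay: float = 0.0
    island: int | None = None


def true_suitability(vs: VirtualSpecies, env: LayerStack, arch: Archipelago) -> RasterGrid:
    """Ground-truth suitability in [0, 1]; NaN on sea, 0 off an endemic's island."""
    suit = np.ones(arch.dem.shape)
    for layer, (opt, tol) in vs.niche_params.items():
        x = env[layer].data
        suit = suit * np.exp(-0.5 * ((x - opt) / tol) ** 2)
    if vs.island is not None:
        suit = np.where(arch.components == vs.island, suit, 0.0)
    suit = np.where(arch.land, suit, np.nan)
    return arch.dem.like(suit)


def default_virtual_species(env: LayerStack, arch: Archipelago) -> list[VirtualSpecies]:
    """Twelve archetypes anchored at quantiles of the realized environment.

    The set spans cold-adapted (contraction under warming), warm-adapted
    (stable/expansion), moisture-limited, broad generalist, single-island
    endemic and microhabitat (montane south-slope) archetypes so every
    downstream code path is exercised. ``env`` must provide bio1, bio12,
    bio6 and hli layers.
    """
    b1 = env["bio1"].valid_values()
    b12 = env["bio12"].valid_values()
    b6 = env["bio6"].valid_values()
    hl = env["hli"].valid_values()

    def t1(q):  # BIO1 value at quantile q
        return float(np.quantile(b1, q))

    def t12(q):
        return float(np.quantile(b12, q))

    # tolerances scale with the robust (q10-q90) spread, not the full range:
    # a handful of extreme summit cells must not dilate every niche
    s1 = float(np.quantile(b1, 0.90) - np.quantile(b1, 0.10))
    s12 = float(np.quantile(b12, 0.90) - np.quantile(b12, 0.10))
    s6 = float(np.quantile(b6, 0.90) - np.quantile(b6, 0.10))
    sh = float(np.quantile(hl, 0.90) - np.quantile(hl, 0.10))
    # island holding the highest peak, for the cold endemic
    peak_island = int(arch.components[np.unravel_index(np.nanargmax(arch.dem.data), arch.dem.shape)])

    return [
        VirtualSpecies("vs_cold_narrow", {"bio1": (t1(0.04), 0.15 * s1)}),
        VirtualSpecies("vs_cold_mid", {"bio1": (t1(0.10), 0.25 * s1)}),
        VirtualSpecies("vs_cool_wet", {"bio1": (t1(0.20), 0.30 * s1), "bio12": (t12(0.80), 0.40 * s12)}),
        VirtualSpecies("vs_warm_generalist", {"bio1": (t1(0.70), 0.60 * s1)}),
        VirtualSpecies("vs_warm_narrow", {"bio1": (t1(0.88), 0.20 * s1)}),
        VirtualSpecies("vs_wet_mesic", {"bio12": (t12(0.85), 0.30 * s12)}),
        VirtualSpecies("vs_dry_arid", {"bio12": (t12(0.15), 0.30 * s12)}),
        VirtualSpecies("vs_endemic_cold", {"bio1": (t1(0.06), 0.20 * s1)}, island=peak_island),
        VirtualSpecies("vs_endemic_warm", {"bio1": (t1(0.80), 0.30 * s1)}, island=1),
        VirtualSpecies("vs_mid_generalist", {"bio1": (t1(0.50), 0.70 * s1)}),
        # montane south-slope specialist: cool winters x high insolation —
        # its two drivers sit on near-orthogonal retained axes, the clean
        # ground-truth-identifiability case; well sampled (high prevalence)
        VirtualSpecies(
            "vs_montane_sunny",
            {"bio6": (float(np.quantile(b6, 0.08)), 0.22 * s6), "hli": (float(np.quantile(hl, 0.80)), 0.35 * sh)},
            prevalence=0.30,
        ),
        VirtualSpecies("vs_broad_rare", {"bio1": (t1(0.60), 0.50 * s1)}, prevalence=0.05),
    ]


def sample_virtual_occurrences(
    vs: VirtualSpecies,
    env: LayerStack,
    arch: Archipelago,
    n_records: int,
    bias_strength: float = 0.0,
    seed: int = 0,
    jitter: bool = True,
) -> tuple[pd.DataFrame, RasterGrid]:
    """Draw biased occurrence records from the true suitability surface.

    Cells are drawn with replacement with probability proportional to
    suitability x exp(-bias_strength x km to nearest settlement); records are
    jittered uniformly inside their cell. Returns (records, truth raster).
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    suit = true_suitability(vs, env, arch)
    w = np.where(arch.land, np.nan_to_num(suit.data), 0.0)
    if bias_strength != 0.0:
        d = distance_to_settlements(arch).data
        w = w * np.exp(-bias_strength * d)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"all-zero sampling weights for {vs.name}")
    flat = w.ravel() / total
    idx = rng.choice(flat.size, size=n_records, replace=True, p=flat)
    rows, cols = np.unravel_index(idx, w.shape)
    lon, lat = arch.dem.cell_center(rows, cols)
    if jitter:
        lon = lon + rng.uniform(-0.5, 0.5, n_records) * arch.dem.dlon
        lat = lat + rng.uniform(-0.5, 0.5, n_records) * arch.dem.dlat
    df = pd.DataFrame({"species": vs.name, "lon": lon, "lat": lat, "stage": "raw"})
    return df, suit


# ---------------------------------------------------------------------------
# protected areas & human modification
# ---------------------------------------------------------------------------

def land_polygon(arch: Archipelago):
    """Union of land-cell rectangles (lon/lat degrees), row-run compressed."""
    g = arch.dem
    boxes = []
    for r in range(g.shape[0]):
        row = arch.land[r]
        c = 0
        while c < g.shape[1]:
            if row[c]:
                c0 = c
                while c < g.shape[1] and row[c]:
                    c += 1
                boxes.append(
                    box(
                        g.west + c0 * g.dlon,
                        g.north - (r + 1) * g.dlat,
                        g.west + c * g.dlon,
                        g.north - r * g.dlat,
                    )
                )
            else:
                c += 1
    return unary_union(boxes)


def make_protected_areas(arch: Archipelago, coverage: float = 0.28, seed: int = 0) -> list[Polygon]:
    """Random land patches whose union covers ~``coverage`` of land cells.

    Patches are buffered random points clipped to land; generation stops
    once the rasterized (cell-center) coverage reaches the target, keeping
    the overshoot below one patch (~1% of land).
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if coverage == 0.0:
        return []
    land_poly = land_polygon(arch)
    if coverage >= 1.0:
        geoms = getattr(land_poly, "geoms", [land_poly])
        return list(geoms)

    rng = np.random.default_rng(seed)
    g = arch.dem
    rows, cols = np.nonzero(arch.land)
    lonc, latc = g.cell_center(rows, cols)
    n_land = rows.size
    covered = np.zeros(n_land, dtype=bool)
    patches = []
    deg_per_km = g.dlat / g.cell_km
    for _ in range(2000):
        if covered.mean() >= coverage - 0.01:
            break
        k = int(rng.integers(n_land))
        radius_km = rng.uniform(2.5, 7.0)
        patch = Point(lonc[k], latc[k]).buffer(radius_km * deg_per_km, quad_segs=8)
        patch = patch.intersection(land_poly)
        if patch.is_empty:
            continue
        patches.append(patch)
        covered |= shapely.contains_xy(patch, lonc, latc)
    out = []
    for p in patches:
        out.extend(getattr(p, "geoms", [p]))
    return [p for p in out if isinstance(p, Polygon) and not p.is_empty]


def make_human_modification(arch: Archipelago, seed: int = 0) -> RasterGrid:
    """Human-modification proxy in [0, 1]: smooth field + settlement halos."""
    rng = np.random.default_rng(seed)
    fld = gaussian_random_field(arch.dem.shape, 6.0, rng)
    base = (fld - fld.min()) / max(fld.max() - fld.min(), 1e-12)  # [0, 1]
    d = distance_to_settlements(arch).data
    ghm = 0.08 + 0.45 * base + 0.65 * np.exp(-d / 5.0)
    ghm = np.clip(ghm, 0.0, 1.0)
    return arch.nan_on_sea(ghm)
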