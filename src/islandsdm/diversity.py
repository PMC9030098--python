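"""Diversity surfaces, L1 hotspots, and hotspot shift statistics.

Species richness (SR) is the cellwise presence count; weighted endemism
(WE) sums the inverse range sizes of the species present, so WE summed over
all cells equals the number of species with a nonempty range; corrected
weighted endemism (CWE) is WE/SR. L1 hotspots are the cells at or above the
99th percentile of a metric. Shift tests: Kruskal-Wallis on hotspot
elevations and a permutation Watson two-sample U-squared on bearings from
the current-period centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import RasterGrid
from .projection import BinaryRangeMap
from .scenario import ScenarioSpec, BASELINE

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity surfaces
# ---------------------------------------------------------------------------

@dataclass
class DiversityMaps:
    """SR / WE / CWE rasters for one scenario."""

    sr: RasterGrid
    we: RasterGrid
    cwe: RasterGrid
    scenario: ScenarioSpec
    n_species: int


def stack_diversity(ranges: list[BinaryRangeMap], scenario: ScenarioSpec = BASELINE) -> DiversityMaps:
    """Stack aligned binary ranges into SR, WE and CWE surfaces."""
    if not ranges:
        raise ValueError("no range maps given")
    tpl = ranges[0].presence
    sr = np.zeros(tpl.shape)
    we = np.zeros(tpl.shape)
    n_used = 0
    for rm in ranges:
        if not rm.presence.same_geometry(tpl):
            raise ValueError("range maps are not aligned")
        pres = rm.presence.data == 1
        size = int(pres.sum())
        if size == 0:
            log.warning("stack_diversity: %s has an empty range; excluded from WE", rm.species)
            continue
        sr += pres
        we += pres / size
        n_used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        cwe = np.where(sr > 0, we / np.where(sr > 0, sr, 1.0), 0.0)
    valid = np.isfinite(tpl.data)
    sr = np.where(valid, sr, np.nan)
    we = np.where(valid, we, np.nan)
    cwe = np.where(valid, cwe, np.nan)
    return DiversityMaps(sr=tpl.like(sr), we=tpl.like(we), cwe=tpl.like(cwe), scenario=scenario, n_species=n_used)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

@dataclass
class HotspotSet:
    """Cells at or above the metric's hotspot quantile, with coordinates."""

    metric: str
    rows: np.ndarray
    cols: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    elevation: np.ndarray
    quantile: float
    cutoff: float
    scenario: ScenarioSpec = BASELINE

    def __len__(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.lon.mean()), float(self.lat.mean())


def l1_hotspots(
    metric_map: RasterGrid,
    dem: RasterGrid,
    quantile: float = 0.99,
    metric: str = "SR",
    scenario: ScenarioSpec = BASELINE,
) -> HotspotSet:
    """Cells with value >= the empirical ``quantile`` percentile.

    Linear-interpolation percentile; ties at the cutoff are all included
    (conservative: never drops a top-scoring cell).
    """
    vals = metric_map.valid_values()
    if vals.size < 100:
        raise ValueError("need at least 100 valid cells")
    if np.min(vals) == np.max(vals):
        raise ValueError("constant metric map: hotspots undefined")
    cutoff = float(np.quantile(vals, quantile))
    mask = metric_map.valid & (metric_map.data >= cutoff)
    rows, cols = np.nonzero(mask)
    lon, lat = metric_map.cell_center(rows, cols)
    return HotspotSet(
        metric=metric,
        rows=rows,
        cols=cols,
        lon=lon,
        lat=lat,
        elevation=dem.data[rows, cols],
        quantile=quantile,
        cutoff=cutoff,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# Watson two-sample U2 (circular)
# ---------------------------------------------------------------------------

def watson_u2(angles1: np.ndarray, angles2: np.ndarray) -> float:
    """Watson two-sample U-squared statistic for circular data (radians)."""
    a = np.sort(np.mod(angles1, 2 * np.pi))
    b = np.sort(np.mod(angles2, 2 * np.pi))
    n, m = a.size, b.size
    N = n + m
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    from1 = (order < n).astype(float)
    cum1 = np.cumsum(from1) / n
    cum2 = np.cumsum(1.0 - from1) / m
    d = cum1 - cum2
    return float(n * m / N**2 * (np.sum(d * d) - np.sum(d) ** 2 / N))


def watson_u2_test(angles1, angles2, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Permutation p-value for the Watson U2 statistic (label shuffles)."""
    a = np.asarray(angles1, dtype=float)
    b = np.asarray(angles2, dtype=float)
    obs = watson_u2(a, b)
    pooled = np.concatenate([a, b])
    n = a.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        if watson_u2(pooled[perm[:n]], pooled[perm[n:]]) >= obs:
            exceed += 1
    return obs, (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# shift tests
# ---------------------------------------------------------------------------

@dataclass
class ShiftTestResult:
    kw_H: float
    kw_df: int
    kw_p: float
    watson_U2: float
    watson_p: float
    centroid_current: tuple[float, float]
    centroid_future: tuple[float, float]
    mean_alt_current: float
    mean_alt_future: float
    skipped: bool = False

    def to_dict(self) -> dict:
        return {
            "kw_H": self.kw_H,
            "kw_df": self.kw_df,
            "kw_p": self.kw_p,
            "watson_U2": self.watson_U2,
            "watson_p": self.watson_p,
            "centroid_current": list(self.centroid_current),
            "centroid_future": list(self.centroid_future),
            "mean_alt_current": self.mean_alt_current,
            "mean_alt_future": self.mean_alt_future,
            "skipped": self.skipped,
        }


def _bearings(lon, lat, origin):
    """Compass-style bearings (radians) from origin to points, equirect approx."""
    olon, olat = origin
    dx = (np.asarray(lon) - olon) * np.cos(np.radians(olat))
    dy = np.asarray(lat) - olat
    return np.arctan2(dx, dy)


def shift_tests(current: HotspotSet, future: HotspotSet, n_perm: int = 999, seed: int = 0) -> ShiftTestResult:
    """Altitudinal (Kruskal-Wallis) and directional (Watson U2) shift tests.

    Bearings are taken from the current-period centroid. Groups with fewer
    than 3 cells skip the tests but still report centroids.
    """
    if len(current) == 0 or len(future) == 0:
        raise ValueError("both hotspot sets must be non-empty")
    c_cen = current.centroid
    f_cen = future.centroid
    base = dict(
        centroid_current=c_cen,
        centroid_future=f_cen,
        mean_alt_current=float(current.elevation.mean()),
        mean_alt_future=float(future.elevation.mean()),
    )
    if len(current) < 3 or len(future) < 3:
        return ShiftTestResult(kw_H=float("nan"), kw_df=1, kw_p=float("nan"), watson_U2=float("nan"), watson_p=float("nan"), skipped=True, **base)
    try:
        kw = stats.kruskal(current.elevation, future.elevation)
        kw_H, kw_p = float(kw.statistic), float(kw.pvalue)
    except ValueError:  # identical values everywhere
        kw_H, kw_p = 0.0, 1.0
    ang_c = _bearings(current.lon, current.lat, c_cen)
    ang_f = _bearings(future.lon, future.lat, c_cen)
    u2, u2_p = watson_u2_test(ang_c, ang_f, n_perm=n_perm, seed=seed)
    return ShiftTestResult(kw_H=kw_H, kw_df=1, kw_p=kw_p, watson_U2=u2, watson_p=u2_p, **base)


# ---------------------------------------------------------------------------
# human-modification contrast
# ---------------------------------------------------------------------------

GHM_CLASS_NAMES = ["low", "moderate", "high", "very_high"]


def human_mod_contrast(div: DiversityMaps, ghm: RasterGrid, breaks=(0.1, 0.4, 0.7)) -> dict:
    """SR distributions across human-modification classes + Kruskal-Wallis.

    Classes are cut at ``breaks`` (strictly increasing, within (0, 1)).
    Empty classes are reported with n=0 and excluded from the test.
    """
    breaks = list(breaks)
    if any(not 0 < b < 1 for b in breaks) or sorted(breaks) != breaks or len(set(breaks)) != len(breaks):
        raise ValueError("breaks must be strictly increasing within (0, 1)")
    if not div.sr.same_geometry(ghm):
        raise ValueError("GHM raster not aligned")
    valid = div.sr.valid & ghm.valid
    sr = div.sr.data[valid]
    cls = np.digitize(ghm.data[valid], breaks)
    names = GHM_CLASS_NAMES[: len(breaks) + 1]
    samples = {name: sr[cls == i] for i, name in enumerate(names)}
    nonempty = [v for v in samples.values() if v.size > 0]
    result = {
        "classes": {name: {"n": int(v.size), "median_sr": float(np.median(v)) if v.size else float("nan")} for name, v in samples.items()},
        "kw_H": float("nan"),
        "kw_p": float("nan"),
        "tested": False,
    }
    if len(nonempty) >= 2 and all(np.ptp(np.concatenate(nonempty)) > 0 for _ in [0]):
        try:
            kw = stats.kruskal(*nonempty)
            result.update(kw_H=float(kw.statistic), kw_p=float(kw.pvalue), tested=True)
        except ValueError:
            pass
    result["samples"] = samples
    return result


def sr_difference(current: DiversityMaps, future: DiversityMaps) -> RasterGrid:
    """Future minus current species richness, cellwise."""
    return current.sr.like(future.sr.data - current.sr.data)
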