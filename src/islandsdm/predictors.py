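"""Environmental predictor derivation and collinearity reduction.

Derives the candidate predictor stack from monthly climate and the DEM:

* the 19 standard bioclimatic variables (quarters are all 12 wrap-around
  consecutive 3-month windows; warmest/coldest by mean temperature,
  wettest/driest by precipitation sum; ties go to the lowest start month),
* a PET-family set (Hargreaves monthly PET with FAO-56 extraterrestrial
  radiation), Thornthwaite aridity, climatic moisture index, continentality
  and growing-degree proxies,
* five topographic variables (Horn slope/aspect, TPI, TRI, McCune-Keon
  heat-load index),

then reduces the stack to a non-collinear subset (pairwise |Spearman| <
rho_max, then VIF < vif_max) with a self-verifying report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import RasterGrid, LayerStack
from .synth import Archipelago, ClimateSet, DAYS_IN_MONTH

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quarters
# ---------------------------------------------------------------------------

def _quarter_windows(arr: np.ndarray, reduce: str) -> np.ndarray:
    """(12, ...) -> (12, ...) of 3-month wrap-around window aggregates.

    Window w covers months (w, w+1, w+2 mod 12). reduce: 'mean' or 'sum'.
    """
    out = np.empty_like(arr)
    for w in range(12):
        sel = arr[[w, (w + 1) % 12, (w + 2) % 12]]
        out[w] = sel.mean(axis=0) if reduce == "mean" else sel.sum(axis=0)
    return out


def _pick(windows: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Select windows[idx[c], c] cellwise."""
    return np.take_along_axis(windows, idx[None, ...], axis=0)[0]


def quarter_indices(tavg: np.ndarray, prec: np.ndarray):
    """Cellwise start-month of warmest/coldest/wettest/driest quarter.

    argmax/argmin return the lowest index on ties (the documented tie rule).
    """
    qt = _quarter_windows(tavg, "mean")
    qp = _quarter_windows(prec, "sum")
    qt_f = np.nan_to_num(qt, nan=-1e30)
    qp_f = np.nan_to_num(qp, nan=-1e30)
    return {
        "qtemp": qt,
        "qprec": qp,
        "warmest": np.argmax(qt_f, axis=0),
        "coldest": np.argmin(np.nan_to_num(qt, nan=1e30), axis=0),
        "wettest": np.argmax(qp_f, axis=0),
        "driest": np.argmin(np.nan_to_num(qp, nan=1e30), axis=0),
    }


# ---------------------------------------------------------------------------
# bioclim
# ---------------------------------------------------------------------------

def derive_bioclim(clim: ClimateSet) -> LayerStack:
    """BIO1-BIO19 from 12 monthly tmin/tmax/prec grids."""
    for name in ("tmin", "tmax", "prec"):
        arr = getattr(clim, name)
        if arr.shape[0] != 12:
            raise ValueError(f"{name} must have 12 months, got {arr.shape[0]}")
    g = clim.grid
    tmin, tmax, prec = clim.tmin, clim.tmax, clim.prec
    tavg = clim.tavg

    q = quarter_indices(tavg, prec)

    bio = {}
    bio["bio1"] = tavg.mean(axis=0)
    bio["bio2"] = (tmax - tmin).mean(axis=0)
    bio["bio4"] = 100.0 * tavg.std(axis=0, ddof=1)
    bio["bio5"] = tmax.max(axis=0)
    bio["bio6"] = tmin.min(axis=0)
    bio["bio7"] = bio["bio5"] - bio["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio3"] = np.where(bio["bio7"] != 0, 100.0 * bio["bio2"] / bio["bio7"], 0.0)
    bio["bio8"] = _pick(q["qtemp"], q["wettest"])
    bio["bio9"] = _pick(q["qtemp"], q["driest"])
    bio["bio10"] = _pick(q["qtemp"], q["warmest"])
    bio["bio11"] = _pick(q["qtemp"], q["coldest"])
    bio["bio12"] = prec.sum(axis=0)
    bio["bio13"] = prec.max(axis=0)
    bio["bio14"] = prec.min(axis=0)
    bio["bio15"] = 100.0 * prec.std(axis=0, ddof=1) / (1.0 + bio["bio12"] / 12.0)
    bio["bio16"] = _pick(q["qprec"], q["wettest"])
    bio["bio17"] = _pick(q["qprec"], q["driest"])
    bio["bio18"] = _pick(q["qprec"], q["warmest"])
    bio["bio19"] = _pick(q["qprec"], q["coldest"])

    nodata = ~np.isfinite(tavg).all(axis=0)
    stack = LayerStack()
    for i in range(1, 20):
        name = f"bio{i}"
        data = np.where(nodata, np.nan, bio[name])
        stack.add(name, g.like(data), "bioclim from monthly climate")
    return stack


# ---------------------------------------------------------------------------
# PET family
# ---------------------------------------------------------------------------

#: mid-month day-of-year used for extraterrestrial radiation
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 162, 198, 228, 259, 289, 319, 345])


def extraterrestrial_radiation(lat_deg: np.ndarray, month: int) -> np.ndarray:
    """FAO-56 daily extraterrestrial radiation Ra (MJ m-2 day-1) at mid-month."""
    if np.any(np.abs(lat_deg) > 90):
        raise ValueError("latitude outside [-90, 90]")
    phi = np.radians(lat_deg)
    j = _MID_MONTH_DOY[month]
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * j / 365.0)
    dec = 0.409 * np.sin(2 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(dec), -1.0, 1.0))
    return (24 * 60 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws)
    )


def monthly_pet(clim: ClimateSet, lat: np.ndarray) -> np.ndarray:
    """Hargreaves monthly PET (mm/month), floored at zero."""
    tavg = clim.tavg
    trange = np.clip(clim.tmax - clim.tmin, 0.0, None)
    pet = np.empty_like(tavg)
    for m in range(12):
        ra = extraterrestrial_radiation(lat, m) * 0.408  # -> mm/day equivalent
        pet[m] = np.clip(0.0023 * ra * (tavg[m] + 17.8) * np.sqrt(trange[m]), 0.0, None) * DAYS_IN_MONTH[m]
    return pet


def derive_envirem(clim: ClimateSet, latitude: RasterGrid | None = None) -> LayerStack:
    """PET family, aridity, moisture index, continentality, degree-day proxies.

    The quarter convention is identical to :func:`derive_bioclim`. The
    Thornthwaite aridity index is 100 x (annual water deficit) / (annual
    PET), maximal (100) in a zero-precipitation year.
    """
    g = clim.grid
    if latitude is None:
        lat = np.repeat(g.lat_centers()[:, None], g.shape[1], axis=1)
    else:
        if not latitude.same_geometry(g):
            raise ValueError("latitude grid not aligned with climate grids")
        lat = latitude.data
    pet = monthly_pet(clim, lat)
    tavg = clim.tavg
    prec = clim.prec
    q = quarter_indices(tavg, prec)
    qpet = _quarter_windows(pet, "mean")

    annual_pet = pet.sum(axis=0)
    deficit = np.clip(pet - prec, 0.0, None).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        aridity = np.where(annual_pet > 0, 100.0 * deficit / annual_pet, 0.0)
        p_ann = prec.sum(axis=0)
        cmi = np.where(p_ann >= annual_pet, 1.0 - np.where(p_ann > 0, annual_pet / p_ann, 1.0), p_ann / np.where(annual_pet > 0, annual_pet, 1.0) - 1.0)
    monthly_means = tavg  # (12, ...)
    continentality = monthly_means.max(axis=0) - monthly_means.min(axis=0)
    gdd0 = (np.clip(tavg, 0.0, None) * DAYS_IN_MONTH[:, None, None]).sum(axis=0)
    gdd5 = (np.clip(tavg - 5.0, 0.0, None) * DAYS_IN_MONTH[:, None, None]).sum(axis=0)

    layers = {
        "annual_pet": annual_pet,
        "pet_seasonality": 100.0 * pet.std(axis=0, ddof=1),
        "pet_coldest_quarter": _pick(qpet, q["coldest"]),
        "pet_warmest_quarter": _pick(qpet, q["warmest"]),
        "pet_wettest_quarter": _pick(qpet, q["wettest"]),
        "pet_driest_quarter": _pick(qpet, q["driest"]),
        "aridity_thornthwaite": aridity,
        "climatic_moisture_index": cmi,
        "continentality": continentality,
        "growing_deg_days0": gdd0,
        "growing_deg_days5": gdd5,
        "max_temp_coldest_month": _pick(clim.tmax, np.argmin(np.nan_to_num(tavg, nan=1e30), axis=0)),
        "min_temp_warmest_month": _pick(clim.tmin, np.argmax(np.nan_to_num(tavg, nan=-1e30), axis=0)),
    }
    # integer month-count layers are quasi-categorical at km scale and are
    # deliberately not offered to the collinearity filter
    nodata = ~np.isfinite(tavg).all(axis=0)
    stack = LayerStack()
    for name, data in layers.items():
        stack.add(name, g.like(np.where(nodata, np.nan, data)), "PET-family from monthly climate")
    return stack


# ---------------------------------------------------------------------------
# topographic
# ---------------------------------------------------------------------------

def derive_topographic(dem: RasterGrid) -> LayerStack:
    """Slope, aspect, TPI, TRI and heat-load index from the DEM.

    Horn 3x3 finite differences for slope/aspect; TPI/TRI against the 8
    neighbours; HLI per the McCune-Keon closed formula on the folded aspect
    A' = |180 - |aspect - 225||. Edge cells are nodata.
    """
    z = dem.data
    if not np.isfinite(z).any():
        raise ValueError("all-nodata DEM")
    dx = dem.cell_km * 1000.0
    nrows, ncols = z.shape
    out_shape = z.shape

    def shifted(dr, dc):
        return z[1 + dr : nrows - 1 + dr, 1 + dc : ncols - 1 + dc]

    zc = shifted(0, 0)
    nw, n_, ne = shifted(-1, -1), shifted(-1, 0), shifted(-1, 1)
    w_, e_ = shifted(0, -1), shifted(0, 1)
    sw, s_, se = shifted(1, -1), shifted(1, 0), shifted(1, 1)

    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * dx)  # east+
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * dx)  # north+
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0  # downslope compass bearing
    aspect = np.where(slope > 0, aspect, 0.0)

    neigh = np.stack([nw, n_, ne, w_, e_, sw, s_, se])
    tpi = zc - neigh.mean(axis=0)
    tri = np.abs(neigh - zc).mean(axis=0)

    lat = np.repeat(dem.lat_centers()[1:-1, None], ncols - 2, axis=1)
    folded = np.abs(180.0 - np.abs(aspect - 225.0))
    lat_r, slope_r, fold_r = np.radians(lat), np.radians(slope), np.radians(folded)
    hli = np.exp(
        -1.467
        + 1.582 * np.cos(lat_r) * np.cos(slope_r)
        - 1.500 * np.cos(fold_r) * np.sin(slope_r) * np.cos(lat_r)
        - 0.262 * np.sin(lat_r) * np.sin(slope_r)
        + 0.607 * np.sin(fold_r) * np.sin(slope_r)
    )

    stack = LayerStack()
    for name, arr in (("slope", slope), ("aspect", aspect), ("tpi", tpi), ("tri", tri), ("hli", hli)):
        full = np.full(out_shape, np.nan)
        full[1:-1, 1:-1] = arr
        stack.add(name, dem.like(full), "topographic from DEM (Horn 3x3)")
    return stack


def heat_load_index(lat_deg: float, slope_deg: float, aspect_deg: float) -> float:
    """Pointwise McCune-Keon HLI (same formula as the raster path)."""
    folded = abs(180.0 - abs(aspect_deg - 225.0))
    lat, slope, fold = np.radians([lat_deg, slope_deg, folded])
    return float(
        np.exp(
            -1.467
            + 1.582 * np.cos(lat) * np.cos(slope)
            - 1.500 * np.cos(fold) * np.sin(slope) * np.cos(lat)
            - 0.262 * np.sin(lat) * np.sin(slope)
            + 0.607 * np.sin(fold) * np.sin(slope)
        )
    )


def build_predictor_stack(clim: ClimateSet, arch: Archipelago) -> LayerStack:
    """Full candidate stack (bioclim + PET family + topographic), land-masked."""
    stack = LayerStack()
    land = arch.land
    for sub in (derive_bioclim(clim), derive_envirem(clim), derive_topographic(arch.dem)):
        for name in sub.names:
            g = sub[name]
            stack.add(name, g.like(np.where(land, g.data, np.nan)), sub.provenance[name])
    return stack


# ---------------------------------------------------------------------------
# collinearity filter
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    """Outcome of the Spearman/VIF reduction; retained + dropped partition the input."""

    retained: list[str]
    dropped: list[tuple[str, str]]  # (name, reason)
    rho_max: float
    vif_max: float

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "dropped": [{"name": n, "reason": r} for n, r in self.dropped],
            "rho_max": self.rho_max,
            "vif_max": self.vif_max,
        }


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors via per-column OLS R^2."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    n, d = Xs.shape
    out = np.empty(d)
    for j in range(d):
        y = Xs[:, j]
        A = np.column_stack([Xs[:, [k for k in range(d) if k != j]], np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def filter_collinear(
    stack: LayerStack,
    samples: int = 10000,
    rho_max: float = 0.7,
    vif_max: float = 10.0,
    seed: int = 0,
) -> CollinearityReport:
    """Iteratively reduce the stack to |Spearman| < rho_max and VIF < vif_max.

    Correlation pass first: while any pair violates, drop the member of the
    worst pair with the higher mean absolute correlation against the rest.
    Then the VIF pass drops the highest-VIF layer until all are below the
    threshold. Statistics are computed on a seeded sample of valid cells.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least 2 layers")
    rng = np.random.default_rng(seed)
    rows, cols, X = stack.to_matrix()
    if rows.size < 2:
        raise ValueError("not enough jointly valid cells")
    if rows.size > samples:
        sel = rng.choice(rows.size, samples, replace=False)
        X = X[sel]

    dropped: list[tuple[str, str]] = []
    keep = list(range(len(names)))

    # zero-variance layers can't enter rank correlations
    for j in list(keep):
        if np.nanstd(X[:, j]) == 0:
            dropped.append((names[j], "zero variance"))
            keep.remove(j)

    def spearman(cols_idx):
        sub = X[:, cols_idx]
        if len(cols_idx) == 2:
            r = stats.spearmanr(sub[:, 0], sub[:, 1]).statistic
            return np.array([[1.0, r], [r, 1.0]])
        return stats.spearmanr(sub).statistic

    while len(keep) >= 2:
        rho = np.abs(spearman(keep))
        np.fill_diagonal(rho, 0.0)
        i, j = np.unravel_index(np.argmax(rho), rho.shape)
        if rho[i, j] < rho_max:
            break
        mean_abs = rho.mean(axis=0) * len(keep) / max(len(keep) - 1, 1)
        victim = i if mean_abs[i] >= mean_abs[j] else j
        other = j if victim == i else i
        dropped.append(
            (names[keep[victim]], f"|rho|={rho[i, j]:.3f} with {names[keep[other]]}")
        )
        del keep[victim]

    while len(keep) >= 2:
        vifs = _vif(X[:, keep])
        worst = int(np.argmax(vifs))
        if vifs[worst] < vif_max:
            break
        dropped.append((names[keep[worst]], f"VIF={vifs[worst]:.1f}" if np.isfinite(vifs[worst]) else "VIF=inf"))
        del keep[worst]

    return CollinearityReport(
        retained=[names[k] for k in keep], dropped=dropped, rho_max=rho_max, vif_max=vif_max
    )
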