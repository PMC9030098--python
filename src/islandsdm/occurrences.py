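"""Occurrence cleaning and the accessibility-bias (sampling effort) model.

The cleaning chain is dedupe (one record per species x grid cell) ->
spatial thinning (randomized greedy maximal subset with all pairwise
great-circle distances >= thin_dist) -> minimum-record filter (species with
fewer than ``min_n`` thinned records are dropped).

The bias model is the sampbias-style Poisson rate model: expected records
per cell lambda_i = q * exp(-sum_f w_f d_{f,i}) with d a distance raster
(km) per accessibility factor, fitted by maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .grid import RasterGrid, LayerStack, haversine_km

log = logging.getLogger(__name__)


def dedupe(occ: pd.DataFrame, grid: RasterGrid) -> pd.DataFrame:
    """Keep at most one record per (species, grid cell).

    ``grid`` is the land mask (1 = land); off-grid or sea records are
    dropped with a logged warning. The first record per cell survives.
    """
    row, col, inside = grid.index_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    on_land = np.zeros(len(occ), dtype=bool)
    on_land[inside] = grid.data[row[inside], col[inside]] > 0
    n_bad = int((~on_land).sum())
    if n_bad:
        log.warning("dedupe: dropped %d off-grid or at-sea records", n_bad)
    df = occ.loc[on_land].copy()
    df["_cell"] = row[on_land] * grid.shape[1] + col[on_land]
    df = df.drop_duplicates(subset=["species", "_cell"], keep="first").drop(columns="_cell")
    df["stage"] = "deduped"
    return df.reset_index(drop=True)


def _thin_one(lon: np.ndarray, lat: np.ndarray, thin_dist: float, rng, repeats: int) -> np.ndarray:
    """Indices of a (near-)maximal subset with pairwise distances >= thin_dist.

    Randomized greedy removal of the most-conflicted point, best of
    ``repeats`` runs; exact search is only used as a test oracle.
    """
    n = lon.size
    if n <= 1:
        return np.arange(n)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    conflict = d < thin_dist
    np.fill_diagonal(conflict, False)
    if not conflict.any():
        return np.arange(n)
    best = None
    for _ in range(repeats):
        alive = np.ones(n, dtype=bool)
        c = conflict.copy()
        deg = c.sum(axis=1)
        while True:
            mx = deg[alive].max() if alive.any() else 0
            if mx == 0:
                break
            cand = np.flatnonzero(alive & (deg == mx))
            v = cand[rng.integers(cand.size)]
            alive[v] = False
            deg = deg - c[:, v]
            c[v, :] = False
            c[:, v] = False
            deg[v] = 0
        if best is None or alive.sum() > best.sum():
            best = alive.copy()
    return np.flatnonzero(best)


def thin(occ: pd.DataFrame, thin_dist: float, seed: int = 0, repeats: int = 20) -> pd.DataFrame:
    """Per-species spatial thinning to pairwise distances >= thin_dist km."""
    if thin_dist <= 0:
        raise ValueError("thin_dist must be > 0")
    rng = np.random.default_rng(seed)
    parts = []
    for sp, grp in occ.groupby("species", sort=True):
        keep = _thin_one(grp["lon"].to_numpy(), grp["lat"].to_numpy(), thin_dist, rng, repeats)
        parts.append(grp.iloc[np.sort(keep)])
    if not parts:
        out = occ.copy()
    else:
        out = pd.concat(parts, ignore_index=True)
    out["stage"] = "thinned"
    return out


def filter_min_records(occ: pd.DataFrame, min_n: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Drop species with fewer than min_n records; returns (kept, dropped names)."""
    counts = occ.groupby("species").size()
    dropped = sorted(counts.index[counts < min_n])
    kept = occ[~occ["species"].isin(dropped)].reset_index(drop=True)
    return kept, list(dropped)


@dataclass
class BiasModel:
    """Fitted accessibility model: rate q * exp(-sum_f w_f d_f) per cell."""

    q: float
    w: dict  # factor name -> decay per km
    loglik: float
    rate: RasterGrid  # projected sampling-rate surface

    def to_dict(self) -> dict:
        return {"q": self.q, "w": self.w, "loglik": self.loglik}


def fit_bias_model(occ: pd.DataFrame, distance_rasters: LayerStack, land: RasterGrid, seed: int = 0) -> BiasModel:
    """Poisson MLE of the per-cell record-count rate against distance factors.

    ``distance_rasters`` holds one km-distance raster per factor (e.g.
    distance to settlements). Counts are all records pooled across species.
    """
    if len(distance_rasters) < 1:
        raise ValueError("need at least one distance raster")
    g = land
    row, col, inside = g.index_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    land_cells = g.data > 0
    counts = np.zeros(g.shape)
    np.add.at(counts, (row[inside], col[inside]), 1)

    rows, cols = np.nonzero(land_cells)
    y = counts[rows, cols]
    D = np.column_stack([distance_rasters[n].data[rows, cols] for n in distance_rasters.names])
    ok = np.isfinite(D).all(axis=1)
    y, D = y[ok], D[ok]

    def nll(params):
        logq = params[0]
        w = params[1:]
        lam = np.exp(logq - D @ w)
        return float(lam.sum() - (y * (logq - D @ w)).sum())

    x0 = np.concatenate([[np.log(max(y.mean(), 1e-9))], np.full(D.shape[1], 0.01)])
    bounds = [(None, None)] + [(0.0, None)] * D.shape[1]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        raise RuntimeError(f"bias-model optimizer failed: {res.message}")
    q = float(np.exp(res.x[0]))
    w = {n: float(v) for n, v in zip(distance_rasters.names, res.x[1:])}
    full_D = np.stack([distance_rasters[n].data for n in distance_rasters.names])
    rate = q * np.exp(-(np.tensordot(res.x[1:], full_D, axes=1)))
    rate = np.where(land_cells, rate, np.nan)
    return BiasModel(q=q, w=w, loglik=-float(res.fun), rate=g.like(rate))
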