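"""Protected-area overlap of hotspot cells.

A hotspot cell counts as protected when its center lies inside any
protected-area polygon (cell-center dialect); the overlap fraction is the
percent of hotspot cells protected, tabulated per metric x scenario with a
monotonic-trend summary across time-slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .diversity import HotspotSet
from .grid import RasterGrid


def rasterize_pa(polygons, grid: RasterGrid) -> RasterGrid:
    """Boolean mask: cell center inside any polygon AND on land.

    ``grid`` is the land mask; invalid polygons are repaired with
    make_valid and rejected if still broken.
    """
    fixed = []
    for i, poly in enumerate(polygons):
        if not poly.is_valid:
            poly = shapely.make_valid(poly)
            if not poly.is_valid:
                raise ValueError(f"invalid polygon at index {i}")
        fixed.append(poly)
    land = grid.data > 0
    out = np.zeros(grid.shape, dtype=bool)
    if fixed:
        rows, cols = np.nonzero(land)
        lon, lat = grid.cell_center(rows, cols)
        union = shapely.union_all(fixed)
        shapely.prepare(union)
        inside = shapely.contains_xy(union, lon, lat)
        out[rows[inside], cols[inside]] = True
    data = np.where(np.isfinite(grid.data), out.astype(float), np.nan)
    return grid.like(data)


@dataclass
class OverlapReport:
    """Fraction of one hotspot set inside the protected-area mask."""

    metric: str
    scenario: str
    n_hotspot_cells: int
    n_inside: int
    fraction: float  # percent
    flagged_empty: bool = False

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "scenario": self.scenario,
            "n_hotspot_cells": self.n_hotspot_cells,
            "n_inside": self.n_inside,
            "fraction": self.fraction,
        }


def overlap_fraction(hotspots: HotspotSet, pa_mask: RasterGrid) -> OverlapReport:
    """Percent of hotspot cells whose center lies in a protected area."""
    n = len(hotspots)
    if n == 0:
        return OverlapReport(hotspots.metric, hotspots.scenario.label, 0, 0, float("nan"), flagged_empty=True)
    inside = pa_mask.data[hotspots.rows, hotspots.cols] == 1
    n_in = int(inside.sum())
    return OverlapReport(hotspots.metric, hotspots.scenario.label, n, n_in, 100.0 * n_in / n)


SLICE_ORDER = ["current", "2020s", "2050s", "2080s"]


def overlap_table(reports: list[tuple[OverlapReport, str, str, str]]) -> tuple[pd.DataFrame, dict]:
    """Batch table (metric x GCM x RCP x slice) + per-series trend flags.

    ``reports`` holds (report, gcm, rcp, slice) tuples. The trend summary
    flags a series 'decreasing' when fractions are monotone non-increasing
    across its ordered slices.
    """
    rows = [
        {"metric": r.metric, "gcm": g, "rcp": p, "slice": s, "n_hotspot_cells": r.n_hotspot_cells, "n_inside": r.n_inside, "fraction": r.fraction}
        for r, g, p, s in reports
    ]
    df = pd.DataFrame(rows)
    trend = {}
    for (metric, gcm, rcp), grp in df[df["slice"] != "current"].groupby(["metric", "gcm", "rcp"]):
        grp = grp.set_index("slice").reindex([s for s in SLICE_ORDER if s in grp["slice"].values])
        fr = grp["fraction"].to_numpy()
        current = df[(df["metric"] == metric) & (df["slice"] == "current")]["fraction"]
        series = np.concatenate([[current.iloc[0]], fr]) if len(current) else fr
        decreasing = bool(np.all(np.diff(series) <= 1e-9))
        trend[f"{metric}_{gcm}_rcp{rcp}"] = "decreasing" if decreasing else "mixed"
    return df, trend


# ---------------------------------------------------------------------------
# GeoJSON I/O (plain text)
# ---------------------------------------------------------------------------

def write_geojson(polygons, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)} for i, p in enumerate(polygons)],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path):
    fc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in fc["features"]]
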