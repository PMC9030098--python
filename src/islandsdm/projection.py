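"""Projection of fitted ensembles and extrapolation diagnostics.

Covers: projecting the TSS-weighted ensemble onto an environment stack,
clamping (suitability nullified wherever any predictor leaves its training
range), maxSSS binarization, ExDet univariate/combinatorial novelty with
%N, a niche-truncation index, and per-species range change under a
configurable dispersal assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .esm import EsmEnsemble
from .grid import RasterGrid, LayerStack
from .metrics import maxsss_threshold  # noqa: F401 (module surface)
from .scenario import ScenarioSpec, BASELINE

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# projection + clamping
# ---------------------------------------------------------------------------

def project(ens: EsmEnsemble, env: LayerStack) -> RasterGrid:
    """Weighted-mean pair-model suitability per cell; nodata propagated."""
    for name in ens.predictor_names:
        if name not in env:
            raise KeyError(f"projection stack is missing predictor {name!r}")
    sub = env.subset(ens.predictor_names)
    rows, cols, X = sub.to_matrix()
    suit = ens.predict(X)
    out = np.full(sub.template.shape, np.nan)
    out[rows, cols] = suit
    return sub.template.like(out)


def clamp(ens: EsmEnsemble, env: LayerStack, suitability: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Nullify suitability where any predictor is outside its training range.

    Returns (clamped suitability, clamping mask counting offending
    predictors per cell).
    """
    counts = np.zeros(suitability.shape)
    for name in ens.predictor_names:
        lo, hi = ens.training_ranges[name]
        x = env[name].data
        counts += ((x < lo) | (x > hi)).astype(float)
    clamped = np.where(counts > 0, 0.0, suitability.data)
    clamped = np.where(np.isfinite(suitability.data), clamped, np.nan)
    counts = np.where(np.isfinite(suitability.data), counts, np.nan)
    return suitability.like(clamped), suitability.like(counts)


@dataclass
class BinaryRangeMap:
    """Presence/absence map for one species under one scenario."""

    presence: RasterGrid  # 1/0, NaN on sea
    species: str
    scenario: ScenarioSpec
    threshold: float

    @property
    def cells(self) -> int:
        return int(np.nansum(self.presence.data))


def binarize(suitability: RasterGrid, threshold: float, species: str, scenario: ScenarioSpec = BASELINE) -> BinaryRangeMap:
    """Presence where suitability >= threshold (monotone in the threshold)."""
    pres = np.where(np.isfinite(suitability.data), (suitability.data >= threshold).astype(float), np.nan)
    return BinaryRangeMap(presence=suitability.like(pres), species=species, scenario=scenario, threshold=threshold)


# ---------------------------------------------------------------------------
# ExDet
# ---------------------------------------------------------------------------

@dataclass
class ExtrapolationReport:
    """ExDet novelty fields over the projection samples.

    nt1 <= 0 (univariate range novelty), nt2 >= 0 (Mahalanobis combination
    novelty, scaled so values > 1 are novel), exdet = nt1 where nt1 < 0
    else nt2; analogue_fraction is the percent of projection samples with
    nt1 == 0 and nt2 in [0, 1]; pct_nearby is the %N surface.
    """

    nt1: np.ndarray
    nt2: np.ndarray
    exdet: np.ndarray
    analogue_fraction: float
    pct_nearby: np.ndarray


def exdet(reference: np.ndarray, projection: np.ndarray, chunk: int = 2000) -> ExtrapolationReport:
    """ExDet + %N for projection samples against a reference sample.

    NT1 sums, over variables, the (negative) fraction of the reference
    range by which a point falls outside it. Points inside every range get
    NT2 = squared Mahalanobis distance to the reference mean scaled by the
    largest reference distance. %N is the percent of reference points whose
    Gower distance to the projection point is within the reference set's
    median nearest-neighbour Gower distance.
    """
    ref = np.asarray(reference, dtype=float)
    proj = np.asarray(projection, dtype=float)
    n_ref, d = ref.shape
    if n_ref < d + 2:
        raise ValueError("need at least dim+2 reference samples")
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    rng_ = hi - lo
    if np.any(rng_ <= 0):
        raise ValueError("reference has a zero-range variable; reduce predictors")

    ud = np.minimum(np.minimum(proj - lo, hi - proj), 0.0) / rng_
    nt1 = ud.sum(axis=1)

    mean = ref.mean(axis=0)
    cov = np.atleast_2d(np.cov(ref.T))
    if np.linalg.cond(cov) > 1e10:
        raise ValueError("singular reference covariance; reduce predictors")
    cov_inv = np.linalg.inv(cov)
    dref = ref - mean
    d2_ref = np.einsum("ij,jk,ik->i", dref, cov_inv, dref)
    d2_max = float(d2_ref.max())
    dproj = proj - mean
    d2 = np.einsum("ij,jk,ik->i", dproj, cov_inv, dproj)
    nt2 = np.where(nt1 == 0, d2 / d2_max, 0.0)

    combined = np.where(nt1 < 0, nt1, nt2)
    analogue = float(100.0 * np.mean((nt1 == 0) & (nt2 <= 1.0)))

    # %N via Gower distance
    ref_scaled = ref / rng_
    proj_scaled = proj / rng_
    # reference's own median nearest-neighbour Gower distance
    nn = np.full(n_ref, np.inf)
    for a in range(0, n_ref, chunk):
        block = ref_scaled[a : a + chunk]
        g = np.abs(block[:, None, :] - ref_scaled[None, :, :]).mean(axis=2)
        g[np.arange(block.shape[0]), a + np.arange(block.shape[0])] = np.inf
        nn[a : a + chunk] = g.min(axis=1)
    t = float(np.median(nn))
    pct = np.empty(proj.shape[0])
    for a in range(0, proj.shape[0], chunk):
        block = proj_scaled[a : a + chunk]
        g = np.abs(block[:, None, :] - ref_scaled[None, :, :]).mean(axis=2)
        pct[a : a + chunk] = 100.0 * (g <= t).mean(axis=1)

    return ExtrapolationReport(nt1=nt1, nt2=nt2, exdet=combined, analogue_fraction=analogue, pct_nearby=pct)


def exdet_stack(ens_or_names, reference: np.ndarray, env: LayerStack) -> tuple[ExtrapolationReport, dict]:
    """ExDet of a projection stack against training samples; returns rasters too."""
    names = ens_or_names.predictor_names if isinstance(ens_or_names, EsmEnsemble) else list(ens_or_names)
    sub = env.subset(names)
    rows, cols, X = sub.to_matrix()
    rep = exdet(reference, X)
    shape = sub.template.shape

    def to_grid(v):
        out = np.full(shape, np.nan)
        out[rows, cols] = v
        return sub.template.like(out)

    grids = {"nt1": to_grid(rep.nt1), "nt2": to_grid(rep.nt2), "exdet": to_grid(rep.exdet), "pct_nearby": to_grid(rep.pct_nearby)}
    return rep, grids


# ---------------------------------------------------------------------------
# niche truncation
# ---------------------------------------------------------------------------

def niche_truncation_index(study_occ_env: np.ndarray, full_occ_env: np.ndarray, grid_bins: int = 100) -> float:
    """Half the L1 distance between kernel-smoothed occurrence densities.

    Densities are built on the first two principal axes of the pooled,
    standardized environments, normalized to sum 1 on a grid_bins^2
    lattice; 0 = no truncation (identical niches), 1 = fully disjoint.
    """
    a = np.asarray(study_occ_env, dtype=float)
    b = np.asarray(full_occ_env, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("need at least 10 samples each")
    pooled = np.vstack([a, b])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance environmental variable")
    z = (pooled - mu) / sd
    # first two principal axes
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    k = min(2, vt.shape[0])
    scores = z @ vt[:k].T
    sa, sb = scores[: len(a)], scores[len(a):]
    lo = scores.min(axis=0) - 1e-9
    hi = scores.max(axis=0) + 1e-9
    if k == 1:
        ha = np.histogram(sa[:, 0], bins=grid_bins, range=(lo[0], hi[0]))[0].astype(float)
        hb = np.histogram(sb[:, 0], bins=grid_bins, range=(lo[0], hi[0]))[0].astype(float)
    else:
        ha = np.histogram2d(sa[:, 0], sa[:, 1], bins=grid_bins, range=[(lo[0], hi[0]), (lo[1], hi[1])])[0]
        hb = np.histogram2d(sb[:, 0], sb[:, 1], bins=grid_bins, range=[(lo[0], hi[0]), (lo[1], hi[1])])[0]
    sigma = grid_bins / 25.0
    ha = ndimage.gaussian_filter(ha, sigma)
    hb = ndimage.gaussian_filter(hb, sigma)
    ha /= ha.sum()
    hb /= hb.sum()
    return float(0.5 * np.abs(ha - hb).sum())


# ---------------------------------------------------------------------------
# range change
# ---------------------------------------------------------------------------

@dataclass
class RangeChange:
    """Loss/gain/stable cell counts and percent change for one species."""

    loss_cells: int
    gain_cells: int
    stable_cells: int
    change_pct: float
    dispersal_mode: str
    flagged_empty: bool = False


def range_change(
    current: BinaryRangeMap,
    future: BinaryRangeMap,
    dispersal_mode: str = "buffered",
    buffer_km: float | None = None,
) -> RangeChange:
    """Contraction/expansion bookkeeping between two binary maps.

    Gains are masked to nothing (mode 'none'), to cells within
    ``buffer_km`` of the current range (mode 'buffered'; Chebyshev cell
    distance via 8-connected dilation), or unrestricted (mode 'full').
    change_pct = 100 x (gain - loss) / current cells.
    """
    if not current.presence.same_geometry(future.presence):
        raise ValueError("grids are not aligned")
    if current.species != future.species:
        raise ValueError("range maps belong to different species")
    cur = current.presence.data == 1
    fut = future.presence.data == 1
    n_cur = int(cur.sum())
    loss = cur & ~fut
    gain = fut & ~cur
    if dispersal_mode == "none":
        gain = np.zeros_like(gain)
    elif dispersal_mode == "buffered":
        if buffer_km is None:
            buffer_km = 2.0 * current.presence.cell_km
        it = max(1, int(round(buffer_km / current.presence.cell_km)))
        reachable = ndimage.binary_dilation(cur, structure=np.ones((3, 3), bool), iterations=it)
        gain = gain & reachable
    elif dispersal_mode != "full":
        raise ValueError(f"unknown dispersal_mode {dispersal_mode!r}")
    stable = cur & fut
    if n_cur == 0:
        log.warning("range_change %s: empty current range", current.species)
        return RangeChange(0, int(gain.sum()), 0, float("nan"), dispersal_mode, flagged_empty=True)
    change = 100.0 * (int(gain.sum()) - int(loss.sum())) / n_cur
    return RangeChange(int(loss.sum()), int(gain.sum()), int(stable.sum()), change, dispersal_mode)
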