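"""Per-species Ensembles of Small Models (ESMs).

Rare species defeat full multivariate SDMs, so every unordered pair of
retained predictors gets its own small Random-Forest classifier; the
ensemble suitability is the TSS-weighted mean of the pair models
(negative-skill pairs carry weight 0). Supporting machinery: taxon-specific
pseudo-absence sets at a minimum distance from presences, spatial-block
cross-validation sized by the median autocorrelation range of the
predictors, and a permutation-style null-model significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .grid import RasterGrid, LayerStack, haversine_km
from .metrics import EvalReport, evaluate_scores, max_tss, maxsss_threshold, tss  # noqa: F401 (module surface)

log = logging.getLogger(__name__)

DEFAULT_LEARNER_PARAMS = {"n_estimators": 500, "min_samples_leaf": 1}


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------

@dataclass
class PseudoAbsenceSet:
    """One set of background points, all >= min_dist km from every presence."""

    points: np.ndarray  # (n, 2) lon/lat
    set_id: int
    species: str
    min_dist: float


def count_eligible_cells(presences: np.ndarray, region: RasterGrid, min_dist: float = 5.5) -> int:
    """Number of land cells >= min_dist km from every presence (non-presence cells)."""
    presences = np.asarray(presences, dtype=float)
    rows, cols = np.nonzero(region.data > 0)
    lon, lat = region.cell_center(rows, cols)
    dmin = np.full(lon.size, np.inf)
    for plon, plat in presences:
        dmin = np.minimum(dmin, haversine_km(lon, lat, plon, plat))
    prow, pcol, ins = region.index_of(presences[:, 0], presences[:, 1])
    pres_cells = set(zip(prow[ins].tolist(), pcol[ins].tolist()))
    not_pres = np.array([(r, c) not in pres_cells for r, c in zip(rows, cols)])
    return int(((dmin >= min_dist) & not_pres).sum())


def generate_pseudo_absences(
    species: str,
    presences: np.ndarray,
    region: RasterGrid,
    min_dist: float = 5.5,
    n_sets: int = 5,
    n_per_set: int = 1000,
    seed: int = 0,
) -> list[PseudoAbsenceSet]:
    """Uniform samples of eligible land cells, >= min_dist km from presences.

    ``region`` is the land mask; ``presences`` an (n, 2) lon/lat array.
    Each set is seeded disjointly. Raises when fewer than n_per_set cells
    are eligible (suggesting a smaller min_dist).
    """
    presences = np.asarray(presences, dtype=float)
    rows, cols = np.nonzero(region.data > 0)
    lon, lat = region.cell_center(rows, cols)
    dmin = np.full(lon.size, np.inf)
    for plon, plat in presences:
        dmin = np.minimum(dmin, haversine_km(lon, lat, plon, plat))
    # exclude presence cells themselves even at min_dist = 0
    prow, pcol, ins = region.index_of(presences[:, 0], presences[:, 1])
    pres_cells = set(zip(prow[ins].tolist(), pcol[ins].tolist()))
    not_pres = np.array([(r, c) not in pres_cells for r, c in zip(rows, cols)])
    eligible = (dmin >= min_dist) & not_pres
    n_eligible = int(eligible.sum())
    if n_eligible < n_per_set:
        raise ValueError(
            f"{species}: only {n_eligible} eligible cells for {n_per_set} pseudo-absences; "
            "reduce min_dist or n_per_set"
        )
    elon, elat = lon[eligible], lat[eligible]
    sets = []
    ss = np.random.SeedSequence(seed)
    for set_id, child in enumerate(ss.spawn(n_sets)):
        rng = np.random.default_rng(child)
        sel = rng.choice(n_eligible, size=n_per_set, replace=False)
        sets.append(
            PseudoAbsenceSet(
                points=np.column_stack([elon[sel], elat[sel]]),
                set_id=set_id,
                species=species,
                min_dist=min_dist,
            )
        )
    return sets


# ---------------------------------------------------------------------------
# autocorrelation range
# ---------------------------------------------------------------------------

def _variogram_range(grid: RasterGrid, rng, n_cells: int, n_bins: int, sill_quantile: float = 0.95):
    rows, cols = np.nonzero(grid.valid)
    if rows.size < 10:
        return None
    vals = grid.data[rows, cols]
    if np.std(vals) == 0:
        return None
    if rows.size > n_cells:
        sel = rng.choice(rows.size, n_cells, replace=False)
        rows, cols, vals = rows[sel], cols[sel], vals[sel]
    lon, lat = grid.cell_center(rows, cols)
    x, y = grid.xy_km(lon, lat)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    d = np.sqrt(dx * dx + dy * dy)
    gamma = 0.5 * (vals[:, None] - vals[None, :]) ** 2
    iu = np.triu_indices(d.shape[0], k=1)
    d, gamma = d[iu], gamma[iu]
    max_lag = d.max() / 2.0
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    binned = np.full(n_bins, np.nan)
    idx = np.digitize(d, edges[1:-1])
    for b in range(n_bins):
        m = idx == b
        if m.any():
            binned[b] = gamma[m].mean()
    tail = binned[int(0.6 * n_bins):]
    sill = np.nanmean(tail)
    if not np.isfinite(sill) or sill <= 0:
        return None
    hit = np.flatnonzero(np.nan_to_num(binned, nan=-np.inf) >= sill_quantile * sill)
    return float(mids[hit[0]]) if hit.size else float(max_lag)


def median_autocorrelation_range(stack: LayerStack, seed: int = 0, n_cells: int = 1200, n_bins: int = 24) -> float:
    """Median over layers of the empirical variogram range (km).

    Per layer the range is the smallest lag whose semivariance reaches 95%
    of the sill (mean semivariance at large lags); flat layers are skipped
    with a warning.
    """
    if len(stack) < 1:
        raise ValueError("need at least one layer")
    rng = np.random.default_rng(seed)
    ranges = []
    for name in stack.names:
        r = _variogram_range(stack[name], rng, n_cells, n_bins)
        if r is None:
            log.warning("median_autocorrelation_range: skipping flat/empty layer %s", name)
        else:
            ranges.append(r)
    if not ranges:
        raise ValueError("no layer yielded a variogram range")
    return float(np.median(ranges))


# ---------------------------------------------------------------------------
# spatial block CV
# ---------------------------------------------------------------------------

@dataclass
class BlockCV:
    """Square-lattice spatial blocking; all points of a block share a fold."""

    block_size: float
    n_folds: int
    assignment: np.ndarray  # fold id per point
    block_of_point: np.ndarray
    fold_of_block: dict

    def folds(self):
        for f in range(self.n_folds):
            yield f, self.assignment == f


def assign_blocks(
    points: np.ndarray,
    extent: RasterGrid,
    block_size: float,
    n_folds: int = 5,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> BlockCV:
    """Deal lattice blocks (random origin) to folds, balancing presences.

    Blocks are assigned greedily, largest presence count first, each to the
    fold currently holding the fewest presences (ties: fewest points, then
    lowest fold id). With n_folds=5 each fold's test share is ~20%.
    """
    if block_size <= 0:
        raise ValueError("block_size must be > 0")
    points = np.asarray(points, dtype=float)
    labels = np.ones(points.shape[0]) if labels is None else np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    x, y = extent.xy_km(points[:, 0], points[:, 1])
    ox, oy = rng.uniform(0.0, block_size, 2)
    bx = np.floor((x + ox) / block_size).astype(int)
    by = np.floor((y + oy) / block_size).astype(int)
    block_ids = bx * 100003 + by
    uniq, inv = np.unique(block_ids, return_inverse=True)

    pres_in_block = np.zeros(uniq.size)
    np.add.at(pres_in_block, inv, labels)
    tot_in_block = np.bincount(inv, minlength=uniq.size).astype(float)
    if (pres_in_block > 0).sum() < 2:
        raise ValueError("all presences fall in a single block; split rejected")

    order = np.argsort(-(pres_in_block * 1e6 + tot_in_block), kind="stable")
    fold_pres = np.zeros(n_folds)
    fold_tot = np.zeros(n_folds)
    fold_of_block = {}
    for b in order:
        key = np.lexsort((np.arange(n_folds), fold_tot, fold_pres))[0]
        fold_of_block[int(uniq[b])] = int(key)
        fold_pres[key] += pres_in_block[b]
        fold_tot[key] += tot_in_block[b]
    assignment = np.array([fold_of_block[int(bid)] for bid in block_ids])
    return BlockCV(
        block_size=block_size,
        n_folds=n_folds,
        assignment=assignment,
        block_of_point=inv,
        fold_of_block=fold_of_block,
    )


# ---------------------------------------------------------------------------
# the ensemble
# ---------------------------------------------------------------------------

@dataclass
class EsmEnsemble:
    """TSS-weighted ensemble of bivariate Random-Forest models for one species."""

    species: str
    predictor_names: list[str]
    pairs: list[tuple[str, str]]
    models: list
    weights: np.ndarray
    training_ranges: dict  # name -> (min, max)
    ensemble_tss: float
    threshold: float
    eval_report: EvalReport | None
    n_presences: int
    training_lonlat: np.ndarray | None = None  # presences + pseudo-absences

    @property
    def modellable(self) -> bool:
        return bool(np.nansum(self.weights) > 0)

    def admitted(self, tss_min: float = 0.8) -> bool:
        """The admission gate for downstream projection."""
        return self.modellable and self.ensemble_tss >= tss_min

    def pair_columns(self) -> list[tuple[int, int]]:
        name_ix = {n: i for i, n in enumerate(self.predictor_names)}
        return [(name_ix[a], name_ix[b]) for a, b in self.pairs]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-mean suitability for an (n, d) predictor matrix."""
        if not self.modellable:
            raise ValueError(f"{self.species}: no pair carries positive weight")
        w = np.clip(self.weights, 0.0, None)
        acc = np.zeros(X.shape[0])
        for (ia, ib), model, wk in zip(self.pair_columns(), self.models, w):
            if wk > 0:
                acc += wk * model.predict_proba(X[:, [ia, ib]])[:, 1]
        return acc / w.sum()


def fit_esm(
    species: str,
    presences: np.ndarray,
    pa_sets: list[PseudoAbsenceSet],
    predictors: LayerStack,
    block_size: float,
    n_folds: int = 5,
    n_repeats: int = 10,
    learner_params: dict | None = None,
    final_learner_params: dict | None = None,
    pair_tss_min: float = 0.5,
    seed: int = 0,
) -> EsmEnsemble:
    """Fit all bivariate pair models and their cross-validated TSS weights.

    Per (pseudo-absence set, repeat) a fresh random-origin block CV is
    drawn; per pair the out-of-fold predictions pooled over folds give one
    TSS, and the pair weight is the mean over sets x repeats, floored at 0.
    The ensemble TSS is the same statistic for the weighted ensemble of the
    out-of-fold pair predictions; the binarization threshold is the maxSSS
    threshold on the pooled out-of-fold ensemble predictions. Final per-pair
    models for projection are refit on presences + pooled pseudo-absences.
    """
    params = dict(DEFAULT_LEARNER_PARAMS, **(learner_params or {}))
    # the handful of final projection models can afford a larger forest than
    # the thousands of cross-validation fits
    final_params = dict(params, n_estimators=max(250, params["n_estimators"]))
    final_params.update(final_learner_params or {})
    names = predictors.names
    if len(names) < 2:
        raise ValueError("need at least 2 retained predictors")
    presences = np.asarray(presences, dtype=float)

    Xp = predictors.values_at(presences[:, 0], presences[:, 1])
    okp = np.isfinite(Xp).all(axis=1)
    Xp, pres_pts = Xp[okp], presences[okp]
    Xa_sets, abs_pts = [], []
    for pa in pa_sets:
        Xa = predictors.values_at(pa.points[:, 0], pa.points[:, 1])
        oka = np.isfinite(Xa).all(axis=1)
        Xa_sets.append(Xa[oka])
        abs_pts.append(pa.points[oka])

    pair_idx = list(combinations(range(len(names)), 2))
    n_pairs = len(pair_idx)
    ss = np.random.SeedSequence(seed)
    rf_seed = iter(np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1, size=10 * n_pairs * max(1, len(pa_sets)) * max(1, n_repeats) * (n_folds + 1)))
    cv_rng = np.random.default_rng(ss.spawn(2)[1])

    tss_acc = [[] for _ in range(n_pairs)]
    oof_store = []  # (oof matrix, labels)

    for si, (Xa, apts) in enumerate(zip(Xa_sets, abs_pts)):
        pts = np.vstack([pres_pts, apts])
        X = np.vstack([Xp, Xa])
        y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])
        for rep in range(n_repeats):
            cv = None
            for _ in range(5):
                try:
                    cv = assign_blocks(pts, predictors.template, block_size, n_folds, int(cv_rng.integers(2**31 - 1)), labels=y)
                    break
                except ValueError:
                    continue
            if cv is None:
                log.warning("fit_esm %s: degenerate blocking for set %d rep %d", species, si, rep)
                continue
            oof = np.full((len(y), n_pairs), np.nan)
            fold_tss = [[] for _ in range(n_pairs)]
            for f, test in cv.folds():
                train = ~test
                if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                    continue
                for k, (ia, ib) in enumerate(pair_idx):
                    rf = RandomForestClassifier(random_state=int(next(rf_seed)), n_jobs=1, **params)
                    rf.fit(X[train][:, [ia, ib]], y[train])
                    oof[test, k] = rf.predict_proba(X[test][:, [ia, ib]])[:, 1]
                    # weight-relevant skill: threshold chosen on the training
                    # predictions, TSS evaluated on the held-out fold — keeps
                    # small-sample optimism out of the pair weights
                    try:
                        thr = maxsss_threshold(rf.predict_proba(X[train][:, [ia, ib]])[:, 1], y[train])
                        pred = oof[test, k] >= thr
                        yt = y[test]
                        fold_tss[k].append(
                            tss((np.sum(pred & (yt == 1)), np.sum(pred & (yt == 0)),
                                 np.sum(~pred & (yt == 1)), np.sum(~pred & (yt == 0))))
                        )
                    except ValueError:
                        pass
            valid = np.isfinite(oof).all(axis=1)
            if valid.sum() < 4 or len(np.unique(y[valid])) < 2:
                continue
            for k in range(n_pairs):
                if fold_tss[k]:
                    tss_acc[k].append(float(np.mean(fold_tss[k])))
            oof_store.append((oof[valid], y[valid]))

    # pair weight = mean cross-validated TSS, floored at 0; pairs below the
    # skill threshold are excluded outright (the ESM weighting-score rule) —
    # marginal pairs otherwise dilute the ensemble
    weights = np.array([np.clip(np.mean(v), 0.0, None) if v else 0.0 for v in tss_acc])
    if np.any(weights >= pair_tss_min):
        weights = np.where(weights >= pair_tss_min, weights, 0.0)

    # ensemble skill/threshold from the stored out-of-fold predictions
    ens_tss_vals, pooled_pred, pooled_y = [], [], []
    if weights.sum() > 0:
        wsum = weights.sum()
        for oof, y in oof_store:
            ens = oof @ weights / wsum
            try:
                ens_tss_vals.append(max_tss(ens, y))
            except ValueError:
                continue
            pooled_pred.append(ens)
            pooled_y.append(y)
    ensemble_tss = float(np.mean(ens_tss_vals)) if ens_tss_vals else float("nan")
    if pooled_pred:
        pp = np.concatenate(pooled_pred)
        yy = np.concatenate(pooled_y)
        threshold = maxsss_threshold(pp, yy)
        eval_report = evaluate_scores(pp, yy, background=pp[yy == 0])
    else:
        threshold, eval_report = float("nan"), None

    # final projection models: presences + pooled pseudo-absence sets
    X_all = np.vstack([Xp] + Xa_sets)
    y_all = np.concatenate([np.ones(len(Xp))] + [np.zeros(len(a)) for a in Xa_sets])
    models = []
    for k, (ia, ib) in enumerate(pair_idx):
        rf = RandomForestClassifier(random_state=int(next(rf_seed)), n_jobs=1, class_weight="balanced", **final_params)
        rf.fit(X_all[:, [ia, ib]], y_all)
        models.append(rf)

    training_ranges = {n: (float(np.min(X_all[:, j])), float(np.max(X_all[:, j]))) for j, n in enumerate(names)}
    ens = EsmEnsemble(
        species=species,
        predictor_names=list(names),
        pairs=[(names[a], names[b]) for a, b in pair_idx],
        models=models,
        weights=weights,
        training_ranges=training_ranges,
        ensemble_tss=ensemble_tss,
        threshold=threshold,
        eval_report=eval_report,
        n_presences=int(len(Xp)),
        training_lonlat=np.vstack([pres_pts] + abs_pts),
    )
    if not ens.modellable:
        log.warning("fit_esm %s: all pair weights are zero; species unmodellable", species)
    return ens


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def null_model_test(observed_tss: float, null_fit, n_null: int = 99, seed: int = 0) -> float:
    """p-value of the observed skill against refits on randomized presences.

    ``null_fit(rng) -> tss`` must refit the model with presence locations
    resampled at random (same n) and return its skill.
    p = (1 + #{null >= observed}) / (n_null + 1).
    """
    if n_null < 19:
        raise ValueError("n_null must be >= 19")
    ss = np.random.SeedSequence(seed)
    exceed = 0
    for child in ss.spawn(n_null):
        if null_fit(np.random.default_rng(child)) >= observed_tss:
            exceed += 1
    return (1 + exceed) / (n_null + 1)
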