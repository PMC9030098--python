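"""Discrimination/calibration metrics shared by model fitting and projection.

TSS and the maxSSS threshold are the load-bearing quantities: per-pair TSS
weights the small-model ensemble, and the maxSSS threshold binarizes the
projected suitability. AUC / AUC-PR / CBI / ECE round out the evaluation
roster reported per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


def tss(confusion: tuple[float, float, float, float]) -> float:
    """True Skill Statistic = sensitivity + specificity - 1.

    confusion is (tp, fp, fn, tn); raises on an empty class where the
    statistic is undefined.
    """
    tp, fp, fn, tn = confusion
    if tp + fn <= 0 or tn + fp <= 0:
        raise ValueError("TSS undefined: one class is empty")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def _sens_spec_at_thresholds(scores: np.ndarray, labels: np.ndarray):
    """Candidate thresholds (midpoints + extremes) and sens+spec at each.

    A point is predicted present when score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("need at least two distinct scores")
    mid = 0.5 * (distinct[:-1] + distinct[1:])
    span = distinct[-1] - distinct[0]
    cand = np.concatenate([[distinct[0] - 0.01 * span], mid, [distinct[-1] + 0.01 * span]])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    pred = scores[None, :] >= cand[:, None]
    sens = (pred & labels[None, :]).sum(axis=1) / n_pos
    spec = ((~pred) & (~labels[None, :])).sum(axis=1) / n_neg
    return cand, sens + spec


def maxsss_threshold(pred, labels) -> float:
    """Threshold maximizing sensitivity + specificity; ties -> lowest threshold."""
    cand, ss = _sens_spec_at_thresholds(np.asarray(pred), np.asarray(labels))
    # lowest threshold among (numerically) tied optima
    best = np.flatnonzero(ss >= ss.max() - 1e-10)[0]
    return float(cand[best])


def max_tss(pred, labels) -> float:
    """TSS evaluated at the maxSSS threshold (= max over thresholds of sens+spec-1)."""
    _, ss = _sens_spec_at_thresholds(np.asarray(pred), np.asarray(labels))
    return float(ss.max() - 1.0)


def continuous_boyce_index(pres_suit, background_suit, window_frac: float = 0.1, n_windows: int = 100):
    """Boyce index: Spearman rho of predicted/expected ratio vs window midpoint.

    Moving windows of width ``window_frac`` of the suitability range, with
    ``n_windows`` evenly spaced starts. Returns NaN when undefined
    (degenerate range or constant ratio).
    """
    pres = np.asarray(pres_suit, dtype=float)
    back = np.asarray(background_suit, dtype=float)
    lo = min(pres.min(), back.min())
    hi = max(pres.max(), back.max())
    if hi <= lo:
        return float("nan")
    width = window_frac * (hi - lo)
    starts = np.linspace(lo, hi - width, n_windows)
    mids, ratios = [], []
    for a in starts:
        b = a + width
        p = ((pres >= a) & (pres < b)).mean() if a + width < hi else ((pres >= a) & (pres <= b)).mean()
        e = ((back >= a) & (back < b)).mean() if a + width < hi else ((back >= a) & (back <= b)).mean()
        if e > 0:
            mids.append(a + width / 2.0)
            ratios.append(p / e)
    if len(ratios) < 3 or np.std(ratios) == 0:
        return float("nan")
    return float(stats.spearmanr(ratios, mids).statistic)


def expected_calibration_error(pred, labels, n_bins: int = 10) -> float:
    """ECE over equal-width probability bins."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(pred, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        m = idx == b
        if m.any():
            ece += m.mean() * abs(pred[m].mean() - labels[m].mean())
    return float(ece)


@dataclass
class EvalReport:
    """Per-species evaluation roster (AUC, AUC-PR, TSS, CBI, ECE)."""

    auc: float
    auc_pr: float
    tss: float
    cbi: float
    ece: float
    threshold_used: float
    n_test: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("auc", "auc_pr", "tss", "cbi", "ece", "threshold_used", "n_test")}


def evaluate_scores(pred, labels, background) -> EvalReport:
    """Score a set of test predictions against presence/absence labels.

    AUC by rank statistic (ties half credit), AUC-PR by step integration,
    TSS at the maxSSS threshold, CBI against the background suitabilities,
    ECE over 10 equal-width bins. Degenerate constant predictions give
    AUC = 0.5 and NaN CBI.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("need at least one presence and one absence")
    if np.unique(pred).size < 2:
        auc = 0.5
        auc_pr = float(labels.mean())
        t = float("nan")
        tss_val = 0.0
        cbi = float("nan")
    else:
        auc = float(roc_auc_score(labels, pred))
        auc_pr = float(average_precision_score(labels, pred))
        t = maxsss_threshold(pred, labels)
        tss_val = max_tss(pred, labels)
        cbi = continuous_boyce_index(pred[labels == 1], np.asarray(background, dtype=float))
    ece = expected_calibration_error(pred, labels)
    return EvalReport(auc=auc, auc_pr=auc_pr, tss=tss_val, cbi=cbi, ece=ece, threshold_used=t, n_test=int(labels.size))
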