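"""Discrimination, calibration, decision-curve and operating-point metrics.

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative (ties counted ½); AUPRC is average precision (the step-wise
integral of precision over recall, no linear interpolation); ECE bins the
normalized score (score / 100) into equal-count deciles and takes the
prevalence-weighted mean absolute gap between predicted and observed risk.
Decision curves report net benefit NB(pt) = TPR·π − FPR·(1−π)·pt/(1−pt) and
its standardized form sNB = NB/π.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import UndefinedMetricError, round_half_up


def _clean(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and congruent")
    if np.isnan(s).any():
        raise ValueError("scores contain NaN")
    return s, y


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney form, ties ½)."""
    s, y = _clean(scores, labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUROC undefined with a single class")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auprc(scores, labels) -> float:
    """Average precision: Σ (R_k − R_{k−1})·P_k over distinct score cuts."""
    s, y = _clean(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC undefined without positives")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group ties: evaluate precision/recall only at distinct score cuts
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    cut_idx = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(y)[cut_idx].astype(float)
    n_flag = cut_idx + 1.0
    precision = tp / n_flag
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class CalibrationReport:
    """Per-decile predicted vs observed risk and the resulting ECE."""

    bin_mean_predicted: np.ndarray
    bin_observed_rate: np.ndarray
    bin_count: np.ndarray
    ece: float


def ece(scores_normalized, labels, n_bins: int = 10) -> CalibrationReport:
    """Estimated calibration error over equal-count score deciles.

    ``scores_normalized`` must already be on the 0–1 scale (raw 0–100 model
    scores divided by 100); the report is precisely the diagnostic of how
    far those normalized scores sit from observed risk.
    """
    s, y = _clean(scores_normalized, labels)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must be normalized to [0, 1]")
    if s.size < n_bins:
        raise UndefinedMetricError(f"need at least {n_bins} instances for {n_bins} bins")
    order = np.argsort(s, kind="stable")
    chunks = np.array_split(order, n_bins)
    mean_pred = np.array([s[c].mean() for c in chunks])
    obs = np.array([y[c].mean() for c in chunks])
    counts = np.array([c.size for c in chunks])
    e = float(np.sum(counts / s.size * np.abs(obs - mean_pred)))
    return CalibrationReport(mean_pred, obs, counts, e)


@dataclass
class DecisionCurve:
    """Net benefit of score-threshold policies across threshold probabilities."""

    threshold_probabilities: np.ndarray
    net_benefit: np.ndarray
    standardized_net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(scores_normalized, labels, pt_grid=None) -> DecisionCurve:
    """Decision curve: classify positive at normalized score ≥ pt.

    ``NB(pt) = TPR·π − FPR·(1−π)·pt/(1−pt)``; the treat-all reference uses
    TPR = FPR = 1 and treat-none is 0 everywhere; sNB divides by prevalence
    (1 for a perfect classifier at every pt).
    """
    s, y = _clean(scores_normalized, labels)
    if pt_grid is None:
        pt_grid = np.arange(0.01, 0.51, 0.01)
    pt = np.asarray(pt_grid, dtype=float)
    if ((pt <= 0) | (pt >= 1)).any():
        raise ValueError("threshold probabilities must lie in (0, 1)")
    pi = y.mean()
    if pi == 0:
        raise UndefinedMetricError("decision curve undefined without positives")
    n1, n0 = y.sum(), (~y).sum()
    tpr = np.array([(s[y] >= p).sum() / n1 for p in pt])
    fpr = np.array([(s[~y] >= p).sum() / n0 for p in pt]) if n0 else np.zeros_like(pt)
    odds = pt / (1 - pt)
    nb = tpr * pi - fpr * (1 - pi) * odds
    treat_all = pi - (1 - pi) * odds
    return DecisionCurve(pt, nb, nb / pi, treat_all, np.zeros_like(pt))


# ---------------------------------------------------------------------------
# Threshold sweeps and operating points
# ---------------------------------------------------------------------------


def threshold_sweep(instances: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    """Operating characteristics per integer score threshold 0–100.

    ``instances`` carries ``max_score_pre_t0`` and ``label``; rows without
    an eligible prediction (NaN score) are dropped.  An encounter is flagged
    at threshold t iff its score ≥ t.  Returns columns
    ``threshold,precision,recall,fpr,nne,n_flagged,flagged_fraction``
    (NNE exact, ``nne·precision = 1``; display rounding happens in reports).
    """
    inst = instances.dropna(subset=["max_score_pre_t0"])
    s = inst["max_score_pre_t0"].to_numpy(dtype=float)
    y = inst["label"].to_numpy(dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("threshold sweep undefined with a single class")
    if thresholds is None:
        thresholds = np.arange(0, 101)
    t = np.asarray(thresholds, dtype=float)

    s_sorted = np.sort(s)
    pos_sorted = np.sort(s[y])
    n = s.size
    n_flagged = n - np.searchsorted(s_sorted, t, side="left")
    tp = n1 - np.searchsorted(pos_sorted, t, side="left")
    fp = n_flagged - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(n_flagged > 0, tp / np.maximum(n_flagged, 1), np.nan)
        nne = np.where((n_flagged > 0) & (tp > 0), n_flagged / np.maximum(tp, 1), np.nan)
    return pd.DataFrame(
        {
            "threshold": t.astype(int),
            "precision": precision,
            "recall": tp / n1,
            "fpr": fp / n0,
            "nne": nne,
            "n_flagged": n_flagged,
            "flagged_fraction": n_flagged / n,
        }
    )


def youden_top_left(sweep: pd.DataFrame, mode: str = "top_left") -> pd.Series:
    """Best-balanced threshold on the ROC curve.

    ``top_left`` (default) minimizes the Euclidean distance to the (0, 1)
    corner, √(FPR² + (1−TPR)²); ``youden_j`` maximizes TPR − FPR.  Ties
    break toward the higher threshold.
    """
    if sweep.empty:
        raise UndefinedMetricError("empty sweep")
    if mode == "top_left":
        crit = -np.sqrt(sweep["fpr"] ** 2 + (1 - sweep["recall"]) ** 2)
    elif mode == "youden_j":
        crit = sweep["recall"] - sweep["fpr"]
    else:
        raise ValueError("mode must be 'top_left' or 'youden_j'")
    best = crit.to_numpy()
    idx = np.flatnonzero(best == best.max())[-1]  # ties -> higher threshold
    return sweep.iloc[idx]


def select_operating_points(
    sweep: pd.DataFrame, min_recall: float = 0.8, min_precision: float = 0.15
) -> dict:
    """The three predefined operating points: the highest threshold keeping
    recall ≥ 0.8, the point maximizing recall subject to precision ≥ 0.15,
    and the Youden top-left; unattainable points come back as None."""
    out: dict[str, pd.Series | None] = {}
    hr = sweep[sweep["recall"] >= min_recall]
    out["high_recall"] = hr.loc[hr["threshold"].idxmax()] if not hr.empty else None
    hp = sweep[sweep["precision"] >= min_precision]
    if hp.empty:
        out["high_precision"] = None
    else:
        best = hp[hp["recall"] == hp["recall"].max()]
        out["high_precision"] = best.loc[best["threshold"].idxmax()]
    out["youden_top_left"] = youden_top_left(sweep)
    for name, pt in out.items():
        if pt is None:
            import warnings

            warnings.warn(f"operating point '{name}' unattainable on this sweep", stacklevel=2)
    return out


def stratified_metrics(instances: pd.DataFrame, strata_fields: list[str]) -> pd.DataFrame:
    """AUROC/AUPRC with case counts per stratum; single-class strata are
    reported as NaN (the 'NA' convention for empty subgroups)."""
    inst = instances.dropna(subset=["max_score_pre_t0"])
    rows = []
    for keys, g in inst.groupby(strata_fields, dropna=False, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        s = g["max_score_pre_t0"].to_numpy(dtype=float)
        y = g["label"].to_numpy(dtype=bool)
        n_case = int(y.sum())
        try:
            a = auroc(s, y)
            p = auprc(s, y) if n_case else np.nan
        except UndefinedMetricError:
            a, p = np.nan, np.nan
        rows.append((*keys, n_case, len(g), a, p))
    return pd.DataFrame(
        rows, columns=[*strata_fields, "n_cases", "n_total", "auroc", "auprc"]
    )


def operating_point_report(point: pd.Series) -> dict:
    """Display-rounded view of one operating point (percent scales, NNE to
    one decimal, half-up)."""
    return {
        "threshold": int(point["threshold"]),
        "precision_pct": round_half_up(100 * point["precision"], 1),
        "recall_pct": round_half_up(100 * point["recall"], 1),
        "fpr_pct": round_half_up(100 * point["fpr"], 1),
        "nne": round_half_up(point["nne"], 1) if np.isfinite(point["nne"]) else None,
        "flagged_pct": round_half_up(100 * point["flagged_fraction"], 1),
    }
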