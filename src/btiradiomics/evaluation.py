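"""Discrimination, clinical-utility and reclassification statistics.

Covers the evaluation layer of the interface analysis: confusion-matrix
rates with exact binomial CIs, ROC AUC with the DeLong variance,
precision-recall AUC, decision-curve net benefit, categorical/continuous
NRI and IDI against a reference model, and BH-FDR-adjusted pairwise
comparison of per-iteration AUC distributions across the nine ROIs.

Reported rates are rounded half-up to 3 decimals with trailing zeros
trimmed (matching clinical-table style); all computations use full
precision internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionMatrix",
    "confusion_metrics",
    "round_half_up",
    "printed",
    "roc_auc",
    "delong_ci",
    "pr_auc",
    "decision_curve",
    "NetBenefitCurve",
    "reclassification",
    "ReclassificationReport",
    "compare_models",
    "bh_adjust",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    TN: int
    FP: int
    FN: int
    TP: int

    def __post_init__(self) -> None:
        if min(self.TN, self.FP, self.FN, self.TP) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.TN + self.FP + self.FN + self.TP

    @classmethod
    def from_predictions(cls, probabilities, labels, threshold: float = 0.20):
        p = np.asarray(probabilities, dtype=float)
        y = np.asarray(labels).astype(int)
        pred = (p >= threshold).astype(int)
        return cls(
            TN=int(((pred == 0) & (y == 0)).sum()),
            FP=int(((pred == 1) & (y == 0)).sum()),
            FN=int(((pred == 0) & (y == 1)).sum()),
            TP=int(((pred == 1) & (y == 1)).sum()),
        )


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal round-half-up (0.0005 -> 0.001), as clinical tables print."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def printed(x: float, decimals: int = 3) -> str:
    """Half-up rounding with trailing zeros trimmed: 0.800 -> '0.8'."""
    s = f"{round_half_up(x, decimals):.{decimals}f}".rstrip("0").rstrip(".")
    return s if s else "0"


def confusion_metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> dict:
    """Sensitivity, specificity, accuracy (with Clopper-Pearson CI), PPV and
    NPV; undefined rates (zero denominators) are reported as NaN with a
    flag list."""
    flags = []

    def rate(num, den, name):
        if den == 0:
            flags.append(name)
            return float("nan")
        return num / den

    n = cm.total
    acc = (cm.TP + cm.TN) / n
    lo, hi = _clopper_pearson(cm.TP + cm.TN, n, alpha)
    out = {
        "sensitivity": rate(cm.TP, cm.TP + cm.FN, "sensitivity"),
        "specificity": rate(cm.TN, cm.TN + cm.FP, "specificity"),
        "accuracy": acc,
        "accuracy_ci": (lo, hi),
        "PPV": rate(cm.TP, cm.TP + cm.FP, "PPV"),
        "NPV": rate(cm.TN, cm.TN + cm.FN, "NPV"),
        "flags": flags,
    }
    out["rounded"] = {
        k: round_half_up(v) for k, v in out.items()
        if isinstance(v, float) and np.isfinite(v)
    }
    out["printed"] = {
        k: printed(v) for k, v in out.items()
        if isinstance(v, float) and np.isfinite(v)
    }
    return out


def _clopper_pearson(k: int, n: int, alpha: float = 0.05):
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# ROC / PR


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(probabilities, labels) -> float:
    """AUC as the tie-corrected Mann-Whitney concordance probability."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    r = _midrank(p)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def delong_ci(probabilities, labels, alpha: float = 0.05):
    """AUC with its DeLong variance and normal-approximation CI.

    Degenerate cases (zero variance, e.g. perfect ranking) are flagged and
    the CI collapses to the point estimate.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n if m > 1 and n > 1 else 0.0
    degenerate = var <= 0
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return {
        "auc": float(auc), "se": float(se), "ci": (float(lo), float(hi)),
        "degenerate": bool(degenerate),
    }


def pr_auc(probabilities, labels) -> float:
    """Precision-recall AUC by interpolation-free step integration over
    recall (the average-precision estimator); the random-classifier
    baseline is the prevalence."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-p, kind="mergesort")
    y = y[order]
    p = p[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    npos = tp[-1]
    if npos == 0:
        raise ValueError("no positive labels")
    # evaluate at distinct thresholds only (ties grouped)
    last = np.r_[p[1:] != p[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / npos
    d_recall = np.diff(np.r_[0.0, recall])
    return float((precision * d_recall).sum())


# ---------------------------------------------------------------------------
# decision curves


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    @property
    def best_threshold(self) -> float:
        return float(self.thresholds[int(np.argmax(self.model))])


def decision_curve(probabilities, labels, thresholds=None) -> NetBenefitCurve:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt) over a threshold
    grid, with treat-all and treat-none references."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = len(y)
    prev = y.mean()
    nb = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = p >= pt
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[i] = tp - fp * pt / (1 - pt)
    treat_all = prev - (1 - prev) * thresholds / (1 - thresholds)
    return NetBenefitCurve(thresholds, nb, treat_all, np.zeros_like(thresholds))


# ---------------------------------------------------------------------------
# reclassification


@dataclass
class ReclassificationReport:
    nri_categorical: float
    nri_continuous: float
    idi: float
    nri_categorical_ci: tuple[float, float]
    nri_continuous_ci: tuple[float, float]
    idi_ci: tuple[float, float]
    reference: str = "reference"


def _nri_idi(p_ref, p_new, y, cuts):
    cats_ref = np.digitize(p_ref, cuts)
    cats_new = np.digitize(p_new, cuts)
    ev, ne = y == 1, y == 0
    up, down = cats_new > cats_ref, cats_new < cats_ref
    nri_cat = (up[ev].mean() - down[ev].mean()) - (up[ne].mean() - down[ne].mean())
    upc, downc = p_new > p_ref, p_new < p_ref
    nri_cont = (upc[ev].mean() - downc[ev].mean()) - (upc[ne].mean() - downc[ne].mean())
    idi = (p_new[ev].mean() - p_new[ne].mean()) - (p_ref[ev].mean() - p_ref[ne].mean())
    return nri_cat, nri_cont, idi


def reclassification(
    p_ref,
    p_new,
    labels,
    cut_points=(0.20,),
    n_boot: int = 2000,
    seed: int = 0,
    reference: str = "reference",
) -> ReclassificationReport:
    """Categorical / continuous net reclassification improvement and IDI of
    ``p_new`` over ``p_ref``.

    Categories are defined by ``cut_points`` (default the 0.20 decision
    threshold).  The continuous NRI is the sum of the event and non-event
    components (each in [-1, 1], so the total lies in [-2, 2]).  IDI is the
    difference in discrimination slopes.  CIs are percentile bootstrap with
    ``n_boot`` seeded replicates.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(labels).astype(int)
    cuts = np.asarray(cut_points, dtype=float)
    nri_cat, nri_cont, idi = _nri_idi(p_ref, p_new, y, cuts)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))
    idx = np.arange(len(y))
    for b in range(n_boot):
        take = rng.choice(idx, size=len(idx), replace=True)
        yb = y[take]
        if yb.min() == yb.max():
            boots[b] = np.nan
            continue
        boots[b] = _nri_idi(p_ref[take], p_new[take], yb, cuts)
    ci = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return ReclassificationReport(
        nri_categorical=float(nri_cat),
        nri_continuous=float(nri_cont),
        idi=float(idi),
        nri_categorical_ci=(float(ci[0, 0]), float(ci[1, 0])),
        nri_continuous_ci=(float(ci[0, 1]), float(ci[1, 1])),
        idi_ci=(float(ci[0, 2]), float(ci[1, 2])),
        reference=reference,
    )


# ---------------------------------------------------------------------------
# multi-model comparison


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def compare_models(auc_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank tests between the
    per-iteration AUC distributions (columns = models/ROIs), BH-adjusted
    across all pairs.

    Returns a long DataFrame with raw and adjusted p-values; identical
    distributions give p = 1.
    """
    cols = list(auc_table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x = auc_table[a].to_numpy(dtype=float)
            z = auc_table[b].to_numpy(dtype=float)
            if np.allclose(x, z):
                p = 1.0
            else:
                p = float(stats.wilcoxon(x, z, zero_method="wilcox").pvalue)
            rows.append({"model_a": a, "model_b": b, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out
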