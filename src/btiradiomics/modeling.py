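"""Classifier fitting and resampling over the nine interface ROIs.

The study design is a temporal 80/20 split of the internal cohort plus a
repeated resampling scheme: per iteration, a stratified subsample without
replacement is drawn and a stratified five-fold cross-validation is run,
recording the pooled-fold AUC.  Classifiers are backward-stepwise logistic
regression (AIC) on PCA component scores — optionally with peritumoral
edema volume as a clinical covariate — and a random forest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SplitPlan",
    "temporal_split",
    "repeated_cv",
    "fit_stepwise_lr",
    "fit_rf",
    "StepwiseLrModel",
]


@dataclass
class SplitPlan:
    """Resampling design: temporal split fraction, CV folds, outer
    iterations and the per-iteration subsample fraction."""

    train_fraction: float = 0.8
    cv_folds: int = 5
    n_iterations: int = 100
    subsample_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_fraction", "subsample_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def temporal_split(
    dates: pd.Series, train_fraction: float = 0.8
) -> tuple[pd.Index, pd.Index]:
    """Earliest ``train_fraction`` of subjects by acquisition date form the
    training set; ties are broken by index (subject id) so the split is a
    pure function of its inputs."""
    order = dates.reset_index()
    order.columns = ["subject", "date"]
    order = order.sort_values(["date", "subject"], kind="mergesort")
    n_train = int(round(train_fraction * len(order)))
    train = pd.Index(order["subject"].iloc[:n_train])
    valid = pd.Index(order["subject"].iloc[n_train:])
    return train, valid


def _make_model(kind: str, seed: int):
    if kind in ("lr", "logistic"):
        return LogisticRegression(max_iter=1000, random_state=seed)
    if kind in ("rf", "random-forest"):
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
        )
    raise ValueError(f"unknown model kind {kind!r}")


def repeated_cv(
    features: pd.DataFrame,
    labels: np.ndarray,
    plan: SplitPlan,
    model_kind: str = "lr",
) -> np.ndarray:
    """Per-iteration pooled-fold cross-validated AUCs.

    Each iteration draws a stratified subsample without replacement
    (``subsample_fraction``), runs stratified ``cv_folds``-fold CV with
    min-max scaling re-fitted inside every training fold (no leakage), and
    records the AUC of the pooled out-of-fold predictions.  Returns the
    ``n_iterations`` AUC values; fully determined by ``plan.seed``.
    """
    y = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=np.float64)
    rng = np.random.default_rng(plan.seed)
    aucs = np.empty(plan.n_iterations)
    for it in range(plan.n_iterations):
        sub = _stratified_subsample(y, plan.subsample_fraction, rng)
        Xs, ys = X[sub], y[sub]
        fold_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(plan.cv_folds, shuffle=True, random_state=fold_seed)
        pooled = np.empty(len(ys))
        for tr, te in skf.split(Xs, ys):
            if len(np.unique(ys[tr])) < 2:  # re-stratify defensively
                warnings.warn("fold missing a class; reshuffling", stacklevel=2)
                skf = StratifiedKFold(plan.cv_folds, shuffle=True,
                                      random_state=fold_seed + 1)
                return repeated_cv(features, labels, plan, model_kind)
            # min-max scaling re-fitted on the training fold (same contract
            # as minmax_scale/apply_minmax, in-place for speed; constant
            # columns carry no information and scale to 0)
            lo = Xs[tr].min(axis=0)
            rngv = Xs[tr].max(axis=0) - lo
            rngv[rngv == 0] = 1.0
            model = _make_model(model_kind, fold_seed)
            model.fit((Xs[tr] - lo) / rngv, ys[tr])
            pooled[te] = model.predict_proba((Xs[te] - lo) / rngv)[:, 1]
        aucs[it] = roc_auc_score(ys, pooled)
    return aucs


def _stratified_subsample(y: np.ndarray, fraction: float, rng) -> np.ndarray:
    keep = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        n = max(int(round(fraction * len(idx))), 2)
        keep.append(rng.choice(idx, size=min(n, len(idx)), replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class StepwiseLrModel:
    """Backward-stepwise logistic model (AIC) with serializable state."""

    predictors: list[str]
    coefficients: dict[str, float]  # includes "const"
    aic: float
    odds_ratios: dict[str, float]
    penalized_fallback: bool = False
    eliminated: list[str] = field(default_factory=list)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.coefficients["const"])
        for name in self.predictors:
            eta = eta + self.coefficients[name] * table[name].to_numpy(dtype=np.float64)
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "logistic-backward-stepwise",
                "predictors": self.predictors,
                "coefficients": self.coefficients,
                "aic": self.aic,
                "odds_ratios": self.odds_ratios,
                "penalized_fallback": self.penalized_fallback,
                "eliminated": self.eliminated,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "StepwiseLrModel":
        d = json.loads(text)
        d.pop("kind", None)
        return cls(**d)


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        res = model.fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        raise np.linalg.LinAlgError("separation suspected")
    return res


def fit_stepwise_lr(
    predictors: pd.DataFrame, labels: np.ndarray
) -> StepwiseLrModel:
    """Backward elimination by AIC from the full logistic model.

    At each step the predictor whose removal most lowers the AIC is
    dropped; elimination stops when no removal improves AIC.  Complete
    separation triggers an L2-penalized fallback, flagged on the result.
    """
    y = np.asarray(labels).astype(int)
    cols = list(predictors.columns)
    eliminated: list[str] = []
    try:
        res = _fit_logit(predictors[cols], y)
        aic = res.aic
        while len(cols) > 1:
            best = None
            for c in cols:
                trial = [x for x in cols if x != c]
                r = _fit_logit(predictors[trial], y)
                if r.aic < aic and (best is None or r.aic < best[1]):
                    best = (c, r.aic, r)
            if best is None:
                break
            cols = [x for x in cols if x != best[0]]
            eliminated.append(best[0])
            aic, res = best[1], best[2]
        params = res.params
        coefs = {("const" if k == "const" else k): float(v) for k, v in params.items()}
        return StepwiseLrModel(
            predictors=cols,
            coefficients=coefs,
            aic=float(res.aic),
            odds_ratios={k: float(np.exp(v)) for k, v in coefs.items() if k != "const"},
            eliminated=eliminated,
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(predictors.to_numpy(dtype=np.float64), y)
        coefs = {"const": float(clf.intercept_[0])}
        coefs.update({c: float(b) for c, b in zip(predictors.columns, clf.coef_.ravel())})
        return StepwiseLrModel(
            predictors=list(predictors.columns),
            coefficients=coefs,
            aic=float("nan"),
            odds_ratios={k: float(np.exp(v)) for k, v in coefs.items() if k != "const"},
            penalized_fallback=True,
        )


@dataclass
class RfModel:
    model: RandomForestClassifier
    feature_names: list[str]
    oob_auc: float | None

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(
            table[self.feature_names].to_numpy(dtype=np.float64)
        )[:, 1]


def fit_rf(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 500,
) -> RfModel:
    """Random forest (500 trees, sqrt(p) candidate predictors per split)
    with an out-of-bag AUC estimate."""
    y = np.asarray(labels).astype(int)
    rf = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(features.to_numpy(dtype=np.float64), y)
    oob = None
    if hasattr(rf, "oob_decision_function_"):
        probs = rf.oob_decision_function_[:, 1]
        ok = np.isfinite(probs)
        if ok.sum() > 1 and len(np.unique(y[ok])) == 2:
            oob = float(roc_auc_score(y[ok], probs[ok]))
    return RfModel(rf, list(features.columns), oob)
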