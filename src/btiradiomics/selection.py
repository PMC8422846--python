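"""Feature-reduction chain: ICC reproducibility filter, Spearman
redundancy filter, cross-validated LASSO screening with an
events-per-variable cap, and varimax-rotated PCA.

Every stage is fitted on training data only and stores its state, so it
can be re-applied (never re-estimated) to held-out cohorts.  Stages only
remove or linearly transform features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionConfig",
    "icc_2_1",
    "icc_filter",
    "spearman_filter",
    "lasso_screen",
    "varimax",
    "pca_varimax",
    "PcaModel",
]


@dataclass
class SelectionConfig:
    """Thresholds and knobs of the selection chain.

    ``epv_target`` caps the screened feature count at
    ``floor(events / epv_target)``; ``k_features`` overrides the cap
    (presets 9 and 3 replicate the two modeled cohorts).
    """

    icc_min: float = 0.8
    spearman_max: float = 0.9
    lasso_folds: int = 10
    epv_target: float = 10.0
    k_features: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("icc_min", "spearman_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.lasso_folds < 2:
            raise ValueError("lasso_folds must be >= 2")


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n_subjects, n_raters).  Computed from the classical
    ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN when the denominator vanishes (e.g. zero variance
    everywhere).
    """
    y = np.asarray(ratings, dtype=np.float64)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    grand = y.mean()
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    ss_r = k * ((row_m - grand) ** 2).sum()
    ss_c = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_e = ss_tot - ss_r - ss_c
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = ss_e / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if not np.isfinite(denom) or abs(denom) < 1e-300:
        return float("nan")
    return float((msr - mse) / denom)


def icc_filter(
    rater1: pd.DataFrame, rater2: pd.DataFrame, icc_min: float = 0.8
) -> tuple[list[str], pd.Series]:
    """Keep features whose ICC(2,1) across the two segmentations is at
    least ``icc_min``; undefined ICCs drop the feature.

    Returns ``(surviving feature names, per-feature ICC)``.
    """
    if list(rater1.columns) != list(rater2.columns) or len(rater1) != len(rater2):
        raise ValueError("the two rater tables must share subjects and features")
    iccs = {}
    for col in rater1.columns:
        iccs[col] = icc_2_1(np.column_stack([rater1[col].to_numpy(),
                                             rater2[col].to_numpy()]))
    iccs = pd.Series(iccs, name="ICC")
    keep = [c for c in rater1.columns if np.isfinite(iccs[c]) and iccs[c] >= icc_min]
    return keep, iccs


def spearman_filter(
    table: pd.DataFrame, labels: np.ndarray | None = None, spearman_max: float = 0.9
) -> list[str]:
    """Greedy redundancy filter.

    Features are ranked by the absolute Spearman correlation of the feature
    with the class label (ties broken lexicographically; rank order is the
    column order when labels are absent).  Scanning in priority order, a
    feature is dropped if its |Spearman rho| with any already-kept feature
    exceeds ``spearman_max``.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    if labels is not None:
        labels = np.asarray(labels)
        prio = {
            c: abs(stats.spearmanr(table[c].to_numpy(), labels).statistic)
            for c in cols
        }
        order = sorted(cols, key=lambda c: (-(0.0 if np.isnan(prio[c]) else prio[c]), c))
    else:
        order = cols
    rho = stats.spearmanr(table[order].to_numpy()).statistic
    if np.ndim(rho) == 0:  # two features
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.abs(np.nan_to_num(rho))
    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(rho[i, j] <= spearman_max for j in kept_idx):
            kept_idx.append(i)
    kept = {order[i] for i in kept_idx}
    return [c for c in cols if c in kept]


@dataclass
class LassoScreenResult:
    ranked: list[str]
    selected: list[str]
    coefficients: pd.Series
    C: float
    fallback: bool = False


def lasso_screen(
    table: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig | None = None,
    objective: str = "logistic",
    alpha: float | None = None,
) -> LassoScreenResult:
    """L1-penalized screening.

    With the default logistic objective the penalty is chosen by
    ``lasso_folds``-fold cross-validated deviance (lambda at the minimum);
    features with nonzero coefficients are ranked by |coefficient| and the
    top ``k = min(k_features, floor(events / epv_target))`` are selected.
    If the chosen penalty zeroes every coefficient, the weakest penalty on
    the path with a nonzero coefficient is used instead and the result is
    flagged.  ``objective='linear'`` uses the squared-error lasso (on
    orthonormal designs its solution is exactly the soft-thresholded
    least-squares estimate); ``alpha`` then fixes the penalty instead of CV.
    """
    config = config or SelectionConfig()
    X = table.to_numpy(dtype=np.float64)
    if objective == "linear":
        from sklearn.linear_model import Lasso, LassoCV

        if alpha is not None:
            lin = Lasso(alpha=alpha, fit_intercept=False, max_iter=50000, tol=1e-10)
        else:
            lin = LassoCV(cv=config.lasso_folds, random_state=config.seed,
                          max_iter=50000)
        lin.fit(X, np.asarray(labels, dtype=np.float64))
        s = pd.Series(lin.coef_, index=table.columns, name="coef")
        active = s[s != 0.0]
        ranked = sorted(active.index, key=lambda c: (-abs(active[c]), c))
        return LassoScreenResult(ranked, ranked, s, float(getattr(lin, "alpha_", alpha)))
    if objective != "logistic":
        raise ValueError(f"unknown objective {objective!r}")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cv = StratifiedKFold(config.lasso_folds, shuffle=True, random_state=config.seed)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-3, 2, 40), cv=cv, penalty="l1", solver="liblinear",
        scoring="neg_log_loss", max_iter=2000, random_state=config.seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    coef = clf.coef_.ravel()
    fallback = False
    C = float(clf.C_[0])
    if not np.any(coef != 0):
        fallback = True
        for C_try in np.logspace(-3, 3, 60):
            m = LogisticRegression(penalty="l1", C=C_try, solver="liblinear",
                                   max_iter=2000, random_state=config.seed)
            m.fit(X, y)
            if np.any(m.coef_ != 0):
                coef, C = m.coef_.ravel(), float(C_try)
                break
    s = pd.Series(coef, index=table.columns, name="coef")
    active = s[s != 0.0]
    ranked = sorted(active.index, key=lambda c: (-abs(active[c]), c))
    events = int(min((y == 1).sum(), (y == 0).sum()))
    k = int(events // config.epv_target)
    if config.k_features is not None:
        k = min(config.k_features, k)
    k = max(k, 1)
    return LassoScreenResult(ranked, ranked[:k], s, C, fallback)


def varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 1000,
            kaiser_normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix).

    Raises on non-convergence.  The rotation is orthogonal, so row
    communalities are preserved.
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    A = np.asarray(loadings, dtype=np.float64)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    h = np.sqrt((A**2).sum(axis=1)) if kaiser_normalize else np.ones(p)
    h[h == 0] = 1.0
    B = A / h[:, None]
    L, R = rotate_factors(B, "varimax", tol=tol, max_tries=max_iter)
    if not np.allclose(R.T @ R, np.eye(k), atol=1e-8):
        raise RuntimeError(
            f"varimax rotation failed to converge within {max_iter} iterations"
        )
    return L * h[:, None], R


@dataclass
class PcaModel:
    """Varimax-rotated PCA of standardized features.

    ``loadings`` / ``rotated_loadings`` are (p, k) with columns PC1..PCk;
    ``scores`` are unit-variance component scores for the fitting set.
    ``transform`` projects new subjects with the stored standardization and
    rotation (nothing is re-fitted).
    """

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    rotated_loadings: np.ndarray
    rotation: np.ndarray
    components: np.ndarray  # (p, k) orthonormal PC directions
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame = field(repr=False)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def component_names(self) -> list[str]:
        return list(self.scores.columns)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        X = table[self.feature_names].to_numpy(dtype=np.float64)
        Z = (X - self.mean) / self.std
        U = Z @ self.components / np.sqrt(self.eigenvalues)
        return pd.DataFrame(U @ self.rotation, index=table.index,
                            columns=self.component_names)


def pca_varimax(
    table: pd.DataFrame,
    n_components: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PcaModel:
    """PCA on the feature correlation matrix with varimax rotation.

    Components are retained by the Kaiser rule (eigenvalue >= 1) unless
    ``n_components`` overrides it.  Loadings are eigenvector *
    sqrt(eigenvalue); after rotation each component's sign is fixed so its
    largest-|loading| entry is positive.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need at least 2 features and 3 subjects")
    X = table.to_numpy(dtype=np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    n = len(Z)
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    eig = svals**2 / (n - 1)
    if n_components is None:
        k = max(int((eig >= 1.0).sum()), 1)
    else:
        k = min(n_components, len(eig))
    V = vt.T[:, :k]
    lam = eig[:k]
    A = V * np.sqrt(lam)
    A_rot, R = varimax(A, tol=tol, max_iter=max_iter)
    sign = np.sign(A_rot[np.abs(A_rot).argmax(axis=0), np.arange(k)])
    sign[sign == 0] = 1.0
    A_rot = A_rot * sign
    R = R * sign
    U = Z @ V / np.sqrt(lam)
    names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U @ R, index=table.index, columns=names)
    return PcaModel(
        feature_names=list(table.columns),
        mean=mean,
        std=std,
        eigenvalues=lam,
        loadings=A,
        rotated_loadings=A_rot,
        rotation=R,
        components=V,
        explained_variance_ratio=eig[:k] / eig.sum(),
        scores=scores,
    )
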