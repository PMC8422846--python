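"""End-to-end orchestration of the interface-radiomics experiment.

``roi_auc_experiment`` runs the structural comparison at the heart of the
analysis on a phantom cohort: extract features from each of the nine ROIs,
run the repeated stratified-subsample five-fold CV, and return the AUC
distribution per ROI.  ``run_pipeline`` adds the temporal-split modeling
chain (scaling -> LASSO screen -> varimax PCA -> stepwise LR, plus the
clinical and combined models) and the evaluation layer, emitting a
machine-readable report.

For cohort-scale runs the extractor uses a reduced single-image feature
configuration (first-order + GLCM + GLDM on the original image, native
grid) and the fast ``edt`` distance backend; both are configuration, not
separate code paths.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    ConfusionMatrix,
    compare_models,
    confusion_metrics,
    decision_curve,
    delong_ci,
    pr_auc,
    reclassification,
)
from .feature_extraction import PreprocessSpec, apply_minmax, extract_all, minmax_scale
from .grids import MaskVolume, VoxelGrid
from .modeling import SplitPlan, fit_stepwise_lr, repeated_cv, temporal_split
from .roi_geometry import ALL_ROI_SPECS, build_region_set, volume_metrics
from .selection import SelectionConfig, lasso_screen, pca_varimax, spearman_filter
from .synthetic_cohort import PhantomConfig, Subject, generate_cohort

__all__ = [
    "StudyConfig",
    "fast_preprocess_spec",
    "extract_cohort_features",
    "roi_auc_experiment",
    "run_pipeline",
]

_ROI_NAMES = [s.name for s in ALL_ROI_SPECS]


def fast_preprocess_spec() -> PreprocessSpec:
    """Reduced extraction configuration for cohort-scale phantom runs:
    original image only, native grid, first-order + GLCM + GLDM."""
    return PreprocessSpec(
        resample_spacing_mm=None,
        wavelet=None,
        log_sigmas_mm=(),
        texture_classes=("glcm", "gldm"),
    )


@dataclass
class StudyConfig:
    """Serializable configuration of a full pipeline run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    rois: list[str] = field(default_factory=lambda: list(_ROI_NAMES))
    threshold: float = 0.20
    distance_method: str = "edt"
    full_filter_bank: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.rois) - set(_ROI_NAMES)
        if unknown:
            raise ValueError(f"unknown ROI name(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("phantom", "split", "selection"):
            d[key] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d[key].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        known = {"phantom", "split", "selection", "rois", "threshold",
                 "distance_method", "full_filter_bank", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, typ in (("phantom", PhantomConfig), ("split", SplitPlan),
                         ("selection", SelectionConfig)):
            if key in d and isinstance(d[key], dict):
                sub = {
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in d[key].items()
                }
                if key == "phantom" and "edema_volume_params" in sub:
                    sub["edema_volume_params"] = {
                        k: tuple(v) for k, v in dict(sub["edema_volume_params"]).items()
                    }
                d[key] = typ(**sub)
        return cls(**d)


def extract_cohort_features(
    subjects: list[Subject],
    spec: PreprocessSpec | None = None,
    rois: list[str] | None = None,
    distance_method: str = "edt",
    include_shape: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-ROI feature tables (subjects x features) for a cohort."""
    spec = spec or fast_preprocess_spec()
    rois = rois or _ROI_NAMES
    specs = tuple(s for s in ALL_ROI_SPECS if s.name in rois)
    tables: dict[str, list[dict]] = {r: [] for r in rois}
    index = []
    from .feature_extraction import preprocess

    for subj in subjects:
        index.append(subj.record.subject_id)
        img, _ = preprocess(subj.image, subj.tumor, spec, brain=subj.brain)
        regions = build_region_set(
            subj.tumor, brain=subj.brain, skull=subj.skull, specs=specs,
            method=distance_method, subject=subj.record.subject_id,
        )
        for name, roi in regions.items():
            if img.shape != roi.grid.shape:
                raise ValueError("cohort extraction requires native-grid spec")
            fv = extract_all(
                img, MaskVolume(roi.data, img), spec,
                include_shape=include_shape, preprocessed=True,
            )
            tables[name].append(fv)
    return {
        r: pd.DataFrame(rows, index=index) for r, rows in tables.items()
    }


def roi_auc_experiment(
    config: PhantomConfig,
    plan: SplitPlan | None = None,
    rois: list[str] | None = None,
    model_kind: str = "lr",
    spec: PreprocessSpec | None = None,
) -> pd.DataFrame:
    """Repeated-CV AUC distributions per ROI on one phantom cohort.

    Returns a DataFrame (iterations x ROIs).  The CV seed derives from the
    phantom seed so one integer reproduces the whole experiment.
    """
    plan = plan or SplitPlan(n_iterations=10, seed=config.seed + 1)
    subjects = generate_cohort(config)
    labels = np.array([s.record.invasion for s in subjects])
    tables = extract_cohort_features(subjects, spec=spec, rois=rois)
    out = {}
    for name, table in tables.items():
        out[name] = repeated_cv(table, labels, plan, model_kind=model_kind)
    return pd.DataFrame(out)


def _radiomics_chain(train_feats, valid_feats, train_labels, sel_cfg):
    """Scale -> Spearman filter -> LASSO screen -> varimax PCA -> stepwise LR,
    fitted on the training split only."""
    scaled_tr, params = minmax_scale(train_feats)
    scaled_va = apply_minmax(valid_feats, params)
    kept = spearman_filter(scaled_tr, train_labels, sel_cfg.spearman_max)
    scaled_tr, scaled_va = scaled_tr[kept], scaled_va[kept]
    screen = lasso_screen(scaled_tr, train_labels, sel_cfg)
    sel = screen.selected
    if len(sel) < 2:
        sel = screen.ranked[:2] if len(screen.ranked) >= 2 else kept[:2]
    pca = pca_varimax(scaled_tr[sel])
    model = fit_stepwise_lr(pca.scores, train_labels)
    scores_va = pca.transform(scaled_va[sel])
    return {
        "selected_features": sel,
        "pca": pca,
        "model": model,
        "train_scores": pca.scores,
        "valid_scores": scores_va,
        "screen": screen,
    }


def _metric_block(probs, labels, threshold):
    cm = ConfusionMatrix.from_predictions(probs, labels, threshold)
    mets = confusion_metrics(cm)
    roc = delong_ci(probs, labels)
    return {
        "confusion": {"TN": cm.TN, "FP": cm.FP, "FN": cm.FN, "TP": cm.TP},
        "auc": roc["auc"],
        "auc_ci": list(roc["ci"]),
        "pr_auc": pr_auc(probs, labels),
        "metrics": {
            k: mets[k] for k in ("sensitivity", "specificity", "accuracy", "PPV", "NPV")
        },
        "accuracy_ci": list(mets["accuracy_ci"]),
    }


def run_pipeline(config: StudyConfig, outdir: str | None = None) -> dict:
    """Run the full phantom study and return (optionally write) the report.

    Stages: cohort generation, per-ROI AUC distributions under repeated CV,
    temporal-split modeling for every ROI (radiomics chain), clinical-only
    (PEV) and combined (PEV + interface radiomics) models, decision curves
    and reclassification against the combined reference, and BH-adjusted
    pairwise ROI comparisons.
    """
    subjects = generate_cohort(config.phantom)
    labels = pd.Series(
        [s.record.invasion for s in subjects],
        index=[s.record.subject_id for s in subjects],
    )
    spec = None if not config.full_filter_bank else PreprocessSpec(
        resample_spacing_mm=None
    )
    tables = extract_cohort_features(
        subjects, spec=spec, rois=config.rois, distance_method=config.distance_method
    )
    pev = pd.Series(
        [volume_metrics(s.tumor, s.edema_outlined).PEV_ml for s in subjects],
        index=labels.index, name="PEV_ml",
    )
    dates = pd.Series(
        [s.record.acquisition_date for s in subjects], index=labels.index
    )
    train_idx, valid_idx = temporal_split(dates, config.split.train_fraction)
    y_tr = labels.loc[train_idx].to_numpy()
    y_va = labels.loc[valid_idx].to_numpy()

    # per-ROI AUC distributions (repeated CV on the full cohort)
    auc_dists = pd.DataFrame(
        {
            name: repeated_cv(table, labels.to_numpy(), config.split)
            for name, table in tables.items()
        }
    )
    comparisons = compare_models(auc_dists)

    report: dict = {
        "config": config.to_dict(),
        "n_subjects": len(subjects),
        "prevalence": float(labels.mean()),
        "split": {"train": len(train_idx), "validation": len(valid_idx)},
        "auc_distributions_mean": auc_dists.mean().to_dict(),
        "roi_ranking": list(auc_dists.mean().sort_values(ascending=False).index),
        "comparisons": comparisons.to_dict(orient="records"),
        "models": {},
    }

    best_roi = report["roi_ranking"][0]
    chains = {}
    for name, table in tables.items():
        try:
            chain = _radiomics_chain(
                table.loc[train_idx], table.loc[valid_idx], y_tr, config.selection
            )
        except Exception as exc:  # pragma: no cover - defensive per-ROI guard
            report["models"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            continue
        chains[name] = chain
        p_tr = chain["model"].predict_proba(chain["train_scores"])
        p_va = chain["model"].predict_proba(chain["valid_scores"])
        report["models"][name] = {
            "selected_features": chain["selected_features"],
            "n_components": chain["pca"].n_components,
            "predictors": chain["model"].predictors,
            "train": _metric_block(p_tr, y_tr, config.threshold),
            "validation": _metric_block(p_va, y_va, config.threshold),
        }

    # clinical-only (PEV) and combined (PEV + best-ROI components)
    pev_tr = pd.DataFrame({"PEV_ml": pev.loc[train_idx]})
    pev_va = pd.DataFrame({"PEV_ml": pev.loc[valid_idx]})
    clin = fit_stepwise_lr(pev_tr, y_tr)
    p_clin_tr, p_clin_va = clin.predict_proba(pev_tr), clin.predict_proba(pev_va)
    report["models"]["clinical"] = {
        "predictors": clin.predictors,
        "train": _metric_block(p_clin_tr, y_tr, config.threshold),
        "validation": _metric_block(p_clin_va, y_va, config.threshold),
    }
    if best_roi in chains:
        chain = chains[best_roi]
        comb_tr = chain["train_scores"].copy()
        comb_tr["PEV_ml"] = pev.loc[train_idx].to_numpy()
        comb_va = chain["valid_scores"].copy()
        comb_va["PEV_ml"] = pev.loc[valid_idx].to_numpy()
        comb = fit_stepwise_lr(comb_tr, y_tr)
        p_comb_tr, p_comb_va = comb.predict_proba(comb_tr), comb.predict_proba(comb_va)
        p_rad_va = chain["model"].predict_proba(chain["valid_scores"])
        dca = decision_curve(p_comb_va, y_va)
        recl = reclassification(
            p_comb_va, p_rad_va, y_va, cut_points=(config.threshold,),
            seed=config.seed, reference="combined",
        )
        report["models"]["combined"] = {
            "roi": best_roi,
            "predictors": comb.predictors,
            "train": _metric_block(p_comb_tr, y_tr, config.threshold),
            "validation": _metric_block(p_comb_va, y_va, config.threshold),
            "dca_best_threshold": dca.best_threshold,
            "reclassification_radiomics_vs_combined": {
                "nri_categorical": recl.nri_categorical,
                "nri_continuous": recl.nri_continuous,
                "idi": recl.idi,
            },
        }

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        auc_long = auc_dists.reset_index(names="iteration").melt(
            id_vars="iteration", var_name="roi", value_name="auc"
        )
        auc_long.to_csv(os.path.join(outdir, "auc_distributions.csv"), index=False)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        lines = [
            f"subjects: {len(subjects)} (prevalence {labels.mean():.3f})",
            f"ROI ranking by mean CV AUC: {', '.join(report['roi_ranking'])}",
        ]
        for name in report["roi_ranking"]:
            m = report["models"].get(name, {})
            if "validation" in m:
                lines.append(
                    f"  {name}: validation AUC {m['validation']['auc']:.3f}"
                )
        with open(os.path.join(outdir, "summary.txt"), "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return report
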