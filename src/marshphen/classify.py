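"""Feature-plan assembly and random-forest classification.

Five experimental feature plans combine the six phenological metrics
with the 24 monthly SAR polarization features:

1. phenology only (SOS, EOS, MV, BV, ROI, ROD);
2. SAR only (12 monthly VV-VH differences + 12 monthly VH/VV ratios);
3. phenology + monthly ratios;
4. phenology + monthly differences;
5. phenology + all 24 SAR features.

Classification uses a 500-tree random forest with a stratified 5-fold
cross-validated grid search over the per-split feature-subsampling rule
(square root vs. logarithmic), mirroring common practice for land-cover
mapping.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict

from .errors import ConfigError, DegenerateLabelsError, SchemaError
from .phenology import PHENO_FEATURE_NAMES
from .sar import SAR_DIFF_NAMES, SAR_RATIO_NAMES

PLAN_FEATURES: dict[int, tuple[str, ...]] = {
    1: PHENO_FEATURE_NAMES,
    2: SAR_DIFF_NAMES + SAR_RATIO_NAMES,
    3: PHENO_FEATURE_NAMES + SAR_RATIO_NAMES,
    4: PHENO_FEATURE_NAMES + SAR_DIFF_NAMES,
    5: PHENO_FEATURE_NAMES + SAR_DIFF_NAMES + SAR_RATIO_NAMES,
}

#: Stack band order assumed for the combined 30-feature raster.
ALL_FEATURE_NAMES = PLAN_FEATURES[5]


def plan_feature_names(plan_id: int) -> tuple[str, ...]:
    """Ordered feature columns of one experimental plan."""
    try:
        return PLAN_FEATURES[int(plan_id)]
    except (KeyError, ValueError):
        raise ConfigError(f"plan_id must be 1-5, got {plan_id!r}") from None


def stack_for_plan(plan_id: int, pheno_stack: np.ndarray, sar_stack: np.ndarray) -> np.ndarray:
    """Select the plan's bands from the 6-band phenology and 24-band SAR stacks."""
    names = plan_feature_names(plan_id)
    if pheno_stack.shape[0] != 6 or sar_stack.shape[0] != 24:
        raise SchemaError("expected a 6-band phenology stack and a 24-band SAR stack")
    if pheno_stack.shape[1:] != sar_stack.shape[1:]:
        raise SchemaError("phenology and SAR stacks must share one grid")
    full = np.concatenate([pheno_stack, sar_stack], axis=0)
    index = {name: i for i, name in enumerate(ALL_FEATURE_NAMES)}
    return full[[index[n] for n in names]]


def assemble_features(
    plan_id: int,
    pheno_stack: np.ndarray,
    sar_stack: np.ndarray,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Build the labeled feature table for one plan.

    ``samples`` needs columns (row, col, class_code).  Rows landing on
    pixels with any undefined feature (tidally excluded or unfit) are
    dropped; the count of dropped rows is recorded in
    ``table.attrs["n_dropped"]``.
    """
    names = plan_feature_names(plan_id)
    stack = stack_for_plan(plan_id, pheno_stack, sar_stack)
    rows_, cols_ = stack.shape[1:]
    r = samples["row"].to_numpy()
    c = samples["col"].to_numpy()
    if np.any((r < 0) | (r >= rows_) | (c < 0) | (c >= cols_)):
        raise SchemaError("sample point outside the raster grid")

    values = stack[:, r, c].T  # (n_samples, n_features)
    table = pd.DataFrame(values, columns=list(names))
    table.insert(0, "class_code", samples["class_code"].to_numpy())
    table.insert(0, "pixel_id", r * cols_ + c)
    keep = ~table[list(names)].isna().any(axis=1)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs["plan_id"] = int(plan_id)
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


@dataclass(frozen=True)
class CVReport:
    """Cross-validation summary for one feature plan."""

    plan_id: int
    fold_accuracies: tuple
    cv_mean: float
    cv_sd: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    best_params: dict
    n_samples: int
    n_features: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "fold_accuracies": [round(float(a), 10) for a in self.fold_accuracies],
            "cv_mean": round(float(self.cv_mean), 10),
            "cv_sd": round(float(self.cv_sd), 10),
            "precision_macro": round(float(self.precision_macro), 10),
            "recall_macro": round(float(self.recall_macro), 10),
            "f1_macro": round(float(self.f1_macro), 10),
            "best_params": self.best_params,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "seed": self.seed,
        }


def train_and_cv(
    table: pd.DataFrame,
    seed: int,
    n_estimators: int = 500,
    n_folds: int = 5,
    max_depth: int | None = None,
) -> tuple[CVReport, RandomForestClassifier]:
    """Grid-searched, cross-validated random forest on a feature table.

    Stratified ``n_folds``-fold CV with a grid over the feature
    subsampling rule {sqrt, log2}; the report carries per-fold and
    mean ± sd accuracy plus macro precision/recall/F1 from
    cross-validated predictions, and the returned model is refit on the
    full table with the best parameters.  Deterministic given ``seed``.
    """
    feature_cols = [c for c in table.columns if c not in ("pixel_id", "class_code")]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["class_code"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateLabelsError("training requires at least 2 classes")
    if counts.min() < n_folds:
        raise DegenerateLabelsError(
            f"smallest class has {counts.min()} samples; need >= {n_folds} for {n_folds}-fold CV"
        )

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=int(seed)
    )
    search = GridSearchCV(
        forest,
        param_grid={"max_features": ["sqrt", "log2"]},
        cv=cv,
        scoring="accuracy",
        refit=True,
    )
    search.fit(X, y)
    best = search.best_index_
    folds = tuple(
        float(search.cv_results_[f"split{k}_test_score"][best]) for k in range(n_folds)
    )
    y_cv = cross_val_predict(search.best_estimator_, X, y, cv=cv)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, y_cv, average="macro", zero_division=0
    )
    report = CVReport(
        plan_id=int(table.attrs.get("plan_id", 0)),
        fold_accuracies=folds,
        cv_mean=float(np.mean(folds)),
        cv_sd=float(np.std(folds, ddof=1)),
        precision_macro=float(prec),
        recall_macro=float(rec),
        f1_macro=float(f1),
        best_params=dict(search.best_params_),
        n_samples=int(X.shape[0]),
        n_features=int(X.shape[1]),
        seed=int(seed),
    )
    return report, search.best_estimator_


def predict_map(
    model: RandomForestClassifier,
    plan_id: int,
    pheno_stack: np.ndarray,
    sar_stack: np.ndarray,
    nodata_code: int = 0,
) -> np.ndarray:
    """Classify every pixel with defined features; others get ``nodata_code``."""
    stack = stack_for_plan(plan_id, pheno_stack, sar_stack)
    n_feat = stack.shape[0]
    if getattr(model, "n_features_in_", n_feat) != n_feat:
        raise SchemaError(
            f"model expects {model.n_features_in_} features, stack has {n_feat}"
        )
    rows_, cols_ = stack.shape[1:]
    flat = stack.reshape(n_feat, -1).T
    ok = ~np.isnan(flat).any(axis=1)
    out = np.full(rows_ * cols_, nodata_code, dtype=np.uint8)
    if ok.any():
        out[ok] = model.predict(flat[ok])
    return out.reshape(rows_, cols_)
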