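"""Condition discrimination from nucleus feature vectors.

Evaluation follows the grouped cross-validation design appropriate for
microscopy, where nuclei from one image share acquisition batch effects:
Leave-2-Opposite-Groups-Out (L2OGO) holds out one whole image per class as
the test fold (one fold per opposite-class image pair), trains on all
remaining images with random uniform class balancing, and scores both single
cells and small cell sets (3–31 cells, majority vote) with a 1,000-repetition
bootstrap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .features import FEATURE_COLUMNS

log = logging.getLogger(__name__)

DEFAULT_SET_SIZES = tuple(range(3, 32, 2))  # odd sizes 3..31
DEFAULT_N_BOOTSTRAP = 1000

#: classifier presets for the two benchmark experiments (serum-starved vs
#: proliferating fibroblasts; epithelial vs mesenchymal PC3 cells), plus a
#: light preset for quick runs
MODEL_PRESETS: Mapping[str, dict] = {
    # stochastic gradient boosting: 1,500 base learners, depth 8, subsample 0.5
    "fibroblast-gb": {
        "kind": "gb", "n_estimators": 1500, "max_depth": 8, "subsample": 0.5,
    },
    # random forest: 1,000 trees, depth 12, 40% of features per split
    "pc3-rf": {
        "kind": "rf", "n_estimators": 1000, "max_depth": 12, "max_features": 0.4,
    },
    "fast-rf": {
        "kind": "rf", "n_estimators": 100, "max_depth": 8, "max_features": 0.4,
    },
}


def make_model(preset: str, seed: int = 0):
    """Instantiate a preset classifier with a fixed random state."""
    try:
        cfg = dict(MODEL_PRESETS[preset])
    except KeyError:
        raise ValueError(f"unknown model preset {preset!r}; "
                         f"one of {sorted(MODEL_PRESETS)}") from None
    kind = cfg.pop("kind")
    if kind == "gb":
        return GradientBoostingClassifier(random_state=seed, **cfg)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **cfg)
    raise AssertionError(kind)


# ---------------------------------------------------------------------------
# L2OGO fold construction

@dataclass(frozen=True)
class FoldSpec:
    """One L2OGO fold: a test image from each class, all other images train."""

    test_pair: tuple[str, str]
    train_image_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.test_pair) & set(self.train_image_ids):
            raise ValueError("an image cannot be in both train and test")


def l2ogo_splits(table: pd.DataFrame) -> list[FoldSpec]:
    """Enumerate every opposite-class image pair as a test fold.

    All nuclei of one image fall on one side of the split; with n_A and n_B
    images per class there are exactly n_A x n_B folds.  Binary problems
    only; a class with zero images, or a fold with an empty training set
    (one image per class), is an error.
    """
    conds = sorted(table["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"L2OGO requires exactly 2 conditions, got {conds}")
    by_cond = {
        c: sorted(table.loc[table["condition"] == c, "image_id"].unique()) for c in conds
    }
    for c, imgs in by_cond.items():
        if not imgs:
            raise ValueError(f"condition {c!r} has no images")
    all_images = sorted(table["image_id"].unique())
    if len(all_images) < 3:
        raise ValueError(
            "L2OGO is degenerate with one image per class: every fold would "
            "have an empty training set"
        )
    folds = []
    for a in by_cond[conds[0]]:
        for b in by_cond[conds[1]]:
            train = tuple(i for i in all_images if i not in (a, b))
            folds.append(FoldSpec(test_pair=(a, b), train_image_ids=train))
    return folds


def balance_classes(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Random uniform sub-sampling of the majority class down to the minority
    count (without replacement, deterministic given seed)."""
    rng = np.random.default_rng(seed)
    counts = train["condition"].value_counts()
    n_min = int(counts.min())
    parts = []
    for cond, n in counts.items():
        rows = train[train["condition"] == cond]
        if n > n_min:
            rows = rows.iloc[np.sort(rng.choice(n, size=n_min, replace=False))]
        parts.append(rows)
    return pd.concat(parts)


# ---------------------------------------------------------------------------
# Single-cell scoring and metrics

def fit_and_score_cells(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model_config: str = "fast-rf",
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> tuple[np.ndarray, object]:
    """Fit a preset classifier on the training nuclei and return predicted
    positive-class probabilities for the test nuclei (and the fitted model).

    The positive class is the lexicographically larger condition label.
    """
    cols = list(feature_columns) if feature_columns is not None else list(FEATURE_COLUMNS)
    classes = sorted(train["condition"].unique())
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    model = make_model(model_config, seed=seed) if isinstance(model_config, str) \
        else model_config
    y = (train["condition"] == classes[-1]).to_numpy()
    model.fit(train[cols].to_numpy(), y)
    pos_col = list(model.classes_).index(True)
    probs = model.predict_proba(test[cols].to_numpy())[:, pos_col]
    return probs, model


def evaluate_metrics(scores: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.5) -> dict[str, float]:
    """Binary accuracy, precision, sensitivity, and rank-based AUC.

    ``labels`` are booleans (positive class = True); hard predictions use
    the given probability threshold.  Degenerate denominators (no predicted
    positives, or a single class present) fall back to 0 and 0.5 (AUC).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    acc = (tp + tn) / len(labels)
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    if labels.all() or not labels.any():
        auc = 0.5
    else:
        auc = float(roc_auc_score(labels, scores))
    return {"accuracy": acc, "precision": precision, "sensitivity": sensitivity,
            "auc": auc}


# ---------------------------------------------------------------------------
# Cell-set classification

@dataclass
class SetEvalResult:
    """Bootstrap cell-set metrics for one set size, per fold and summarized."""

    set_size: int
    n_bootstrap: int
    seed: int
    per_fold: pd.DataFrame  # columns: fold, accuracy, precision, sensitivity, auc
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metric in ("accuracy", "precision", "sensitivity", "auc"):
            vals = self.per_fold[metric].to_numpy()
            self.mean[metric] = float(vals.mean())
            self.sd[metric] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def classify_sets(
    cell_results: pd.DataFrame,
    set_size: int,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
) -> SetEvalResult:
    """Bootstrap cell-set classification from per-cell probabilities.

    ``cell_results`` must have columns ``fold``, ``image_id``, ``label``
    (bool), ``score``.  Per bootstrap repetition and per test image, a set of
    ``set_size`` cells is drawn uniformly from that image (without
    replacement when the image has enough cells, with replacement otherwise),
    so every set carries a single true label.  The set score is the mean of
    member probabilities; the set label is the majority vote of member hard
    labels, with ties broken by the set score.  Metrics are computed over the
    sets of a repetition and averaged over repetitions, then summarized
    across folds (mean ± SD).
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if set_size % 2 == 0:
        log.warning("even set_size %d is tie-prone; ties broken by mean probability",
                    set_size)
    rng = np.random.default_rng(seed)
    rows = []
    for fold, grp in cell_results.groupby("fold", sort=True):
        labels, set_scores, set_preds = [], [], []
        for _, g in grp.groupby("image_id", sort=True):
            scores = g["score"].to_numpy()
            labels.append(bool(g["label"].iloc[0]))
            n = len(scores)
            if n >= set_size:  # without replacement via random-key selection
                keys = rng.random((n_bootstrap, n))
                idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
            else:
                idx = rng.integers(0, n, size=(n_bootstrap, set_size))
            drawn = scores[idx]  # (n_bootstrap, set_size)
            mean_p = drawn.mean(axis=1)
            votes = (drawn >= 0.5).sum(axis=1)
            set_scores.append(mean_p)
            set_preds.append(np.where(votes * 2 == set_size, mean_p >= 0.5,
                                      votes * 2 > set_size))
        lab = np.array(labels)[:, None]  # (n_images, 1)
        P = np.stack(set_scores)  # (n_images, n_bootstrap)
        PR = np.stack(set_preds).astype(bool)
        acc = (PR == lab).mean(axis=0)
        tp = (PR & lab).sum(axis=0)
        fp = (PR & ~lab).sum(axis=0)
        fn = (~PR & lab).sum(axis=0)
        with np.errstate(invalid="ignore"):
            precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
            sensitivity = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        pos, neg = P[lab[:, 0]], P[~lab[:, 0]]
        if len(pos) and len(neg):  # per-repetition rank AUC over the fold's sets
            gt = (pos[:, None, :] > neg[None, :, :]).mean(axis=(0, 1))
            eq = (pos[:, None, :] == neg[None, :, :]).mean(axis=(0, 1))
            auc = gt + 0.5 * eq
        else:
            auc = np.full(n_bootstrap, 0.5)
        rows.append({
            "fold": fold,
            "accuracy": float(acc.mean()),
            "precision": float(precision.mean()),
            "sensitivity": float(sensitivity.mean()),
            "auc": float(auc.mean()),
        })
    per_fold = pd.DataFrame(rows)
    return SetEvalResult(set_size=set_size, n_bootstrap=n_bootstrap, seed=seed,
                         per_fold=per_fold)


def feature_importance(models: Sequence, feature_columns: Sequence[str] | None = None
                       ) -> pd.DataFrame:
    """Impurity-based importances averaged across folds, normalized to sum 1,
    ranked descending."""
    cols = list(feature_columns) if feature_columns is not None else list(FEATURE_COLUMNS)
    imps = np.mean([m.feature_importances_ for m in models], axis=0)
    total = imps.sum()
    if total > 0:
        imps = imps / total
    df = pd.DataFrame({"feature": cols, "importance": imps})
    return df.sort_values("importance", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Full L2OGO evaluation driver

@dataclass
class L2OGOResult:
    cell_results: pd.DataFrame  # fold, image_id, label, score (one row per test cell)
    single_cell: pd.DataFrame  # per-fold single-cell metrics
    set_results: list[SetEvalResult]
    importance: pd.DataFrame

    def set_summary(self) -> pd.DataFrame:
        rows = []
        for r in self.set_results:
            row = {"set_size": r.set_size}
            for k in ("accuracy", "precision", "sensitivity", "auc"):
                row[f"{k}_mean"] = r.mean[k]
                row[f"{k}_sd"] = r.sd[k]
            rows.append(row)
        return pd.DataFrame(rows)


def run_l2ogo(
    table: pd.DataFrame,
    model_config: str = "fast-rf",
    set_sizes: Sequence[int] = DEFAULT_SET_SIZES,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> L2OGOResult:
    """Evaluate condition discrimination over all L2OGO folds.

    Per fold: balance the training classes, fit the preset model, score the
    test cells; then bootstrap cell-set metrics for every requested set size.
    Deterministic given ``seed``.
    """
    folds = l2ogo_splits(table)
    cell_rows = []
    single_rows = []
    models = []
    classes = sorted(table["condition"].unique())
    for fi, fold in enumerate(folds):
        test = table[table["image_id"].isin(fold.test_pair)]
        train = table[table["image_id"].isin(fold.train_image_ids)]
        train = balance_classes(train, seed=seed + fi)
        probs, model = fit_and_score_cells(train, test, model_config,
                                           seed=seed + fi,
                                           feature_columns=feature_columns)
        models.append(model)
        labels = (test["condition"] == classes[-1]).to_numpy()
        single = evaluate_metrics(probs, labels)
        single["fold"] = fi
        single_rows.append(single)
        cell_rows.append(pd.DataFrame({
            "fold": fi,
            "image_id": test["image_id"].to_numpy(),
            "label": labels,
            "score": probs,
        }))
    cell_results = pd.concat(cell_rows, ignore_index=True)
    set_results = [
        classify_sets(cell_results, s, n_bootstrap=n_bootstrap, seed=seed + 10_000 + s)
        for s in set_sizes
    ]
    importance = feature_importance(models, feature_columns)
    return L2OGOResult(
        cell_results=cell_results,
        single_cell=pd.DataFrame(single_rows),
        set_results=set_results,
        importance=importance,
    )
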