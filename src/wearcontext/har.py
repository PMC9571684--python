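"""Three-class human activity recognition (sedentary / walking / cycling).

A gradient-boosted-tree classifier over the 228-dimensional 15 s window
features, tuned with subject-grouped 5-fold cross-validation (tree-depth
grid) and class weights inversely proportional to class frequency.  Window
probabilities at the 7.5 s stride are aggregated to per-minute labels by
summing probability vectors over each clock minute, and minute labels are
counted per hour into the three activity-minute context features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GroupKFold

from .features import FeatureCatalogue, extract_har_features_batch
from .timeseries import Recording, Window, slide_windows

log = logging.getLogger(__name__)

CLASS_ORDER = ("sedentary", "walking", "cycling")


@dataclass
class HarConfig:
    depth_grid: tuple = (4, 6, 8, 10)
    n_folds: int = 5
    n_estimators: int = 200
    learning_rate: float = 0.1
    min_child_samples: int = 10
    seed: int = 0


@dataclass
class HarModel:
    model: LGBMClassifier
    class_order: tuple = CLASS_ORDER
    class_weights: dict = field(default_factory=dict)
    tuned_depth: int = 0
    feature_columns: list = field(default_factory=list)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability simplex over (sedentary, walking, cycling)."""
        proba = self.model.predict_proba(X[self.feature_columns])
        cols = list(self.model.classes_)
        order = [cols.index(c) for c in self.class_order]
        return proba[:, order]


def balanced_class_weights(labels: pd.Series) -> dict[str, float]:
    """``n_total / (n_classes * n_class)`` per class."""
    counts = labels.value_counts()
    n, k = len(labels), len(counts)
    return {cls: n / (k * c) for cls, c in counts.items()}


def _fit_lgbm(X, y, weights, depth, config: HarConfig) -> LGBMClassifier:
    clf = LGBMClassifier(
        max_depth=depth,
        num_leaves=min(2 ** depth, 63),
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        min_child_samples=config.min_child_samples,
        class_weight=weights,
        random_state=config.seed,
        n_jobs=1,
        verbose=-1,
    )
    clf.fit(X, y)
    return clf


def train_har(
    rows: pd.DataFrame,
    config: HarConfig | None = None,
    label_col: str = "label",
    group_col: str = "subject_id",
) -> HarModel:
    """Train the HAR classifier with grouped-CV depth tuning.

    ``rows`` holds the 228 feature columns plus label and subject columns.
    Tree depth is selected by subject-grouped K-fold macro F1 on the
    training subjects; the final model is refit on all rows.  Folds where a
    validation split lacks a class trigger a fallback to 3 folds.
    """
    config = config or HarConfig()
    feature_cols = [c for c in rows.columns
                    if c not in (label_col, group_col, "window_start")]
    groups = rows[group_col]
    y = rows[label_col]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 subjects for grouped tuning")
    if y.nunique() < len(CLASS_ORDER):
        raise ValueError("all three activity classes must be present")
    X = rows[feature_cols]
    weights = balanced_class_weights(y)

    def _fold_scores(n_folds: int) -> dict[int, float] | None:
        splitter = GroupKFold(n_splits=min(n_folds, groups.nunique()))
        scores: dict[int, list[float]] = {d: [] for d in config.depth_grid}
        for tr, va in splitter.split(X, y, groups):
            if y.iloc[tr].nunique() < len(CLASS_ORDER):
                return None
            for d in config.depth_grid:
                clf = _fit_lgbm(X.iloc[tr], y.iloc[tr],
                                balanced_class_weights(y.iloc[tr]), d, config)
                pred = clf.predict(X.iloc[va])
                _, _, f1, _ = precision_recall_fscore_support(
                    y.iloc[va], pred, labels=list(CLASS_ORDER), zero_division=0)
                scores[d].append(float(np.mean(f1)))
        return {d: float(np.mean(v)) for d, v in scores.items()}

    scores = _fold_scores(config.n_folds)
    if scores is None:
        log.warning("a tuning fold lacked a class; falling back to 3 folds")
        scores = _fold_scores(3)
        if scores is None:
            raise ValueError("cannot form class-complete grouped folds")
    best_depth = max(config.depth_grid, key=lambda d: (scores[d], -d))
    final = _fit_lgbm(X, y, weights, best_depth, config)
    return HarModel(final, CLASS_ORDER, weights, best_depth, feature_cols)


def build_training_rows(
    recording: Recording,
    bouts: list[tuple[pd.Timestamp, pd.Timestamp, str]],
    catalogue: FeatureCatalogue,
) -> pd.DataFrame:
    """Labelled 15 s feature rows from a recording with ground-truth bouts.

    Windows are kept only when they lie entirely inside one bout, and bouts
    shorter than one minute are discarded (matching the annotation rule the
    HAR training data follows).
    """
    windows = slide_windows(recording, 15.0, 0.5)
    keep: list[Window] = []
    labels: list[str] = []
    usable_bouts = [b for b in bouts if (b[1] - b[0]) >= pd.Timedelta(minutes=1)]
    for w in windows:
        w_end = w.start + pd.Timedelta(seconds=w.duration)
        for b0, b1, kind in usable_bouts:
            if b0 <= w.start and w_end <= b1:
                keep.append(w)
                labels.append(kind)
                break
    if not keep:
        return pd.DataFrame()
    df = extract_har_features_batch(keep, catalogue)
    df["label"] = labels[: len(df)]
    df["subject_id"] = recording.subject_id
    return df


def predict_windows(
    model: HarModel, recording: Recording, catalogue: FeatureCatalogue
) -> pd.DataFrame:
    """Per-stride activity probabilities: one row every 7.5 s.

    Returns columns (window_start, p_sedentary, p_walking, p_cycling);
    unusable windows are absent (gaps in the timeline are allowed).
    """
    windows = slide_windows(recording, 15.0, 0.5)
    feats = extract_har_features_batch(windows, catalogue)
    if feats.empty:
        return pd.DataFrame(
            columns=["window_start"] + [f"p_{c}" for c in model.class_order])
    proba = model.predict_proba(feats)
    out = pd.DataFrame({"window_start": feats["window_start"]})
    for i, c in enumerate(model.class_order):
        out[f"p_{c}"] = proba[:, i]
    return out


def aggregate_minutes(window_probs: pd.DataFrame) -> pd.DataFrame:
    """Per-minute labels: sum the probability vectors of all windows
    *starting* in each clock minute and take the argmax (ties resolved in
    class order, sedentary first).  Minutes without windows are absent."""
    if window_probs.empty:
        return pd.DataFrame(columns=["minute_start", "label"])
    df = window_probs.copy()
    df["minute_start"] = pd.DatetimeIndex(df["window_start"]).floor("min")
    pcols = [c for c in df.columns if c.startswith("p_")]
    sums = df.groupby("minute_start", sort=True)[pcols].sum()
    idx = np.argmax(sums.to_numpy(), axis=1)  # first max wins the tie
    labels = [pcols[i][2:] for i in idx]
    return pd.DataFrame({"minute_start": sums.index, "label": labels})


def hourly_activity_minutes(minute_labels: pd.DataFrame) -> pd.DataFrame:
    """Count per-minute labels per clock hour into the three context
    features; unlabeled minutes simply do not count (sums may be < 60)."""
    if minute_labels.empty:
        return pd.DataFrame(
            columns=["hour_start"] + [f"minutes_{c}" for c in CLASS_ORDER])
    df = minute_labels.copy()
    df["hour_start"] = pd.DatetimeIndex(df["minute_start"]).floor("h")
    counts = (df.groupby(["hour_start", "label"]).size().unstack(fill_value=0))
    for c in CLASS_ORDER:
        if c not in counts.columns:
            counts[c] = 0
    out = counts[list(CLASS_ORDER)].rename(
        columns={c: f"minutes_{c}" for c in CLASS_ORDER}).reset_index()
    return out


class _LoadedBooster:
    """Prediction shim around a booster restored from its text dump."""

    def __init__(self, booster, classes):
        self._booster = booster
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self._booster.predict(np.asarray(X, dtype=np.float64))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def save_har_model(model: HarModel, path) -> None:
    """Persist as the booster's text dump plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    model.model.booster_.save_model(str(path))
    meta = {
        "classes": list(model.model.classes_),
        "class_order": list(model.class_order),
        "class_weights": model.class_weights,
        "tuned_depth": model.tuned_depth,
        "feature_columns": model.feature_columns,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))


def load_har_model(path) -> HarModel:
    import json
    from pathlib import Path

    import lightgbm as lgb

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    booster = lgb.Booster(model_file=str(path))
    shim = _LoadedBooster(booster, meta["classes"])
    return HarModel(shim, tuple(meta["class_order"]), meta["class_weights"],
                    meta["tuned_depth"], meta["feature_columns"])


def evaluate_har(model: HarModel, test_rows: pd.DataFrame,
                 label_col: str = "label") -> dict:
    """Per-class precision/recall/F1 plus absolute and row-normalized
    confusion matrices on held-out labelled rows."""
    y = test_rows[label_col]
    pred = model.model.predict(test_rows[model.feature_columns])
    present = [c for c in CLASS_ORDER if (y == c).any()]
    p, r, f1, support = precision_recall_fscore_support(
        y, pred, labels=list(CLASS_ORDER), zero_division=0)
    cm = confusion_matrix(y, pred, labels=list(CLASS_ORDER))
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_norm = cm / cm.sum(axis=1, keepdims=True)
    per_class = {}
    for i, c in enumerate(CLASS_ORDER):
        if c not in present:
            per_class[c] = {"precision": float("nan"), "recall": float("nan"),
                            "f1": float("nan"), "support": 0}
        else:
            per_class[c] = {"precision": float(p[i]), "recall": float(r[i]),
                            "f1": float(f1[i]), "support": int(support[i])}
    return {"per_class": per_class, "confusion": cm,
            "confusion_normalized": cm_norm}
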