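"""The context-ablation stress experiment.

Hourly stress self-reports (5-level scale collapsed to no / medium / high)
are aligned with the hour's physiological features and with context from
one of two sources: the participant's own reports (reported activity set
split equally over the mapped classes; bed / get-up times taken literally)
or machine-learned context (HAR activity minutes; detected sleep period of
the preceding 13:00 → 13:00 day window).

Four gradient-boosted-tree models are trained on identical subject-grouped
3-fold rotations — physiology only, +activity, +sleep, +activity+sleep —
and compared on accuracy, Cohen's kappa, weighted F1 and weighted F1 minus
a majority-class dummy.  Tree depth and early stopping (patience 150,
max 10000 iterations) are tuned on the validation fold by quadratic
weighted kappa over the ordinal stress classes; the reported kappa is the
unweighted Cohen statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, early_stopping
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score
from sklearn.model_selection import GroupKFold

from .synthetic import HourlyReport, NightReport
from .sleep import SleepEstimate

log = logging.getLogger(__name__)

STRESS3_ORDER = ("no", "medium", "high")

#: app vocabulary → activity class
TOKEN_CLASS = {
    "sitting": "sedentary",
    "standing": "sedentary",
    "lying_down": "sedentary",
    "walking": "walking",
    "running": "walking",
    "biking": "cycling",
}

ACTIVITY_CTX_COLS = ("ctx_minutes_sedentary", "ctx_minutes_walking",
                     "ctx_minutes_cycling")
SLEEP_CTX_COLS = ("ctx_bed_hour", "ctx_getup_hour", "ctx_sleep_duration")

VARIANTS = ("baseline", "+activity", "+sleep", "+activity+sleep")


def collapse_stress(level5: int) -> str:
    """5-level stress scale → 3 classes (the top three levels merge)."""
    if level5 == 1:
        return "no"
    if level5 == 2:
        return "medium"
    if level5 in (3, 4, 5):
        return "high"
    raise ValueError(f"stress level must be 1..5, got {level5!r}")


def selfreport_activity_ctx(tokens) -> tuple[float, float, float]:
    """Equal-split featurization of a reported activity set.

    The hour's 60 minutes are split equally among the *distinct* activity
    classes present after mapping the app tokens; unknown tokens are
    rejected (logged and ignored).  An empty set yields (0, 0, 0).
    """
    classes = set()
    for tok in tokens:
        cls = TOKEN_CLASS.get(tok)
        if cls is None:
            log.warning("unknown activity token %r rejected", tok)
            continue
        classes.add(cls)
    if not classes:
        return (0.0, 0.0, 0.0)
    share = 60.0 / len(classes)
    return tuple(share if c in classes else 0.0
                 for c in ("sedentary", "walking", "cycling"))


def _hour_of_day(ts: pd.Timestamp) -> float:
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0


def _circular_duration(bed_hour: float, getup_hour: float) -> float:
    d = (getup_hour - bed_hour) % 24.0
    return d if d > 0 else 24.0


def selfreport_sleep_ctx(report: NightReport) -> tuple[float, float, float]:
    """(bed hour-of-day, get-up hour-of-day, duration h) from a night report."""
    bed = _hour_of_day(report.bed_time)
    getup = _hour_of_day(report.getup_time)
    return (bed, getup, _circular_duration(bed, getup))


def sleep_estimate_ctx(estimate: SleepEstimate) -> tuple[float, float, float]:
    """Same (bed, get-up, duration) encoding, from a detected rest period."""
    bed = _hour_of_day(estimate.onset)
    getup = _hour_of_day(estimate.offset)
    return (bed, getup, _circular_duration(bed, getup))


# ---------------------------------------------------------------------------
# event assembly
# ---------------------------------------------------------------------------

def assemble_events(
    hour_features: pd.DataFrame,
    hourly_reports: list[HourlyReport],
    context_source: str = "self_report",
    night_reports: list[NightReport] | None = None,
    activity_minutes: pd.DataFrame | None = None,
    sleep_estimates: pd.DataFrame | None = None,
    circular_hours: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One stress event per reported hour with complete physiology + context.

    ``hour_features`` needs columns (subject_id, hour_start, usable, <physio>).
    With ``circular_hours`` the bed/get-up hour-of-day features are encoded
    as (sin, cos) pairs instead of plain reals (off by default).
    For ``self_report`` context pass ``night_reports``; for ``ml`` context
    pass ``activity_minutes`` (subject_id, hour_start, minutes_*) and
    ``sleep_estimates`` (subject_id, day_window_start, onset, offset,
    status).  Incomplete events are dropped and counted so all four model
    variants later train on identical rows.
    """
    if context_source not in ("self_report", "ml"):
        raise ValueError("context_source must be 'self_report' or 'ml'")
    physio_cols = [c for c in hour_features.columns
                   if c not in ("subject_id", "hour_start", "usable")]
    feat_ix = hour_features.set_index(["subject_id", "hour_start"])

    night_ix: dict[tuple[str, pd.Timestamp], NightReport] = {}
    if night_reports:
        for nr in night_reports:
            night_ix[(nr.subject, pd.Timestamp(nr.date).normalize())] = nr
    act_ix = (activity_minutes.set_index(["subject_id", "hour_start"])
              if activity_minutes is not None and not activity_minutes.empty else None)
    slp_ix = None
    if sleep_estimates is not None and not sleep_estimates.empty:
        slp_ix = sleep_estimates.set_index(["subject_id", "day_window_start"])

    drops = {"no_physio": 0, "unusable_physio": 0, "no_activity_ctx": 0,
             "no_sleep_ctx": 0}
    rows = []
    for rep in hourly_reports:
        key = (rep.subject, rep.hour_start)
        if key not in feat_ix.index:
            drops["no_physio"] += 1
            continue
        frow = feat_ix.loc[key]
        if not bool(frow["usable"]):
            drops["unusable_physio"] += 1
            continue
        event_date = rep.hour_start.normalize()
        if context_source == "self_report":
            act = selfreport_activity_ctx(rep.activities)
            nr = night_ix.get((rep.subject, event_date))
            if nr is None:
                drops["no_sleep_ctx"] += 1
                continue
            slp = selfreport_sleep_ctx(nr)
        else:
            if act_ix is None or key not in act_ix.index:
                drops["no_activity_ctx"] += 1
                continue
            arow = act_ix.loc[key]
            act = tuple(float(arow[f"minutes_{c}"])
                        for c in ("sedentary", "walking", "cycling"))
            wstart = event_date - pd.Timedelta(days=1) + pd.Timedelta(hours=13)
            if slp_ix is None or (rep.subject, wstart) not in slp_ix.index:
                drops["no_sleep_ctx"] += 1
                continue
            srow = slp_ix.loc[(rep.subject, wstart)]
            if srow["status"] != "ok":
                drops["no_sleep_ctx"] += 1
                continue
            bed = _hour_of_day(pd.Timestamp(srow["onset"]))
            getup = _hour_of_day(pd.Timestamp(srow["offset"]))
            slp = (bed, getup, _circular_duration(bed, getup))
        row = {
            "subject_id": rep.subject,
            "hour_start": rep.hour_start,
            "stress3": collapse_stress(rep.stress_1to5),
        }
        row.update({c: float(frow[c]) for c in physio_cols if c != "usable"})
        row.update(dict(zip(ACTIVITY_CTX_COLS, act)))
        if circular_hours:
            bed, getup, dur = slp
            for label, h in (("bed", bed), ("getup", getup)):
                row[f"ctx_{label}_sin"] = float(np.sin(2 * np.pi * h / 24))
                row[f"ctx_{label}_cos"] = float(np.cos(2 * np.pi * h / 24))
            row["ctx_sleep_duration"] = dur
        else:
            row.update(dict(zip(SLEEP_CTX_COLS, slp)))
        rows.append(row)
    events = pd.DataFrame(rows)
    return events, drops


def variant_columns(events: pd.DataFrame, variant: str) -> list[str]:
    sleep_cols = [c for c in events.columns
                  if c in SLEEP_CTX_COLS or c.startswith(("ctx_bed_", "ctx_getup_"))]
    ctx = set(ACTIVITY_CTX_COLS) | set(sleep_cols)
    physio = [c for c in events.columns
              if c not in ("subject_id", "hour_start", "stress3") and c not in ctx]
    if variant == "baseline":
        return physio
    if variant == "+activity":
        return physio + list(ACTIVITY_CTX_COLS)
    if variant == "+sleep":
        return physio + sleep_cols
    if variant == "+activity+sleep":
        return physio + list(ACTIVITY_CTX_COLS) + sleep_cols
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# model fitting and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    depth_grid: tuple = (4, 6, 8)
    max_iterations: int = 10000
    early_stopping_rounds: int = 150
    learning_rate: float = 0.1
    min_child_samples: int = 20
    colsample_bytree: float = 1.0
    n_folds: int = 3
    seed: int = 0


def _encode(y: pd.Series) -> np.ndarray:
    return y.map({c: i for i, c in enumerate(STRESS3_ORDER)}).to_numpy()


def _qwk_eval(y_true, y_pred):
    """Quadratic-weighted kappa eval callable for the boosting library."""
    if y_pred.ndim == 1:
        y_pred = y_pred.reshape(len(np.unique(y_true)), -1).T
    pred_cls = np.argmax(y_pred, axis=1)
    return "qwk", cohen_kappa_score(y_true, pred_cls, weights="quadratic"), True


def assign_folds(events: pd.DataFrame, n_folds: int = 3) -> np.ndarray:
    """Subject-grouped fold index per event (same folds for all variants)."""
    if events["subject_id"].nunique() < n_folds:
        raise ValueError(f"need at least {n_folds} subjects")
    folds = np.empty(len(events), dtype=int)
    gkf = GroupKFold(n_splits=n_folds)
    for k, (_, test_ix) in enumerate(
            gkf.split(events, groups=events["subject_id"])):
        folds[test_ix] = k
    return folds


def train_variant(
    events: pd.DataFrame,
    variant: str,
    train_mask: np.ndarray,
    val_mask: np.ndarray,
    config: ExperimentConfig,
):
    """Fit one variant on a train fold with depth tuning + early stopping on
    the validation fold (quadratic weighted kappa).  Returns (model, cols,
    best_depth)."""
    cols = variant_columns(events, variant)
    Xtr, ytr = events.loc[train_mask, cols], _encode(events.loc[train_mask, "stress3"])
    Xva, yva = events.loc[val_mask, cols], _encode(events.loc[val_mask, "stress3"])
    if len(np.unique(ytr)) < 2:
        raise ValueError("training fold has fewer than 2 classes")
    classes, counts = np.unique(ytr, return_counts=True)
    weights = {int(c): len(ytr) / (len(classes) * n) for c, n in zip(classes, counts)}
    best = None
    for depth in config.depth_grid:
        clf = LGBMClassifier(
            max_depth=depth,
            num_leaves=min(2 ** depth, 63),
            n_estimators=config.max_iterations,
            learning_rate=config.learning_rate,
            min_child_samples=config.min_child_samples,
            colsample_bytree=config.colsample_bytree,
            class_weight=weights,
            random_state=config.seed,
            n_jobs=1,
            verbose=-1,
        )
        clf.fit(
            Xtr, ytr,
            eval_set=[(Xva, yva)],
            eval_metric=_qwk_eval,
            callbacks=[early_stopping(config.early_stopping_rounds, verbose=False)],
        )
        score = clf.best_score_["valid_0"]["qwk"]
        if best is None or score > best[0]:
            best = (score, depth, clf)
    _, best_depth, model = best
    return model, cols, best_depth


def _metrics(y_true: np.ndarray, y_pred: np.ndarray,
             dummy_class: int) -> dict[str, float]:
    wf1 = f1_score(y_true, y_pred, average="weighted", zero_division=0)
    dummy_pred = np.full_like(y_true, dummy_class)
    wf1_dummy = f1_score(y_true, dummy_pred, average="weighted", zero_division=0)
    return {
        "accuracy": 100.0 * accuracy_score(y_true, y_pred),
        "kappa": 100.0 * cohen_kappa_score(y_true, y_pred),
        "weighted_f1": 100.0 * wf1,
        "vs_dummy": 100.0 * (wf1 - wf1_dummy),
    }


def run_experiment(
    events: pd.DataFrame,
    config: ExperimentConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train and evaluate all four variants over the 3 cyclic fold rotations.

    Rotation ``r`` uses fold ``r`` for testing, ``r+1`` for validation and
    ``r+2`` for training; the same assignment is reused by every variant.
    Returns (summary table, per-rotation metrics).  Metrics are percentages
    (kappa × 100); the summary holds mean and sd over rotations.
    """
    config = config or ExperimentConfig()
    folds = assign_folds(events, config.n_folds)
    per_rotation = []
    for r in range(config.n_folds):
        test_mask = folds == r
        val_mask = folds == (r + 1) % config.n_folds
        train_mask = ~(test_mask | val_mask)
        ytr = _encode(events.loc[train_mask, "stress3"])
        dummy_class = int(np.bincount(ytr).argmax())
        yte = _encode(events.loc[test_mask, "stress3"])
        for variant in VARIANTS:
            model, cols, depth = train_variant(
                events, variant, train_mask, val_mask, config)
            pred = model.predict(events.loc[test_mask, cols])
            m = _metrics(yte, pred, dummy_class)
            m.update({"variant": variant, "rotation": r, "depth": depth})
            per_rotation.append(m)
    detail = pd.DataFrame(per_rotation)
    rows = []
    for variant in VARIANTS:
        d = detail[detail["variant"] == variant]
        row = {"variant": variant}
        for metric in ("accuracy", "kappa", "weighted_f1", "vs_dummy"):
            row[f"{metric}_mean"] = float(d[metric].mean())
            row[f"{metric}_sd"] = float(d[metric].std(ddof=0))
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("variant")
    return summary, detail


def format_results_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Render the summary in the mean (std) layout of the results tables."""
    out = {}
    for metric, label in (("accuracy", "Accuracy (std)"),
                          ("kappa", "Cohen Kappa (std)"),
                          ("weighted_f1", "Weighted F1 (std)"),
                          ("vs_dummy", "Compared to dummy (std)")):
        out[label] = [f"{m:.2f} ({s:.2f})" for m, s in
                      zip(summary[f"{metric}_mean"], summary[f"{metric}_sd"])]
    return pd.DataFrame(out, index=summary.index)
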