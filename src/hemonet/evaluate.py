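"""Splitting, evaluation metrics, and end-to-end experiment orchestration.

Accuracy is the indicator mean  sum_i I(y_pred_i == y_true_i) / N; per-class
precision Tp/(Tp+Fp) and recall Tp/(Tp+Fn) are computed from the confusion
matrix, with F1 their harmonic mean.  Zero denominators yield 0 and set a
zero-division flag (real experiments never hit this; degenerate synthetic
runs can).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .features import (
    EventAverageSet,
    FeatureMatrix,
    build_feature_matrix,
    event_average,
    extract_epochs,
    standard_scale,
)
from .models import MODEL_REGISTRY, make_model
from .preprocess import PreprocessSettings, run_pipeline
from .simulate import build_paradigm, preset_config, simulate_recording

__all__ = [
    "SplitPlan", "EvaluationReport", "split", "confusion", "report",
    "evaluate_predictions", "simulate_feature_runs", "run_experiment",
]


@dataclass(frozen=True)
class SplitPlan:
    """How to partition the feature matrix into train and test."""

    strategy: str = "stratified-pooled"   # or "by-run"
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.strategy not in ("stratified-pooled", "by-run"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")


def split(fm: FeatureMatrix, plan: SplitPlan = SplitPlan()) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Deterministic train/test split under the plan's seed.

    ``stratified-pooled`` preserves class proportions; ``by-run`` keeps all
    rows of a run on one side (requires a ``run`` metadata column).
    """
    idx = np.arange(fm.n_samples)
    if plan.strategy == "stratified-pooled":
        tr, te = train_test_split(
            idx, test_size=plan.test_fraction, stratify=fm.y,
            random_state=plan.seed,
        )
    else:
        if "run" not in fm.meta.columns:
            raise ValueError("by-run split needs a 'run' metadata column")
        groups = fm.meta["run"].to_numpy()
        gss = GroupShuffleSplit(
            n_splits=1, test_size=plan.test_fraction, random_state=plan.seed
        )
        tr, te = next(gss.split(idx, fm.y, groups))
    tr, te = np.sort(tr), np.sort(te)

    def _take(sel):
        return FeatureMatrix(
            X=fm.X[sel], y=fm.y[sel],
            meta=fm.meta.iloc[sel].reset_index(drop=True) if len(fm.meta) else fm.meta,
        )

    train, test = _take(tr), _take(te)
    missing = (set(np.unique(fm.y)) - set(np.unique(train.y))) | (
        set(np.unique(fm.y)) - set(np.unique(test.y)))
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from one split")
    return train, test


def confusion(y_true, y_pred, labels=None) -> np.ndarray:
    """K x K count matrix; entry (i, j) = true class i predicted as j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label arrays")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    else:
        labels = np.asarray(labels)
        known = set(labels.tolist())
        out = set(y_true.tolist()) | set(y_pred.tolist())
        if out - known:
            raise ValueError(f"labels outside the declared set: {sorted(out - known)}")
    return _sk_confusion(y_true, y_pred, labels=labels)


@dataclass
class EvaluationReport:
    """Confusion matrix plus the derived per-class and average metrics."""

    classes: tuple[str, ...]
    confusion_matrix: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    zero_division_flags: tuple[str, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        """Classification-report table: per-class rows then summary rows."""
        n = int(self.support.sum())
        rows = [
            {"class": c, "precision": p, "recall": r, "f1": f, "support": int(s)}
            for c, p, r, f, s in zip(
                self.classes, self.precision, self.recall, self.f1, self.support
            )
        ]
        rows.append({"class": "accuracy", "precision": np.nan, "recall": np.nan,
                     "f1": self.accuracy, "support": n})
        rows.append({"class": "macro avg", "precision": self.macro_precision,
                     "recall": self.macro_recall, "f1": self.macro_f1, "support": n})
        rows.append({"class": "weighted avg", "precision": self.weighted_precision,
                     "recall": self.weighted_recall, "f1": self.weighted_f1,
                     "support": n})
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "zero_division_flags": list(self.zero_division_flags),
        }


def report(conf: np.ndarray, classes=None) -> EvaluationReport:
    """Derive accuracy, per-class precision/recall/F1 and their macro and
    support-weighted averages from a confusion matrix."""
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    K = conf.shape[0]
    classes = tuple(f"C{i + 1}" for i in range(K)) if classes is None else tuple(classes)
    n = conf.sum()
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    tn = n - tp - fp - fn
    flags = []
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    for i, c in enumerate(classes):
        if tp[i] + fp[i] == 0:
            flags.append(f"precision:{c}")
        if tp[i] + fn[i] == 0:
            flags.append(f"recall:{c}")
    support = conf.sum(axis=1)
    weights = support / n if n > 0 else np.zeros(K)
    return EvaluationReport(
        classes=classes,
        confusion_matrix=conf,
        accuracy=float(tp.sum() / n) if n > 0 else 0.0,
        precision=precision, recall=recall, f1=f1,
        support=support, tp=tp, tn=tn, fp=fp, fn=fn,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float(precision @ weights),
        weighted_recall=float(recall @ weights),
        weighted_f1=float(f1 @ weights),
        zero_division_flags=tuple(flags),
    )


def evaluate_predictions(y_true, y_pred, labels=None) -> EvaluationReport:
    y_true = np.asarray(y_true)
    if labels is None:
        labels = np.unique(y_true)
    conf = confusion(y_true, y_pred, labels=labels)
    return report(conf, classes=labels)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

def simulate_feature_runs(
    preset: str = "default",
    n_runs: int = 1,
    montage_channels: int = 48,
    seed: int = 0,
    settings: PreprocessSettings = PreprocessSettings(),
    include_hbt: bool = True,
    shuffle_order: bool = True,
) -> FeatureMatrix:
    """Simulate -> preprocess -> epoch -> average for ``n_runs`` independent
    runs (one synthetic participant each) and pool the rows.

    By default each run presents the conditions in an independently shuffled
    order per session; with a fixed order, condition would be confounded
    with trial position (filter edge effects, the first trial's baseline),
    which is exactly the confound randomised designs exist to break.
    """
    sets: list[EventAverageSet] = []
    for r in range(n_runs):
        run_seed = seed * 10_000 + r
        timeline = build_paradigm(
            shuffle_seed=run_seed if shuffle_order else None
        )
        cfg = preset_config(preset, montage_channels=montage_channels,
                            seed=run_seed)
        rec, _ = simulate_recording(timeline, cfg)
        hb, _ = run_pipeline(rec, timeline, settings)
        epochs = extract_epochs(hb, timeline)
        sets.append(event_average(epochs, run_id=f"run{r}"))
    return build_feature_matrix(sets, include_hbt=include_hbt)


#: Per-model keyword arguments used by run_experiment for scaled-down runs.
_DEEP_MODELS = {"dnn", "lstm", "bilstm", "hybrid", "hemonet"}


def run_experiment(config: dict) -> dict:
    """Run the full pipeline and write report artifacts.

    ``config`` keys (all optional):
      preset (default "default"), n_runs (2), montage_channels (16),
      models (list of registry names; default all ten),
      model_params ({name: kwargs}), test_fraction (0.2), seed (0),
      out_dir (None: nothing written).

    Returns {model: {"train_accuracy", "test_accuracy", "report", ...}}.
    Stage failures propagate with the stage name prepended.
    """
    preset = config.get("preset", "default")
    n_runs = config.get("n_runs", 2)
    montage = config.get("montage_channels", 16)
    names = config.get("models", list(MODEL_REGISTRY))
    model_params = config.get("model_params", {})
    seed = config.get("seed", 0)
    out_dir = config.get("out_dir")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

    fm = _stage("simulate+preprocess+features", simulate_feature_runs,
                preset=preset, n_runs=n_runs, montage_channels=montage, seed=seed)
    plan = SplitPlan(test_fraction=config.get("test_fraction", 0.2), seed=seed)
    train, test = _stage("split", split, fm, plan)
    Xtr, scaler = standard_scale(train.X)
    Xte = scaler.transform(test.X)

    results: dict[str, dict] = {}
    for name in names:
        params = dict(model_params.get(name, {}))
        if name in _DEEP_MODELS:
            params.setdefault("random_state", seed)
            params.setdefault("max_epochs", 30)
            params.setdefault("patience", 10)
        elif name in ("rf", "xgboost"):
            params.setdefault("random_state", seed)
        model = make_model(name, **params)
        _stage(f"train:{name}", model.fit, Xtr, train.y)
        rep_train = evaluate_predictions(train.y, model.predict(Xtr))
        rep_test = evaluate_predictions(test.y, model.predict(Xte))
        results[name] = {
            "train_accuracy": rep_train.accuracy,
            "test_accuracy": rep_test.accuracy,
            "report": rep_test,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        acc = pd.DataFrame(
            [{"model": m,
              "train_accuracy_pct": 100 * r["train_accuracy"],
              "test_accuracy_pct": 100 * r["test_accuracy"]}
             for m, r in results.items()]
        )
        acc.to_csv(out / "accuracy_table.csv", index=False)
        for m, r in results.items():
            rep: EvaluationReport = r["report"]
            rep.as_frame().to_csv(out / f"classification_report_{m}.csv", index=False)
            pd.DataFrame(
                rep.confusion_matrix, index=rep.classes, columns=rep.classes
            ).to_csv(out / f"confusion_{m}.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {m: {"train_accuracy": r["train_accuracy"],
                     "test_accuracy": r["test_accuracy"]}
                 for m, r in results.items()},
                fh, indent=2,
            )
    return results
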