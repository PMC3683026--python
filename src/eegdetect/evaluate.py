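"""Evaluation: confusion metrics, ROC comparison, k-fold CV, full pipeline.

Per-class results are reported one-vs-rest: each class in turn is the
designated positive class of a confusion table with accuracy
Acc = (TP+TN)/(TP+FP+TN+FN), sensitivity Sen = TP/(TP+FN) and specificity
Spe = TN/(TN+FP).  ROC curves compare the classifier variants (SVM-only,
GA+SVM, GA+SVM with post-classification spike matching); the binary spike
matcher is placed on the ROC by promoting matched epochs to the maximal
decision score.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import __version__ as _pkg_version
from .features import FeatureConfig, extract_feature_matrix, feature_name_hash
from .montage import MontageSpec, default_montage
from .preprocess import EegRecording, make_epoch_pairs
from .select_classify import (
    GaConfig,
    SvmConfig,
    TrainedModel,
    class_score,
    ga_select,
    predict,
    train_svm,
)
from .spike_match import SpikeMatchConfig, followup_screen
from .synthetic import GroundTruth


@dataclass
class ConfusionTable:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray, positive: str) -> ConfusionTable:
    yt = np.asarray(y_true, dtype=object) == positive
    yp = np.asarray(y_pred, dtype=object) == positive
    return ConfusionTable(
        tp=int(np.sum(yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
        fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)),
    )


def metrics(table: ConfusionTable) -> dict[str, float | bool]:
    """Acc/Sen/Spe of a confusion table.

    Ratios with a zero denominator are reported as NaN with a flag; an
    all-zero table raises (nothing was evaluated).
    """
    if table.total == 0:
        raise ValueError("empty confusion table")
    out: dict[str, float | bool] = {
        "accuracy": (table.tp + table.tn) / table.total,
        "undefined": False,
    }
    for name, num, den in (
        ("sensitivity", table.tp, table.tp + table.fn),
        ("specificity", table.tn, table.tn + table.fp),
    ):
        if den == 0:
            out[name] = float("nan")
            out["undefined"] = True
        else:
            out[name] = num / den
    return out


def per_class_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                      classes: tuple[str, ...] = ("normal", "spike", "seizure")
                      ) -> dict[str, dict]:
    return {c: metrics(confusion(y_true, y_pred, c)) for c in classes}


def roc_compare(
    scores_by_method: dict[str, np.ndarray],
    labels: np.ndarray,
    positive: str = "spike",
) -> dict[str, dict]:
    """ROC points (threshold sweep) and trapezoid areas per method."""
    y = np.asarray(labels, dtype=object) == positive
    if y.all() or not y.any():
        raise ValueError("ROC needs both positive and negative labels")
    out = {}
    for method, scores in scores_by_method.items():
        fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
        out[method] = {
            "fpr": fpr,
            "tpr": tpr,
            "thresholds": thr,
            "auc": float(np.trapezoid(tpr, fpr)),
        }
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    variant: str = "ga_svm",
    ga_config: GaConfig | None = None,
    svm_config: SvmConfig | None = None,
) -> pd.DataFrame:
    """Stratified k-fold evaluation of a classifier variant.

    Feature selection (for the ``ga_svm`` variant) runs inside each training
    fold.  Returns one row per (fold, class) with Acc/Sen/Spe, plus the
    stored fold predictions for recounting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} members; "
            f"use k <= {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(cv.split(X, y)):
        if variant == "ga_svm":
            ga = ga_config or GaConfig(population=20, max_generations=10,
                                       plateau_patience=3, seed=seed)
            model = ga_select(X[tr], y[tr], ga, svm_config)
        elif variant == "svm":
            model = train_svm(X[tr], y[tr], svm_config, seed=seed)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        pred, _ = predict(model, X[te])
        for c in classes:
            m = metrics(confusion(y[te], pred, str(c)))
            rows.append(
                {
                    "fold": fold,
                    "class": c,
                    "accuracy": m["accuracy"],
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "n_test": len(te),
                    "test_indices": tuple(int(i) for i in te),
                    "predictions": tuple(str(p) for p in pred),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    use_ga: bool = True
    use_spike_matching: bool = True
    train_fraction: float = 0.5
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    ga_config: GaConfig | None = None
    svm_config: SvmConfig = field(default_factory=SvmConfig)
    spm_config: SpikeMatchConfig = field(default_factory=SpikeMatchConfig)
    wavelet_denoise: bool = True


@dataclass
class PipelineReport:
    kept_indices: np.ndarray
    test_indices: np.ndarray
    true_labels: np.ndarray            # test epochs
    classifier_labels: np.ndarray      # test epochs, SVM output
    final_labels: np.ndarray           # after follow-up screening
    metrics_classifier: dict
    metrics_final: dict
    roc: dict
    manifest: dict
    models: dict


def _assert_metric_identity(table: ConfusionTable) -> None:
    m = metrics(table)
    p = table.tp + table.fn
    n = table.tn + table.fp
    if p and n:
        lhs = m["accuracy"]
        rhs = (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
        assert abs(lhs - rhs) < 1e-12


def run_pipeline(
    recording: EegRecording,
    truth: GroundTruth,
    config: PipelineConfig | None = None,
    montage: MontageSpec | None = None,
) -> PipelineReport:
    """Preprocess -> features -> train/predict -> spike matching -> report.

    The surviving epochs are split in time: the first ``train_fraction`` of
    them train the classifier, the remainder forms the time-ordered test
    stream on which follow-up screening runs.  Identical inputs and config
    produce identical reports.
    """
    cfg = config or PipelineConfig()
    montage = montage or default_montage()
    uni, bip = make_epoch_pairs(
        recording, montage, truth_labels=truth.labels,
        wavelet_denoise=cfg.wavelet_denoise,
    )
    if not uni:
        return PipelineReport(
            kept_indices=np.array([], dtype=int),
            test_indices=np.array([], dtype=int),
            true_labels=np.array([], dtype=object),
            classifier_labels=np.array([], dtype=object),
            final_labels=np.array([], dtype=object),
            metrics_classifier={},
            metrics_final={},
            roc={},
            manifest={"warning": "no epochs survived artifact rejection"},
            models={},
        )
    X, names, idxs, y = extract_feature_matrix(
        uni, bip, cfg.feature_config, montage
    )
    n_train = int(round(cfg.train_fraction * len(idxs)))
    # extend the temporal split until every class has at least two training
    # members (CV fitness needs two); the stream order is preserved
    classes_present = np.unique(y)
    while n_train < len(idxs) - 1 and any(
        np.sum(y[:n_train] == c) < 2 for c in classes_present
    ):
        n_train += 1
    tr = slice(0, n_train)
    te = slice(n_train, None)
    ga = cfg.ga_config or GaConfig(
        population=20, max_generations=10, plateau_patience=3, seed=cfg.seed
    )
    svm_model = train_svm(X[tr], y[tr], cfg.svm_config, seed=cfg.seed,
                          feature_names=names)
    if cfg.use_ga:
        model = ga_select(X[tr], y[tr], ga, cfg.svm_config, feature_names=names)
    else:
        model = svm_model

    clf_labels, scores = predict(model, X[te])
    svm_labels, svm_scores = predict(svm_model, X[te])
    y_test = y[te]

    if cfg.use_spike_matching:
        final_labels, fired, _ = followup_screen(
            bip[n_train:], clf_labels, montage, cfg.spm_config
        )
    else:
        final_labels, fired = clf_labels.copy(), np.zeros(len(clf_labels), bool)

    metrics_clf = per_class_metrics(y_test, clf_labels)
    metrics_fin = per_class_metrics(y_test, final_labels)
    for y_pred in (clf_labels, final_labels):
        for c in ("normal", "spike", "seizure"):
            _assert_metric_identity(confusion(y_test, y_pred, c))

    roc = {}
    if ("spike" in set(y_test)) and len(set(y_test)) > 1:
        spike_svm = class_score(svm_model, svm_scores, "spike")
        spike_model = class_score(model, scores, "spike")
        promoted = spike_model.copy()
        promoted[fired] = max(promoted.max(), 0.0) + 1.0
        roc = roc_compare(
            {
                "svm": spike_svm,
                "ga_svm": spike_model,
                "ga_svm_spm": promoted,
            },
            y_test,
            positive="spike",
        )

    manifest = {
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "versions": {
            "eegdetect": _pkg_version,
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
        },
        "feature_name_hash": feature_name_hash(names),
        "n_epochs_kept": int(len(idxs)),
        "n_train": int(n_train),
    }
    return PipelineReport(
        kept_indices=idxs,
        test_indices=idxs[te],
        true_labels=y_test,
        classifier_labels=clf_labels,
        final_labels=final_labels,
        metrics_classifier=metrics_clf,
        metrics_final=metrics_fin,
        roc=roc,
        manifest=manifest,
        models={"selected": model, "svm_only": svm_model},
    )
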