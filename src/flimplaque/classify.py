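"""Random-forest plaque component classification and burden quantitation.

A random forest maps the three-feature readout (ch.1 FL, ch.2 FL, IR1) of
every A-line location to one of the five component classes. Evaluation is
by ROI-grouped k-fold cross-validation (whole ROIs move between folds so
that neighbouring locations of one ROI never straddle the train/test
split), with a confusion matrix, per-class sensitivity/specificity and
one-vs-rest ROC analysis computed from the out-of-fold probabilities. The
compositional burden index summarizes a classified segment as the
percentage of valid locations assigned to each class (0-100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedGroupKFold

from .core import CLASS_LABELS, CLASS_ORDER, CLASSIFIER_FEATURES, ComponentClass
from .processing import PullbackReadouts

__all__ = [
    "RfcConfig",
    "RfcModel",
    "CvReport",
    "ClassificationMap",
    "train_rfc",
    "cross_validate",
    "classify_pullback",
    "burden_index",
]

UNCLASSIFIED = -1


@dataclass(frozen=True)
class RfcConfig:
    """Forest hyperparameters; the seed is mandatory for reproducibility."""

    n_trees: int = 100
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    seed: int = 0


@dataclass
class RfcModel:
    """A trained forest plus its immutable feature/class contract."""

    forest: RandomForestClassifier
    features: tuple[str, ...]
    class_order: tuple[str, ...]
    config: RfcConfig
    n_training_rows: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in the fixed class order."""
        proba = self.forest.predict_proba(x)
        order = [list(self.forest.classes_).index(c) for c in self.class_order]
        return proba[:, order]


def _design_matrix(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = features[list(CLASSIFIER_FEATURES)].to_numpy(dtype=float)
    y = features["label"].to_numpy()
    keep = np.isfinite(x).all(axis=1)
    groups = features["roi_id"].to_numpy() if "roi_id" in features else np.arange(len(features))
    return x[keep], y[keep], groups[keep]


def train_rfc(features: pd.DataFrame, config: RfcConfig | None = None) -> RfcModel:
    """Train the 5-class forest on a location-level feature table.

    All five component classes must be present in the training data.
    """
    config = config if config is not None else RfcConfig()
    x, y, _ = _design_matrix(features)
    missing = sorted(set(CLASS_LABELS) - set(np.unique(y)))
    if missing:
        raise ValueError(f"training data lacks classes: {missing}")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    ).fit(x, y)
    return RfcModel(forest, CLASSIFIER_FEATURES, CLASS_LABELS, config, len(x))


@dataclass
class CvReport:
    """Cross-validation evaluation of the classifier.

    The confusion matrix has truth on rows and prediction on columns, in
    the fixed class order. Sensitivities/specificities are one-vs-rest
    percentages; ROC curves are computed from out-of-fold probabilities.
    ``roi_accuracy`` scores majority-vote predictions per ROI.
    """

    confusion: np.ndarray  # (5, 5) counts
    accuracy: float  # fraction of locations
    sensitivity: dict[str, float]  # percent
    specificity: dict[str, float]  # percent
    auc: dict[str, float]
    macro_auc: float
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    fold_of_roi: dict[int, int]
    roi_accuracy: float
    n_locations: int
    seed: int

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy


def _per_class_rates(cm: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
    total = cm.sum()
    sens, spec = {}, {}
    for i, name in enumerate(CLASS_LABELS):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[name] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec[name] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def cross_validate(
    features: pd.DataFrame,
    k: int = 5,
    config: RfcConfig | None = None,
    seed: int | None = None,
) -> CvReport:
    """ROI-grouped k-fold cross-validation of the 5-class forest.

    Folds are stratified by class at the ROI level; every class must
    contribute at least ``k`` ROIs so that each fold can hold one.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    config = config if config is not None else RfcConfig()
    seed = config.seed if seed is None else seed
    x, y, groups = _design_matrix(features)
    missing = sorted(set(CLASS_LABELS) - set(np.unique(y)))
    if missing:
        raise ValueError(f"dataset lacks classes: {missing}")
    roi_label = pd.Series(y).groupby(groups).first()
    starved = sorted(roi_label.value_counts()[lambda s: s < k].index)
    if starved:
        raise ValueError(f"fewer ROIs than folds for classes: {starved}")

    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_pred = np.empty(len(y), dtype=object)
    oof_proba = np.zeros((len(y), len(CLASS_LABELS)))
    fold_of_roi: dict[int, int] = {}
    for fold, (tr, te) in enumerate(splitter.split(x, y, groups)):
        fold_cfg = RfcConfig(config.n_trees, config.max_depth, config.max_features, seed)
        model = train_rfc(
            pd.DataFrame(x[tr], columns=list(CLASSIFIER_FEATURES)).assign(
                label=y[tr], roi_id=groups[tr]
            ),
            fold_cfg,
        )
        oof_proba[te] = model.predict_proba(x[te])
        oof_pred[te] = np.array(CLASS_LABELS)[np.argmax(oof_proba[te], axis=1)]
        for g in np.unique(groups[te]):
            fold_of_roi[int(g)] = fold

    cm = confusion_matrix(y, oof_pred.astype(str), labels=list(CLASS_LABELS))
    accuracy = float(np.trace(cm) / cm.sum())
    sens, spec = _per_class_rates(cm)

    aucs, curves = {}, {}
    for i, name in enumerate(CLASS_LABELS):
        fpr, tpr, _ = roc_curve((y == name).astype(int), oof_proba[:, i])
        curves[name] = (fpr, tpr)
        aucs[name] = float(auc(fpr, tpr))
    macro_auc = float(np.mean(list(aucs.values())))

    roi_df = pd.DataFrame({"roi": groups, "truth": y, "pred": oof_pred.astype(str)})
    per_roi = roi_df.groupby("roi").agg(
        truth=("truth", "first"), pred=("pred", lambda s: s.mode().iat[0])
    )
    roi_accuracy = float((per_roi["truth"] == per_roi["pred"]).mean())

    return CvReport(
        confusion=cm,
        accuracy=accuracy,
        sensitivity=sens,
        specificity=spec,
        auc=aucs,
        macro_auc=macro_auc,
        roc_curves=curves,
        fold_of_roi=fold_of_roi,
        roi_accuracy=roi_accuracy,
        n_locations=len(y),
        seed=seed,
    )


@dataclass
class ClassificationMap:
    """Per-location predicted class of a pullback.

    ``classes`` holds indices into the fixed class order, -1 where the
    location was invalid and left unclassified; ``proba`` the per-location
    class-probability vectors (NaN rows where unclassified).
    """

    classes: np.ndarray  # (F, L) int8
    proba: np.ndarray  # (F, L, 5)

    @property
    def n_frames(self) -> int:
        return self.classes.shape[0]

    def class_name(self, frame: int, location: int) -> str | None:
        idx = self.classes[frame, location]
        return None if idx == UNCLASSIFIED else CLASS_LABELS[idx]


def classify_pullback(model: RfcModel, readouts: PullbackReadouts) -> ClassificationMap:
    """Classify every valid location of a pullback."""
    F, L = readouts.valid.shape
    x = np.stack(
        [readouts.feature(name).reshape(-1) for name in model.features], axis=-1
    )
    ok = readouts.valid.reshape(-1) & np.isfinite(x).all(axis=1)
    proba = np.full((F * L, len(CLASS_LABELS)), np.nan)
    classes = np.full(F * L, UNCLASSIFIED, dtype=np.int8)
    if ok.any():
        p = model.predict_proba(x[ok])
        proba[ok] = p
        classes[ok] = np.argmax(p, axis=1)
    return ClassificationMap(classes.reshape(F, L), proba.reshape(F, L, -1))


def burden_index(cmap: ClassificationMap) -> dict[str, float]:
    """Compositional burden index: percent of valid locations per class.

    The five percentages are taken over the classified locations of the
    whole scanned segment (normal wall counts as a class) and sum to 100.
    """
    flat = cmap.classes.reshape(-1)
    valid = flat != UNCLASSIFIED
    if not valid.any():
        raise ValueError("no validly classified locations in the map")
    counts = np.bincount(flat[valid], minlength=len(CLASS_ORDER))
    pct = 100.0 * counts / valid.sum()
    return {name: float(p) for name, p in zip(CLASS_LABELS, pct)}
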