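"""Spectral feature extraction, gradient-boosted classification, and
patient-grouped k-fold evaluation.

One sample = one lesion image.  Features summarise the distribution of the
PCA scores of the per-pixel reconstructed spectra inside the lesion mask
(mean, standard deviation, and 10/50/90th percentiles of each of the 12
components: a 60-dimensional vector).  Classification is a 4-class
gradient-boosted tree ensemble (XGBoost).  Evaluation uses k-fold
cross-validation grouped by patient — a patient never contributes images
to both the training and the test side of a fold, the leakage guard that
image-level folding would violate.

Reported metrics are macro one-vs-rest sensitivity, specificity, F1 and
ROC-AUC, pooled over folds (per-fold values and mean-of-fold aggregates
are also emitted), plus the pooled confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .errors import EmptyRegionError, ValidationError
from .image_pipeline import LesionMask
from .spectral_model import SpectralBasis
from .synthetic_data import CLASSES

FEATURE_STATS = ("mean", "std", "p10", "p50", "p90")


@dataclass
class LesionSample:
    features: np.ndarray
    label: str
    patient_id: str
    image_id: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("features must be finite")
        if self.label not in CLASSES:
            raise ValidationError(f"unknown label {self.label!r}")


def extract_features(
    cube: np.ndarray, mask: LesionMask, basis: SpectralBasis
) -> np.ndarray:
    """Aggregate per-pixel PCA scores over the masked region.

    Each masked pixel's spectrum (minus the basis mean) is projected onto
    the components; the score distribution is summarised per component by
    mean, std and the 10/50/90th percentiles, giving n_components x 5
    features in stat-major order [means | stds | p10s | p50s | p90s].
    """
    arr = np.asarray(cube, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != basis.EV.shape[0]:
        raise ValidationError("cube must be H x W x 401")
    if mask.shape != arr.shape[:2]:
        raise ValidationError("mask dimensions must match the cube")
    pixels = arr[mask.grid]
    pixels = pixels[~np.isnan(pixels).any(axis=1)]
    if pixels.shape[0] == 0:
        raise EmptyRegionError("mask selects no valid pixels")
    scores = (pixels - basis.mean_spectrum) @ basis.EV  # n_pix x k
    pct = np.percentile(scores, (10, 50, 90), axis=0)
    return np.concatenate(
        [scores.mean(axis=0), scores.std(axis=0), pct[0], pct[1], pct[2]]
    )


def make_group_folds(
    samples: Sequence[LesionSample], k: int, seed: int
) -> dict[str, int]:
    """Partition patients (not images) into k folds of near-equal size.

    Returns a patient_id -> fold index map; counts differ by at most one
    and the assignment is deterministic for a fixed seed.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    patients = sorted({s.patient_id for s in samples})
    if k > len(patients):
        raise ValidationError(f"k={k} exceeds the {len(patients)} distinct patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignment: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignment[patients[idx]] = fold
    return assignment


@dataclass(frozen=True)
class BoostingParams:
    """XGBoost hyperparameters; the defaults are artifact decisions
    (moderate depth, a few hundred trees, fixed seed), not tuned values."""

    n_estimators: int = 300
    max_depth: int = 4
    learning_rate: float = 0.1
    subsample: float = 0.9
    reg_lambda: float = 1.0
    seed: int = 0


def train_classifier(
    samples: Sequence[LesionSample], params: BoostingParams | None = None
):
    """Fit a gradient-boosted tree ensemble emitting class probabilities.

    Returns (model, class_names): ``model.predict_proba`` columns follow
    ``class_names`` (canonical order restricted to the classes present).
    """
    if params is None:
        params = BoostingParams()
    labels = [s.label for s in samples]
    present = [c for c in CLASSES if c in set(labels)]
    if len(present) < 2:
        raise ValidationError("training set must contain at least 2 classes")
    X = np.vstack([s.features for s in samples])
    y = np.array([present.index(lab) for lab in labels])
    model = XGBClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        subsample=params.subsample,
        reg_lambda=params.reg_lambda,
        objective="multi:softprob",
        random_state=params.seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X, y)
    return model, present


def per_class_metrics(confusion: np.ndarray) -> dict[str, np.ndarray]:
    """One-vs-rest sensitivity, specificity and F1 per class from a
    confusion matrix (rows = truth, columns = prediction)."""
    cm = np.asarray(confusion, dtype=float)
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        prec = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        f1 = np.where(
            np.nan_to_num(prec) + np.nan_to_num(sens) > 0,
            2 * prec * sens / (prec + sens),
            0.0,
        )
    return {"sensitivity": sens, "specificity": spec, "f1": f1}


@dataclass
class CVReport:
    """Patient-grouped cross-validation results."""

    k: int
    classes: list
    per_fold: list  # one metric dict per fold
    aggregate: dict  # pooled-over-folds macro metrics
    fold_means: dict  # mean-of-fold macro metrics
    confusion: np.ndarray  # pooled, rows = truth in `classes` order
    fold_assignment: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "classes": self.classes,
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
            "fold_means": self.fold_means,
            "confusion": self.confusion.tolist(),
            "fold_assignment": self.fold_assignment,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def run_cross_validation(
    samples: Sequence[LesionSample],
    k: int,
    seed: int = 0,
    params: BoostingParams | None = None,
) -> CVReport:
    """Patient-grouped k-fold CV with pooled macro one-vs-rest metrics.

    Folds with a class entirely absent are still scored on the remaining
    classes; that class's fold-level AUC is undefined and excluded from the
    fold's mean.  The pooled aggregate is unaffected.
    """
    samples = list(samples)
    assignment = make_group_folds(samples, k, seed)
    classes = [c for c in CLASSES if c in {s.label for s in samples}]
    n_classes = len(classes)

    X = np.vstack([s.features for s in samples])
    y = np.array([classes.index(s.label) for s in samples])
    folds = np.array([assignment[s.patient_id] for s in samples])

    pooled_proba = np.zeros((len(samples), n_classes))
    pooled_pred = np.zeros(len(samples), dtype=int)
    per_fold = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        train_patients = {s.patient_id for s, t in zip(samples, train) if t}
        test_patients = {s.patient_id for s, t in zip(samples, test) if t}
        assert not (train_patients & test_patients), "patient leakage across folds"
        if not np.any(test):
            continue
        model, present = train_classifier(
            [s for s, t in zip(samples, train) if t], params
        )
        proba_present = model.predict_proba(X[test])
        proba = np.zeros((int(test.sum()), n_classes))
        for j, cls in enumerate(present):
            proba[:, classes.index(cls)] = proba_present[:, j]
        pooled_proba[test] = proba
        pred = np.array([classes.index(present[i]) for i in proba_present.argmax(axis=1)])
        pooled_pred[test] = pred

        cm = _sk_confusion(y[test], pred, labels=range(n_classes))
        metrics = per_class_metrics(cm)
        aucs = _safe_ovr_auc(y[test], proba, n_classes)
        per_fold.append(
            {
                "fold": fold,
                "n_test": int(test.sum()),
                "sensitivity": float(np.nanmean(metrics["sensitivity"])),
                "specificity": float(np.nanmean(metrics["specificity"])),
                "f1": float(np.nanmean(metrics["f1"])),
                "roc_auc": float(np.nanmean(aucs)) if np.any(~np.isnan(aucs)) else None,
            }
        )

    confusion = _sk_confusion(y, pooled_pred, labels=range(n_classes))
    pooled = per_class_metrics(confusion)
    aggregate = {
        "sensitivity": float(np.nanmean(pooled["sensitivity"])),
        "specificity": float(np.nanmean(pooled["specificity"])),
        "f1": float(np.nanmean(pooled["f1"])),
        "roc_auc": float(
            roc_auc_score(y, pooled_proba, multi_class="ovr", average="macro")
        ),
    }
    fold_means = {
        key: float(np.mean([f[key] for f in per_fold if f[key] is not None]))
        for key in ("sensitivity", "specificity", "f1", "roc_auc")
    }
    return CVReport(
        k=k,
        classes=classes,
        per_fold=per_fold,
        aggregate=aggregate,
        fold_means=fold_means,
        confusion=confusion,
        fold_assignment=assignment,
    )


def _safe_ovr_auc(y_true: np.ndarray, proba: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class one-vs-rest AUC; NaN where the fold lacks a class."""
    out = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = y_true == c
        if pos.any() and (~pos).any():
            out[c] = roc_auc_score(pos.astype(int), proba[:, c])
    return out


# ---------------------------------------------------------------------------
# Dataset-to-samples pipeline


def samples_from_dataset(
    dataset,
    calib,
    basis: SpectralBasis,
    use_truth_masks: bool = True,
    params=None,
) -> list[LesionSample]:
    """Turn rendered lesion images into feature samples.

    Masks come from the dataset ground truth (default) or from the
    stand-in segmenter.  Images with an empty mask (normal skin) fall back
    to a centred elliptical region — normal skin is still classified, just
    without a lesion to delineate.
    """
    from .image_pipeline import image_to_cube, segment_lesion

    out = []
    for item in dataset:
        if use_truth_masks:
            mask = LesionMask(item.mask)
        else:
            mask = segment_lesion(item.image, params)
        if not mask.grid.any():
            mask = LesionMask(_central_region(item.image.shape[:2]))
        cube = image_to_cube(item.image, calib, basis, mask=mask)
        feats = extract_features(cube, mask, basis)
        out.append(
            LesionSample(
                features=feats,
                label=item.label,
                patient_id=item.patient_id,
                image_id=item.image_id,
            )
        )
    return out


def _central_region(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - h / 2) / (0.3 * h)) ** 2 + ((xx - w / 2) / (0.3 * w)) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# Sample-table I/O


def samples_to_csv(path, samples: Sequence[LesionSample]) -> None:
    rows = []
    for s in samples:
        row = {"image_id": s.image_id, "patient_id": s.patient_id, "label": s.label}
        row.update({f"feature_{i}": v for i, v in enumerate(s.features)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def samples_from_csv(path) -> list[LesionSample]:
    table = pd.read_csv(path)
    feature_cols = [c for c in table.columns if c.startswith("feature_")]
    feature_cols.sort(key=lambda c: int(c.split("_")[1]))
    return [
        LesionSample(
            features=row[feature_cols].to_numpy(dtype=float),
            label=row["label"],
            patient_id=str(row["patient_id"]),
            image_id=str(row["image_id"]),
        )
        for _, row in table.iterrows()
    ]
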