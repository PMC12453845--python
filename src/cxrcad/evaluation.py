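"""Confusion-matrix metrics, grouped stratified k-fold CV, and the
end-to-end cross-validated pipeline.

The positive class is ``cancer``. The five reported scores are

* accuracy    = (TP + TN) / (TP + TN + FP + FN)
* sensitivity = TP / (TP + FN)            (recall)
* specificity = TN / (TN + FP)
* precision   = TP / (TP + FP)
* F1          = 2 * precision * sensitivity / (precision + sensitivity)

Folds partition *images* (stratified by label, 10 folds by default) and
every patch follows its parent image, so overlapping patches of one
radiograph can never appear on both sides of a split. Patch predictions
are aggregated into one diagnosis per radiograph (mean softmax
probability by default; majority vote available; ties resolve to
cancer) and metrics are reported at both the patch level and the
full-image level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import AggregationError, ValidationError
from .image_io import ChestImage, Manifest
from .model_zoo import (
    LABEL_TO_INT,
    ModelConfig,
    TrainConfig,
    build_baseline,
    build_custom_cnn,
    train_classifier,
)
from .patching import PatchConfig, extract_patches, resize_to_working
from .selection import SelectionConfig, select_patches, threshold_select

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    degenerate: bool = False  # True when any 0/0 was replaced by the 0 sentinel

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with ``cancer`` as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValidationError(f"length mismatch: {len(y_true)} truths vs {len(y_pred)} predictions")
    t = np.array([LABEL_TO_INT[str(v).lower()] for v in y_true])
    p = np.array([LABEL_TO_INT[str(v).lower()] for v in y_pred])
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Derive the five scores from a confusion matrix.

    Any 0/0 ratio (e.g. precision with no predicted positives) yields a
    0 sentinel and sets the ``degenerate`` flag instead of raising, so
    fold aggregation never crashes.
    """
    if cm.total < 1:
        raise ValidationError("confusion matrix is empty")
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = ratio(cm.tp, cm.tp + cm.fn)
    specificity = ratio(cm.tn, cm.tn + cm.fp)
    precision = ratio(cm.tp, cm.tp + cm.fp)
    if precision + sensitivity == 0:
        degenerate = True
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return Metrics(accuracy, sensitivity, specificity, precision, f1, degenerate)


def grouped_stratified_kfold(
    manifest: Manifest, k: int = 10, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Partition image ids into k label-stratified folds.

    Every id lands in exactly one validation fold; per-fold class
    counts differ from perfect proportionality by at most one image.
    Grouping is inherent: the split is at image level and all patches
    of an image follow it. Deterministic given ``seed``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    ids = np.array(manifest.ids)
    labels = np.array(manifest.labels)
    counts = manifest.label_counts()
    if min(counts.values()) < k:
        raise ValidationError(f"need at least {k} images per class, have {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (list(ids[tr]), list(ids[va]))
        for tr, va in skf.split(np.zeros(len(ids)), labels)
    ]


def aggregate_image(patch_probs: Sequence[float], rule: str = "mean") -> tuple[float, str]:
    """Fuse patch-level cancer probabilities into one image diagnosis.

    ``mean``: average probability, cancer iff >= 0.5. ``majority``:
    cancer iff cancer votes (prob >= 0.5) are at least as many as
    normal votes. Ties resolve to cancer (the clinically safer call).
    """
    probs = np.asarray(patch_probs, dtype=float)
    if probs.size == 0:
        raise AggregationError("image has no patch predictions to aggregate")
    if rule == "mean":
        p = float(probs.mean())
        return p, "cancer" if p >= 0.5 else "normal"
    if rule == "majority":
        votes = int((probs >= 0.5).sum())
        label = "cancer" if votes >= probs.size - votes else "normal"
        return float(probs.mean()), label
    raise ValidationError(f"unknown aggregation rule {rule!r}")


@dataclass
class CVReport:
    """Per-fold and summary metrics of one cross-validation run."""

    fold_patch_metrics: list[Metrics]
    fold_image_metrics: list[Metrics]
    config: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @staticmethod
    def _summarize(folds: list[Metrics]) -> dict[str, dict[str, float]]:
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([getattr(m, name) for m in folds], dtype=float)
            out[name] = {
                "mean": float(vals.mean()),
                "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        return out

    @property
    def patch_summary(self) -> dict[str, dict[str, float]]:
        return self._summarize(self.fold_patch_metrics)

    @property
    def image_summary(self) -> dict[str, dict[str, float]]:
        return self._summarize(self.fold_image_metrics)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "folds": {
                "patch": [m.as_dict() for m in self.fold_patch_metrics],
                "image": [m.as_dict() for m in self.fold_image_metrics],
            },
            "summary": {"patch": self.patch_summary, "image": self.image_summary},
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def metrics_rows(self) -> list[dict]:
        rows = []
        for level, folds in (("patch", self.fold_patch_metrics), ("image", self.fold_image_metrics)):
            for i, m in enumerate(folds):
                rows.append({"fold": i, "level": level, **m.as_dict()})
        return rows


def _prepare_images(
    images: Sequence[ChestImage],
    patch_config: PatchConfig,
    selection: str,
    selection_config: SelectionConfig,
):
    """Patch + select every image once (extraction is fold-independent).

    Returns per-image dicts with the retained and pre-selection patch
    stacks; an image whose selection removed every patch falls back to
    its pre-selection patches with a warning (no silent drop).
    """
    prepared, warnings = {}, []
    for image in images:
        working = resize_to_working(image, patch_config.working_resolution)
        patches = extract_patches(image, patch_config)
        if selection == "ttest":
            retained, _ = select_patches(patches, lambda _pid: working.mask, selection_config)
        elif selection == "threshold":
            retained = threshold_select(patches)
        elif selection == "none":
            retained = patches
        else:
            raise ValidationError(f"unknown selection mode {selection!r}")
        if not retained:
            warnings.append(f"{image.id}: selection removed all patches; using pre-selection set")
            retained = patches
        prepared[image.id] = {
            "label": image.label,
            "pixels": np.stack([p.pixels for p in retained]).astype(np.float32),
        }
    return prepared, warnings


def _build_model(arch: str, model_config: ModelConfig, seed: int):
    if arch == "custom":
        return build_custom_cnn(model_config, seed=seed)
    return build_baseline(arch, model_config.input_size, model_config.n_classes, seed=seed)


def _calibration_split(train_ids, labels, seed, fraction=0.2):
    """Stratified split of the training fold into fit/calibration ids."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA11)))
    fit_ids, cal_ids = [], []
    for label in ("cancer", "normal"):
        ids = sorted(i for i in train_ids if labels[i] == label)
        perm = rng.permutation(len(ids))
        n_cal = max(1, int(round(fraction * len(ids))))
        cal_ids += [ids[j] for j in perm[:n_cal]]
        fit_ids += [ids[j] for j in perm[n_cal:]]
    return fit_ids, cal_ids


def _calibrate_decision_bias(models, prepared, cal_ids, position: float = 0.3) -> float:
    """Choose a cancer-logit offset that centers the decision boundary
    between the two classes' image-mean probabilities.

    The boundary is placed ``position`` of the way from the normal-side
    mean toward the cancer-side mean. The cancer side is left-skewed
    (images differ in how many patches their nodule reaches) while the
    normal side is tight, so a screening-oriented boundary sits nearer
    the normal mode; 0.3 is the operating point used by the synthetic
    benchmarks. Uses calibration images held out of model fitting (but
    inside the training fold), so the validation fold is untouched.
    Returns the offset; callers apply it to each model's final-layer
    bias.
    """
    zdiffs, labels = [], []
    for iid in cal_ids:
        probs = np.stack([m.predict(prepared[iid]["pixels"])[:, 1] for m in models])
        p = np.clip(probs, 1e-6, 1 - 1e-6)
        zdiffs.append(np.log(p / (1 - p)))  # (n_models, n_patches)
        labels.append(prepared[iid]["label"])
    grid = np.linspace(-3.0, 3.0, 241)
    best_b, best_gap = 0.0, np.inf
    for b in grid:
        means = np.array([(1 / (1 + np.exp(-(z + b)))).mean() for z in zdiffs])
        mc = means[[lab == "cancer" for lab in labels]].mean()
        mn = means[[lab == "normal" for lab in labels]].mean()
        gap = abs(mn + position * (mc - mn) - 0.5)
        if gap < best_gap:
            best_gap, best_b = gap, float(b)
    return best_b


def cross_validate(
    images: Sequence[ChestImage],
    patch_config: PatchConfig | None = None,
    selection_config: SelectionConfig | None = None,
    model_config: ModelConfig | None = None,
    hyper: TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
    selection: str = "ttest",
    arch: str = "custom",
    aggregation: str = "mean",
    ensemble: int = 1,
    calibrate: bool = False,
) -> CVReport:
    """Grouped stratified k-fold evaluation of the full pipeline.

    For each fold: extract overlapping patches, select them (t-test,
    thresholding, or none), train a fresh classifier on the training
    images' patches, predict the validation patches, and score at both
    the patch level and the aggregated full-image level.

    ``ensemble`` > 1 trains that many classifiers per fold from
    different derived seeds and averages their predicted probabilities
    — a variance-reduction device for small training sets.

    ``calibrate`` holds out a stratified 20% of each training fold's
    images from model fitting and uses them to center the decision:
    the final-layer cancer bias is offset so the midpoint between the
    two classes' image-mean probabilities lands on the fixed 0.5
    threshold. The validation fold plays no part in the calibration.
    """
    patch_config = patch_config or PatchConfig()
    selection_config = selection_config or SelectionConfig()
    model_config = model_config or ModelConfig()
    hyper = hyper or TrainConfig()
    if model_config.input_size != patch_config.patch_size:
        raise ValidationError(
            f"model input_size {model_config.input_size} != patch_size {patch_config.patch_size}"
        )

    from .image_io import images_from_manifest, manifest_from_images

    if isinstance(images, Manifest):
        images = images_from_manifest(images)
    manifest = manifest_from_images(images)
    manifest.validate()
    prepared, warnings = _prepare_images(images, patch_config, selection, selection_config)
    folds = grouped_stratified_kfold(manifest, k=k, seed=seed)

    from dataclasses import replace as _replace

    label_by_id = {im.id: im.label for im in images}
    fold_patch, fold_image = [], []
    for fold_idx, (train_ids, val_ids) in enumerate(folds):
        fit_ids = train_ids
        cal_ids: list[str] = []
        if calibrate:
            fit_ids, cal_ids = _calibration_split(train_ids, label_by_id, seed)
        x_train = np.concatenate([prepared[i]["pixels"] for i in fit_ids])
        y_train = np.concatenate(
            [[prepared[i]["label"]] * len(prepared[i]["pixels"]) for i in fit_ids]
        )
        models = []
        for member in range(ensemble):
            fold_seed = int(
                np.random.SeedSequence((seed, fold_idx, member)).generate_state(1)[0] % (2**31)
            )
            model = _build_model(arch, model_config, seed=fold_seed)
            model, _history = train_classifier(
                model, x_train, y_train, _replace(hyper, seed=fold_seed)
            )
            models.append(model)

        if calibrate and cal_ids:
            offset = _calibrate_decision_bias(models, prepared, cal_ids)
            for model in models:
                final = model.network.layers[-1]
                final.params["b"][1] += offset / 2
                final.params["b"][0] -= offset / 2
            logger.info("fold %d: decision-bias offset %.3f", fold_idx + 1, offset)

        patch_true, patch_pred, img_true, img_pred = [], [], [], []
        for iid in val_ids:
            probs = np.mean(
                [m.predict(prepared[iid]["pixels"])[:, 1] for m in models], axis=0
            )
            label = prepared[iid]["label"]
            patch_true += [label] * len(probs)
            patch_pred += ["cancer" if p >= 0.5 else "normal" for p in probs]
            _, img_label = aggregate_image(probs, rule=aggregation)
            img_true.append(label)
            img_pred.append(img_label)
        fold_patch.append(compute_metrics(confusion(patch_true, patch_pred)))
        fold_image.append(compute_metrics(confusion(img_true, img_pred)))
        logger.info(
            "fold %d/%d: patch acc %.3f, image acc %.3f",
            fold_idx + 1, k, fold_patch[-1].accuracy, fold_image[-1].accuracy,
        )

    config = {
        "k": k,
        "seed": seed,
        "selection": selection,
        "arch": arch,
        "aggregation": aggregation,
        "ensemble": ensemble,
        "calibrate": calibrate,
        "patching": patch_config.__dict__.copy(),
        "selection_config": selection_config.__dict__.copy(),
        "model": {**model_config.__dict__},
        "training": hyper.__dict__.copy(),
    }
    return CVReport(fold_patch, fold_image, config=config, warnings=warnings)
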