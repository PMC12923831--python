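"""Nested cross-validated classification of texture feature maps.

Subjects with versus without subtle visual dysfunctions (VisDys+/VisDys-)
are discriminated from their texture feature maps with a compact 3D
convolutional network.  Generalization is estimated by nested
cross-validation: stratified outer folds give held-out test sets, and within
every outer training set an inner cross-validation selects hyperparameters,
so no selection step ever sees outer test data.  The headline metric is
balanced accuracy, BAC = (sensitivity + specificity)/2, robust to class
imbalance.  A frozen "winner" model (the most frequently selected
hyperparameters, refit on all data) can then be applied unchanged to an
independent validation cohort.
"""

from __future__ import annotations

import collections
import itertools
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .texture import TextureFeatureMap

__all__ = [
    "ClassificationMetrics",
    "CVResult",
    "TextureClassifier",
    "balanced_accuracy",
    "balanced_accuracy_from_rates",
    "metrics_from_predictions",
    "nested_cv_train",
    "external_validate",
    "DEFAULT_ARCHITECTURE",
    "DEFAULT_HYPER_GRID",
]

logger = logging.getLogger(__name__)

#: Compact default network shape: two conv-pool blocks, global average
#: pooling and a two-way dense read-out, preceded by an average-pooling stem
#: that brings near-voxel-resolution feature maps down to a tractable grid.
#: :func:`adaptive_architecture` instantiates it for a concrete input size.
DEFAULT_ARCHITECTURE = (
    ("avgpool", {"factor": 4}),
    ("conv", {"c_in": 1, "c_out": 4, "kernel_size": 3}),
    ("relu", {}),
    ("avgpool", {"factor": 2}),
    ("conv", {"c_in": 4, "c_out": 8, "kernel_size": 3}),
    ("relu", {}),
    ("gap", {}),
    ("dense", {"n_in": 8, "n_out": 2}),
)


def adaptive_architecture(input_shape) -> tuple:
    """The default two-block conv net sized for a given map grid.

    The stem pool factor is chosen so the pooled grid lands around 8-12
    voxels per axis; kernel sizes shrink near the lower limit so every layer
    keeps a positive spatial extent.  Grids of at least 5³ are supported.
    """
    m = min(int(n) for n in input_shape)
    if m < 5:
        raise ValueError(f"feature-map grid {tuple(input_shape)} too small "
                         "for the convolutional default (need >= 5 per axis)")
    f = max(1, m // 8)
    s = m // f
    k1 = 3
    s = s - k1 + 1          # after first conv
    s2 = s // 2             # after second pool
    k2 = min(3, s2)
    arch = [
        ("avgpool", {"factor": f}),
        ("conv", {"c_in": 1, "c_out": 4, "kernel_size": k1}),
        ("relu", {}),
        ("avgpool", {"factor": 2}),
        ("conv", {"c_in": 4, "c_out": 8, "kernel_size": k2}),
        ("relu", {}),
        ("gap", {}),
        ("dense", {"n_in": 8, "n_out": 2}),
    ]
    return tuple((name, kw) for name, kw in arch)

#: Inner-loop selection grid: learning rate × weight decay.
DEFAULT_HYPER_GRID = {
    "lr": [3e-3, 1e-2, 3e-2],
    "weight_decay": [0.0, 1e-4, 1e-3],
}

_LAYER_BUILDERS = {
    "avgpool": lambda rng, **kw: nn.AvgPool3d(**kw),
    "conv": lambda rng, **kw: nn.Conv3d(rng=rng, **kw),
    "relu": lambda rng, **kw: nn.ReLU(),
    "gap": lambda rng, **kw: nn.GlobalAvgPool(),
    "flatten": lambda rng, **kw: nn.Flatten(),
    "dense": lambda rng, **kw: nn.Dense(rng=rng, **kw),
}


def _round2(x) -> float:
    """Round to two decimals, half away from zero, in decimal arithmetic."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ClassificationMetrics:
    """Confusion counts with percentage sensitivity/specificity/BAC.

    Percentages are reported to two decimals (round half away from zero,
    computed in decimal arithmetic so printed values are reproducible).
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        self.tp, self.tn = int(self.tp), int(self.tn)
        self.fp, self.fn = int(self.fp), int(self.fn)
        if self.tp + self.fn == 0:
            raise ValueError("positive class is empty (tp + fn == 0)")
        if self.tn + self.fp == 0:
            raise ValueError("negative class is empty (tn + fp == 0)")

    @property
    def sensitivity(self) -> float:
        return _round2(Decimal(100 * self.tp) / Decimal(self.tp + self.fn))

    @property
    def specificity(self) -> float:
        return _round2(Decimal(100 * self.tn) / Decimal(self.tn + self.fp))

    @property
    def balanced_accuracy(self) -> float:
        return balanced_accuracy_from_rates(self.sensitivity,
                                            self.specificity)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


def balanced_accuracy(tp, fn, tn, fp) -> ClassificationMetrics:
    """Metrics from confusion counts; errors if either class is empty."""
    return ClassificationMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def balanced_accuracy_from_rates(sensitivity, specificity) -> float:
    """BAC from already-computed percentage rates, in decimal arithmetic.

    This is the arithmetic behind published per-cohort result rows where
    only sensitivity and specificity percentages are given.
    """
    bac = (Decimal(repr(float(sensitivity)))
           + Decimal(repr(float(specificity)))) / 2
    return float(bac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metrics_from_predictions(y_true, y_pred,
                             positive=1) -> ClassificationMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    return ClassificationMetrics(
        tp=int(((y_pred == positive) & pos).sum()),
        fn=int(((y_pred != positive) & pos).sum()),
        tn=int(((y_pred != positive) & ~pos).sum()),
        fp=int(((y_pred == positive) & ~pos).sum()),
    )


class TextureClassifier:
    """A trained network plus the preprocessing that must travel with it.

    Wraps a :class:`braintexture.nn.Sequential` together with per-voxel
    standardization statistics (estimated on training data only) and the
    texture-extraction configuration its inputs were computed with, so the
    model can refuse feature maps from a mismatched configuration.
    """

    def __init__(self, architecture=None, seed=0, texture_config=None):
        """``architecture=None`` sizes the default conv net to the feature
        maps at fit time (see :func:`adaptive_architecture`)."""
        self.architecture = (
            None if architecture is None
            else tuple((name, dict(kw)) for name, kw in architecture))
        self.seed = seed
        self.texture_config = dict(texture_config or {})
        self.net = None
        if self.architecture is not None:
            self._build()
        self._mu = None
        self._sd = None
        self.hyperparams: dict = {}

    def _build(self):
        rng = np.random.default_rng(self.seed)
        self.net = nn.Sequential(
            [_LAYER_BUILDERS[name](rng, **kw)
             for name, kw in self.architecture])

    # -- preprocessing -------------------------------------------------
    @staticmethod
    def stack_maps(feature_maps) -> np.ndarray:
        """(N, 1, D, H, W) array from a mapping subject → TextureFeatureMap.

        Invalid (background) positions carry 0; non-finite values at *valid*
        positions are an error naming the offending subjects.
        """
        bad = []
        arrs = []
        for sid, fmap in feature_maps.items():
            vals = fmap.values if isinstance(fmap, TextureFeatureMap) else fmap
            if isinstance(fmap, TextureFeatureMap):
                filled = np.where(fmap.valid_mask, vals, 0.0)
                if not np.all(np.isfinite(filled)):
                    bad.append(sid)
                arrs.append(filled)
            else:
                if not np.all(np.isfinite(vals)):
                    bad.append(sid)
                arrs.append(np.asarray(vals, dtype=float))
        if bad:
            raise ValueError(f"non-finite feature values for subjects: {bad}")
        return np.stack(arrs)[:, None]

    def _standardize(self, x, fit=False):
        if fit:
            self._mu = x.mean(axis=0, keepdims=True)
            self._sd = x.std(axis=0, keepdims=True)
            self._sd[self._sd < 1e-8] = 1.0
        return (x - self._mu) / self._sd

    # -- training / prediction -----------------------------------------
    def _frozen_prefix_split(self):
        """Leading parameter-free layers can be applied once per fit instead
        of once per epoch; the split changes nothing numerically."""
        k = 0
        for lay in self.net.layers:
            if lay.params:
                break
            k += 1
        return self.net.layers[:k], nn.Sequential(self.net.layers[k:])

    def fit(self, x, y, lr=1e-2, weight_decay=0.0, epochs=150, seed=None,
            x_val=None, y_val=None, patience=30):
        if self.net is None:
            self.architecture = adaptive_architecture(x.shape[2:])
            self._build()
        xs = self._standardize(x, fit=True)
        xv = self._standardize(x_val) if x_val is not None else None
        self.hyperparams = {"lr": lr, "weight_decay": weight_decay,
                            "epochs": epochs}
        prefix, trainable = self._frozen_prefix_split()
        for lay in prefix:
            xs = lay.forward(xs)
            if xv is not None:
                xv = lay.forward(xv)
        trainable.fit(xs, y, epochs=epochs, lr=lr, weight_decay=weight_decay,
                      seed=self.seed if seed is None else seed,
                      x_val=xv, y_val=y_val, patience=patience)
        return self

    def predict(self, x):
        return self.net.predict(self._standardize(x))

    def predict_scores(self, x):
        return self.net.predict_scores(self._standardize(x))

    def standardized_input(self, x):
        """The network-input view of raw feature maps (for explanation)."""
        return self._standardize(x)


@dataclass
class CVResult:
    """Everything a nested cross-validation run produced."""

    outer_folds: list
    per_fold_metrics: list
    pooled_metrics: ClassificationMetrics
    winner_model: TextureClassifier
    selected_hyperparams: dict
    fold_hyperparams: list = field(default_factory=list)
    pooled_predictions: dict = field(default_factory=dict)


def _grid_points(hyper_grid):
    keys = sorted(hyper_grid)
    for combo in itertools.product(*(hyper_grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def nested_cv_train(
    feature_maps,
    labels,
    outer_k=20,
    inner_k=20,
    hyper_grid=None,
    seed=0,
    architecture=None,
    epochs=120,
    n_repeats=1,
) -> CVResult:
    """Nested cross-validation over a subject → feature-map mapping.

    ``labels`` maps subject id → class (VisDys+ coded as the positive class;
    any two labels work — the lexicographically larger one is positive).
    Outer folds are stratified; each outer-train set runs an inner stratified
    CV over ``hyper_grid``, the best mean inner BAC picks the fold's
    hyperparameters, and the refit fold model predicts the outer test set.
    Outer-test predictions are pooled into ``pooled_metrics``.  The winner
    model uses the modal fold hyperparameters, refit on all subjects.

    With ``n_repeats > 1`` the whole outer loop is repeated with reshuffled
    partitions and predictions are pooled across repeats.
    """
    hyper_grid = hyper_grid or DEFAULT_HYPER_GRID
    subjects = list(feature_maps)
    classes = sorted({labels[s] for s in subjects})
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = np.array([classes.index(labels[s]) for s in subjects])
    per_class = np.bincount(y)
    if per_class.min() < outer_k:
        raise ValueError(
            f"stratified {outer_k}-fold CV impossible: smallest class has "
            f"{per_class.min()} subjects"
        )
    x = TextureClassifier.stack_maps(feature_maps)
    tex_cfg = _common_texture_config(feature_maps)

    outer_folds = []
    per_fold_metrics = []
    fold_hyperparams = []
    pooled_true, pooled_pred, pooled_sids = [], [], []
    grid = list(_grid_points(hyper_grid))
    for rep in range(n_repeats):
        outer = StratifiedKFold(n_splits=outer_k, shuffle=True,
                                random_state=seed + 1000 * rep)
        for fold, (tr, te) in enumerate(outer.split(x, y)):
            best_hp, best_score = None, -np.inf
            for hp in grid:
                inner = StratifiedKFold(
                    n_splits=inner_k, shuffle=True,
                    random_state=seed + 1000 * rep + fold + 1)
                scores = []
                for itr, iva in inner.split(x[tr], y[tr]):
                    clf = TextureClassifier(architecture, seed=seed,
                                            texture_config=tex_cfg)
                    clf.fit(x[tr][itr], y[tr][itr], epochs=epochs,
                            x_val=x[tr][iva], y_val=y[tr][iva], **hp)
                    scores.append(
                        nn._bac_fraction(clf.predict(x[tr][iva]), y[tr][iva]))
                mean_score = float(np.mean(scores))
                if mean_score > best_score:  # ties keep grid order
                    best_hp, best_score = hp, mean_score
            clf = TextureClassifier(architecture, seed=seed,
                                    texture_config=tex_cfg)
            clf.fit(x[tr], y[tr], epochs=epochs, **best_hp)
            pred = clf.predict(x[te])
            outer_folds.append(([subjects[i] for i in tr],
                                [subjects[i] for i in te]))
            fold_hyperparams.append(best_hp)
            try:
                per_fold_metrics.append(metrics_from_predictions(y[te], pred))
            except ValueError:
                per_fold_metrics.append(None)  # class absent in a tiny fold
            pooled_true.extend(y[te])
            pooled_pred.extend(pred)
            pooled_sids.extend(subjects[i] for i in te)
    pooled_metrics = metrics_from_predictions(pooled_true, pooled_pred)

    counter = collections.Counter(
        tuple(sorted(hp.items())) for hp in fold_hyperparams)
    winner_hp = dict(counter.most_common(1)[0][0])
    winner = TextureClassifier(architecture, seed=seed,
                               texture_config=tex_cfg)
    winner.fit(x, y, epochs=epochs, **winner_hp)
    winner.classes_ = classes
    logger.info("nested CV pooled BAC %.2f%% with winner %s",
                pooled_metrics.balanced_accuracy, winner_hp)
    return CVResult(
        outer_folds=outer_folds,
        per_fold_metrics=per_fold_metrics,
        pooled_metrics=pooled_metrics,
        winner_model=winner,
        selected_hyperparams=winner_hp,
        fold_hyperparams=fold_hyperparams,
        pooled_predictions=dict(
            zip(pooled_sids, (classes[p] for p in pooled_pred))),
    )


def _common_texture_config(feature_maps):
    cfgs = {
        tuple(sorted(m.config.items()))
        for m in feature_maps.values()
        if isinstance(m, TextureFeatureMap)
    }
    if len(cfgs) > 1:
        raise ValueError("feature maps mix texture configurations")
    return dict(cfgs.pop()) if cfgs else {}


def external_validate(model: TextureClassifier, feature_maps,
                      labels) -> ClassificationMetrics:
    """Apply a frozen winner model to an independent cohort (no refitting).

    The validation maps must have been extracted with the identical texture
    configuration (grey levels, cube, stride, offsets) as the training maps;
    a mismatch raises an error naming the differing keys.
    """
    cfg = _common_texture_config(feature_maps)
    if model.texture_config and cfg:
        diff = {
            k for k in set(model.texture_config) | set(cfg)
            if model.texture_config.get(k) != cfg.get(k)
        }
        if diff:
            raise ValueError(
                f"texture configuration mismatch on keys: {sorted(diff)}"
            )
    subjects = list(feature_maps)
    classes = getattr(model, "classes_", sorted({labels[s] for s in subjects}))
    y = np.array([classes.index(labels[s]) for s in subjects])
    x = TextureClassifier.stack_maps(feature_maps)
    pred = model.predict(x)
    return metrics_from_predictions(y, pred)
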