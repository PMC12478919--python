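"""Hybrid classification: CNN feature maps -> multi-scale head -> kernel SVM.

The classifier follows the hybrid recipe: a convolutional backbone produces
a feature map F (channels x height x width); three parallel branches with
3x3, 5x5 and 7x7 kernels each apply convolution, LeakyReLU, max-pooling and
adaptive average pooling to 1x1, giving F1, F2, F3; their concatenation
F_concat is the feature vector. A softmax layer on F_concat trains the head
by categorical cross-entropy; the standardized feature vectors then train a
grid-searched SVM whose RBF decision rule is
``f(x) = sign(sum_i alpha_i y_i exp(-gamma ||x_i - x||^2) + b)``, extended
to three classes one-vs-rest by taking the argmax of per-class decision
scores (which is also what the per-class ROC analysis needs).

The reference backbone in the literature this mirrors is a pretrained
EfficientNet-B0 final convolutional stage (1280 channels, total stride 32);
any object satisfying the small ``Backbone`` protocol can be plugged in.
The default concrete backbone here is ``SmallCNNBackbone``, a compact
random-initialized CNN with the same interface, which keeps the package
self-contained (no weight downloads) — on the synthetic phantoms its random
convolutional features are already highly discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import nn

CLASSES = ("AD", "CN", "MCI")

# Documented contract of the reference EfficientNet-B0 backbone.
EFFICIENTNET_B0_CHANNELS = 1280
EFFICIENTNET_B0_STRIDE = 32


class ClfConfigError(ValueError):
    """Raised for invalid classifier configuration."""


class ClfInputError(ValueError):
    """Raised for invalid data passed to the classification stage."""


# ---------------------------------------------------------------------------
# backbone

class SmallCNNBackbone:
    """Compact convolutional backbone: ``n_stages`` blocks of (3x3 conv,
    ReLU, 2x2 max-pool), so the total stride is ``2**n_stages``.

    Randomly initialized and frozen by default; it exists to provide the
    same (channels, stride, differentiability) contract as a pretrained
    feature extractor without shipping weights.
    """

    def __init__(self, input_size: int = 64, out_channels: int = 32,
                 n_stages: int = 3, seed: int = 0):
        if input_size % (2 ** n_stages) != 0:
            raise ClfConfigError(
                f"input_size {input_size} not divisible by 2^{n_stages}")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.in_channels = 1
        self.out_channels = out_channels
        self.total_stride = 2 ** n_stages
        chans = [max(4, out_channels // 2 ** (n_stages - 1 - i))
                 for i in range(n_stages - 1)] + [out_channels]
        layers: list[nn.Layer] = []
        cin = 1
        for c in chans:
            layers += [nn.Conv2d(cin, c, 3, rng), nn.ReLU(), nn.MaxPool2d()]
            cin = c
        self.net = nn.Sequential(*layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(x, training=training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def params(self) -> list[nn.Param]:
        return self.net.params()


def extract_features(backbone, images: np.ndarray) -> np.ndarray:
    """Run the backbone's final convolutional stage on slice(s).

    ``images`` is (H, W), (N, H, W) or (N, H, W, C); grayscale input is
    replicated to the backbone's channel count. Returns the feature map(s)
    as (N, h, w, C_out) — or (h, w, C_out) for a single 2D input — where
    ``h = w = input_size / total_stride``.
    """
    arr = np.asarray(images, dtype=np.float32)
    single = arr.ndim == 2
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[..., None]
    n, h, w, c = arr.shape
    if h != backbone.input_size or w != backbone.input_size:
        raise ClfInputError(
            f"backbone expects {backbone.input_size}px square input, got {h}x{w}")
    if c != backbone.in_channels:
        if c == 1:
            arr = np.repeat(arr, backbone.in_channels, axis=3)
        else:
            raise ClfInputError(
                f"cannot adapt {c}-channel input to {backbone.in_channels} channels")
    fmap = backbone.forward(arr, training=False)
    return fmap[0] if single else fmap


# ---------------------------------------------------------------------------
# multi-scale head

@dataclass(frozen=True)
class MultiScaleConfig:
    """Three parallel branches with increasing receptive fields."""

    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    branch_channels: int = 128
    leaky_slope: float = 0.01
    dropout_rate: float = 0.3

    def __post_init__(self):
        if len(self.kernel_sizes) != 3:
            raise ClfConfigError("the multi-scale head has exactly three branches")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ClfConfigError("kernel sizes must be odd")


class MultiScaleHead:
    """Parallel convolution branches over a shared feature map, concatenated
    into one feature vector, plus a softmax classification layer.

    Each branch: same-padded conv -> LeakyReLU -> 2x2 max-pool (skipped when
    the map is a single pixel) -> adaptive average-pool to 1x1 -> dropout
    (training only). Branch outputs are concatenated in kernel-size order,
    so the feature vector has length ``len(kernel_sizes) * branch_channels``.

    ``kernel_sizes`` may be overridden (e.g. a single 3x3 branch) to build
    the single-scale ablation variant through the same class.
    """

    def __init__(self, in_channels: int, config: MultiScaleConfig | None = None,
                 n_classes: int = 3, seed: int = 0,
                 kernel_sizes: tuple[int, ...] | None = None):
        self.config = config or MultiScaleConfig()
        self.kernel_sizes = tuple(kernel_sizes if kernel_sizes is not None
                                  else self.config.kernel_sizes)
        self.in_channels = in_channels
        self.n_classes = n_classes
        bc = self.config.branch_channels
        rng = np.random.default_rng(seed)
        self.branches = []
        for k in self.kernel_sizes:
            self.branches.append({
                "conv": nn.Conv2d(in_channels, bc, k, rng),
                "act": nn.LeakyReLU(self.config.leaky_slope),
                "pool": nn.MaxPool2d(),
                "gap": nn.GlobalAvgPool2d(),
                "drop": nn.Dropout(self.config.dropout_rate, rng),
            })
        self.feature_length = len(self.kernel_sizes) * bc
        self.classifier = nn.Linear(self.feature_length, n_classes, rng)

    def params(self) -> list[nn.Param]:
        ps = []
        for b in self.branches:
            ps += b["conv"].params()
        ps += self.classifier.params()
        return ps

    def forward_features(self, fmap: np.ndarray, training: bool = False) -> np.ndarray:
        """F_concat: (N, h, w, C) feature maps -> (N, 3 * branch_channels)."""
        if fmap.ndim != 4:
            raise ClfInputError("expected feature maps of shape (N, h, w, C)")
        if fmap.shape[3] != self.in_channels:
            raise ClfConfigError(
                f"head built for {self.in_channels} channels, got {fmap.shape[3]}")
        outs = []
        self._pooled = []
        for b in self.branches:
            h = b["conv"].forward(fmap, training)
            h = b["act"].forward(h, training)
            use_pool = h.shape[1] >= 2 and h.shape[1] % 2 == 0
            if use_pool:
                h = b["pool"].forward(h, training)
            self._pooled.append(use_pool)
            h = b["gap"].forward(h, training)
            h = b["drop"].forward(h, training)
            outs.append(h)
        return np.concatenate(outs, axis=1)

    def backward_features(self, dfeat: np.ndarray) -> np.ndarray:
        """Gradient of F_concat back to the shared feature map."""
        bc = self.config.branch_channels
        dfmap = None
        for i, b in enumerate(self.branches):
            d = dfeat[:, i * bc:(i + 1) * bc]
            d = b["drop"].backward(d)
            d = b["gap"].backward(d)
            if self._pooled[i]:
                d = b["pool"].backward(d)
            d = b["act"].backward(d)
            d = b["conv"].backward(d)
            dfmap = d if dfmap is None else dfmap + d
        return dfmap

    def forward(self, fmap: np.ndarray, training: bool = False) -> np.ndarray:
        """Class logits (pre-softmax scores), shape (N, n_classes)."""
        return self.classifier.forward(self.forward_features(fmap, training), training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.backward_features(self.classifier.backward(dlogits))


def multi_scale_forward(head: MultiScaleHead, fmap: np.ndarray,
                        training: bool = False) -> np.ndarray:
    """Feature vector(s) F_concat for one feature map (h, w, C) or a batch."""
    single = fmap.ndim == 3
    f = fmap[None] if single else fmap
    out = head.forward_features(f, training=training)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# head training

@dataclass
class HeadTrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 20
    seed: int = 42


def labels_to_onehot(labels) -> np.ndarray:
    idx = np.array([CLASSES.index(l) for l in labels])
    oh = np.zeros((len(idx), len(CLASSES)), dtype=np.float32)
    oh[np.arange(len(idx)), idx] = 1.0
    return oh


def train_head(backbone, head: MultiScaleHead, train_data,
               config: HeadTrainConfig | None = None) -> dict:
    """Train the multi-scale head (backbone frozen) by categorical
    cross-entropy over its softmax layer with Adam.

    ``train_data`` is ``(images, labels)`` with labels in {AD, CN, MCI}.
    Feature maps are extracted once up front since the backbone is frozen.
    Returns a history dict with per-epoch mean loss.
    """
    config = config or HeadTrainConfig()
    images, labels = train_data
    if len(images) == 0:
        raise ClfInputError("empty training data")
    for l in labels:
        if l not in CLASSES:
            raise ClfInputError(f"unknown label {l!r}")
    fmaps = extract_features(backbone, np.asarray(images, dtype=np.float32))
    onehot = labels_to_onehot(labels)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(head.params(), lr=config.learning_rate)
    n = fmaps.shape[0]
    history = {"loss": []}
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = head.forward(fmaps[idx], training=True)
            loss, grad = nn.softmax_cross_entropy(logits, onehot[idx])
            head.backward(grad)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
    return history


# ---------------------------------------------------------------------------
# feature scaling

def fit_scaler(train_features: np.ndarray) -> StandardScaler:
    """Standard scaler fitted on training features only; constant
    dimensions keep scale 1 so they pass through after centering."""
    return StandardScaler().fit(np.asarray(train_features, dtype=np.float64))


def apply_scaler(scaler: StandardScaler, features: np.ndarray) -> np.ndarray:
    return scaler.transform(np.asarray(features, dtype=np.float64))


# ---------------------------------------------------------------------------
# SVM

@dataclass(frozen=True)
class SVMGridSpec:
    """Hyperparameter grid; the documented iteration order (rbf before
    linear, larger C first, 'scale' before 'auto') is the tie-break order."""

    kernels: tuple[str, ...] = ("rbf", "linear")
    C: tuple[float, ...] = (0.1, 1.0, 10.0)
    gamma: tuple[str, ...] = ("scale", "auto")
    scoring: str = "accuracy"
    cv_folds: int = 5

    def __post_init__(self):
        if not (self.kernels and self.C and self.gamma):
            raise ClfConfigError("grids must be non-empty")

    def cells(self):
        for kernel in self.kernels:
            for c in sorted(self.C, reverse=True):
                for g in self.gamma:
                    yield kernel, c, g


class TrainedSVM:
    """One-vs-rest ensemble of binary kernel SVMs over {AD, CN, MCI}.

    For each class a binary SVC is fitted with that class as +1 against the
    rest; multi-class prediction is the argmax of the per-class decision
    scores. The per-class support vectors, dual coefficients alpha_i*y_i,
    bias b and kernel coefficient gamma are exposed so the decision values
    can be reproduced from the stored parameters alone.
    """

    def __init__(self, kernel: str, C: float, gamma: str):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.models: dict[str, SVC] = {}
        self.classes_: tuple[str, ...] = ()

    def fit(self, features: np.ndarray, labels) -> "TrainedSVM":
        X = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels)
        present = [c for c in CLASSES if c in set(y)]
        if len(present) < 2:
            raise ClfInputError("need at least two classes to fit an SVM")
        self.classes_ = tuple(present)
        for cls in present:
            binary = np.where(y == cls, 1, -1)
            svc = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
            svc.fit(X, binary)
            self.models[cls] = svc
        return self

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        """(n, n_classes) one-vs-rest decision values, columns in
        ``classes_`` order, positive meaning 'this class'."""
        X = np.asarray(features, dtype=np.float64)
        if X.shape[1] != self.models[self.classes_[0]].support_vectors_.shape[1]:
            raise ClfInputError("feature length does not match the fitted model")
        return np.column_stack([self.models[c].decision_function(X)
                                for c in self.classes_])

    def predict(self, features: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(features)
        return np.array([self.classes_[i] for i in scores.argmax(axis=1)])

    def class_parameters(self, cls: str) -> dict:
        """Stored decision-rule parameters of one binary machine:
        support vectors x_i, dual coefficients alpha_i*y_i, bias b, gamma."""
        svc = self.models[cls]
        return {
            "support_vectors": svc.support_vectors_.copy(),
            "dual_coef": svc.dual_coef_[0].copy(),
            "bias": float(svc.intercept_[0]),
            "gamma": float(svc._gamma),
            "kernel": self.kernel,
        }


def svm_predict(model: TrainedSVM, features: np.ndarray):
    """Predicted labels plus the (n, n_classes) decision-score matrix."""
    scores = model.decision_scores(features)
    labels = np.array([model.classes_[i] for i in scores.argmax(axis=1)])
    return labels, scores


def grid_search_svm(features: np.ndarray, labels, grid: SVMGridSpec | None = None,
                    seed: int = 42):
    """Exhaustive grid search by stratified cross-validated accuracy.

    Returns ``(best_model, table)`` where the table has columns
    (kernel, C, gamma, accuracy) sorted by accuracy descending with ties
    broken by grid order, and the best model is refitted on all data.
    """
    grid = grid or SVMGridSpec()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(set(y)) < 2:
        raise ClfInputError("grid search needs at least two classes")
    # stratified CV cannot use more folds than the smallest class has members
    smallest = min(np.sum(y == c) for c in set(y))
    if smallest < 2:
        raise ClfInputError("every class needs >= 2 samples for cross-validation")
    folds = min(grid.cv_folds, int(smallest))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for kernel, c, g in grid.cells():
        accs = []
        for tr, te in skf.split(X, y):
            m = TrainedSVM(kernel, c, g).fit(X[tr], y[tr])
            accs.append(float(np.mean(m.predict(X[te]) == y[te])))
        rows.append({"kernel": kernel, "C": c, "gamma": g,
                     "accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    table = table.sort_values("accuracy", ascending=False, kind="stable"
                              ).reset_index(drop=True)
    best = table.iloc[0]
    best_model = TrainedSVM(best["kernel"], float(best["C"]), best["gamma"]
                            ).fit(X, y)
    return best_model, table


# ---------------------------------------------------------------------------
# evaluation battery

@dataclass
class ClassificationReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]   # precision / recall / f1 / support
    confusion: pd.DataFrame                  # rows = true class, cols = predicted


def evaluate_classifier(pred_labels, true_labels) -> ClassificationReport:
    """Overall accuracy, one-vs-rest per-class precision/recall/F1, and the
    3x3 confusion matrix (true classes as rows)."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ClfInputError("label vectors must have equal length")
    for l in np.concatenate([pred, true]):
        if l not in CLASSES:
            raise ClfInputError(f"unknown label {l!r}")
    cm = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for t, p in zip(true, pred):
        cm[CLASSES.index(t), CLASSES.index(p)] += 1
    accuracy = float(np.trace(cm)) / max(1, cm.sum())
    per_class = {}
    for i, cls in enumerate(CLASSES):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = {"precision": float(prec), "recall": float(rec),
                          "f1": float(f1), "support": int(cm[i, :].sum())}
    confusion = pd.DataFrame(cm, index=list(CLASSES), columns=list(CLASSES))
    return ClassificationReport(accuracy=accuracy, per_class=per_class,
                                confusion=confusion)


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimal_threshold: float


def _roc_binary(scores: np.ndarray, positive: np.ndarray) -> RocResult:
    # sweep every distinct score as a threshold (predict positive if
    # score >= t), from +inf (nothing positive) downwards
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = positive[order].astype(bool)
    n_pos = int(p.sum())
    n_neg = p.size - n_pos
    distinct = np.r_[True, np.diff(s) != 0]
    tps = np.cumsum(p)
    fps = np.cumsum(~p)
    keep = np.r_[np.where(distinct)[0][1:] - 1, p.size - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    finite = np.isfinite(thresholds)
    best = np.max(j[finite])
    # smallest qualifying threshold on ties: thresholds are descending,
    # so take the last index attaining the maximum of Youden's J
    idx = np.where(finite & (j >= best - 1e-12))[0][-1]
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     optimal_threshold=float(thresholds[idx]))


def roc_one_vs_rest(scores: np.ndarray, true_labels,
                    classes: tuple[str, ...] = CLASSES) -> dict[str, RocResult | None]:
    """Per-class one-vs-rest ROC curve, trapezoidal AUC, and the optimal
    operating threshold (argmax of TPR - FPR; smallest threshold on ties).

    ``scores`` is (n, n_classes) with columns in ``classes`` order. A class
    with no positive or no negative samples gets ``None`` (undefined AUC is
    reported as missing, never as 0).
    """
    scores = np.asarray(scores, dtype=np.float64)
    true = np.asarray(true_labels)
    if not np.all(np.isfinite(scores)):
        raise ClfInputError("scores must be finite")
    if scores.shape != (true.size, len(classes)):
        raise ClfInputError("score matrix must be n_samples x n_classes")
    out: dict[str, RocResult | None] = {}
    for i, cls in enumerate(classes):
        pos = true == cls
        if pos.all() or not pos.any():
            out[cls] = None
            continue
        out[cls] = _roc_binary(scores[:, i], pos)
    return out


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int   # A correct, B wrong
    c: int   # A wrong, B correct


def mcnemar_test(preds_a, preds_b, truth, correction: bool = False) -> McNemarResult:
    """McNemar's paired test on the discordant counts of two classifiers.

    ``b`` counts samples A got right and B got wrong, ``c`` the reverse;
    the statistic is ``(b - c)^2 / (b + c)`` (or the continuity-corrected
    ``(|b - c| - 1)^2 / (b + c)``) referred to chi-square with 1 df. With no
    discordant pairs the statistic is 0 and p is 1.
    """
    a = np.asarray(preds_a)
    bb = np.asarray(preds_b)
    t = np.asarray(truth)
    if not (a.shape == bb.shape == t.shape):
        raise ClfInputError("prediction and truth vectors must share length")
    ca = a == t
    cb = bb == t
    b = int(np.sum(ca & ~cb))
    c = int(np.sum(~ca & cb))
    if b + c == 0:
        return McNemarResult(0.0, 1.0, b, c)
    if correction:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    return McNemarResult(float(stat), float(chi2.sf(stat, df=1)), b, c)


def mcnemar_pvalue(statistic: float) -> float:
    """Upper-tail chi-square(1) p-value for a McNemar statistic."""
    return float(chi2.sf(statistic, df=1))
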