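"""Training protocol: subject-independent splitting, training-only
augmentation, cross-entropy + Adam with decoupled weight decay, cosine
learning-rate annealing, and early stopping on the validation F1-score.

The binary cross-entropy of the paper is implemented as 2-class categorical
cross-entropy over the softmax head, which is mathematically identical for a
two-way posterior. PD (label 1, class column 0) is the positive class for
sensitivity, precision and F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .network import MgmaDscnn, ModelConfig

__all__ = [
    "LeakageError",
    "SplitPlan",
    "AugmentConfig",
    "AugmentSample",
    "TrainConfig",
    "MetricsReport",
    "split_subjects",
    "sample_augmentation",
    "apply_augmentation",
    "augment",
    "bce_loss",
    "cosine_lr",
    "EarlyStopping",
    "confusion_metrics",
    "evaluate_model",
    "train_model",
]


class LeakageError(RuntimeError):
    """A subject appears in more than one split role."""


# --------------------------------------------------------------------------
# subject-independent splitting
# --------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Test reservation plus a k-fold partition of the remaining pool.

    ``folds[i]`` lists the subjects serving as validation in fold ``i``; the
    fold's training set is the rest of the pool.
    """

    test_subjects: list
    folds: list
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def pool(self) -> list:
        return [s for fold in self.folds for s in fold]

    def roles(self, fold: int):
        """(train, val, test) subject lists for one fold."""
        val = list(self.folds[fold])
        train = [s for i, f in enumerate(self.folds) if i != fold for s in f]
        return train, val, list(self.test_subjects)

    def validate(self) -> None:
        groups = [set(self.test_subjects)] + [set(f) for f in self.folds]
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(union):
            raise LeakageError("subject assigned to more than one split role")


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` across classes proportional to
    ``quotas`` (largest-remainder rounding)."""
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(quotas - floors))
    out = floors.copy()
    for i in range(short):
        out[order[i % len(out)]] += 1
    return out


def split_subjects(manifest, test_fraction: float = 0.2, k: int = 5,
                   seed: int = 0) -> SplitPlan:
    """Stratified subject-level split: reserve ``round(test_fraction * n)``
    subjects for the held-out test set (allocated per class by largest
    remainder) and partition the rest into ``k`` stratified validation folds.

    ``manifest`` is a CohortManifest, a manifest DataFrame with
    ``subject_id``/``label`` columns, or a dict subject_id -> label.
    """
    if hasattr(manifest, "records"):
        sub = manifest.records.drop_duplicates("subject_id")
        labels = dict(zip(sub["subject_id"], sub["label"]))
    elif hasattr(manifest, "drop_duplicates"):
        sub = manifest.drop_duplicates("subject_id")
        labels = dict(zip(sub["subject_id"], sub["label"]))
    else:
        labels = dict(manifest)

    rng = np.random.default_rng(seed)
    classes = sorted(set(labels.values()))
    by_class = {c: sorted(s for s, l in labels.items() if l == c) for c in classes}
    n = len(labels)
    n_test = int(round(test_fraction * n))
    quotas = np.array([test_fraction * len(by_class[c]) for c in classes])
    alloc = _largest_remainder(quotas, n_test)

    test_subjects = []
    pool_by_class = {}
    for c, take in zip(classes, alloc):
        members = np.array(by_class[c])
        rng.shuffle(members)
        test_subjects.extend(members[:take])
        pool_by_class[c] = members[take:]
        if len(pool_by_class[c]) < k:
            raise ValueError(
                f"class {c} leaves {len(pool_by_class[c])} pool subjects; "
                f"need at least k={k} per class")

    folds = [[] for _ in range(k)]
    for c in classes:
        members = pool_by_class[c]
        rng.shuffle(members)
        for i, s in enumerate(members):
            folds[i % k].append(s)
    plan = SplitPlan(test_subjects=sorted(test_subjects),
                     folds=[sorted(f) for f in folds], seed=seed)
    plan.validate()
    return plan


# --------------------------------------------------------------------------
# training-only augmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Legibility-preserving augmentation ranges (training stream only)."""

    rotation_deg: float = 5.0          # +/- range
    scale_range: tuple = (0.9, 1.1)
    shift_fraction: float = 0.05       # of the image size, each axis
    elastic_alpha: float = 4.0         # displacement magnitude, px
    elastic_sigma: float = 8.0         # displacement-field smoothness, px
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rotation_deg > 5.0 + 1e-9 or self.shift_fraction > 0.05 + 1e-9:
            raise ValueError("augmentation ranges exceed the stated bounds")
        if self.scale_range[0] < 0.9 - 1e-9 or self.scale_range[1] > 1.1 + 1e-9:
            raise ValueError("scale range must lie within [0.9, 1.1]")


@dataclass(frozen=True)
class AugmentSample:
    rotation_deg: float
    scale: float
    shift: tuple          # (dy, dx) in pixels after multiplying by size
    elastic_seed: int


def sample_augmentation(config: AugmentConfig, rng: np.random.Generator,
                        size: int) -> AugmentSample:
    return AugmentSample(
        rotation_deg=float(rng.uniform(-config.rotation_deg, config.rotation_deg)),
        scale=float(rng.uniform(*config.scale_range)),
        shift=(float(rng.uniform(-config.shift_fraction, config.shift_fraction) * size),
               float(rng.uniform(-config.shift_fraction, config.shift_fraction) * size)),
        elastic_seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def apply_augmentation(image: np.ndarray, sample: AugmentSample,
                       config: AugmentConfig) -> np.ndarray:
    """Rotation -> isotropic scale -> shift (one affine warp), then a mild
    elastic deformation; output shape and value range are preserved."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = math.radians(sample.rotation_deg)
    s = sample.scale
    # inverse map for ndi.affine_transform: output coords -> input coords
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]]) / s
    offset = np.array([cy, cx]) - rot @ np.array([cy + sample.shift[0],
                                                  cx + sample.shift[1]])

    erng = np.random.default_rng(sample.elastic_seed)
    dy = ndi.gaussian_filter(erng.uniform(-1, 1, (h, w)), config.elastic_sigma)
    dx = ndi.gaussian_filter(erng.uniform(-1, 1, (h, w)), config.elastic_sigma)
    for d in (dy, dx):
        m = np.abs(d).max()
        if m > 0:
            d *= config.elastic_alpha / m
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")

    chans = img[..., None] if img.ndim == 2 else img
    out = np.empty_like(chans)
    for c in range(chans.shape[2]):
        warped = ndi.affine_transform(chans[..., c], rot, offset=offset,
                                      order=1, mode="constant", cval=0.0)
        out[..., c] = ndi.map_coordinates(warped, [rows + dy, cols + dx],
                                          order=1, mode="constant", cval=0.0)
    out = np.clip(out, 0.0, 1.0)
    return out[..., 0] if img.ndim == 2 else out


def augment(image: np.ndarray, config: AugmentConfig, seed) -> np.ndarray:
    """One random legibility-preserving distortion of a fused input. A
    disabled config is the identity. ``seed`` may be an int or a Generator."""
    if not config.enabled:
        return np.asarray(image, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sample = sample_augmentation(config, rng, np.asarray(image).shape[0])
    return apply_augmentation(image, sample, config)


# --------------------------------------------------------------------------
# loss, schedule, early stopping, metrics
# --------------------------------------------------------------------------

_EPS = 1e-12


def bce_loss(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log posterior of the true class; posteriors are (n, 2)
    rows (p_PD, p_healthy), labels in {0, 1} with 1 = PD. Probabilities are
    clamped at 1e-12 before the log."""
    post = np.atleast_2d(np.asarray(posteriors, dtype=float))
    labels = np.asarray(labels, dtype=int).reshape(-1)
    p_true = post[np.arange(len(labels)), 1 - labels]
    return float(-np.mean(np.log(np.clip(p_true, _EPS, None))))


def cosine_lr(t: int, total: int, eta0: float = 1e-3,
              eta_min: float = 1e-6) -> float:
    """Cosine annealing: eta(t) = eta_min + (eta0 - eta_min)(1 + cos(pi t/T))/2."""
    if not 0 <= t <= total:
        raise ValueError("epoch index must satisfy 0 <= t <= T")
    return eta_min + (eta0 - eta_min) * (1.0 + math.cos(math.pi * t / total)) / 2.0


class EarlyStopping:
    """Stop when the validation F1 has not strictly improved for ``patience``
    consecutive epochs; tracks the best epoch (1-based)."""

    def __init__(self, patience: int = 15):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.epoch = 0
        self.stale = 0

    def update(self, f1: float) -> bool:
        """Record one epoch's validation F1; returns True when training
        should stop after this epoch."""
        self.epoch += 1
        if f1 > self.best:
            self.best = f1
            self.best_epoch = self.epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


@dataclass
class MetricsReport:
    """Confusion-matrix metrics with PD as the positive class. Ratios with a
    zero denominator are NaN and listed in ``undefined``."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: frozenset = frozenset()


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    acc = (tp + tn) / (tp + fp + tn + fn)
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if "sensitivity" in undefined or "precision" in undefined \
            or (prec + sens) == 0 or math.isnan(prec + sens):
        undefined.add("f1")
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(tp, fp, tn, fn, acc, sens, spec, prec, f1,
                         frozenset(undefined))


def _metrics_from_preds(labels: np.ndarray, preds: np.ndarray) -> MetricsReport:
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    return confusion_metrics(tp, fp, tn, fn)


def evaluate_model(model: MgmaDscnn, X: np.ndarray, y: np.ndarray,
                   batch_size: int = 32):
    """(MetricsReport, PD scores) on a dataset, without augmentation."""
    y = np.asarray(y, dtype=int)
    scores = []
    for i in range(0, len(X), batch_size):
        probs = np.atleast_2d(model.forward(X[i:i + batch_size], train=False))
        scores.append(probs[:, 0])
    scores = np.concatenate(scores) if scores else np.empty(0)
    preds = (scores > 0.5).astype(int)
    return _metrics_from_preds(y, preds), scores


# --------------------------------------------------------------------------
# the training loop
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    eta0: float = 1e-3
    eta_min: float = 1e-6
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 15
    weight_decay: float = 1e-4
    dropout: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.eta0 > self.eta_min > 0:
            raise ValueError("need eta0 > eta_min > 0")


def _is_decayed(name: str) -> bool:
    # decoupled weight decay on conv/dense/attention weights, not biases or BN
    return not (name.endswith("_b") or name.endswith("_beta")
                or name.endswith("_gamma") or name == "gate_b")


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr, weight_decay):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if weight_decay and _is_decayed(k):
                params[k] -= lr * weight_decay * params[k]


def _check_disjoint(train_subjects, val_subjects) -> None:
    overlap = set(train_subjects) & set(val_subjects)
    if overlap:
        raise LeakageError(f"subjects in both train and val: {sorted(overlap)}")


def train_model(train_data, val_data, model_config: ModelConfig,
                train_config: TrainConfig = TrainConfig(),
                augment_config: AugmentConfig = AugmentConfig(),
                seed: int = 0):
    """Fit the classifier; returns (model at the best-F1 checkpoint, history).

    ``train_data``/``val_data`` are ``(X, y, subject_ids)`` triples with X of
    shape (n, H, W, 3). Subject sets must be disjoint (checked; a violation
    is a hard failure). Augmentation, when enabled, is re-sampled on the fly
    each epoch and applied to the training stream only.
    """
    Xtr, ytr, subj_tr = train_data
    Xva, yva, subj_va = val_data
    _check_disjoint(subj_tr, subj_va)
    ytr = np.asarray(ytr, dtype=int)
    yva = np.asarray(yva, dtype=int)

    model_config = replace(model_config, dropout=train_config.dropout)
    model = MgmaDscnn(model_config, seed=seed)
    opt = _Adam(model.params)
    rng = np.random.default_rng(seed)
    stopper = EarlyStopping(train_config.patience)
    history = []
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_buffers = {k: {kk: vv.copy() for kk, vv in v.items()}
                    for k, v in model.buffers.items()}

    n = len(Xtr)
    for epoch in range(1, train_config.max_epochs + 1):
        lr = cosine_lr(epoch - 1, train_config.max_epochs,
                       train_config.eta0, train_config.eta_min)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, train_config.batch_size):
            idx = order[i:i + train_config.batch_size]
            xb = Xtr[idx]
            if augment_config.enabled:
                xb = np.stack([augment(img, augment_config, rng) for img in xb])
            loss, grads = model.loss_and_grad(xb, ytr[idx], train=True, rng=rng)
            opt.step(model.params, grads, lr, train_config.weight_decay)
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        report, _ = evaluate_model(model, Xva, yva,
                                   batch_size=train_config.batch_size)
        val_f1 = 0.0 if math.isnan(report.f1) else report.f1
        history.append({"epoch": epoch, "lr": lr, "train_loss": epoch_loss,
                        "val_f1": val_f1, "val_accuracy": report.accuracy})
        stop = stopper.update(val_f1)
        if stopper.best_epoch == epoch:
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_buffers = {k: {kk: vv.copy() for kk, vv in v.items()}
                            for k, v in model.buffers.items()}
        if stop:
            break

    model.params = best_params
    model.buffers = best_buffers
    return model, history
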