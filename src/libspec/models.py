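"""Classifier zoo: three spectral CNNs with staged SGD, plus LDA/KNN/SVM.

The two 1-D networks consume selected-variable spectra; the 2-D network
consumes the n×h spectral matrix.  Training follows a staged protocol: a
sequence of (learning rate, validation-accuracy threshold) stages, each run
until the validation accuracy reaches the stage threshold or an iteration cap
(1,000 epochs) is hit, with learning rates decreasing and thresholds
increasing stage over stage.

Classical baselines wrap scikit-learn: LDA (ridge fallback on collinear
inputs), KNN with k searched over 3–20 on validation accuracy, and an RBF
SVM with C and gamma grid-searched over integer powers of ten in
[1e-8, 1e8] by cross-validation on the calibration set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import nn

__all__ = [
    "ArchitectureSpec",
    "TrainSchedule",
    "TrainResult",
    "FittedBaseline",
    "SizeError",
    "ScheduleError",
    "PAPER_SCHEDULE",
    "build_cnn1d_1",
    "build_cnn1d_2",
    "build_cnn2d",
    "train_staged",
    "fit_baseline",
    "predict",
]

DROPOUT_P = 0.3


class SizeError(ValueError):
    """Input too small for the architecture's pooling pyramid."""


class ScheduleError(ValueError):
    """A staged-training schedule violates its monotonicity contracts."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one of the three networks.

    ``build(seed)`` instantiates a fresh :class:`libspec.nn.Network`; the
    descriptive fields (kernel counts/sizes, dense widths, residual channels)
    are readable without building.
    """

    name: str
    input_shape: tuple[int, ...]
    n_classes: int
    conv_kernel_counts: tuple[int, ...]
    conv_kernel_sizes: tuple[int, ...]
    dense_widths: tuple[int, ...]
    residual_blocks: tuple[tuple[int, int], ...] = ()
    dropout: float = DROPOUT_P
    pool_sizes: tuple = ()

    def build(self, seed: int = 0, dtype=np.float32) -> nn.Network:
        rng = np.random.default_rng(seed)
        builder = _BUILDERS[self.name]
        return builder(self, rng, dtype)

    @property
    def n_params(self) -> int:
        return self.build(seed=0).n_params


def _conv1_block(rng, dtype, c_in, c_out, k, idx, layers):
    layers.append((f"conv_block{idx}_conv", nn.Conv1d(c_in, c_out, k, rng, dtype)))
    layers.append((f"conv_block{idx}_bn", nn.BatchNorm(c_out, dtype)))
    layers.append((f"conv_block{idx}_pool", nn.MaxPool1d(2)))
    layers.append((f"conv_block{idx}", nn.ReLU()))


def _dense_block(rng, dtype, d_in, d_out, idx, layers, dropout):
    layers.append((f"dense{idx}_fc", nn.Dense(d_in, d_out, rng, dtype)))
    layers.append((f"dense{idx}", nn.ReLU()))
    layers.append((f"dense{idx}_drop", nn.Dropout(dropout, rng)))


def _build_net_cnn1d_1(spec: ArchitectureSpec, rng, dtype) -> nn.Network:
    (length,) = spec.input_shape
    layers: list[tuple[str, nn.Layer]] = []
    c_in = 1
    for i, (c_out, k) in enumerate(
        zip(spec.conv_kernel_counts, spec.conv_kernel_sizes), start=1
    ):
        _conv1_block(rng, dtype, c_in, c_out, k, i, layers)
        c_in = c_out
        length //= 2
    layers.append(("flatten", nn.Flatten()))
    d_in = c_in * length
    for i, width in enumerate(spec.dense_widths, start=1):
        _dense_block(rng, dtype, d_in, width, i, layers, spec.dropout)
        d_in = width
    layers.append(("logits", nn.Dense(d_in, spec.n_classes, rng, dtype)))
    return nn.Network(layers, spec.n_classes, dtype)


def _build_net_cnn1d_2(spec: ArchitectureSpec, rng, dtype) -> nn.Network:
    (length,) = spec.input_shape
    layers: list[tuple[str, nn.Layer]] = []
    c_out, k = spec.conv_kernel_counts[0], spec.conv_kernel_sizes[0]
    _conv1_block(rng, dtype, 1, c_out, k, 1, layers)
    c_in = c_out
    length //= 2
    for i, (channels, n_convs) in enumerate(spec.residual_blocks, start=1):
        branch: list[nn.Layer] = []
        b_in = c_in
        for j in range(n_convs):
            branch.append(nn.Conv1d(b_in, channels, 3, rng, dtype))
            branch.append(nn.BatchNorm(channels, dtype))
            if j < n_convs - 1:
                branch.append(nn.ReLU())
            b_in = channels
        projection = None
        if c_in != channels:
            projection = [nn.Conv1d(c_in, channels, 1, rng, dtype), nn.BatchNorm(channels, dtype)]
        layers.append((f"res_block{i}", nn.Residual(branch, projection)))
        layers.append((f"res_block{i}_pool", nn.MaxPool1d(2)))
        c_in = channels
        length //= 2
    layers.append(("flatten", nn.Flatten()))
    d_in = c_in * length
    for i, width in enumerate(spec.dense_widths, start=1):
        _dense_block(rng, dtype, d_in, width, i, layers, spec.dropout)
        d_in = width
    layers.append(("logits", nn.Dense(d_in, spec.n_classes, rng, dtype)))
    return nn.Network(layers, spec.n_classes, dtype)


def _build_net_cnn2d(spec: ArchitectureSpec, rng, dtype) -> nn.Network:
    hh, ww = spec.input_shape
    layers: list[tuple[str, nn.Layer]] = []
    c_in = 1
    for i, ((c_out, k), pool) in enumerate(
        zip(
            zip(spec.conv_kernel_counts, spec.conv_kernel_sizes),
            spec.pool_sizes,
        ),
        start=1,
    ):
        layers.append((f"conv_block{i}_conv", nn.Conv2d(c_in, c_out, k, rng, dtype)))
        layers.append((f"conv_block{i}_bn", nn.BatchNorm(c_out, dtype)))
        layers.append((f"conv_block{i}_pool", nn.MaxPool2d(pool)))
        layers.append((f"conv_block{i}", nn.ReLU()))
        c_in = c_out
        hh //= pool[0]
        ww //= pool[1]
    layers.append(("flatten", nn.Flatten()))
    d_in = c_in * hh * ww
    for i, width in enumerate(spec.dense_widths, start=1):
        _dense_block(rng, dtype, d_in, width, i, layers, spec.dropout)
        d_in = width
    layers.append(("logits", nn.Dense(d_in, spec.n_classes, rng, dtype)))
    return nn.Network(layers, spec.n_classes, dtype)


_BUILDERS = {
    "cnn1d_1": _build_net_cnn1d_1,
    "cnn1d_2": _build_net_cnn1d_2,
    "cnn2d": _build_net_cnn2d,
}


def build_cnn1d_1(input_length: int, n_classes: int = 12) -> ArchitectureSpec:
    """AlexNet-flavoured 1-D CNN: four conv blocks (512/128/64/16 kernels of
    size 3, each with batch norm, max-pool 2 and ReLU) and dense blocks of
    256/64/32 with dropout 0.3."""
    if input_length < 16:
        raise SizeError("input_length must be >= 16 (four pooling stages)")
    return ArchitectureSpec(
        name="cnn1d_1",
        input_shape=(input_length,),
        n_classes=n_classes,
        conv_kernel_counts=(512, 128, 64, 16),
        conv_kernel_sizes=(3, 3, 3, 3),
        dense_widths=(256, 64, 32),
    )


def build_cnn1d_2(input_length: int, n_classes: int = 12) -> ArchitectureSpec:
    """ResNet-flavoured 1-D CNN: an initial 64-kernel conv block followed by
    residual blocks of (64, 2), (128, 2), (256, 2) convs with skip paths, then
    a dense block of 128."""
    if input_length < 16:
        raise SizeError("input_length must be >= 16 (four pooling stages)")
    return ArchitectureSpec(
        name="cnn1d_2",
        input_shape=(input_length,),
        n_classes=n_classes,
        conv_kernel_counts=(64,),
        conv_kernel_sizes=(3,),
        residual_blocks=((64, 2), (128, 2), (256, 2)),
        dense_widths=(128,),
    )


def build_cnn2d(input_shape: tuple[int, int], n_classes: int = 12) -> ArchitectureSpec:
    """2-D CNN for spectral matrices: two conv blocks (64 kernels of 7×7 then
    16 of 3×3), dense blocks of 256 and 64.  Pooling is 4×4 per block (shrunk
    per-axis where an input dimension is too small), which keeps this network
    far smaller than the 1-D architectures."""
    hh, ww = input_shape
    if hh < 8 or ww < 8:
        raise SizeError("spectral matrix must be at least 8x8")
    pools = []
    for _ in range(2):
        p = (min(4, hh), min(4, ww))
        pools.append(p)
        hh //= p[0]
        ww //= p[1]
        if hh < 1 or ww < 1:
            raise SizeError("input too small for two pooling stages")
    return ArchitectureSpec(
        name="cnn2d",
        input_shape=input_shape,
        n_classes=n_classes,
        conv_kernel_counts=(64, 16),
        conv_kernel_sizes=(7, 3),
        dense_widths=(256, 64),
        pool_sizes=tuple(pools),
    )


@dataclass(frozen=True)
class TrainSchedule:
    """Staged SGD protocol: (learning rate, validation threshold) pairs.

    Learning rates must strictly decrease and thresholds strictly increase
    (each within [0, 1]); a stage ends at its threshold or at
    ``max_iterations_per_stage`` epochs.
    """

    stages: tuple[tuple[float, float], ...]
    max_iterations_per_stage: int = 1000
    seed: int = 0
    batch_size: int = 32
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if not self.stages:
            raise ScheduleError("schedule needs at least one stage")
        lrs = [s[0] for s in self.stages]
        ths = [s[1] for s in self.stages]
        if any(lr <= 0 for lr in lrs):
            raise ScheduleError("learning rates must be positive")
        if any(b >= a for a, b in zip(lrs, lrs[1:])):
            raise ScheduleError("learning rates must strictly decrease")
        if any(not 0 <= t <= 1 for t in ths):
            raise ScheduleError("thresholds must lie in [0, 1]")
        if any(b <= a for a, b in zip(ths, ths[1:])):
            raise ScheduleError("thresholds must strictly increase")
        if self.max_iterations_per_stage < 1:
            raise ScheduleError("max_iterations_per_stage must be >= 1")


#: The staged protocol reported for the 2-D CNN at h=150 (underground parts).
PAPER_SCHEDULE = TrainSchedule(
    stages=((0.1, 0.6), (0.05, 0.75), (0.01, 0.92), (0.005, 0.96))
)


@dataclass
class TrainResult:
    """Full staged-training record plus the trained network."""

    history: list[tuple[int, int, float, float]] = field(default_factory=list)
    stopped_reason: list[str] = field(default_factory=list)
    model_ref: nn.Network | None = None
    classes_: np.ndarray | None = None

    def final_validation_accuracy(self) -> float:
        return self.history[-1][3] if self.history else float("nan")


def _as_channeled(x: np.ndarray) -> np.ndarray:
    """Insert the channel axis: (N, L) → (N, 1, L); (N, n, h) → (N, 1, n, h)."""
    x = np.asarray(x)
    if x.ndim in (2, 3):
        return x[:, None, ...]
    return x


def train_staged(
    spec: ArchitectureSpec,
    calibration: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    schedule: TrainSchedule,
) -> TrainResult:
    """Run the staged SGD protocol; deterministic for a given schedule seed.

    Labels may be arbitrary (e.g. origin codes 1..12); they are indexed
    against their sorted unique values.  The recorded calibration accuracy is
    the epoch's running mini-batch accuracy.
    """
    x_cal, y_cal = calibration
    x_val, y_val = validation
    x_cal = np.ascontiguousarray(_as_channeled(x_cal), dtype=np.float32)
    x_val = np.ascontiguousarray(_as_channeled(x_val), dtype=np.float32)
    classes = np.unique(np.concatenate([y_cal, y_val]))
    if classes.size > spec.n_classes:
        raise ValueError(f"{classes.size} classes exceed n_classes={spec.n_classes}")
    y_cal_idx = np.searchsorted(classes, y_cal)
    y_val_idx = np.searchsorted(classes, y_val)

    net = spec.build(seed=schedule.seed)
    rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, 0xC4A5]))
    result = TrainResult(model_ref=net, classes_=classes)
    n = x_cal.shape[0]
    for stage_idx, (lr, threshold) in enumerate(schedule.stages, start=1):
        reason = "iteration_cap"
        for epoch in range(1, schedule.max_iterations_per_stage + 1):
            order = rng.permutation(n)
            accs, losses = [], []
            for start in range(0, n, schedule.batch_size):
                batch = order[start : start + schedule.batch_size]
                loss, acc = net.train_batch(
                    x_cal[batch], y_cal_idx[batch], lr, schedule.momentum
                )
                if not np.isfinite(loss):
                    raise nn.DivergenceError(
                        f"non-finite loss in stage {stage_idx} (lr={lr})"
                    )
                losses.append(loss)
                accs.append(acc)
            val_acc = float(np.mean(net.predict(x_val) == y_val_idx))
            result.history.append((stage_idx, epoch, float(np.mean(accs)), val_acc))
            if val_acc >= threshold:
                reason = "threshold_met"
                break
        result.stopped_reason.append(reason)
    return result


@dataclass
class FittedBaseline:
    kind: str
    model: object
    hyperparams: dict
    classes_: np.ndarray


def fit_baseline(
    kind: str,
    calibration: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    search: dict | None = None,
) -> FittedBaseline:
    """Fit one classical baseline with its standard hyperparameter search.

    ``search`` may override: ``k_range`` (KNN), ``c_exponents``/``g_exponents``
    and ``cv_folds`` (SVM), ``seed``.
    """
    search = dict(search or {})
    x_cal, y_cal = calibration
    x_val, y_val = validation
    x_cal = np.asarray(x_cal, dtype=float).reshape(len(y_cal), -1)
    x_val = np.asarray(x_val, dtype=float).reshape(len(y_val), -1)

    if kind == "lda":
        model = LinearDiscriminantAnalysis()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model.fit(x_cal, y_cal)
        if any("collinear" in str(w.message).lower() for w in caught):
            warnings.warn(
                "collinear calibration variables: refitting LDA with ridge "
                "(lsqr + automatic shrinkage)",
                stacklevel=2,
            )
            model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            model.fit(x_cal, y_cal)
        hyper = {"solver": model.solver}
    elif kind == "knn":
        k_range = search.get("k_range", range(3, 21))
        best_k, best_acc = None, -1.0
        for k in k_range:
            if k > len(y_cal):
                continue
            model = KNeighborsClassifier(n_neighbors=k).fit(x_cal, y_cal)
            acc = float(np.mean(model.predict(x_val) == y_val))
            if acc > best_acc:  # ties keep the smaller (earlier) k
                best_k, best_acc = k, acc
        model = KNeighborsClassifier(n_neighbors=best_k).fit(x_cal, y_cal)
        hyper = {"k": best_k, "validation_accuracy": best_acc}
    elif kind == "svm":
        c_exps = search.get("c_exponents", range(-8, 9))
        g_exps = search.get("g_exponents", range(-8, 9))
        folds = search.get("cv_folds", 5)
        seed = search.get("seed", 0)
        cv = StratifiedKFold(
            n_splits=min(folds, np.bincount(np.unique(y_cal, return_inverse=True)[1]).min()),
            shuffle=True,
            random_state=seed,
        )
        best, best_acc = None, -1.0
        for ce in c_exps:
            for ge in g_exps:
                clf = SVC(kernel="rbf", C=10.0**ce, gamma=10.0**ge)
                acc = float(np.mean(cross_val_score(clf, x_cal, y_cal, cv=cv)))
                if acc > best_acc:  # ties keep the smaller (c, g) pair
                    best, best_acc = (ce, ge), acc
        model = SVC(kernel="rbf", C=10.0 ** best[0], gamma=10.0 ** best[1]).fit(x_cal, y_cal)
        hyper = {"c": 10.0 ** best[0], "gamma": 10.0 ** best[1], "cv_accuracy": best_acc}
    else:
        raise ValueError(f"unknown baseline kind '{kind}'")
    return FittedBaseline(kind=kind, model=model, hyperparams=hyper, classes_=np.unique(y_cal))


def predict(model_ref, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus class scores for either model family.

    For networks the scores are softmax probabilities (rows sum to 1) and
    labels come from the training-time class order stored by the caller; for
    baselines, predict/predict_proba or the decision function.
    """
    if isinstance(model_ref, TrainResult):
        x = _as_channeled(data)
        proba = model_ref.model_ref.predict_proba(x)
        labels = model_ref.classes_[np.argmax(proba, axis=1)]
        return labels, proba
    if isinstance(model_ref, nn.Network):
        x = _as_channeled(data)
        proba = model_ref.predict_proba(x)
        return np.argmax(proba, axis=1), proba
    if isinstance(model_ref, FittedBaseline):
        model_ref = model_ref.model
    x = np.asarray(data, dtype=float).reshape(len(data), -1)
    labels = model_ref.predict(x)
    if hasattr(model_ref, "predict_proba"):
        scores = model_ref.predict_proba(x)
    else:
        scores = model_ref.decision_function(x)
    return labels, scores
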