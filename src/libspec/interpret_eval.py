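"""Model evaluation and interpretation.

Accuracy and confusion matrices follow the usual convention (rows = true
class, columns = predicted).  Saliency maps are input gradients: the absolute
gradient of the target class's pre-softmax score with respect to each input
pixel of the spectral matrix; per-origin maps average the saliency of every
prediction-set spectrum of that origin, and the pixel↔variable bijection of
the matrixization maps ranked pixels back to wavelengths.  t-SNE views embed
intermediate network activations (channels as features, spatial positions
averaged) after a PCA reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .matrixize import pixel_to_variable
from .models import TrainResult, _as_channeled
from .nn import Network

__all__ = [
    "ConfusionMatrix",
    "SaliencyResult",
    "accuracy",
    "round_percent",
    "confusion",
    "saliency_map",
    "origin_average_saliency",
    "tsne_layer_view",
]


def accuracy(y_true, y_pred) -> float:
    """Percentage of correctly discriminated spectra: 100 · correct / total."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot compute accuracy of an empty label set")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return 100.0 * float(np.mean(y_true == y_pred))


def round_percent(value: float, ndigits: int = 2) -> float:
    """Two-decimal half-up rounding used when reporting accuracies."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be K x K")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.total


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Tally counts[i, j] = #{true class i+1 predicted as class j+1}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 1 or y.max() > n_classes):
            raise ValueError(f"{name} labels must lie in 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts=counts, classes=tuple(range(1, n_classes + 1)))


@dataclass(frozen=True)
class SaliencyResult:
    """Per-origin averaged pixel weights plus their wavelength ranking."""

    weights: np.ndarray  # (n, h), non-negative
    origin: int
    ranked_wavelengths: tuple  # ((wavelength_nm, weight), ...) descending


def saliency_map(model_ref, input_matrix: np.ndarray, target_class_index: int) -> np.ndarray:
    """|∂ score_c / ∂ pixel| for one input; same shape as the input."""
    net = model_ref.model_ref if isinstance(model_ref, TrainResult) else model_ref
    if not isinstance(net, Network):
        raise TypeError("saliency requires a differentiable network handle")
    x = np.asarray(input_matrix, dtype=float)
    batch = _as_channeled(x[None, ...])
    grad = net.input_gradient(batch, target_class_index)
    return np.abs(grad[0, 0])


def origin_average_saliency(
    train_result: TrainResult,
    prediction_stack: np.ndarray,
    origins: np.ndarray,
    origin: int,
    wavelengths: np.ndarray,
) -> SaliencyResult:
    """Average the saliency maps of every prediction-set spectrum of an origin
    (for that origin's true class) and rank the pixels' wavelengths.

    ``prediction_stack`` is the (n_spectra, n, h) matrixized prediction set;
    ``wavelengths`` is the full axis (the first n·h entries are the retained
    variables).
    """
    origins = np.asarray(origins)
    rows = np.nonzero(origins == origin)[0]
    if rows.size == 0:
        raise ValueError(f"origin {origin} absent from the prediction set")
    class_index = int(np.searchsorted(train_result.classes_, origin))
    if train_result.classes_[class_index] != origin:
        raise ValueError(f"origin {origin} unknown to the model")
    net = train_result.model_ref
    batch = _as_channeled(prediction_stack[rows])
    grads = np.abs(net.input_gradient(batch, class_index))[:, 0]
    weights = grads.mean(axis=0)
    n, h = weights.shape
    flat = weights.reshape(-1)
    order = np.argsort(-flat, kind="stable")
    ranked = tuple(
        (float(wavelengths[pixel_to_variable(i // h, i % h, h)]), float(flat[i]))
        for i in order
    )
    return SaliencyResult(weights=weights, origin=origin, ranked_wavelengths=ranked)


def tsne_layer_view(
    model_ref,
    data: np.ndarray,
    layer_name: str,
    perplexity: float = 30.0,
    init_dims: int = 12,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding of a layer's activations, one point per spectrum.

    Convolutional activations are averaged over their spatial axes, keeping
    channels as features; the features are PCA-reduced to ``init_dims`` before
    t-SNE (perplexity 30 by default).  Seeded and reproducible.
    """
    net = model_ref.model_ref if isinstance(model_ref, TrainResult) else model_ref
    acts = net.activations(_as_channeled(np.asarray(data, dtype=float)), layer_name)
    if acts.ndim > 2:
        acts = acts.mean(axis=tuple(range(2, acts.ndim)))
    acts = np.asarray(acts, dtype=np.float64)
    n = acts.shape[0]
    n_comp = min(init_dims, acts.shape[1], n)
    reduced = PCA(n_components=n_comp, random_state=seed).fit_transform(acts)
    perplexity = min(perplexity, (n - 1) / 3.0)
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    ).fit_transform(reduced)
    return np.asarray(emb)
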