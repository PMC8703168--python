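"""Spectrum ↔ matrix recombination.

A 1-D spectrum of V variables is cut into n = ⌊V/h⌋ consecutive segments of h
variables and the segments stacked row-wise into an n×h "spectral matrix" that
a 2-D CNN can consume.  The map is bijective on the retained prefix: pixel
(row, col) holds variable row·h + col (0-based, row-major), so saliency
weights on pixels translate back to wavelengths exactly.  The V − n·h
trailing variables that cannot fill a complete row are discarded (and
counted); callers are warned because discarded channels may carry lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralMatrix",
    "to_matrix",
    "from_matrix",
    "pixel_to_variable",
    "variable_to_pixel",
    "stack_matrices",
]

DEFAULT_H = 150


@dataclass(frozen=True)
class SpectralMatrix:
    values: np.ndarray  # (n, h)
    h: int
    n: int
    discarded: int
    source_length: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.n, self.h):
            raise ValueError(f"values shape {v.shape} != (n={self.n}, h={self.h})")
        if self.n != self.source_length // self.h:
            raise ValueError("n must be floor(V / h)")
        if self.discarded != self.source_length - self.n * self.h:
            raise ValueError("discarded must be V - n*h")


def to_matrix(spectrum: np.ndarray, h: int = DEFAULT_H) -> SpectralMatrix:
    """Segment a spectrum into ⌊V/h⌋ rows of h variables (row-major)."""
    x = np.asarray(spectrum, dtype=float).ravel()
    v = x.size
    if h < 1:
        raise ValueError("h must be >= 1")
    if h > v:
        raise ValueError(f"segment length h={h} exceeds spectrum length V={v}")
    n = v // h
    discarded = v - n * h
    if discarded:
        warnings.warn(
            f"discarding {discarded} trailing variables (indices {n * h}..{v - 1})",
            stacklevel=2,
        )
    return SpectralMatrix(
        values=x[: n * h].reshape(n, h), h=h, n=n, discarded=discarded, source_length=v
    )


def from_matrix(matrix: SpectralMatrix) -> np.ndarray:
    """Undo the segmentation: the n·h retained variables in original order."""
    return matrix.values.reshape(-1).copy()


def pixel_to_variable(row: int, col: int, h: int) -> int:
    """Variable index of pixel (row, col) under segment length h (0-based)."""
    if not 0 <= col < h:
        raise IndexError(f"column {col} outside [0, {h})")
    if row < 0:
        raise IndexError("row must be >= 0")
    return row * h + col


def variable_to_pixel(index: int, h: int) -> tuple[int, int]:
    """Inverse of pixel_to_variable."""
    if index < 0:
        raise IndexError("variable index must be >= 0")
    return index // h, index % h


def stack_matrices(intensities: np.ndarray, h: int = DEFAULT_H) -> tuple[np.ndarray, SpectralMatrix]:
    """Matrixize every row of an (n_spectra, V) array.

    Returns the (n_spectra, n, h) stack plus the SpectralMatrix of the first
    spectrum as the shared geometry/provenance record.
    """
    intensities = np.asarray(intensities, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        first = to_matrix(intensities[0], h)
    n = first.n
    stack = intensities[:, : n * h].reshape(intensities.shape[0], n, h)
    return stack, first
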