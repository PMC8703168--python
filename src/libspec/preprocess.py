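"""Spectral preprocessing: wavelet denoising and area normalization.

Denoising is a multi-level Daubechies decomposition with soft thresholding of
the detail coefficients at the universal threshold sigma·sqrt(2·ln V), where
sigma is the robust MAD estimate from the finest detail level.  The wavelet
order and decomposition level are tuned by exhaustive grid search over [3, 10]
maximizing the mean signal-to-noise ratio across spectra.

Area normalization divides each spectrum by its total intensity, X_i = x_i/Σx_j,
removing shot-to-shot energy fluctuations so spectra sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pywt

from .io_core import SpectrumSet

__all__ = [
    "WaveletParams",
    "ParameterError",
    "DegenerateSNRError",
    "NormalizationError",
    "wavelet_denoise",
    "snr",
    "optimize_wavelet",
    "area_normalize",
    "denoise_set",
    "normalize_set",
]

PARAM_RANGE = (3, 10)


class ParameterError(ValueError):
    """Wavelet parameters outside the supported range for this input."""


class DegenerateSNRError(ZeroDivisionError):
    """Residual is exactly zero: SNR is unbounded.

    Callers searching over parameters should treat this candidate as +inf.
    """


class NormalizationError(ValueError):
    """Spectrum total intensity is not positive."""


@dataclass(frozen=True)
class WaveletParams:
    """Daubechies order and decomposition level, both searched in [3, 10]."""

    family_order: int
    level: int

    def __post_init__(self) -> None:
        lo, hi = PARAM_RANGE
        if not (lo <= self.family_order <= hi and lo <= self.level <= hi):
            raise ParameterError(
                f"wavelet order/level must lie in [{lo}, {hi}], "
                f"got ({self.family_order}, {self.level})"
            )

    @property
    def wavelet(self) -> str:
        return f"db{self.family_order}"


def wavelet_denoise(spectrum: np.ndarray, params: WaveletParams) -> np.ndarray:
    """Soft-threshold wavelet denoising; output has the input's length.

    Symmetric boundary extension; the universal threshold uses the MAD-based
    noise estimate from the finest detail level.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1:
        raise ParameterError("spectrum must be 1-D")
    if x.size < 2**params.level:
        raise ParameterError(
            f"spectrum of length {x.size} too short for level {params.level}"
        )
    coeffs = pywt.wavedec(x, params.wavelet, mode="symmetric", level=params.level)
    detail_fine = coeffs[-1]
    sigma = np.median(np.abs(detail_fine - np.median(detail_fine))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(x.size))
    denoised_coeffs = [coeffs[0]] + [
        pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
    ]
    out = pywt.waverec(denoised_coeffs, params.wavelet, mode="symmetric")
    return out[: x.size]


def snr(original: np.ndarray, denoised: np.ndarray) -> float:
    """Peak signal over residual noise: max(denoised) / SD(original − denoised)."""
    original = np.asarray(original, dtype=float)
    denoised = np.asarray(denoised, dtype=float)
    if original.shape != denoised.shape:
        raise ParameterError("original and denoised must have equal length")
    resid_sd = float(np.std(original - denoised))
    if resid_sd == 0.0:
        raise DegenerateSNRError(
            "residual SD is zero; treat this candidate as +inf in a search"
        )
    return float(np.max(denoised)) / resid_sd


def _mean_snr(intensities: np.ndarray, params: WaveletParams) -> float:
    vals = []
    for row in intensities:
        den = wavelet_denoise(row, params)
        try:
            vals.append(snr(row, den))
        except DegenerateSNRError:
            vals.append(np.inf)
    return float(np.mean(vals))


def optimize_wavelet(
    sset: SpectrumSet,
    order_range: tuple[int, int] = PARAM_RANGE,
    level_range: tuple[int, int] = PARAM_RANGE,
) -> WaveletParams:
    """Exhaustive (order, level) grid search maximizing mean SNR over spectra.

    Ties break to the lexicographically smallest (order, level), so the result
    is deterministic.
    """
    if sset.n_spectra == 0:
        raise ParameterError("cannot optimize wavelet parameters on an empty set")
    best: WaveletParams | None = None
    best_snr = -np.inf
    orders = range(order_range[0], order_range[1] + 1)
    levels = range(level_range[0], level_range[1] + 1)
    for order, level in product(orders, levels):
        params = WaveletParams(order, level)
        if sset.n_variables < 2**level:
            continue
        value = _mean_snr(sset.intensities, params)
        if value > best_snr:
            best, best_snr = params, value
    if best is None:
        raise ParameterError("no feasible (order, level) candidate for this set")
    return best


def area_normalize(spectrum: np.ndarray) -> np.ndarray:
    """X_i = x_i / Σ_j x_j; the result sums to 1 (within 1e-12)."""
    x = np.asarray(spectrum, dtype=float)
    total = x.sum()
    if not total > 0:
        raise NormalizationError("spectrum sum must be positive for area normalization")
    return x / total


def denoise_set(sset: SpectrumSet, params: WaveletParams) -> SpectrumSet:
    """Denoise every spectrum of a set with one (order, level) pair."""
    out = np.stack([wavelet_denoise(row, params) for row in sset.intensities])
    return sset.with_intensities(
        out, note=f"wavelet_denoise:db{params.family_order},level={params.level}"
    )


def normalize_set(sset: SpectrumSet) -> SpectrumSet:
    out = np.stack([area_normalize(row) for row in sset.intensities])
    return sset.with_intensities(out, note="area_normalize")
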