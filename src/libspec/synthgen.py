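"""Synthetic LIBS-like datasets with a known hierarchical sampling design.

Real LIBS surveys of medicinal plants sample a hierarchy: geographical origin
→ plant → pressed tablet (one per plant part) → laser position on the tablet.
This module emulates that design on a synthetic emission spectrum so every
stage of the classification pipeline has a planted ground truth: which
channels carry signal, which are pure near-zero noise, and which emission
lines actually differ between origins.

The spectral model is deliberately simple — a sum of Gaussian (optionally
Lorentzian) emission lines on a uniform wavelength grid, with multiplicative
origin and plant effects and additive channel noise.  It is a test harness
for the pipeline, not a plasma model: no self-absorption, Stark broadening or
matrix effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .io_core import SpectrumSet, ValidationError, WavelengthAxis

__all__ = [
    "LineSpec",
    "OriginProfile",
    "GeneratorConfig",
    "default_lines",
    "default_profiles",
    "default_config",
    "acceptance_fixture_config",
    "render_clean_spectrum",
    "generate_dataset",
    "baseline_channel_mask",
    "planted_discriminative_channels",
    "between_class_distance",
]

#: Part-specific intensity factors by element: aerial tissue shows stronger Ca
#: emission while H lines are essentially invisible there but clear in roots.
PART_FACTORS = {
    "Ca": {"underground": 1.0, "aerial": 1.5},
    "H": {"underground": 1.0, "aerial": 0.1},
}


@dataclass(frozen=True)
class LineSpec:
    """One emission line: Gaussian centre/width in nm and a base peak height."""

    center: float
    width: float
    base_intensity: float
    element: str = ""
    discriminative: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"line {self.center} nm: width must be > 0")
        if self.base_intensity < 0:
            raise ValidationError(f"line {self.center} nm: base_intensity must be >= 0")


@dataclass(frozen=True)
class OriginProfile:
    """Per-origin multiplicative line factors plus plant-level jitter scale."""

    origin: int
    multipliers: np.ndarray
    jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        m = np.asarray(self.multipliers, dtype=float)
        object.__setattr__(self, "multipliers", m)
        if np.any(m <= 0):
            raise ValidationError("origin multipliers must be positive")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_variables: int
    axis_range: tuple[float, float]
    lines: tuple[LineSpec, ...]
    profiles: tuple[OriginProfile, ...]
    plants_per_origin: tuple[int, ...]
    tablets_per_plant_part: int = 1
    positions_per_tablet: int = 16
    parts: tuple[str, ...] = ("underground", "aerial")
    noise_sd: float = 0.01
    baseline_noise_factor: float = 1e-4  # ε: baseline channels get ε·noise_sd
    baseline_fraction: float = 0.85
    peak_shape: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.plants_per_origin) != len(self.profiles):
            raise ValidationError("plants_per_origin must match number of profiles")
        if not (0 <= self.baseline_fraction < 1):
            raise ValidationError("baseline_fraction must lie in [0, 1)")
        if self.peak_shape not in {"gaussian", "lorentzian"}:
            raise ValidationError("peak_shape must be 'gaussian' or 'lorentzian'")
        for p in self.profiles:
            if len(p.multipliers) != len(self.lines):
                raise ValidationError("each profile needs one multiplier per line")

    @property
    def n_records(self) -> int:
        return (
            sum(self.plants_per_origin)
            * len(self.parts)
            * self.tablets_per_plant_part
            * self.positions_per_tablet
        )

    def axis(self) -> WavelengthAxis:
        lo, hi = self.axis_range
        return WavelengthAxis(np.linspace(lo, hi, self.n_variables))


def default_lines() -> tuple[LineSpec, ...]:
    """The shipped ~40-line list (Ca/H lines at their printed NIST positions)."""
    with resources.files("libspec.data").joinpath("default_lines.csv").open() as fh:
        table = pd.read_csv(fh)
    return tuple(
        LineSpec(
            center=row.center_nm,
            width=row.width_nm,
            base_intensity=row.base_intensity,
            element=row.element,
            discriminative=bool(row.discriminative),
        )
        for row in table.itertuples()
    )


def default_profiles(
    lines: tuple[LineSpec, ...],
    n_origins: int = 12,
    effect_scale: float = 0.35,
    jitter_sd: float = 0.05,
    seed: int = 20211210,
) -> tuple[OriginProfile, ...]:
    """Log-normal origin effects on the discriminative (nutrient-element) lines.

    Matrix-element lines (C, H, N, O, CN, C2, CH) are held constant across
    origins — every sample is the same species — while nutrient lines get a
    per-origin multiplier exp(effect_scale · z).  The profile table is frozen
    by its own seed so datasets differ only through ``GeneratorConfig.seed``.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    disc = np.array([ln.discriminative for ln in lines])
    for origin in range(1, n_origins + 1):
        mult = np.ones(len(lines))
        mult[disc] = np.exp(effect_scale * rng.standard_normal(disc.sum()))
        profiles.append(OriginProfile(origin=origin, multipliers=mult, jitter_sd=jitter_sd))
    return tuple(profiles)


def signature_profiles(
    lines: tuple[LineSpec, ...],
    n_origins: int = 12,
    effect_scale: float = 0.5,
    jitter_sd: float = 0.02,
) -> tuple[OriginProfile, ...]:
    """Equidistant origin signatures from Hadamard sign patterns.

    Each origin's discriminative-line multipliers are exp(±effect_scale) with
    the signs taken from distinct rows of a Hadamard matrix (cycled over the
    lines), so every pair of origins differs on exactly half the pattern and
    no two origins collapse onto each other after area normalization.  Used
    by the separable test fixture.
    """
    from scipy.linalg import hadamard

    disc_idx = [i for i, ln in enumerate(lines) if ln.discriminative]
    size = 1
    while size < n_origins + 1:
        size *= 2
    had = hadamard(size)
    profiles = []
    for origin in range(1, n_origins + 1):
        mult = np.ones(len(lines))
        row = had[origin]  # skip the all-ones row 0
        for j, li in enumerate(disc_idx):
            mult[li] = np.exp(effect_scale * row[j % size])
        profiles.append(OriginProfile(origin=origin, multipliers=mult, jitter_sd=jitter_sd))
    return tuple(profiles)


def default_config(seed: int = 0) -> GeneratorConfig:
    """The full-survey design: 22015 channels over 229–878 nm, 12 origins,
    ten plants each except origin 2 with eight, both plant parts, one tablet
    per plant and part, 16 laser positions per tablet → 3,776 spectra."""
    lines = default_lines()
    plants = tuple(8 if origin == 2 else 10 for origin in range(1, 13))
    return GeneratorConfig(
        n_variables=22015,
        axis_range=(229.0, 878.0),
        lines=lines,
        profiles=default_profiles(lines),
        plants_per_origin=plants,
        seed=seed,
    )


def acceptance_fixture_config(seed: int = 0) -> GeneratorConfig:
    """Reduced, strongly separable fixture: 12 origins, two plants per origin,
    eight positions per tablet, 2400 channels on the same 229–878 nm range.

    Effect sizes are large and noise small so the classes are separable by
    design; this is the harness for end-to-end recovery tests, not a model of
    real between-origin effect sizes.
    """
    lines = default_lines()
    return GeneratorConfig(
        n_variables=1200,
        axis_range=(229.0, 878.0),
        lines=lines,
        profiles=signature_profiles(lines, effect_scale=1.0, jitter_sd=0.01),
        plants_per_origin=(2,) * 12,
        positions_per_tablet=8,
        noise_sd=0.003,
        seed=seed,
    )


def render_clean_spectrum(lines, multipliers, axis: WavelengthAxis, peak_shape="gaussian") -> np.ndarray:
    """Noise-free spectrum: Σ multiplier·base_intensity·unit-peak(λ; center, width).

    The unit peak is a Gaussian with sigma = width (or a Lorentzian with HWHM
    = width), so each line contributes a peak of height multiplier·base.
    """
    lam = axis.values
    out = np.zeros_like(lam)
    multipliers = np.asarray(multipliers, dtype=float)
    for line, mult in zip(lines, multipliers, strict=True):
        z = (lam - line.center) / line.width
        if peak_shape == "gaussian":
            peak = np.exp(-0.5 * z * z)
        else:
            peak = 1.0 / (1.0 + z * z)
        out += mult * line.base_intensity * peak
    return out


def baseline_channel_mask(config: GeneratorConfig) -> np.ndarray:
    """Boolean mask of the planted pure-noise channels.

    The ``floor(baseline_fraction · V)`` channels farthest (in units of each
    line's width) from every line centre are designated baseline: they carry
    only near-zero noise, giving the SD filter an exact ground truth.
    """
    lam = config.axis().values
    dist = np.full(lam.size, np.inf)
    for line in config.lines:
        np.minimum(dist, np.abs(lam - line.center) / line.width, out=dist)
    n_baseline = int(np.floor(config.baseline_fraction * lam.size))
    mask = np.zeros(lam.size, dtype=bool)
    if n_baseline:
        # ties broken by channel order via stable argsort on (-dist, index)
        order = np.argsort(-dist, kind="stable")
        mask[order[:n_baseline]] = True
    return mask


def planted_discriminative_channels(
    config: GeneratorConfig, n_widths: float = 1.0
) -> np.ndarray:
    """Indices of non-baseline channels within ``n_widths``·width of a line
    whose multiplier actually varies across origins (the planted signal)."""
    mult = np.stack([p.multipliers for p in config.profiles])
    varies = mult.max(axis=0) / mult.min(axis=0) > 1.05
    lam = config.axis().values
    near = np.zeros(lam.size, dtype=bool)
    for line, v in zip(config.lines, varies, strict=True):
        if v:
            near |= np.abs(lam - line.center) <= n_widths * line.width
    near &= ~baseline_channel_mask(config)
    return np.nonzero(near)[0]


def between_class_distance(config: GeneratorConfig, part: str = "underground") -> float:
    """Mean pairwise Euclidean distance between the origins' clean spectra —
    a Bayes-separability proxy that grows with origin effect spread."""
    axis = config.axis()
    part_mult = _part_multipliers(config.lines, part)
    clean = np.stack(
        [
            render_clean_spectrum(
                config.lines, p.multipliers * part_mult, axis, config.peak_shape
            )
            for p in config.profiles
        ]
    )
    k = clean.shape[0]
    dists = [
        float(np.linalg.norm(clean[i] - clean[j]))
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return float(np.mean(dists))


def _part_multipliers(lines, part: str) -> np.ndarray:
    return np.array(
        [PART_FACTORS.get(ln.element, {}).get(part, 1.0) for ln in lines]
    )


def generate_dataset(config: GeneratorConfig) -> SpectrumSet:
    """Draw the full hierarchical dataset described by ``config``.

    Per plant a multiplicative log-normal random effect on every line, per
    spectrum additive Gaussian channel noise; baseline channels carry only
    |N(0, ε·noise_sd)|.  A given seed is bit-reproducible.
    """
    axis = config.axis()
    rng = np.random.default_rng(config.seed)
    baseline = baseline_channel_mask(config)
    signal_ch = ~baseline

    meta_rows: list[tuple] = []
    spectra: list[np.ndarray] = []
    plant_counter = 0
    for profile, n_plants in zip(config.profiles, config.plants_per_origin, strict=True):
        for _ in range(n_plants):
            plant_counter += 1
            plant_id = f"P{plant_counter:03d}"
            plant_effect = np.exp(
                profile.jitter_sd * rng.standard_normal(len(config.lines))
            )
            for part in config.parts:
                part_mult = _part_multipliers(config.lines, part)
                clean = render_clean_spectrum(
                    config.lines,
                    profile.multipliers * plant_effect * part_mult,
                    axis,
                    config.peak_shape,
                )
                clean = np.where(baseline, 0.0, clean)
                for tablet_k in range(config.tablets_per_plant_part):
                    tablet_id = f"{plant_id}-{part[:1]}{tablet_k + 1}"
                    for position in range(1, config.positions_per_tablet + 1):
                        spec = np.empty(config.n_variables)
                        spec[signal_ch] = np.maximum(
                            clean[signal_ch]
                            + config.noise_sd * rng.standard_normal(signal_ch.sum()),
                            0.0,
                        )
                        spec[baseline] = np.abs(
                            config.baseline_noise_factor
                            * config.noise_sd
                            * rng.standard_normal(baseline.sum())
                        )
                        meta_rows.append(
                            (profile.origin, plant_id, tablet_id, part, position)
                        )
                        spectra.append(spec)
    meta = pd.DataFrame(
        meta_rows, columns=["origin", "plant_id", "tablet_id", "part", "position"]
    )
    sset = SpectrumSet(
        axis=axis,
        meta=meta,
        intensities=np.asarray(spectra),
        provenance=[f"synthgen:seed={config.seed}"],
    )
    return sset


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Same design, different random draw."""
    return replace(config, seed=seed)
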