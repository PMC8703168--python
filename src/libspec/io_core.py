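"""Data model, file I/O and tablet-level splitting for hierarchical LIBS spectra.

A LIBS dataset is a flat table: one row per spectrum, with sample metadata
(geographical origin, plant, tablet, plant part, laser position on the tablet)
followed by the emission intensities on a shared wavelength axis.  Tablets are
the physical sampling unit (a pressed pellet ablated at several positions), so
dataset splitting happens at tablet level to avoid position-level leakage
between calibration, validation and prediction sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthAxis",
    "SpectrumSet",
    "DatasetSplit",
    "FormatError",
    "ValidationError",
    "read_spectra",
    "write_spectra",
    "split_by_tablet",
]

META_COLUMNS = ["origin", "plant_id", "tablet_id", "part", "position"]
PARTS = ("underground", "aerial")


class FormatError(ValueError):
    """A spectra/axis file does not have the expected shape or columns."""


class ValidationError(ValueError):
    """Metadata violates the data model (labels, positions, axis)."""


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing wavelength grid in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("wavelength axis must be a non-empty 1-D array")
        if not np.all(np.diff(values) > 0):
            raise ValidationError("wavelength axis must be strictly increasing")
        if values[0] < 100.0 or values[-1] > 1000.0:
            raise ValidationError("wavelength axis must lie within [100, 1000] nm")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class SpectrumSet:
    """A set of spectra sharing one wavelength axis.

    ``meta`` is a DataFrame with columns origin, plant_id, tablet_id, part,
    position (one row per spectrum); ``intensities`` is the aligned
    (n_spectra, n_variables) float array; ``provenance`` is an append-only log
    of the transforms already applied.
    """

    axis: WavelengthAxis
    meta: pd.DataFrame
    intensities: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-D array")
        if self.intensities.shape[1] != len(self.axis):
            raise ValidationError(
                f"intensities have {self.intensities.shape[1]} variables, "
                f"axis has {len(self.axis)}"
            )
        if list(self.meta.columns) != META_COLUMNS:
            raise ValidationError(f"meta columns must be {META_COLUMNS}")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValidationError("meta rows and intensity rows differ")
        origins = self.meta["origin"].to_numpy()
        if len(origins) and not np.all((origins >= 1) & (origins <= 12)):
            raise ValidationError("origin labels must lie in 1..12")
        bad_part = set(self.meta["part"]) - set(PARTS)
        if bad_part:
            raise ValidationError(f"unknown part labels: {sorted(bad_part)}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.intensities.shape[1]

    def tablet_ids(self) -> np.ndarray:
        """Distinct tablet identifiers, in order of first appearance."""
        return self.meta["tablet_id"].unique()

    def subset(self, row_mask: np.ndarray, note: str | None = None) -> "SpectrumSet":
        """Row-subset (spectra), keeping the axis and extending provenance."""
        sub = SpectrumSet(
            axis=self.axis,
            meta=self.meta.loc[row_mask].reset_index(drop=True),
            intensities=self.intensities[np.asarray(row_mask)],
            provenance=list(self.provenance),
        )
        if note:
            sub.provenance.append(note)
        return sub

    def select_part(self, part: str) -> "SpectrumSet":
        if part not in PARTS:
            raise ValidationError(f"part must be one of {PARTS}")
        mask = (self.meta["part"] == part).to_numpy()
        return self.subset(mask, note=f"select_part:{part}")

    def select_tablets(self, tablet_ids, note: str | None = None) -> "SpectrumSet":
        mask = self.meta["tablet_id"].isin(list(tablet_ids)).to_numpy()
        return self.subset(mask, note=note)

    def with_intensities(self, intensities: np.ndarray, note: str) -> "SpectrumSet":
        """Same metadata/axis, new intensity matrix; logs ``note``."""
        out = SpectrumSet(
            axis=self.axis,
            meta=self.meta.copy(),
            intensities=intensities,
            provenance=list(self.provenance),
        )
        out.provenance.append(note)
        return out


@dataclass(frozen=True)
class DatasetSplit:
    """Tablet-level partition into calibration/validation/prediction sets."""

    calibration: tuple
    validation: tuple
    prediction: tuple
    ratio: tuple

    def __post_init__(self) -> None:
        cal, val, pre = (
            set(self.calibration),
            set(self.validation),
            set(self.prediction),
        )
        if cal & val or cal & pre or val & pre:
            raise ValidationError("split subsets must be pairwise disjoint")

    def subset_of(self, sset: SpectrumSet, which: str) -> SpectrumSet:
        ids = getattr(self, which)
        return sset.select_tablets(ids, note=f"split:{which}")


def _read_axis(axis_path: Path) -> WavelengthAxis:
    try:
        values = (
            pd.read_csv(axis_path, header=None, float_precision="round_trip")
            .iloc[:, 0]
            .to_numpy(dtype=float)
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"cannot parse wavelength axis file {axis_path}: {exc}") from exc
    return WavelengthAxis(values)


def read_spectra(path, axis_path) -> SpectrumSet:
    """Read a spectra table (CSV/TSV) plus its wavelength axis file.

    The table must have the metadata columns origin, plant_id, tablet_id,
    part, position followed by one intensity column per axis wavelength
    (named v1..vV by convention; names beyond the count are not enforced).
    A ``<path>.provenance.json`` sidecar, if present, restores the transform log.
    """
    path, axis_path = Path(path), Path(axis_path)
    axis = _read_axis(axis_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    value_cols = [c for c in table.columns if c not in META_COLUMNS]
    if len(value_cols) != len(axis):
        raise FormatError(
            f"{path}: {len(value_cols)} intensity columns but axis has {len(axis)}"
        )
    intens = table[value_cols].to_numpy(dtype=float)
    bad_rows = np.nonzero(~np.isfinite(intens).all(axis=1))[0]
    if bad_rows.size:
        raise FormatError(f"{path}: non-finite intensity in data row {bad_rows[0]}")
    meta = table[META_COLUMNS].copy()
    provenance: list[str] = []
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())["provenance"]
    return SpectrumSet(axis=axis, meta=meta, intensities=intens, provenance=provenance)


def write_spectra(sset: SpectrumSet, path, axis_path=None) -> None:
    """Write a SpectrumSet as CSV/TSV (+ JSON provenance sidecar).

    Intensities are written with ``repr`` round-trip precision so that
    read_spectra(write_spectra(s)) reproduces finite values bit-exactly.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    value_cols = [f"v{i + 1}" for i in range(sset.n_variables)]
    table = pd.concat(
        [
            sset.meta.reset_index(drop=True),
            pd.DataFrame(sset.intensities, columns=value_cols),
        ],
        axis=1,
    )
    table.to_csv(path, sep=sep, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps({"provenance": sset.provenance}, indent=1))
    if axis_path is not None:
        pd.Series(sset.axis.values).to_csv(
            axis_path, index=False, header=False, float_format="%.17g"
        )


def split_counts(n_tablets: int, ratio) -> tuple[int, int, int]:
    """Tablet counts per subset for a cal:val:pre ratio.

    The two smaller subsets are rounded to the nearest tablet and the
    calibration set takes the remainder, e.g. 118 tablets at 3:1:1 give
    70/24/24 tablets (1120/384/384 spectra at 16 positions per tablet).
    """
    r = np.asarray(ratio, dtype=float)
    if r.shape != (3,) or np.any(r <= 0):
        raise ValidationError("ratio must be three positive numbers")
    total = r.sum()
    n_val = int(round(n_tablets * r[1] / total))
    n_pre = int(round(n_tablets * r[2] / total))
    n_cal = n_tablets - n_val - n_pre
    if min(n_cal, n_val, n_pre) < 1:
        raise ValidationError(
            f"cannot split {n_tablets} tablets into three non-empty subsets"
        )
    return n_cal, n_val, n_pre


def stratified_split_by_tablet(sset: SpectrumSet, ratio=(3, 1, 1), seed: int = 0) -> DatasetSplit:
    """Origin-stratified tablet split: every origin keeps at least one
    calibration tablet.

    Needed for designs with very few tablets per origin, where a plain random
    tablet split can leave a class entirely out of the calibration set and no
    classifier could predict it.  Per origin, tablets are shuffled and dealt
    to calibration first, then alternately to validation and prediction
    (alternation continues across origins so both stay balanced).
    """
    meta = sset.meta[["origin", "tablet_id"]].drop_duplicates()
    rng = np.random.default_rng(seed)
    cal: list = []
    val: list = []
    pre: list = []
    toggle = 0
    for origin in sorted(meta["origin"].unique()):
        tablets = np.sort(meta.loc[meta["origin"] == origin, "tablet_id"].to_numpy())
        tablets = tablets[rng.permutation(tablets.size)]
        if tablets.size >= 3:
            n_cal, n_val, n_pre = split_counts(tablets.size, ratio)
            cal += tablets[:n_cal].tolist()
            val += tablets[n_cal : n_cal + n_val].tolist()
            pre += tablets[n_cal + n_val :].tolist()
        else:
            cal.append(tablets[0])
            for t in tablets[1:]:
                (val if toggle == 0 else pre).append(t)
                toggle ^= 1
    return DatasetSplit(
        calibration=tuple(cal), validation=tuple(val), prediction=tuple(pre), ratio=tuple(ratio)
    )


def position_holdout_split(
    sset: SpectrumSet, seed: int = 0, n_val_positions: int = 2
) -> tuple[SpectrumSet, SpectrumSet, SpectrumSet]:
    """Few-tablet evaluation split: (calibration, validation, prediction) sets.

    For designs with only two tablets per origin a three-way tablet split
    cannot give every origin a calibration tablet *and* a validation tablet.
    Here, per origin, half the tablets (rounded up) go to calibration and the
    rest form a tablet-level prediction holdout; validation is carved out of
    the calibration tablets position-wise (``n_val_positions`` random laser
    positions per tablet), so it covers every origin and can steer early
    stopping, while the prediction set stays a clean unseen-tablet holdout.
    """
    rng = np.random.default_rng(seed)
    meta = sset.meta
    cal_rows = np.zeros(len(meta), dtype=bool)
    val_rows = np.zeros(len(meta), dtype=bool)
    pre_rows = np.zeros(len(meta), dtype=bool)
    for origin in sorted(meta["origin"].unique()):
        tablets = np.sort(meta.loc[meta["origin"] == origin, "tablet_id"].unique())
        tablets = tablets[rng.permutation(tablets.size)]
        n_cal = (tablets.size + 1) // 2
        for t in tablets[:n_cal]:
            rows = np.nonzero((meta["tablet_id"] == t).to_numpy())[0]
            held = rng.choice(rows, size=min(n_val_positions, rows.size - 1), replace=False)
            val_rows[held] = True
            cal_rows[np.setdiff1d(rows, held)] = True
        for t in tablets[n_cal:]:
            pre_rows[(meta["tablet_id"] == t).to_numpy()] = True
    return (
        sset.subset(cal_rows, note="split:calibration"),
        sset.subset(val_rows, note="split:validation"),
        sset.subset(pre_rows, note="split:prediction"),
    )


def split_by_tablet(sset: SpectrumSet, ratio=(3, 1, 1), seed: int = 0) -> DatasetSplit:
    """Randomly partition tablets into calibration/validation/prediction sets.

    The assignment is a seeded uniform permutation of the tablet identifiers;
    every spectrum of one tablet lands in exactly one subset.
    """
    tablets = np.sort(np.asarray(sset.tablet_ids()))
    if tablets.size < 3:
        raise ValidationError("need at least 3 tablets to split")
    n_cal, n_val, n_pre = split_counts(tablets.size, ratio)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(tablets.size)
    shuffled = tablets[perm]
    cal = tuple(shuffled[:n_cal].tolist())
    val = tuple(shuffled[n_cal : n_cal + n_val].tolist())
    pre = tuple(shuffled[n_cal + n_val :].tolist())
    return DatasetSplit(calibration=cal, validation=val, prediction=pre, ratio=tuple(ratio))
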