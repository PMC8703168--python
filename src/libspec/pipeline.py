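"""End-to-end pipeline orchestration.

A :class:`RunConfig` fully determines a run: the input (a spectra/axis file
pair or a simulation preset), the preprocessing, one of the two analysis
paths — ``variable_selection`` (SD filter → RF elimination → 1-D model or
classical baseline) or ``spectral_matrix`` (matrixize → 2-D CNN) — and the
named seeds for every source of randomness.  ``run_pipeline`` executes the
chosen path and returns a JSON-serializable report; reruns with the same
config reproduce all numeric outputs bit-exactly on one machine.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import interpret_eval, io_core, matrixize, models, preprocess, synthgen, varselect

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_pipeline"]

CNN_MODELS = {"cnn1d_1", "cnn1d_2", "cnn2d"}
BASELINES = {"lda", "knn", "svm"}
DEFAULT_SCHEDULE = [[0.1, 0.6], [0.05, 0.75], [0.01, 0.92], [0.005, 0.96]]


class ConfigError(ValueError):
    """The run configuration is not runnable."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    input: dict = field(default_factory=lambda: {"simulate": {"preset": "reduced"}})
    part: str = "underground"
    wavelet: object = None  # None | "auto" | [order, level]
    normalize: bool = True
    split_ratio: tuple = (3, 1, 1)
    split_method: str = "tablet"  # tablet | stratified_tablet | position_holdout
    path: str = "spectral_matrix"
    model: str = "cnn2d"
    h: int = matrixize.DEFAULT_H
    sd_mode: str = "knee"
    sd_threshold: float | None = None
    sd_keep_top: int | None = None
    max_iter: int = 60
    schedule: list = field(default_factory=lambda: [list(s) for s in DEFAULT_SCHEDULE])
    max_epochs_per_stage: int = 1000
    saliency_top: int = 0
    tsne_layers: list = field(default_factory=list)
    seeds: dict = field(
        default_factory=lambda: {"split": 0, "selection": 0, "training": 0, "simulation": 0}
    )
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.seeds = {**{"split": 0, "selection": 0, "training": 0, "simulation": 0}, **cfg.seeds}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_ratio"] = list(self.split_ratio)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Returns an empty list iff the config is runnable; each problem names
    the offending field."""
    problems: list[str] = []
    if "simulate" in config.input:
        preset = config.input["simulate"].get("preset", "reduced")
        if preset not in {"reduced", "full"}:
            problems.append(f"input.simulate.preset: unknown preset '{preset}'")
    elif "spectra" in config.input:
        for key in ("spectra", "axis"):
            p = config.input.get(key)
            if not p:
                problems.append(f"input.{key}: required for file input")
            elif not Path(p).exists():
                problems.append(f"input.{key}: file '{p}' does not exist")
    else:
        problems.append("input: needs either a 'simulate' or a 'spectra'/'axis' entry")
    if config.part not in io_core.PARTS:
        problems.append(f"part: must be one of {io_core.PARTS}")
    if config.path not in {"variable_selection", "spectral_matrix"}:
        problems.append("path: must be 'variable_selection' or 'spectral_matrix'")
    if config.h < 1:
        problems.append("h: segment length must be >= 1")
    if config.path == "spectral_matrix" and config.model != "cnn2d":
        problems.append("model: the spectral_matrix path requires the cnn2d model")
    if config.path == "variable_selection" and config.model == "cnn2d":
        problems.append("model: cnn2d requires the spectral_matrix path")
    if config.split_method not in {"tablet", "stratified_tablet", "position_holdout"}:
        problems.append(
            "split_method: must be 'tablet', 'stratified_tablet' or 'position_holdout'"
        )
    if config.model not in CNN_MODELS | BASELINES:
        problems.append(f"model: unknown model '{config.model}'")
    if config.max_iter < 0:
        problems.append("max_iter: must be >= 0")
    if config.wavelet not in (None, "auto"):
        try:
            order, level = config.wavelet
            preprocess.WaveletParams(int(order), int(level))
        except Exception as exc:  # noqa: BLE001
            problems.append(f"wavelet: {exc}")
    if config.model in CNN_MODELS:
        try:
            models.TrainSchedule(
                stages=tuple(tuple(s) for s in config.schedule),
                max_iterations_per_stage=config.max_epochs_per_stage,
            )
        except models.ScheduleError as exc:
            problems.append(f"schedule: {exc}")
    try:
        r = np.asarray(config.split_ratio, dtype=float)
        if r.shape != (3,) or np.any(r <= 0):
            problems.append("split_ratio: must be three positive numbers")
    except Exception:  # noqa: BLE001
        problems.append("split_ratio: must be three positive numbers")
    for key, value in config.seeds.items():
        if not isinstance(value, (int, np.integer)):
            problems.append(f"seeds.{key}: must be an integer")
    return problems


def _stage(name):
    class _Ctx:
        def __init__(self, timings):
            self.timings = timings

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

    return _Ctx


def _load(config: RunConfig) -> io_core.SpectrumSet:
    if "simulate" in config.input:
        sim = config.input["simulate"]
        preset = sim.get("preset", "reduced")
        seed = int(sim.get("seed", config.seeds["simulation"]))
        gen = (
            synthgen.acceptance_fixture_config(seed)
            if preset == "reduced"
            else synthgen.default_config(seed)
        )
        return synthgen.generate_dataset(gen)
    return io_core.read_spectra(config.input["spectra"], config.input["axis"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured path end to end and return the run report."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))

    timings: dict[str, float] = {}
    stage = lambda name: _stage(name)(timings)  # noqa: E731
    report: dict = {"config": config.to_dict(), "stages": {}}

    with stage("load"):
        full = _load(config)
        sset = full.select_part(config.part)
    report["stages"]["load"] = {
        "n_spectra": sset.n_spectra,
        "n_variables": sset.n_variables,
        "n_tablets": int(len(sset.tablet_ids())),
    }

    with stage("preprocess"):
        if config.wavelet is not None:
            if config.wavelet == "auto":
                params = preprocess.optimize_wavelet(sset)
            else:
                params = preprocess.WaveletParams(*map(int, config.wavelet))
            sset = preprocess.denoise_set(sset, params)
            report["stages"]["preprocess"] = {
                "wavelet_order": params.family_order,
                "wavelet_level": params.level,
            }
        if config.normalize:
            sset = preprocess.normalize_set(sset)

    with stage("split"):
        if config.split_method == "position_holdout":
            cal, val, pre = io_core.position_holdout_split(
                sset, seed=config.seeds["split"]
            )
        else:
            splitter = (
                io_core.stratified_split_by_tablet
                if config.split_method == "stratified_tablet"
                else io_core.split_by_tablet
            )
            split = splitter(sset, config.split_ratio, seed=config.seeds["split"])
            cal = split.subset_of(sset, "calibration")
            val = split.subset_of(sset, "validation")
            pre = split.subset_of(sset, "prediction")
    report["stages"]["split"] = {
        "method": config.split_method,
        "tablets": [
            int(len(s.meta["tablet_id"].unique())) for s in (cal, val, pre)
        ],
        "spectra": [cal.n_spectra, val.n_spectra, pre.n_spectra],
    }

    schedule = models.TrainSchedule(
        stages=tuple(tuple(s) for s in config.schedule),
        max_iterations_per_stage=config.max_epochs_per_stage,
        seed=config.seeds["training"],
    )
    y_cal = cal.meta["origin"].to_numpy()
    y_val = val.meta["origin"].to_numpy()
    y_pre = pre.meta["origin"].to_numpy()
    n_classes = int(max(sset.meta["origin"].max(), 12))

    if config.path == "variable_selection":
        with stage("sd_filter"):
            mask1 = varselect.sd_filter(
                cal,
                config.sd_mode,
                threshold=config.sd_threshold,
                keep_top=config.sd_keep_top,
            )
        report["stages"]["sd_filter"] = {"kept": mask1.n_kept, "mode": config.sd_mode}

        with stage("elimination"):
            selection = varselect.iterative_elimination(
                cal, mask1, max_iter=config.max_iter, seed=config.seeds["selection"]
            )
        report["stages"]["elimination"] = {
            "best_iteration": selection.best_iteration,
            "kept": selection.final_mask.n_kept,
            "selected_variables": selection.final_mask.indices().tolist(),
            "trace": [
                dataclasses.asdict(rec) for rec in selection.trace.records
            ],
        }
        kept = selection.final_mask.kept
        x_cal, x_val, x_pre = (s.intensities[:, kept] for s in (cal, val, pre))
    else:
        with stage("matrixize"):
            x_cal, geom = matrixize.stack_matrices(cal.intensities, config.h)
            x_val, _ = matrixize.stack_matrices(val.intensities, config.h)
            x_pre, _ = matrixize.stack_matrices(pre.intensities, config.h)
        report["stages"]["matrixize"] = {
            "h": geom.h,
            "n": geom.n,
            "discarded": geom.discarded,
        }

    with stage("train"):
        if config.model in CNN_MODELS:
            if config.model == "cnn2d":
                spec = models.build_cnn2d((x_cal.shape[1], x_cal.shape[2]), n_classes)
            elif config.model == "cnn1d_1":
                spec = models.build_cnn1d_1(x_cal.shape[1], n_classes)
            else:
                spec = models.build_cnn1d_2(x_cal.shape[1], n_classes)
            fitted = models.train_staged(spec, (x_cal, y_cal), (x_val, y_val), schedule)
            report["stages"]["train"] = {
                "model": config.model,
                "n_params": fitted.model_ref.n_params,
                "epochs": len(fitted.history),
                "stopped_reason": fitted.stopped_reason,
            }
        else:
            fitted = models.fit_baseline(
                config.model,
                (x_cal, y_cal),
                (x_val, y_val),
                search={"seed": config.seeds["training"]},
            )
            report["stages"]["train"] = {
                "model": config.model,
                "hyperparams": {
                    k: v for k, v in fitted.hyperparams.items() if np.isscalar(v)
                },
            }

    with stage("evaluate"):
        accs = {}
        for name, (x, y) in {
            "calibration": (x_cal, y_cal),
            "validation": (x_val, y_val),
            "prediction": (x_pre, y_pre),
        }.items():
            labels, _ = models.predict(fitted, x)
            accs[name] = interpret_eval.round_percent(interpret_eval.accuracy(y, labels))
        labels_pre, _ = models.predict(fitted, x_pre)
        cm = interpret_eval.confusion(y_pre, labels_pre, n_classes)
    report["accuracies_percent"] = accs
    report["confusion_prediction"] = cm.counts.tolist()

    if config.saliency_top > 0 and config.model == "cnn2d":
        with stage("saliency"):
            sal = {}
            for origin in sorted(set(y_pre.tolist())):
                res = interpret_eval.origin_average_saliency(
                    fitted, x_pre, y_pre, origin, sset.axis.values
                )
                sal[str(origin)] = [
                    [wl, w] for wl, w in res.ranked_wavelengths[: config.saliency_top]
                ]
        report["saliency_top_wavelengths"] = sal

    report["timings_s"] = timings
    payload = {k: v for k, v in report.items() if k != "timings_s"}
    report["results_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return report
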