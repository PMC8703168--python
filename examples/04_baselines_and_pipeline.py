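"""Classical baselines and the one-call configured pipeline.

Compares LDA / KNN / SVM on the SD-filtered variables, then runs the same
analysis through `run_pipeline` with a YAML-style config dict.
"""

from libspec import io_core, models, pipeline, preprocess, synthgen, varselect
from libspec.interpret_eval import accuracy, round_percent

config = synthgen.acceptance_fixture_config(seed=1)
dataset = preprocess.normalize_set(
    synthgen.generate_dataset(config).select_part("underground")
)
cal, val, pre = io_core.position_holdout_split(dataset, seed=1)
mask = varselect.sd_filter(cal, "knee")
x = lambda s: s.intensities[:, mask.kept]  # noqa: E731
y = lambda s: s.meta["origin"].to_numpy()  # noqa: E731

for kind in ("lda", "knn", "svm"):
    search = {"c_exponents": range(-2, 5), "g_exponents": range(-4, 2)} if kind == "svm" else None
    fitted = models.fit_baseline(kind, (x(cal), y(cal)), (x(val), y(val)), search)
    labels, _ = models.predict(fitted, x(pre))
    print(f"{kind.upper():4s} prediction accuracy: "
          f"{round_percent(accuracy(y(pre), labels)):6.2f}%  "
          f"hyperparams: { {k: v for k, v in fitted.hyperparams.items()} }")

report = pipeline.run_pipeline(
    pipeline.RunConfig.from_dict({
        "input": {"simulate": {"preset": "reduced", "seed": 1}},
        "path": "variable_selection",
        "model": "knn",
        "split_method": "position_holdout",
        "max_iter": 5,
        "seeds": {"split": 1, "selection": 1, "training": 1, "simulation": 1},
    })
)
print("\npipeline report accuracies:", report["accuracies_percent"])
print("variables kept after elimination:", report["stages"]["elimination"]["kept"])
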