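"""End-to-end spectral-matrix path: matrixize, train the 2-D CNN, interpret.

Cuts each spectrum into h=150-variable segments stacked into a matrix, trains
the two-block 2-D CNN with the staged SGD protocol (decreasing learning
rates, increasing validation thresholds), then evaluates on the held-out
tablets and back-maps saliency to wavelengths.
"""

import dataclasses

import numpy as np

from libspec import interpret_eval, io_core, matrixize, models, preprocess, synthgen

config = synthgen.acceptance_fixture_config(seed=1)
dataset = preprocess.normalize_set(
    synthgen.generate_dataset(config).select_part("underground")
)
cal, val, pre = io_core.position_holdout_split(dataset, seed=1)

x_cal, geom = matrixize.stack_matrices(cal.intensities, h=150)
x_val, _ = matrixize.stack_matrices(val.intensities, h=150)
x_pre, _ = matrixize.stack_matrices(pre.intensities, h=150)
print(f"spectral matrix: {geom.n}x{geom.h} ({geom.discarded} trailing "
      "variables discarded)")

spec = models.build_cnn2d((geom.n, geom.h), n_classes=12)
print(f"2D-CNN parameters: {spec.n_params:,}")

schedule = dataclasses.replace(models.PAPER_SCHEDULE, seed=1)
result = models.train_staged(
    spec,
    (x_cal, cal.meta["origin"].to_numpy()),
    (x_val, val.meta["origin"].to_numpy()),
    schedule,
)
print(f"training: {len(result.history)} epochs over {len(schedule.stages)} "
      f"stages, stop reasons {result.stopped_reason}")

y_pre = pre.meta["origin"].to_numpy()
labels, _ = models.predict(result, x_pre)
acc = interpret_eval.round_percent(interpret_eval.accuracy(y_pre, labels))
print(f"prediction-set accuracy: {acc}%  "
      "(spectra from tablets never seen in training)")

sal = interpret_eval.origin_average_saliency(
    result, x_pre, y_pre, origin=1, wavelengths=dataset.axis.values
)
top5 = ", ".join(f"{wl:.1f} nm" for wl, _ in sal.ranked_wavelengths[:5])
print(f"origin 1 saliency, top wavelengths: {top5}")
planted = set(np.round(dataset.axis.values[
    synthgen.planted_discriminative_channels(config)], 1))
print("planted discriminative lines among them:",
      sorted(float(w) for w in
             {round(w, 1) for w, _ in sal.ranked_wavelengths[:12]} & planted))
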