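import numpy as np
import pytest

from libspec import models, nn
from libspec.models import (
    PAPER_SCHEDULE,
    ScheduleError,
    SizeError,
    TrainSchedule,
    build_cnn1d_1,
    build_cnn1d_2,
    build_cnn2d,
    fit_baseline,
    predict,
    train_staged,
)


class TestArchitectures:
    def test_cnn1d_1_reads_back_printed_design(self):
        spec = build_cnn1d_1(325)
        assert spec.conv_kernel_counts == (512, 128, 64, 16)
        assert spec.conv_kernel_sizes == (3, 3, 3, 3)
        assert spec.dense_widths == (256, 64, 32)
        assert spec.dropout == 0.3

    def test_cnn1d_1_forward_is_probabilistic(self):
        net = build_cnn1d_1(325).build(seed=0)
        proba = net.predict_proba(np.random.default_rng(0).random((4, 1, 325)))
        assert proba.shape == (4, 12)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, rtol=1e-5)

    def test_cnn1d_1_too_short_input(self):
        with pytest.raises(SizeError):
            build_cnn1d_1(8)

    def test_cnn1d_2_residual_channels(self):
        spec = build_cnn1d_2(325)
        assert tuple(c for c, _ in spec.residual_blocks) == (64, 128, 256)
        net = spec.build(seed=0)
        proba = net.predict_proba(np.random.default_rng(0).random((3, 1, 325)))
        assert proba.shape == (3, 12)

    def test_zeroed_residual_branch_is_identity(self):
        """With all branch parameters zeroed, a channel-preserving residual
        block passes its (non-negative) input through unchanged."""
        spec = build_cnn1d_2(64)
        net = spec.build(seed=0)
        res = dict(net.layers)["res_block1"]
        assert res.projection == []  # 64 -> 64: identity skip
        for layer in res.branch:
            for p in layer.params():
                p.value[...] = 0
        x = np.abs(np.random.default_rng(1).random((2, 64, 32))).astype(np.float32)
        out = res.forward(x, train=False)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_cnn2d_reads_back_printed_design(self):
        spec = build_cnn2d((146, 150))
        assert spec.conv_kernel_counts == (64, 16)
        assert spec.conv_kernel_sizes == (7, 3)
        assert spec.dense_widths == (256, 64)

    def test_cnn2d_forward_shape(self):
        net = build_cnn2d((16, 150)).build(seed=0)
        proba = net.predict_proba(np.random.default_rng(0).random((5, 1, 16, 150)))
        assert proba.shape == (5, 12)

    def test_cnn2d_simpler_than_cnn1d_1(self):
        """The 2-D network at the full-survey matrix size has strictly fewer
        parameters than the 1-D network on the SD-filtered spectrum."""
        assert build_cnn2d((146, 150)).n_params < build_cnn1d_1(2016).n_params

    def test_cnn2d_too_small_input(self):
        with pytest.raises(SizeError):
            build_cnn2d((4, 150))

    def test_builders_are_pure(self):
        a = build_cnn2d((16, 150)).build(seed=5)
        b = build_cnn2d((16, 150)).build(seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestTrainSchedule:
    def test_printed_schedule_is_valid(self):
        assert PAPER_SCHEDULE.stages == ((0.1, 0.6), (0.05, 0.75), (0.01, 0.92), (0.005, 0.96))
        assert PAPER_SCHEDULE.max_iterations_per_stage == 1000

    @pytest.mark.parametrize(
        "stages",
        [
            ((0.1, 0.6), (0.2, 0.75)),  # rates must decrease
            ((0.1, 0.8), (0.05, 0.7)),  # thresholds must increase
            ((0.1, 1.5),),  # threshold outside [0, 1]
            ((-0.1, 0.5),),  # rate must be positive
        ],
    )
    def test_monotonicity_contracts(self, stages):
        with pytest.raises(ScheduleError):
            TrainSchedule(stages=stages)


@pytest.fixture(scope="module")
def toy_task():
    """Tiny, cleanly separable 3-class task on 32-variable spectra."""
    rng = np.random.default_rng(0)
    centers = rng.normal(0, 1, (3, 32))
    def draw(n):
        y = np.tile([1, 2, 3], n // 3 + 1)[:n]
        x = centers[y - 1] * 5 + rng.normal(0, 0.1, (n, 32))
        return x.astype(np.float32), y
    return draw(48), draw(24)


class TestTrainStaged:
    def test_zero_threshold_ends_each_stage_after_one_epoch(self, toy_task):
        cal, val = toy_task
        schedule = TrainSchedule(stages=((0.1, 0.0),), seed=0)
        spec = build_cnn1d_1(32, n_classes=3)
        result = train_staged(spec, cal, val, schedule)
        assert result.stopped_reason == ["threshold_met"]
        assert len(result.history) == 1

    def test_stage_never_exceeds_iteration_cap(self, toy_task):
        cal, val = toy_task
        schedule = TrainSchedule(stages=((0.1, 1.0),), max_iterations_per_stage=3, seed=0)
        result = train_staged(build_cnn1d_1(32, n_classes=3), cal, val, schedule)
        per_stage = [it for (_, it, _, _) in result.history]
        assert max(per_stage) <= 3

    def test_deterministic_given_seed(self, toy_task):
        cal, val = toy_task
        schedule = TrainSchedule(stages=((0.05, 0.9),), max_iterations_per_stage=5, seed=3)
        a = train_staged(build_cnn1d_1(32, n_classes=3), cal, val, schedule)
        b = train_staged(build_cnn1d_1(32, n_classes=3), cal, val, schedule)
        assert a.history == b.history

    def test_recovers_separable_classes(self, toy_task):
        """Staged training solves an easy task to high validation accuracy."""
        cal, val = toy_task
        schedule = TrainSchedule(
            stages=((0.1, 0.6), (0.05, 0.95)), max_iterations_per_stage=50, seed=1
        )
        result = train_staged(build_cnn1d_1(32, n_classes=3), cal, val, schedule)
        assert result.final_validation_accuracy() >= 0.95


class TestBaselines:
    def test_lda_separates_linear_classes(self, toy_task):
        cal, val = toy_task
        fitted = fit_baseline("lda", cal, val)
        labels, _ = predict(fitted, cal[0])
        assert np.mean(labels == cal[1]) == 1.0

    def test_knn_search_range_starts_at_three(self, toy_task):
        cal, val = toy_task
        fitted = fit_baseline("knn", cal, val)
        assert 3 <= fitted.hyperparams["k"] <= 20

    def test_svm_grid_argmax_confirmed_by_exhaustive_oracle(self, toy_task):
        cal, val = toy_task
        search = {"c_exponents": range(-1, 3), "g_exponents": range(-3, 0), "cv_folds": 3, "seed": 0}
        fitted = fit_baseline("svm", cal, val, search)
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.svm import SVC
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        best, best_acc = None, -1.0
        for ce in search["c_exponents"]:
            for ge in search["g_exponents"]:
                acc = float(np.mean(cross_val_score(
                    SVC(kernel="rbf", C=10.0**ce, gamma=10.0**ge),
                    cal[0].reshape(len(cal[1]), -1), cal[1], cv=cv)))
                if acc > best_acc:
                    best, best_acc = (10.0**ce, 10.0**ge), acc
        assert (fitted.hyperparams["c"], fitted.hyperparams["gamma"]) == best

    def test_predict_is_equivariant_to_row_permutation(self, toy_task):
        cal, val = toy_task
        fitted = fit_baseline("knn", cal, val)
        x = val[0]
        perm = np.random.default_rng(0).permutation(len(x))
        labels, _ = predict(fitted, x)
        labels_p, _ = predict(fitted, x[perm])
        np.testing.assert_array_equal(labels_p, labels[perm])

    def test_single_record_batch(self, toy_task):
        cal, val = toy_task
        fitted = fit_baseline("lda", cal, val)
        labels, _ = predict(fitted, cal[0][:1])
        assert labels.shape == (1,)
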