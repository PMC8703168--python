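import numpy as np
import pytest

from libspec import synthgen, varselect
from libspec.varselect import (
    EmptyMaskError,
    OOBForest,
    VariableMask,
    elimination_schedule,
    iterative_elimination,
    removal_count,
    sd_filter,
    vim_scores,
)

from conftest import make_set


def classed_set(rng, n_per_class=8, n_classes=3, n_vars=12, n_signal=3, effect=4.0):
    """Tabular fixture: the first ``n_signal`` variables carry class means,
    the rest are pure noise."""
    n = n_per_class * n_classes
    X = rng.normal(0, 1.0, (n, n_vars))
    origins = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    for j in range(n_signal):
        X[:, j] += effect * origins
    return make_set(np.abs(X) + 0.1, origins=origins.tolist())


class TestRemovalCount:
    @pytest.mark.parametrize("n,expected", [(2016, 101), (20, 1), (1, 1), (19, 1), (21, 2)])
    def test_examples(self, n, expected):
        assert removal_count(n) == expected

    def test_matches_exact_ceiling_for_all_counts(self):
        n = np.arange(1, 25001)
        got = np.array([removal_count(int(k)) for k in n])
        expected = -(-n // 20)  # exact integer ceil(n/20)
        np.testing.assert_array_equal(got, expected)


class TestEliminationSchedule:
    def test_strictly_decreasing_and_data_free(self):
        seq = elimination_schedule(2016, 60)
        assert all(b < a for a, b in zip(seq, seq[1:]))
        assert seq[0] == 2016

    def test_terminates_at_one_variable(self):
        seq = elimination_schedule(3, 100)
        assert seq[-1] == 1


class TestSDFilter:
    def test_keep_top_recovers_planted_channels(self, fixture_config, small_dataset):
        baseline = synthgen.baseline_channel_mask(fixture_config)
        n_lines = int((~baseline).sum())
        mask = sd_filter(small_dataset, "keep_top", keep_top=n_lines)
        np.testing.assert_array_equal(mask.kept, ~baseline)

    def test_all_identical_spectra_degenerate_in_knee_mode(self):
        sset = make_set(np.tile(np.linspace(1, 2, 6), (4, 1)))
        with pytest.raises(EmptyMaskError):
            sd_filter(sset, "knee")

    def test_keep_top_all_variables(self):
        rng = np.random.default_rng(0)
        sset = make_set(rng.random((5, 7)))
        mask = sd_filter(sset, "keep_top", keep_top=7)
        assert mask.kept.all()

    def test_threshold_above_max_sd_rejected(self):
        rng = np.random.default_rng(0)
        sset = make_set(rng.random((5, 7)))
        with pytest.raises(EmptyMaskError):
            sd_filter(sset, "threshold", threshold=10.0)


class TestVIMScores:
    def test_constant_variable_scores_zero(self):
        rng = np.random.default_rng(2)
        sset = classed_set(rng)
        sset.intensities[:, 5] = 0.5  # constant: permutation is a no-op
        mask = VariableMask(np.ones(12, dtype=bool), "all")
        scores = vim_scores(sset, mask, n_trees=30, seed=0)
        assert scores.scores[5] == pytest.approx(0.0, abs=1e-12)

    def test_separating_variable_has_max_score(self):
        rng = np.random.default_rng(3)
        sset = classed_set(rng, n_signal=1, effect=10.0)
        mask = VariableMask(np.ones(12, dtype=bool), "all")
        scores = vim_scores(sset, mask, n_trees=40, seed=1)
        assert int(np.argmax(scores.scores)) == 0

    def test_two_tree_forest_matches_per_tree_oracle(self):
        """Recompute Eq.-style Vim from the forest's own trees and bootstrap
        record, using sklearn's public predict as the independent path."""
        rng = np.random.default_rng(5)
        sset = classed_set(rng, n_per_class=3, n_classes=2, n_vars=4, n_signal=1)
        X = sset.intensities
        y = sset.meta["origin"].to_numpy()
        seed = 11
        forest = OOBForest(n_trees=2, seed=seed).fit(X, y)
        vim = forest.permutation_vim(
            np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        )
        # oracle: identical permutation stream, plain sklearn predict calls
        oracle_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        expected = np.zeros(4)
        for t, (tree, oob) in enumerate(zip(forest.trees, forest.oob_masks)):
            if not oob.any():
                continue
            x_oob = X[oob].astype(np.float32)
            y_oob = y[oob]
            err1 = np.mean(tree.predict(x_oob) != y_oob)
            for j in range(4):
                xp = x_oob.copy()
                xp[:, j] = xp[oracle_rng.permutation(len(y_oob)), j]
                err2 = np.mean(tree.predict(xp) != y_oob)
                expected[j] += err2 - err1
        expected /= 2
        np.testing.assert_allclose(vim, expected, atol=1e-12)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        sset = make_set(rng.random((6, 5)), origins=[2] * 6)
        mask = VariableMask(np.ones(5, dtype=bool), "all")
        with pytest.raises(varselect.LabelError):
            vim_scores(sset, mask, n_trees=5, seed=0)


class TestIterativeElimination:
    @pytest.fixture(scope="class")
    def sset(self):
        return classed_set(np.random.default_rng(8), n_per_class=10, n_vars=20, n_signal=4)

    def test_zero_iterations_is_identity(self, sset):
        mask = VariableMask(np.ones(20, dtype=bool), "all")
        res = iterative_elimination(sset, mask, max_iter=0, tree_grid=(25,), seed=0)
        assert res.best_iteration == 0
        np.testing.assert_array_equal(res.final_mask.kept, mask.kept)

    def test_masks_nested_and_counts_follow_schedule(self, sset):
        mask = VariableMask(np.ones(20, dtype=bool), "all")
        res = iterative_elimination(sset, mask, max_iter=6, tree_grid=(25,), seed=0)
        counts = [m.n_kept for m in res.masks]
        assert counts == elimination_schedule(20, 6)
        for a, b in zip(res.masks, res.masks[1:]):
            assert np.all(a.kept[b.kept])  # each kept set nested in the previous
        assert [r.iteration for r in res.trace.records] == list(range(len(res.masks)))

    def test_best_iteration_maximizes_oob_accuracy(self, sset):
        mask = VariableMask(np.ones(20, dtype=bool), "all")
        res = iterative_elimination(sset, mask, max_iter=5, tree_grid=(25,), seed=1)
        accs = [r.oob_accuracy for r in res.trace.records]
        assert accs[res.best_iteration] == max(accs)
        assert res.best_iteration == int(np.argmax(accs))  # ties go earliest
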