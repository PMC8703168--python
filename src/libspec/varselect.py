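"""Two-stage variable selection for high-dimensional LIBS spectra.

Stage 1 removes channels whose standard deviation across spectra is near zero:
detector channels that never see an emission line carry only readout noise and
cannot help discrimination.  Stage 2 iteratively eliminates variables by
random-forest permutation importance: per iteration the forest size is tuned
on out-of-bag (OOB) accuracy, each variable is scored by the mean per-tree
increase in OOB error after permuting that variable's OOB values,

    Vim_j = Σ_t (OOBerror2_tj − OOBerror1_t) / N ,

and the 5% of variables with the lowest score (⌈0.05·n⌉) are dropped.  The
schedule runs for a fixed number of rounds (60 by default) and the retained
set is the iteration with the best OOB accuracy.

The forest is an ensemble of scikit-learn decision trees over a
package-controlled bootstrap, so OOB membership per tree is explicit and the
per-tree score above is computable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .io_core import SpectrumSet, ValidationError

__all__ = [
    "VariableMask",
    "VIMScores",
    "EliminationTrace",
    "SelectionResult",
    "OOBForest",
    "EmptyMaskError",
    "LabelError",
    "sd_filter",
    "vim_scores",
    "removal_count",
    "elimination_schedule",
    "iterative_elimination",
]

DEFAULT_TREE_GRID = tuple(range(50, 111, 10))


class EmptyMaskError(ValueError):
    """A selection stage would keep zero variables."""


class LabelError(ValueError):
    """Class labels unusable for supervised selection (e.g. a single class)."""


@dataclass(frozen=True)
class VariableMask:
    """Boolean keep-mask over the full variable axis, tagged with its stage."""

    kept: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        kept = np.asarray(self.kept, dtype=bool)
        object.__setattr__(self, "kept", kept)
        if kept.ndim != 1 or not kept.any():
            raise EmptyMaskError(f"stage '{self.stage}' keeps no variables")

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def indices(self) -> np.ndarray:
        return np.nonzero(self.kept)[0]


@dataclass(frozen=True)
class VIMScores:
    scores: np.ndarray  # one per kept variable, order = mask.indices()
    n_trees: int

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if not np.all(np.isfinite(s)):
            raise ValueError("VIM scores must be finite")


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    n_variables: int
    n_trees: int
    oob_accuracy: float


@dataclass
class EliminationTrace:
    records: list[TraceRecord] = field(default_factory=list)

    def append(self, rec: TraceRecord) -> None:
        if self.records and rec.n_variables >= self.records[-1].n_variables:
            if rec.iteration != 0:
                raise ValueError("variables remaining must strictly decrease")
        self.records.append(rec)

    def best_iteration(self) -> int:
        """Argmax of OOB accuracy; ties resolve to the earliest iteration."""
        accs = [r.oob_accuracy for r in self.records]
        return self.records[int(np.argmax(accs))].iteration


@dataclass(frozen=True)
class SelectionResult:
    final_mask: VariableMask
    best_iteration: int
    trace: EliminationTrace
    masks: tuple[VariableMask, ...]  # mask after k removals, k = 0..len-1


# ---------------------------------------------------------------------------
# Stage 1: standard-deviation filter
# ---------------------------------------------------------------------------

def _knee_cutoff(sorted_sd: np.ndarray) -> float:
    """SD value at the maximum-curvature point of the ascending SD curve.

    Found as the point of maximum perpendicular distance to the chord joining
    the curve's endpoints, computed in unit-normalized coordinates (the
    standard discrete knee detection).
    """
    n = sorted_sd.size
    if sorted_sd[-1] == sorted_sd[0]:
        raise EmptyMaskError("all variables have identical SD; no knee exists")
    x = np.linspace(0.0, 1.0, n)
    y = (sorted_sd - sorted_sd[0]) / (sorted_sd[-1] - sorted_sd[0])
    # distance to chord y = x is |y - x| / sqrt(2); argmax below the chord
    knee = int(np.argmax(x - y))
    return float(sorted_sd[knee])


def sd_filter(sset: SpectrumSet, mode: str = "knee", *, threshold: float | None = None,
              keep_top: int | None = None) -> VariableMask:
    """Keep variables whose cross-spectrum SD exceeds a cutoff.

    Modes: ``knee`` (cutoff at the maximum-curvature point of the sorted SD
    curve), ``threshold`` (fixed SD value ``threshold``), ``keep_top`` (the
    ``keep_top`` largest-SD variables).
    """
    if sset.n_spectra < 2:
        raise ValidationError("need at least 2 spectra to compute SDs")
    sd = sset.intensities.std(axis=0, ddof=1)
    if mode == "knee":
        cutoff = _knee_cutoff(np.sort(sd))
        kept = sd > cutoff
    elif mode == "threshold":
        if threshold is None:
            raise ValueError("threshold mode requires a threshold value")
        if threshold >= sd.max():
            raise EmptyMaskError("threshold is above the maximum variable SD")
        kept = sd > threshold
    elif mode == "keep_top":
        if keep_top is None:
            raise ValueError("keep_top mode requires a count")
        if keep_top > sd.size:
            raise EmptyMaskError(f"keep_top={keep_top} exceeds {sd.size} variables")
        order = np.argsort(-sd, kind="stable")
        kept = np.zeros(sd.size, dtype=bool)
        kept[order[:keep_top]] = True
    else:
        raise ValueError(f"unknown sd_filter mode '{mode}'")
    return VariableMask(kept=kept, stage=f"sd_filter:{mode}")


# ---------------------------------------------------------------------------
# Stage 2: random forest with explicit OOB bookkeeping
# ---------------------------------------------------------------------------

def _fast_tree_predict(tree: DecisionTreeClassifier, x32: np.ndarray) -> np.ndarray:
    """Predict labels through the fitted tree's C-level structure (skips the
    per-call input validation of ``tree.predict``, which dominates at our
    OOB-block sizes)."""
    counts = tree.tree_.predict(x32)
    counts = counts.reshape(counts.shape[0], -1)
    return tree.classes_[np.argmax(counts, axis=1)]


class OOBForest:
    """Bagged decision trees with package-controlled bootstrap and OOB records.

    Each tree is a sklearn ``DecisionTreeClassifier`` (max_features='sqrt')
    grown on a bootstrap resample drawn here, so each tree's out-of-bag rows
    are known exactly — required for the per-tree permutation importance.
    """

    def __init__(self, n_trees: int, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.seed = seed
        self.trees: list[DecisionTreeClassifier] = []
        self.oob_masks: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OOBForest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise LabelError("need at least 2 classes to fit the forest")
        n = y.size
        rng = np.random.default_rng(self.seed)
        self._X32, self._y = X, y
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(rng.integers(2**31))
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        return self

    def tree_oob_errors(self) -> np.ndarray:
        """Per-tree OOB misclassification rate (OOBerror1 of each tree)."""
        errs = []
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                errs.append(0.0)
                continue
            pred = _fast_tree_predict(tree, self._X32[oob])
            errs.append(float(np.mean(pred != self._y[oob])))
        return np.asarray(errs)

    def oob_accuracy(self) -> float:
        """Forest-level OOB accuracy: majority vote over trees for which each
        sample is out of bag (samples never OOB are excluded)."""
        n = self._y.size
        k = self.classes_.size
        votes = np.zeros((n, k), dtype=np.int64)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                continue
            pred = _fast_tree_predict(tree, self._X32[oob])
            cols = np.fromiter((class_index[p] for p in pred), dtype=np.int64)
            np.add.at(votes, (np.nonzero(oob)[0], cols), 1)
        covered = votes.sum(axis=1) > 0
        if not covered.any():
            raise ValueError("no sample is out of bag; cannot compute OOB accuracy")
        pred = self.classes_[np.argmax(votes[covered], axis=1)]
        return float(np.mean(pred == self._y[covered]))

    def permutation_vim(self, rng: np.random.Generator) -> np.ndarray:
        """Eq.-style per-variable importance: mean over trees of the OOB-error
        increase after permuting that variable's OOB values within each tree."""
        base_errors = self.tree_oob_errors()
        p = self._X32.shape[1]
        vim = np.zeros(p)
        for t, (tree, oob) in enumerate(zip(self.trees, self.oob_masks)):
            m = int(oob.sum())
            if m == 0:
                continue
            x_oob = np.ascontiguousarray(self._X32[oob])
            y_oob = self._y[oob]
            for j in range(p):
                saved = x_oob[:, j].copy()
                x_oob[:, j] = saved[rng.permutation(m)]
                pred = _fast_tree_predict(tree, x_oob)
                err2 = float(np.mean(pred != y_oob))
                x_oob[:, j] = saved
                vim[j] += err2 - base_errors[t]
        return vim / self.n_trees


def vim_scores(sset: SpectrumSet, mask: VariableMask, n_trees: int, seed: int = 0) -> VIMScores:
    """Permutation variable-importance scores on the masked variables."""
    X = sset.intensities[:, mask.kept]
    y = sset.meta["origin"].to_numpy()
    forest = OOBForest(n_trees=n_trees, seed=seed).fit(X, y)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    return VIMScores(scores=forest.permutation_vim(rng), n_trees=n_trees)


# ---------------------------------------------------------------------------
# Elimination schedule (pure arithmetic) and the iterative eliminator
# ---------------------------------------------------------------------------

def removal_count(n_current: int) -> int:
    """Number of variables dropped per round: ⌈0.05 · n⌉ (never 0)."""
    if n_current < 1:
        raise ValueError("n_current must be >= 1")
    return (n_current + 19) // 20  # exact integer ceil(n/20)


def elimination_schedule(n_start: int, n_iterations: int) -> list[int]:
    """Variables remaining after each round: n ← n − ⌈0.05·n⌉, stopping early
    at one variable.  Element k is the count after k rounds (element 0 = start)."""
    seq = [n_start]
    n = n_start
    for _ in range(n_iterations):
        if n <= 1:
            break
        n -= removal_count(n)
        seq.append(n)
    return seq


def _optimize_forest(X: np.ndarray, y: np.ndarray, tree_grid, seed: int) -> OOBForest:
    """Best forest over the tree-count grid by OOB accuracy (ties → fewest trees)."""
    best: OOBForest | None = None
    best_acc = -1.0
    for k, n_trees in enumerate(tree_grid):
        forest = OOBForest(n_trees=n_trees, seed=seed + k).fit(X, y)
        acc = forest.oob_accuracy()
        if acc > best_acc:
            best, best_acc = forest, acc
    best._oob_acc = best_acc
    return best


def iterative_elimination(
    sset: SpectrumSet,
    initial_mask: VariableMask,
    max_iter: int = 60,
    tree_grid=DEFAULT_TREE_GRID,
    seed: int = 0,
) -> SelectionResult:
    """Iterative VIM elimination with OOB-accuracy stopping.

    Round k: score the current variables on the tree-count-optimized forest,
    drop the ⌈0.05·n⌉ lowest-Vim variables (Vim ties drop the larger variable
    index), refit the optimized forest on the survivors and record its OOB
    accuracy.  The returned mask is the round with the best OOB accuracy
    (ties → earliest round, so ``max_iter=0`` returns the initial mask).
    """
    y = sset.meta["origin"].to_numpy()
    if np.unique(y).size < 2:
        raise LabelError("need at least 2 classes for elimination")
    seeds = np.random.SeedSequence(seed).generate_state(2 * (max_iter + 1)) % (2**31 - 1)

    trace = EliminationTrace()
    masks: list[VariableMask] = [
        VariableMask(kept=initial_mask.kept.copy(), stage="elimination:0")
    ]
    current = masks[0]
    forest = _optimize_forest(
        sset.intensities[:, current.kept], y, tree_grid, int(seeds[0])
    )
    trace.append(TraceRecord(0, current.n_kept, forest.n_trees, forest._oob_acc))

    for k in range(1, max_iter + 1):
        if current.n_kept <= 1:
            break
        rng = np.random.default_rng(int(seeds[2 * k - 1]))
        vim = forest.permutation_vim(rng)
        local_idx = np.arange(current.n_kept)
        # ascending Vim; equal scores remove the larger variable index first
        order = np.lexsort((-local_idx, vim))
        n_drop = removal_count(current.n_kept)
        drop_local = order[:n_drop]
        global_idx = current.indices()
        kept = current.kept.copy()
        kept[global_idx[drop_local]] = False
        current = VariableMask(kept=kept, stage=f"elimination:{k}")
        masks.append(current)
        forest = _optimize_forest(
            sset.intensities[:, current.kept], y, tree_grid, int(seeds[2 * k])
        )
        trace.append(TraceRecord(k, current.n_kept, forest.n_trees, forest._oob_acc))

    best_it = trace.best_iteration()
    return SelectionResult(
        final_mask=masks[best_it],
        best_iteration=best_it,
        trace=trace,
        masks=tuple(masks),
    )
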