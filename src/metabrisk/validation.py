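"""Monte-Carlo cross-validation and permutation testing for two-class models.

The validation scheme is model-agnostic: any *model spec* object exposing
``fit(x_train, y_train) -> fitted`` where the fitted object has
``predict(x_test) -> labels`` can be evaluated. Each Monte-Carlo iteration
draws a stratified random train/test split (default 90%/10%, 100 iterations)
and scores the held-out samples; performance is averaged over iterations.

Statistical significance of a model is assessed by a label-permutation test:
the same data are refitted under randomly reassigned class labels, and the
empirical P-value is the fraction of permutations whose mean cross-validated
accuracy strictly exceeds the observed one. A P-value of 0 is therefore
possible and is rendered as "<1/n_permutations" (e.g. "<0.001") in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .multivariate import _as_array

__all__ = [
    "Performance",
    "PerformanceSummary",
    "McCvResult",
    "PermutationResult",
    "evaluate",
    "monte_carlo_cv",
    "permutation_test",
    "format_p_value",
]


@dataclass(frozen=True)
class Performance:
    """Confusion counts for one evaluation; metrics as percentages in [0, 100]."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")


@dataclass(frozen=True)
class PerformanceSummary:
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class McCvResult:
    """Performance over Monte-Carlo cross-validation iterations."""

    n_iterations: int
    train_fraction: float
    iterations: list[Performance]
    mean_performance: PerformanceSummary
    seed: "int | None" = None

    def to_dict(self) -> dict:
        mp = self.mean_performance
        return {
            "n_iterations": self.n_iterations,
            "train_fraction": self.train_fraction,
            "accuracy": mp.accuracy,
            "sensitivity": mp.sensitivity,
            "specificity": mp.specificity,
            "seed": self.seed,
        }


@dataclass
class PermutationResult:
    """Empirical significance of a model against label-permuted refits."""

    n_permutations: int
    observed: float
    permuted: np.ndarray
    p_value: float
    seed: "int | None" = None

    def formatted_p(self) -> str:
        return format_p_value(self.p_value, self.n_permutations)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "observed": self.observed,
            "p_value": self.p_value,
            "p_formatted": self.formatted_p(),
            "seed": self.seed,
        }


def evaluate(truth, predicted, positive_class) -> Performance:
    """Confusion counts of a prediction against the truth.

    Any label other than the two present in ``truth`` is rejected.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted have different lengths")
    labels = set(pd.unique(truth))
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} absent from truth labels")
    unknown = set(pd.unique(predicted)) - labels
    if unknown:
        raise ValueError(f"predicted contains unknown label(s): {sorted(map(str, unknown))}")
    pos_t = truth == positive_class
    pos_p = predicted == positive_class
    return Performance(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _stratified_train_indices(y: np.ndarray, train_fraction: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Random stratified training indices totalling floor(train_fraction * n).

    Class allocations follow the largest-remainder rule, bounded so every
    class keeps at least one sample in both the training and the test set.
    """
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = [str(c) for c, k in zip(classes, counts) if k < 2]
        raise ValueError(f"class too small to stratify (needs >= 2 samples): {small}")
    target = int(np.floor(train_fraction * n))
    lo, hi = np.ones_like(counts), counts - 1
    if not lo.sum() <= target <= hi.sum():
        raise ValueError(
            f"train_fraction={train_fraction} infeasible for class sizes {counts.tolist()}"
        )
    quota = train_fraction * counts
    alloc = np.clip(np.floor(quota).astype(int), lo, hi)
    rema = quota - alloc
    while alloc.sum() < target:
        cand = np.where(alloc < hi)[0]
        j = cand[int(np.argmax(rema[cand]))]
        alloc[j] += 1
        rema[j] -= 1.0
    while alloc.sum() > target:
        cand = np.where(alloc > lo)[0]
        j = cand[int(np.argmin(rema[cand]))]
        alloc[j] -= 1
        rema[j] += 1.0
    picks = []
    for c, k in zip(classes, alloc):
        idx = np.nonzero(y == c)[0]
        picks.append(rng.permutation(idx)[:k])
    return np.sort(np.concatenate(picks))


def monte_carlo_cv(x, y, model_spec, n_iterations: int = 100,
                   train_fraction: float = 0.9, seed: "int | None" = None,
                   positive_class=None) -> McCvResult:
    """Repeated stratified random-split cross-validation.

    Each iteration fits ``model_spec`` on a random stratified training subset
    (size ``floor(train_fraction * n)``) and scores the complementary test
    set. Mean metrics are arithmetic means over iterations; iterations whose
    test set lacks a class contribute to accuracy but not to the undefined
    sensitivity/specificity (which are skipped in the mean).
    """
    arr = _as_array(x)
    y = np.asarray(y)
    if arr.shape[0] != len(y):
        raise ValueError("x and y have different numbers of samples")
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError(f"two-class validation requires 2 classes, got {len(classes)}")
    if positive_class is None:
        positive_class = classes[1]
    rng = np.random.default_rng(np.random.SeedSequence(seed) if seed is not None else None)
    iters: list[Performance] = []
    all_idx = np.arange(arr.shape[0])
    for _ in range(n_iterations):
        train = _stratified_train_indices(y, train_fraction, rng)
        test = np.setdiff1d(all_idx, train, assume_unique=True)
        fitted = model_spec.fit(arr[train], y[train])
        pred = fitted.predict(arr[test])
        iters.append(evaluate(y[test], pred, positive_class))
    with np.errstate(invalid="ignore"):
        mean = PerformanceSummary(
            accuracy=float(np.nanmean([p.accuracy for p in iters])),
            sensitivity=float(np.nanmean([p.sensitivity for p in iters])),
            specificity=float(np.nanmean([p.specificity for p in iters])),
        )
    return McCvResult(n_iterations, train_fraction, iters, mean, seed)


def permutation_test(x, y, model_spec, n_permutations: int = 1000,
                     seed: "int | None" = None, n_iterations: int = 20,
                     train_fraction: float = 0.9, positive_class=None,
                     observed: "float | None" = None) -> PermutationResult:
    """Label-permutation significance test of a two-class model.

    The test statistic is the mean Monte-Carlo cross-validated accuracy.
    ``p_value`` is the fraction of label permutations whose statistic is
    *strictly greater* than the observed one. ``n_iterations`` controls the
    inner cross-validation loop (default 20 for tractability; set 100 to
    match the outer validation settings exactly).
    """
    y = np.asarray(y)
    ss = np.random.SeedSequence(seed if seed is not None else np.random.SeedSequence().entropy)
    children = ss.spawn(n_permutations + 2)

    def _stat(labels, child) -> float:
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = monte_carlo_cv(x, labels, model_spec, n_iterations=n_iterations,
                             train_fraction=train_fraction, seed=sub_seed,
                             positive_class=positive_class)
        return res.mean_performance.accuracy

    if observed is None:
        observed = _stat(y, children[0])
    perm_rng = np.random.default_rng(children[1])
    permuted = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted[i] = _stat(perm_rng.permutation(y), children[i + 2])
    p = float(np.sum(permuted > observed) / n_permutations)
    return PermutationResult(n_permutations, float(observed), permuted, p, seed)


def format_p_value(p: float, n_permutations: int) -> str:
    """Render an empirical P-value; values below 1/n are shown as e.g. "<0.001"."""
    floor_p = 1.0 / n_permutations
    if p < floor_p:
        return f"<{floor_p:g}"
    return f"{p:.3f}"
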