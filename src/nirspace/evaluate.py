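"""Repeated stratified k-fold cross-validation and classifier comparison.

Two classifiers are compared on *identical* fold partitions: R repetitions
of stratified K-fold cross-validation (default 10 x 10) yield an R x K
matrix of per-fold misclassification rates for each classifier, and the
paired fold-wise loss differences feed a corrected resampled t statistic.

With ``d_{r,k} = err_a(r,k) - err_b(r,k)``:

    E(d_r)   = (1/K) sum_k d_{r,k}
    E(d)     = (1/R) sum_r E(d_r)
    sigma_r^2 = (1/K) sum_k (d_{r,k} - E(d_r))^2
    E(sigma^2) = (1/R) sum_r sigma_r^2
    S^2      = (1/RK) sum_{r,k} (d_{r,k} - E(d))^2
    t        = E(d) / sqrt(S^2 / (df + 1)),   df = 10 by default

The fixed low degrees of freedom compensate for the dependence between
folds that share training data, which makes the naive paired t-test wildly
anti-conservative; this corrected form errs on the conservative side.
p-values are two-sided from a Student t distribution with ``df`` degrees
of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .ensemble import (
    StrongLearner,
    SubspaceEnsemble,
    SubspaceSpec,
    predict_strong,
    predict_with_first_n,
    train_ensemble,
    train_strong,
)
from .features import FeatureMatrix

__all__ = [
    "CVResult",
    "CorrectedTTestResult",
    "LearnerCountComparison",
    "make_partitions",
    "repeated_kfold",
    "corrected_t_test",
    "compare_over_learner_counts",
    "ladder_search",
    "ensemble_factory",
    "strong_factory",
]


class FoldClassifier(Protocol):
    """Anything trainable per fold: ``fit(X, y)`` then ``predict(X)``."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> object: ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


#: Builds a fresh classifier for one fold; receives a fold-specific seed so
#: internal randomness (e.g. subset draws) is reproducible yet varies by fold.
ClassifierFactory = Callable[[int], FoldClassifier]


def _derive_seed(*keys: int) -> int:
    """Deterministic sub-seed below 2**31 from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass
class CVResult:
    """Per-fold losses and the fold partitions that produced them."""

    losses: np.ndarray  # R x K misclassification rates
    fold_assignments: np.ndarray  # R x n_trials fold index of each trial
    R: int
    K: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(1.0 - self.losses.mean())


@dataclass
class CorrectedTTestResult:
    """Corrected repeated-CV comparison of two classifiers' fold losses."""

    mean_diff: float  # E(d)
    per_rep_means: np.ndarray  # E(d_r), length R
    per_rep_vars: np.ndarray  # sigma_r^2, length R
    mean_var: float  # E(sigma^2)
    overall_var: float  # S^2
    t: float
    df: int
    p: float


@dataclass
class LearnerCountComparison:
    """Ensemble-vs-strong comparison along the weak-learner-count axis."""

    n_grid: np.ndarray
    ensemble_losses: np.ndarray  # R x K x len(n_grid)
    strong_losses: np.ndarray  # R x K
    tests: list[CorrectedTTestResult]
    p_fdr: np.ndarray
    significant: np.ndarray

    @property
    def ensemble_accuracy(self) -> np.ndarray:
        return 1.0 - self.ensemble_losses.mean(axis=(0, 1))

    @property
    def strong_accuracy(self) -> float:
        return float(1.0 - self.strong_losses.mean())


class _SubspaceFoldClassifier:
    def __init__(self, M: int, N: int, seed: int):
        self.M, self.N, self.seed = M, N, seed
        self.ensemble: SubspaceEnsemble | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SubspaceFoldClassifier":
        from .features import FeatureDescriptor

        fm = FeatureMatrix(
            values=X,
            columns=[
                FeatureDescriptor("AVG", "HbO", f"F{j}", (0.0, float(j + 1)))
                for j in range(X.shape[1])
            ],
            labels=y,
        )
        spec = SubspaceSpec(D=X.shape[1], M=self.M, N=self.N, seed=self.seed)
        self.ensemble = train_ensemble(fm, spec)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        assert self.ensemble is not None
        return predict_with_first_n(self.ensemble, X, self.N)


class _StrongFoldClassifier:
    def __init__(self, kind: str):
        self.kind = kind
        self.learner: StrongLearner | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_StrongFoldClassifier":
        from .features import FeatureDescriptor

        fm = FeatureMatrix(
            values=X,
            columns=[
                FeatureDescriptor("AVG", "HbO", f"F{j}", (0.0, float(j + 1)))
                for j in range(X.shape[1])
            ],
            labels=y,
        )
        self.learner = train_strong(fm, kind=self.kind)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        assert self.learner is not None
        return predict_strong(self.learner, X)


def ensemble_factory(
    M: int, N: int = 100, subset_seed: int | None = None
) -> ClassifierFactory:
    """Factory for random-subspace ensembles.

    By default the subset draw is part of per-fold fitting (seeded by the
    fold).  Passing ``subset_seed`` fixes the draw across folds instead,
    which makes two ensembles differing only in that seed an exchangeable
    pair with a replicate-level conditional difference — useful for
    calibration experiments on the corrected test.
    """
    if subset_seed is None:
        return lambda fold_seed: _SubspaceFoldClassifier(M=M, N=N, seed=fold_seed)
    return lambda fold_seed: _SubspaceFoldClassifier(M=M, N=N, seed=subset_seed)


def strong_factory(kind: str) -> ClassifierFactory:
    """Factory for a strong learner (deterministic; ignores the fold seed)."""
    return lambda fold_seed: _StrongFoldClassifier(kind=kind)


def make_partitions(
    labels: np.ndarray, R: int, K: int, seed: int
) -> tuple[list[list[tuple[np.ndarray, np.ndarray]]], np.ndarray]:
    """R independent seeded stratified K-fold partitions of the trials.

    Returns the (train, test) index pairs per repetition and an
    ``R x n_trials`` matrix of test-fold assignments.  Classifiers compared
    with the same ``seed`` are guaranteed identical partitions.
    """
    y = np.asarray(labels).astype(str)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ValueError(
            f"stratified {K}-fold needs >= {K} trials per class, "
            f"got class counts {counts.tolist()}"
        )
    partitions = []
    assignments = np.empty((R, y.size), dtype=int)
    for r in range(R):
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=_derive_seed(seed, r))
        folds = list(skf.split(np.zeros((y.size, 1)), y))
        for k, (_, test_idx) in enumerate(folds):
            assignments[r, test_idx] = k
        partitions.append(folds)
    return partitions, assignments


def repeated_kfold(
    features: FeatureMatrix,
    factory: ClassifierFactory,
    R: int = 10,
    K: int = 10,
    seed: int = 0,
) -> CVResult:
    """R repetitions of stratified K-fold CV; returns per-fold losses.

    All fitting — including standardization and subset drawing — happens
    inside each training fold.  The loss is the misclassification rate on
    the held-out fold.
    """
    partitions, assignments = make_partitions(features.labels, R, K, seed)
    y = features.labels.astype(str)
    losses = np.empty((R, K))
    for r in range(R):
        for k, (train_idx, test_idx) in enumerate(partitions[r]):
            clf = factory(_derive_seed(seed, r, k))
            clf.fit(features.values[train_idx], y[train_idx])
            pred = np.asarray(clf.predict(features.values[test_idx])).astype(str)
            losses[r, k] = np.mean(pred != y[test_idx])
    return CVResult(losses=losses, fold_assignments=assignments, R=R, K=K, seed=seed)


def corrected_t_test(
    losses_a: np.ndarray, losses_b: np.ndarray, df: int = 10
) -> CorrectedTTestResult:
    """Corrected resampled t test on paired R x K fold losses.

    See the module docstring for the exact moment definitions.  Degenerate
    cases: if every fold difference is identical and nonzero the variance
    vanishes and ``t = +/-inf, p = 0`` (with a warning); if all differences
    are zero, ``t = 0, p = 1``.
    """
    a = np.asarray(losses_a, dtype=float)
    b = np.asarray(losses_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("losses must be two R x K matrices of equal shape")
    if df < 1:
        raise ValueError("df must be >= 1")
    d = a - b
    R, K = d.shape
    per_rep_means = d.mean(axis=1)
    mean_diff = float(per_rep_means.mean())
    per_rep_vars = ((d - per_rep_means[:, None]) ** 2).mean(axis=1)
    mean_var = float(per_rep_vars.mean())
    overall_var = float(((d - mean_diff) ** 2).mean())

    if overall_var == 0.0:
        if mean_diff == 0.0:
            t_val, p_val = 0.0, 1.0
        else:
            warnings.warn(
                "zero variance with nonzero mean difference; t is infinite",
                RuntimeWarning,
                stacklevel=2,
            )
            t_val = np.inf if mean_diff > 0 else -np.inf
            p_val = 0.0
    else:
        t_val = mean_diff / np.sqrt(overall_var / (df + 1))
        p_val = float(2.0 * stats.t.sf(abs(t_val), df))
    return CorrectedTTestResult(
        mean_diff=mean_diff,
        per_rep_means=per_rep_means,
        per_rep_vars=per_rep_vars,
        mean_var=mean_var,
        overall_var=overall_var,
        t=float(t_val),
        df=df,
        p=p_val,
    )


def compare_over_learner_counts(
    features: FeatureMatrix,
    M: int,
    N: int = 100,
    strong_kind: str = "linear_svm",
    n_grid: Sequence[int] | None = None,
    R: int = 10,
    K: int = 10,
    seed: int = 0,
    df: int = 10,
    test: str = "corrected",
    fdr_q: float = 0.05,
) -> LearnerCountComparison:
    """Accuracy and significance of the ensemble vs. a strong learner per n.

    One ensemble of N weak learners is trained per fold; predictions with
    the first ``n`` learners give the accuracy curve over ``n_grid`` without
    refitting.  The strong learner is evaluated on the *same* partitions.
    Per-n p-values (``test='corrected'`` for the corrected repeated-CV
    statistic, ``'paired'`` for a naive paired t-test across all R*K folds)
    are Benjamini-Hochberg adjusted at ``fdr_q``.
    """
    if n_grid is None:
        n_grid = range(1, N + 1)
    n_grid = np.asarray(sorted(n_grid), dtype=int)
    if n_grid[0] < 1 or n_grid[-1] > N:
        raise ValueError(f"n_grid must lie within 1..{N}")
    if test not in ("corrected", "paired"):
        raise ValueError("test must be 'corrected' or 'paired'")

    partitions, _ = make_partitions(features.labels, R, K, seed)
    y = features.labels.astype(str)
    ens_losses = np.empty((R, K, n_grid.size))
    strong_losses = np.empty((R, K))
    strong = strong_factory(strong_kind)
    for r in range(R):
        for k, (train_idx, test_idx) in enumerate(partitions[r]):
            fold_seed = _derive_seed(seed, r, k)
            ens_clf = _SubspaceFoldClassifier(M=M, N=N, seed=fold_seed)
            ens_clf.fit(features.values[train_idx], y[train_idx])
            assert ens_clf.ensemble is not None
            for i, n in enumerate(n_grid):
                pred = predict_with_first_n(
                    ens_clf.ensemble, features.values[test_idx], int(n)
                ).astype(str)
                ens_losses[r, k, i] = np.mean(pred != y[test_idx])
            s_clf = strong(fold_seed)
            s_clf.fit(features.values[train_idx], y[train_idx])
            pred = np.asarray(s_clf.predict(features.values[test_idx])).astype(str)
            strong_losses[r, k] = np.mean(pred != y[test_idx])

    tests = [
        corrected_t_test(ens_losses[:, :, i], strong_losses, df=df)
        for i in range(n_grid.size)
    ]
    if test == "corrected":
        pvals = np.array([t.p for t in tests])
    else:
        pvals = np.array(
            [
                stats.ttest_rel(
                    ens_losses[:, :, i].ravel(), strong_losses.ravel()
                ).pvalue
                if np.any(ens_losses[:, :, i] != strong_losses)
                else 1.0
                for i in range(n_grid.size)
            ]
        )
    reject, p_fdr, _, _ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
    return LearnerCountComparison(
        n_grid=n_grid,
        ensemble_losses=ens_losses,
        strong_losses=strong_losses,
        tests=tests,
        p_fdr=p_fdr,
        significant=reject,
    )


def ladder_search(
    features: FeatureMatrix,
    N: int = 100,
    R: int = 10,
    K: int = 10,
    seed: int = 0,
    ladder: Sequence[int] | None = None,
) -> tuple[int, dict[int, CVResult]]:
    """Cross-validate the ensemble at every ladder subset size.

    Returns the best M (highest mean CV accuracy, smallest M on ties) and
    the per-M results.  This mirrors the report-best-over-ladder reading of
    the original analysis; for an unbiased estimate wrap it in an outer CV.
    """
    from .ensemble import subset_size_ladder

    if ladder is None:
        ladder = subset_size_ladder(features.n_features)
    results = {
        int(M): repeated_kfold(features, ensemble_factory(M=int(M), N=N), R=R, K=K, seed=seed)
        for M in ladder
    }
    best_m = max(sorted(results), key=lambda m: results[m].mean_accuracy)
    return best_m, results
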