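"""Strong learners and the random-subspace LDA ensemble.

The strong learners are a linear soft-margin SVM (with per-feature
z-standardization fitted on the training rows) and an LDA on the raw
features, both trained on all D features.  The random-subspace ensemble
draws N independent subsets of M feature indices (uniform, without
replacement within a subset), trains one LDA weak learner per subset, and
predicts by majority vote over the weak learners.

The candidate subset sizes follow a ladder centred at
``c = floor(sqrt(D) + 0.5)``: ``{c-4, c-2, c, c+2, c+4}`` clipped to
``[1, D]``.  For D = 50 this gives {3, 5, 7, 9, 11}; for D = 480, center 22
and ladder {18, 20, 22, 24, 26}.

LDA fits use a pooled within-class covariance with a small ridge
(1e-6 x mean diagonal) so the high-dimensional strong-LDA case stays
numerically defined while still exhibiting its characteristic
small-sample degradation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "SubspaceSpec",
    "SubspaceEnsemble",
    "StrongLearner",
    "subset_size_ladder",
    "draw_subsets",
    "train_ensemble",
    "predict_majority",
    "predict_with_first_n",
    "train_strong",
    "predict_strong",
]


class _RidgedCovariance(BaseEstimator):
    """Empirical covariance plus a small diagonal ridge.

    Plugged into sklearn's LDA as ``covariance_estimator`` so that singular
    within-class covariances (feature count >= training size) stay
    invertible.  The ridge is ``alpha * mean(diag)``, or ``alpha`` itself
    for an all-zero diagonal.
    """

    def __init__(self, alpha: float = 1e-6):
        self.alpha = alpha

    def fit(self, X: np.ndarray) -> "_RidgedCovariance":
        X = np.asarray(X, dtype=float)
        cov = np.atleast_2d(np.cov(X, rowvar=False, bias=True))
        mean_diag = float(np.mean(np.diag(cov)))
        ridge = self.alpha * (mean_diag if mean_diag > 0 else 1.0)
        self.covariance_ = cov + ridge * np.eye(cov.shape[0])
        self.location_ = X.mean(axis=0)
        return self


def _make_lda() -> LinearDiscriminantAnalysis:
    return LinearDiscriminantAnalysis(
        solver="lsqr", covariance_estimator=_RidgedCovariance()
    )


@dataclass(frozen=True)
class SubspaceSpec:
    """Random-subspace configuration: N weak learners on M of D features."""

    D: int
    M: int
    N: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.M <= self.D:
            raise ValueError(f"need 1 <= M <= D, got M={self.M}, D={self.D}")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass
class SubspaceEnsemble:
    """N trained LDA weak learners, each bound to its feature-index subset."""

    subsets: list[np.ndarray]
    learners: list[LinearDiscriminantAnalysis]
    classes: np.ndarray
    spec: SubspaceSpec

    @property
    def n_learners(self) -> int:
        return len(self.learners)


@dataclass
class StrongLearner:
    """A full-feature classifier: linear SVM (standardized) or LDA (raw)."""

    kind: str
    model: Pipeline | LinearDiscriminantAnalysis
    n_features: int


def subset_size_ladder(D: int) -> list[int]:
    """Candidate subset sizes around ``c = floor(sqrt(D) + 0.5)``.

    Returns ``{c-4, c-2, c, c+2, c+4}`` intersected with ``[1, D]``,
    deduplicated and sorted.

    >>> subset_size_ladder(50)
    [3, 5, 7, 9, 11]
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    c = math.floor(math.sqrt(D) + 0.5)
    ladder = {c + delta for delta in (-4, -2, 0, 2, 4)}
    return sorted(m for m in ladder if 1 <= m <= D)


def draw_subsets(spec: SubspaceSpec) -> list[np.ndarray]:
    """Draw N independent M-element feature-index subsets.

    Within a subset, indices are distinct and uniform over ``0..D-1``;
    subsets of different learners may overlap.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    return [
        np.sort(rng.choice(spec.D, size=spec.M, replace=False))
        for _ in range(spec.N)
    ]


def train_ensemble(features: FeatureMatrix, spec: SubspaceSpec) -> SubspaceEnsemble:
    """Fit one LDA weak learner per random feature subset (no standardization)."""
    if spec.D != features.n_features:
        raise ValueError(
            f"spec.D={spec.D} does not match feature count {features.n_features}"
        )
    y = features.labels
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 training trials each")
    subsets = draw_subsets(spec)
    learners = []
    for subset in subsets:
        lda = _make_lda()
        lda.fit(features.values[:, subset], y.astype(str))
        learners.append(lda)
    return SubspaceEnsemble(
        subsets=subsets, learners=learners, classes=classes, spec=spec
    )


def predict_with_first_n(
    ensemble: SubspaceEnsemble, values: np.ndarray, n: int
) -> np.ndarray:
    """Majority vote of the first ``n`` trained weak learners.

    Ties (possible for even ``n``) are broken by a seeded coin flip derived
    from the ensemble's own seed, so repeated calls are reproducible.
    """
    if not 1 <= n <= ensemble.n_learners:
        raise ValueError(f"need 1 <= n <= {ensemble.n_learners}, got {n}")
    values = np.asarray(values, dtype=float)
    if values.shape[1] != ensemble.spec.D:
        raise ValueError(
            f"feature count {values.shape[1]} does not match trained D={ensemble.spec.D}"
        )
    # votes[i, j]: class index voted by learner i for trial j
    votes = np.stack(
        [
            np.searchsorted(ensemble.classes, lrn.predict(values[:, sub]))
            for lrn, sub in zip(ensemble.learners[:n], ensemble.subsets[:n])
        ]
    )
    counts_1 = votes.sum(axis=0)
    winner = (counts_1 * 2 > n).astype(int)
    tied = counts_1 * 2 == n
    if tied.any():
        rng = np.random.default_rng(ensemble.spec.seed + 0x7EA)
        winner[tied] = rng.integers(0, 2, size=int(tied.sum()))
    return ensemble.classes[winner]


def predict_majority(ensemble: SubspaceEnsemble, values: np.ndarray) -> np.ndarray:
    """Majority vote over all N weak learners."""
    return predict_with_first_n(ensemble, values, ensemble.n_learners)


def train_strong(features: FeatureMatrix, kind: str = "linear_svm") -> StrongLearner:
    """Fit a strong learner on all D features.

    ``linear_svm``: per-feature z-standardization (fitted on the training
    rows; zero-variance features keep unit scale) followed by a linear-kernel
    soft-margin SVM with unit cost.  ``lda``: discriminant on the raw
    features, ridge-stabilized.
    """
    y = features.labels.astype(str)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes in the training data")
    if kind == "linear_svm":
        model: Pipeline | LinearDiscriminantAnalysis = Pipeline(
            [
                ("standardize", StandardScaler()),
                ("svm", SVC(kernel="linear", C=1.0)),
            ]
        )
    elif kind == "lda":
        model = _make_lda()
    else:
        raise ValueError("kind must be 'linear_svm' or 'lda'")
    model.fit(features.values, y)
    return StrongLearner(kind=kind, model=model, n_features=features.n_features)


def predict_strong(learner: StrongLearner, values: np.ndarray) -> np.ndarray:
    """Predict class labels with a trained strong learner."""
    values = np.asarray(values, dtype=float)
    if values.shape[1] != learner.n_features:
        raise ValueError(
            f"feature count {values.shape[1]} does not match trained "
            f"D={learner.n_features}"
        )
    return learner.model.predict(values)
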