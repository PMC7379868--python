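"""Subset-size ladder, random subsets, weak/strong learners, majority vote."""

import numpy as np
import pytest

from nirspace import (
    SubspaceSpec,
    draw_subsets,
    predict_majority,
    predict_strong,
    predict_with_first_n,
    subset_size_ladder,
    train_ensemble,
    train_strong,
)
from conftest import gaussian_features


class TestSubsetSizeLadder:
    def test_worked_example_d50(self):
        assert subset_size_ladder(50) == [3, 5, 7, 9, 11]

    def test_clipping_at_d1(self):
        assert subset_size_ladder(1) == [1]

    def test_d480_centers_at_22(self):
        assert subset_size_ladder(480) == [18, 20, 22, 24, 26]

    @pytest.mark.parametrize("D", [2, 9, 30, 100, 960])
    def test_center_is_rounded_square_root(self, D):
        import math

        ladder = subset_size_ladder(D)
        c = math.floor(math.sqrt(D) + 0.5)
        assert (c in ladder) or c > D
        assert all(1 <= m <= D for m in ladder)
        assert ladder == sorted(set(ladder))

    def test_invalid_d_rejected(self):
        with pytest.raises(ValueError):
            subset_size_ladder(0)


class TestDrawSubsets:
    def test_m_equals_d_gives_full_range(self):
        subsets = draw_subsets(SubspaceSpec(D=6, M=6, N=4, seed=0))
        for s in subsets:
            assert np.array_equal(s, np.arange(6))

    def test_seed_determinism(self):
        a = draw_subsets(SubspaceSpec(D=30, M=5, N=10, seed=9))
        b = draw_subsets(SubspaceSpec(D=30, M=5, N=10, seed=9))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_each_subset_has_m_distinct_indices(self):
        for s in draw_subsets(SubspaceSpec(D=20, M=7, N=25, seed=3)):
            assert len(np.unique(s)) == 7
            assert s.min() >= 0 and s.max() < 20

    def test_marginal_inclusion_is_uniform(self):
        # Monte-Carlo: with D=10, M=3 each index should appear in ~30% of sets
        subsets = draw_subsets(SubspaceSpec(D=10, M=3, N=10_000, seed=7))
        counts = np.zeros(10)
        for s in subsets:
            counts[s] += 1
        freq = counts / 10_000
        assert np.all(np.abs(freq - 0.3) < 0.02)

    def test_m_larger_than_d_rejected(self):
        with pytest.raises(ValueError):
            SubspaceSpec(D=5, M=6, N=1)


class TestEnsembleTraining:
    def test_separable_clouds_fit_perfectly(self):
        fm = gaussian_features(n_per_class=15, n_features=10, separation=8.0, seed=1)
        ens = train_ensemble(fm, SubspaceSpec(D=10, M=3, N=21, seed=2))
        pred = predict_majority(ens, fm.values)
        assert np.array_equal(pred.astype(str), fm.labels.astype(str))

    def test_single_learner_ensemble_equals_that_learner(self):
        fm = gaussian_features(n_per_class=12, n_features=6, separation=1.0, seed=4)
        ens = train_ensemble(fm, SubspaceSpec(D=6, M=4, N=1, seed=5))
        direct = ens.learners[0].predict(fm.values[:, ens.subsets[0]])
        assert np.array_equal(predict_majority(ens, fm.values).astype(str), direct)

    def test_majority_vote_matches_explicit_counting(self):
        fm = gaussian_features(n_per_class=20, n_features=8, separation=0.8, seed=6)
        ens = train_ensemble(fm, SubspaceSpec(D=8, M=3, N=15, seed=7))
        got = predict_majority(ens, fm.values)
        # brute-force oracle: count votes learner by learner
        for j in range(fm.n_trials):
            tally = {c: 0 for c in ens.classes}
            for lrn, sub in zip(ens.learners, ens.subsets):
                vote = lrn.predict(fm.values[j : j + 1, sub])[0]
                tally[vote] += 1
            winner = max(tally, key=tally.get)  # N odd: no ties
            assert got[j] == winner

    def test_prefix_property_full_n_equals_majority(self):
        fm = gaussian_features(n_per_class=15, n_features=9, separation=0.5, seed=8)
        ens = train_ensemble(fm, SubspaceSpec(D=9, M=3, N=17, seed=9))
        a = predict_with_first_n(ens, fm.values, 17)
        b = predict_majority(ens, fm.values)
        assert np.array_equal(a, b)

    def test_tie_break_is_reproducible(self):
        fm = gaussian_features(n_per_class=15, n_features=8, separation=0.0, seed=10)
        ens = train_ensemble(fm, SubspaceSpec(D=8, M=2, N=10, seed=11))
        a = predict_with_first_n(ens, fm.values, 10)
        b = predict_with_first_n(ens, fm.values, 10)
        assert np.array_equal(a, b)

    def test_column_permutation_with_consistent_subsets_is_invariant(self):
        fm = gaussian_features(n_per_class=12, n_features=7, separation=0.7, seed=12)
        ens = train_ensemble(fm, SubspaceSpec(D=7, M=3, N=9, seed=13))
        perm = np.random.default_rng(14).permutation(7)
        inv = np.argsort(perm)
        permuted_values = fm.values[:, perm]
        import copy

        ens_p = copy.copy(ens)
        ens_p.subsets = [inv[s] for s in ens.subsets]
        a = predict_majority(ens, fm.values)
        b = predict_majority(ens_p, permuted_values)
        assert np.array_equal(a, b)

    def test_missing_class_rejected(self):
        fm = gaussian_features(n_per_class=10, n_features=5, seed=15)
        fm.labels[:] = "idle"
        with pytest.raises(ValueError):
            train_ensemble(fm, SubspaceSpec(D=5, M=2, N=3, seed=0))

    def test_n_beyond_trained_learners_rejected(self):
        fm = gaussian_features(n_per_class=10, n_features=5, separation=1.0, seed=16)
        ens = train_ensemble(fm, SubspaceSpec(D=5, M=2, N=5, seed=1))
        with pytest.raises(ValueError):
            predict_with_first_n(ens, fm.values, 6)


class TestStrongLearners:
    @pytest.mark.parametrize("kind", ["linear_svm", "lda"])
    def test_separable_clouds_train_perfectly(self, kind):
        fm = gaussian_features(n_per_class=15, n_features=6, separation=8.0, seed=20)
        learner = train_strong(fm, kind=kind)
        pred = predict_strong(learner, fm.values)
        assert np.array_equal(pred.astype(str), fm.labels.astype(str))

    def test_zero_variance_feature_does_not_crash_svm(self):
        fm = gaussian_features(n_per_class=10, n_features=4, separation=3.0, seed=21)
        fm.values[:, 2] = 1.0  # constant column
        learner = train_strong(fm, kind="linear_svm")
        assert predict_strong(learner, fm.values).shape == (20,)

    def test_duplicated_columns_keep_lda_defined(self):
        # duplicate every feature: within-class covariance is singular, the
        # ridge keeps the discriminant defined
        fm = gaussian_features(n_per_class=10, n_features=4, separation=3.0, seed=22)
        doubled = gaussian_features(n_per_class=10, n_features=4, separation=3.0, seed=22)
        doubled.values = np.hstack([fm.values, fm.values])
        from nirspace.features import FeatureDescriptor

        doubled.columns = [
            FeatureDescriptor("AVG", "HbO", f"F{j}", (0.0, float(j + 1)))
            for j in range(8)
        ]
        learner = train_strong(doubled, kind="lda")
        pred = predict_strong(learner, doubled.values)
        assert np.isin(pred.astype(str), ["idle", "mental_arithmetic"]).all()

    def test_high_dimensional_lda_stays_defined(self):
        # more features than trials: the classical pooled covariance is
        # singular; training and prediction must still work
        fm = gaussian_features(n_per_class=10, n_features=50, separation=1.0, seed=23)
        learner = train_strong(fm, kind="lda")
        assert predict_strong(learner, fm.values).shape == (20,)

    def test_informative_feature_beats_chance_held_out(self):
        train = gaussian_features(
            n_per_class=30, n_features=20, separation=2.0, seed=24, informative="first"
        )
        test = gaussian_features(
            n_per_class=30, n_features=20, separation=2.0, seed=25, informative="first"
        )
        learner = train_strong(train, kind="linear_svm")
        acc = np.mean(
            predict_strong(learner, test.values).astype(str)
            == test.labels.astype(str)
        )
        assert acc > 0.7

    def test_unknown_kind_rejected(self):
        fm = gaussian_features(seed=26)
        with pytest.raises(ValueError):
            train_strong(fm, kind="rbf_svm")
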