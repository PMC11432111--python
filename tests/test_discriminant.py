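"""PLS-DA fitting, validation statistics, VIP selection and clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylage import discriminant as disc


def gaussian_two_class(
    rng, n_features=20, n_per_group=7, effect_sd=3.0, n_informative=None
):
    """Features x samples matrix with a planted mean shift in one class."""
    if n_informative is None:
        n_informative = n_features
    X = rng.normal(size=(n_features, 2 * n_per_group))
    X[:n_informative, n_per_group:] += effect_sd
    cols = [f"s{j}" for j in range(2 * n_per_group)]
    frame = pd.DataFrame(X, index=[f"f{i}" for i in range(n_features)], columns=cols)
    y = pd.Series(["S1"] * n_per_group + ["S3"] * n_per_group, index=cols)
    return frame, y


class TestFit:
    def test_separable_feature_separates_scores(self, rng):
        X, y = gaussian_two_class(rng, n_features=1, effect_sd=10.0)
        model = disc.fit_plsda(X, y, n_components=1)
        s1 = model.scores[:7, 0]
        s3 = model.scores[7:, 0]
        assert max(s1) < min(s3) or max(s3) < min(s1)
        assert model.r2y > 0.9

    def test_same_input_same_model(self, rng):
        X, y = gaussian_two_class(rng)
        a = disc.fit_plsda(X, y)
        b = disc.fit_plsda(X, y)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.scores, b.scores)
        assert a.r2y == b.r2y

    def test_constant_features_dropped_with_warning(self, rng):
        X, y = gaussian_two_class(rng, n_features=5)
        X.iloc[0] = 7.0
        with pytest.warns(RuntimeWarning, match="constant"):
            model = disc.fit_plsda(X, y)
        assert model.dropped_features == ["f0"]
        assert len(model.feature_ids) == 4

    def test_too_many_components_rejected(self, rng):
        X, y = gaussian_two_class(rng, n_per_group=3)
        with pytest.raises(ValueError, match="n_components"):
            disc.fit_plsda(X, y, n_components=6)

    def test_noise_data_fails_permutation_validation(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(30, 14)),
            index=[f"f{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(14)],
        )
        y = pd.Series(["S1"] * 7 + ["S3"] * 7, index=X.columns)
        p_r2y, p_q2 = disc.permutation_test(X, y, n_perm=99, seed=0)
        assert p_r2y > 0.05
        assert p_q2 > 0.05


class TestVIP:
    def test_squared_vip_averages_to_one(self, rng):
        X, y = gaussian_two_class(rng, n_features=40, n_informative=5)
        model = disc.fit_plsda(X, y)
        assert model.vip.pow(2).sum() == pytest.approx(40.0, rel=1e-12)

    def test_informative_feature_has_maximal_vip(self, rng):
        X, y = gaussian_two_class(rng, n_features=30, n_informative=1,
                                  effect_sd=6.0)
        model = disc.fit_plsda(X, y)
        assert model.vip.idxmax() == "f0"
        assert model.vip["f0"] >= 1.0

    def test_two_equal_features_both_have_unit_vip(self, rng):
        X, y = gaussian_two_class(rng, n_features=2, effect_sd=4.0)
        # make the two features identical so contributions match exactly
        X.iloc[1] = X.iloc[0]
        model = disc.fit_plsda(X, y, n_components=1)
        assert model.vip["f0"] == pytest.approx(1.0)
        assert model.vip["f1"] == pytest.approx(1.0)
        assert disc.select_vip(model, 1.0) == ["f0", "f1"]

    def test_vip_invariant_to_feature_order(self, rng):
        X, y = gaussian_two_class(rng, n_features=25, n_informative=8)
        a = disc.fit_plsda(X, y).vip.sort_index()
        b = disc.fit_plsda(X.iloc[::-1], y).vip.sort_index()
        assert np.allclose(a, b)


class TestQ2:
    def test_strong_signal_gives_high_q2(self, rng):
        X, y = gaussian_two_class(rng, n_features=20, effect_sd=3.0)
        q2 = disc.q2_cross_validation(X, y, n_folds=7, seed=0)
        assert q2 > 0.5

    def test_permuted_labels_give_low_q2(self, rng):
        X, y = gaussian_two_class(rng, n_features=20, effect_sd=3.0)
        perm = pd.Series(
            rng.permutation(y.to_numpy()), index=y.index
        )
        # permuted labels break the planted structure
        q2 = disc.q2_cross_validation(X, perm, n_folds=7, seed=0)
        assert q2 < 0.3

    def test_loo_equals_nfolds_equal_samples(self, rng):
        X, y = gaussian_two_class(rng, n_features=10, n_per_group=4)
        a = disc.q2_cross_validation(X, y, n_folds=8, seed=1)
        b = disc.q2_cross_validation(X, y, n_folds=len(y), seed=2)
        # every fold is a single sample in both cases -> same PRESS
        assert a == pytest.approx(b)

    def test_q2_not_above_r2y(self, rng):
        X, y = gaussian_two_class(rng, n_features=15, effect_sd=1.0)
        model = disc.fit_plsda(X, y)
        q2 = disc.q2_cross_validation(X, y, seed=0)
        assert q2 <= model.r2y + 1e-9


class TestPermutation:
    def test_strong_signal_reaches_minimal_p(self, rng):
        X, y = gaussian_two_class(rng, n_features=20, effect_sd=3.0)
        p_r2y, p_q2 = disc.permutation_test(X, y, n_perm=99, seed=0)
        assert p_r2y == pytest.approx(1 / 100)
        assert p_q2 == pytest.approx(1 / 100)

    def test_p_values_bounded_below_by_add_one_rule(self, rng):
        X, y = gaussian_two_class(rng)
        p_r2y, p_q2 = disc.permutation_test(X, y, n_perm=49, seed=3)
        assert p_r2y >= 1 / 50
        assert p_q2 >= 1 / 50

    def test_invariant_to_feature_order(self, rng):
        X, y = gaussian_two_class(rng, n_features=12, effect_sd=2.0)
        a = disc.permutation_test(X, y, n_perm=30, seed=7)
        b = disc.permutation_test(X.iloc[::-1], y, n_perm=30, seed=7)
        assert a == b


class TestSelectionCircularity:
    def test_prefiltering_on_same_samples_inflates_r2y(self, rng):
        """Feature selection by per-feature t-test on the same samples
        biases the downstream model's explained variance upward even for
        pure noise; the pipeline inherits this optimism by design.  The
        fair null reference is a random subset of equal size (a full
        many-features fit is already saturated at small n)."""
        from scipy import stats

        n_features, n = 400, 14
        y = pd.Series(["S1"] * 7 + ["S3"] * 7,
                      index=[f"s{j}" for j in range(n)])
        r2y_selected, r2y_random = [], []
        for rep in range(10):
            X = pd.DataFrame(
                rng.normal(size=(n_features, n)),
                index=[f"f{i}" for i in range(n_features)],
                columns=y.index,
            )
            t, p = stats.ttest_ind(
                X.iloc[:, :7], X.iloc[:, 7:], axis=1, equal_var=False
            )
            chosen = X[p < 0.05]
            if len(chosen) < 3:
                continue
            random_subset = X.iloc[
                rng.choice(n_features, size=len(chosen), replace=False)
            ]
            r2y_selected.append(disc.fit_plsda(chosen, y).r2y)
            r2y_random.append(disc.fit_plsda(random_subset, y).r2y)
        assert np.mean(r2y_selected) > np.mean(r2y_random)


class TestClusterPurity:
    def test_separated_groups_cluster_purely(self, rng):
        X, y = gaussian_two_class(rng, n_features=20, effect_sd=3.0)
        purity, leaves = disc.cluster_purity(X, y)
        assert purity
        assert sorted(leaves) == sorted(X.columns)

    def test_shuffled_labels_rarely_pure(self, rng):
        X, _ = gaussian_two_class(rng, n_features=20, effect_sd=0.0)
        hits = 0
        n_trials = 50
        for _ in range(n_trials):
            y = pd.Series(
                rng.permutation(["S1"] * 7 + ["S3"] * 7), index=X.columns
            )
            purity, _ = disc.cluster_purity(X, y)
            hits += purity
        assert hits / n_trials < 0.2

    def test_single_group_duplicates_handled(self):
        X = pd.DataFrame(
            np.tile(np.arange(5.0)[:, None], 4),
            index=[f"f{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(4)],
        )
        y = pd.Series(["S1"] * 4, index=X.columns)
        purity, leaves = disc.cluster_purity(X, y)
        assert isinstance(purity, bool)
        assert len(leaves) == 4
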