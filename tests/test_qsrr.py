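import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eluorder import (
    GeneratorSpec,
    elution_ranks,
    evaluate_model,
    fit_mlr,
    generate_linear_dataset,
    kennard_stone_split,
    percent_rmse_order,
    percent_rmse_tr,
    predict,
)
from eluorder.errors import SingularDesignError, ValidationError
from eluorder.qsrr import QSRRModel

from conftest import make_table_1d


# --- independent oracles ---------------------------------------------------


def brute_force_kennard_stone(X, n_train):
    """Naive greedy max-min selection in autoscaled space (test oracle)."""
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    n = len(Z)
    D = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1))
    best_pair, best_d = None, -1.0
    for i, j in itertools.combinations(range(n), 2):
        if D[i, j] > best_d:
            best_pair, best_d = (i, j), D[i, j]
    sel = list(best_pair)
    while len(sel) < n_train:
        best_i, best_min = None, -1.0
        for i in range(n):
            if i in sel:
                continue
            dmin = min(D[i, j] for j in sel)
            if dmin > best_min:
                best_i, best_min = i, dmin
        sel.append(best_i)
    return sel


def normal_equations(A, y):
    return np.linalg.solve(A.T @ A, A.T @ y)


# --- Kennard-Stone ---------------------------------------------------------


class TestKennardStone:
    def test_collinear_extremes_selected(self):
        table = make_table_1d(np.arange(10.0))
        split = kennard_stone_split(table, 0.2)
        assert sorted(split.train_indices) == [0, 9]

    def test_maxmin_third_pick(self):
        # points {0, 1, 2, 10}: seed pair (0, 10); 2 beats 1 on min-distance
        table = make_table_1d([0.0, 1.0, 2.0, 10.0])
        split = kennard_stone_split(table, 0.75)
        assert list(split.train_indices) == [0, 3, 2]
        assert list(split.test_indices) == [1]

    def test_single_test_point(self, small_table):
        n = small_table.n
        split = kennard_stone_split(small_table, (n - 1) / n - 1e-9)
        assert len(split.test_indices) == 1

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(n=st.integers(5, 12), k=st.integers(1, 3), seed=st.integers(0, 10**6))
    def test_matches_brute_force(self, n, k, seed):
        """Greedy selection equals the naive max-min oracle on small tables."""
        rng = np.random.default_rng(seed)
        spec = GeneratorSpec(
            n=n, K=k, true_coefficients=(20.0, *([2.0] * k)),
            noise_sd=0.5, seed=seed,
        )
        table, _ = generate_linear_dataset(spec)
        n_train = max(2, int(np.floor(0.7 * n + 0.5)))
        split = kennard_stone_split(table, 0.7)
        assert list(split.train_indices) == brute_force_kennard_stone(
            table.X, n_train
        )

    def test_partition_and_determinism(self, small_table):
        a = kennard_stone_split(small_table, 0.7)
        b = kennard_stone_split(small_table, 0.7)
        assert a == b
        assert sorted(a.train_indices + a.test_indices) == list(range(small_table.n))

    def test_too_small_errors(self):
        with pytest.raises(ValidationError):
            kennard_stone_split(make_table_1d([0.0, 1.0]), 0.5)


# --- MLR -------------------------------------------------------------------


class TestFitMLR:
    def test_exact_interpolation(self, noiseless):
        table, truth = noiseless
        model = fit_mlr(table, range(table.n))
        assert model.intercept == pytest.approx(truth.intercept, rel=1e-8)
        np.testing.assert_allclose(model.coefficients, truth.coefficients, rtol=1e-8)
        np.testing.assert_allclose(predict(model, table), table.t_obs, rtol=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(n=st.integers(8, 50), seed=st.integers(0, 10**6))
    def test_matches_normal_equations(self, n, seed):
        """OLS coefficients equal the (X'X)^-1 X'y oracle on random designs."""
        spec = GeneratorSpec(
            n=n, K=3, true_coefficients=(15.0, 2.0, -1.0, 0.5),
            noise_sd=1.0, seed=seed,
        )
        table, _ = generate_linear_dataset(spec)
        model = fit_mlr(table, range(n))
        A = np.column_stack([np.ones(n), table.X])
        beta = normal_equations(A, table.t_obs)
        np.testing.assert_allclose(model.beta, beta, rtol=1e-8)

    def test_residual_orthogonality(self, small_table):
        model = fit_mlr(small_table, range(small_table.n))
        resid = small_table.t_obs - predict(model, small_table)
        assert abs(resid.sum()) < 1e-8
        np.testing.assert_allclose(small_table.X.T @ resid, 0.0, atol=1e-7)

    def test_two_points_one_descriptor_interpolates(self):
        table = make_table_1d([0.0, 1.0, 2.0])
        model = fit_mlr(table, [0, 2])
        np.testing.assert_allclose(
            predict(model, table, [0, 2]), table.t_obs[[0, 2]], atol=1e-10
        )

    def test_rank_deficiency_raises(self):
        spec = GeneratorSpec(n=10, K=1, true_coefficients=(5.0, 1.0), seed=0)
        table, _ = generate_linear_dataset(spec)
        constant = type(table)(
            ids=table.ids,
            descriptor_names=("x",),
            X=np.ones_like(table.X),
            t_obs=table.t_obs,
        )
        with pytest.raises(SingularDesignError):
            fit_mlr(constant, range(10))


# --- metrics ---------------------------------------------------------------


class TestRetentionMetric:
    def test_hand_computed_ten_percent(self):
        assert percent_rmse_tr([1, 2, 4], [1.1, 1.8, 4.4]) == pytest.approx(10.0)

    def test_close_peak_scenario(self):
        # two peaks 0.1 min apart, each predicted 0.1 min early
        assert percent_rmse_tr([5.1, 5.2], [5.0, 5.1]) == pytest.approx(
            1.942, abs=5e-4
        )

    def test_zero_iff_identical(self, rng):
        t = np.abs(rng.normal(10, 2, 20)) + 1
        assert percent_rmse_tr(t, t) == 0.0
        bumped = t.copy()
        bumped[3] *= 1.01
        assert percent_rmse_tr(t, bumped) > 0.0

    def test_literal_variant_is_signed_mean(self):
        assert percent_rmse_tr([1, 2], [1.1, 1.8], "signed_mean") == pytest.approx(
            100 * (0.1 - 0.1) / 2, abs=1e-12
        )
        assert percent_rmse_tr([1, 1], [0.9, 0.9], "signed_mean") < 0

    def test_errors(self):
        with pytest.raises(ValidationError):
            percent_rmse_tr([1, 2], [1])
        with pytest.raises(ValidationError):
            percent_rmse_tr([0.0, 1.0], [1.0, 1.0])


class TestElutionRanks:
    @pytest.mark.parametrize(
        "t, expected",
        [
            ([5.1, 5.2], [1, 2]),
            ([1.0, 2.0, 3.0], [1, 2, 3]),
            ([3.0, 1.0, 2.0], [3, 1, 2]),
            ([2.0, 2.0, 1.0], [2, 3, 1]),  # tie broken by row order
        ],
    )
    def test_examples(self, t, expected):
        assert list(elution_ranks(t)) == expected

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.1, 100, allow_nan=False), min_size=1, max_size=40),
    )
    def test_always_a_permutation(self, t):
        ranks = elution_ranks(np.array(t))
        assert sorted(ranks) == list(range(1, len(t) + 1))


class TestOrderMetric:
    def test_swap_of_two(self):
        assert percent_rmse_order([1, 2], [2, 1]) == pytest.approx(79.057, abs=5e-4)

    def test_three_with_one_swap(self):
        assert percent_rmse_order([1, 2, 3], [1, 3, 2]) == pytest.approx(
            34.694, abs=5e-4
        )

    def test_full_reversal_n4(self):
        # hand oracle: 100*sqrt(((3/1)^2+(1/2)^2+(1/3)^2+(3/4)^2)/4)
        expected = 100 * np.sqrt((9 + 0.25 + 1 / 9 + 0.5625) / 4)
        assert percent_rmse_order([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(
            expected
        )

    def test_identical_is_zero(self):
        assert percent_rmse_order([2, 1, 3], [2, 1, 3]) == 0.0

    def test_non_permutation_rejected(self):
        with pytest.raises(ValidationError):
            percent_rmse_order([1, 1, 3], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(n=st.integers(2, 30), seed=st.integers(0, 10**6))
    def test_monotone_transform_invariance(self, n, seed):
        """%RMSE(order) depends on predicted times only through their ranks."""
        rng = np.random.default_rng(seed)
        t_obs = np.sort(rng.uniform(1, 50, n)) + np.arange(n) * 1e-6
        t_pred = rng.uniform(1, 50, n)
        obs_r = elution_ranks(t_obs)
        base = percent_rmse_order(obs_r, elution_ranks(t_pred))
        warped = percent_rmse_order(obs_r, elution_ranks(np.exp(t_pred / 20)))
        assert warped == pytest.approx(base)


class TestEvaluateModel:
    def test_noise_free_is_zero_zero(self, noiseless):
        table, truth = noiseless
        f1, f2 = evaluate_model(truth, table, None)
        assert f1 == pytest.approx(0.0, abs=1e-10)
        assert f2 == 0.0

    def test_subset_ranks_are_local(self, small_table):
        """Ranks inside a subset run 1..m, independent of excluded rows."""
        model = fit_mlr(small_table, range(small_table.n))
        subset = [3, 7, 11, 15]
        f1, f2 = evaluate_model(model, small_table, subset)
        t_obs = small_table.t_obs[subset]
        t_pred = predict(model, small_table, subset)
        assert f2 == pytest.approx(
            percent_rmse_order(elution_ranks(t_obs), elution_ranks(t_pred))
        )
        assert f1 == pytest.approx(percent_rmse_tr(t_obs, t_pred))

    def test_constant_model_predicts_intercept(self, small_table):
        model = QSRRModel(5.0, np.zeros(3), small_table.descriptor_names, 10, 0.0)
        np.testing.assert_allclose(predict(model, small_table), 5.0)
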