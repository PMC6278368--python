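"""Validation suite: fit stats, external stats, GT criteria, QUIK, scrambling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mgmtqsar.synthetic import QsarSimSpec, simulate_qsar
from mgmtqsar.validation import (
    external_stats,
    fit_stats,
    golbraikh_tropsha,
    k_index,
    mcdm_score,
    quik_check,
    validate_model,
    y_scramble,
)


class TestFitStats:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        s = fit_stats(y, y, n=6, p=1)
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(0.0)
        assert s.ccc == pytest.approx(1.0)

    def test_adjusted_r2_formula(self):
        # 1 - (1 - 0.68) * 82 / 77 = 0.659, printed as 0.66
        r2 = 0.68
        r2_adj = 1 - (1 - r2) * (83 - 1) / (83 - 5 - 1)
        assert round(r2_adj, 2) == 0.66
        assert r2_adj == pytest.approx(0.659, abs=5e-4)

    def test_hand_computed_sums_of_squares(self):
        # 6-point fixture, all five statistics against explicit sums
        y = np.array([1.0, 2.0, 2.5, 4.0, 5.0, 5.5])
        yhat = np.array([1.2, 1.8, 3.0, 3.8, 4.6, 5.6])
        n, p = 6, 2
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_reg = float(((yhat - y.mean()) ** 2).sum())
        s = fit_stats(y, yhat, n, p)
        assert s.r2 == pytest.approx(1 - ss_res / ss_tot)
        assert s.r2_adj == pytest.approx(1 - (1 - s.r2) * 5 / 3)
        assert s.rmse == pytest.approx(np.sqrt(ss_res / 6))
        assert s.f == pytest.approx((ss_reg / 2) / (ss_res / 3))
        sxy = np.mean((y - y.mean()) * (yhat - yhat.mean()))
        ccc = 2 * sxy / (y.var() + yhat.var() + (y.mean() - yhat.mean()) ** 2)
        assert s.ccc == pytest.approx(ccc)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_stats(np.ones(6), np.ones(6), 6, 1)

    def test_ccc_bounded_by_pearson(self, rng):
        y = rng.standard_normal(30)
        yhat = 0.5 * y + 0.3 + 0.2 * rng.standard_normal(30)
        s = fit_stats(y, yhat, 30, 1)
        assert abs(s.ccc) <= abs(np.corrcoef(y, yhat)[0, 1]) + 1e-12


class TestExternalStats:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        s = external_stats(y, y, y_train_mean=1.5, ss_train=10.0, n_train=20)
        assert s.q2_f1 == s.q2_f2 == s.q2_f3 == 1.0

    def test_train_mean_predictor_scores_zero_f1(self):
        y = np.array([1.0, 2.0, 4.0])
        yhat = np.full(3, 2.0)
        s = external_stats(y, yhat, y_train_mean=2.0, ss_train=10.0, n_train=20)
        assert s.q2_ext == pytest.approx(0.0)

    def test_five_point_fixture_against_sums_of_squares(self):
        y = np.array([0.5, 1.5, 2.0, 3.5, 4.0])
        yhat = np.array([0.8, 1.2, 2.5, 3.0, 4.3])
        ybar_tr, ss_tr, n_tr = 2.1, 30.0, 40
        press = ((y - yhat) ** 2).sum()
        s = external_stats(y, yhat, ybar_tr, ss_tr, n_tr)
        assert s.q2_f1 == pytest.approx(1 - press / ((y - ybar_tr) ** 2).sum())
        assert s.q2_f2 == pytest.approx(1 - press / ((y - y.mean()) ** 2).sum())
        assert s.q2_f3 == pytest.approx(1 - (press / 5) / (ss_tr / n_tr))
        assert s.rmse_test == pytest.approx(np.sqrt(press / 5))
        assert s.r2_ext == pytest.approx(np.corrcoef(y, yhat)[0, 1] ** 2)

    def test_q2_f1_at_least_q2_f2(self, rng):
        # the train mean is off the test mean, so its SS is larger
        for _ in range(20):
            y = rng.standard_normal(8)
            yhat = y + 0.3 * rng.standard_normal(8)
            s = external_stats(y, yhat, rng.standard_normal() + y.mean(), 5.0, 10)
            assert s.q2_f1 >= s.q2_f2 - 1e-12

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            external_stats(np.array([]), np.array([]), 0.0, 1.0, 5)


class TestGolbraikhTropsha:
    def test_identity_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        g = golbraikh_tropsha(y, y, q2_loo=0.9)
        assert g.k == pytest.approx(1.0)
        assert g.k_prime == pytest.approx(1.0)
        assert g.r0_sq == pytest.approx(1.0)
        assert g.passed

    def test_published_model_condition_iii(self):
        # the second literature model reports (R2_ext - R0^2)/R2_ext = 0.04
        # and k = 0.9885, which satisfies the 0.1 / [0.85, 1.15] thresholds
        assert 0.04 < 0.1 and 0.85 <= 0.9885 <= 1.15

    def test_four_point_through_origin_slopes(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.1, 1.9, 3.2, 3.8])
        g = golbraikh_tropsha(y, yhat)
        assert g.k == pytest.approx((y @ yhat) / (yhat @ yhat))
        assert g.k_prime == pytest.approx((y @ yhat) / (y @ y))
        r0 = 1 - ((y - g.k * yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert g.r0_sq == pytest.approx(r0)

    def test_zero_vectors_rejected(self):
        with pytest.raises(ValueError):
            golbraikh_tropsha(np.zeros(3), np.zeros(3))


class TestQuik:
    def test_identical_columns_k_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(30)
        assert k_index(np.column_stack([a, a])) == pytest.approx(1.0)

    def test_orthogonal_columns_k_is_zero(self):
        # exactly uncorrelated pair
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert k_index(np.column_stack([a, b])) == pytest.approx(0.0, abs=1e-12)

    def test_half_correlation_gives_half_k(self):
        # correlation 0.5 -> eigenvalues (1.5, 0.5) -> K = 0.5
        rng = np.random.default_rng(1)
        z = rng.standard_normal((200_000, 2))
        a = z[:, 0]
        b = 0.5 * z[:, 0] + np.sqrt(1 - 0.25) * z[:, 1]
        assert k_index(np.column_stack([a, b])) == pytest.approx(0.5, abs=0.01)

    def test_scale_and_sign_invariance(self, rng):
        X = rng.standard_normal((50, 3))
        k0 = k_index(X)
        X2 = X * np.array([10.0, -0.01, 3.0])
        assert k_index(X2) == pytest.approx(k0, abs=1e-10)

    def test_quik_passes_on_informative_model(self):
        spec = QsarSimSpec(n_compounds=80, n_descriptors=3, n_informative=3,
                           noise_sd=0.2, seed=6)
        X, y, _ = simulate_qsar(spec)
        res = quik_check(X, y.to_numpy())
        assert res.k_xy > res.k_x
        assert res.passed

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            quik_check(X, np.array([1.0, 2.0, 3.0]))


class TestYScramble:
    def test_deterministic_pair(self, small_qsar):
        X, y = small_qsar
        r1 = y_scramble(X, y.to_numpy(), iterations=2, seed=3)
        r2 = y_scramble(X, y.to_numpy(), iterations=2, seed=3)
        np.testing.assert_array_equal(r1.q2_scrambled, r2.q2_scrambled)
        assert r1.iterations == 2

    def test_signal_beats_null(self):
        from mgmtqsar.qsar import loo_press

        spec = QsarSimSpec(n_compounds=60, n_descriptors=3, n_informative=3,
                           noise_sd=0.3, seed=9)
        X, y, _ = simulate_qsar(spec)
        _, q2, _ = loo_press(X, y)
        null = y_scramble(X, y.to_numpy(), iterations=100, seed=0)
        assert q2 > null.q2_percentile(95)

    def test_zero_iterations_warns_and_returns_empty(self, small_qsar):
        X, y = small_qsar
        with pytest.warns(UserWarning):
            res = y_scramble(X, y.to_numpy(), iterations=0)
        assert res.iterations == 0


class TestMcdm:
    def test_all_ideal_scores_one(self):
        assert mcdm_score({"a": (1.0, 1.0, 0.0), "b": (0.0, 0.0, 2.0)}) == 1.0

    def test_all_worst_scores_zero(self):
        assert mcdm_score({"a": (0.0, 1.0, 0.0), "b": (2.0, 0.0, 2.0)}) == 0.0

    def test_mean_of_desirabilities(self):
        score = mcdm_score({"a": (0.4, 1.0, 0.0), "b": (0.8, 1.0, 0.0)})
        assert score == pytest.approx(0.6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_each_criterion(self, v1, v2):
        lo, hi = sorted([v1, v2])
        s_lo = mcdm_score({"a": (lo, 1.0, 0.0), "b": (0.5, 1.0, 0.0)})
        s_hi = mcdm_score({"a": (hi, 1.0, 0.0), "b": (0.5, 1.0, 0.0)})
        assert s_hi >= s_lo

    def test_degenerate_criterion_rejected(self):
        with pytest.raises(ValueError):
            mcdm_score({"a": (0.5, 1.0, 1.0)})


def test_validate_model_end_to_end():
    spec = QsarSimSpec(n_compounds=60, n_descriptors=4, n_informative=3,
                       noise_sd=0.3, seed=10)
    X, y, _ = simulate_qsar(spec)
    report = validate_model(
        X.iloc[:48], y.iloc[:48].to_numpy(), X.iloc[48:], y.iloc[48:].to_numpy(),
        scramble_iterations=20, seed=1,
    )
    assert 0 <= report.fit.r2 <= 1
    assert report.fit.r2_adj <= report.fit.r2
    assert report.external is not None
    assert report.external.q2_f1 >= report.external.q2_f2 - 1e-12
    assert report.gt is not None and report.gt.passed
    assert report.mcdm is not None and 0 <= report.mcdm <= 1
    assert "N_tr = 48" in report.summary()
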