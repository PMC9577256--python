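"""Two-stage TrAdaBoost.R2: weight algebra, boosting contracts, transfer behaviour."""

import warnings

import numpy as np
import pytest

from nirtransfer.svr_pso import SvrParams, svr_fit
from nirtransfer.transfer import (
    AdaBoostR2Ensemble,
    BoostState,
    TransferConfig,
    adaboost_r2_fit,
    adjusted_error,
    fit_two_stage,
    init_weights,
    stage1_update,
    target_weight_fraction,
    weighted_median,
)

PARAMS = SvrParams(C=10.0, gamma=0.3, epsilon=0.01)


def domain_data(seed, m=40, n=20, shift=0.0, d=3, noise=0.05):
    rng = np.random.default_rng(seed)
    Xs = rng.uniform(-2, 2, (m, d))
    ys = np.sin(Xs[:, 0]) + 0.3 * Xs[:, 1] + rng.normal(0, noise, m)
    Xt = rng.uniform(-2, 2, (n, d))
    yt = np.sin(Xt[:, 0]) + 0.3 * Xt[:, 1] + shift + rng.normal(0, noise, n)
    return Xs, ys, Xt, yt


class TestWeightAlgebra:
    def test_uniform_init(self):
        assert np.allclose(init_weights(3, 1), 0.25)
        assert init_weights(118, 118).sum() == pytest.approx(1.0)
        assert np.allclose(init_weights(118, 118), 1.0 / 236)

    def test_init_errors(self):
        with pytest.raises(ValueError):
            init_weights(0, 5)

    def test_fraction_endpoints_and_worked_case(self):
        assert target_weight_fraction(80, 20, 0, 5) == pytest.approx(0.2)
        assert target_weight_fraction(80, 20, 4, 5) == pytest.approx(1.0)
        # n/(m+n) + (t/(K-1)) * (1 - n/(m+n)) = 0.2 + 0.5*0.8
        assert target_weight_fraction(80, 20, 2, 5) == pytest.approx(0.6)

    def test_fraction_monotone_in_t(self):
        fr = [target_weight_fraction(100, 30, t, 8) for t in range(8)]
        assert all(b > a for a, b in zip(fr, fr[1:]))
        with pytest.raises(ValueError):
            target_weight_fraction(10, 10, 0, 1)

    def test_adjusted_error_linear(self):
        assert np.allclose(adjusted_error(np.array([1.0, 2.0, 4.0])), [0.25, 0.5, 1.0])
        assert adjusted_error(np.array([3.0, -7.0])).max() == 1.0
        assert np.all(adjusted_error(np.zeros(4)) == 0.0)

    def test_adjusted_error_shapes_bounded(self, rng):
        r = rng.standard_normal(30)
        for shape in ("linear", "square", "exponential"):
            e = adjusted_error(r, shape)
            assert np.all((e >= 0) & (e <= 1))


class TestStage1Update:
    def test_fixed_point_when_fraction_already_met(self):
        w = init_weights(2, 2)
        w2, beta = stage1_update(w, np.array([0.5, 0.5]), 0.5)
        assert beta == 1.0
        assert np.allclose(w2, w)

    def test_worked_case_beta_half(self):
        """m=n=2, uniform weights, source errors 1: requested fraction 2/3
        needs 2*(beta/4)/(2*beta/4 + 1/2) ... solved by beta = 0.5."""
        w = init_weights(2, 2)
        w2, beta = stage1_update(w, np.array([1.0, 1.0]), 2.0 / 3.0)
        assert beta == pytest.approx(0.5, abs=1e-8)
        assert w2[2:].sum() == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_matches_beta_grid_oracle(self):
        rng = np.random.default_rng(8)
        w = rng.uniform(0.1, 1.0, 7)
        w /= w.sum()
        e = rng.uniform(0.1, 1.0, 4)  # 4 source, 3 target
        req = 0.8

        grid = np.linspace(1e-6, 1.0, 1_000_001)
        src_sum = (w[:4, None] * grid[None, :] ** e[:, None]).sum(axis=0)
        frac = w[4:].sum() / (src_sum + w[4:].sum())
        beta_oracle = grid[np.argmin(np.abs(frac - req))]
        _, beta = stage1_update(w, e, req)
        assert beta == pytest.approx(beta_oracle, abs=1e-5)

    def test_beta_range_and_normalisation(self, rng):
        for _ in range(5):
            w = rng.uniform(0.01, 1, 10)
            w /= w.sum()
            e = rng.uniform(0, 1, 6)
            req = rng.uniform(w[6:].sum(), 1.0)
            w2, beta = stage1_update(w, e, req)
            assert 0 < beta <= 1
            assert w2.sum() == pytest.approx(1.0)
            assert np.all(w2 >= 0)

    def test_requested_below_current_warns_beta_one(self):
        w = np.array([0.1, 0.1, 0.4, 0.4])
        with pytest.warns(UserWarning, match="up-weighting"):
            _, beta = stage1_update(w, np.array([1.0, 1.0]), 0.5)
        assert beta == 1.0


class TestWeightedMedian:
    def test_three_member_exhaustive_oracle(self, rng):
        """For 3 candidates, check against direct enumeration of the
        smallest value whose cumulative sorted weight reaches half."""
        for _ in range(30):
            vals = rng.standard_normal(3)
            wts = rng.uniform(0.1, 2.0, 3)
            order = np.argsort(vals)
            csum = np.cumsum(wts[order])
            expected = None
            for k in range(3):
                if csum[k] >= 0.5 * wts.sum():
                    expected = vals[order][k]
                    break
            assert weighted_median(vals, wts) == expected

    def test_dominant_weight_wins(self):
        assert weighted_median(np.array([1.0, 5.0, 9.0]), np.array([0.1, 0.1, 10.0])) == 9.0


class TestAdaboostR2:
    def test_single_iteration_equals_weighted_svr(self):
        Xs, ys, Xt, yt = domain_data(0)
        X = np.vstack([Xs, Xt])
        y = np.concatenate([ys, yt])
        w = init_weights(len(ys), len(yt))
        ens = adaboost_r2_fit(X, y, w, N=1, base_params=PARAMS)
        single = svr_fit(X, y, PARAMS, sample_weight=w)
        assert np.allclose(ens.predict(X), single.predict(X))

    def test_weight_conservation_through_iterations(self):
        Xs, ys, Xt, yt = domain_data(1)
        X = np.vstack([Xs, Xt])
        y = np.concatenate([ys, yt])
        m = len(ys)
        state = BoostState(w=init_weights(m, len(yt)))
        mask = np.zeros(len(y), dtype=bool)
        mask[:m] = True
        adaboost_r2_fit(X, y, state.w, N=8, base_params=PARAMS, source_mask=mask, state=state)
        # every recorded beta within (0, 1) before the 0.5 stop
        assert all(0 < b < 1 for b in state.beta)

    def test_ensemble_prediction_uses_weighted_median(self, rng):
        class Stub:
            def __init__(self, c):
                self.c = c

            def predict(self, X):
                return np.full(len(X), self.c)

        ens = AdaBoostR2Ensemble([Stub(1.0), Stub(5.0), Stub(9.0)], betas=[0.5, 0.5, 0.5])
        # equal member weights -> middle member
        assert np.all(ens.predict(np.zeros((4, 2))) == 5.0)
        ens2 = AdaBoostR2Ensemble([Stub(1.0), Stub(5.0), Stub(9.0)], betas=[0.9, 0.9, 0.01])
        assert np.all(ens2.predict(np.zeros((2, 2))) == 9.0)


class TestTwoStage:
    def _fit(self, seed, shift, K=3, N=5, m=40, n=20):
        Xs, ys, Xt, yt = domain_data(seed, m=m, n=n, shift=shift)
        cfg = TransferConfig(K=K, N=N, cv_folds=3, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_two_stage(Xs, ys, Xt, yt, cfg, PARAMS)
        return model, (Xs, ys, Xt, yt)

    def test_source_total_weight_nonincreasing(self):
        model, _ = self._fit(0, shift=0.3)
        fr = model.state.target_fraction
        # summed target weight follows the increasing schedule
        assert all(b >= a - 1e-9 for a, b in zip(fr, fr[1:]))

    def test_selected_index_valid_and_errors_finite(self):
        model, _ = self._fit(1, shift=0.2)
        assert 0 <= model.selected < len(model.ensembles)
        assert all(np.isfinite(e) for e in model.step_cv_error)

    def test_no_shift_does_no_harm(self):
        """Source == target distribution: transfer ~ matches target-only SVR."""
        ratios = []
        for seed in range(5):
            model, (Xs, ys, Xt, yt) = self._fit(seed, shift=0.0)
            rng = np.random.default_rng(seed + 100)
            Xq = rng.uniform(-2, 2, (40, 3))
            yq = np.sin(Xq[:, 0]) + 0.3 * Xq[:, 1]
            hybrid = np.sqrt(np.mean((model.predict(Xq) - yq) ** 2))
            solo = svr_fit(Xt, yt, PARAMS)
            solo_rmse = np.sqrt(np.mean((solo.predict(Xq) - yq) ** 2))
            ratios.append(hybrid / solo_rmse)
        assert np.median(ratios) <= 1.1

    def test_planted_shift_beats_source_only(self):
        """With a strong label shift and few target samples, transfer wins."""
        wins = 0
        for seed in range(5):
            Xs, ys, Xt, yt = domain_data(seed, m=60, n=10, shift=0.5)
            cfg = TransferConfig(K=3, N=5, cv_folds=3, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_two_stage(Xs, ys, Xt, yt, cfg, PARAMS)
            rng = np.random.default_rng(seed + 500)
            Xq = rng.uniform(-2, 2, (40, 3))
            yq = np.sin(Xq[:, 0]) + 0.3 * Xq[:, 1] + 0.5
            hybrid = np.sqrt(np.mean((model.predict(Xq) - yq) ** 2))
            src_only = svr_fit(Xs, ys, PARAMS)
            src_rmse = np.sqrt(np.mean((src_only.predict(Xq) - yq) ** 2))
            wins += hybrid < src_rmse
        assert wins >= 4

    def test_prediction_contracts(self):
        model, (Xs, ys, Xt, yt) = self._fit(2, shift=0.2)
        q = Xt[:8]
        p1 = model.predict(q)
        p2 = model.predict(q)
        assert np.array_equal(p1, p2)  # inference determinism
        perm = np.array([3, 0, 7, 1, 2, 6, 4, 5])
        assert np.allclose(model.predict(q[perm]), p1[perm])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TransferConfig(K=1)
        with pytest.raises(ValueError):
            TransferConfig(N=0)
        with pytest.raises(ValueError):
            TransferConfig(loss_shape="cubic")
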