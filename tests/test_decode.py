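import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.linear_model import Ridge

from gazedecode import decode, synthdata
from gazedecode.decode import (
    CHANNELS,
    DecodedEPS,
    TargetEPS,
    ZeroVarianceError,
    cross_validate,
    fit_weights,
    fixation_only_mask,
    make_target,
    predict,
    r_squared,
    target_correlation,
)
from gazedecode.rates import RateMatrices, RateTensor, default_grid
from gazedecode.synthdata import DIRECTIONS, TaskConfig


class TestMakeTarget:
    def test_zero_lag_midpoint(self):
        target = make_target(0.0)
        i = int(np.flatnonzero(target.times == 25.0)[0])
        assert target.X_rwd[i] == pytest.approx(5.0)

    def test_lagged_midpoint_shifts_with_lag(self):
        target = make_target(-100.0)
        i = int(np.flatnonzero(target.times == -75.0)[0])
        assert target.X_rwd[i] == pytest.approx(5.0)

    def test_orthogonal_channels_are_zero(self):
        for lag in (-400.0, 0.0, 400.0):
            target = make_target(lag)
            assert np.all(target.X_dwd == 0.0)
            assert np.all(target.Y_rwd == 0.0)

    def test_vertical_channel_falls_to_minus_amplitude(self):
        target = make_target(0.0)
        assert target.Y_dwd[-1] == pytest.approx(-10.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            make_target(0.0, sigma=0.0)


def _random_matrices(n_neurons, seed=0, include_target=None):
    rng = np.random.default_rng(seed)
    times = default_grid()
    R_rwd = rng.uniform(0, 40, (len(times), n_neurons))
    R_dwd = rng.uniform(0, 40, (len(times), n_neurons))
    if include_target is not None:
        R_rwd[:, 0] = 20.0 + include_target.X_rwd
        R_dwd[:, 0] = 20.0 + include_target.X_dwd
        R_rwd[:, 1] = 20.0 - include_target.Y_rwd
        R_dwd[:, 1] = 20.0 - include_target.Y_dwd
    return RateMatrices(times=times, R_rwd=R_rwd, R_dwd=R_dwd)


class TestFitWeights:
    def test_unregularized_interpolation_reproduces_target(self):
        target = make_target(0.0)
        R = _random_matrices(6, seed=1, include_target=target)
        w = fit_weights(R, target, gamma=0.0)
        pred = predict(R, w)
        for ch in CHANNELS:
            np.testing.assert_allclose(pred[ch], target.channel(ch), atol=1e-8)

    def test_matches_independent_ridge_solver(self):
        # closed-form check against scikit-learn on the standardized scale
        target = make_target(0.0)
        R = _random_matrices(20, seed=2)
        gamma = 30.0
        w = fit_weights(R, target, gamma=gamma)
        Z = R.stacked()
        xm, xs = Z.mean(0), Z.std(0, ddof=1)
        Zs = (Z - xm) / xs
        for channel, beta, c in (("X", w.beta_X, w.c_X), ("Y", w.beta_Y, w.c_Y)):
            y = target.stacked(channel)
            ref = Ridge(alpha=gamma, fit_intercept=True).fit(Zs, y)
            np.testing.assert_allclose(beta, ref.coef_ / xs, atol=1e-8)
            pred_ref = ref.predict(Zs)
            np.testing.assert_allclose(Z @ beta + c, pred_ref, atol=1e-8)

    def test_extreme_shrinkage_returns_training_mean(self):
        target = make_target(0.0)
        R = _random_matrices(10, seed=3)
        w = fit_weights(R, target, gamma=1e12)
        assert np.all(np.abs(w.beta_X) < 1e-6)
        pred = predict(R, w)
        assert np.allclose(pred["X_rwd"], target.stacked("X").mean(), atol=1e-3)

    def test_shrinkage_is_monotone_in_gamma(self):
        target = make_target(0.0)
        R = _random_matrices(15, seed=4)
        norms = [
            np.linalg.norm(fit_weights(R, target, gamma=gam).beta_X)
            for gam in (0.0, 1.0, 10.0, 30.0, 100.0, 1000.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_zero_variance_column_dropped_with_warning(self):
        target = make_target(0.0)
        R = _random_matrices(5, seed=5)
        R.R_rwd[:, 3] = 7.0
        R.R_dwd[:, 3] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            w = fit_weights(R, target, gamma=30.0)
        assert w.beta_X[3] == 0.0
        assert w.dropped_neurons == (3,)


class TestPredict:
    def test_zero_weights_give_constant_output(self):
        R = _random_matrices(4, seed=6)
        w = fit_weights(R, make_target(0.0), gamma=30.0)
        w.beta_X[:] = 0.0
        w.c_X = 3.0
        pred = predict(R, w)
        assert np.allclose(pred["X_rwd"], 3.0)
        assert np.allclose(pred["X_dwd"], 3.0)

    def test_same_weights_applied_to_both_directions(self):
        R = _random_matrices(4, seed=7)
        R.R_dwd = R.R_rwd.copy()
        pred = predict(R, fit_weights(R, make_target(0.0), gamma=30.0))
        np.testing.assert_array_equal(pred["X_rwd"], pred["X_dwd"])
        np.testing.assert_array_equal(pred["Y_rwd"], pred["Y_dwd"])

    def test_neuron_mismatch_rejected(self):
        R = _random_matrices(4, seed=8)
        w = fit_weights(R, make_target(0.0), gamma=30.0)
        with pytest.raises(ValueError, match="neuron mismatch"):
            predict(_random_matrices(5, seed=9), w)


def _noise_free_setup(n_trials=4):
    """Session + tensor whose per-trial rates are identical across trials."""
    times = default_grid()
    target = make_target(0.0)
    rng = np.random.default_rng(10)
    base = {d: rng.uniform(5, 30, (len(times), 8)) for d in DIRECTIONS}
    base["rightward"][:, 0] = 20.0 + target.X_rwd
    base["downward"][:, 0] = 20.0
    base["rightward"][:, 1] = 20.0
    base["downward"][:, 1] = 20.0 + target.Y_dwd
    rows, rate_list, tid = [], [], 0
    for p in range(1, 6):
        for d in DIRECTIONS:
            for _ in range(n_trials):
                rows.append((tid, p, d))
                rate_list.append(base[d])
                tid += 1
    trials = pd.DataFrame(rows, columns=["trial_id", "position_index", "direction"])
    session = synthdata.SpikeSession(
        neurons=list(range(8)),
        trials=trials,
        spikes=pd.DataFrame(
            {"trial_id": [], "neuron_id": [], "spike_time_ms": []}
        ).astype({"trial_id": int, "neuron_id": int, "spike_time_ms": float}),
        time_span=(-900.0, 900.0),
    )
    tensor = RateTensor(
        times=times,
        rates=np.stack(rate_list),
        trials=trials,
        window_ms=50.0,
        step_ms=25.0,
    )
    return session, tensor, target


class TestCrossValidate:
    def test_same_seed_reproduces_decoding(self):
        session, tensor, target = _noise_free_setup()
        a = cross_validate(session, target, n_sets=2, seed=3, tensor=tensor)
        b = cross_validate(session, target, n_sets=2, seed=3, tensor=tensor)
        for ch in CHANNELS:
            np.testing.assert_array_equal(a.mean[ch], b.mean[ch])

    def test_noise_free_rates_have_zero_spread(self):
        session, tensor, target = _noise_free_setup()
        dec = cross_validate(session, target, n_sets=5, seed=1, tensor=tensor)
        for ch in CHANNELS:
            assert np.all(dec.sd[ch] < 1e-8)

    def test_grid_mismatch_rejected(self):
        session, tensor, _ = _noise_free_setup()
        target = make_target(0.0, times=np.arange(-100.0, 101.0, 25.0))
        with pytest.raises(ValueError, match="grid"):
            cross_validate(session, target, n_sets=1, seed=0, tensor=tensor)

    def test_weight_stacks_recorded(self):
        session, tensor, target = _noise_free_setup()
        dec = cross_validate(session, target, n_sets=3, seed=2, tensor=tensor)
        assert dec.beta_X.shape == (3, 8)
        assert dec.beta_Y.shape == (3, 8)


def _decoded_from(target, override=None):
    mean = {ch: target.channel(ch).copy() for ch in CHANNELS}
    if override:
        mean.update(override)
    sd = {ch: np.zeros_like(target.times) for ch in CHANNELS}
    return DecodedEPS(times=target.times, mean=mean, sd=sd, n_sets=1)


class TestRSquared:
    def test_perfect_prediction_gives_one(self):
        target = make_target(0.0)
        assert r_squared(_decoded_from(target), target) == pytest.approx(1.0)

    def test_pooled_mean_prediction_gives_zero(self):
        target = make_target(0.0)
        pooled = np.concatenate([target.channel(ch) for ch in CHANNELS]).mean()
        decoded = _decoded_from(
            target, {ch: np.full_like(target.times, pooled) for ch in CHANNELS}
        )
        assert r_squared(decoded, target) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy_value(self):
        # single active channel [0,0,10,10] decoded as [0,0,5,10]:
        # SSE = 25; pooled mean over 16 values = 1.25; SST = 175
        times = np.arange(4, dtype=float)
        zeros = np.zeros(4)
        target = TargetEPS(
            lag=0.0,
            times=times,
            X_rwd=np.array([0.0, 0.0, 10.0, 10.0]),
            X_dwd=zeros.copy(),
            Y_rwd=zeros.copy(),
            Y_dwd=zeros.copy(),
            mu=1.5,
            sigma=0.5,
            amplitude=10.0,
        )
        decoded = _decoded_from(target, {"X_rwd": np.array([0.0, 0.0, 5.0, 10.0])})
        assert r_squared(decoded, target) == pytest.approx(1.0 - 25.0 / 175.0)

    def test_perisaccadic_window_centered_on_target_transition(self):
        target = make_target(200.0)  # transition at 225 ms
        decoded = _decoded_from(target)
        decoded.mean["X_rwd"] = decoded.mean["X_rwd"].copy()
        # corrupt far outside the window; peri R^2 must stay perfect
        decoded.mean["X_rwd"][target.times < 0.0] += 50.0
        assert r_squared(decoded, target, window="perisaccadic") == pytest.approx(1.0)
        assert r_squared(decoded, target, window="full") < 0.5

    def test_zero_variance_target_signalled(self):
        target = make_target(0.0)
        flat = TargetEPS(
            lag=0.0,
            times=target.times,
            X_rwd=np.zeros_like(target.times),
            X_dwd=np.zeros_like(target.times),
            Y_rwd=np.zeros_like(target.times),
            Y_dwd=np.zeros_like(target.times),
            mu=25.0,
            sigma=10.0,
            amplitude=0.0,
        )
        with pytest.raises(ZeroVarianceError):
            r_squared(_decoded_from(flat), flat)


class TestFixationOnlyMask:
    def test_zero_exclusion_keeps_every_row(self):
        times = default_grid()
        assert fixation_only_mask(times, exclusion=0.0).all()

    def test_default_exclusion_removes_perisaccadic_rows(self):
        times = default_grid()
        mask = fixation_only_mask(times, exclusion=100.0)
        removed = times[~mask]
        assert removed.min() == -75.0
        assert removed.max() == 125.0


class TestTargetCorrelation:
    def test_nine_default_lags_give_36_pairs(self):
        tc = target_correlation()
        assert tc.n_pairs == 36
        assert tc.matrix.shape == (9, 9)

    def test_adjacent_lags_more_similar_than_extremes(self):
        tc = target_correlation()
        r_adjacent = tc.matrix[4, 5]  # lags 0 and +100
        r_extreme = tc.matrix[0, 8]  # lags -400 and +400
        assert r_adjacent > r_extreme

    def test_identical_lags_would_correlate_perfectly(self):
        tc = target_correlation(lags=[0.0, 0.0])
        assert tc.matrix[0, 1] == pytest.approx(1.0)
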