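"""Behavioral decoding, mixed models, rhythm coupling, state contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neurocomm.cca import SharedLocalSeries
from neurocomm.decode import (
    FeatureMatrix,
    build_features,
    compare_mixed_models,
    compute_idphi,
    evaluate_decoding,
    fit_behavior_glm,
    rhythm_coupling_over_epochs,
    state_density_contrast,
)
from neurocomm.windows import WindowSet


def _sl(T=2000, k=12, seed=0):
    rng = np.random.default_rng(seed)
    return SharedLocalSeries(
        aligned=rng.normal(size=(T, k)),
        local=rng.normal(size=(T, k)),
        times=np.arange(T) * 0.05,
    )


class TestBuildFeatures:
    def test_column_layout(self):
        fm = build_features(_sl(), k=10)
        assert fm.values.shape == (2000, 20)
        assert fm.names[0] == "aligned_1" and fm.names[10] == "local_1"
        assert fm.aligned_cols == list(range(10))
        assert fm.local_cols == list(range(10, 20))

    def test_values_match_source_series(self):
        sl = _sl()
        fm = build_features(sl, k=10)
        assert np.array_equal(fm.values[:, :10], sl.aligned[:, :10])
        assert np.array_equal(fm.values[:, 10:], sl.local[:, :10])

    def test_too_few_components_errors(self):
        with pytest.raises(ValueError):
            build_features(_sl(k=5), k=10)


class TestGlmFits:
    def test_noiseless_linear_position_high_r2(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 6))
        y = X @ rng.normal(size=6) + 2.0
        fit = fit_behavior_glm(X, y, family="robust_t", seed=0)
        assert fit.heldout_metric >= 0.95

    def test_null_labels_near_prevalence_baseline(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4000, 5))
        y = (rng.random(4000) < 0.5).astype(float)
        fit = fit_behavior_glm(X, y, family="bernoulli", seed=0)
        # cannot beat the prevalence (always-positive) baseline F1 = 2p/(1+p)
        p = y.mean()
        assert fit.heldout_metric <= 2 * p / (1 + p) + 0.1

    def test_separable_binary_perfect_heldout(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 3))
        y = (X[:, 0] > 0).astype(float)
        fit = fit_behavior_glm(X, y, family="bernoulli", seed=0)
        assert fit.heldout_metric == pytest.approx(1.0, abs=0.01)

    def test_gaussian_matches_statsmodels_irls_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.3 * rng.normal(size=500)
        fit = fit_behavior_glm(X, y, family="gaussian", train_bins=400, seed=0)
        Xd = sm.add_constant(X[fit.train_idx])
        oracle = sm.GLM(y[fit.train_idx], Xd).fit()
        assert np.max(np.abs(fit.coef - oracle.params)) < 1e-6

    def test_bernoulli_matches_statsmodels_irls_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 3))
        p = 1 / (1 + np.exp(-(X @ np.array([0.8, -0.5, 0.2]))))
        y = (rng.random(2000) < p).astype(float)
        fit = fit_behavior_glm(X, y, family="bernoulli", train_bins=1500, seed=0)
        Xd = sm.add_constant(X[fit.train_idx])
        oracle = sm.GLM(y[fit.train_idx], Xd, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coef - oracle.params)) < 1e-5

    def test_robust_t_downweights_outliers_vs_ols(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3000, 2))
        beta = np.array([1.0, -1.0])
        y = X @ beta + 0.1 * rng.normal(size=3000)
        out = rng.choice(3000, 150, replace=False)
        y[out] += rng.choice([-30, 30], 150)
        fit_t = fit_behavior_glm(X, y, family="robust_t", train_bins=2500, seed=0)
        fit_g = fit_behavior_glm(X, y, family="gaussian", train_bins=2500, seed=0)
        err_t = np.abs(fit_t.coef[1:] - beta).max()
        err_g = np.abs(fit_g.coef[1:] - beta).max()
        assert err_t < err_g

    def test_mcmc_sampler_not_available(self):
        with pytest.raises(NotImplementedError):
            fit_behavior_glm(np.zeros((10, 2)), np.zeros(10), sampler="mcmc")

    def test_shuffled_features_never_beat_intact(self):
        """Median held-out R² over shuffles stays below the intact fit."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(3000, 4))
        y = X @ np.array([1.0, 0.5, -0.5, 0.2]) + 0.5 * rng.normal(size=3000)
        intact = fit_behavior_glm(X, y, family="gaussian", seed=0).heldout_metric
        shuffled = []
        for s in range(10):
            Xs = X[np.random.default_rng(s).permutation(3000)]
            shuffled.append(
                fit_behavior_glm(Xs, y, family="gaussian", seed=0).heldout_metric
            )
        assert np.median(shuffled) < intact


class TestEvaluateDecoding:
    def _features_behavior(self, planted="aligned", T=6000, seed=0):
        rng = np.random.default_rng(seed)
        aligned = rng.normal(size=(T, 10))
        local = rng.normal(size=(T, 10))
        times = np.arange(T) * 0.05
        pos = (np.sin(times / 20.0) + 1) / 2
        src = aligned if planted == "aligned" else local
        src[:, 0] = 2.0 * (pos - pos.mean()) + 0.05 * rng.normal(size=T)
        fm = FeatureMatrix(
            values=np.hstack([aligned, local]),
            names=[f"aligned_{i+1}" for i in range(10)] + [f"local_{i+1}" for i in range(10)],
            times=times,
        )
        beh = pd.DataFrame({"time": times, "lin_pos": pos})
        return fm, beh

    def test_aligned_planted_dissociation(self):
        fm, beh = self._features_behavior("aligned")
        out = evaluate_decoding(fm, beh, behaviors=["lin_pos"], seed=0)
        row = out.iloc[0]
        assert row["aligned_metric"] >= 0.5
        assert row["local_metric"] <= 0.1
        assert row["coef_ratio"] > 1.0

    def test_local_planted_reverses(self):
        fm, beh = self._features_behavior("local")
        out = evaluate_decoding(fm, beh, behaviors=["lin_pos"], seed=0)
        row = out.iloc[0]
        assert row["local_metric"] >= 0.5
        assert row["aligned_metric"] <= 0.1
        assert row["coef_ratio"] < 1.0

    def test_identical_feature_blocks_ratio_one(self):
        rng = np.random.default_rng(8)
        block = rng.normal(size=(3000, 10))
        times = np.arange(3000) * 0.05
        fm = FeatureMatrix(
            values=np.hstack([block, block]),
            names=[f"aligned_{i+1}" for i in range(10)] + [f"local_{i+1}" for i in range(10)],
            times=times,
        )
        y = block @ rng.normal(size=10)
        beh = pd.DataFrame({"time": times, "lin_pos": y})
        out = evaluate_decoding(fm, beh, behaviors=["lin_pos"], seed=0)
        # duplicated blocks split the coefficients evenly
        assert out.iloc[0]["coef_ratio"] == pytest.approx(1.0, abs=0.05)


class TestMixedModels:
    def _data(self, kind, T=2000, seed=0):
        rng = np.random.default_rng(seed)
        b = rng.normal(size=T)
        theta = rng.normal(size=T)
        noise = 0.3 * rng.normal(size=T)
        if kind == "behavior":
            r = 2.0 * b + noise
        elif kind == "interaction":
            r = b + theta + 1.5 * b * theta + noise
        else:
            r = noise
        return r, b, theta

    def test_behavior_response_prefers_behavior_model(self):
        wins = 0
        for s in range(20):
            r, b, theta = self._data("behavior", seed=s)
            out = compare_mixed_models(r, b, theta)
            aic = out.set_index("model")["aic"]
            wins += aic["R~B"] <= aic["R~theta"]
        assert wins >= 18

    def test_nested_training_r2_ordering(self):
        for s in range(5):
            r, b, theta = self._data("interaction", seed=s)
            out = compare_mixed_models(r, b, theta).set_index("model")["r2"]
            assert out["R~B*theta"] >= out["R~B+theta"] - 1e-12
            assert out["R~B+theta"] >= out["R~B"] - 1e-12

    def test_interaction_response_prefers_interaction_model(self):
        wins = 0
        for s in range(20):
            r, b, theta = self._data("interaction", seed=s)
            out = compare_mixed_models(r, b, theta).set_index("model")["aic"]
            wins += out["R~B*theta"] == out.min()
        assert wins >= 18

    def test_grouped_intercepts_absorb_group_offsets(self):
        rng = np.random.default_rng(9)
        groups = np.repeat([0, 1, 2, 3], 300)
        b = rng.normal(size=1200)
        theta = rng.normal(size=1200)
        r = b + theta + 5.0 * groups + 0.2 * rng.normal(size=1200)
        out = compare_mixed_models(r, b, theta, groups=groups).set_index("model")
        assert out.loc["R~B+theta|group", "aic"] < out.loc["R~B+theta", "aic"]


class TestRhythmCoupling:
    def test_exact_response_gives_r2_one(self):
        sl = _sl(T=1600, seed=10)
        epochs = np.repeat(np.arange(4), 400)
        out = rhythm_coupling_over_epochs(sl, sl.aligned[:, 0], epochs, seed=0)
        assert np.allclose(out["r2"], 1.0)

    def test_independent_noise_low_r2(self):
        sl = _sl(T=4000, seed=11)
        epochs = np.repeat(np.arange(4), 1000)
        noise = np.random.default_rng(12).normal(size=4000)
        out = rhythm_coupling_over_epochs(sl, noise, epochs, seed=0)
        assert out["r2"].mean() <= 0.05

    def test_ramping_coupling_detected_by_trend(self):
        from neurocomm import stats as ncstats

        rng = np.random.default_rng(13)
        sl = _sl(T=4800, seed=13)
        epochs = np.repeat(np.arange(8), 600)
        weight = (epochs + 1) / 8.0
        response = weight * sl.aligned[:, 0] + 0.5 * rng.normal(size=4800)
        out = rhythm_coupling_over_epochs(sl, response, epochs, seed=0)
        means = out.groupby("epoch")["r2"].mean().to_numpy()
        mk = ncstats.mann_kendall(means)
        assert mk.statistic > 0 and mk.p_value < 0.05


class TestStateDensityContrast:
    def _windows(self, starts_hi, starts_lo):
        return {
            "theta": (
                WindowSet(np.asarray(starts_hi), 0.3, "theta", "high"),
                WindowSet(np.asarray(starts_lo), 0.3, "theta", "low"),
            )
        }

    def test_identical_distributions_p_near_one(self):
        sl = _sl(T=1000, seed=14)
        ws = self._windows(np.arange(0.0, 15.0, 0.6), np.arange(0.3, 15.0, 0.6))
        out = state_density_contrast(sl, ws, n_perm=500, seed=0)
        assert (out["p_value"] > 0.1).all()

    def test_shifted_high_windows_significant(self):
        sl = _sl(T=2000, seed=15)
        hi = WindowSet(np.arange(0.0, 60.0, 0.6), 0.3, "theta", "high")
        lo = WindowSet(np.arange(0.3, 60.0, 0.6), 0.3, "theta", "low")
        bin_t = sl.times
        mask = np.zeros(bin_t.size, dtype=bool)
        for s0, s1 in hi.intervals():
            mask |= (bin_t >= s0) & (bin_t < s1)
        sl.aligned[mask, 0] += 1.0
        out = state_density_contrast(sl, {"theta": (hi, lo)}, n_perm=3000, seed=0)
        aligned_row = out[out.axis == "aligned"].iloc[0]
        assert aligned_row["n_high"] >= 100
        assert aligned_row["p_value"] < 0.001

    def test_permutation_matches_exhaustive_enumeration_tiny_n(self):
        from neurocomm import stats as ncstats

        a = np.array([0.3, 1.2, 0.8, 1.9])
        b = np.array([0.1, -0.4, 0.6, -0.2])
        res = ncstats.permutation_test_means(a, b, n_perm=20_000, seed=1)
        pooled = np.concatenate([a, b])
        d_obs = a.mean() - b.mean()
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            sel = np.zeros(8, dtype=bool)
            sel[list(idx)] = True
            d = pooled[sel].mean() - pooled[~sel].mean()
            total += 1
            count += abs(d) >= abs(d_obs) - 1e-12
        assert res.p_value == pytest.approx(count / total, abs=0.02)


def test_idphi_elevated_during_turning():
    fs = 30.0
    t = np.arange(0, 20.0, 1 / fs)
    # straight run then a tight spiral (continuous heading change)
    x = np.where(t < 10, t, np.cos(6 * (t - 10)))
    y = np.where(t < 10, 0.01 * t, np.sin(6 * (t - 10)))
    idphi = compute_idphi(x, y, fs)
    straight = idphi[(t > 2) & (t < 8)].mean()
    turning = idphi[(t > 12) & (t < 18)].mean()
    assert turning > 5 * straight
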