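"""Multitaper coherence, WPLI, normalization and learning-trend analytics."""

import numpy as np
import pandas as pd
import pytest

from neurocomm import stats as ncstats
from neurocomm.coherence import (
    SpectralSeries,
    epoch_trend,
    multitaper_coherence,
    multitaper_power,
    normalize_spectral,
    power_coherence_stats,
    spatial_binned_coherence,
    wpli,
)
from neurocomm.preprocess import LfpTrace

FS = 1000.0


def _trace(samples, region="CA1"):
    return LfpTrace(samples=np.asarray(samples, float), fs_hz=FS, region=region)


def _noise(n, seed):
    return np.random.default_rng(seed).normal(size=n)


class TestMultitaperCoherence:
    def test_identical_signals_coherence_one(self):
        x = _trace(_noise(int(20 * FS), 0))
        coh = multitaper_coherence(x, _trace(x.samples.copy(), "PFC"))
        assert np.nanmax(np.abs(coh.values - 1.0)) < 1e-10

    def test_shared_tone_peaks_at_tone_frequency(self):
        n = int(60 * FS)
        t = np.arange(n) / FS
        tone = np.sin(2 * np.pi * 8 * t)
        x = _trace(tone + 0.8 * _noise(n, 1))
        y = _trace(tone + 0.8 * _noise(n, 2), "PFC")
        coh = multitaper_coherence(x, y)
        mean = np.nanmean(coh.values, axis=0)
        at8 = mean[np.argmin(np.abs(coh.frequencies - 8.0))]
        at20 = mean[np.argmin(np.abs(coh.frequencies - 20.0))]
        assert at8 > at20 + 0.3

    def test_independent_noise_below_bias_floor(self):
        x = _trace(_noise(int(120 * FS), 3))
        y = _trace(_noise(int(120 * FS), 4), "PFC")
        coh = multitaper_coherence(x, y, n_tapers=5)
        assert np.nanmean(coh.values) < 1.0 / 5 + 0.05

    def test_symmetry_and_scale_invariance(self):
        n = int(30 * FS)
        x = _trace(_noise(n, 5))
        y = _trace(0.5 * _noise(n, 6) + 0.5 * x.samples, "PFC")
        c_xy = multitaper_coherence(x, y).values
        c_yx = multitaper_coherence(y, x).values
        assert np.nanmax(np.abs(c_xy - c_yx)) < 1e-10
        y_scaled = _trace(7.3 * y.samples, "PFC")
        c_scaled = multitaper_coherence(x, y_scaled).values
        assert np.nanmax(np.abs(c_xy - c_scaled)) < 1e-10

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            multitaper_coherence(_trace(np.zeros(2000)), _trace(np.zeros(3000), "PFC"))


class TestWpli:
    def test_constant_quarter_cycle_lag_gives_one(self):
        n = int(30 * FS)
        t = np.arange(n) / FS
        x = _trace(np.sin(2 * np.pi * 8 * t))
        y = _trace(np.sin(2 * np.pi * 8 * t - np.pi / 2), "PFC")
        res = wpli(x, y, band=(6, 12))
        at8 = res.values[np.argmin(np.abs(res.frequencies - 8.0))]
        assert at8 == pytest.approx(1.0, abs=1e-6)

    def test_balanced_lead_lag_cancels(self):
        # half the windows lead, half lag by the same amount: WPLI -> 0
        win = int(FS)
        t = np.arange(win) / FS
        segs = []
        for i in range(40):
            lag = np.pi / 2 if i % 2 == 0 else -np.pi / 2
            segs.append((np.sin(2 * np.pi * 8 * t), np.sin(2 * np.pi * 8 * t - lag)))
        x = _trace(np.concatenate([a for a, _ in segs]))
        y = _trace(np.concatenate([b for _, b in segs]), "PFC")
        res = wpli(x, y, band=(6, 12))
        at8 = res.values[np.argmin(np.abs(res.frequencies - 8.0))]
        assert at8 == pytest.approx(0.0, abs=1e-6)

    def test_independent_noise_near_zero(self):
        x = _trace(_noise(100_000, 7))
        y = _trace(_noise(100_000, 8), "PFC")
        res = wpli(x, y, band=(6, 12))
        assert np.nanmean(res.values) <= 0.15
        assert np.nanmedian(res.values) <= 0.12

    def test_zero_lag_common_signal_discounted(self):
        """A purely real cross-spectral contribution does not raise WPLI."""
        n = int(40 * FS)
        t = np.arange(n) / FS
        common = np.sin(2 * np.pi * 8 * t)
        x = _trace(common + 0.5 * _noise(n, 9))
        y = _trace(common + 0.5 * _noise(n, 10), "PFC")
        res = wpli(x, y, band=(6, 12))
        at8 = res.values[np.argmin(np.abs(res.frequencies - 8.0))]
        assert at8 < 0.3  # strong zero-lag coupling, no consistent lag


class TestNormalization:
    def _tidy(self):
        rng = np.random.default_rng(11)
        rows = []
        for animal, offset in (("a", 0.0), ("b", 5.0)):
            for f in (7.0, 8.0):
                vals = rng.normal(size=50) + offset + np.linspace(0, 1, 50)
                for i, v in enumerate(vals):
                    rows.append(
                        {"animal": animal, "frequency": f, "time": float(i), "value": v}
                    )
        return pd.DataFrame(rows)

    def test_zscore_zero_mean_per_group(self):
        out = normalize_spectral(self._tidy(), "zscore")
        g = out.groupby(["animal", "frequency"])["value"].mean()
        assert np.max(np.abs(g.to_numpy())) < 1e-10

    def test_minmax_extremes_per_group(self):
        out = normalize_spectral(self._tidy(), "minmax")
        g = out.groupby(["animal", "frequency"])["value"]
        assert np.allclose(g.min().to_numpy(), 0.0)
        assert np.allclose(g.max().to_numpy(), 1.0)

    def test_offset_animals_collapse_to_same_trend(self):
        df = self._tidy()
        # identical trends, different offsets by construction below
        base = np.linspace(0, 1, 50)
        rows = []
        for animal, offset in (("a", 0.0), ("b", 5.0)):
            for i, v in enumerate(base + offset):
                rows.append({"animal": animal, "frequency": 8.0, "time": float(i), "value": v})
        out = normalize_spectral(pd.DataFrame(rows), "minmax")
        a = out[out.animal == "a"].sort_values("time")["value"].to_numpy()
        b = out[out.animal == "b"].sort_values("time")["value"].to_numpy()
        assert np.allclose(a, b)

    def test_constant_series_minmax_flagged_nan(self):
        df = pd.DataFrame(
            {"animal": "a", "frequency": 8.0, "time": [0.0, 1.0], "value": [2.0, 2.0]}
        )
        out = normalize_spectral(df, "minmax")
        assert out["value"].isna().all()


class TestEpochTrend:
    def _df(self, slope=0.0, noise=0.0, seed=0, n_epochs=8, n_per=40):
        rng = np.random.default_rng(seed)
        rows = []
        for animal in ("a", "b", "c"):
            for ep in range(n_epochs):
                vals = 1.0 + slope * ep + noise * rng.normal(size=n_per)
                rows += [{"animal": animal, "epoch": ep, "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_identical_values_zero_width_ci(self):
        out = epoch_trend(self._df(), n_boot=100, seed=0)
        assert np.allclose(out["cis"][:, 0], out["cis"][:, 1])
        assert out["mann_kendall"].statistic == 0.0

    def test_planted_decline_detected(self):
        out = epoch_trend(self._df(slope=-0.1, noise=0.02, seed=1), n_boot=200, seed=0)
        mk = out["mann_kendall"]
        assert mk.statistic < 0 and mk.p_value < 0.05

    def test_bootstrap_seeded(self):
        df = self._df(slope=-0.05, noise=0.1, seed=2)
        o1 = epoch_trend(df, n_boot=100, seed=3)
        o2 = epoch_trend(df, n_boot=100, seed=3)
        assert np.array_equal(o1["cis"], o2["cis"])


class TestSpatialBinning:
    def _coh_and_behavior(self, f):
        n_windows = 400
        times = np.arange(n_windows) + 0.5
        lin = np.tile(np.linspace(0, 1, 40), 10)
        beh = pd.DataFrame(
            {
                "time": times,
                "lin_pos": lin,
                "outbound": np.ones(n_windows, dtype=bool),
                "epoch": np.zeros(n_windows, dtype=int),
            }
        )
        vals = f(lin)[:, None] * np.ones((1, 3))
        coh = SpectralSeries(
            frequencies=np.array([7.0, 8.0, 9.0]),
            times=times,
            values=vals,
            method="multitaper",
            params={"window_s": 1.0},
        )
        return coh, beh

    def test_constant_coherence_flat_zscored_curves(self):
        coh, beh = self._coh_and_behavior(lambda p: np.ones_like(p))
        out = spatial_binned_coherence(coh, beh, n_bins=10, n_boot=50)
        assert np.allclose(out["mean"], 0.0)

    def test_center_arm_peak_localized(self):
        coh, beh = self._coh_and_behavior(lambda p: np.where(p < 0.3, 2.0, 0.0))
        out = spatial_binned_coherence(coh, beh, n_bins=10, n_boot=50)
        peak_bin = out.loc[out["mean"].idxmax(), "pos_center"]
        assert peak_bin < 0.3

    def test_bin_occupancy_matches_histogram(self):
        coh, beh = self._coh_and_behavior(lambda p: p)
        out = spatial_binned_coherence(coh, beh, n_bins=10, n_boot=10)
        edges = np.linspace(0, 1, 11)
        hist, _ = np.histogram(beh["lin_pos"], bins=edges)
        got = out.sort_values("pos_bin")["n"].to_numpy()
        assert np.array_equal(got, hist[hist > 0])


class TestPowerCoherenceStats:
    def _tidy(self, values_by_animal):
        rows = []
        for animal, vals in values_by_animal.items():
            for i, v in enumerate(vals):
                rows.append({"animal": animal, "time": float(i), "value": v})
        return pd.DataFrame(rows)

    def test_identical_inputs_equal_correlations(self):
        rng = np.random.default_rng(13)
        series = {a: rng.normal(size=100) for a in "abcd"}
        df = self._tidy(series)
        out = power_coherence_stats(df, df.copy(), df.copy())
        pp = np.array(list(out["r_power_power"].values()))
        pc = np.array(list(out["r_power_coherence"].values()))
        assert np.allclose(pp, pc)
        assert out["wilcoxon"] is None  # no paired differences to test

    def test_common_drive_beats_independent_coherence(self):
        rng = np.random.default_rng(14)
        pcs = {}
        pps = {}
        ca1, pfc, coh = {}, {}, {}
        for a in "abcde":
            drive = rng.normal(size=300)
            ca1[a] = drive + 0.3 * rng.normal(size=300)
            pfc[a] = drive + 0.3 * rng.normal(size=300)
            coh[a] = rng.normal(size=300)
        out = power_coherence_stats(self._tidy(ca1), self._tidy(pfc), self._tidy(coh))
        pp = np.array(list(out["r_power_power"].values()))
        pc = np.array(list(out["r_power_coherence"].values()))
        assert pp.mean() > pc.mean() + 0.5
        assert out["wilcoxon"].p_value < 0.1

    def test_single_peak_spectrum_peak_extraction(self):
        freqs = np.arange(4.0, 13.0)
        rows = []
        for a in "ab":
            for f in freqs:
                rows.append(
                    {"animal": a, "time": 0.0, "frequency": f, "value": -((f - 8.0) ** 2)}
                )
        df = pd.DataFrame(rows)
        out = power_coherence_stats(df, df.copy(), df.copy())
        for peaks in out["peak_frequencies"]:
            assert np.allclose(peaks, 8.0)


def test_multitaper_power_same_grid_as_coherence():
    x = _trace(_noise(int(10 * FS), 20))
    p = multitaper_power(x, fmax=50.0)
    c = multitaper_coherence(x, _trace(_noise(int(10 * FS), 21), "PFC"), fmax=50.0)
    assert np.array_equal(p.frequencies, c.frequencies)
    assert np.array_equal(p.times, c.times)
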