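"""Multitaper coherence and weighted phase lag index between regional LFPs.

Coherence is estimated in sliding windows (default 1 s, time–bandwidth 3,
5 DPSS tapers), giving a time × frequency magnitude-squared coherence in
[0, 1].  WPLI summarizes phase-lag consistency across windows while
discounting zero-lag (volume-conducted) coupling:
WPLI(f) = |E[Im S_xy]| / E[|Im S_xy|].

Learning-trend utilities normalize per animal (z-score within frequency
band, or min–max per frequency), bootstrap epoch means with equal samples
per animal, and test monotone trends with Mann–Kendall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal.windows import dpss

from . import stats as ncstats
from .preprocess import LfpTrace


@dataclass
class SpectralSeries:
    """Time–frequency coherence-type values with method provenance."""

    frequencies: np.ndarray  # Hz
    times: np.ndarray  # window centers (s); empty for window-pooled measures
    values: np.ndarray  # (n_times × n_freqs) or (n_freqs,) for pooled
    method: str  # "multitaper" | "wpli"
    params: dict = field(default_factory=dict)

    def band_mean(self, band: tuple[float, float]) -> np.ndarray:
        sel = (self.frequencies >= band[0]) & (self.frequencies <= band[1])
        return np.nanmean(self.values[..., sel], axis=-1)


def _tapered_ffts(x: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """FFT of each taper applied to one window: (n_tapers, n_freqs)."""
    return np.fft.rfft(tapers * x[None, :], axis=1)


def _window_slices(n: int, win: int, step: int):
    starts = range(0, n - win + 1, step)
    return [(s, s + win) for s in starts]


def multitaper_coherence(
    x: LfpTrace,
    y: LfpTrace,
    window_s: float = 1.0,
    nw: float = 3.0,
    n_tapers: int = 5,
    step_s: float | None = None,
    fmax: float | None = None,
) -> SpectralSeries:
    """Sliding-window multitaper magnitude-squared coherence.

    Cross/auto spectra are averaged across tapers within each window;
    coherence per window is |S_xy|² / (S_xx S_yy).
    """
    if x.fs_hz != y.fs_hz:
        raise ValueError("sample rates must match")
    if x.samples.size != y.samples.size:
        raise ValueError("traces must have equal lengths")
    fs = x.fs_hz
    win = int(round(window_s * fs))
    step = win if step_s is None else max(1, int(round(step_s * fs)))
    tapers = dpss(win, nw, n_tapers)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    fsel = slice(None) if fmax is None else freqs <= fmax
    freqs_out = freqs[fsel]
    slices = _window_slices(x.samples.size, win, step)
    if not slices:
        raise ValueError("trace shorter than one window")
    coh = np.empty((len(slices), freqs_out.size))
    times = np.empty(len(slices))
    for i, (s0, s1) in enumerate(slices):
        fx = _tapered_ffts(x.samples[s0:s1], tapers)[:, fsel]
        fy = _tapered_ffts(y.samples[s0:s1], tapers)[:, fsel]
        sxx = np.mean(np.abs(fx) ** 2, axis=0)
        syy = np.mean(np.abs(fy) ** 2, axis=0)
        sxy = np.mean(fx * np.conj(fy), axis=0)
        denom = sxx * syy
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.abs(sxy) ** 2 / denom
        c[denom <= 0] = np.nan
        coh[i] = np.clip(c, 0.0, 1.0)
        times[i] = x.t0 + (s0 + s1) / 2.0 / fs
    return SpectralSeries(
        frequencies=freqs_out,
        times=times,
        values=coh,
        method="multitaper",
        params={"window_s": window_s, "nw": nw, "n_tapers": n_tapers},
    )


def multitaper_power(x: LfpTrace, window_s: float = 1.0, nw: float = 3.0,
                     n_tapers: int = 5, step_s: float | None = None,
                     fmax: float | None = None) -> SpectralSeries:
    """Sliding-window multitaper power spectral estimate (same grid as coherence)."""
    fs = x.fs_hz
    win = int(round(window_s * fs))
    step = win if step_s is None else max(1, int(round(step_s * fs)))
    tapers = dpss(win, nw, n_tapers)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    fsel = slice(None) if fmax is None else freqs <= fmax
    freqs_out = freqs[fsel]
    slices = _window_slices(x.samples.size, win, step)
    out = np.empty((len(slices), freqs_out.size))
    times = np.empty(len(slices))
    for i, (s0, s1) in enumerate(slices):
        fx = _tapered_ffts(x.samples[s0:s1], tapers)[:, fsel]
        out[i] = np.mean(np.abs(fx) ** 2, axis=0)
        times[i] = x.t0 + (s0 + s1) / 2.0 / fs
    return SpectralSeries(freqs_out, times, out, "multitaper-power",
                          {"window_s": window_s, "nw": nw, "n_tapers": n_tapers})


def wpli(
    x: LfpTrace,
    y: LfpTrace,
    band: tuple[float, float] = (6.0, 12.0),
    window_s: float = 1.0,
    debias: bool = False,
) -> SpectralSeries:
    """Weighted phase lag index over the given band, pooled across windows.

    WPLI(f) = |E[Im S_xy(f)]| / E[|Im S_xy(f)|], expectation over 1 s
    windows (single-taper cross-spectra).  Frequencies whose imaginary
    cross-spectrum vanishes in every window are undefined and reported NaN.
    The debiased (squared) estimator is available behind ``debias``.
    """
    if x.fs_hz != y.fs_hz or x.samples.size != y.samples.size:
        raise ValueError("traces must share sample rate and length")
    fs = x.fs_hz
    win = int(round(window_s * fs))
    taper = np.hanning(win)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    slices = _window_slices(x.samples.size, win, win)
    if not slices:
        raise ValueError("trace shorter than one window")
    imag = np.empty((len(slices), int(fsel.sum())))
    for i, (s0, s1) in enumerate(slices):
        fx = np.fft.rfft(taper * x.samples[s0:s1])[fsel]
        fy = np.fft.rfft(taper * y.samples[s0:s1])[fsel]
        imag[i] = np.imag(fx * np.conj(fy))
    num = np.abs(imag.mean(axis=0))
    den = np.abs(imag).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if debias:
            n = imag.shape[0]
            num2 = (imag.sum(0) ** 2 - (imag**2).sum(0))
            den2 = (np.abs(imag).sum(0) ** 2 - (imag**2).sum(0))
            vals = num2 / den2
        else:
            vals = num / den
    vals = np.where(den > 0, vals, np.nan)
    return SpectralSeries(
        frequencies=freqs[fsel],
        times=np.zeros(0),
        values=vals,
        method="wpli",
        params={"band": band, "window_s": window_s, "debias": debias},
    )


# ---------------------------------------------------------------------------
# Normalization and learning trends (tidy-table interfaces)


def normalize_spectral(df: pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Per-animal normalization of a tidy (animal, frequency|band, value) table.

    ``zscore``: mean 0, sd 1 per animal within each frequency band (column
    "band" if present, else per frequency); ``minmax``: scale to [0, 1] per
    animal per frequency over the animal's full dataset.  Constant groups
    are undefined under min–max and flagged NaN.
    """
    if method not in ("zscore", "minmax"):
        raise ValueError("method must be 'zscore' or 'minmax'")
    df = df.copy()
    group_col = "band" if (method == "zscore" and "band" in df.columns) else "frequency"

    def _norm(g: pd.Series) -> pd.Series:
        if method == "zscore":
            sd = g.std(ddof=0)
            if sd == 0:
                return g - g.mean()
            return (g - g.mean()) / sd
        lo, hi = g.min(), g.max()
        if hi <= lo:
            return pd.Series(np.nan, index=g.index)
        return (g - lo) / (hi - lo)

    df["value"] = df.groupby(["animal", group_col], group_keys=False)["value"].apply(_norm)
    return df


def epoch_trend(
    df: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Epoch means with balanced-bootstrap CIs and trend tests.

    ``df`` is tidy with columns (animal, epoch, value).  Per bootstrap draw,
    each animal contributes an equal-sized random time subset per epoch; the
    draw's epoch mean averages over animals.  Returns epoch means,
    percentile CIs, a Mann–Kendall trend test on the epoch means, and a
    one-way ANOVA across epochs.
    """
    rng = np.random.default_rng(seed)
    epochs = np.sort(df["epoch"].unique())
    per_epoch_groups = {}
    for ep in epochs:
        sub = df[df["epoch"] == ep]
        groups = {a: g["value"].to_numpy() for a, g in sub.groupby("animal") if len(g)}
        per_epoch_groups[ep] = groups
    means = np.empty(epochs.size)
    cis = np.empty((epochs.size, 2))
    for i, ep in enumerate(epochs):
        groups = per_epoch_groups[ep]
        point, (lo, hi), _ = ncstats.bootstrap_ci(
            groups, n_boot=n_boot, seed=rng.integers(2**31), ci=ci
        )
        means[i] = point
        cis[i] = (lo, hi)
    mk = ncstats.mann_kendall(means) if epochs.size >= 4 else None
    anova = None
    valid = [df.loc[df["epoch"] == ep, "value"].to_numpy() for ep in epochs]
    if len(valid) >= 2 and all(v.size >= 2 for v in valid):
        anova = ncstats.one_way_anova(*valid)
    return {
        "epochs": epochs,
        "means": means,
        "cis": cis,
        "mann_kendall": mk,
        "anova": anova,
    }


def spatial_binned_coherence(
    coh: SpectralSeries,
    behavior: pd.DataFrame,
    band: tuple[float, float] = (6.0, 12.0),
    n_bins: int = 20,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean z-scored band coherence per linear-distance bin.

    Spectral window centers are matched to the nearest behavior sample
    (within half a window); curves are split outbound/inbound and by epoch,
    with bootstrap CIs over the time samples in each bin.
    """
    series = coh.band_mean(band)
    sd = np.nanstd(series)
    series = (series - np.nanmean(series)) / (sd if sd > 0 else 1.0)
    beh_t = behavior["time"].to_numpy()
    idx = np.clip(np.searchsorted(beh_t, coh.times, side="right") - 1, 0, beh_t.size - 1)
    half = coh.params.get("window_s", 1.0) / 2.0
    ok = np.abs(beh_t[idx] - coh.times) <= half + 1.0 / 30.0
    rng = np.random.default_rng(seed)
    tbl = pd.DataFrame(
        {
            "value": series[ok],
            "lin_pos": behavior["lin_pos"].to_numpy()[idx[ok]],
            "outbound": behavior["outbound"].to_numpy()[idx[ok]],
            "epoch": behavior["epoch"].to_numpy()[idx[ok]],
        }
    ).dropna()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    tbl["pos_bin"] = np.clip(np.digitize(tbl["lin_pos"], edges) - 1, 0, n_bins - 1)
    rows = []
    for (ep, out, b), g in tbl.groupby(["epoch", "outbound", "pos_bin"]):
        vals = g["value"].to_numpy()
        draws = rng.choice(vals, size=(n_boot, vals.size)).mean(axis=1) if vals.size else []
        lo, hi = (np.quantile(draws, [0.025, 0.975]) if vals.size else (np.nan, np.nan))
        rows.append(
            {
                "epoch": ep,
                "outbound": out,
                "pos_bin": b,
                "pos_center": (edges[b] + edges[b + 1]) / 2,
                "mean": vals.mean() if vals.size else np.nan,
                "ci_lo": lo,
                "ci_hi": hi,
                "n": vals.size,
            }
        )
    return pd.DataFrame(rows)


def power_coherence_stats(
    power_ca1: pd.DataFrame,
    power_pfc: pd.DataFrame,
    coherence: pd.DataFrame,
) -> dict:
    """Power–power vs power–coherence correlation structure across animals.

    Inputs are tidy (animal, time, value) tables on a common time grid.
    Per animal: Pearson r of CA1 vs PFC theta power, and of CA1 power vs
    theta coherence; a Wilcoxon signed-rank across animals compares the two
    paired correlation sets.  Peak frequencies (if a "frequency" column is
    present with per-frequency values) are compared across the three inputs
    by Kruskal–Wallis.
    """
    def _per_animal(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, float]:
        out = {}
        for animal in sorted(set(a["animal"]) & set(b["animal"])):
            va = a[a["animal"] == animal].sort_values("time")["value"].to_numpy()
            vb = b[b["animal"] == animal].sort_values("time")["value"].to_numpy()
            n = min(va.size, vb.size)
            if n >= 3 and va[:n].std() > 0 and vb[:n].std() > 0:
                out[animal] = float(np.corrcoef(va[:n], vb[:n])[0, 1])
            else:
                out[animal] = 1.0 if n >= 1 and np.allclose(va[:n], vb[:n]) else np.nan
        return out

    r_pp = _per_animal(power_ca1, power_pfc)
    r_pc = _per_animal(power_ca1, coherence)
    animals = sorted(set(r_pp) & set(r_pc))
    pp = np.array([r_pp[a] for a in animals])
    pc = np.array([r_pc[a] for a in animals])
    result = {"r_power_power": r_pp, "r_power_coherence": r_pc}
    if len(animals) >= 3 and not np.allclose(pp, pc):
        result["wilcoxon"] = ncstats.wilcoxon_signed_rank(pp, pc)
    else:
        result["wilcoxon"] = None

    def _peaks(df: pd.DataFrame) -> np.ndarray:
        if "frequency" not in df.columns:
            return np.zeros(0)
        out = []
        for (animal,), g in df.groupby(["animal"]):
            prof = g.groupby("frequency")["value"].mean()
            out.append(float(prof.idxmax()))
        return np.asarray(out)

    peaks = [_peaks(power_ca1), _peaks(power_pfc), _peaks(coherence)]
    if all(p.size >= 2 for p in peaks) and len({tuple(p) for p in peaks}) > 1:
        try:
            result["kruskal_peaks"] = ncstats.kruskal_wallis(*peaks)
        except ValueError:
            result["kruskal_peaks"] = None
    else:
        result["kruskal_peaks"] = None
    result["peak_frequencies"] = peaks
    return result
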