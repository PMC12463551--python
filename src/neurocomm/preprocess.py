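"""Spike and LFP preprocessing.

Turns raw spike times and LFP traces into the containers the subspace
analyses consume: a T×N binned count matrix (50 ms bins by convention),
optionally z-scored over run-period bins, and band-filtered LFP with a
Hilbert-magnitude envelope for the delta (0.5–4 Hz), theta (6–12 Hz) and
ripple (150–250 Hz) bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

#: canonical passbands (Hz)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (6.0, 12.0),
    "ripple": (150.0, 250.0),
}

#: minimum mean rate (Hz) for a unit to be analyzed
MIN_RATE_HZ = 0.1


@dataclass
class SpikeSet:
    """Per-unit spike times with region labels."""

    spike_times: list[np.ndarray]  # seconds, each sorted ascending
    unit_ids: list[str]
    regions: list[str]  # "CA1" | "PFC" per unit

    def __post_init__(self) -> None:
        if not (len(self.spike_times) == len(self.unit_ids) == len(self.regions)):
            raise ValueError("spike_times, unit_ids, regions must align")
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        for t in self.spike_times:
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted ascending")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def units_in(self, region: str) -> list[int]:
        return [i for i, r in enumerate(self.regions) if r == region]


@dataclass
class BinnedCounts:
    """T_bins × N_units matrix of spike counts (or z-scores)."""

    counts: np.ndarray
    bin_s: float
    bin_starts: np.ndarray  # left edge of each bin (s)
    unit_ids: list[str]
    regions: list[str]
    zscored: bool = False
    zero_variance_units: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bin_s <= 0:
            raise ValueError("bin width must be positive")
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        if self.counts.shape[0] != self.bin_starts.size:
            raise ValueError("row count must equal number of bins")
        if self.counts.shape[1] != len(self.unit_ids):
            raise ValueError("column count must equal number of units")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def select_units(self, idx: Sequence[int]) -> "BinnedCounts":
        idx = list(idx)
        return replace(
            self,
            counts=self.counts[:, idx],
            unit_ids=[self.unit_ids[i] for i in idx],
            regions=[self.regions[i] for i in idx],
            zero_variance_units=(
                None
                if self.zero_variance_units is None
                else self.zero_variance_units[idx]
            ),
        )

    def region_block(self, region: str) -> "BinnedCounts":
        return self.select_units([i for i, r in enumerate(self.regions) if r == region])

    def mean_rates_hz(self) -> np.ndarray:
        if self.zscored:
            raise ValueError("rates undefined for z-scored counts")
        return self.counts.mean(axis=0) / self.bin_s


@dataclass
class LfpTrace:
    """A single region's LFP (reference-relative µV)."""

    samples: np.ndarray
    fs_hz: float
    region: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sample rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs_hz


@dataclass
class BandEnvelope:
    """Band-filtered trace plus its (non-negative) amplitude envelope."""

    band: str
    passband: tuple[float, float]
    filtered: np.ndarray
    envelope: np.ndarray
    fs_hz: float
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.envelope.size) / self.fs_hz


# ---------------------------------------------------------------------------


def bin_spikes(spikes: SpikeSet, bin_s: float, span: tuple[float, float]) -> BinnedCounts:
    """Count spikes in half-open bins [t, t+bin_s) anchored at span start.

    Spikes outside the span are dropped; the number of bins is
    floor(span / bin_s), so a trailing partial bin is discarded.
    """
    t_start, t_stop = span
    if t_stop <= t_start:
        raise ValueError("span must be a non-empty increasing interval")
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.floor((t_stop - t_start) / bin_s + 1e-9))
    edges = t_start + bin_s * np.arange(n_bins + 1)
    counts = np.zeros((n_bins, spikes.n_units))
    for j, times in enumerate(spikes.spike_times):
        if times.size == 0 or n_bins == 0:
            continue
        # np.histogram closes the last bin on the right; shave the edge spike
        in_span = times[(times >= edges[0]) & (times < edges[-1])]
        counts[:, j], _ = np.histogram(in_span, bins=edges)
    return BinnedCounts(
        counts=counts,
        bin_s=bin_s,
        bin_starts=edges[:-1],
        unit_ids=list(spikes.unit_ids),
        regions=list(spikes.regions),
    )


def filter_low_rate_units(counts: BinnedCounts, min_rate_hz: float = MIN_RATE_HZ) -> BinnedCounts:
    """Drop units firing strictly below ``min_rate_hz`` on average."""
    if counts.zscored:
        raise ValueError("rate filtering requires raw counts")
    rates = counts.mean_rates_hz()
    keep = [i for i in range(counts.n_units) if rates[i] >= min_rate_hz - 1e-12]
    if not keep:
        raise ValueError("all units fall below the minimum rate; nothing to analyze")
    return counts.select_units(keep)


def zscore_counts(counts: BinnedCounts, bins_mask: np.ndarray | None = None) -> BinnedCounts:
    """Z-score each unit using mean/sd over the masked (e.g. run-period) bins.

    Zero-variance columns are set to zero and flagged rather than erroring.
    The transform is applied to *all* bins; only the moments come from the
    masked region.
    """
    if bins_mask is None:
        bins_mask = np.ones(counts.n_bins, dtype=bool)
    bins_mask = np.asarray(bins_mask, dtype=bool)
    if bins_mask.sum() < 2:
        raise ValueError("need at least 2 masked bins to estimate moments")
    sub = counts.counts[bins_mask]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    flat = sd <= 0
    safe_sd = np.where(flat, 1.0, sd)
    z = (counts.counts - mu) / safe_sd
    z[:, flat] = 0.0
    return replace(counts, counts=z, zscored=True, zero_variance_units=flat)


def bandpass(lfp: LfpTrace, band: tuple[float, float] | str, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward–backward, order per pass)."""
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    nyq = lfp.fs_hz / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=lfp.fs_hz, output="sos")
    return signal.sosfiltfilt(sos, lfp.samples)


def band_envelope(
    filtered: np.ndarray,
    fs_hz: float,
    band: str = "",
    passband: tuple[float, float] = (0.0, 0.0),
    smooth_s: float = 0.1,
    t0: float = 0.0,
) -> BandEnvelope:
    """Amplitude envelope = |analytic signal|, boxcar-smoothed (default 100 ms)."""
    filtered = np.asarray(filtered, dtype=float)
    env = np.abs(signal.hilbert(filtered))
    if smooth_s and smooth_s > 0:
        w = max(1, int(round(smooth_s * fs_hz)))
        kernel = np.ones(w) / w
        env = np.convolve(env, kernel, mode="same")
    return BandEnvelope(
        band=band,
        passband=passband,
        filtered=filtered,
        envelope=env,
        fs_hz=fs_hz,
        t0=t0,
    )


def lfp_band_envelope(lfp: LfpTrace, band: str, smooth_s: float = 0.1) -> BandEnvelope:
    """Convenience: bandpass a trace in a named band and take its envelope."""
    filt = bandpass(lfp, band)
    return band_envelope(
        filt, lfp.fs_hz, band=band, passband=BANDS[band], smooth_s=smooth_s, t0=lfp.t0
    )
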