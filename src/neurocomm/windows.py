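"""Rhythm/state window detection and sample assembly.

A high-state window of fixed length (default 300 ms) opens at each upward
crossing of the 85th percentile of a scalar state series (band power,
coherence, or running speed); low-state windows open at downward crossings
of the 15th percentile.  Windows that overlap a window of another state set
are removed from both sets, and surviving sets are subsampled to a common
count, stratified over the recording so retained windows stay approximately
uniform in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import BinnedCounts


@dataclass
class WindowSet:
    """Equal-duration, sorted, pairwise-disjoint half-open intervals."""

    starts: np.ndarray  # seconds
    duration_s: float
    state: str  # e.g. "theta" | "ripple" | "speed"
    level: str  # "high" | "low"
    matched: bool = False

    def __post_init__(self) -> None:
        self.starts = np.sort(np.asarray(self.starts, dtype=float))
        if self.duration_s <= 0:
            raise ValueError("window duration must be positive")
        if self.starts.size > 1 and np.any(np.diff(self.starts) < self.duration_s - 1e-12):
            raise ValueError("windows within a set must be disjoint")

    @property
    def n(self) -> int:
        return self.starts.size

    @property
    def stops(self) -> np.ndarray:
        return self.starts + self.duration_s

    @property
    def label(self) -> str:
        return f"{self.state}-{self.level}"

    def intervals(self) -> np.ndarray:
        return np.column_stack([self.starts, self.stops])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"start": self.starts, "stop": self.stops, "label": self.label}
        )


def threshold_windows(
    state: np.ndarray,
    times: np.ndarray,
    high_q: float = 0.85,
    low_q: float = 0.15,
    window_s: float = 0.3,
    state_name: str = "state",
) -> tuple[WindowSet, WindowSet]:
    """Detect high/low state windows from quantile threshold crossings.

    A high window [t_c, t_c + window_s) opens at every upward crossing of
    the ``high_q`` quantile of the state distribution; low windows open at
    downward crossings of the ``low_q`` quantile.  Crossings that occur
    while a window of the same set is still open are ignored.
    """
    state = np.asarray(state, dtype=float)
    times = np.asarray(times, dtype=float)
    if state.size != times.size:
        raise ValueError("state and times must align")
    if not (0.0 < low_q < high_q < 1.0):
        raise ValueError("need 0 < low_q < high_q < 1")
    hi_thr = np.quantile(state, high_q)
    lo_thr = np.quantile(state, low_q)
    if hi_thr <= lo_thr or np.ptp(state) == 0:
        warnings.warn(f"degenerate state series for {state_name!r}: no windows")
        empty = np.zeros(0)
        return (
            WindowSet(empty, window_s, state_name, "high"),
            WindowSet(empty, window_s, state_name, "low"),
        )

    def _crossings(upward: bool, thr: float) -> np.ndarray:
        if upward:
            hit = (state[:-1] < thr) & (state[1:] >= thr)
        else:
            hit = (state[:-1] > thr) & (state[1:] <= thr)
        cand = times[1:][hit]
        keep: list[float] = []
        open_until = -np.inf
        for t in cand:
            if t >= open_until:
                keep.append(t)
                open_until = t + window_s
        return np.asarray(keep)

    high = WindowSet(_crossings(True, hi_thr), window_s, state_name, "high")
    low = WindowSet(_crossings(False, lo_thr), window_s, state_name, "low")
    return high, low


def prune_overlaps(sets: list[WindowSet]) -> list[WindowSet]:
    """Remove windows overlapping a window of a *different* set, from both sets."""
    if not sets:
        raise ValueError("need at least one WindowSet")
    doomed = [np.zeros(ws.n, dtype=bool) for ws in sets]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            if a.n == 0 or b.n == 0:
                continue
            # overlap iff a.start < b.stop and b.start < a.stop
            sa, sb = a.starts[:, None], b.starts[None, :]
            hit = (sa < sb + b.duration_s) & (sb < sa + a.duration_s)
            doomed[i] |= hit.any(axis=1)
            doomed[j] |= hit.any(axis=0)
    return [
        replace(ws, starts=ws.starts[~bad]) for ws, bad in zip(sets, doomed)
    ]


def balance_windows(
    sets: list[WindowSet],
    n_strata: int = 10,
    seed: int | np.random.Generator = 0,
    span: tuple[float, float] | None = None,
) -> list[WindowSet]:
    """Subsample every set to the global minimum count, stratified in time.

    The session span is cut into ``n_strata`` equal segments; each set's
    per-stratum quota is the target count divided evenly, with shortfalls in
    sparse strata spilled over to strata that still have windows, so the
    retained windows are as uniform over the recording as the data allow.
    """
    rng = np.random.default_rng(seed)
    for ws in sets:
        if ws.n == 0:
            raise ValueError(f"window set {ws.label!r} is empty; cannot balance")
    n_target = min(ws.n for ws in sets)
    if span is None:
        lo = min(ws.starts.min() for ws in sets)
        hi = max(ws.stops.max() for ws in sets)
    else:
        lo, hi = span
    edges = np.linspace(lo, hi, n_strata + 1)
    out = []
    for ws in sets:
        stratum = np.clip(np.searchsorted(edges, ws.starts, side="right") - 1, 0, n_strata - 1)
        pools = [np.nonzero(stratum == s)[0] for s in range(n_strata)]
        base = n_target // n_strata
        quotas = np.full(n_strata, base)
        quotas[: n_target - base * n_strata] += 1
        chosen: list[np.ndarray] = []
        deficit = 0
        # first pass: take up to quota per stratum
        leftovers = []
        for pool, quota in zip(pools, quotas):
            take = min(quota, pool.size)
            deficit += quota - take
            picked = rng.choice(pool, size=take, replace=False) if take else np.zeros(0, int)
            chosen.append(picked)
            leftovers.append(np.setdiff1d(pool, picked))
        # spillover: fill the deficit from remaining windows anywhere
        if deficit > 0:
            remaining = np.concatenate(leftovers) if leftovers else np.zeros(0, int)
            extra = rng.choice(remaining, size=deficit, replace=False)
            chosen.append(extra)
        idx = np.sort(np.concatenate(chosen).astype(int))
        out.append(replace(ws, starts=ws.starts[idx], matched=True))
    return out


def gather_samples(counts: BinnedCounts, ws: WindowSet) -> np.ndarray:
    """Stack the t_w bins of each window into an (N * t_w) × units matrix.

    Bin values are copied exactly (no resampling); windows running past the
    end of the count matrix are dropped with a warning.
    """
    ratio = ws.duration_s / counts.bin_s
    t_w = int(round(ratio))
    if abs(ratio - t_w) > 1e-6 or t_w < 1:
        raise ValueError("window duration must be a multiple of the bin width")
    if ws.n == 0:
        return np.zeros((0, counts.n_units))
    t0 = counts.bin_starts[0]
    rows = []
    dropped = 0
    for start in ws.starts:
        i0 = int(round((start - t0) / counts.bin_s))
        if i0 < 0 or i0 + t_w > counts.n_bins:
            dropped += 1
            continue
        rows.append(counts.counts[i0 : i0 + t_w])
    if dropped:
        warnings.warn(f"{dropped} window(s) extended past the data and were dropped")
    if not rows:
        return np.zeros((0, counts.n_units))
    return np.vstack(rows)
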