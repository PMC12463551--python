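"""Firing-rate mean-matched source/target unit partitions.

Dimensionality comparisons between within-region (CA1→CA1) and
across-region (CA1→PFC) predictions are only fair if the target
populations have matched sizes and firing-rate distributions.  Rates are
histogrammed into 20 equal-range bins over the pooled range, and from each
bin the minimum count across the two regions is drawn at random from each —
yielding matched target populations.  Partitioning is repeated (default 50
times) and held fixed across window conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import BinnedCounts


@dataclass
class Partition:
    """One source/target unit split (unit indices into the parent matrix)."""

    source: list[int]  # CA1 source units
    target: list[int]
    target_region: str  # "CA1" | "PFC"
    index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target:
            raise ValueError("target population is empty")
        if self.target_region == "CA1" and set(self.source) & set(self.target):
            raise ValueError("CA1 source and CA1 target must be disjoint")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "Partition":
        return cls(**json.loads(s))


def _rate_bin_assign(rates: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign rates to equal-range bins; the top edge goes to the last bin."""
    idx = np.searchsorted(edges, rates, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def mean_match_selection(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    n_bins: int = 20,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Select index subsets of two populations with matched rate histograms.

    Bin edges span the pooled min–max range in ``n_bins`` equal widths; from
    each bin, min(count_a, count_b) units are drawn uniformly without
    replacement from each population.  Returns (idx_a, idx_b).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    if rates_a.size == 0 or rates_b.size == 0:
        raise ValueError("both populations must be non-empty")
    pooled = np.concatenate([rates_a, rates_b])
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    bins_a = _rate_bin_assign(rates_a, edges)
    bins_b = _rate_bin_assign(rates_b, edges)
    sel_a: list[np.ndarray] = []
    sel_b: list[np.ndarray] = []
    for b in range(n_bins):
        ia = np.nonzero(bins_a == b)[0]
        ib = np.nonzero(bins_b == b)[0]
        k = min(ia.size, ib.size)
        if k == 0:
            continue
        sel_a.append(rng.choice(ia, size=k, replace=False))
        sel_b.append(rng.choice(ib, size=k, replace=False))
    if not sel_a:
        raise ValueError("no rate bin contains units from both populations")
    return np.sort(np.concatenate(sel_a)), np.sort(np.concatenate(sel_b))


def mean_match_partition(
    rates_src: np.ndarray,
    rates_tgt: np.ndarray,
    n_bins: int = 20,
    seed: int | np.random.Generator = 0,
    target_region: str = "PFC",
    index: int = 0,
) -> Partition:
    """Single mean-matched partition between a source and a target region.

    The returned target indices refer to the *target* rate vector; the
    source is every source unit not consumed by matching (all of them when
    the target is the other region).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx_src_matched, idx_tgt_matched = mean_match_selection(
        rates_src, rates_tgt, n_bins=n_bins, rng=rng
    )
    if target_region == "CA1":
        # target drawn from the source region itself: sources are the rest
        source = sorted(set(range(len(rates_src))) - set(idx_src_matched.tolist()))
        target = idx_src_matched.tolist()
    else:
        source = list(range(len(rates_src)))
        target = idx_tgt_matched.tolist()
    return Partition(source=source, target=target, target_region=target_region, index=index)


def generate_partitions(
    counts: BinnedCounts,
    n_partitions: int = 50,
    n_bins: int = 20,
    seed: int = 0,
) -> list[Partition]:
    """Repeated mean-matched partitions for both target conditions.

    Per repetition, CA1 units are rate-matched against PFC units; the
    matched CA1 subset serves as the CA1→CA1 target (disjoint from the
    remaining CA1 sources), the matched PFC subset as the CA1→PFC target,
    and the same CA1 source set is shared by both conditions.  Target sizes
    are therefore identical across conditions within a repetition.
    """
    ca1 = counts.units_in("CA1") if hasattr(counts, "units_in") else [
        i for i, r in enumerate(counts.regions) if r == "CA1"
    ]
    pfc = [i for i, r in enumerate(counts.regions) if r == "PFC"]
    if not ca1 or not pfc:
        raise ValueError("need units in both CA1 and PFC")
    rates = counts.mean_rates_hz()
    r_ca1 = rates[ca1]
    r_pfc = rates[pfc]
    out: list[Partition] = []
    for rep in range(n_partitions):
        rng = np.random.default_rng([seed, rep])
        sel_ca1, sel_pfc = mean_match_selection(r_ca1, r_pfc, n_bins=n_bins, rng=rng)
        src = sorted(set(range(len(ca1))) - set(sel_ca1.tolist()))
        if not src:
            raise ValueError(
                "every CA1 unit was consumed by rate matching; "
                "no CA1 source units remain (need more CA1 than PFC units)"
            )
        source_units = [ca1[i] for i in src]
        out.append(
            Partition(
                source=source_units,
                target=[ca1[i] for i in sel_ca1],
                target_region="CA1",
                index=rep,
                seed=seed,
            )
        )
        out.append(
            Partition(
                source=source_units,
                target=[pfc[i] for i in sel_pfc],
                target_region="PFC",
                index=rep,
                seed=seed,
            )
        )
    return out
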