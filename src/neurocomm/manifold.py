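"""Geometry of the communication subspace across behavioral states.

Sessions (animals) are pooled into a pseudopopulation: spiking is averaged
per unique behavioral state — trajectory direction (outbound/inbound) ×
turn (left/right) × linearized-distance bin — and neurons are concatenated
across animals into a "super animal" state × neuron rate matrix.  CCA
between its CA1 and PFC column blocks yields a shared (aligned) embedding
of behavioral states; trajectory manifolds appear as closed curves whose
separation is quantified by contrasting within- vs between-manifold
distances among states sharing a linear-distance bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as ncstats
from .cca import _cca_weights, _fix_signs
from .preprocess import BinnedCounts


@dataclass
class Pseudopopulation:
    """Behavioral-state × neuron mean-rate matrix pooled across animals."""

    rates: np.ndarray  # n_states × n_neurons
    states: pd.DataFrame  # columns: outbound, turn_left, dist_bin, dist_center
    regions: list[str]  # per column
    provenance: list[str]  # per column: "animal/unit"

    def __post_init__(self) -> None:
        if self.rates.shape[0] != len(self.states):
            raise ValueError("state rows must align with rate rows")
        if self.rates.shape[1] != len(self.regions):
            raise ValueError("column metadata must align with rate columns")


@dataclass
class ManifoldEmbedding:
    """Per-state coordinates in the top shared (and local) components."""

    shared: np.ndarray  # n_states × n_components, aligned (U+V)/√2
    local: np.ndarray
    states: pd.DataFrame

    def __post_init__(self) -> None:
        if self.shared.shape[0] != len(self.states):
            raise ValueError("embedding rows must align with state labels")


def _session_state_means(
    counts: BinnedCounts, behavior: pd.DataFrame, n_distance_bins: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """State-mean firing rates (Hz) for one session."""
    beh_t = behavior["time"].to_numpy()
    idx = np.clip(
        np.searchsorted(beh_t, counts.bin_starts + counts.bin_s / 2, side="right") - 1,
        0,
        beh_t.size - 1,
    )
    on_track = behavior["trial"].to_numpy()[idx] >= 0
    lin = behavior["lin_pos"].to_numpy()[idx]
    outb = behavior["outbound"].to_numpy()[idx]
    left = behavior["turn_left"].to_numpy()[idx]
    edges = np.linspace(0.0, 1.0, n_distance_bins + 1)
    dbin = np.clip(np.digitize(lin, edges) - 1, 0, n_distance_bins - 1)

    states = []
    for outv in (True, False):
        for leftv in (True, False):
            for b in range(n_distance_bins):
                states.append((outv, leftv, b, (edges[b] + edges[b + 1]) / 2))
    state_df = pd.DataFrame(states, columns=["outbound", "turn_left", "dist_bin", "dist_center"])

    rates = np.full((len(state_df), counts.n_units), np.nan)
    for si, (outv, leftv, b, _) in enumerate(states):
        sel = on_track & (outb == outv) & (left == leftv) & (dbin == b)
        if sel.any():
            rates[si] = counts.counts[sel].mean(axis=0) / counts.bin_s

    # interpolate unoccupied distance bins along each trajectory type
    for outv in (True, False):
        for leftv in (True, False):
            rows = state_df.index[(state_df.outbound == outv) & (state_df.turn_left == leftv)].to_numpy()
            block = rates[rows]
            occupied = ~np.isnan(block[:, 0])
            if occupied.all():
                continue
            if not occupied.any():
                warnings.warn(
                    f"trajectory (outbound={outv}, left={leftv}) never occupied; zero-filled"
                )
                rates[rows] = 0.0
                continue
            xs = np.nonzero(occupied)[0]
            for c in range(block.shape[1]):
                block[:, c] = np.interp(np.arange(block.shape[0]), xs, block[xs, c])
            rates[rows] = block
    return rates, state_df


def build_pseudopopulation(
    sessions: list[tuple[BinnedCounts, pd.DataFrame]],
    n_distance_bins: int = 100,
) -> Pseudopopulation:
    """Concatenate per-session state-mean rates into a super-animal matrix.

    All sessions are binned on the identical behavioral state grid
    (direction × turn × distance bin), so columns can be concatenated as if
    simultaneously recorded.  Unoccupied states are filled by linear
    interpolation along the distance axis within trajectory type.
    """
    if not sessions:
        raise ValueError("need at least one session")
    blocks = []
    regions: list[str] = []
    provenance: list[str] = []
    state_df = None
    for ai, (counts, behavior) in enumerate(sessions):
        rates, sdf = _session_state_means(counts, behavior, n_distance_bins)
        if state_df is None:
            state_df = sdf
        blocks.append(rates)
        regions.extend(counts.regions)
        provenance.extend(f"animal{ai}/{u}" for u in counts.unit_ids)
    return Pseudopopulation(
        rates=np.hstack(blocks), states=state_df, regions=regions, provenance=provenance
    )


def embed_cca(pp: Pseudopopulation, n_components: int = 3) -> ManifoldEmbedding:
    """Super-animal CCA between CA1 and PFC blocks over behavioral states.

    Each neuron's state profile is z-scored (rate-scale invariance across
    animals), CCA is fit across states, and the embedding coordinates are
    the aligned (U+V)/√2 components; the local (U−V)/√2 coordinates are
    returned alongside for contrast analyses.
    """
    ca1 = [i for i, r in enumerate(pp.regions) if r == "CA1"]
    pfc = [i for i, r in enumerate(pp.regions) if r == "PFC"]
    if len(ca1) < n_components or len(pfc) < n_components:
        raise ValueError(f"need at least {n_components} units per region")
    def _z(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        return (M - mu) / sd
    X = _z(pp.rates[:, ca1])
    Y = _z(pp.rates[:, pfc])
    a, b, _ = _cca_weights(X, Y, n_components)
    a, b = _fix_signs(a, b, X, Y)
    u = (X - X.mean(axis=0)) @ a
    v = (Y - Y.mean(axis=0)) @ b
    s = 1.0 / np.sqrt(2.0)
    return ManifoldEmbedding(shared=(u + v) * s, local=(u - v) * s, states=pp.states.copy())


def ring_distance_contrast(
    emb: ManifoldEmbedding,
    which: str = "shared",
    manifold_col: str = "outbound",
) -> dict:
    """Within- vs between-manifold distances among states sharing a distance bin.

    A manifold is a trajectory class (default: direction, so the
    left/right turn variants are members of the same manifold).  For every
    pair of states in the same distance bin: the Euclidean embedding
    distance, labeled within-manifold when both states share the class and
    between-manifold otherwise.  Rank-sum test plus a bootstrap-free normal
    CI of the difference of means.
    """
    coords = emb.shared if which == "shared" else emb.local
    states = emb.states
    within: list[float] = []
    between: list[float] = []
    for b, grp in states.groupby("dist_bin"):
        idxs = grp.index.to_numpy()
        for i in range(len(idxs)):
            for j in range(i + 1, len(idxs)):
                a, c = idxs[i], idxs[j]
                d = float(np.linalg.norm(coords[a] - coords[c]))
                if states.loc[a, manifold_col] == states.loc[c, manifold_col]:
                    within.append(d)
                else:
                    between.append(d)
    within_a = np.asarray(within)
    between_a = np.asarray(between)
    result = {
        "within": within_a,
        "between": between_a,
        "mean_within": float(within_a.mean()) if within_a.size else np.nan,
        "mean_between": float(between_a.mean()) if between_a.size else np.nan,
    }
    if within_a.size and between_a.size:
        result["mean_diff"] = result["mean_between"] - result["mean_within"]
        se = np.sqrt(
            within_a.var(ddof=1) / max(within_a.size, 2)
            + between_a.var(ddof=1) / max(between_a.size, 2)
        )
        result["diff_ci"] = (result["mean_diff"] - 1.96 * se, result["mean_diff"] + 1.96 * se)
        if np.ptp(np.concatenate([within_a, between_a])) > 0:
            result["rank_sum"] = ncstats.rank_sum(between_a, within_a)
        else:
            result["rank_sum"] = None
    return result
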