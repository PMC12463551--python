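"""Pseudopopulation construction, super-animal CCA embedding, ring contrast."""

import numpy as np
import pandas as pd
import pytest

from neurocomm.manifold import (
    ManifoldEmbedding,
    Pseudopopulation,
    build_pseudopopulation,
    embed_cca,
    ring_distance_contrast,
)
from neurocomm.preprocess import BinnedCounts


def _session(n_ca1=8, n_pfc=6, T=4000, bin_s=0.05, seed=0, f=None):
    """Counts whose rates optionally depend on the behavioral state."""
    rng = np.random.default_rng(seed)
    times = np.arange(T) * bin_s
    n_trials = 16
    per = T // n_trials
    lin = np.zeros(T)
    outb = np.zeros(T, dtype=bool)
    left = np.zeros(T, dtype=bool)
    trial = np.zeros(T, dtype=int)
    for k in range(n_trials):
        sl = slice(k * per, (k + 1) * per)
        ramp = np.linspace(0, 1, per)
        is_out = k % 2 == 0
        lin[sl] = ramp if is_out else 1 - ramp
        outb[sl] = is_out
        left[sl] = (k // 2) % 2 == 0
        trial[sl] = k
    beh = pd.DataFrame(
        {
            "time": times + bin_s / 2,
            "lin_pos": lin,
            "outbound": outb,
            "turn_left": left,
            "trial": trial,
            "epoch": 0,
        }
    )
    n = n_ca1 + n_pfc
    base = rng.uniform(1.0, 4.0, n)
    rates = np.tile(base, (T, 1))
    if f is not None:
        rates = rates * f(lin, outb, left, n, rng)
    counts = rng.poisson(rates * bin_s)
    bc = BinnedCounts(
        counts=counts.astype(float),
        bin_s=bin_s,
        bin_starts=times,
        unit_ids=[f"u{j}" for j in range(n)],
        regions=["CA1"] * n_ca1 + ["PFC"] * n_pfc,
    )
    return bc, beh


class TestPseudopopulation:
    def test_single_animal_matches_groupby_oracle(self):
        bc, beh = _session(seed=1)
        pp = build_pseudopopulation([(bc, beh)], n_distance_bins=5)
        # brute-force oracle: group bins by (direction, turn, distance bin)
        idx = np.clip(
            np.searchsorted(beh["time"].to_numpy(), bc.bin_starts + bc.bin_s / 2, side="right") - 1,
            0, len(beh) - 1,
        )
        edges = np.linspace(0, 1, 6)
        dbin = np.clip(np.digitize(beh["lin_pos"].to_numpy()[idx], edges) - 1, 0, 4)
        for si, row in pp.states.iterrows():
            sel = (
                (beh["outbound"].to_numpy()[idx] == row.outbound)
                & (beh["turn_left"].to_numpy()[idx] == row.turn_left)
                & (dbin == row.dist_bin)
            )
            if sel.any():
                oracle = bc.counts[sel].mean(axis=0) / bc.bin_s
                assert np.allclose(pp.rates[si], oracle)

    def test_column_concatenation_across_animals(self):
        a = _session(n_ca1=8, n_pfc=6, seed=2)
        b = _session(n_ca1=10, n_pfc=4, seed=3)
        pp = build_pseudopopulation([a, b], n_distance_bins=4)
        assert pp.rates.shape[1] == 28
        assert pp.regions.count("CA1") == 18

    def test_state_grid_complete_and_unique(self):
        bc, beh = _session(seed=4)
        pp = build_pseudopopulation([(bc, beh)], n_distance_bins=6)
        assert len(pp.states) == 2 * 2 * 6
        assert not pp.states.duplicated(["outbound", "turn_left", "dist_bin"]).any()

    def test_empty_sessions_error(self):
        with pytest.raises(ValueError):
            build_pseudopopulation([])


def _state_tuned(lin, outb, left, n, rng, direction_gain=2.0):
    """Rate modulation: position tuning shared by regions + direction gain."""
    mods = []
    for j in range(n):
        center = rng.uniform(0, 1)
        tuning = np.exp(-((lin - center) ** 2) / 0.02)
        gain = 1.0 + direction_gain * tuning * (outb if j % 2 == 0 else ~outb)
        mods.append(gain)
    return np.column_stack(mods)


class TestEmbedding:
    def test_embedding_rows_align_with_states(self):
        bc, beh = _session(T=8000, seed=5, f=_state_tuned)
        pp = build_pseudopopulation([(bc, beh)], n_distance_bins=8)
        emb = embed_cca(pp)
        assert emb.shared.shape == (len(pp.states), 3)
        assert emb.local.shape == (len(pp.states), 3)

    def test_circular_latent_recovers_ring_order(self):
        """States on a planted ring embed in matching angular order."""
        n_states = 40
        theta = np.linspace(0, 2 * np.pi, n_states, endpoint=False)
        rng = np.random.default_rng(6)
        lat = np.column_stack([np.cos(theta), np.sin(theta)])
        ca1 = lat @ rng.normal(size=(2, 10)) + 0.02 * rng.normal(size=(n_states, 10))
        pfc = lat @ rng.normal(size=(2, 8)) + 0.02 * rng.normal(size=(n_states, 8))
        states = pd.DataFrame(
            {
                "outbound": True,
                "turn_left": True,
                "dist_bin": np.arange(n_states),
                "dist_center": theta / (2 * np.pi),
            }
        )
        pp = Pseudopopulation(
            rates=np.hstack([ca1, pfc]),
            states=states,
            regions=["CA1"] * 10 + ["PFC"] * 8,
            provenance=[f"a/{i}" for i in range(18)],
        )
        emb = embed_cca(pp, n_components=3)
        ang = np.arctan2(emb.shared[:, 1], emb.shared[:, 0])
        # circular-order correlation: successive states advance monotonically
        steps = np.angle(np.exp(1j * np.diff(ang)))
        assert abs(np.mean(np.sign(steps))) > 0.9

    def test_block_independent_rates_no_separation(self):
        bc, beh = _session(T=6000, seed=7)  # untuned Poisson rates
        pp = build_pseudopopulation([(bc, beh)], n_distance_bins=8)
        emb = embed_cca(pp)
        res = ring_distance_contrast(emb)
        assert res["rank_sum"] is None or res["rank_sum"].p_value > 0.001

    def test_duplicated_animal_preserves_geometry_shape(self):
        bc, beh = _session(T=6000, seed=8, f=_state_tuned)
        pp1 = build_pseudopopulation([(bc, beh)], n_distance_bins=6)
        pp2 = build_pseudopopulation([(bc, beh), (bc, beh)], n_distance_bins=6)
        e1 = ring_distance_contrast(embed_cca(pp1))
        e2 = ring_distance_contrast(embed_cca(pp2))
        # same states, duplicated columns: contrast sign and rough scale agree
        assert np.sign(e1["mean_diff"]) == np.sign(e2["mean_diff"])

    def test_column_permutation_invariance_of_contrast(self):
        bc, beh = _session(T=6000, seed=9, f=_state_tuned)
        pp = build_pseudopopulation([(bc, beh)], n_distance_bins=6)
        rng = np.random.default_rng(10)
        ca1 = [i for i, r in enumerate(pp.regions) if r == "CA1"]
        pfc = [i for i, r in enumerate(pp.regions) if r == "PFC"]
        perm = np.concatenate([rng.permutation(ca1), rng.permutation(pfc)])
        pp_perm = Pseudopopulation(
            rates=pp.rates[:, perm],
            states=pp.states,
            regions=[pp.regions[i] for i in perm],
            provenance=[pp.provenance[i] for i in perm],
        )
        r1 = ring_distance_contrast(embed_cca(pp))
        r2 = ring_distance_contrast(embed_cca(pp_perm))
        assert r1["mean_diff"] == pytest.approx(r2["mean_diff"], rel=1e-6)


class TestRingContrast:
    def _embedding(self, offset):
        """Two parallel rings (out/in), two members each (turn L/R)."""
        n_bins = 30
        t = np.linspace(0, 2 * np.pi, n_bins, endpoint=False)
        rows = []
        coords = []
        for outb in (True, False):
            for left in (True, False):
                ring = np.column_stack([np.cos(t), np.sin(t), np.zeros(n_bins)])
                if not outb:
                    ring = ring + np.array([0.0, 0.0, offset])
                for b in range(n_bins):
                    rows.append(
                        {"outbound": outb, "turn_left": left, "dist_bin": b,
                         "dist_center": b / n_bins}
                    )
                    coords.append(ring[b])
        states = pd.DataFrame(rows)
        coords = np.asarray(coords)
        return ManifoldEmbedding(shared=coords, local=np.zeros_like(coords), states=states)

    def test_identical_manifolds_no_difference(self):
        emb = self._embedding(offset=0.0)
        res = ring_distance_contrast(emb)
        assert res["mean_within"] == pytest.approx(res["mean_between"])

    def test_parallel_rings_between_minus_within_equals_offset(self):
        d = 1.7
        emb = self._embedding(offset=d)
        res = ring_distance_contrast(emb)
        assert res["mean_within"] == pytest.approx(0.0, abs=1e-12)
        # between pairs differ only along the offset axis
        assert res["mean_between"] == pytest.approx(d, abs=1e-12)
        assert res["rank_sum"].p_value < 0.01

    def test_pair_counts_match_enumeration(self):
        emb = self._embedding(offset=1.0)
        res = ring_distance_contrast(emb)
        n_bins = 30
        # per distance bin: 4 states -> C(4,2)=6 pairs, 2 within + 4 between
        assert len(res["within"]) == 2 * n_bins
        assert len(res["between"]) == 4 * n_bins

    def test_translation_and_rotation_invariance(self):
        emb = self._embedding(offset=1.0)
        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = ManifoldEmbedding(
            shared=emb.shared @ q + np.array([3.0, -2.0, 1.0]),
            local=emb.local,
            states=emb.states,
        )
        r1 = ring_distance_contrast(emb)
        r2 = ring_distance_contrast(moved)
        assert r1["mean_diff"] == pytest.approx(r2["mean_diff"], abs=1e-9)
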