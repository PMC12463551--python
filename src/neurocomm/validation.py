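"""Synthetic-recovery benchmarks.

Each function runs one planted-ground-truth experiment end to end through
the public pipeline pieces (generator → preprocessing → analysis) and
returns the quantities a correct implementation must reproduce: oracle
agreement errors, planted-rank recovery rates, state-gating win counts,
canonical-correlation recovery errors, the shared/local behavioral
dissociation, spectral sanity values, windowing exactness and the
manifold ring contrast.  The acceptance script and the acceptance tests
both drive these.

Problem sizes default to desk-scale runs (tens of seconds each): 20 k
50 ms bins (~17 min of session) for rank recovery and gating, 50 k
samples for CCA recovery, two 450 s epochs for decoding and manifold
geometry.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import stats as ncstats
from .cca import aligned_orthogonal, fit_cca, project_variates
from .coherence import multitaper_coherence, wpli
from .decode import build_features, evaluate_decoding
from .manifold import build_pseudopopulation, embed_cca, ring_distance_contrast
from .preprocess import (
    LfpTrace,
    bin_spikes,
    filter_low_rate_units,
    lfp_band_envelope,
    zscore_counts,
)
from .rrr import cv_rank_curve, ols_fit, optimal_rank, rrr_truncate
from .synthgen import SynthConfig, generate_session
from .windows import balance_windows, gather_samples, prune_overlaps, threshold_windows


def _session_matrices(session):
    cfg = session.config
    counts = zscore_counts(
        filter_low_rate_units(bin_spikes(session.spikes, cfg.bin_s, session.span))
    )
    x = counts.counts[:, [i for i, r in enumerate(counts.regions) if r == "CA1"]]
    y = counts.counts[:, [i for i, r in enumerate(counts.regions) if r == "PFC"]]
    return counts, x, y


# ---------------------------------------------------------------------------
# 1. RRR oracle equivalence


def rrr_oracle_error(n_instances: int = 50, seed: int = 0) -> dict:
    """Max |ΔR²| between rrr_truncate and a brute-force SVD oracle.

    Random instances with p, q ≤ 8 and T = 500; training R² compared at
    every rank.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        p = int(rng.integers(2, 9))
        q = int(rng.integers(2, 9))
        x = rng.normal(size=(500, p))
        w = rng.normal(size=(p, q))
        y = x @ w + rng.normal(size=(500, q))
        b = ols_fit(x, y)
        yhat = x @ b
        u, s, vt = np.linalg.svd(yhat, full_matrices=False)
        sst = ((y - y.mean(axis=0)) ** 2).sum()
        for m in range(1, q + 1):
            y_impl = x @ rrr_truncate(b, x, m)
            r2_impl = 1.0 - ((y - y_impl) ** 2).sum() / sst
            y_oracle = (u[:, :m] * s[:m]) @ vt[:m]
            r2_oracle = 1.0 - ((y - y_oracle) ** 2).sum() / sst
            worst = max(worst, abs(r2_impl - r2_oracle))
    return {"max_abs_diff": worst, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# 2. Planted-rank recovery


def rank_recovery(n_seeds: int = 20, seed: int = 0, t_bins: int = 20_000) -> dict:
    """Optimal-rank recovery of the planted communication dimension.

    Default generator conditions (comm_rank 3, gains 2.0/0.5, 30/20 units)
    at ``t_bins`` 50 ms bins; success = m̂ within ±1 of the planted rank.
    """
    epoch_s = t_bins * 0.05 / 2.0
    m_hats = []
    for i in range(n_seeds):
        cfg = SynthConfig(n_epochs=2, epoch_duration_s=epoch_s, seed=seed + i)
        session = generate_session(cfg)
        _, x, y = _session_matrices(session)
        T = (x.shape[0] // 6) * 6
        curves = cv_rank_curve(x[:T], y[:T], t_w=6, folds=5, m_max=12, seed=seed + i)
        m_hats.append(optimal_rank(curves))
    m_hats = np.asarray(m_hats)
    k = 3
    ok = np.abs(m_hats - k) <= 1
    return {
        "m_hats": m_hats.tolist(),
        "recovery_rate": float(ok.mean()),
        "planted_rank": k,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 3. State-gated subspace performance


def state_gate_contrast(n_seeds: int = 20, seed: int = 0, t_bins: int = 20_000) -> dict:
    """High- vs low-theta-state CA1→PFC cross-validated R².

    Pure gated communication is planted (behavior coupling off) with gains
    2.0 / 0.5; windows come from the theta-envelope thresholding path
    (detect → prune → balance → gather).  Returns the fraction of seeds in
    which the high-state R² at m̂ exceeds the low-state value.
    """
    epoch_s = t_bins * 0.05 / 2.0
    wins = 0
    highs, lows = [], []
    for i in range(n_seeds):
        cfg = SynthConfig(
            n_epochs=2, epoch_duration_s=epoch_s, seed=seed + i, behavior_coupling={}
        )
        session = generate_session(cfg)
        counts, _, _ = _session_matrices(session)
        env = lfp_band_envelope(session.lfp["CA1"], "theta")
        per = int(round(cfg.lfp_fs_hz * cfg.bin_s))
        nb = min(counts.n_bins, env.envelope.size // per)
        state = env.envelope[: nb * per].reshape(nb, per).mean(axis=1)
        hi, lo = threshold_windows(state, counts.bin_starts[:nb], state_name="theta")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hi, lo = balance_windows(prune_overlaps([hi, lo]), seed=seed + i)
            r2 = {}
            for name, ws in (("high", hi), ("low", lo)):
                m = gather_samples(counts, ws)
                x = m[:, [j for j, r in enumerate(counts.regions) if r == "CA1"]]
                y = m[:, [j for j, r in enumerate(counts.regions) if r == "PFC"]]
                curves = cv_rank_curve(x, y, t_w=6, folds=5, m_max=12, seed=seed + i)
                m_hat = optimal_rank(curves)
                r2[name] = float(curves.mean(axis=0)[m_hat - 1])
        highs.append(r2["high"])
        lows.append(r2["low"])
        wins += r2["high"] > r2["low"]
    return {
        "wins": wins,
        "n_seeds": n_seeds,
        "win_fraction": wins / n_seeds,
        "r2_high_mean": float(np.mean(highs)),
        "r2_low_mean": float(np.mean(lows)),
    }


# ---------------------------------------------------------------------------
# 4. CCA recovery and oracle


def planted_cca_data(rhos, p, q, T, seed=0):
    """Gaussian populations with known canonical correlations ``rhos``."""
    rng = np.random.default_rng(seed)
    rhos = np.asarray(rhos, dtype=float)
    k = rhos.size
    s = rng.normal(size=(T, k))
    u = s
    v = s * rhos + rng.normal(size=(T, k)) * np.sqrt(1.0 - rhos**2)
    qx, _ = np.linalg.qr(rng.normal(size=(p, p)))
    qy, _ = np.linalg.qr(rng.normal(size=(q, q)))
    x = np.hstack([u, rng.normal(size=(T, p - k))]) @ qx
    y = np.hstack([v, rng.normal(size=(T, q - k))]) @ qy
    return x, y


def cca_recovery(seed: int = 0, T: int = 50_000) -> dict:
    """Held-out recovery of planted canonical correlations (0.9, 0.6, 0.3)
    plus training-ρ agreement with a generalized-eigenproblem oracle."""
    from scipy import linalg as sla

    rhos = np.array([0.9, 0.6, 0.3])
    x, y = planted_cca_data(rhos, 20, 15, T, seed=seed)
    fit = fit_cca(x, y, k=5, folds=5, seed=seed)
    heldout_err = float(np.max(np.abs(fit.rho_heldout[:3] - rhos)))

    rng = np.random.default_rng(seed + 1)
    worst = 0.0
    from .cca import REG_SCALE, _cca_weights

    for _ in range(8):
        p = int(rng.integers(3, 11))
        q = int(rng.integers(3, 11))
        k = min(p, q)
        xo, yo = planted_cca_data([0.7, 0.4][: min(2, k)], p, q, 800, seed=int(rng.integers(2**31)))
        _, _, rho_impl = _cca_weights(xo, yo, k)
        Ti = xo.shape[0]
        xc = xo - xo.mean(axis=0)
        yc = yo - yo.mean(axis=0)
        cxx = xc.T @ xc / (Ti - 1)
        cyy = yc.T @ yc / (Ti - 1)
        cxy = xc.T @ yc / (Ti - 1)
        for c in (cxx, cyy):
            c[np.diag_indices_from(c)] += REG_SCALE * np.trace(c) / c.shape[0]
        m = cxy @ np.linalg.solve(cyy, cxy.T)
        vals = np.clip(np.sort(sla.eigh(m, cxx, eigvals_only=True))[::-1][:k], 0, 1)
        worst = max(worst, float(np.max(np.abs(rho_impl - np.sqrt(vals)))))
    return {
        "rho_heldout": fit.rho_heldout[:3].tolist(),
        "planted": rhos.tolist(),
        "heldout_max_abs_err": heldout_err,
        "oracle_max_abs_err": worst,
    }


# ---------------------------------------------------------------------------
# 5. Aligned/local isometry


def isometry_error(seed: int = 0) -> dict:
    from .cca import VariateSeries

    rng = np.random.default_rng(seed)
    u = rng.normal(size=(2000, 6))
    v = rng.normal(size=(2000, 6))
    sl = aligned_orthogonal(VariateSeries(u=u, v=v, times=np.arange(2000.0)))
    lhs = (sl.aligned**2 + sl.local**2).sum(axis=1)
    rhs = (u**2 + v**2).sum(axis=1)
    return {"max_abs_err": float(np.max(np.abs(lhs - rhs)))}


# ---------------------------------------------------------------------------
# 6. Shared/local behavioral dissociation


def decoding_dissociation(seed: int = 0, epoch_s: float = 450.0) -> dict:
    """Decode linearized position from aligned vs local features.

    Behavior is planted in the shared latents (default generator mode);
    the negative control plants it on the unreciprocated axis.
    """
    out = {}
    for mode, label in (("shared", ""), ("local", "control_")):
        cfg = SynthConfig(
            n_epochs=2, epoch_duration_s=epoch_s, seed=seed, behavior_target=mode
        )
        session = generate_session(cfg)
        counts, x, y = _session_matrices(session)
        fit = fit_cca(x, y, k=10, folds=5, seed=seed)
        sl = aligned_orthogonal(project_variates(fit, x, y, times=counts.bin_starts))
        table = evaluate_decoding(
            build_features(sl, k=10), session.behavior, behaviors=["lin_pos"], seed=seed
        )
        row = table.iloc[0]
        out[label + "aligned_r2"] = float(row["aligned_metric"])
        out[label + "local_r2"] = float(row["local_metric"])
    return out


# ---------------------------------------------------------------------------
# 7. Spectral analytics sanity


def spectral_checks(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    fs = 1000.0
    n = int(60 * fs)
    t = np.arange(n) / fs
    x8 = np.sin(2 * np.pi * 8 * t)
    y8_lag = np.sin(2 * np.pi * 8 * t - np.pi / 2)
    w = wpli(
        LfpTrace(x8, fs, "CA1"), LfpTrace(y8_lag, fs, "PFC"), band=(6, 12)
    )
    wpli_lag = float(w.values[np.argmin(np.abs(w.frequencies - 8.0))])

    noise = rng.normal(size=n)
    coh_id = multitaper_coherence(
        LfpTrace(noise, fs, "CA1"), LfpTrace(noise.copy(), fs, "PFC")
    )
    coh_identical_dev = float(np.nanmax(np.abs(coh_id.values - 1.0)))

    a = rng.normal(size=n)
    b = rng.normal(size=n)
    coh_null = multitaper_coherence(
        LfpTrace(a, fs, "CA1"), LfpTrace(b, fs, "PFC"), n_tapers=5
    )
    coh_null_mean = float(np.nanmean(coh_null.values))
    w_null = wpli(
        LfpTrace(rng.normal(size=100_000), fs, "CA1"),
        LfpTrace(rng.normal(size=100_000), fs, "PFC"),
        band=(6, 12),
    )
    return {
        "wpli_quarter_cycle_lag": wpli_lag,
        "coherence_identical_max_dev": coh_identical_dev,
        "coherence_null_mean": coh_null_mean,
        "coherence_null_floor": 1.0 / 5 + 0.05,
        "wpli_null_mean": float(np.nanmean(w_null.values)),
    }


# ---------------------------------------------------------------------------
# 8. Windowing exactness


def _cross_set_overlaps(sets) -> int:
    """Brute-force count of overlapping cross-set window pairs."""
    violations = 0
    for i, a in enumerate(sets):
        for j in range(i + 1, len(sets)):
            c = sets[j]
            for s1 in a.starts:
                for s2 in c.starts:
                    if s1 < s2 + c.duration_s and s2 < s1 + a.duration_s:
                        violations += 1
    return violations


def windowing_exactness(seed: int = 0) -> dict:
    """Constructed envelopes: exact window duration/start, prune/balance laws.

    The state series is two-level: a low jittery baseline and 2 s plateaus
    covering ~20% of the time, so the 85th-percentile threshold sits at the
    plateau level and each plateau onset is the exact crossing sample.
    """
    rng = np.random.default_rng(seed)
    dt = 0.05
    times = np.arange(0, 400.0, dt)
    state = rng.uniform(0.0, 0.1, times.size)
    burst_starts = (20.0 + 9.0 * np.arange(40)).astype(float)
    for b in burst_starts:
        state[(times >= b) & (times < b + 2.0)] = 1.0
    hi, lo = threshold_windows(state, times, high_q=0.85, low_q=0.15)
    start_err = float(np.max(np.abs(np.sort(hi.starts) - burst_starts))) if hi.n else np.inf
    dur_err = float(np.max(np.abs((hi.stops - hi.starts) - 0.3))) if hi.n else np.inf

    # a deliberately half-overlapping second set must be pruned to disjointness
    shifted = hi.starts[::2] + 0.15
    from .windows import WindowSet

    other = WindowSet(shifted, 0.3, "shifted", "high")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pruned = prune_overlaps([hi, other])
        violations = _cross_set_overlaps(pruned)
        balanced = balance_windows(prune_overlaps([hi, lo]), seed=seed)
        balance_violations = _cross_set_overlaps(balanced)
    counts = {w.label: w.n for w in balanced}
    return {
        "window_start_max_err": start_err,
        "window_duration_max_err": dur_err,
        "prune_violations": violations + balance_violations,
        "balanced_counts": counts,
        "balanced_equal": float(len(set(counts.values())) == 1),
    }


# ---------------------------------------------------------------------------
# 9. Small-sample test oracles


def small_sample_oracles(seed: int = 0) -> dict:
    """BH / Mann–Kendall / permutation against exhaustive enumeration."""
    import itertools

    rng = np.random.default_rng(seed)

    # Benjamini–Hochberg vs literal max-i definition
    bh_ok = True
    for _ in range(20):
        m = int(rng.integers(1, 10))
        p = rng.random(m)
        q = 0.1
        reject, _ = ncstats.benjamini_hochberg(p, q=q)
        order = np.argsort(p)
        ks = [i + 1 for i in range(m) if p[order[i]] <= (i + 1) * q / m]
        k_star = max(ks) if ks else 0
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_star]] = True
        bh_ok &= bool(np.array_equal(reject, expected))

    # Mann–Kendall exact p vs full permutation enumeration (n = 6)
    x = rng.normal(size=6)
    res = ncstats.mann_kendall(x)
    n = x.size
    count = total = 0
    for perm in itertools.permutations(range(n)):
        xs = np.asarray(perm, dtype=float)
        s = sum(np.sign(xs[j] - xs[i]) for i in range(n) for j in range(i + 1, n))
        total += 1
        count += abs(s) >= abs(res.extra["S"])
    mk_err = abs(res.p_value - count / total)

    # permutation test vs exhaustive label enumeration (n = 4 + 4)
    a = rng.normal(1.0, 1.0, 4)
    b = rng.normal(0.0, 1.0, 4)
    pooled = np.concatenate([a, b])
    d_obs = a.mean() - b.mean()
    count = total = 0
    for idx in itertools.combinations(range(8), 4):
        sel = np.zeros(8, dtype=bool)
        sel[list(idx)] = True
        d = pooled[sel].mean() - pooled[~sel].mean()
        total += 1
        count += abs(d) >= abs(d_obs) - 1e-12
    exact = count / total
    sampled = ncstats.permutation_test_means(a, b, n_perm=20_000, seed=seed).p_value
    return {
        "bh_exhaustive_agreement": float(bh_ok),
        "mk_exact_p_abs_err": float(mk_err),
        "perm_p_abs_err": float(abs(sampled - exact)),
    }


# ---------------------------------------------------------------------------
# 10. Manifold ring contrast


def manifold_contrast(seed: int = 0, epoch_s: float = 450.0, n_distance_bins: int = 25) -> dict:
    """Between- vs within-manifold distances on a trajectory-coupled session."""
    cfg = SynthConfig(n_epochs=2, epoch_duration_s=epoch_s, seed=seed)
    session = generate_session(cfg)
    counts_raw = filter_low_rate_units(
        bin_spikes(session.spikes, cfg.bin_s, session.span)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pp = build_pseudopopulation(
            [(counts_raw, session.behavior)], n_distance_bins=n_distance_bins
        )
        emb = embed_cca(pp)
        res = ring_distance_contrast(emb)
    return {
        "mean_within": res["mean_within"],
        "mean_between": res["mean_between"],
        "mean_diff": res.get("mean_diff", float("nan")),
        "p_rank_sum": res["rank_sum"].p_value if res.get("rank_sum") else float("nan"),
    }
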