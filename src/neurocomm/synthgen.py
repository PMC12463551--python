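"""Synthetic two-region session generator with planted communication structure.

Emulates a W-track alternation session recorded simultaneously from
hippocampal CA1 and prefrontal cortex: Poisson spike counts driven by a
low-rank set of shared latents (gated by theta state) plus per-region
private latents; LFP with delta/theta/ripple band structure and a
controllable inter-region theta phase lag; and a behavior table with run
epochs, four trajectory types (C-to-L, L-to-C, C-to-R, R-to-C), linearized
position, velocity, and trial outcome labels.

Every generated quantity that downstream analyses try to recover — the
shared-latent rank, the state gate, loadings, behavior couplings — is
returned as ground truth, so subspace dimensionality, CCA recovery, and
decoding dissociations can all be tested without any recorded data.

All randomness flows from a single seed through named substreams, so a
(config, seed) pair is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import LfpTrace, SpikeSet

BEHAVIOR_FS = 30.0  # video-tracking sample rate (Hz)
TRAJ_CYCLE = ["C-to-L", "L-to-C", "C-to-R", "R-to-C"]

# substream codes for the named-substream seeding scheme
_STREAM = {"behavior": 1, "lfp": 2, "ensembles": 3}


@dataclass
class SynthConfig:
    """Parameters of a synthetic session.

    Rates are Hz, durations seconds.  ``comm_rank`` is the planted shared
    (communication) dimension; ``comm_gain_high``/``comm_gain_low`` scale the
    shared latents inside/outside theta-high bins.  ``behavior_coupling``
    maps behavior column names to length-``comm_rank`` loading vectors onto
    the shared latents (None → a default coupling of linearized position,
    outbound flag and velocity onto the first latents).
    ``behavior_target`` is "shared" (default: the coupled signal is
    reciprocated across regions) or "local" (equal-and-opposite loading —
    the negative control planting behavior on the unreciprocated axis).
    """

    n_ca1: int = 30
    n_pfc: int = 20
    n_epochs: int = 8
    epoch_duration_s: float = 900.0
    bin_s: float = 0.05
    comm_rank: int = 3
    comm_gain_high: float = 2.0
    comm_gain_low: float = 0.5
    private_rank: int = 5
    base_rate_hz: tuple[float, float] = (5.0, 20.0)
    lfp_fs_hz: float = 1500.0
    theta_hz: float = 8.0
    ripple_hz: float = 180.0
    delta_hz: float = 2.0
    phase_lag_rad: float = 0.0
    behavior_coupling: Mapping[str, np.ndarray] | None = None
    behavior_target: str = "shared"
    seed: int = 0
    # behavior shape parameters
    trials_per_epoch: int | None = None
    trial_duration_s: float = 22.5
    movement_fraction: float = 0.6
    vte_fraction: float = 0.2
    accuracy_start: float = 0.6
    accuracy_end: float = 0.95
    # signal scales
    shared_strength: float = 0.3  # per-unit log-rate SD from shared latents at gain 1
    private_strength: float = 0.3
    behavior_strength: float = 1.3
    # intrinsic-latent amplitude on behavior-coupled channels ("shared" mode).
    # The "local" negative control always keeps the full intrinsic latent:
    # it anchors the sign of the canonical pair that the unreciprocated
    # behavior signal rides on, and must stay stronger than that signal.
    coupled_latent_z_scale: float = 0.25
    ar_coef: float = 0.8  # AR(1) coefficient of all latents, per 50 ms step
    theta_amp: float = 1.0
    theta_amp_still: float = 0.2
    ripple_amp: float = 0.5
    ripple_rate_hz: float = 0.1  # burst rate during stillness
    delta_amp: float = 0.3
    noise_amp: float = 0.2

    def __post_init__(self) -> None:
        if min(self.n_ca1, self.n_pfc, self.n_epochs, self.comm_rank) <= 0:
            raise ValueError("unit/epoch/rank counts must be positive")
        if self.epoch_duration_s <= 0 or self.bin_s <= 0:
            raise ValueError("durations must be positive")
        if self.comm_rank > min(self.n_ca1, self.n_pfc):
            raise ValueError("comm_rank cannot exceed min(n_ca1, n_pfc)")
        if self.comm_gain_high < 0 or self.comm_gain_low < 0:
            raise ValueError("gains must be non-negative")
        if self.behavior_target not in ("shared", "local"):
            raise ValueError("behavior_target must be 'shared' or 'local'")

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_duration_s

    @property
    def n_bins(self) -> int:
        return int(np.floor(self.duration_s / self.bin_s + 1e-9))

    @property
    def n_trials_per_epoch(self) -> int:
        if self.trials_per_epoch is not None:
            return self.trials_per_epoch
        return max(1, int(self.epoch_duration_s // self.trial_duration_s))

    def echo(self) -> dict:
        d = asdict(self)
        if d["behavior_coupling"] is not None:
            d["behavior_coupling"] = {
                k: np.asarray(v).tolist() for k, v in d["behavior_coupling"].items()
            }
        return d


@dataclass
class GroundTruth:
    """Planted structure a successful analysis should recover."""

    shared_latents: np.ndarray  # k × T
    gate: np.ndarray  # T, bool: theta-high bins
    loadings_ca1: np.ndarray  # n_ca1 × k
    loadings_pfc: np.ndarray  # n_pfc × k
    private_latents_ca1: np.ndarray
    private_latents_pfc: np.ndarray
    private_loadings_ca1: np.ndarray
    private_loadings_pfc: np.ndarray
    behavior_loadings: dict[str, np.ndarray]
    behavior_target: str


@dataclass
class SyntheticSession:
    """A complete generated session: spikes, LFP, behavior, and the truth."""

    spikes: SpikeSet
    lfp: dict[str, LfpTrace]
    behavior: pd.DataFrame
    truth: GroundTruth
    config: SynthConfig

    @property
    def span(self) -> tuple[float, float]:
        return (0.0, self.config.n_bins * self.config.bin_s)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.config.n_bins) * self.config.bin_s


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream]])


def default_behavior_coupling(k: int) -> dict[str, np.ndarray]:
    """Couple linearized position, direction and velocity onto the first latents."""
    coupling = {}
    vars_ = ["lin_pos", "outbound", "velocity"]
    for i, var in enumerate(vars_):
        vec = np.zeros(k)
        vec[i % k] += 1.0
        coupling[var] = vec
    return coupling


# ---------------------------------------------------------------------------
# Behavior


def _wtrack_xy(lin_pos: np.ndarray, side: str, outbound: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map linearized position to 2-D W-track coordinates.

    The track is an ~1 m square: center well at (0.5, 0), a vertical center
    arm to (0.5, 0.8), a top rail to the side arm, and the side arm down to
    the side well at (0 or 1, 0).  ``lin_pos`` is 0 at the center well and 1
    at the side well regardless of direction.
    """
    x_side = 0.0 if side == "L" else 1.0
    # path segments measured along the track, normalized to total length 1
    seg1 = 0.8  # center arm
    seg2 = 0.5  # top rail (half track width)
    seg3 = 0.8  # side arm
    total = seg1 + seg2 + seg3
    d = lin_pos * total
    x = np.empty_like(d)
    y = np.empty_like(d)
    in1 = d <= seg1
    in2 = (d > seg1) & (d <= seg1 + seg2)
    in3 = d > seg1 + seg2
    x[in1] = 0.5
    y[in1] = d[in1]
    frac2 = (d[in2] - seg1) / seg2
    x[in2] = 0.5 + (x_side - 0.5) * frac2
    y[in2] = 0.8
    frac3 = (d[in3] - seg1 - seg2) / seg3
    x[in3] = x_side
    y[in3] = 0.8 * (1.0 - frac3)
    return x, y


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def generate_behavior(cfg: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """W-track behavior table sampled at 30 samples/s.

    Trials cycle through the four trajectory types; each trial has a run
    phase (smooth monotone traversal of linearized position) followed by a
    reward-well dwell.  IdPhi is elevated in the choice zone of a random
    fraction of outbound trials (vicarious trial and error), and
    correct/error labels follow a per-epoch accuracy ramp.
    """
    if cfg.epoch_duration_s <= 0 or cfg.duration_s <= 0:
        raise ValueError("non-positive durations are invalid")
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, "behavior")
    fs = BEHAVIOR_FS
    n_samples = int(np.floor(cfg.duration_s * fs))
    t = np.arange(n_samples) / fs

    lin = np.zeros(n_samples)
    x = np.full(n_samples, 0.5)
    y = np.zeros(n_samples)
    trial_id = np.full(n_samples, -1)
    epoch_id = np.zeros(n_samples, dtype=int)
    traj = np.array([""] * n_samples, dtype=object)
    outbound = np.zeros(n_samples, dtype=bool)
    turn_left = np.zeros(n_samples, dtype=bool)
    moving = np.zeros(n_samples, dtype=bool)
    correct = np.zeros(n_samples, dtype=bool)
    idphi = np.abs(rng.normal(0.0, 0.1, size=n_samples))

    n_tpe = cfg.n_trials_per_epoch
    trial_len = cfg.epoch_duration_s / n_tpe
    run_len = cfg.movement_fraction * trial_len
    if cfg.n_epochs > 1:
        acc = np.linspace(cfg.accuracy_start, cfg.accuracy_end, cfg.n_epochs)
    else:
        acc = np.array([cfg.accuracy_end])

    trial = 0
    for ep in range(cfg.n_epochs):
        ep_t0 = ep * cfg.epoch_duration_s
        for k in range(n_tpe):
            t0 = ep_t0 + k * trial_len
            t1 = t0 + trial_len
            i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n_samples)
            if i1 <= i0:
                continue
            ttype = TRAJ_CYCLE[trial % 4]
            is_out = ttype.startswith("C")
            side = "L" if "L" in ttype else "R"
            tt = t[i0:i1] - t0
            # raised-cosine monotone ramp over the run phase, flat dwell after
            phase = np.clip(tt / run_len, 0.0, 1.0)
            ramp = 0.5 * (1.0 - np.cos(np.pi * phase))
            lp = ramp if is_out else 1.0 - ramp
            lin[i0:i1] = lp
            xi, yi = _wtrack_xy(lp, side, is_out)
            x[i0:i1], y[i0:i1] = xi, yi
            trial_id[i0:i1] = trial
            epoch_id[i0:i1] = ep
            traj[i0:i1] = ttype
            outbound[i0:i1] = is_out
            turn_left[i0:i1] = side == "L"
            moving[i0:i1] = phase < 1.0
            correct[i0:i1] = rng.random() < acc[ep]
            if is_out and rng.random() < cfg.vte_fraction:
                zone = (lp > 0.35) & (lp < 0.65) & (phase < 1.0)
                idphi[i0:i1][zone] += 2.0
            trial += 1

    # velocity = smoothed derivative of 2-D position; acceleration likewise
    w = max(1, int(round(0.5 * fs)))
    vx = np.gradient(_smooth(x, w), 1.0 / fs)
    vy = np.gradient(_smooth(y, w), 1.0 / fs)
    velocity = _smooth(np.hypot(vx, vy), w)
    acceleration = _smooth(np.gradient(velocity, 1.0 / fs), w)

    return pd.DataFrame(
        {
            "time": t,
            "x": x,
            "y": y,
            "lin_pos": lin,
            "velocity": velocity,
            "acceleration": acceleration,
            "idphi": idphi,
            "traj_type": traj,
            "outbound": outbound,
            "turn_left": turn_left,
            "moving": moving,
            "trial": trial_id,
            "epoch": epoch_id,
            "correct": correct,
        }
    )


# ---------------------------------------------------------------------------
# LFP


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit-variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / (sd if sd > 0 else 1.0)


def generate_lfp(
    cfg: SynthConfig, behavior: pd.DataFrame, seed: int | None = None
) -> tuple[dict[str, LfpTrace], np.ndarray]:
    """Two-region LFP plus the per-bin theta-state gate.

    Each region's trace is an amplitude-modulated theta carrier (amplitude
    high during movement bouts — these bouts define the gate), ripple bursts
    during stillness (full amplitude in CA1, attenuated in PFC), a delta
    component, and 1/f noise.  The PFC theta carrier lags CA1 by
    ``phase_lag_rad``.
    """
    if cfg.lfp_fs_hz < 2.0 * cfg.ripple_hz:
        raise ValueError(
            f"lfp_fs_hz={cfg.lfp_fs_hz} aliases the {cfg.ripple_hz} Hz ripple carrier"
        )
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, "lfp")
    fs = cfg.lfp_fs_hz
    duration = cfg.duration_s
    if behavior["time"].iloc[-1] < duration - 1.0:
        raise ValueError("behavior table does not span the configured duration")
    n = int(np.floor(duration * fs))
    t = np.arange(n) / fs

    # movement-driven theta amplitude (smoothed square modulation)
    beh_t = behavior["time"].to_numpy()
    moving = behavior["moving"].to_numpy().astype(float)
    idx = np.clip(np.searchsorted(beh_t, t, side="right") - 1, 0, len(beh_t) - 1)
    mov = moving[idx]
    mov_smooth = _smooth(mov, max(1, int(round(0.25 * fs))))
    amp_theta = cfg.theta_amp_still + (cfg.theta_amp - cfg.theta_amp_still) * mov_smooth

    phase = 2.0 * np.pi * cfg.theta_hz * t
    traces = {}
    for region, lag in (("CA1", 0.0), ("PFC", cfg.phase_lag_rad)):
        sig = amp_theta * np.sin(phase - lag)
        sig = sig + cfg.delta_amp * np.sin(
            2.0 * np.pi * cfg.delta_hz * t + rng.uniform(0, 2 * np.pi)
        )
        if cfg.noise_amp > 0:
            sig = sig + cfg.noise_amp * _pink_noise(n, rng)
        traces[region] = sig

    # ripple bursts during stillness (CA1 events, attenuated volume echo in PFC)
    if cfg.ripple_amp > 0:
        still = mov < 0.5
        expected = cfg.ripple_rate_hz * still.sum() / fs
        n_events = rng.poisson(expected)
        still_idx = np.nonzero(still)[0]
        if n_events > 0 and still_idx.size > 0:
            centers = t[rng.choice(still_idx, size=n_events)]
            burst_sd = 0.025  # ~100 ms burst
            for t0 in centers:
                lo = max(0, int((t0 - 0.1) * fs))
                hi = min(n, int((t0 + 0.1) * fs))
                tt = t[lo:hi]
                env = np.exp(-0.5 * ((tt - t0) / burst_sd) ** 2)
                burst = env * np.sin(2 * np.pi * cfg.ripple_hz * (tt - t0))
                traces["CA1"][lo:hi] += cfg.ripple_amp * burst
                traces["PFC"][lo:hi] += 0.2 * cfg.ripple_amp * burst

    lfp = {r: LfpTrace(samples=s, fs_hz=fs, region=r) for r, s in traces.items()}

    # gate: a bin is theta-high when mostly inside a movement bout
    n_bins = cfg.n_bins
    bin_idx = np.minimum((beh_t / cfg.bin_s).astype(int), n_bins - 1)
    frac = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    np.add.at(frac, bin_idx, moving)
    np.add.at(cnt, bin_idx, 1.0)
    with np.errstate(invalid="ignore"):
        frac = np.where(cnt > 0, frac / np.maximum(cnt, 1), 0.0)
    gate = frac > 0.5
    return lfp, gate


# ---------------------------------------------------------------------------
# Spiking ensembles


def _ar1(rng: np.random.Generator, shape: tuple[int, int], phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) rows."""
    k, T = shape
    innov_sd = np.sqrt(1.0 - phi**2)
    z = np.empty((k, T))
    z[:, 0] = rng.normal(size=k)
    eps = rng.normal(scale=innov_sd, size=(k, T - 1)) if T > 1 else None
    for t in range(1, T):
        z[:, t] = phi * z[:, t - 1] + eps[:, t - 1]
    return z


def _row_normalized_loadings(
    rng: np.random.Generator, n_units: int, k: int, strength: float
) -> np.ndarray:
    """Gaussian loadings with each unit's row scaled to norm ``strength``."""
    L = rng.normal(size=(n_units, k))
    norms = np.linalg.norm(L, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return strength * L / norms


def generate_ensembles(
    cfg: SynthConfig,
    behavior: pd.DataFrame,
    gate: np.ndarray,
    seed: int | None = None,
) -> tuple[SpikeSet, GroundTruth]:
    """Poisson spike trains from gated shared + private latents + behavior.

    Per-bin log-rates are
    base + L·[g(gate)·z_shared ; z_private] + W_behavior·b(t), with the
    shared latents loading on both regions, private latents on one, and the
    behavior couplings entering through the shared loading vectors (or, for
    the negative control, with opposite sign in the two regions so the
    signal lies on the unreciprocated axis).  A variance-matched offset
    keeps each unit's mean rate near its base rate.
    """
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, "ensembles")
    gate = np.asarray(gate, dtype=bool)
    T = gate.size
    k = cfg.comm_rank
    r = cfg.private_rank

    z_shared = _ar1(rng, (k, T), cfg.ar_coef)
    z_ca1 = _ar1(rng, (max(r, 1), T), cfg.ar_coef)[:r] if r > 0 else np.zeros((0, T))
    z_pfc = _ar1(rng, (max(r, 1), T), cfg.ar_coef)[:r] if r > 0 else np.zeros((0, T))

    L_sh_ca1 = _row_normalized_loadings(rng, cfg.n_ca1, k, cfg.shared_strength)
    L_sh_pfc = _row_normalized_loadings(rng, cfg.n_pfc, k, cfg.shared_strength)
    if r > 0:
        L_pr_ca1 = _row_normalized_loadings(rng, cfg.n_ca1, r, cfg.private_strength)
        L_pr_pfc = _row_normalized_loadings(rng, cfg.n_pfc, r, cfg.private_strength)
    else:
        L_pr_ca1 = np.zeros((cfg.n_ca1, 0))
        L_pr_pfc = np.zeros((cfg.n_pfc, 0))

    gain = np.where(gate, cfg.comm_gain_high, cfg.comm_gain_low)

    # behavior couplings through the shared-latent loading vectors
    coupling = cfg.behavior_coupling
    if coupling is None:
        coupling = default_behavior_coupling(k)
    beh_t = behavior["time"].to_numpy()
    bin_starts = np.arange(T) * cfg.bin_s
    idx = np.clip(np.searchsorted(beh_t, bin_starts + cfg.bin_s / 2) - 1, 0, len(beh_t) - 1)
    b_latent = np.zeros((k, T))
    behavior_loadings: dict[str, np.ndarray] = {}
    for var, vec in coupling.items():
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (k,):
            raise ValueError(f"coupling for {var!r} must have length comm_rank={k}")
        series = behavior[var].to_numpy().astype(float)[idx]
        sd = series.std()
        series = (series - series.mean()) / (sd if sd > 0 else 1.0)
        b_latent += cfg.behavior_strength * vec[:, None] * series[None, :]
        behavior_loadings[var] = vec.copy()

    sign_pfc = 1.0 if cfg.behavior_target == "shared" else -1.0

    # intrinsic-latent amplitude per channel: behavior-coupled channels are
    # attenuated in shared mode; the local control keeps the full anchor
    coupled = np.zeros(k, dtype=bool)
    for vec in behavior_loadings.values():
        coupled |= np.abs(vec) > 0
    alpha = np.ones(k)
    if cfg.behavior_target == "shared":
        alpha[coupled] = cfg.coupled_latent_z_scale
    shared_drive = gain[None, :] * (alpha[:, None] * z_shared)  # k × T

    base = np.exp(
        rng.uniform(np.log(cfg.base_rate_hz[0]), np.log(cfg.base_rate_hz[1]), cfg.n_ca1 + cfg.n_pfc)
    )
    mean_gain2 = float(np.mean(gain**2))
    # per-channel latent power: gated intrinsic part + ungated behavior part
    chan_var = mean_gain2 * alpha**2 + np.mean(b_latent**2, axis=1)

    def _lograte(L_sh, L_pr, z_pr, base_r, sign):
        drive = L_sh @ (shared_drive + sign * b_latent)
        if z_pr.shape[0]:
            drive = drive + L_pr @ z_pr
        # per-unit variance correction so E[rate] ≈ base
        var = (L_sh**2) @ chan_var + np.sum(L_pr**2, axis=1)
        lograte = np.log(base_r * cfg.bin_s)[:, None] + drive - 0.5 * var[:, None]
        return np.clip(lograte, -30.0, np.log(50.0))

    lr_ca1 = _lograte(L_sh_ca1, L_pr_ca1, z_ca1, base[: cfg.n_ca1], 1.0)
    lr_pfc = _lograte(L_sh_pfc, L_pr_pfc, z_pfc, base[cfg.n_ca1 :], sign_pfc)

    counts = rng.poisson(np.exp(np.vstack([lr_ca1, lr_pfc])))  # units × T

    # spike times: counts spread uniformly within their bin
    spike_times: list[np.ndarray] = []
    unit_ids: list[str] = []
    regions: list[str] = []
    for i in range(cfg.n_ca1 + cfg.n_pfc):
        c = counts[i]
        nz = np.nonzero(c)[0]
        reps = np.repeat(nz, c[nz])
        times = (reps + rng.random(reps.size)) * cfg.bin_s
        spike_times.append(np.sort(times))
        region = "CA1" if i < cfg.n_ca1 else "PFC"
        unit_ids.append(f"{region.lower()}_{i if i < cfg.n_ca1 else i - cfg.n_ca1:03d}")
        regions.append(region)

    spikes = SpikeSet(spike_times=spike_times, unit_ids=unit_ids, regions=regions)
    truth = GroundTruth(
        shared_latents=z_shared,
        gate=gate,
        loadings_ca1=L_sh_ca1,
        loadings_pfc=L_sh_pfc,
        private_latents_ca1=z_ca1,
        private_latents_pfc=z_pfc,
        private_loadings_ca1=L_pr_ca1,
        private_loadings_pfc=L_pr_pfc,
        behavior_loadings=behavior_loadings,
        behavior_target=cfg.behavior_target,
    )
    return spikes, truth


def generate_session(cfg: SynthConfig, seed: int | None = None) -> SyntheticSession:
    """Compose behavior, LFP and spiking into one deterministic session."""
    seed = cfg.seed if seed is None else seed
    behavior = generate_behavior(cfg, seed)
    lfp, gate = generate_lfp(cfg, behavior, seed)
    spikes, truth = generate_ensembles(cfg, behavior, gate, seed)
    return SyntheticSession(spikes=spikes, lfp=lfp, behavior=behavior, truth=truth, config=cfg)
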