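"""One-command analysis pipeline: session in → stage outputs + summary out.

Stages run in dependency order (preprocess → windows → partition → RRR;
preprocess → CCA → decode/manifold; LFP → coherence), each writing a tidy
CSV under the output directory.  Stage outputs are cached on disk keyed by
a hash of the relevant configuration subset, so partial reruns reuse
upstream results.  A stage failure is recorded in the bundle without
aborting the remaining independent stages.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cca as cca_mod
from . import coherence as coh_mod
from . import decode as dec_mod
from . import io as io_mod
from . import manifold as man_mod
from . import rrr as rrr_mod
from .partition import generate_partitions
from .preprocess import bin_spikes, filter_low_rate_units, lfp_band_envelope, zscore_counts
from .windows import balance_windows, gather_samples, prune_overlaps, threshold_windows


@dataclass
class AnalysisConfig:
    """All pipeline parameters; every random stage gets an explicit seed."""

    session_dir: str = ""
    out_dir: str = "neurocomm_out"
    bin_s: float = 0.05
    window_s: float = 0.3
    high_q: float = 0.85
    low_q: float = 0.15
    bands: tuple[str, ...] = ("theta", "ripple")
    n_partitions: int = 10
    rrr_folds: int = 5
    rrr_m_max: int = 12
    cca_k: int = 10
    cca_folds: int = 5
    decode_train_bins: int = 50_000
    manifold_distance_bins: int = 25
    seed: int = 0
    run_rrr: bool = True
    run_cca: bool = True
    run_decode: bool = True
    run_coherence: bool = True
    run_manifold: bool = True

    def config_hash(self, keys: tuple[str, ...]) -> str:
        payload = {k: getattr(self, k) for k in sorted(keys)}
        return hashlib.sha1(json.dumps(payload, default=str).encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """Stage outputs, errors and the configuration echo."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    config: AnalysisConfig | None = None
    log: list[str] = field(default_factory=list)

    def ok(self, stage: str) -> bool:
        return stage in self.tables and stage not in self.errors


def _cached(out: Path, name: str, chash: str, compute) -> pd.DataFrame:
    """Load a cached stage table when its config hash matches, else compute."""
    csv = out / f"{name}.csv"
    meta = out / f"{name}.hash"
    if csv.exists() and meta.exists() and meta.read_text() == chash:
        return pd.read_csv(csv)
    table = compute()
    table.to_csv(csv, index=False)
    meta.write_text(chash)
    return table


def run_pipeline(cfg: AnalysisConfig) -> ReportBundle:
    bundle = ReportBundle(config=cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = bundle.log.append

    # ---- preprocess -------------------------------------------------------
    spikes = io_mod.load_spikes(cfg.session_dir)
    lfp = io_mod.load_lfp(cfg.session_dir)
    behavior = io_mod.load_behavior(cfg.session_dir)
    span = (0.0, float(behavior["time"].iloc[-1]))
    counts_raw = filter_low_rate_units(bin_spikes(spikes, cfg.bin_s, span))
    counts = zscore_counts(counts_raw)
    log(f"preprocess: {counts.n_units} units, {counts.n_bins} bins")

    # state series on the bin grid
    def _bin_series(samples: np.ndarray, fs: float) -> np.ndarray:
        per = int(round(fs * cfg.bin_s))
        n = min(counts.n_bins, samples.size // per)
        return samples[: n * per].reshape(n, per).mean(axis=1)

    envelopes = {}
    for band in cfg.bands:
        env = lfp_band_envelope(lfp["CA1"], band)
        envelopes[band] = _bin_series(env.envelope, lfp["CA1"].fs_hz)

    speed = None
    if "velocity" in behavior.columns:
        idx = np.clip(
            np.searchsorted(behavior["time"].to_numpy(), counts.bin_starts + cfg.bin_s / 2) - 1,
            0,
            len(behavior) - 1,
        )
        speed = behavior["velocity"].to_numpy()[idx]

    # ---- windows + partitions + RRR --------------------------------------
    state_sets = {}
    if cfg.run_rrr:
        try:
            all_sets = []
            labels = []
            for band, series in envelopes.items():
                nb = series.size
                hi, lo = threshold_windows(
                    series, counts.bin_starts[:nb], cfg.high_q, cfg.low_q, cfg.window_s, band
                )
                all_sets += [hi, lo]
                labels += [(band, "high"), (band, "low")]
            pruned = prune_overlaps(all_sets)
            balanced = balance_windows(pruned, seed=cfg.seed)
            state_sets = {lab: ws for lab, ws in zip(labels, balanced)}
            partitions = generate_partitions(counts_raw, cfg.n_partitions, seed=cfg.seed)
            t_w = int(round(cfg.window_s / cfg.bin_s))
            chash = cfg.config_hash(
                ("bin_s", "window_s", "high_q", "low_q", "bands", "n_partitions",
                 "rrr_folds", "rrr_m_max", "seed", "session_dir")
            )

            def _rrr_table() -> pd.DataFrame:
                rows = []
                for (band, level), ws in state_sets.items():
                    M = gather_samples(counts, ws)
                    if M.shape[0] < cfg.rrr_folds * t_w:
                        continue
                    for part in partitions:
                        X = M[:, part.source]
                        Y = M[:, part.target]
                        curves = rrr_mod.cv_rank_curve(
                            X, Y, t_w=t_w, folds=cfg.rrr_folds,
                            m_max=cfg.rrr_m_max, seed=cfg.seed,
                        )
                        m_hat = rrr_mod.optimal_rank(curves)
                        rows.append(
                            {
                                "partition": part.index,
                                "state": band,
                                "level": level,
                                "target": part.target_region,
                                "m_hat": m_hat,
                                "r2": curves.mean(0)[m_hat - 1],
                                "r2_full": curves.mean(0)[-1],
                            }
                        )
                return pd.DataFrame(rows)

            table = _cached(out, "rrr", chash, _rrr_table)
            bundle.tables["rrr"] = table
            if not table.empty:
                bundle.tables["rrr_contrast"] = rrr_mod.state_contrast(table)
                bundle.tables["rrr_contrast"].to_csv(out / "rrr_contrast.csv", index=False)
        except Exception:
            bundle.errors["rrr"] = traceback.format_exc()

    # ---- CCA --------------------------------------------------------------
    sl = None
    if cfg.run_cca or cfg.run_decode or cfg.run_manifold:
        try:
            X = counts.counts[:, [i for i, r in enumerate(counts.regions) if r == "CA1"]]
            Y = counts.counts[:, [i for i, r in enumerate(counts.regions) if r == "PFC"]]
            k = min(cfg.cca_k, X.shape[1], Y.shape[1])
            fit = cca_mod.fit_cca(X, Y, k=k, folds=cfg.cca_folds, seed=cfg.seed)
            vs = cca_mod.project_variates(fit, X, Y, times=counts.bin_starts)
            sl = cca_mod.aligned_orthogonal(vs)
            table = pd.DataFrame(
                {
                    "component": np.arange(1, k + 1),
                    "rho_train": fit.rho_train,
                    "rho_heldout": fit.rho_heldout,
                }
            )
            table.to_csv(out / "cca.csv", index=False)
            bundle.tables["cca"] = table
            variates = pd.DataFrame(
                np.hstack([vs.times[:, None], vs.u, vs.v, sl.aligned, sl.local]),
                columns=["time"]
                + [f"U_{i+1}" for i in range(k)]
                + [f"V_{i+1}" for i in range(k)]
                + [f"aligned_{i+1}" for i in range(k)]
                + [f"local_{i+1}" for i in range(k)],
            )
            variates.to_csv(out / "variates.csv", index=False)
        except Exception:
            bundle.errors["cca"] = traceback.format_exc()

    # ---- decoding ---------------------------------------------------------
    if cfg.run_decode and sl is not None:
        try:
            feats = dec_mod.build_features(sl, k=min(10, sl.k))
            table = dec_mod.evaluate_decoding(
                feats, behavior, train_bins=cfg.decode_train_bins, seed=cfg.seed
            )
            table.to_csv(out / "decode.csv", index=False)
            bundle.tables["decode"] = table
        except Exception:
            bundle.errors["decode"] = traceback.format_exc()

    # ---- coherence --------------------------------------------------------
    if cfg.run_coherence:
        try:
            coh = coh_mod.multitaper_coherence(lfp["CA1"], lfp["PFC"], fmax=50.0)
            theta_coh = coh.band_mean((6.0, 12.0))
            idx = np.clip(
                np.searchsorted(behavior["time"].to_numpy(), coh.times) - 1,
                0,
                len(behavior) - 1,
            )
            tidy = pd.DataFrame(
                {
                    "animal": "synthetic",
                    "epoch": behavior["epoch"].to_numpy()[idx],
                    "time": coh.times,
                    "value": theta_coh,
                }
            )
            trend = coh_mod.epoch_trend(tidy, n_boot=200, seed=cfg.seed)
            table = pd.DataFrame(
                {
                    "epoch": trend["epochs"],
                    "mean": trend["means"],
                    "ci_lo": trend["cis"][:, 0],
                    "ci_hi": trend["cis"][:, 1],
                }
            )
            table.to_csv(out / "coherence_trend.csv", index=False)
            bundle.tables["coherence"] = table
        except Exception:
            bundle.errors["coherence"] = traceback.format_exc()

    # ---- manifold ---------------------------------------------------------
    if cfg.run_manifold:
        try:
            pp = man_mod.build_pseudopopulation(
                [(counts_raw, behavior)], n_distance_bins=cfg.manifold_distance_bins
            )
            emb = man_mod.embed_cca(pp)
            contrast = man_mod.ring_distance_contrast(emb)
            table = pd.DataFrame(
                [
                    {
                        "mean_within": contrast["mean_within"],
                        "mean_between": contrast["mean_between"],
                        "mean_diff": contrast.get("mean_diff", np.nan),
                        "p_rank_sum": (
                            contrast["rank_sum"].p_value
                            if contrast.get("rank_sum") is not None
                            else np.nan
                        ),
                    }
                ]
            )
            table.to_csv(out / "manifold.csv", index=False)
            bundle.tables["manifold"] = table
        except Exception:
            bundle.errors["manifold"] = traceback.format_exc()

    (out / "log.txt").write_text("\n".join(bundle.log))
    (out / "config_echo.json").write_text(json.dumps(asdict(cfg), default=str, indent=1))
    if bundle.errors:
        (out / "errors.txt").write_text("\n\n".join(f"[{k}]\n{v}" for k, v in bundle.errors.items()))
    return bundle
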