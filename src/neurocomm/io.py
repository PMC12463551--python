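"""Session directory serialization.

A session directory holds: ``spikes/<unit_id>.txt`` (one spike time per
line, seconds), ``lfp_<REGION>.f32`` (raw little-endian float32 samples)
with a ``lfp_<REGION>.json`` sidecar carrying the sample rate, a
``behavior.csv`` table, and ``config.json`` echoing the generator or
recording configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import LfpTrace, SpikeSet
from .synthgen import SynthConfig, SyntheticSession


def save_session(session: SyntheticSession, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "spikes").mkdir(parents=True, exist_ok=True)
    for times, uid, region in zip(
        session.spikes.spike_times, session.spikes.unit_ids, session.spikes.regions
    ):
        np.savetxt(out / "spikes" / f"{region}__{uid}.txt", times, fmt="%.6f")
    for region, trace in session.lfp.items():
        trace.samples.astype(np.float32).tofile(out / f"lfp_{region}.f32")
        (out / f"lfp_{region}.json").write_text(
            json.dumps({"fs_hz": trace.fs_hz, "region": region, "t0": trace.t0})
        )
    session.behavior.to_csv(out / "behavior.csv", index=False)
    (out / "config.json").write_text(json.dumps(session.config.echo(), indent=1))
    return out


def load_spikes(session_dir: str | Path) -> SpikeSet:
    d = Path(session_dir) / "spikes"
    times, uids, regions = [], [], []
    for f in sorted(d.glob("*.txt")):
        region, uid = f.stem.split("__", 1)
        arr = np.atleast_1d(np.loadtxt(f, dtype=float))
        times.append(np.sort(arr))
        uids.append(uid)
        regions.append(region)
    return SpikeSet(spike_times=times, unit_ids=uids, regions=regions)


def load_lfp(session_dir: str | Path) -> dict[str, LfpTrace]:
    d = Path(session_dir)
    out = {}
    for sidecar in sorted(d.glob("lfp_*.json")):
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(sidecar.with_suffix(".f32"), dtype=np.float32).astype(float)
        out[meta["region"]] = LfpTrace(
            samples=samples, fs_hz=meta["fs_hz"], region=meta["region"], t0=meta.get("t0", 0.0)
        )
    return out


def load_behavior(session_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(session_dir) / "behavior.csv")


def load_config(session_dir: str | Path) -> SynthConfig:
    raw = json.loads((Path(session_dir) / "config.json").read_text())
    if raw.get("behavior_coupling") is not None:
        raw["behavior_coupling"] = {
            k: np.asarray(v) for k, v in raw["behavior_coupling"].items()
        }
    if raw.get("base_rate_hz") is not None:
        raw["base_rate_hz"] = tuple(raw["base_rate_hz"])
    return SynthConfig(**raw)
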