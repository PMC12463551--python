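"""Theta coherence between CA1 and PFC and its trend over epochs.

Multitaper coherence (1 s windows, 5 DPSS tapers) and the weighted phase
lag index are computed between the two simulated LFPs; theta-band
coherence is then averaged per behavioral epoch with balanced-bootstrap
confidence intervals and a Mann–Kendall trend test.
"""

import numpy as np
import pandas as pd

from neurocomm.coherence import epoch_trend, multitaper_coherence, wpli
from neurocomm.synthgen import SynthConfig, generate_behavior, generate_lfp

cfg = SynthConfig(n_epochs=4, epoch_duration_s=150.0, seed=2, phase_lag_rad=np.pi / 4)
behavior = generate_behavior(cfg)
lfp, _ = generate_lfp(cfg, behavior)

coh = multitaper_coherence(lfp["CA1"], lfp["PFC"], fmax=50.0)
theta = coh.band_mean((6.0, 12.0))
beta = coh.band_mean((20.0, 30.0))
print(f"mean theta-band coherence: {np.nanmean(theta):.3f}")
print(f"mean 20-30 Hz coherence:   {np.nanmean(beta):.3f}")

w = wpli(lfp["CA1"], lfp["PFC"], band=(6.0, 12.0))
at8 = w.values[np.argmin(np.abs(w.frequencies - 8.0))]
print(f"WPLI at 8 Hz (planted 45-degree lag): {at8:.3f}")

idx = np.clip(
    np.searchsorted(behavior["time"].to_numpy(), coh.times, side="right") - 1,
    0, len(behavior) - 1,
)
tidy = pd.DataFrame(
    {"animal": "synthetic", "epoch": behavior["epoch"].to_numpy()[idx], "value": theta}
)
trend = epoch_trend(tidy, n_boot=300, seed=0)
print("\ntheta coherence by epoch (mean [95% CI]):")
for ep, m, (lo, hi) in zip(trend["epochs"], trend["means"], trend["cis"]):
    print(f"  epoch {ep}: {m:.3f} [{lo:.3f}, {hi:.3f}]")
mk = trend["mann_kendall"]
print(f"Mann–Kendall trend: tau = {mk.statistic:.2f}, p = {mk.p_value:.2f}")
# The simulated carrier has a fixed inter-region lag, so theta coherence
# is high and flat across epochs; the 20-30 Hz band is the noise floor.
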