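import numpy as np
import pytest

from neurocomm.preprocess import bin_spikes, filter_low_rate_units, zscore_counts
from neurocomm.synthgen import (
    SynthConfig,
    generate_behavior,
    generate_ensembles,
    generate_lfp,
    generate_session,
)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A short two-epoch session with the default (shared) behavior coupling."""
    return SynthConfig(n_epochs=2, epoch_duration_s=450.0, seed=11)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg)


@pytest.fixture(scope="session")
def small_counts(small_session):
    cfg = small_session.config
    raw = filter_low_rate_units(
        bin_spikes(small_session.spikes, cfg.bin_s, small_session.span)
    )
    return zscore_counts(raw)


@pytest.fixture(scope="session")
def small_counts_raw(small_session):
    cfg = small_session.config
    return filter_low_rate_units(
        bin_spikes(small_session.spikes, cfg.bin_s, small_session.span)
    )


def region_split(counts):
    x_cols = [i for i, r in enumerate(counts.regions) if r == "CA1"]
    y_cols = [i for i, r in enumerate(counts.regions) if r == "PFC"]
    return counts.counts[:, x_cols], counts.counts[:, y_cols]
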