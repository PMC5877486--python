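"""Shared fixtures: small synthetic epochs and fast parameter sets."""

import numpy as np
import pytest

import somnograph as sg


@pytest.fixture(scope="session")
def fast_sl_params() -> sg.SLParams:
    """Light SL parameters for desk-scale tests (short windows, big stride)."""
    return sg.SLParams(l=1, m=3, w1=4, w2=204, p_ref=0.05, stride=8)


@pytest.fixture(scope="session")
def small_cfg() -> sg.SimConfig:
    return sg.SimConfig(
        n_channels=4, fs=128.0, epoch_len=10.0,
        epochs_per_stage={s: 1 for s in sg.STAGES}, seed=0,
    )


@pytest.fixture(scope="session")
def n3_epoch(small_cfg) -> sg.Epoch:
    """One delta-dominant (N3) epoch, 4 channels x 10 s at 128 Hz."""
    return sg.generate_stage_epoch(sg.default_profiles()["N3"], small_cfg, 42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
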