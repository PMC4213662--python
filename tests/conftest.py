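"""Shared simulated datasets (session-scoped; everything is generated)."""

import numpy as np
import pytest

import srptrace as st
from srptrace.pipeline import headline_statistics


@pytest.fixture(scope="session")
def run750():
    """500 cWT traces at the 750 nM EF-G defaults, simulated + analyzed."""
    cfg = st.FullConfig(kinetics=st.default_kinetics(750))
    ds, gt = st.simulate_dataset(cfg, 500, seed=1)
    res = st.analyze_dataset(ds)
    return dict(cfg=cfg, ds=ds, gt=gt, res=res, stats=headline_statistics(res))


@pytest.fixture(scope="session")
def run250():
    """500 cWT traces at the 250 nM EF-G defaults."""
    cfg = st.FullConfig(kinetics=st.default_kinetics(250))
    ds, gt = st.simulate_dataset(cfg, 500, seed=2)
    res = st.analyze_dataset(ds)
    return dict(cfg=cfg, ds=ds, gt=gt, res=res, stats=headline_statistics(res))


@pytest.fixture(scope="session")
def run_cmt():
    """300 traces of the signal-sequence mutant (cMT) at 750 nM defaults."""
    cfg = st.FullConfig(construct=st.default_construct("cMT"))
    ds, gt = st.simulate_dataset(cfg, 300, seed=5)
    res = st.analyze_dataset(ds)
    return dict(cfg=cfg, ds=ds, gt=gt, res=res)


@pytest.fixture(scope="session")
def run_zero_noise():
    """200 noise-free cWT renders for the detection oracle."""
    cfg = st.FullConfig(optics=st.OpticsConfig(noise_sd=0.0))
    ds, gt = st.simulate_dataset(cfg, 200, seed=7)
    res = st.analyze_dataset(ds)
    return dict(cfg=cfg, ds=ds, gt=gt, res=res)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
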