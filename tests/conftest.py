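import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import locowave as lw

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")

#: Seed for every session-scoped simulation in the suite.
SUITE_SEED = 1


@pytest.fixture(scope="session")
def params():
    return lw.WaveletParams()


@pytest.fixture(scope="session")
def fixture_cfgs():
    return lw.fixture_configs(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def fixture_results(fixture_cfgs):
    """Full-pipeline analysis of every simulated fixture (computed once)."""
    return {name: lw.analyze_episode(lw.simulate(cfg))
            for name, cfg in fixture_cfgs.items()}


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory):
    """The canonical fixture suite written to disk once per session."""
    outdir = tmp_path_factory.mktemp("fixture_suite")
    lw.make_fixture_suite(outdir, seed=SUITE_SEED)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_spectrum(coeffs, freqs=None, times=None, ready=True):
    """CrossSpectrum from a plain complex matrix, optionally analysis-ready
    (normalized + masked + phase-filtered flags set)."""
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=complex))
    if freqs is None:
        freqs = np.arange(1.0, coeffs.shape[0] + 1)
    if times is None:
        times = np.arange(coeffs.shape[1], dtype=float)
    kw = {}
    if ready:
        kw = dict(normalized=True, sig_mask=coeffs != 0, phase_filtered=True)
    return lw.CrossSpectrum(coeffs=coeffs, freqs=np.asarray(freqs, float),
                            times=np.asarray(times, float), **kw)


def voices_off(f, f0, voices=12):
    """Distance between two frequencies in voices (log2 steps)."""
    return np.abs(np.log2(np.asarray(f, float) / f0)) * voices
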