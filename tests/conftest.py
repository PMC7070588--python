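import numpy as np
import pytest

from nodulescan import GatedEcho, RunConfig, builtin_scenario, run_pipeline


def make_echo(samples, sampling_rate=1.0):
    """GatedEcho wrapper around a raw array, for index-formula tests."""
    samples = np.asarray(samples, dtype=float)
    return GatedEcho(samples=samples, start=0, stop=samples.size,
                     peak_time=0.0, sampling_rate=sampling_rate)


@pytest.fixture(scope="session")
def agar_phantom():
    return builtin_scenario("agar_fig5")


@pytest.fixture(scope="session")
def agar_result():
    """Full pipeline on the four-sphere agar scenario, seed 0 (shared)."""
    return run_pipeline(RunConfig(phantom="agar_fig5", seed=0))
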