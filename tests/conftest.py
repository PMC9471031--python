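import numpy as np
import pytest
from hypothesis import settings

import ventmux as vm

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def full_chain(wave: vm.FlowWaveform, cfg: vm.ProcessingConfig | None = None):
    """Noise floor -> median smooth -> breaths, with the standard constants."""
    cfg = cfg or vm.ProcessingConfig()
    return vm.analyze_waveform(wave, cfg)


def match_truth(breaths, truth):
    """Pair each detected breath with the nearest ground-truth onset."""
    onsets = truth["onset_s"].to_numpy()
    pairs = []
    for b in breaths:
        i = int(np.argmin(np.abs(onsets - b.onset)))
        pairs.append((b, truth.iloc[i]))
    return pairs


@pytest.fixture(scope="session")
def vc_config():
    """Volume-control split-circuit run mirroring the in vivo protocol:
    20 breaths at 12/min, 1200 mL total per breath, 2 kHz sampling,
    0.02 L/s transducer noise."""
    return vm.CircuitConfig(
        settings=vm.VentilatorSettings(mode="volume_control"),
        duration=100.0,
        noise_sd=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def vc_waves(vc_config):
    return vm.simulate(vc_config)


@pytest.fixture(scope="session")
def pc_config():
    """Pressure-control bench-style run, valve fully open."""
    return vm.CircuitConfig(duration=30.0, noise_sd=0.02, seed=11)


@pytest.fixture(scope="session")
def pc_waves(pc_config):
    return vm.simulate(pc_config)


@pytest.fixture()
def ramp_wave():
    fs = 200.0
    t = np.arange(400) / fs
    return vm.FlowWaveform(time=t, flow=0.5 * t, sample_rate=fs, patient_id="ramp")
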