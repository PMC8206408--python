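import numpy as np
import pytest

from lgnenc import preprocess as pp
from lgnenc import simulate as sim
from lgnenc import stimulus as st


@pytest.fixture(scope="session")
def small_checkerboard():
    """(2,4) grid, 8 balanced patterns, 12 passes: 48 s recording."""
    return st.make_checkerboard(
        grid=(2, 4), n_patterns=8, pixels_per_pattern=2, trials=12, seed=1
    )


@pytest.fixture(scope="session")
def small_population():
    return [
        sim.NeuronSpec(rf_center=(i % 2, i % 4), polarity="ON" if i % 2 else "OFF",
                       kernel="transient" if i < 3 else "sustained", snr=1.0, baseline=3)
        for i in range(5)
    ]


@pytest.fixture(scope="session")
def small_recording(small_checkerboard, small_population):
    spikes = sim.simulate_population(small_checkerboard, small_population, seed=3)
    return spikes, pp.bin_rates(spikes, 50)


@pytest.fixture(scope="session")
def single_pixel_recording():
    """Single-pixel stimulation driving four known phenotypes."""
    stim = st.make_single_pixel(trials_per_pixel=20)
    specs = [
        sim.NeuronSpec(rf_center=(2, 3), polarity="ON", kernel="transient",
                       snr=1.0, onset_gain=200, offset_gain=40, baseline=2),
        sim.NeuronSpec(rf_center=(1, 5), polarity="OFF", kernel="transient",
                       snr=1.0, onset_gain=200, offset_gain=40, baseline=2),
        sim.NeuronSpec(rf_center=(2, 3), polarity="ON", kernel="sustained",
                       snr=1.0, onset_gain=100, offset_gain=40, baseline=2),
        sim.NeuronSpec(rf_center=(3, 1), polarity="OFF", kernel="sustained",
                       snr=1.0, onset_gain=100, offset_gain=40, baseline=2),
    ]
    spikes = sim.simulate_population(stim, specs, seed=2)
    return stim, specs, spikes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
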