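import numpy as np
import pytest

from intradental.synthgen import (SynthMovieSpec, generate_movie,
                                  make_electrical_train)


@pytest.fixture(scope="session")
def blob_scene():
    """Static synthetic scene (no motion, no noise) for registration tests."""
    spec = SynthMovieSpec(n_frames=2, n_cells=10, responder_fraction=0.0,
                          motion_model="none", noise_sd=0.0, seed=11)
    movie, truth = generate_movie(spec, make_electrical_train(
        n_rounds=1, pulses_per_round=1, start_s=0.2))
    return movie.frames[0]


@pytest.fixture(scope="session")
def default_stim():
    # 0.625 Hz = exactly 8 frames between pulses at 5 Hz, so the sampled
    # transient peak equals the generative amplitude at every pulse
    return make_electrical_train(n_rounds=3, pulses_per_round=3,
                                 rate_hz=0.625, start_s=8.0)


@pytest.fixture(scope="session")
def quiet_movie(default_stim):
    """Motion-free movie with responders, mild noise and neuropil."""
    spec = SynthMovieSpec(n_frames=200, n_cells=16, responder_fraction=0.5,
                          transient_amplitude=20.0, neuropil_amplitude=10.0,
                          motion_model="none", noise_sd=1.0, seed=7)
    return generate_movie(spec, default_stim)


def pytest_configure(config):
    np.seterr(all="ignore")
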