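import numpy as np
import pytest

import wristgait as wg


@pytest.fixture(scope="session")
def six_class_bank():
    return wg.default_style_bank(6)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial 6-class segment set (4 subjects x 20 s)."""
    cfg = wg.SimConfig(
        styles=wg.default_style_bank(6), n_subjects=4, duration_s=20.0, seed=11
    )
    return wg.build_segment_set(wg.simulate_dataset(cfg), T=100)


@pytest.fixture()
def clean_style():
    """Deterministic single-harmonic style: no noise, no jitter."""
    return wg.GaitStyleParams(
        class_id=0,
        name="clean",
        fundamental_hz=1.0,
        amplitude=np.array([1.0, 0, 0, 0, 0, 0]),
        harmonic_weights=(1.0,),
        phase_offsets=np.zeros(6),
        baseline_offset=np.array([0.0, 2.0, -1.0, 0.5, 0.0, 3.0]),
        noise_sd=0.0,
        freq_jitter_sd=0.0,
        amp_jitter_sd=0.0,
    )
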