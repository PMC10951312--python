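"""Shared phantom fixtures.

Session-scoped because the realistic phantom + full pipeline run are the
expensive objects many tests share; everything is seeded so the suite is
deterministic.
"""

import numpy as np
import pytest

from octcycle import DenoiseParams, PhantomConfig, denoise, make_clean_frame, make_phantom


@pytest.fixture(scope="session")
def bench_config() -> PhantomConfig:
    """Realistic desk-scale acquisition: speckle, pulsation, jitter and tilt on."""
    return PhantomConfig.desk(
        rng_seed=7,
        frame_height=192,
        frame_width=128,
        duration_s=10.0,
        n_interfaces=6,
        layer_thickness_um=60.0,
    )


@pytest.fixture(scope="session")
def bench_phantom(bench_config):
    return make_phantom(bench_config)


@pytest.fixture(scope="session")
def bench_onecycle(bench_phantom):
    return denoise(bench_phantom.video, bench_phantom.pulse, DenoiseParams(n_bins=100))


@pytest.fixture(scope="session")
def fine_phantom():
    """Small phantom sampled at the instrument's 1.95 um axial pitch.

    Keeps the resolution-ellipse cut-offs below Nyquist so the FFT noise
    metric is well defined.
    """
    cfg = PhantomConfig(
        rng_seed=41,
        frame_height=224,
        frame_width=128,
        duration_s=6.0,
        bscan_rate_hz=50.0,
        n_interfaces=4,
        layer_thickness_um=50.0,
    )
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def fine_onecycle(fine_phantom):
    return denoise(fine_phantom.video, fine_phantom.pulse, DenoiseParams(n_bins=50))


@pytest.fixture(scope="session")
def clean_frame_full():
    """Noise-free default-geometry frame (1536x1024, 1.95 um/px) + masks."""
    cfg = PhantomConfig(rng_seed=1)
    frame, masks = make_clean_frame(cfg)
    return cfg, frame, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
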