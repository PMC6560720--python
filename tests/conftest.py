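import numpy as np
import pytest

from swayrisk import synthetic

# quarter-resolution camera for fast test renders
SMALL_SHAPE = (212, 256)
SMALL_INTRINSICS = (182.728, 182.728, 128.0, 106.0)


def fast_render(trace, **kwargs):
    kwargs.setdefault("image_shape", SMALL_SHAPE)
    kwargs.setdefault("intrinsics", SMALL_INTRINSICS)
    kwargs.setdefault("background_frames", 10)
    return synthetic.render_depth_sequence(trace, **kwargs)


@pytest.fixture(scope="session")
def sinusoid_render():
    """Noiseless lateral sinusoid (A=0.02 m, f=0.5 Hz, 30 Hz, 10 s)."""
    profile = synthetic.SwayProfile(
        lateral_amplitude=0.02, ap_amplitude=0.0, sway_frequency=0.5, seed=5
    )
    trace = synthetic.simulate_sway_trace(profile, duration_s=10.0, rate_hz=30.0)
    return fast_render(trace)


@pytest.fixture(scope="session")
def default_cohort():
    return synthetic.generate_feature_cohort(synthetic.CohortSpec(seed=11))
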