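import numpy as np
import pytest

from embryomech import (
    HUMAN_PROTOCOL,
    CohortSpec,
    ModelKind,
    ViscoParams,
    aspiration_motion,
    cohort_to_frame,
    creep,
    render_video,
    sample_cohort,
    step_force,
)
from embryomech.synthetic import VideoScene


@pytest.fixture(scope="session")
def human_params():
    """The viable-cluster center mechanics of human zygotes."""
    return ViscoParams(k0=0.12, k1=0.30, eta1=0.59, eta0=5.0)


@pytest.fixture(scope="session")
def f0_human():
    return step_force(HUMAN_PROTOCOL)


@pytest.fixture(scope="session")
def human_cohort_df():
    return cohort_to_frame(sample_cohort(CohortSpec(seed=11)))


@pytest.fixture(scope="session")
def small_scene():
    """Compact aspiration scene for fast tracking tests."""
    return VideoScene(
        shape=(120, 260),
        wall_inner_rows=(40, 80),
        wall_thickness_px=6,
        opening_column=170,
        embryo_radius_px=45.0,
    )


@pytest.fixture(scope="session")
def creep_video(human_params, small_scene):
    """Short noiseless aspiration video of the human-center creep response."""
    motion, onset = aspiration_motion(
        human_params, HUMAN_PROTOCOL, duration_s=1.5,
        holding_depth_m=3e-6,
    )
    seq = render_video(motion, small_scene, noise_sd=0.0, seed=0)
    truth_px = (motion - motion[onset]) / small_scene.pixel_size_m
    return seq, onset, truth_px


def draw_positive_params(rng, low=10.0**-1.5, high=10.0**0.5):
    """Random positive modified-Zener parameters on a log-uniform scale
    bracketing the measured embryo range."""
    k0, k1, eta1, eta0 = np.exp(rng.uniform(np.log(low), np.log(high), 4))
    return ViscoParams(k0=k0, k1=k1, eta1=eta1, eta0=10 * eta0)
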