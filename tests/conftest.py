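import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from posturebench.cohort import (
    SEGMENTS,
    Group,
    MedState,
    Segment,
    SubjectProfile,
    simulate_session,
)
from posturebench.protocol import PerturbationSpec

LINK_GAINS = {Segment.PELVIS: 0.85, Segment.TRUNK: 0.80, Segment.HEAD: 0.90}
LINK_PHASES = {Segment.PELVIS: 8.0, Segment.TRUNK: 12.0, Segment.HEAD: 10.0}


def make_profile(subject_id="S1", group=Group.HC, state=MedState.NONE,
                 ml_amp=6.0, ap_amp=8.0, accel_noise=0.0, orient_noise=0.0,
                 **overrides) -> SubjectProfile:
    kwargs = dict(
        subject_id=subject_id, group=group, state=state,
        link_gain=dict(LINK_GAINS), link_phase_deg=dict(LINK_PHASES),
        sway_amp_ml_mm={s: ml_amp for s in SEGMENTS},
        sway_amp_ap_mm={s: ap_amp for s in SEGMENTS},
        accel_noise_ms2=accel_noise, orient_noise_deg=orient_noise,
    )
    kwargs.update(overrides)
    return SubjectProfile(**kwargs)


@pytest.fixture
def clean_profile():
    """A noise-free healthy subject with known link gains and phases."""
    return make_profile()


@pytest.fixture
def clean_session(clean_profile):
    """One noise-free medium-perturbation trial of the clean profile."""
    return simulate_session(clean_profile, PerturbationSpec.standard("MP"),
                            rng=np.random.default_rng(7))
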