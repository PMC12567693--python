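import numpy as np
import pytest

from wakebreath import synthgen

FS = synthgen.DEFAULT_FS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def severe_subject():
    spec = synthgen.CohortSpec(n_per_class={"Severe": 1}, seed=7)
    return synthgen.generate_cohort(spec)[0]


@pytest.fixture(scope="session")
def clean_recording(severe_subject):
    """One noiseless 5-cycle recording with ground-truth annotations."""
    effects = synthgen.AcousticEffectSpec(am_depth=0.0, snr_db=60.0)
    wave, anns = synthgen.synthesize_recording(
        severe_subject, effects, fs=FS, route="nose", seed=99)
    return wave, anns


@pytest.fixture(scope="session")
def noisy_recording(severe_subject):
    wave, anns = synthgen.synthesize_recording(
        severe_subject, synthgen.DEFAULT_EFFECTS["Severe"], fs=FS,
        route="mouth", seed=100)
    return wave, anns
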