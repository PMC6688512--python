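import numpy as np
import pytest
from hypothesis import settings

from gaitresp.synthetic import generate_trial
from gaitresp.types import GaitProfile

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


def make_profile(**overrides) -> GaitProfile:
    base = dict(
        step_length_a=0.40, step_length_na=0.40, cadence=100.0,
        stance_pct=63.0, double_support_pct=13.0, step_width=0.16,
        hip_rom_a=33.0, hip_rom_na=33.0, knee_rom_a=45.0, knee_rom_na=48.0,
        ankle_rom_a=24.0, ankle_rom_na=24.0, trunk_rom_sagittal=3.4,
        trunk_rom_frontal=4.0, trunk_rom_transverse=7.0,
    )
    base.update(overrides)
    return GaitProfile.with_derived_speed(**base)


def random_profile(rng: np.random.Generator) -> GaitProfile:
    return make_profile(
        step_length_a=rng.uniform(0.25, 0.55),
        step_length_na=rng.uniform(0.25, 0.55),
        cadence=rng.uniform(80.0, 125.0),
        stance_pct=rng.uniform(56.0, 70.0),
        double_support_pct=None or rng.uniform(6.0, 18.0),
        step_width=rng.uniform(0.10, 0.22),
        hip_rom_a=rng.uniform(20.0, 45.0), hip_rom_na=rng.uniform(20.0, 45.0),
        knee_rom_a=rng.uniform(35.0, 60.0), knee_rom_na=rng.uniform(35.0, 60.0),
        ankle_rom_a=rng.uniform(15.0, 30.0), ankle_rom_na=rng.uniform(15.0, 30.0),
        trunk_rom_sagittal=rng.uniform(2.0, 6.0),
        trunk_rom_frontal=rng.uniform(2.0, 6.0),
        trunk_rom_transverse=rng.uniform(4.0, 14.0),
    )


@pytest.fixture(scope="session")
def profile() -> GaitProfile:
    return make_profile()


@pytest.fixture(scope="session")
def clean_trial(profile):
    """One noise-free trial with its ground-truth events."""
    return generate_trial(profile, n_strides=8, noise_sd=0.0, seed=7,
                          trial_id="clean")


@pytest.fixture(scope="session")
def clean_trials(profile):
    """Six noise-free trials (distinct ids) for a subject-session."""
    return [generate_trial(profile, n_strides=8, noise_sd=0.0, seed=i,
                           trial_id=f"clean{i}")
            for i in range(6)]
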