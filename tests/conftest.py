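"""Shared fixtures: synthetic cohorts, reference curves, trained networks.

Everything is generated programmatically with fixed seeds; the expensive
objects (the normal training cohort and the 36 trained networks) are
session-scoped so the suite trains each network exactly once.
"""

import numpy as np
import pytest

import cyclogait as cg

TRAIN_SEED = 7
COHORT_SEED = 11


@pytest.fixture(scope="session")
def bank():
    return cg.default_templates()


@pytest.fixture(scope="session")
def profiles():
    return cg.default_profiles()


@pytest.fixture(scope="session")
def zero_noise_profile():
    return cg.CohortProfile(cohort="normal")


@pytest.fixture(scope="session")
def normal_cohort(profiles, bank):
    """5 training subjects x 10 trials of synthetic normal gait."""
    return cg.generate_cohort(profiles["normal"], bank, 5, 10, COHORT_SEED)


@pytest.fixture(scope="session")
def reference(normal_cohort):
    return cg.average_reference(normal_cohort)


@pytest.fixture(scope="session")
def networks(normal_cohort, reference):
    """All 36 disparity networks trained on the normal cohort."""
    return cg.train_all_pairs(normal_cohort, reference, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def pairs():
    return cg.enumerate_pairs()


@pytest.fixture()
def one_trial(zero_noise_profile, bank):
    return cg.generate_trial(zero_noise_profile, bank, "N01", 1, seed=0)


def planted_profile(varkey=("knee", "power"), subphase=1, scale=0.2):
    """A pathological profile with a single-variable deficit in one sub-phase."""
    scales = np.ones(7)
    scales[subphase - 1] = scale
    return cg.CohortProfile(
        cohort="transfemoral",
        amplitude_scale={varkey: scales},
        subphase_jitter_sd=1.0,
        trial_noise_sd=0.03,
        subject_offset_sd=0.03,
    )


@pytest.fixture(scope="session")
def planted_subject_factory(bank):
    def make(seed, varkey=("knee", "power"), subphase=1, scale=0.2):
        profile = planted_profile(varkey, subphase, scale)
        return cg.generate_cohort(profile, bank, 1, 10, seed, subject_prefix="PL")

    return make
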