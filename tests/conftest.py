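"""Shared fixtures: small synthetic cohorts and derived feature maps."""

import numpy as np
import pytest

from braintexture.quantize import equalize_histogram
from braintexture.synthetic import (SyntheticCohortSpec, generate_brain_volume,
                                    generate_cohort)
from braintexture.texture import texture_feature_maps


@pytest.fixture(scope="session")
def noisy_volume():
    """One mildly blurred, folded, noisy brain volume (48³)."""
    return generate_brain_volume((48, 48, 48), smoothness=1.0,
                                 folding_amplitude=2.0, noise_sd=0.05, seed=1)


@pytest.fixture(scope="session")
def quantized_volume(noisy_volume):
    return equalize_histogram(noisy_volume, 16)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Strong-contrast cohort for classifier-recovery checks:
    20+20 subjects, 48³ volumes, smoothness 0 vs 2.5, no intensity noise."""
    spec = SyntheticCohortSpec(
        n_per_class=20,
        volume_shape=(48, 48, 48),
        smoothness_by_class={"VisDys-": 0.0, "VisDys+": 2.5},
        folding_amplitude_by_class={"VisDys-": 2.0, "VisDys+": 2.0},
        noise_sd=0.0,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def recovery_maps(recovery_cohort):
    """Energy feature maps (G=16, cube 5, stride 1) of the recovery cohort."""
    maps = {}
    for sid, vol in recovery_cohort.volumes.items():
        q = equalize_histogram(vol, 16)
        maps[sid] = texture_feature_maps(q, cube_size=5, stride=1,
                                         features=("energy",))["energy"]
    labels = recovery_cohort.labels.to_dict()
    return maps, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
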