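"""Shared fixtures: one planted study reused across the suite.

Expensive artifacts (planted truth, generated groups, decoded DSMs) are
session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from crossrep import (GroupSpec, StudyDesign, generate_group_dataset,
                      make_planted_truth, neural_dsm)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def truth(design):
    return make_planted_truth(design, seed=3)


@pytest.fixture(scope="session")
def hi_snr_group(design, truth):
    """Twelve high-SNR subjects sharing the planted geometry."""
    spec = GroupSpec("HI", 12, {"VOTC": 1.0, "EVC": 0.8, "parcels": 1.0})
    return generate_group_dataset(design, truth, spec, master_seed=7)


@pytest.fixture(scope="session")
def hi_snr_dsms(hi_snr_group):
    return [neural_dsm(d, "VOTC") for d in hi_snr_group]


@pytest.fixture(scope="session")
def noise_group(design, truth):
    """Six pure-noise subjects (effect multiplier zero everywhere)."""
    spec = GroupSpec("NZ", 6, {"VOTC": 0.0, "EVC": 0.0, "parcels": 0.0})
    return generate_group_dataset(design, truth, spec, master_seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
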