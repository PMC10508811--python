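"""Shared fixtures: small ground-truth models and cohorts reused across the
suite. Everything is generated programmatically from fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

from psychstruct import synth

PAT_G3 = {
    "TD": {0: 0.8, 1: 0.8},
    "INT": {2: 0.75, 3: 0.70},
    "COMP": {4: 0.70, 5: 0.70},
}
PHI_G3 = np.array([[1.0, 0.45, 0.30], [0.45, 1.0, 0.45], [0.30, 0.45, 1.0]])
# phenotypic level: same groups, but compulsive and internalizing conditions
# are far more correlated environmentally (the decoupling under study)
PHI_E3 = np.array([[1.0, 0.45, 0.35], [0.45, 1.0, 0.89], [0.35, 0.89, 1.0]])

PREV6 = (0.20, 0.15, 0.12, 0.10, 0.15, 0.12)
H2_6 = (0.40, 0.35, 0.30, 0.30, 0.35, 0.30)


def make_model(n=20_000, m=2_000, seed=0, decoupled=True):
    cfg = synth.SimConfig(
        n_individuals=n,
        n_snps=m,
        n_conditions=6,
        prevalences=PREV6,
        h2_targets=H2_6,
        seed=seed,
    )
    phi_e = PHI_E3 if decoupled else PHI_G3
    return synth.simulate_true_model(
        cfg, PAT_G3, PAT_G3, phi_genetic=PHI_G3, phi_env=phi_e
    )


@pytest.fixture(scope="session")
def small_model():
    """6 conditions, 3 genetic factors, decoupled phenotypic level."""
    return make_model(n=8_000, m=800, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    return synth.simulate_cohort(small_model)


@pytest.fixture(scope="session")
def medium_model():
    return make_model(n=20_000, m=2_000, seed=7)


@pytest.fixture(scope="session")
def medium_cohort(medium_model):
    return synth.simulate_cohort(medium_model)
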